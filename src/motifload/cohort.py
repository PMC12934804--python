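"""Donor-level aggregation and cohort statistics.

Downstream of the per-sample enrichment pass, cohort questions are asked at
the donor level: MEML values of all samples from one donor are averaged,
donors are binned into fixed age terciles (0-33.3, 33.4-66.7, 66.8-100
years), and healthy vs diseased donors are compared with a two-sided
Wilcoxon rank-sum test within each study x tercile cell (so that diseased
tissues are only compared against healthy tissues of the same study, which
avoids cross-study batch effects and controls for age).  Clock-like
accumulation is assessed by Spearman correlation of donor-mean MEML with
donor age, and jointly with disease status by an ordinary least-squares
regression of motif MEML on age plus disease indicators.

Also here: 96-channel trinucleotide mutation profiles with cosine
similarity (QC plumbing) and the per-sample proration of single-cell MEML
counts to genome-wide estimates.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from itertools import product
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .enrichment import bh_adjust
from .genome import ReferenceGenome, canonical_substitution, extract_window
from .io import SampleCatalog

logger = logging.getLogger(__name__)

__all__ = [
    "CHANNELS_96",
    "SingleCellScaling",
    "profile_96",
    "cosine_similarity",
    "donor_aggregate",
    "spearman",
    "tercile_of",
    "compare_cohorts",
    "regress_age_disease",
    "prorate_single_cell",
]

_SUBS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_FLANKS = tuple("acgt")

#: the 96 pyrimidine-canonical trinucleotide channels, in fixed order
CHANNELS_96: Tuple[str, ...] = tuple(
    f"{f}{ref}{t}>{f}{alt}{t}"
    for (ref, alt) in (s.split(">") for s in _SUBS)
    for f in _FLANKS
    for t in _FLANKS
)


@dataclass(frozen=True)
class SingleCellScaling:
    """Sample-specific proration factor for single-cell catalogues.

    ``multiplier = estimated_snvs / identified_mutations`` converts MEML
    computed on the called subset to a genome-wide estimate.
    """

    sample_id: str
    estimated_snvs: float
    identified_mutations: float

    def __post_init__(self):
        if self.identified_mutations <= 0:
            raise ValueError("identified_mutations must be > 0")
        if not math.isfinite(self.estimated_snvs) or self.estimated_snvs < 0:
            raise ValueError("estimated_snvs must be finite and >= 0")

    @property
    def multiplier(self) -> float:
        return self.estimated_snvs / self.identified_mutations


def profile_96(
    catalogs: Sequence[SampleCatalog], genome: ReferenceGenome
) -> pd.Series:
    """Pooled 96-channel trinucleotide substitution counts.

    Substitutions are pyrimidine-canonical; records whose reference base
    disagrees with the genome, or that sit on a contig edge (no flanking
    base), are skipped and counted in the series' ``attrs['skipped']``.
    """
    counts: Dict[str, int] = dict.fromkeys(CHANNELS_96, 0)
    skipped = 0
    for cat in catalogs:
        for r in cat.records:
            if genome.base(r.contig, r.pos) != r.ref:
                skipped += 1
                continue
            if r.pos == 1 or r.pos == genome.length(r.contig):
                skipped += 1
                continue
            five = genome.base(r.contig, r.pos - 1)
            three = genome.base(r.contig, r.pos + 1)
            if "N" in (five, three):
                skipped += 1
                continue
            counts[canonical_substitution(r.ref, r.alt, five, three)] += 1
    out = pd.Series(counts, index=list(CHANNELS_96), dtype=int)
    out.attrs["skipped"] = skipped
    return out


def cosine_similarity(u, v) -> float:
    """Cosine similarity u.v / (|u||v|); in [0, 1] for nonnegative vectors.

    Raises on zero vectors (undefined similarity).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for zero vectors")
    return float(np.dot(u, v) / (nu * nv))


def donor_aggregate(
    results: pd.DataFrame, metadata: Optional[pd.DataFrame] = None
) -> pd.DataFrame:
    """Donor x motif MEML summaries from the per-sample enrichment table.

    Returns one row per donor x motif with the mean MEML over the donor's
    samples including zeros (the primary quantity used for age
    correlations) and excluding zeros (NaN when every sample is zero),
    plus the donor's metadata and sample count.  Samples without a donor id
    are reported under donor id ``"<orphan>"`` with a warning.
    """
    df = results.copy()
    if metadata is not None:
        meta = metadata.drop_duplicates("sample_id").set_index("sample_id")
        for col in ("donor_id", "tissue", "disease", "age", "study_id"):
            if col in meta.columns:
                df[col] = df["sample_id"].map(meta[col])
    if "age" not in df.columns:
        df["age"] = np.nan
    orphans = df["donor_id"].isna() | (df["donor_id"] == "")
    if orphans.any():
        logger.warning(
            "%d result rows lack a donor id; reported under '<orphan>'",
            int(orphans.sum()),
        )
        df.loc[orphans, "donor_id"] = "<orphan>"

    def _agg(group: pd.DataFrame) -> pd.Series:
        meml = group["meml"].astype(float)
        nonzero = meml[meml > 0]
        return pd.Series(
            {
                "meml_mean": meml.mean(),
                "meml_mean_nonzero": nonzero.mean() if len(nonzero) else np.nan,
                "n_samples": group["sample_id"].nunique(),
                "tissue": group["tissue"].iloc[0],
                "disease": group["disease"].iloc[0],
                "age": group["age"].iloc[0],
                "study_id": group["study_id"].iloc[0] if "study_id" in group else "",
            }
        )

    out = (
        df.groupby(["donor_id", "motif"], sort=True)
        .apply(_agg, include_groups=False)
        .reset_index()
    )
    return out


def spearman(x, y) -> Tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with two-sided p.

    Requires at least 4 pairs; a constant vector yields (NaN, NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-d arrays")
    if x.size < 4:
        raise ValueError("need at least 4 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return math.nan, math.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p = scipy.stats.spearmanr(x, y)
    return float(rho), float(p)


def tercile_of(age: float) -> str:
    """Fixed age tercile: T1 = [0, 33.3], T2 = (33.3, 66.7], T3 = (66.7, ...].

    Boundaries are the printed ones, not data-driven quantiles; ages above
    100 are assigned T3 with a warning.
    """
    if age < 0 or not math.isfinite(age):
        raise ValueError(f"invalid age {age}")
    if age > 100:
        logger.warning("age %.1f above 100; assigned to T3", age)
        return "T3"
    if age <= 33.3:
        return "T1"
    if age <= 66.7:
        return "T2"
    return "T3"


def compare_cohorts(
    summaries: pd.DataFrame,
    healthy_label: str = "healthy",
    bh_family: str = "run",
) -> pd.DataFrame:
    """Healthy vs diseased Wilcoxon rank-sum tests per study x tercile cell.

    ``summaries`` is the donor x motif table from :func:`donor_aggregate`
    (needs donor_id, motif, meml_mean, disease, age, study_id).  For every
    study x age-tercile x disease x motif combination with at least one
    healthy and one diseased donor, a two-sided rank-sum test (exact for
    small tie-free groups, else the normal approximation with tie
    correction) on donor-mean MEML is emitted; BH
    correction runs across all emitted rows (``bh_family='run'``) or within
    each motif (``'per-motif'``).
    """
    df = summaries.dropna(subset=["age"]).copy()
    df["tercile"] = df["age"].astype(float).map(tercile_of)
    rows = []
    group_cols = ["study_id", "tercile", "motif"]
    for (study, tercile, motif), cell in df.groupby(group_cols, sort=True):
        healthy = cell[cell["disease"] == healthy_label]
        for disease, diseased in cell[cell["disease"] != healthy_label].groupby(
            "disease", sort=True
        ):
            if healthy.empty or diseased.empty:
                continue
            x = healthy["meml_mean"].astype(float).to_numpy()
            y = diseased["meml_mean"].astype(float).to_numpy()
            if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
                w, p = math.nan, 1.0
            else:
                # method="auto" mirrors R's wilcox.test: exact distribution
                # for small tie-free groups, normal approximation with tie
                # correction otherwise
                res = scipy.stats.mannwhitneyu(
                    y, x, alternative="two-sided", method="auto"
                )
                w, p = float(res.statistic), float(res.pvalue)
            rows.append(
                {
                    "study_id": study,
                    "tercile": tercile,
                    "motif": motif,
                    "disease": disease,
                    "n_healthy": len(healthy),
                    "n_diseased": len(diseased),
                    "median_healthy": float(np.median(x)),
                    "median_diseased": float(np.median(y)),
                    "W": w,
                    "p": p,
                    "q": math.nan,
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "study_id", "tercile", "motif", "disease", "n_healthy", "n_diseased",
            "median_healthy", "median_diseased", "W", "p", "q",
        ],
    )
    if out.empty:
        return out
    if bh_family == "per-motif":
        for _, idx in out.groupby("motif").groups.items():
            out.loc[idx, "q"] = bh_adjust(out.loc[idx, "p"].tolist())
    else:
        out["q"] = bh_adjust(out["p"].tolist())
    return out


def regress_age_disease(
    summaries: pd.DataFrame, healthy_label: str = "healthy"
) -> pd.DataFrame:
    """OLS of donor-mean MEML on age and disease indicators, per motif.

    One indicator per disease against the healthy baseline; reports
    estimate, standard error, t and p for every predictor.  Requires at
    least three more donors than predictors per motif; rank deficiency is
    reported in the ``note`` column.
    """
    rows = []
    for motif, cell in summaries.dropna(subset=["age"]).groupby("motif", sort=True):
        diseases = sorted(d for d in cell["disease"].unique() if d != healthy_label)
        X = pd.DataFrame({"age": cell["age"].astype(float).to_numpy()})
        for d in diseases:
            X[f"disease[{d}]"] = (cell["disease"] == d).astype(float).to_numpy()
        X = sm.add_constant(X, prepend=True)
        y = cell["meml_mean"].astype(float).to_numpy()
        if len(cell) < X.shape[1] + 3:
            logger.warning("motif %s: too few donors (%d) to regress", motif, len(cell))
            continue
        fit = sm.OLS(y, X).fit()
        note = ""
        if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
            note = "rank_deficient"
        for term in X.columns:
            rows.append(
                {
                    "motif": motif,
                    "term": term,
                    "estimate": float(fit.params[term]),
                    "std_error": float(fit.bse[term]),
                    "t": float(fit.tvalues[term]),
                    "p": float(fit.pvalues[term]),
                    "n_donors": len(cell),
                    "note": note,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["motif", "term", "estimate", "std_error", "t", "p", "n_donors", "note"],
    )


def prorate_single_cell(meml: float, scaling: SingleCellScaling) -> float:
    """Genome-wide MEML estimate: called-subset MEML times the sample's
    estimated-SNVs / identified-mutations multiplier."""
    if meml < 0:
        raise ValueError("meml must be nonnegative")
    return meml * scaling.multiplier
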