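"""Per-sample motif enrichment, Fisher/BH gating and MEML — the core statistic.

For one sample and one motif (take ``aTn->aCn`` as the running example) the
pipeline counts four quantities:

* ``mut_in_motif`` — mutations matching the full motif (aTn with T->C);
* ``mut_in_class`` — mutations of the motif's substitution class (any T->C,
  reverse complements included);
* ``ctx_motif``    — occurrences of the lowercase motif pattern (``atn``)
  in the +/-20 bp windows around the sample's mutations, both strands;
* ``ctx_center``   — occurrences of the mutated base (``t``) in the same
  windows, both strands.

Enrichment is the ratio of the observed in-motif fraction to the fraction
expected from local sequence composition::

    enrichment = (mut_in_motif * ctx_center) / (mut_in_class * ctx_motif)

Overrepresentation is tested with a one-sided Fisher exact test on the 2x2
table ``[[mut_in_motif, mut_in_class - mut_in_motif], [ctx_motif,
ctx_center - ctx_motif]]`` and corrected across samples per motif with
Benjamini-Hochberg.  Samples passing the gate (enrichment > 1, q <= 0.05)
receive a Minimal Estimate of Mutation Load::

    MEML = mut_in_motif * (enrichment - 1) / enrichment

i.e. the in-motif count minus its random-mutagenesis expectation; all other
samples are recorded with MEML = 0.  'Complex' mutations (calls <= 10 bp
apart in one sample, candidate multi-base events) are excluded before any
counting.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .genome import ContextWindow, ReferenceGenome, count_pattern, extract_window
from .io import SampleCatalog
from .motifs import MotifRegistry, MutationMotif, mutation_matches, substitution_in_class

logger = logging.getLogger(__name__)

__all__ = [
    "MotifCountTable",
    "EnrichmentResult",
    "exclude_complex",
    "build_count_table",
    "enrichment",
    "fisher_one_sided",
    "bh_adjust",
    "meml",
    "run_enrichment",
    "RESULT_COLUMNS",
]

#: maximum distance (bp) defining 'complex' mutations excluded before counting
COMPLEX_MAX_GAP = 10


@dataclass(frozen=True)
class MotifCountTable:
    """The 2x2 counts behind one sample x motif enrichment."""

    mut_in_motif: int
    mut_in_class: int
    ctx_motif: int
    ctx_center: int

    def __post_init__(self):
        if not (0 <= self.mut_in_motif <= self.mut_in_class):
            raise ValueError("need 0 <= mut_in_motif <= mut_in_class")
        if not (0 <= self.ctx_motif <= self.ctx_center):
            raise ValueError("need 0 <= ctx_motif <= ctx_center")

    def as_2x2(self) -> np.ndarray:
        return np.array(
            [
                [self.mut_in_motif, self.mut_in_class - self.mut_in_motif],
                [self.ctx_motif, self.ctx_center - self.ctx_motif],
            ],
            dtype=np.int64,
        )


@dataclass(frozen=True)
class EnrichmentResult:
    """Enrichment, p, q and MEML for one sample x motif."""

    sample_id: str
    motif: str
    table: MotifCountTable
    enrichment: float  # NaN when undefined (zero denominator)
    p_value: float
    q_value: float
    meml: float
    status: str = "ok"


def exclude_complex(catalog: SampleCatalog, max_gap: int = COMPLEX_MAX_GAP) -> SampleCatalog:
    """Remove 'complex' mutations: calls <= ``max_gap`` bp from any other
    call of the same sample on the same contig.

    Chains are removed wholly (every member of a run of close calls goes).
    Returns a new catalog; the input is untouched.  The number of removed
    records is counted under ``complex_excluded``.
    """
    records = catalog.records  # already sorted by (contig, pos)
    keep = []
    n = len(records)
    for i, r in enumerate(records):
        prev_close = (
            i > 0
            and records[i - 1].contig == r.contig
            and r.pos - records[i - 1].pos <= max_gap
        )
        next_close = (
            i < n - 1
            and records[i + 1].contig == r.contig
            and records[i + 1].pos - r.pos <= max_gap
        )
        if not (prev_close or next_close):
            keep.append(r)
    out = catalog.with_records(keep)
    removed = n - len(keep)
    if removed:
        out.filter_counts["complex_excluded"] += removed
    return out


def _windows_for(
    catalog: SampleCatalog, genome: ReferenceGenome, flank: int
) -> tuple:
    """Context windows for every record whose ref base matches the genome.

    Returns (records, windows, n_mismatch); mismatching records are skipped
    and counted, mirroring a catalogue/reference build disagreement.
    """
    records, windows, mismatches = [], [], 0
    for r in catalog.records:
        w = extract_window(genome, r.contig, r.pos, flank=flank)
        if w.center_base != r.ref:
            mismatches += 1
            continue
        records.append(r)
        windows.append(w)
    if mismatches:
        logger.warning(
            "%s: %d records skipped (reference mismatch)", catalog.sample_id, mismatches
        )
    return records, windows, mismatches


def _context_sums(windows: Sequence[ContextWindow], patterns: Iterable[str]) -> Dict[str, int]:
    return {
        p: sum(count_pattern(w, p) for w in windows) for p in set(patterns)
    }


def build_count_table(
    catalog: SampleCatalog,
    motif: MutationMotif,
    genome: ReferenceGenome,
    flank: int = 20,
    class_windows: bool = False,
) -> MotifCountTable:
    """Count table for one (complex-excluded) catalogue and one motif.

    Context sums run over the windows of ALL catalogue mutations by default
    (the sequenced-territory rationale); ``class_windows=True`` restricts
    them to windows of same-substitution-class mutations for sensitivity
    analysis.
    """
    records, windows, _ = _windows_for(catalog, genome, flank)
    in_class = [
        substitution_in_class(motif, r.ref, r.alt) for r in records
    ]
    mut_in_class = int(sum(in_class))
    mut_in_motif = int(
        sum(
            mutation_matches(motif, w, r.ref, r.alt)
            for r, w, c in zip(records, windows, in_class)
            if c
        )
    )
    ctx_windows = (
        [w for w, c in zip(windows, in_class) if c] if class_windows else windows
    )
    sums = _context_sums(ctx_windows, [motif.context_pattern, motif.center_base.lower()])
    return MotifCountTable(
        mut_in_motif=mut_in_motif,
        mut_in_class=mut_in_class,
        ctx_motif=sums[motif.context_pattern],
        ctx_center=sums[motif.center_base.lower()],
    )


def enrichment(table: MotifCountTable) -> float:
    """Enrichment ratio; NaN when the denominator is zero (sparse class)."""
    denom = table.mut_in_class * table.ctx_motif
    if denom == 0:
        return math.nan
    return (table.mut_in_motif * table.ctx_center) / denom


def fisher_one_sided(table: MotifCountTable) -> float:
    """One-sided (overrepresentation) Fisher exact p for the 2x2 table.

    This is the upper hypergeometric tail P(X >= mut_in_motif) with margins
    fixed; degenerate margins (any row or column total zero) give p = 1.
    """
    a = table.mut_in_motif
    row1 = table.mut_in_class
    col1 = table.mut_in_motif + table.ctx_motif
    total = table.mut_in_class + table.ctx_center
    if row1 == 0 or col1 == 0 or row1 == total or col1 == total:
        return 1.0
    p = float(hypergeom.sf(a - 1, total, col1, row1))
    return min(max(p, np.nextafter(0, 1)), 1.0)


def bh_adjust(p_values: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg step-up adjusted q-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def meml(
    table: MotifCountTable,
    enrichment_value: float,
    q_value: float,
    alpha: float = 0.05,
) -> float:
    """Minimal Estimate of Mutation Load for one sample x motif.

    ``mut_in_motif * (E - 1) / E`` when the significance gate passes
    (enrichment > 1 and q <= alpha); zero otherwise, including undefined
    enrichment.
    """
    if not math.isfinite(enrichment_value) or enrichment_value <= 1:
        return 0.0
    if math.isnan(q_value) or q_value > alpha:
        return 0.0
    return table.mut_in_motif * (enrichment_value - 1.0) / enrichment_value


RESULT_COLUMNS = [
    "sample_id",
    "donor_id",
    "tissue",
    "disease",
    "assay",
    "study_id",
    "motif",
    "mut_in_motif",
    "mut_in_class",
    "ctx_motif",
    "ctx_center",
    "enrichment",
    "p",
    "q",
    "meml",
    "status",
]


def run_enrichment(
    catalogs: Sequence[SampleCatalog],
    registry: MotifRegistry,
    genome: ReferenceGenome,
    flank: int = 20,
    alpha: float = 0.05,
    bh_scope: str = "per-motif",
    class_windows: bool = False,
    exclude_complex_first: bool = True,
) -> pd.DataFrame:
    """Full enrichment pass over a cohort: one row per sample x motif.

    Per sample: complex exclusion, count tables for every registry motif,
    enrichment and one-sided Fisher p.  BH correction is applied across all
    samples within each motif (``bh_scope='per-motif'``, the default) or
    across every row of the run (``'global'``); MEML is then gated at
    ``alpha``.  Output rows are ordered by sample, then registry order.
    Failures never drop rows silently: undefined enrichments are flagged in
    ``status`` and carry MEML 0.
    """
    if bh_scope not in ("per-motif", "global"):
        raise ValueError("bh_scope must be 'per-motif' or 'global'")
    motifs = list(registry)
    rows: List[dict] = []
    for catalog in sorted(catalogs, key=lambda c: c.sample_id):
        work = exclude_complex(catalog) if exclude_complex_first else catalog
        records, windows, n_mismatch = _windows_for(work, genome, flank)
        patterns = {m.context_pattern for m in motifs} | {
            m.center_base.lower() for m in motifs
        }
        all_sums = _context_sums(windows, patterns)
        for motif in motifs:
            in_class = [substitution_in_class(motif, r.ref, r.alt) for r in records]
            mut_in_class = int(sum(in_class))
            mut_in_motif = int(
                sum(
                    mutation_matches(motif, w, r.ref, r.alt)
                    for r, w, c in zip(records, windows, in_class)
                    if c
                )
            )
            if class_windows:
                sums = _context_sums(
                    [w for w, c in zip(windows, in_class) if c],
                    [motif.context_pattern, motif.center_base.lower()],
                )
            else:
                sums = all_sums
            table = MotifCountTable(
                mut_in_motif=mut_in_motif,
                mut_in_class=mut_in_class,
                ctx_motif=sums[motif.context_pattern],
                ctx_center=sums[motif.center_base.lower()],
            )
            enr = enrichment(table)
            undefined = not math.isfinite(enr)
            status = "undefined_enrichment" if undefined else "ok"
            if n_mismatch:
                status += ";ref_mismatch_skipped"
            rows.append(
                {
                    "sample_id": work.sample_id,
                    "donor_id": work.donor_id,
                    "tissue": work.tissue,
                    "disease": work.disease,
                    "assay": work.assay,
                    "study_id": work.study_id,
                    "motif": motif.name,
                    "mut_in_motif": table.mut_in_motif,
                    "mut_in_class": table.mut_in_class,
                    "ctx_motif": table.ctx_motif,
                    "ctx_center": table.ctx_center,
                    "enrichment": enr,
                    "p": math.nan if undefined else fisher_one_sided(table),
                    "q": math.nan,
                    "meml": 0.0,
                    "status": status,
                }
            )
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if df.empty:
        return df
    tested = df["p"].notna()
    if bh_scope == "per-motif":
        for _, idx in df[tested].groupby("motif").groups.items():
            df.loc[idx, "q"] = bh_adjust(df.loc[idx, "p"].tolist())
    else:
        idx = df.index[tested]
        df.loc[idx, "q"] = bh_adjust(df.loc[idx, "p"].tolist())
    for i in df.index[tested]:
        row = df.loc[i]
        table = MotifCountTable(
            int(row["mut_in_motif"]),
            int(row["mut_in_class"]),
            int(row["ctx_motif"]),
            int(row["ctx_center"]),
        )
        df.loc[i, "meml"] = meml(table, row["enrichment"], row["q"], alpha=alpha)
    return df
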