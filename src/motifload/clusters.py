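"""Mutation clusters, strand coordination and APOBEC3A/3B dissection.

APOBEC cytidine deaminases attack cytosines in single-stranded DNA, which
produces runs of closely spaced mutations all hitting the same strand —
clusters of coordinated G or C mutations (kataegis) with inter-mutation
distances of roughly 10–10^4 bp.  This module:

* calls clusters as maximal runs of same-contig mutations with every
  consecutive gap <= ``max_imd`` (default 10^4 bp; the 10 bp lower bound is
  enforced upstream by complex-mutation exclusion);
* classifies each cluster's strand coordination (all-G or all-C reference
  bases -> GC-coordinated; all-A or all-T -> AT-coordinated; mixed ->
  non-coordinated);
* applies the enrichment machinery to mutation categories (all GC clusters,
  GC clusters by size stratum, scattered mutations, genome-wide);
* compares APOBEC3A-like (``ytCa``) vs APOBEC3B-like (``rtCa``) enrichment
  with the classic Breslow-Day test of odds-ratio homogeneity where both
  motifs are individually significant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .enrichment import (
    MotifCountTable,
    build_count_table,
    enrichment,
    fisher_one_sided,
)
from .genome import ReferenceGenome
from .io import MutationRecord, SampleCatalog
from .motifs import MotifRegistry, MutationMotif, builtin_registry

logger = logging.getLogger(__name__)

__all__ = [
    "MutationCluster",
    "call_clusters",
    "classify_coordination",
    "scattered_records",
    "category_records",
    "category_enrichment",
    "breslow_day",
    "subtype_analysis",
    "apobec_indicators",
    "clusters_to_frame",
    "DEFAULT_SIZE_BINS",
]

GC_COORDINATED = "GC_coordinated"
AT_COORDINATED = "AT_coordinated"
NON_COORDINATED = "non_coordinated"

#: cluster-size strata (lo, hi); hi None means unbounded
DEFAULT_SIZE_BINS: Tuple[Tuple[int, Optional[int]], ...] = ((2, 2), (3, 3), (4, None))


@dataclass(frozen=True)
class MutationCluster:
    """A maximal run of closely spaced mutations in one sample."""

    sample_id: str
    contig: str
    members: Tuple[MutationRecord, ...]

    def __post_init__(self):
        if len(self.members) < 2:
            raise ValueError("clusters have at least 2 members")
        if any(m.contig != self.contig for m in self.members):
            raise ValueError("cluster members must share a contig")

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def start(self) -> int:
        return self.members[0].pos

    @property
    def end(self) -> int:
        return self.members[-1].pos

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def coordination(self) -> str:
        return classify_coordination(self)


def classify_coordination(cluster: MutationCluster) -> str:
    """Strand-coordination label from the member reference bases."""
    refs = {m.ref for m in cluster.members}
    if refs <= {"G"} or refs <= {"C"}:
        return GC_COORDINATED
    if refs <= {"A"} or refs <= {"T"}:
        return AT_COORDINATED
    return NON_COORDINATED


def call_clusters(
    catalog: SampleCatalog, max_imd: int = 10_000, min_size: int = 2
) -> List[MutationCluster]:
    """Maximal single-linkage runs with consecutive gaps <= ``max_imd``.

    The catalogue should already be complex-excluded (which enforces the
    ~10 bp lower bound of the inter-mutation-distance range).  Every
    mutation belongs to at most one cluster; the rest are 'scattered'.
    The result is independent of input record order (records are kept
    sorted by the catalogue container).
    """
    clusters: List[MutationCluster] = []
    run: List[MutationRecord] = []
    for r in catalog.records:
        if run and r.contig == run[-1].contig and r.pos - run[-1].pos <= max_imd:
            run.append(r)
        else:
            if len(run) >= min_size:
                clusters.append(
                    MutationCluster(catalog.sample_id, run[0].contig, tuple(run))
                )
            run = [r]
    if len(run) >= min_size:
        clusters.append(MutationCluster(catalog.sample_id, run[0].contig, tuple(run)))
    return clusters


def scattered_records(
    catalog: SampleCatalog, clusters: Sequence[MutationCluster]
) -> List[MutationRecord]:
    member_keys = {
        (m.contig, m.pos, m.ref, m.alt) for c in clusters for m in c.members
    }
    return [
        r for r in catalog.records if (r.contig, r.pos, r.ref, r.alt) not in member_keys
    ]


def category_records(
    catalog: SampleCatalog,
    clusters: Sequence[MutationCluster],
    category: str,
    size_bins: Tuple[Tuple[int, Optional[int]], ...] = DEFAULT_SIZE_BINS,
) -> List[MutationRecord]:
    """Mutation subset for an analysis category.

    Categories: ``genome_wide``, ``scattered``, ``gc_clusters_all``, and
    ``gc_clusters_size_<k>`` / ``gc_clusters_size_<k>plus`` for each size
    stratum.
    """
    if category == "genome_wide":
        return list(catalog.records)
    if category == "scattered":
        return scattered_records(catalog, clusters)
    gc = [c for c in clusters if classify_coordination(c) == GC_COORDINATED]
    if category == "gc_clusters_all":
        return [m for c in gc for m in c.members]
    for lo, hi in size_bins:
        if category == _size_label(lo, hi):
            return [
                m
                for c in gc
                if c.size >= lo and (hi is None or c.size <= hi)
                for m in c.members
            ]
    raise ValueError(f"unknown category {category!r}")


def _size_label(lo: int, hi: Optional[int]) -> str:
    if hi is None:
        return f"gc_clusters_size_{lo}plus"
    if hi == lo:
        return f"gc_clusters_size_{lo}"
    return f"gc_clusters_size_{lo}_{hi}"


def category_enrichment(
    catalog: SampleCatalog,
    clusters: Sequence[MutationCluster],
    motif: MutationMotif,
    genome: ReferenceGenome,
    category: str,
    flank: int = 20,
    size_bins: Tuple[Tuple[int, Optional[int]], ...] = DEFAULT_SIZE_BINS,
) -> Tuple[MotifCountTable, float, float, str]:
    """Enrichment machinery applied to one mutation category.

    Context windows are drawn from the category's own mutations.  Returns
    (table, enrichment, one-sided Fisher p, status); an empty category or a
    zero denominator yields an 'undefined_enrichment' status with p = NaN.
    """
    records = category_records(catalog, clusters, category, size_bins)
    sub = catalog.with_records(records)
    table = build_count_table(sub, motif, genome, flank=flank)
    enr = enrichment(table)
    if not math.isfinite(enr):
        return table, enr, math.nan, "undefined_enrichment"
    return table, enr, fisher_one_sided(table), "ok"


def breslow_day(
    strata: Sequence[MotifCountTable], tarone: bool = False
) -> Tuple[float, float]:
    """Classic Breslow-Day chi-square test of odds-ratio homogeneity.

    Tests whether the 2x2 odds ratios of the strata are equal, against the
    Mantel-Haenszel common odds ratio; df = (#usable strata - 1).  Strata
    with a zero margin are dropped with a warning; fewer than two usable
    strata raise.  ``tarone=True`` applies the Tarone adjustment.
    """
    usable = []
    for t in strata:
        arr = t.as_2x2()
        if arr.sum(axis=0).min() == 0 or arr.sum(axis=1).min() == 0:
            logger.warning("Breslow-Day: dropping degenerate stratum %s", arr.tolist())
            continue
        usable.append(arr.astype(float))
    if len(usable) < 2:
        raise ValueError("Breslow-Day needs at least two non-degenerate strata")

    # Mantel-Haenszel common odds ratio
    R = sum(a[0, 0] * a[1, 1] / a.sum() for a in usable)
    S = sum(a[0, 1] * a[1, 0] / a.sum() for a in usable)
    if S == 0 or R == 0:
        # all strata concentrated in one diagonal: no finite common OR
        return math.nan, math.nan
    psi = R / S

    stat = 0.0
    resid_sum = 0.0
    var_sum = 0.0
    for a in usable:
        obs = a[0, 0]
        row1 = a[0].sum()
        col1 = a[:, 0].sum()
        n = a.sum()
        # expected a-cell under the common OR: root of a quadratic
        A = psi - 1.0
        B = -(psi * (row1 + col1) + (n - row1 - col1))
        C = psi * row1 * col1
        if A == 0:
            exp_a = -C / B
        else:
            disc = math.sqrt(B * B - 4 * A * C)
            roots = [(-B - disc) / (2 * A), (-B + disc) / (2 * A)]
            exp_a = next(
                x
                for x in roots
                if -1e-9 <= x <= min(row1, col1) + 1e-9
                and row1 - x >= -1e-9
                and col1 - x >= -1e-9
                and n - row1 - col1 + x >= -1e-9
            )
        cells = [exp_a, row1 - exp_a, col1 - exp_a, n - row1 - col1 + exp_a]
        var = 1.0 / sum(1.0 / max(c, 1e-300) for c in cells)
        stat += (obs - exp_a) ** 2 / var
        resid_sum += obs - exp_a
        var_sum += var
    if tarone:
        stat -= resid_sum**2 / var_sum
    stat = max(stat, 0.0)
    df = len(usable) - 1
    return stat, float(chi2.sf(stat, df))


def subtype_analysis(
    catalogs: Sequence[SampleCatalog],
    genome: ReferenceGenome,
    clusters: Optional[Sequence[MutationCluster]] = None,
    flank: int = 20,
    alpha: float = 0.05,
    max_imd: int = 10_000,
    size_bins: Tuple[Tuple[int, Optional[int]], ...] = DEFAULT_SIZE_BINS,
    registry: Optional[MotifRegistry] = None,
) -> pd.DataFrame:
    """APOBEC3A-like (ytCa) vs 3B-like (rtCa) comparison per category.

    Catalogues (pre-selected APOBEC candidates, typically one tissue) are
    pooled; for each category the two tetranucleotide tables (combined C->T
    and C->G substitutions) are built and tested one-sided; where both are
    individually significant at ``alpha`` the Breslow-Day comparison of the
    two odds ratios is emitted, together with the preferred (larger-
    enrichment) motif.
    """
    registry = registry or builtin_registry()
    ytca, rtca = registry.get("ytCa"), registry.get("rtCa")
    if clusters is None:
        clusters = [cl for c in catalogs for cl in call_clusters(c, max_imd=max_imd)]
    categories = (
        ["gc_clusters_all"]
        + [_size_label(lo, hi) for lo, hi in size_bins]
        + ["scattered", "genome_wide"]
    )
    rows = []
    for category in categories:
        yt_table, yt_enr, yt_p, yt_status = _pooled_category_enrichment(
            catalogs, clusters, ytca, genome, category, flank, size_bins
        )
        rt_table, rt_enr, rt_p, rt_status = _pooled_category_enrichment(
            catalogs, clusters, rtca, genome, category, flank, size_bins
        )
        both_sig = (
            yt_status == "ok"
            and rt_status == "ok"
            and yt_p <= alpha
            and rt_p <= alpha
        )
        bd_stat = bd_p = math.nan
        if both_sig:
            try:
                bd_stat, bd_p = breslow_day([yt_table, rt_table])
            except ValueError:
                both_sig = False
        preferred = ""
        if math.isfinite(yt_enr) and math.isfinite(rt_enr):
            preferred = "ytCa" if yt_enr >= rt_enr else "rtCa"
        rows.append(
            {
                "category": category,
                "ytca_mut_in_motif": yt_table.mut_in_motif,
                "ytca_enrichment": yt_enr,
                "ytca_p": yt_p,
                "rtca_mut_in_motif": rt_table.mut_in_motif,
                "rtca_enrichment": rt_enr,
                "rtca_p": rt_p,
                "both_significant": both_sig,
                "bd_statistic": bd_stat,
                "bd_p": bd_p,
                "preferred_motif": preferred,
            }
        )
    return pd.DataFrame(rows)


def _pooled_category_enrichment(
    catalogs, clusters, motif, genome, category, flank, size_bins
):
    """Category enrichment with counts pooled over samples."""
    records = []
    for cat in catalogs:
        own = [cl for cl in clusters if cl.sample_id == cat.sample_id]
        records.extend(category_records(cat, own, category, size_bins))
    sub = SampleCatalog(sample_id="pooled")
    sub.records = sorted(records)
    table = build_count_table(sub, motif, genome, flank=flank)
    enr = enrichment(table)
    if not math.isfinite(enr):
        return table, enr, math.nan, "undefined_enrichment"
    return table, enr, fisher_one_sided(table), "ok"


def apobec_indicators(
    enrichment_results: pd.DataFrame,
    catalogs: Sequence[SampleCatalog],
    genome: ReferenceGenome,
    max_imd: int = 10_000,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Report of the three qualitative APOBEC-candidacy indicators per sample.

    (i) significant combined-tCw MEML; (ii) balance of tCw->tTw vs tCw->tGw
    inside GC-coordinated clusters; (iii) prevalence of GC-coordinated
    clusters.  A report, not a hard filter: thresholds are left to the
    analyst.
    """
    registry = builtin_registry()
    ttw, tgw = registry.get("tCw>tTw"), registry.get("tCw>tGw")
    tcw_rows = enrichment_results[enrichment_results["motif"] == "tCw"]
    rows = []
    for cat in catalogs:
        from .enrichment import exclude_complex
        from .motifs import mutation_matches
        from .genome import extract_window

        work = exclude_complex(cat)
        clusters = call_clusters(work, max_imd=max_imd)
        gc = [c for c in clusters if classify_coordination(c) == GC_COORDINATED]
        gc_members = [m for c in gc for m in c.members]
        n_ttw = n_tgw = 0
        for m in gc_members:
            w = extract_window(genome, m.contig, m.pos)
            if w.center_base != m.ref:
                continue
            if mutation_matches(ttw, w, m.ref, m.alt):
                n_ttw += 1
            elif mutation_matches(tgw, w, m.ref, m.alt):
                n_tgw += 1
        sample_tcw = tcw_rows[tcw_rows["sample_id"] == cat.sample_id]
        tcw_meml = float(sample_tcw["meml"].iloc[0]) if len(sample_tcw) else math.nan
        rows.append(
            {
                "sample_id": cat.sample_id,
                "tcw_meml": tcw_meml,
                "tcw_significant": bool(tcw_meml > 0),
                "gc_cluster_count": len(gc),
                "cluster_count": len(clusters),
                "gc_cluster_fraction": len(gc) / len(clusters) if clusters else math.nan,
                "gc_ttw_count": n_ttw,
                "gc_tgw_count": n_tgw,
                "gc_ttw_tgw_balance": (
                    min(n_ttw, n_tgw) / max(n_ttw, n_tgw)
                    if max(n_ttw, n_tgw) > 0
                    else math.nan
                ),
            }
        )
    return pd.DataFrame(rows)


def clusters_to_frame(clusters: Sequence[MutationCluster]) -> pd.DataFrame:
    """Tabular cluster report (one row per cluster)."""
    return pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "contig": c.contig,
                "start": c.start,
                "end": c.end,
                "size": c.size,
                "span": c.span,
                "coordination": classify_coordination(c),
                "member_positions": ",".join(str(m.pos) for m in c.members),
            }
            for c in clusters
        ],
        columns=[
            "sample_id",
            "contig",
            "start",
            "end",
            "size",
            "span",
            "coordination",
            "member_positions",
        ],
    )
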