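"""Somatic-SNV catalogue containers and readers/writers (MAF, VCF, TSV).

The unit of analysis is a :class:`SampleCatalog`: every somatic single-base
substitution called in one sample, plus the donor/tissue/disease/age
metadata the cohort statistics need.  Catalogues arrive as MAF tables
(one row per call, possibly many samples per file) or as per-sample VCFs;
both are reduced to the same in-memory records.

Catalogue hygiene implemented here:

* non-SNV rows (indels, DNPs) are skipped and counted;
* duplicate calls within a sample are recorded once;
* calls shared between samples of the same donor and tissue (clones or
  single cells re-sampling the same clonal variant) can be collapsed with
  :func:`dedup_cross_sample`, keeping the call in the sample with the
  highest variant allele frequency.

Each filter increments a named counter so a run can report how many records
survived which rule.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MutationRecord",
    "SampleCatalog",
    "read_maf",
    "write_maf",
    "read_vcf",
    "read_metadata",
    "dedup_cross_sample",
]

_BASES = frozenset("ACGT")

#: MAF columns this package requires; extra columns pass through untouched.
MAF_REQUIRED = [
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Tumor_Sample_Barcode",
]

METADATA_COLUMNS = [
    "sample_id",
    "donor_id",
    "tissue",
    "disease",
    "age",
    "assay",
    "study_id",
    "estimated_snvs",
    "identified_mutations",
]


@dataclass(frozen=True, order=True)
class MutationRecord:
    """One somatic SNV: sample, contig, 1-based position, ref/alt, optional VAF."""

    sample_id: str
    contig: str
    pos: int
    ref: str
    alt: str
    vaf: Optional[float] = field(default=None, compare=False)

    def __post_init__(self):
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"ref/alt must be single ACGT bases: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.pos < 1:
            raise ValueError("positions are 1-based; pos must be >= 1")


@dataclass
class SampleCatalog:
    """All SNVs of one sample plus its donor-level metadata.

    Records are deduplicated by (contig, pos, ref, alt) and kept sorted;
    duplicate inputs are counted in ``filter_counts['duplicate_in_sample']``.
    """

    sample_id: str
    records: List[MutationRecord] = field(default_factory=list)
    donor_id: str = ""
    tissue: str = ""
    disease: str = "healthy"
    age: Optional[float] = None
    assay: str = "WGS"
    study_id: str = ""
    filter_counts: Counter = field(default_factory=Counter)

    def __post_init__(self):
        for r in self.records:
            if r.sample_id != self.sample_id:
                raise ValueError(
                    f"record sample {r.sample_id!r} != catalog sample {self.sample_id!r}"
                )
        seen = {}
        for r in self.records:
            key = (r.contig, r.pos, r.ref, r.alt)
            if key in seen:
                self.filter_counts["duplicate_in_sample"] += 1
            else:
                seen[key] = r
        self.records = sorted(seen.values())

    def __len__(self) -> int:
        return len(self.records)

    def with_records(self, records: Sequence[MutationRecord]) -> "SampleCatalog":
        """Copy of this catalog holding a different record set."""
        new = replace(self, records=list(records))
        new.filter_counts = Counter(self.filter_counts)
        return new

    def strand_flipped(self, genome) -> "SampleCatalog":
        """Image of the catalog on the reverse-complemented genome.

        Positions map to ``L - pos + 1`` and alleles are complemented; used
        by the strand-symmetry invariant checks.
        """
        from .genome import _COMPLEMENT

        flipped = [
            replace(
                r,
                pos=genome.length(r.contig) - r.pos + 1,
                ref=_COMPLEMENT[r.ref],
                alt=_COMPLEMENT[r.alt],
            )
            for r in self.records
        ]
        return self.with_records(flipped)


def _is_snv(ref: str, alt: str) -> bool:
    return (
        isinstance(ref, str)
        and isinstance(alt, str)
        and len(ref) == 1
        and len(alt) == 1
        and ref in _BASES
        and alt in _BASES
        and ref != alt
    )


def _apply_metadata(catalog: SampleCatalog, metadata: Optional[pd.DataFrame]):
    if metadata is None:
        return catalog
    rows = metadata[metadata["sample_id"] == catalog.sample_id]
    if rows.empty:
        logger.warning("sample %s absent from metadata", catalog.sample_id)
        return catalog
    row = rows.iloc[0]
    catalog.donor_id = str(row.get("donor_id", "") or "")
    catalog.tissue = str(row.get("tissue", "") or "")
    catalog.disease = str(row.get("disease", "healthy") or "healthy")
    age = row.get("age")
    catalog.age = float(age) if pd.notna(age) else None
    catalog.assay = str(row.get("assay", "WGS") or "WGS")
    catalog.study_id = str(row.get("study_id", "") or "")
    return catalog


def read_maf(
    path,
    metadata: Optional[pd.DataFrame] = None,
    contig_alias: Optional[Dict[str, str]] = None,
) -> List[SampleCatalog]:
    """Read a MAF file into per-sample catalogues.

    Only SNV rows (single-base ACGT ref and alt) are kept; skipped rows are
    counted per sample under ``non_snv``.  An optional metadata frame (see
    :func:`read_metadata`) attaches donor/tissue/disease/age annotations;
    ``contig_alias`` maps contig names at load (e.g. ``{"1": "chr1"}``) so
    mixed-source inputs agree with the reference.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in MAF_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"MAF {path} missing required columns {missing}")
    catalogs: List[SampleCatalog] = []
    if df.empty:
        return catalogs
    df["Start_Position"] = df["Start_Position"].astype(int)
    vaf_col = "VAF" if "VAF" in df.columns else None
    for sample_id, group in df.groupby("Tumor_Sample_Barcode", sort=True):
        records, counts = [], Counter()
        for row in group.itertuples(index=False):
            ref = getattr(row, "Reference_Allele")
            alt = getattr(row, "Tumor_Seq_Allele2")
            if not _is_snv(ref, alt):
                counts["non_snv"] += 1
                continue
            vaf = None
            if vaf_col:
                raw = getattr(row, vaf_col)
                vaf = float(raw) if pd.notna(raw) and raw != "" else None
            contig = str(getattr(row, "Chromosome"))
            records.append(
                MutationRecord(
                    sample_id=str(sample_id),
                    contig=(contig_alias or {}).get(contig, contig),
                    pos=int(getattr(row, "Start_Position")),
                    ref=ref,
                    alt=alt,
                    vaf=vaf,
                )
            )
        catalog = SampleCatalog(sample_id=str(sample_id), records=records)
        catalog.filter_counts.update(counts)
        catalogs.append(_apply_metadata(catalog, metadata))
    return catalogs


def write_maf(catalogs: Iterable[SampleCatalog], path) -> None:
    """Write catalogues as a minimal MAF (tab-separated, sorted rows)."""
    rows = []
    for cat in sorted(catalogs, key=lambda c: c.sample_id):
        for r in cat.records:
            rows.append(
                {
                    "Chromosome": r.contig,
                    "Start_Position": r.pos,
                    "End_Position": r.pos,
                    "Reference_Allele": r.ref,
                    "Tumor_Seq_Allele2": r.alt,
                    "Tumor_Sample_Barcode": r.sample_id,
                    "VAF": "" if r.vaf is None else r.vaf,
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "Chromosome",
            "Start_Position",
            "End_Position",
            "Reference_Allele",
            "Tumor_Seq_Allele2",
            "Tumor_Sample_Barcode",
            "VAF",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_vcf(
    path,
    sample_id: str,
    metadata: Optional[pd.DataFrame] = None,
    pass_only: bool = True,
    contig_alias: Optional[Dict[str, str]] = None,
) -> SampleCatalog:
    """Read one sample's VCF into a catalogue.

    Biallelic SNVs are kept as-is; multiallelic records are split into one
    record per alternate allele; indels and symbolic alleles are skipped and
    counted.  With ``pass_only`` (default) only FILTER PASS / '.' records
    are used.
    """
    from cyvcf2 import VCF

    records, counts = [], Counter()
    for variant in VCF(str(path)):
        if pass_only and variant.FILTER is not None:
            counts["filtered"] += 1
            continue
        ref = str(variant.REF).upper()
        for alt in variant.ALT:
            alt = str(alt).upper()
            if not _is_snv(ref, alt):
                counts["non_snv"] += 1
                continue
            contig = str(variant.CHROM)
            records.append(
                MutationRecord(
                    sample_id=sample_id,
                    contig=(contig_alias or {}).get(contig, contig),
                    pos=int(variant.POS),
                    ref=ref,
                    alt=alt,
                )
            )
    catalog = SampleCatalog(sample_id=sample_id, records=records)
    catalog.filter_counts.update(counts)
    return _apply_metadata(catalog, metadata)


def read_metadata(path) -> pd.DataFrame:
    """Read the sample metadata TSV (sample_id, donor_id, tissue, disease,
    age, assay, study_id, estimated_snvs, identified_mutations)."""
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValueError(f"metadata {path} must contain a sample_id column")
    df["sample_id"] = df["sample_id"].astype(str)
    return df


def dedup_cross_sample(catalogs: Sequence[SampleCatalog]) -> List[SampleCatalog]:
    """Collapse variants shared across samples of one donor and tissue.

    Each (contig, pos, ref, alt) seen in several samples is kept only in the
    sample with the highest VAF; ties and missing VAFs fall back to the
    first sample in stable (sample_id) order, with a warning.  The union of
    variants over the donor is unchanged.
    """
    donors = {(c.donor_id, c.tissue) for c in catalogs}
    if len(donors) > 1:
        raise ValueError(
            "dedup_cross_sample expects catalogs of one donor and tissue; "
            f"got {sorted(donors)}"
        )
    ordered = sorted(catalogs, key=lambda c: c.sample_id)
    occurrences: Dict[tuple, list] = {}
    for rank, cat in enumerate(ordered):
        for r in cat.records:
            key = (r.contig, r.pos, r.ref, r.alt)
            occurrences.setdefault(key, []).append((rank, cat.sample_id, r.vaf))
    best: Dict[tuple, tuple] = {}  # variant -> (sort key, winning sample_id)
    warned = False
    for key, occs in occurrences.items():
        if len(occs) > 1 and any(v is None for _, _, v in occs):
            warned = True
        # highest VAF wins; missing VAF sorts below any real VAF; then rank
        winner = min(occs, key=lambda o: (-(o[2] if o[2] is not None else -1.0), o[0]))
        best[key] = (None, winner[1])
    if warned:
        logger.warning("cross-sample dedup fell back to first-sample order "
                       "for shared variants without VAF")
    out = []
    for cat in ordered:
        kept = [
            r
            for r in cat.records
            if best[(r.contig, r.pos, r.ref, r.alt)][1] == cat.sample_id
        ]
        dropped = len(cat.records) - len(kept)
        new = cat.with_records(kept)
        if dropped:
            new.filter_counts["cross_sample_duplicate"] += dropped
        out.append(new)
    return out
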