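"""Synthetic reference genomes, mutation catalogues and cohorts.

The generator produces data with exactly the statistical structure the
analysis modules assume, so the whole pipeline is testable without any
download:

* pseudo-random genomes with controllable base composition and CpG
  dinucleotide frequency (first-order Markov adjustment);
* per-sample catalogues mixing a uniform background substitution process
  with motif-targeted processes at controlled intensity — either a fixed
  mutation count or a clock-like per-year rate scaled by donor age and an
  optional disease multiplier;
* strand-coordinated clustered mutations (same-strand runs within a
  bounded span), emulating APOBEC kataegis;
* donor/sample/tissue/disease metadata and a truth table recording every
  injected count.

All randomness flows from explicit integer seeds; identical seeds give
byte-identical FASTA/MAF/metadata/truth outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genome import ReferenceGenome, reverse_complement, _COMPLEMENT, _pattern_regex
from .io import MutationRecord, SampleCatalog
from .motifs import MotifRegistry, MutationMotif, builtin_registry

__all__ = [
    "ProcessSpec",
    "TruthRecord",
    "DonorSpec",
    "make_genome",
    "make_catalog",
    "make_cohort",
    "write_fasta",
]

#: minimum separation (bp) between injected cluster members, so that
#: injected clusters survive complex-mutation exclusion (<=10 bp)
_MIN_CLUSTER_SEP = 11


@dataclass(frozen=True)
class ProcessSpec:
    """One motif-targeted mutational process.

    ``intensity`` is a mutation count (``mode='fixed_count'``) or a
    mutations-per-year rate (``mode='per_year_rate'``, multiplied by donor
    age and, for diseased donors, by ``disease_multiplier``, then
    Poisson-sampled).  ``clustered_fraction`` of the process's mutations
    are placed as same-strand runs spanning at most ``cluster_span`` bp
    with sizes drawn from ``cluster_size_dist``.
    """

    motif: str
    mode: str = "fixed_count"
    intensity: float = 0.0
    disease_multiplier: float = 1.0
    clustered_fraction: float = 0.0
    cluster_size_dist: Dict[int, float] = field(
        default_factory=lambda: {2: 0.5, 3: 0.3, 4: 0.2}
    )
    cluster_span: int = 5000

    def __post_init__(self):
        if self.mode not in ("fixed_count", "per_year_rate"):
            raise ValueError("mode must be 'fixed_count' or 'per_year_rate'")
        if self.intensity < 0:
            raise ValueError("intensity must be >= 0")
        if not 0 <= self.clustered_fraction <= 1:
            raise ValueError("clustered_fraction must lie in [0, 1]")
        if any(k < 2 for k in self.cluster_size_dist):
            raise ValueError("cluster sizes must be >= 2")
        if self.disease_multiplier < 0:
            raise ValueError("disease_multiplier must be >= 0")


@dataclass
class TruthRecord:
    """Ground truth for one simulated sample."""

    sample_id: str
    seed: int
    n_background: int
    processes: List[dict] = field(default_factory=list)
    background_collisions: int = 0

    @property
    def n_injected(self) -> int:
        return sum(p["n_total"] for p in self.processes)


@dataclass(frozen=True)
class DonorSpec:
    """One donor in a simulated cohort design."""

    donor_id: str
    age: float
    tissue: str = "tissue"
    disease: str = "healthy"
    n_samples: int = 1
    study_id: str = "study1"
    assay: str = "WGS"


def make_genome(
    length: int,
    base_composition: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    cpg_factor: float = 1.0,
    seed: int = 0,
    contig_name: str = "chr1",
) -> ReferenceGenome:
    """Pseudo-random genome of one contig.

    ``base_composition`` gives P(A), P(C), P(G), P(T).  ``cpg_factor``
    rescales P(G | previous base is C) by that factor (renormalizing the
    other bases), so values > 1 inflate and < 1 deplete CpG dinucleotides;
    0 removes them entirely.  Fully deterministic in ``seed``.
    """
    if length < 10_000:
        raise ValueError("length must be >= 10^4")
    probs = np.asarray(base_composition, dtype=float)
    if probs.shape != (4,) or np.any(probs < 0) or not math.isclose(probs.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("base_composition must be 4 nonnegative probabilities summing to 1")
    if cpg_factor < 0:
        raise ValueError("cpg_factor must be >= 0")
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    if cpg_factor == 1.0:
        idx = rng.choice(4, size=length, p=probs)
        seq = idx.astype(np.uint8)
    else:
        # first-order Markov: the row after a C rescales P(G)
        after_c = probs.copy()
        after_c[2] *= cpg_factor
        if after_c.sum() == 0:
            raise ValueError("degenerate composition after CpG adjustment")
        after_c /= after_c.sum()
        cum_default = np.cumsum(probs)
        cum_after_c = np.cumsum(after_c)
        u = rng.random(length)
        seq = np.empty(length, dtype=np.uint8)
        prev_c = False
        for i in range(length):
            cum = cum_after_c if prev_c else cum_default
            b = int(np.searchsorted(cum, u[i], side="right"))
            b = min(b, 3)
            seq[i] = b
            prev_c = b == 1
    sequence = bases[seq].tobytes().decode("ascii")
    return ReferenceGenome({contig_name: sequence})


def _motif_sites(
    genome: ReferenceGenome, motif: MutationMotif
) -> Dict[str, List[Tuple[int, str]]]:
    """All (1-based position of mutated base, strand) per contig matching
    the motif's reference pattern on either strand."""
    k = len(motif.ref_pattern)
    c = motif.center_index
    fwd = _pattern_regex(motif.ref_pattern.upper())
    rev_pattern = reverse_complement(motif.ref_pattern).upper()
    rev = _pattern_regex(rev_pattern)
    out: Dict[str, List[Tuple[int, str]]] = {}
    for contig, seq in genome.contigs.items():
        sites = [(m.start() + c + 1, "+") for m in fwd.finditer(seq)]
        sites += [(m.start() + (k - 1 - c) + 1, "-") for m in rev.finditer(seq)]
        sites.sort()
        out[contig] = sites
    return out


def _inject_process(
    genome: ReferenceGenome,
    motif: MutationMotif,
    n: int,
    clustered_fraction: float,
    cluster_size_dist: Dict[int, float],
    cluster_span: int,
    used: set,
    rng: np.random.Generator,
    sample_id: str,
) -> Tuple[List[MutationRecord], int, int, List[dict]]:
    """Place ``n`` motif mutations; returns (records, n_clustered,
    n_scattered, injected cluster runs).

    Fails loudly when the genome does not offer enough motif sites.
    """
    site_map = _motif_sites(genome, motif)
    # flatten to parallel arrays for fast sampling
    contigs, positions, strands = [], [], []
    for contig, sites in site_map.items():
        for pos, strand in sites:
            if (contig, pos) in used:
                continue
            contigs.append(contig)
            positions.append(pos)
            strands.append(strand)
    if not positions:
        raise ValueError(f"no available {motif.name} sites in genome")
    positions = np.asarray(positions)
    order = np.argsort(positions, kind="stable")
    positions = positions[order]
    contigs = np.asarray(contigs, dtype=object)[order]
    strands = np.asarray(strands, dtype=object)[order]
    available = np.ones(len(positions), dtype=bool)

    mutants = sorted(motif.mutant_bases)

    def _record(i: int) -> MutationRecord:
        alt_pyr = mutants[int(rng.integers(len(mutants)))]
        if strands[i] == "+":
            ref, alt = motif.center_base, alt_pyr
        else:
            ref, alt = _COMPLEMENT[motif.center_base], _COMPLEMENT[alt_pyr]
        return MutationRecord(
            sample_id=sample_id,
            contig=str(contigs[i]),
            pos=int(positions[i]),
            ref=ref,
            alt=alt,
        )

    def _claim(i: int):
        available[i] = False
        used.add((str(contigs[i]), int(positions[i])))

    records: List[MutationRecord] = []
    cluster_runs: List[dict] = []
    n_clustered_target = int(round(clustered_fraction * n))
    sizes, probs = zip(*sorted(cluster_size_dist.items())) if cluster_size_dist else ((), ())
    probs = np.asarray(probs, dtype=float)
    if len(probs):
        probs = probs / probs.sum()

    n_clustered = 0
    attempts_left = 200 * max(1, n_clustered_target)
    while n_clustered < n_clustered_target:
        if attempts_left <= 0:
            raise ValueError(
                f"could not place clustered {motif.name} mutations: "
                f"{n_clustered_target - n_clustered} of {n_clustered_target} missing"
            )
        attempts_left -= 1
        remaining = n_clustered_target - n_clustered
        if remaining < 2:
            break  # a single leftover mutation cannot form a cluster
        size = min(int(rng.choice(sizes, p=probs)), remaining)
        avail_idx = np.flatnonzero(available)
        if len(avail_idx) < size:
            raise ValueError(f"site exhaustion for {motif.name} clusters")
        anchor = int(rng.choice(avail_idx))
        strand = strands[anchor]
        contig = contigs[anchor]
        lo_pos, hi_pos = positions[anchor], positions[anchor] + cluster_span
        lo = int(np.searchsorted(positions, lo_pos, side="left"))
        hi = int(np.searchsorted(positions, hi_pos, side="right"))
        chosen = []
        last_pos = None
        for i in range(lo, hi):
            if not available[i] or strands[i] != strand or contigs[i] != contig:
                continue
            if last_pos is not None and positions[i] - last_pos < _MIN_CLUSTER_SEP:
                continue
            chosen.append(i)
            last_pos = positions[i]
            if len(chosen) == size:
                break
        if len(chosen) < size:
            continue  # retry with a new anchor
        for i in chosen:
            _claim(i)
            records.append(_record(i))
        cluster_runs.append(
            {
                "contig": str(contig),
                "strand": str(strand),
                "positions": [int(positions[i]) for i in chosen],
            }
        )
        n_clustered += size

    n_scattered = n - n_clustered
    avail_idx = np.flatnonzero(available)
    if len(avail_idx) < n_scattered:
        raise ValueError(
            f"site exhaustion for {motif.name}: need {n_scattered} scattered sites, "
            f"{len(avail_idx)} available"
        )
    for i in rng.choice(avail_idx, size=n_scattered, replace=False):
        _claim(int(i))
        records.append(_record(int(i)))
    return records, n_clustered, n_scattered, cluster_runs


def make_catalog(
    genome: ReferenceGenome,
    n_background: int,
    processes: Sequence[ProcessSpec],
    seed: int,
    sample_id: str = "S1",
    donor_id: str = "D1",
    tissue: str = "tissue",
    disease: str = "healthy",
    age: Optional[float] = None,
    assay: str = "WGS",
    study_id: str = "study1",
    registry: Optional[MotifRegistry] = None,
    healthy_label: str = "healthy",
) -> Tuple[SampleCatalog, TruthRecord]:
    """Simulate one sample's SNV catalogue.

    Background mutations are uniform over non-N genome positions with a
    uniformly chosen alternate base; each process injects motif-matching
    mutations (see :class:`ProcessSpec`).  All positions are unique;
    background positions colliding with already-used positions are
    resampled and the collision count recorded in the truth record.
    """
    registry = registry or builtin_registry()
    rng = np.random.default_rng(seed)
    used: set = set()
    records: List[MutationRecord] = []
    truth = TruthRecord(sample_id=sample_id, seed=seed, n_background=n_background)

    diseased = disease != healthy_label
    for spec in processes:
        motif = registry.get(spec.motif) if isinstance(spec.motif, str) else spec.motif
        if spec.mode == "fixed_count":
            n = int(round(spec.intensity))
        else:
            if age is None:
                raise ValueError("per_year_rate processes need a donor age")
            lam = spec.intensity * age * (spec.disease_multiplier if diseased else 1.0)
            n = int(rng.poisson(lam))
        recs, n_clustered, n_scattered, cluster_runs = _inject_process(
            genome,
            motif,
            n,
            spec.clustered_fraction,
            spec.cluster_size_dist,
            spec.cluster_span,
            used,
            rng,
            sample_id,
        )
        records.extend(recs)
        truth.processes.append(
            {
                "motif": motif.name,
                "n_total": n,
                "n_in_motif": n,  # by construction every injected call matches
                "n_clustered": n_clustered,
                "n_scattered": n_scattered,
                "cluster_runs": cluster_runs,
            }
        )

    # uniform background
    contig_names = list(genome.contigs)
    lengths = np.array([genome.length(c) for c in contig_names], dtype=float)
    contig_probs = lengths / lengths.sum()
    placed = 0
    collisions = 0
    guard = 0
    while placed < n_background:
        guard += 1
        if guard > 100 * max(1, n_background) + 1000:
            raise ValueError("background site exhaustion")
        ci = int(rng.choice(len(contig_names), p=contig_probs))
        contig = contig_names[ci]
        pos = int(rng.integers(1, genome.length(contig) + 1))
        if (contig, pos) in used:
            collisions += 1
            continue
        ref = genome.base(contig, pos)
        if ref == "N":
            continue
        others = [b for b in "ACGT" if b != ref]
        alt = others[int(rng.integers(3))]
        used.add((contig, pos))
        records.append(
            MutationRecord(sample_id=sample_id, contig=contig, pos=pos, ref=ref, alt=alt)
        )
        placed += 1
    truth.background_collisions = collisions

    catalog = SampleCatalog(
        sample_id=sample_id,
        records=records,
        donor_id=donor_id,
        tissue=tissue,
        disease=disease,
        age=age,
        assay=assay,
        study_id=study_id,
    )
    return catalog, truth


def _child_seed(master_seed: int, *key: int) -> int:
    """Deterministic per-entity seed below 2^31 derived from the master seed."""
    ss = np.random.SeedSequence([int(master_seed), *[int(k) for k in key]])
    return int(ss.generate_state(1)[0] % (2**31))


def make_cohort(
    design: Sequence[DonorSpec],
    processes: Sequence[ProcessSpec],
    genome: ReferenceGenome,
    seed: int,
    n_background: int = 0,
    registry: Optional[MotifRegistry] = None,
) -> Tuple[List[SampleCatalog], pd.DataFrame, pd.DataFrame]:
    """Simulate a donor cohort: catalogues + metadata table + truth table.

    Per-sample seeds are derived deterministically from the master seed and
    the donor/sample indices, so any subset of the cohort reproduces
    identically.  Clock-like (``per_year_rate``) processes give
    age-proportional expected counts; ``disease_multiplier`` applies only
    to donors whose disease label is not 'healthy'.
    """
    if not design:
        raise ValueError("cohort design must be nonempty")
    catalogs: List[SampleCatalog] = []
    meta_rows, truth_rows = [], []
    for di, donor in enumerate(design):
        for si in range(donor.n_samples):
            sample_id = f"{donor.donor_id}_s{si + 1}"
            child = _child_seed(seed, di, si)
            catalog, truth = make_catalog(
                genome,
                n_background=n_background,
                processes=processes,
                seed=child,
                sample_id=sample_id,
                donor_id=donor.donor_id,
                tissue=donor.tissue,
                disease=donor.disease,
                age=donor.age,
                assay=donor.assay,
                study_id=donor.study_id,
                registry=registry,
            )
            catalogs.append(catalog)
            meta_rows.append(
                {
                    "sample_id": sample_id,
                    "donor_id": donor.donor_id,
                    "tissue": donor.tissue,
                    "disease": donor.disease,
                    "age": donor.age,
                    "assay": donor.assay,
                    "study_id": donor.study_id,
                    "estimated_snvs": "",
                    "identified_mutations": "",
                }
            )
            for proc in truth.processes:
                row = {
                    "sample_id": sample_id,
                    "seed": truth.seed,
                    "n_background": truth.n_background,
                    "background_collisions": truth.background_collisions,
                    **proc,
                }
                # per-cluster member positions, serialized for the TSV
                row["cluster_runs"] = ";".join(
                    f"{c['contig']}:{c['strand']}:" + "|".join(map(str, c["positions"]))
                    for c in proc.get("cluster_runs", [])
                )
                truth_rows.append(row)
            if not truth.processes:
                truth_rows.append(
                    {
                        "sample_id": sample_id,
                        "seed": truth.seed,
                        "n_background": truth.n_background,
                        "background_collisions": truth.background_collisions,
                        "motif": "",
                        "n_total": 0,
                        "n_in_motif": 0,
                        "n_clustered": 0,
                        "n_scattered": 0,
                    }
                )
    metadata = pd.DataFrame(meta_rows)
    truth_table = pd.DataFrame(truth_rows)
    return catalogs, metadata, truth_table


def write_fasta(genome: ReferenceGenome, path, width: int = 80) -> None:
    """Write the genome as plain FASTA with fixed line width (deterministic
    bytes for identical genomes)."""
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
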