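"""Reference-genome access, context-window extraction and IUPAC pattern counting.

Every enrichment computation in this package is local: the abundance of a
motif is measured in the +/-20 bp of sequence surrounding each mutated base,
so that the denominator of the enrichment ratio reflects the part of the
genome that was actually sequenced and called in a given sample.  This
module provides the small set of sequence primitives that the rest of the
pipeline builds on:

* :class:`ReferenceGenome` — an in-memory genome restricted to {A,C,G,T,N};
* :func:`extract_window` — the context window around a mutated position;
* :func:`count_pattern` — double-stranded, overlap-aware IUPAC pattern
  counting (the ``Context`` terms of the enrichment ratio);
* :func:`canonical_substitution` — pyrimidine-canonical trinucleotide
  substitution naming (the 96-channel convention).

Coordinates are 1-based at every public surface (matching MAF/VCF); slicing
into contig strings is the only place 0-based arithmetic happens.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, Iterator, Mapping

from Bio import SeqIO

__all__ = [
    "IUPAC_SETS",
    "ReferenceGenome",
    "ContextWindow",
    "load_genome",
    "extract_window",
    "reverse_complement",
    "count_pattern",
    "canonical_substitution",
]

#: IUPAC nucleotide codes mapped to the set of concrete bases they denote.
#: N deliberately denotes {A,C,G,T}: an ambiguous reference base (N) never
#: satisfies any pattern position, including ``n`` itself.
IUPAC_SETS: Mapping[str, frozenset] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}
_COMPLEMENT_TABLE = str.maketrans(
    {**_COMPLEMENT, **{k.lower(): v.lower() for k, v in _COMPLEMENT.items()}}
)
_VALID_CHARS = frozenset(_COMPLEMENT) | frozenset(c.lower() for c in _COMPLEMENT)

_NON_ACGTN = re.compile(r"[^ACGTN]")


class ReferenceGenome:
    """An in-memory reference genome over the alphabet {A,C,G,T,N}.

    Contig sequences are stored uppercase; any character outside ACGTN is
    normalized to N at load time.  Lookups outside ``[1, len(contig)]``
    raise ``ValueError``.
    """

    def __init__(self, contigs: Mapping[str, str]):
        if not contigs:
            raise ValueError("genome must contain at least one contig")
        normalized: Dict[str, str] = {}
        for name, seq in contigs.items():
            seq = _NON_ACGTN.sub("N", str(seq).upper())
            if not seq:
                raise ValueError(f"contig {name!r} is empty")
            normalized[name] = seq
        self._contigs = normalized

    @property
    def contigs(self) -> Mapping[str, str]:
        return self._contigs

    def __contains__(self, name: str) -> bool:
        return name in self._contigs

    def __iter__(self) -> Iterator[str]:
        return iter(self._contigs)

    def __len__(self) -> int:
        return len(self._contigs)

    def length(self, contig: str) -> int:
        return len(self.sequence(contig))

    def sequence(self, contig: str) -> str:
        try:
            return self._contigs[contig]
        except KeyError:
            raise KeyError(f"unknown contig {contig!r}") from None

    def base(self, contig: str, pos: int) -> str:
        """Reference base at a 1-based position."""
        seq = self.sequence(contig)
        if not 1 <= pos <= len(seq):
            raise ValueError(
                f"position {pos} outside [1, {len(seq)}] on contig {contig!r}"
            )
        return seq[pos - 1]

    def reverse_complemented(self) -> "ReferenceGenome":
        """Genome with every contig reverse-complemented (used by the
        strand-symmetry checks)."""
        return ReferenceGenome(
            {name: reverse_complement(seq) for name, seq in self._contigs.items()}
        )


@dataclass(frozen=True)
class ContextWindow:
    """Sequence window around one mutated base.

    ``center_offset`` is the 0-based index of the mutated base within
    ``sequence``; the base at that index equals the mutation's reference
    base.  Windows are truncated (never padded) at contig edges.
    """

    sequence: str
    center_offset: int

    def __post_init__(self):
        if not 0 <= self.center_offset < len(self.sequence):
            raise ValueError("center_offset outside window")

    @property
    def center_base(self) -> str:
        return self.sequence[self.center_offset]


def load_genome(path) -> ReferenceGenome:
    """Read a (plain or gzip-less) FASTA file into a :class:`ReferenceGenome`.

    Sequences are uppercased and non-ACGTN characters mapped to N.
    Raises on a missing/empty file or duplicate contig names.
    """
    contigs: Dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in contigs:
            raise ValueError(f"duplicate contig name {record.id!r} in {path}")
        contigs[record.id] = str(record.seq)
    if not contigs:
        raise ValueError(f"no FASTA records found in {path}")
    return ReferenceGenome(contigs)


def extract_window(
    genome: ReferenceGenome, contig: str, pos: int, flank: int = 20
) -> ContextWindow:
    """Context window of ``+/-flank`` bases around a 1-based position.

    At contig edges the window is truncated to the available sequence.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    seq = genome.sequence(contig)
    if not 1 <= pos <= len(seq):
        raise ValueError(
            f"position {pos} outside [1, {len(seq)}] on contig {contig!r}"
        )
    start = max(1, pos - flank)
    end = min(len(seq), pos + flank)
    return ContextWindow(sequence=seq[start - 1 : end], center_offset=pos - start)


def reverse_complement(seq: str) -> str:
    """Reverse complement; defined for the full (case-preserving) IUPAC
    alphabet and an involution on it."""
    bad = set(seq) - _VALID_CHARS
    if bad:
        raise ValueError(f"cannot complement characters {sorted(bad)!r}")
    return seq.translate(_COMPLEMENT_TABLE)[::-1]


@lru_cache(maxsize=512)
def _pattern_regex(pattern: str) -> "re.Pattern[str]":
    """Compile an IUPAC pattern into an overlap-counting regex.

    Character classes contain concrete bases only, so reference N never
    matches any position.  A lookahead makes overlapping matches count.
    """
    if not pattern:
        raise ValueError("empty pattern")
    parts = []
    for ch in pattern:
        try:
            bases = IUPAC_SETS[ch.upper()]
        except KeyError:
            raise ValueError(f"invalid IUPAC character {ch!r} in {pattern!r}") from None
        sorted_bases = "".join(sorted(bases))
        parts.append(sorted_bases if len(sorted_bases) == 1 else f"[{sorted_bases}]")
    return re.compile("(?=" + "".join(parts) + ")")


def count_pattern(window, pattern: str) -> int:
    """Occurrences of an IUPAC pattern in a window, both strands.

    Counts (overlapping) matches in the forward sequence plus matches in its
    reverse complement, mirroring the double-stranded ``Context`` terms of
    the enrichment ratio.  Accepts a :class:`ContextWindow` or a bare string.
    """
    seq = window.sequence if isinstance(window, ContextWindow) else str(window)
    seq = seq.upper()
    rx = _pattern_regex(pattern)
    return len(rx.findall(seq)) + len(rx.findall(reverse_complement(seq)))


def canonical_substitution(
    ref: str, alt: str, five_prime: str, three_prime: str
) -> str:
    """Pyrimidine-canonical trinucleotide substitution, e.g. ``"aTg>aCg"``.

    If the reference base is a purine the whole triplet and both alleles are
    reverse-complemented so the mutated base is reported as C or T; the
    mutated base is uppercase, the flanks lowercase.
    """
    for name, b in (("ref", ref), ("alt", alt),
                    ("five_prime", five_prime), ("three_prime", three_prime)):
        if b not in ("A", "C", "G", "T"):
            raise ValueError(f"{name} must be one of A,C,G,T, got {b!r}")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    if ref in "AG":  # purine: report the pyrimidine of the base pair
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        five_prime, three_prime = _COMPLEMENT[three_prime], _COMPLEMENT[five_prime]
    f, t = five_prime.lower(), three_prime.lower()
    return f"{f}{ref}{t}>{f}{alt}{t}"
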