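"""Knowledge-based mutational motifs and IUPAC matching semantics.

A mutational motif is a short IUPAC pattern with one designated mutated
base (written uppercase, always a pyrimidine in canonical storage) and a
set of allowed mutant bases.  Motifs encode the sequence preference of a
known mutagenic mechanism: for example ``aTn->aCn`` (T->C preceded by A) is
the preference of small-epoxide / S_N_2-electrophile mutagenesis, while
``nCg->nTg`` is spontaneous deamination of methylated CpG.

Matching is strand-aware: a mutation on the purine strand (e.g. A->G) is
evaluated on the reverse complement, so ``aTn`` matches a forward ``...C A
T...`` A->G call.  Sub-motifs (``aTr`` inside ``aTn``, ``rCg``/``yCg``
inside ``nCg``, ``ytCa``/``rtCa`` inside ``tCw``) restrict an ambiguous
motif to the part not shared with a confounding mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Tuple

import pandas as pd

from .genome import IUPAC_SETS, ContextWindow, _COMPLEMENT, reverse_complement

__all__ = [
    "MutationMotif",
    "MotifRegistry",
    "builtin_registry",
    "mutation_matches",
    "substitution_in_class",
]

_PYRIMIDINES = ("C", "T")


@dataclass(frozen=True)
class MutationMotif:
    """One mutational motif, stored pyrimidine-canonical.

    Parameters
    ----------
    name:
        Short label, e.g. ``"aTn"`` or ``"tCw>tGw"``.
    ref_pattern:
        IUPAC pattern with exactly one uppercase letter (C or T) marking
        the mutated position; flanking positions are lowercase IUPAC codes.
    mutant_bases:
        Allowed alternate bases at the mutated position (on the pyrimidine
        strand), disjoint from the reference pyrimidine.
    mechanism:
        Free-text mechanism annotation (optional).
    """

    name: str
    ref_pattern: str
    mutant_bases: frozenset
    mechanism: str = ""

    def __post_init__(self):
        uppers = [i for i, c in enumerate(self.ref_pattern) if c.isupper()]
        if len(uppers) != 1:
            raise ValueError(
                f"{self.name}: ref_pattern must have exactly one uppercase letter"
            )
        center = self.ref_pattern[uppers[0]]
        if center not in _PYRIMIDINES:
            raise ValueError(f"{self.name}: mutated base must be C or T (canonical)")
        for c in self.ref_pattern:
            if c.upper() not in IUPAC_SETS:
                raise ValueError(f"{self.name}: invalid IUPAC character {c!r}")
        mb = frozenset(str(b).upper() for b in self.mutant_bases)
        if not mb or not mb <= frozenset("ACGT"):
            raise ValueError(f"{self.name}: mutant_bases must be a nonempty ACGT set")
        if center in mb:
            raise ValueError(f"{self.name}: mutant_bases must exclude the ref base")
        object.__setattr__(self, "mutant_bases", mb)

    @property
    def center_index(self) -> int:
        return next(i for i, c in enumerate(self.ref_pattern) if c.isupper())

    @property
    def center_base(self) -> str:
        """Reference pyrimidine at the mutated position (C or T)."""
        return self.ref_pattern[self.center_index]

    @property
    def context_pattern(self) -> str:
        """Lowercase version of the pattern: the Context term of enrichment."""
        return self.ref_pattern.lower()

    @property
    def substitution_class(self) -> Tuple[Tuple[str, str], ...]:
        """Pyrimidine-canonical (ref, alt) substitution pairs."""
        return tuple((self.center_base, b) for b in sorted(self.mutant_bases))


def substitution_in_class(motif: MutationMotif, ref: str, alt: str) -> bool:
    """True if ``ref->alt`` (or its reverse complement) is one of the motif's
    substitutions — the ``Mutations(T->C)``-style class denominator."""
    if ref == alt:
        raise ValueError("ref and alt must differ")
    if ref == motif.center_base:
        return alt in motif.mutant_bases
    if _COMPLEMENT[ref] == motif.center_base:
        return _COMPLEMENT[alt] in motif.mutant_bases
    return False


def mutation_matches(
    motif: MutationMotif, window: ContextWindow, ref: str, alt: str
) -> bool:
    """True if the mutation at the window center matches the motif.

    The test is performed on whichever strand maps ``ref`` onto the motif's
    canonical pyrimidine; flanking bases must satisfy the IUPAC pattern on
    that strand and the strand-adjusted alt must be an allowed mutant base.
    Windows too short to cover the pattern span (contig edges) do not match.
    """
    if ref == motif.center_base:
        seq, idx, alt_c = window.sequence, window.center_offset, alt
    elif _COMPLEMENT.get(ref) == motif.center_base:
        seq = reverse_complement(window.sequence)
        idx = len(window.sequence) - 1 - window.center_offset
        alt_c = _COMPLEMENT[alt]
    else:
        return False
    if alt_c not in motif.mutant_bases:
        return False
    start = idx - motif.center_index
    if start < 0 or start + len(motif.ref_pattern) > len(seq):
        return False
    return all(
        seq[start + i] in IUPAC_SETS[c.upper()]
        for i, c in enumerate(motif.ref_pattern)
    )


class MotifRegistry:
    """Ordered collection of :class:`MutationMotif`, unique by name."""

    def __init__(self, motifs: Optional[List[MutationMotif]] = None):
        self._motifs: Dict[str, MutationMotif] = {}
        for m in motifs or []:
            self.add(m)

    def add(self, motif: MutationMotif) -> None:
        if motif.name in self._motifs:
            raise ValueError(f"duplicate motif name {motif.name!r}")
        self._motifs[motif.name] = motif

    def get(self, name: str) -> MutationMotif:
        try:
            return self._motifs[name]
        except KeyError:
            raise KeyError(f"unknown motif {name!r}") from None

    def names(self) -> List[str]:
        return list(self._motifs)

    def subset(self, names) -> "MotifRegistry":
        return MotifRegistry([self.get(n) for n in names])

    def __iter__(self) -> Iterator[MutationMotif]:
        return iter(self._motifs.values())

    def __len__(self) -> int:
        return len(self._motifs)

    def __contains__(self, name: str) -> bool:
        return name in self._motifs

    # -- serialization ----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "name": m.name,
                    "ref_pattern": m.ref_pattern,
                    "mutant_bases": "".join(sorted(m.mutant_bases)),
                    "mechanism": m.mechanism,
                }
                for m in self
            ]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MotifRegistry":
        required = {"name", "ref_pattern", "mutant_bases"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"motif config missing columns {sorted(missing)}")
        motifs = [
            MutationMotif(
                name=row["name"],
                ref_pattern=row["ref_pattern"],
                mutant_bases=frozenset(str(row["mutant_bases"])),
                mechanism=str(row.get("mechanism", "") or ""),
            )
            for _, row in df.iterrows()
        ]
        return cls(motifs)

    @classmethod
    def from_tsv(cls, path) -> "MotifRegistry":
        return cls.from_frame(pd.read_csv(path, sep="\t", dtype=str).fillna(""))


def builtin_registry() -> MotifRegistry:
    """The default registry of knowledge-derived motifs.

    Contains the eleven primary motifs (epoxide/S_N_2 ``aTn``, UV ``yCn``
    and minor-UV ``nTt``, meCpG ``nCg``, APOBEC ``tCw>tTw``/``tCw>tGw``,
    redox ``tgC``, S_N_2-alkylation ``hTg``, S_N_1-alkylation ``aCy``,
    acetaldehyde ``gCn``, aristolactam ``cTg``), the four disambiguating
    sub-motifs (``aTr``, ``rCg``, ``yCg``, ``yCh``), the combined APOBEC
    motif ``tCw`` (C->T plus C->G) and the APOBEC3A/3B tetranucleotides
    ``ytCa``/``rtCa``.
    """
    M = MutationMotif
    return MotifRegistry(
        [
            M("aTn", "aTn", frozenset("C"), "epoxide / S_N_2 electrophiles"),
            M("yCn", "yCn", frozenset("T"), "UV"),
            M("nCg", "nCg", frozenset("T"), "spontaneous meCpG deamination"),
            M("nTt", "nTt", frozenset("C"), "UV (minor)"),
            M("tCw>tTw", "tCw", frozenset("T"), "APOBEC"),
            M("tCw>tGw", "tCw", frozenset("G"), "APOBEC"),
            M("tgC", "tgC", frozenset("A"), "redox"),
            M("hTg", "hTg", frozenset("G"), "S_N_2 alkylation"),
            M("aCy", "aCy", frozenset("T"), "S_N_1 alkylation"),
            M("gCn", "gCn", frozenset("A"), "acetaldehyde"),
            M("cTg", "cTg", frozenset("A"), "aristolactam"),
            # sub-motifs used to disentangle overlapping mechanisms
            M("aTr", "aTr", frozenset("C"), "epoxide sub-motif (excludes nTt)"),
            M("rCg", "rCg", frozenset("T"), "meCpG sub-motif (excludes UV)"),
            M("yCg", "yCg", frozenset("T"), "meCpG/UV-shared sub-motif"),
            M("yCh", "yCh", frozenset("T"), "UV sub-motif (excludes CpG)"),
            # combined APOBEC motif and A3A/A3B tetranucleotides
            M("tCw", "tCw", frozenset("GT"), "APOBEC combined (C->T | C->G)"),
            M("ytCa", "ytCa", frozenset("GT"), "APOBEC3A-like"),
            M("rtCa", "rtCa", frozenset("GT"), "APOBEC3B-like"),
        ]
    )
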