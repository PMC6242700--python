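"""Codon-level feasibility of amino-acid exchanges.

A protein mutation is realized by one, two, or three base exchanges within the
wild-type codon.  This module maps residue positions to their coding-strand
codons with one flanking base on each side, enumerates every 1- and 2-base
path from the wild-type codon to any codon of the target amino acid (standard
genetic code, translation table 1), and classifies the exchange as SPM, DPM,
TPM or synonymous by the minimum Hamming distance.  Triple-point mutations —
all three codon bases changed — are discarded downstream as biologically
implausible.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from itertools import combinations

from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "Feasibility",
    "CodonContext",
    "BaseChange",
    "MutationPath",
    "PathSet",
    "CodonError",
    "AA_TO_CODONS",
    "SENSE_CODONS",
    "extract_codon_context",
    "enumerate_paths",
    "classify_feasibility",
]

BASES = "ACGT"

#: codon -> one-letter amino acid, 61 sense codons (standard code)
CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    AA_TO_CODONS.setdefault(_aa, ())
    AA_TO_CODONS[_aa] += (_codon,)

AMINO_ACIDS = frozenset(AA_TO_CODONS)  # the 20 standard residues


class CodonError(ValueError):
    """Codon addressing or consistency failure."""


class Feasibility(enum.Enum):
    """Mutational feasibility class by minimum number of base exchanges."""

    SYNONYMOUS = 0
    SPM = 1
    DPM = 2
    TPM = 3


def classify_feasibility(min_changes: int) -> Feasibility:
    if min_changes not in (0, 1, 2, 3):
        raise ValueError(f"min_changes must be 0..3, got {min_changes}")
    return Feasibility(min_changes)


@dataclass(frozen=True)
class CodonContext:
    """A residue's coding-strand codon with its 5' and 3' flanking bases."""

    position: int
    codon: str
    flank5: str
    flank3: str
    offset: int = 1

    def __post_init__(self) -> None:
        for name, seq in (("codon", self.codon), ("flank5", self.flank5), ("flank3", self.flank3)):
            if any(b not in BASES for b in seq):
                raise CodonError(f"{name} contains non-ACGT base: {seq!r}")
        if len(self.codon) != 3 or len(self.flank5) != 1 or len(self.flank3) != 1:
            raise CodonError("codon must be 3 bases, flanks 1 base each")

    @property
    def wt_aa(self) -> str:
        try:
            return CODON_TO_AA[self.codon]
        except KeyError:
            raise CodonError(f"codon {self.codon!r} is a stop codon") from None

    @property
    def padded(self) -> str:
        """flank5 + codon + flank3 (5 bases); change at codon offset j has
        trinucleotide context padded[j:j+3]."""
        return self.flank5 + self.codon + self.flank3


def extract_codon_context(
    cds: str, position: int, offset: int = 1, wt_aa: str | None = None
) -> CodonContext:
    """Slice the codon and flanking bases for a residue out of the CDS.

    ``offset`` maps residue numbering to codon index: codon k = position -
    offset, so with the default offset 1 residue 1 is the first codon.  The
    first and last codons of the CDS have no flank and raise rather than
    being silently padded.
    """
    cds = cds.upper()
    if any(b not in BASES for b in cds):
        raise CodonError("CDS contains non-ACGT characters")
    k = position - offset
    start = 3 * k
    if start - 1 < 0 or start + 4 > len(cds):
        raise CodonError(
            f"residue {position} (codon index {k}) with one flanking base on "
            f"each side does not fit in a CDS of length {len(cds)}"
        )
    ctx = CodonContext(
        position=position,
        codon=cds[start : start + 3],
        flank5=cds[start - 1],
        flank3=cds[start + 3],
        offset=offset,
    )
    if wt_aa is not None and ctx.wt_aa != wt_aa:
        raise CodonError(
            f"residue {position}: codon {ctx.codon} translates to "
            f"{ctx.wt_aa}, not the claimed {wt_aa}"
        )
    return ctx


@dataclass(frozen=True)
class BaseChange:
    """A single base exchange within a codon, with its trinucleotide context
    taken from the wild-type sequence."""

    codon_offset: int  # 0..2
    ref_base: str
    alt_base: str
    tri_context: str  # 3 bases centered on the changed base

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise CodonError("ref_base must differ from alt_base")
        if self.tri_context[1] != self.ref_base:
            raise CodonError(
                f"tri_context {self.tri_context!r} center must be ref_base "
                f"{self.ref_base!r}"
            )


@dataclass(frozen=True)
class MutationPath:
    """One combination of base exchanges converting the WT codon into one
    codon of the target amino acid.  DPM change pairs are unordered."""

    changes: tuple[BaseChange, ...]
    target_codon: str

    @property
    def n_changes(self) -> int:
        return len(self.changes)


@dataclass(frozen=True)
class PathSet:
    """All 1- and 2-base paths to an amino acid, plus the minimum Hamming
    distance over all of its codons (3 means triple-point, no paths)."""

    paths: tuple[MutationPath, ...]
    min_changes: int

    @property
    def n_spm_paths(self) -> int:
        return sum(1 for p in self.paths if p.n_changes == 1)

    @property
    def n_dpm_paths(self) -> int:
        return sum(1 for p in self.paths if p.n_changes == 2)


def enumerate_paths(ctx: CodonContext, mut_aa: str) -> PathSet:
    """Enumerate every 1- and 2-base route from the WT codon to ``mut_aa``.

    For each codon of the target amino acid at Hamming distance 1 or 2 from
    the wild-type codon, one path is emitted (a distance-2 path carries its
    two changes as an unordered pair; both trinucleotide contexts are read
    off the wild-type sequence).  Codons at distance 3 contribute no path.
    ``min_changes`` is 0 when the target amino acid equals the wild type.
    """
    if mut_aa not in AMINO_ACIDS:
        raise CodonError(f"invalid amino acid {mut_aa!r}")
    padded = ctx.padded
    wt_codon = ctx.codon
    paths: list[MutationPath] = []
    min_changes = 3
    for target in AA_TO_CODONS[mut_aa]:
        diff = [j for j in range(3) if wt_codon[j] != target[j]]
        d = len(diff)
        min_changes = min(min_changes, d)
        if d == 0 or d == 3:
            continue
        changes = tuple(
            BaseChange(
                codon_offset=j,
                ref_base=wt_codon[j],
                alt_base=target[j],
                tri_context=padded[j : j + 3],
            )
            for j in diff
        )
        paths.append(MutationPath(changes=changes, target_codon=target))
    return PathSet(paths=tuple(paths), min_changes=min_changes)
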