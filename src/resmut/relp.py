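"""Relative probability (relP) of amino-acid exchanges and relP ranking.

relP sums, over every 1- and 2-base codon path realizing an amino-acid
exchange, the product of the per-base-exchange probabilities drawn from the
cancer type's pSPM table:

    relP = sum_paths  pSPM_1           (single-base path)
         | sum_paths  pSPM_1 * pSPM_2  (two-base path)

relP is a *relative* quantity: only its ordering within one pSPM table is
meaningful, so rankings are invariant under rescaling the whole table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from .codons import (
    CodonContext,
    Feasibility,
    MutationPath,
    classify_feasibility,
    enumerate_paths,
)
from .signatures import PSPMTable, lookup_pspm

__all__ = ["RelPResult", "RelPUnavailableError", "compute_relp", "rank_by_relp"]

ContextMode = Literal["wt", "sequential"]


class RelPUnavailableError(RuntimeError):
    """No pSPM table for the cancer type: relP cannot be computed (it is a
    missing value, not zero)."""


@dataclass
class RelPResult:
    position: int
    wt_aa: str
    mut_aa: str
    relp: float
    n_spm_paths: int
    n_dpm_paths: int
    per_path: list[tuple[MutationPath, float]] = field(default_factory=list)

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.position, self.wt_aa, self.mut_aa)

    @property
    def spm_part(self) -> float:
        return sum(c for p, c in self.per_path if p.n_changes == 1)

    @property
    def dpm_part(self) -> float:
        return sum(c for p, c in self.per_path if p.n_changes == 2)


def _dpm_contribution(
    ctx: CodonContext, path: MutationPath, table: PSPMTable, mode: ContextMode
) -> float:
    """Contribution of a two-base path.

    In "wt" mode both exchanges take their trinucleotide context from the
    wild-type sequence.  In "sequential" mode the second exchange's context
    is recomputed after applying the first, averaged over both orderings
    (the two events have no defined order).
    """
    a, b = path.changes
    if mode == "wt":
        return lookup_pspm(table, a.tri_context, a.ref_base, a.alt_base) * lookup_pspm(
            table, b.tri_context, b.ref_base, b.alt_base
        )
    padded = ctx.padded
    total = 0.0
    for first, second in ((a, b), (b, a)):
        p1 = lookup_pspm(table, first.tri_context, first.ref_base, first.alt_base)
        intermediate = (
            padded[: first.codon_offset + 1]
            + first.alt_base
            + padded[first.codon_offset + 2 :]
        )
        ctx2 = intermediate[second.codon_offset : second.codon_offset + 3]
        total += p1 * lookup_pspm(table, ctx2, second.ref_base, second.alt_base)
    return total / 2.0


def compute_relp(
    ctx: CodonContext,
    mut_aa: str,
    table: PSPMTable | None,
    *,
    context_mode: ContextMode = "wt",
    minimal_only: bool = False,
) -> RelPResult:
    """relP of the exchange ``ctx.wt_aa -> mut_aa`` under a pSPM table.

    ``minimal_only`` restricts the sum to paths of the minimum length
    (sensitivity analysis); by default all 1- and 2-base paths contribute.

    Raises
    ------
    RelPUnavailableError
        ``table`` is None (no signatures for the cancer type).
    ValueError
        The exchange is synonymous or a triple-point mutation.
    """
    if table is None:
        raise RelPUnavailableError(
            "no pSPM table available; relP cannot be computed"
        )
    path_set = enumerate_paths(ctx, mut_aa)
    feas = classify_feasibility(path_set.min_changes)
    if feas in (Feasibility.TPM, Feasibility.SYNONYMOUS):
        raise ValueError(
            f"relP undefined for {feas.name} exchange "
            f"{ctx.wt_aa}{ctx.position}{mut_aa}"
        )
    paths: Iterable[MutationPath] = path_set.paths
    if minimal_only:
        paths = [p for p in path_set.paths if p.n_changes == path_set.min_changes]
    per_path: list[tuple[MutationPath, float]] = []
    for path in paths:
        if path.n_changes == 1:
            chg = path.changes[0]
            contrib = lookup_pspm(table, chg.tri_context, chg.ref_base, chg.alt_base)
        else:
            contrib = _dpm_contribution(ctx, path, table, context_mode)
        per_path.append((path, contrib))
    return RelPResult(
        position=ctx.position,
        wt_aa=ctx.wt_aa,
        mut_aa=mut_aa,
        relp=sum(c for _, c in per_path),
        n_spm_paths=sum(1 for p, _ in per_path if p.n_changes == 1),
        n_dpm_paths=sum(1 for p, _ in per_path if p.n_changes == 2),
        per_path=per_path,
    )


def rank_by_relp(results: Sequence[RelPResult]) -> list[tuple[int, RelPResult]]:
    """Rank results by descending relP with competition ranks (1, 2, 2, 4).

    Ties share a rank; within a tie the order is (position, mut_aa) for
    reproducibility.
    """
    ordered = sorted(results, key=lambda r: (-r.relp, r.position, r.mut_aa))
    ranked: list[tuple[int, RelPResult]] = []
    for i, res in enumerate(ordered):
        if i > 0 and res.relp == ordered[i - 1].relp:
            rank = ranked[-1][0]
        else:
            rank = i + 1
        ranked.append((rank, res))
    return ranked
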