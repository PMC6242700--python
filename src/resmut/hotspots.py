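"""Resistance hotspots: per-residue aggregation, ranking, and prioritization.

A resistance hotspot is a residue position where multiple distinct viable
mutations are predicted to confer resistance; the more independent mutational
routes to resistance a position offers, the more likely it is functionally
relevant.  Hotspots are ranked by their number of surviving mutants with
competition ranks (ties share a rank: 1, 2, 2, 4).  Prioritization then takes
every hotspot ranked <= k — all residues tied at the k-th rank included — and
within each the top m mutations by relP, reproducing the default "top 3
hotspots x top 3 mutations" shortlist of at most ~9 candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .relp import RelPResult, rank_by_relp

__all__ = [
    "MutationCandidate",
    "Hotspot",
    "HotspotReport",
    "identify_hotspots",
    "prioritize",
]


@dataclass
class MutationCandidate:
    """A surviving mutant, optionally annotated with relP and its relP rank
    within its hotspot."""

    position: int
    wt_aa: str
    mut_aa: str
    relp: float | None = None
    relp_rank: int | None = None

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.position, self.wt_aa, self.mut_aa)

    @property
    def label(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"


@dataclass
class Hotspot:
    position: int
    wt_aa: str
    n_resistant_mutants: int
    rank: int
    mutations: list[MutationCandidate] = field(default_factory=list)


@dataclass
class HotspotReport:
    drug_id: str
    target_id: str
    cancer_type: str
    hotspots: list[Hotspot]
    prioritized: list[MutationCandidate]
    relp_available: bool
    k: int = 3
    m: int = 3

    def as_dict(self) -> dict:
        return {
            "drug_id": self.drug_id,
            "target_id": self.target_id,
            "cancer_type": self.cancer_type,
            "relp_available": self.relp_available,
            "k": self.k,
            "m": self.m,
            "hotspots": [
                {
                    "rank": h.rank,
                    "position": h.position,
                    "wt_aa": h.wt_aa,
                    "n_mutations": h.n_resistant_mutants,
                    "mutations": [
                        {
                            "mutation": m.label,
                            "relp": m.relp,
                            "relp_rank": m.relp_rank,
                        }
                        for m in h.mutations
                    ],
                }
                for h in self.hotspots
            ],
            "prioritized": [
                {"mutation": m.label, "relp": m.relp, "relp_rank": m.relp_rank}
                for m in self.prioritized
            ],
        }


def identify_hotspots(
    survivors: Sequence[tuple[int, str, str]],
) -> list[Hotspot]:
    """Group surviving mutants by residue and rank positions by mutant count.

    Returns one hotspot per residue with at least one survivor, sorted by
    descending count (ties share a competition rank, ordered by position
    within a tie).  An empty survivor set yields an empty list.
    """
    by_pos: dict[tuple[int, str], list[MutationCandidate]] = {}
    for position, wt_aa, mut_aa in survivors:
        by_pos.setdefault((position, wt_aa), []).append(
            MutationCandidate(position=position, wt_aa=wt_aa, mut_aa=mut_aa)
        )
    entries = sorted(
        by_pos.items(), key=lambda kv: (-len(kv[1]), kv[0][0])
    )
    hotspots: list[Hotspot] = []
    for i, ((position, wt_aa), muts) in enumerate(entries):
        if i > 0 and len(muts) == len(entries[i - 1][1]):
            rank = hotspots[-1].rank
        else:
            rank = i + 1
        hotspots.append(
            Hotspot(
                position=position,
                wt_aa=wt_aa,
                n_resistant_mutants=len(muts),
                rank=rank,
                mutations=sorted(muts, key=lambda m: m.mut_aa),
            )
        )
    return hotspots


def prioritize(
    hotspots: Sequence[Hotspot],
    relp_results: Mapping[tuple[int, str, str], RelPResult] | None,
    *,
    drug_id: str = "",
    target_id: str = "",
    cancer_type: str = "",
    k: int = 3,
    m: int = 3,
) -> HotspotReport:
    """Shortlist the top mutations of the top hotspots.

    Every hotspot with rank <= k is retained (all residues tied at the k-th
    rank included, as the per-target summary tables do).  Within each
    retained hotspot, mutations are ranked by relP (competition ranks) and
    the top m progressed.  When ``relp_results`` is None — no mutational
    signatures for the cancer type — mutations carry no relP rank and the
    first m in alphabetical order are listed per hotspot.
    """
    if k < 1 or m < 1:
        raise ValueError(f"k and m must be >= 1, got k={k}, m={m}")
    relp_available = relp_results is not None
    selected = [h for h in hotspots if h.rank <= k]
    prioritized: list[MutationCandidate] = []
    for hotspot in selected:
        if relp_available:
            results = []
            for mut in hotspot.mutations:
                res = relp_results.get(mut.key)
                if res is None:
                    raise KeyError(f"no relP result for survivor {mut.label}")
                results.append(res)
            ranked = rank_by_relp(results)
            annotated = []
            for rank, res in ranked:
                annotated.append(
                    MutationCandidate(
                        position=res.position,
                        wt_aa=res.wt_aa,
                        mut_aa=res.mut_aa,
                        relp=res.relp,
                        relp_rank=rank,
                    )
                )
            hotspot.mutations = annotated
            prioritized.extend(annotated[:m])
        else:
            prioritized.extend(hotspot.mutations[:m])
    return HotspotReport(
        drug_id=drug_id,
        target_id=target_id,
        cancer_type=cancer_type,
        hotspots=list(hotspots),
        prioritized=prioritized,
        relp_available=relp_available,
        k=k,
        m=m,
    )
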