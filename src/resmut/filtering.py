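"""Resistance cutoff, per-mutant affinity classification, and the filter cascade.

The cutoff for one (drug, endogenous ligand) pair is

    cutoff = log10(avwt_endogenous / avwt_drug) + range_wt

where ``range_wt`` is the spread (max - min) of the per-run wild-type
log-ratios: the method's intrinsic variation allowance for the input
structure.  A mutant is affinity-resistant when its own log10 K* ratio
(endogenous over drug) strictly exceeds the cutoff for *every* endogenous
ligand.  Mutants with a K* score of 0 for any endogenous ligand are unfit
(the clone loses its function) and are discarded, never reported resistant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .codons import Feasibility
from .kstar import LogicalMutant, WTStatsResult

__all__ = [
    "CutoffModel",
    "AffinityVerdict",
    "AttritionSummary",
    "CascadeResult",
    "compute_cutoff",
    "compute_cutoffs",
    "classify_mutant",
    "apply_cascade",
]


@dataclass(frozen=True)
class CutoffModel:
    """Resistance cutoff for one drug / endogenous-ligand pair."""

    drug_id: str
    endogenous_id: str
    log_ratio_avwt: float
    range_wt: float
    cutoff: float

    def __post_init__(self) -> None:
        if self.range_wt < 0:
            raise ValueError(f"range_wt must be >= 0, got {self.range_wt}")
        if not math.isclose(
            self.cutoff, self.log_ratio_avwt + self.range_wt, abs_tol=1e-12
        ):
            raise ValueError("cutoff must equal log_ratio_avwt + range_wt")


def compute_cutoff(
    wt: WTStatsResult, endogenous_id: str, drug_id: str
) -> CutoffModel:
    """Build the cutoff model from wild-type statistics.

    ``range_wt`` is max - min of the paired per-run WT log-ratios; with a
    single WT run it is exactly 0 and the cutoff reduces to the avwt
    log-ratio.
    """
    stats_e = wt.stats[endogenous_id]
    stats_d = wt.stats[drug_id]
    if stats_e.avwt <= 0 or stats_d.avwt <= 0:
        raise ValueError("avwt must be positive for both ligands")
    ratios = wt.pair_log_ratios[(endogenous_id, drug_id)]
    if not ratios:
        raise ValueError("no paired WT log-ratios available")
    log_ratio_avwt = math.log10(stats_e.avwt / stats_d.avwt)
    range_wt = max(ratios.values()) - min(ratios.values())
    return CutoffModel(
        drug_id=drug_id,
        endogenous_id=endogenous_id,
        log_ratio_avwt=log_ratio_avwt,
        range_wt=range_wt,
        cutoff=log_ratio_avwt + range_wt,
    )


def compute_cutoffs(wt: WTStatsResult, drug_id: str) -> dict[str, CutoffModel]:
    """One CutoffModel per endogenous ligand for the given drug."""
    endo_ids = sorted(l for l, r in wt.roles.items() if r == "endogenous")
    if not endo_ids:
        raise ValueError("no endogenous ligand in WT statistics")
    return {e: compute_cutoff(wt, e, drug_id) for e in endo_ids}


@dataclass
class AffinityVerdict:
    """Classification of one logical mutant against the cutoff(s).

    ``log_kstar_ratio`` is the minimum over endogenous ligands of
    log10(K*_endogenous / K*_drug) (the binding constraint is the weakest
    ratio); +inf when the drug score is 0 for a fit mutant.  For His mutants
    the verdict is the AND over protonation variants.
    """

    position: int
    wt_aa: str
    mut_aa: str
    log_kstar_ratio: float
    fit: bool
    affinity_resistant: bool
    per_endogenous: dict[str, tuple[float, bool]] = field(default_factory=dict)

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.position, self.wt_aa, self.mut_aa)


def _classify_single(
    scores: Mapping[str, float],
    cutoffs: Mapping[str, CutoffModel],
    drug_id: str,
) -> tuple[float, bool, bool, dict[str, tuple[float, bool]]]:
    """Classify one variant score set; returns (ratio, fit, resistant, detail)."""
    if drug_id not in scores:
        raise KeyError(f"missing drug score for ligand {drug_id!r}")
    for endo in cutoffs:
        if endo not in scores:
            raise KeyError(f"missing endogenous score for ligand {endo!r}")
    drug_score = scores[drug_id]
    fit = all(scores[endo] > 0 for endo in cutoffs)
    detail: dict[str, tuple[float, bool]] = {}
    if not fit:
        for endo in cutoffs:
            ratio = (
                -math.inf
                if scores[endo] == 0
                else (
                    math.inf
                    if drug_score == 0
                    else math.log10(scores[endo] / drug_score)
                )
            )
            detail[endo] = (ratio, False)
        return (min(r for r, _ in detail.values()), False, False, detail)
    resistant = True
    for endo, model in cutoffs.items():
        if drug_score == 0:
            ratio = math.inf
            verdict = True
        else:
            ratio = math.log10(scores[endo] / drug_score)
            verdict = ratio > model.cutoff  # strict: ties are sensitive
        detail[endo] = (ratio, verdict)
        resistant = resistant and verdict
    return (min(r for r, _ in detail.values()), True, resistant, detail)


def classify_mutant(
    mutant: LogicalMutant | Mapping[str, float],
    cutoffs: Mapping[str, CutoffModel],
    drug_id: str,
    *,
    position: int = 0,
    wt_aa: str = "",
    mut_aa: str = "",
) -> AffinityVerdict:
    """Classify a mutant (or bare ligand->score mapping) against the cutoffs.

    A His mutant with several protonation variants is resistant only if every
    variant clears every cutoff, and fit only if every variant binds every
    endogenous ligand.  The reported ratio/detail are those of the variant
    with the smallest log-ratio (the binding-constraint bottleneck).
    """
    if isinstance(mutant, LogicalMutant):
        variant_scores = mutant.variant_scores
        position, wt_aa, mut_aa = mutant.position, mutant.wt_aa, mutant.mut_aa
    else:
        variant_scores = {"": dict(mutant)}
    if not variant_scores:
        raise ValueError("mutant has no score sets")

    results = [
        _classify_single(scores, cutoffs, drug_id)
        for _, scores in sorted(variant_scores.items())
    ]
    fit = all(r[1] for r in results)
    resistant = fit and all(r[2] for r in results)
    bottleneck = min(results, key=lambda r: r[0])
    return AffinityVerdict(
        position=position,
        wt_aa=wt_aa,
        mut_aa=mut_aa,
        log_kstar_ratio=bottleneck[0],
        fit=fit,
        affinity_resistant=resistant,
        per_endogenous=bottleneck[3],
    )


@dataclass
class AttritionSummary:
    """Fractions of the initial mutant pool removed by each cascade stage."""

    n_initial: int
    frac_affinity_removed: float
    frac_unfit_removed: float
    frac_tpm_removed: float
    frac_surviving: float
    dpm_share_of_survivors: float

    def as_dict(self) -> dict:
        return {
            "n_initial": self.n_initial,
            "frac_affinity_removed": self.frac_affinity_removed,
            "frac_unfit_removed": self.frac_unfit_removed,
            "frac_tpm_removed": self.frac_tpm_removed,
            "frac_surviving": self.frac_surviving,
            "dpm_share_of_survivors": self.dpm_share_of_survivors,
        }


@dataclass
class CascadeResult:
    """Survivors plus the stage at which each removed mutant fell."""

    survivors: list[tuple[int, str, str]]
    stage_removed: dict[tuple[int, str, str], str]  # "affinity"|"fitness"|"tpm"|"pass"
    summary: AttritionSummary


def apply_cascade(
    verdicts: Mapping[tuple[int, str, str], AffinityVerdict],
    feasibility: Mapping[tuple[int, str, str], Feasibility],
) -> CascadeResult:
    """Apply the ordered filters: affinity, then fitness, then triple-point.

    Stage accounting assigns each removed mutant to the first filter that
    rejects it; final survivor membership is order-independent.  The summary
    fractions (three removal stages plus survivors) sum to 1.
    """
    if not verdicts:
        raise ValueError("empty mutant pool")
    missing_f = set(verdicts) - set(feasibility)
    missing_v = set(feasibility) - set(verdicts)
    if missing_f or missing_v:
        raise KeyError(
            f"mutant keys without feasibility: {sorted(missing_f)}; "
            f"without verdict: {sorted(missing_v)}"
        )

    stage_removed: dict[tuple[int, str, str], str] = {}
    survivors: list[tuple[int, str, str]] = []
    n = len(verdicts)
    counts = {"affinity": 0, "fitness": 0, "tpm": 0}
    n_dpm = 0
    for key in sorted(verdicts):
        v = verdicts[key]
        feas = feasibility[key]
        if v.fit and not v.affinity_resistant:
            stage_removed[key] = "affinity"
            counts["affinity"] += 1
        elif not v.fit:
            stage_removed[key] = "fitness"
            counts["fitness"] += 1
        elif feas is Feasibility.TPM:
            stage_removed[key] = "tpm"
            counts["tpm"] += 1
        else:
            stage_removed[key] = "pass"
            survivors.append(key)
            if feas is Feasibility.DPM:
                n_dpm += 1

    summary = AttritionSummary(
        n_initial=n,
        frac_affinity_removed=counts["affinity"] / n,
        frac_unfit_removed=counts["fitness"] / n,
        frac_tpm_removed=counts["tpm"] / n,
        frac_surviving=len(survivors) / n,
        dpm_share_of_survivors=(n_dpm / len(survivors)) if survivors else 0.0,
    )
    return CascadeResult(
        survivors=survivors, stage_removed=stage_removed, summary=summary
    )
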