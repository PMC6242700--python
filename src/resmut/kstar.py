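"""Reading, validation and aggregation of per-mutant K* affinity score tables.

A K* score is a dimensionless, ensemble-based estimate of ligand binding to a
protein construct produced by a partition-function affinity estimator; a score
of 0 means no predicted binding.  Each table row is one evaluation of one
construct (wild type or a single amino-acid exchange) against one ligand.
Because residue positions are evaluated individually or in pairs, a protein
carries several wild-type scores per ligand; their arithmetic mean (``avwt``)
and the spread of the per-run wild-type log-ratios feed the resistance cutoff.
"""

from __future__ import annotations

import csv
import math
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "KStarRecord",
    "WTStats",
    "WTStatsResult",
    "LogicalMutant",
    "KStarFormatError",
    "KStarValidationError",
    "read_kstar_table",
    "write_kstar_table",
    "aggregate_his_variants",
    "compute_wt_stats",
]

#: exact column order of the on-disk TSV format
COLUMNS = (
    "target_id",
    "ligand_id",
    "ligand_role",
    "run_id",
    "position",
    "wt_aa",
    "mut_aa",
    "variant_tag",
    "kstar_score",
)

ROLES = ("drug", "endogenous")


class KStarFormatError(ValueError):
    """The file does not conform to the score-table layout."""


class KStarValidationError(ValueError):
    """A parsed record violates a domain invariant."""


@dataclass(frozen=True)
class KStarRecord:
    """One affinity score for one (target, ligand, construct) evaluation.

    ``mut_aa == "WT"`` marks a wild-type row; ``variant_tag`` distinguishes
    e.g. histidine protonation variants of the same logical mutant.
    """

    target_id: str
    ligand_id: str
    ligand_role: str
    run_id: str
    position: int
    wt_aa: str
    mut_aa: str
    variant_tag: str
    kstar_score: float

    def __post_init__(self) -> None:
        if self.ligand_role not in ROLES:
            raise KStarValidationError(
                f"ligand_role must be one of {ROLES}, got {self.ligand_role!r}"
            )
        if self.kstar_score < 0:
            raise KStarValidationError(
                f"kstar_score must be >= 0, got {self.kstar_score}"
            )

    @property
    def is_wt(self) -> bool:
        return self.mut_aa == "WT"

    @property
    def key(self) -> tuple:
        """Uniqueness key within a table."""
        return (
            self.target_id,
            self.ligand_id,
            self.run_id,
            self.position,
            self.mut_aa,
            self.variant_tag,
        )

    @property
    def mutant_key(self) -> tuple[int, str, str]:
        """(position, wt_aa, mut_aa) — identity of the protein-level mutant."""
        return (self.position, self.wt_aa, self.mut_aa)


def read_kstar_table(path: str | Path, role: str) -> list[KStarRecord]:
    """Read a K* score TSV and validate every row.

    Parameters
    ----------
    path:
        TSV file with header columns exactly :data:`COLUMNS`.
    role:
        Expected ``ligand_role`` ("drug" or "endogenous"); every row must
        declare this role.

    Raises
    ------
    KStarFormatError
        Missing/extra columns or an empty table.
    KStarValidationError
        Negative score, role mismatch, or duplicate record key; the message
        cites the offending data-row number (1-based, header excluded).
    """
    if role not in ROLES:
        raise ValueError(f"role must be one of {ROLES}, got {role!r}")
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise KStarFormatError(f"{path}: empty file, no header")
        missing = set(COLUMNS) - set(reader.fieldnames)
        if missing:
            raise KStarFormatError(
                f"{path}: missing column(s) {sorted(missing)}"
            )
        records: list[KStarRecord] = []
        seen: set[tuple] = set()
        for i, row in enumerate(reader, start=1):
            try:
                score = float(row["kstar_score"])
                position = int(row["position"])
            except (TypeError, ValueError) as exc:
                raise KStarValidationError(
                    f"{path}: row {i}: unparseable numeric field ({exc})"
                ) from None
            try:
                rec = KStarRecord(
                    target_id=row["target_id"],
                    ligand_id=row["ligand_id"],
                    ligand_role=row["ligand_role"],
                    run_id=row["run_id"],
                    position=position,
                    wt_aa=row["wt_aa"],
                    mut_aa=row["mut_aa"],
                    variant_tag=row["variant_tag"] or "",
                    kstar_score=score,
                )
            except KStarValidationError as exc:
                raise KStarValidationError(f"{path}: row {i}: {exc}") from None
            if rec.ligand_role != role:
                raise KStarValidationError(
                    f"{path}: row {i}: expected ligand_role {role!r}, "
                    f"got {rec.ligand_role!r}"
                )
            if rec.key in seen:
                raise KStarValidationError(
                    f"{path}: row {i}: duplicate record key {rec.key}"
                )
            seen.add(rec.key)
            records.append(rec)
    if not records:
        raise KStarFormatError(f"{path}: table contains no data rows")
    return records


def write_kstar_table(records: Iterable[KStarRecord], path: str | Path) -> None:
    """Write records as a TSV readable by :func:`read_kstar_table`."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.target_id,
                    rec.ligand_id,
                    rec.ligand_role,
                    rec.run_id,
                    rec.position,
                    rec.wt_aa,
                    rec.mut_aa,
                    rec.variant_tag,
                    repr(rec.kstar_score),
                ]
            )


@dataclass
class LogicalMutant:
    """One protein-level mutant with its per-variant, per-ligand scores.

    Histidine mutants carry one score set per protonation variant; all other
    mutants have a single variant keyed by their (usually empty) tag.  A
    mutant scored under several run_ids for the same ligand and variant is
    averaged (in practice each mutant is scored once).
    """

    position: int
    wt_aa: str
    mut_aa: str
    #: variant_tag -> ligand_id -> score
    variant_scores: dict[str, dict[str, float]] = field(default_factory=dict)
    n_variants: int = 1

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.position, self.wt_aa, self.mut_aa)


def aggregate_his_variants(
    records: Sequence[KStarRecord],
) -> dict[tuple[int, str, str], LogicalMutant]:
    """Group mutant records into logical mutants, pooling His protonation states.

    All protonation variants of a histidine mutant are retained as members of
    one logical mutant so the downstream verdict can require *every* variant
    to clear the resistance cutoff.  Non-His mutants pass through unchanged
    (one variant each).  Wild-type rows are ignored here.

    Raises
    ------
    KStarValidationError
        Conflicting ``wt_aa`` among the records of one (position, mut_aa)
        group.
    """
    # (ligand, variant) score accumulation per mutant key
    acc: dict[tuple[int, str], dict] = {}
    for rec in records:
        if rec.is_wt:
            continue
        gkey = (rec.position, rec.mut_aa)
        entry = acc.setdefault(gkey, {"wt_aa": rec.wt_aa, "scores": defaultdict(dict)})
        if entry["wt_aa"] != rec.wt_aa:
            raise KStarValidationError(
                f"conflicting wt_aa at position {rec.position} mutant "
                f"{rec.mut_aa}: {entry['wt_aa']!r} vs {rec.wt_aa!r}"
            )
        per_ligand = entry["scores"][rec.variant_tag]
        per_ligand.setdefault(rec.ligand_id, []).append(rec.kstar_score)

    mutants: dict[tuple[int, str, str], LogicalMutant] = {}
    for (position, mut_aa), entry in acc.items():
        variant_scores = {
            tag: {lig: sum(v) / len(v) for lig, v in per_ligand.items()}
            for tag, per_ligand in entry["scores"].items()
        }
        mut = LogicalMutant(
            position=position,
            wt_aa=entry["wt_aa"],
            mut_aa=mut_aa,
            variant_scores=variant_scores,
            n_variants=len(variant_scores),
        )
        mutants[mut.key] = mut
    return mutants


@dataclass
class WTStats:
    """Wild-type score statistics for one ligand."""

    ligand_id: str
    avwt: float
    n_runs: int
    per_run_scores: dict[str, float]


@dataclass
class WTStatsResult:
    """Per-ligand WT statistics plus paired per-run WT log-ratios.

    ``pair_log_ratios[(endogenous_id, drug_id)]`` maps run_id to
    log10(K*_endogenous,WT / K*_drug,WT) for that run.  Runs present for only
    one ligand use the other ligand's avwt in place of the missing score
    (avwt substitution).
    """

    stats: dict[str, WTStats]
    roles: dict[str, str]
    pair_log_ratios: dict[tuple[str, str], dict[str, float]]


def compute_wt_stats(records: Sequence[KStarRecord]) -> WTStatsResult:
    """Compute avwt per ligand and paired per-run WT log-ratios.

    Raises
    ------
    KStarValidationError
        No WT rows at all, a ligand with no WT rows, or a WT score of 0 (the
        wild-type protein must bind both the drug and the endogenous ligand).
    """
    per_ligand: dict[str, dict[str, list[float]]] = defaultdict(dict)
    roles: dict[str, str] = {}
    for rec in records:
        roles.setdefault(rec.ligand_id, rec.ligand_role)
        if not rec.is_wt:
            continue
        if rec.kstar_score == 0:
            raise KStarValidationError(
                f"WT K* score of 0 for ligand {rec.ligand_id!r} "
                f"(run {rec.run_id!r}): wild type must bind every ligand"
            )
        per_ligand[rec.ligand_id].setdefault(rec.run_id, []).append(rec.kstar_score)

    if not per_ligand:
        raise KStarValidationError("no WT records in input")
    for ligand_id in roles:
        if ligand_id not in per_ligand:
            raise KStarValidationError(
                f"ligand {ligand_id!r} has no WT records"
            )

    stats: dict[str, WTStats] = {}
    for ligand_id, runs in per_ligand.items():
        run_scores = {run: sum(v) / len(v) for run, v in runs.items()}
        scores = list(run_scores.values())
        stats[ligand_id] = WTStats(
            ligand_id=ligand_id,
            avwt=sum(scores) / len(scores),
            n_runs=len(scores),
            per_run_scores=run_scores,
        )

    drug_ids = sorted(l for l, r in roles.items() if r == "drug")
    endo_ids = sorted(l for l, r in roles.items() if r == "endogenous")
    pair_log_ratios: dict[tuple[str, str], dict[str, float]] = {}
    for endo in endo_ids:
        for drug in drug_ids:
            ratios: dict[str, float] = {}
            run_ids = set(stats[endo].per_run_scores) | set(stats[drug].per_run_scores)
            for run in sorted(run_ids):
                e = stats[endo].per_run_scores.get(run, stats[endo].avwt)
                d = stats[drug].per_run_scores.get(run, stats[drug].avwt)
                ratios[run] = math.log10(e / d)
            pair_log_ratios[(endo, drug)] = ratios

    return WTStatsResult(stats=stats, roles=roles, pair_log_ratios=pair_log_ratios)
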