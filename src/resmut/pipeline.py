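"""End-to-end orchestration of the resistance-mutation triage cascade.

Stages: read score tables -> His-variant aggregation -> wild-type statistics
-> cutoff -> affinity/fitness classification -> codon feasibility ->
triple-point filter -> hotspot identification -> relP -> prioritization.
Each stage's output is written as TSV/JSON so runs are auditable and
re-entrant; a manifest records the configuration hash and package version.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml
from Bio import SeqIO

from . import __version__
from .benchmark import ConfusionMatrix, evaluate_against_labels
from .codons import Feasibility, classify_feasibility, enumerate_paths, extract_codon_context
from .filtering import (
    AffinityVerdict,
    CascadeResult,
    CutoffModel,
    apply_cascade,
    classify_mutant,
    compute_cutoffs,
)
from .hotspots import HotspotReport, identify_hotspots, prioritize
from .kstar import (
    LogicalMutant,
    WTStatsResult,
    aggregate_his_variants,
    compute_wt_stats,
    read_kstar_table,
)
from .relp import RelPResult, compute_relp
from .signatures import (
    PSPMTable,
    compute_pspm,
    read_pspm_table,
    read_signature_matrix,
    read_signature_weights,
)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "load_labels_tsv"]

logger = logging.getLogger(__name__)

CANCER_TYPE_UNAVAILABLE = "unavailable"


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of one triage run (YAML-loadable).

    ``cancer_type`` set to "unavailable" skips relP ranking (the behaviour
    when no mutational signatures are reported for the relevant cancer
    type); hotspots are still ranked.
    """

    drug_table: str
    endogenous_tables: list[str]
    cds_fasta: str
    residue_offset: int = 1
    signatures: str | None = None
    weights: str | None = None
    pspm_table: str | None = None
    cancer_type: str = CANCER_TYPE_UNAVAILABLE
    excluded_residues: list[int] = field(default_factory=list)
    k: int = 3
    m: int = 3
    dpm_context_mode: str = "wt"
    minimal_paths_only: bool = False
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with path.open(encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(**raw)
        base = path.parent
        for attr in ("drug_table", "cds_fasta", "signatures", "weights",
                     "pspm_table", "out_dir"):
            value = getattr(cfg, attr)
            if value is not None:
                setattr(cfg, attr, str((base / value)))
        cfg.endogenous_tables = [str(base / p) for p in cfg.endogenous_tables]
        return cfg

    def content_hash(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    report: HotspotReport
    cascade: CascadeResult
    verdicts: dict[tuple[int, str, str], AffinityVerdict]
    feasibility: dict[tuple[int, str, str], Feasibility]
    relp_results: dict[tuple[int, str, str], RelPResult] | None
    cutoffs: dict[str, CutoffModel]
    wt: WTStatsResult
    mutants: dict[tuple[int, str, str], LogicalMutant]

    def predictions(self) -> dict[tuple[int, str, str], bool]:
        """Binary resistant/sensitive call per evaluated mutant."""
        survivors = set(self.cascade.survivors)
        return {key: key in survivors for key in self.verdicts}


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r}: {exc}") from exc
        return wrapper
    return deco


def _load_pspm(config: RunConfig) -> PSPMTable | None:
    if config.cancer_type == CANCER_TYPE_UNAVAILABLE:
        logger.warning(
            "cancer type unavailable: hotspots will be ranked without relP"
        )
        return None
    if config.pspm_table:
        tables = read_pspm_table(config.pspm_table)
        if config.cancer_type not in tables:
            raise KeyError(
                f"cancer type {config.cancer_type!r} not in pSPM table "
                f"(available: {sorted(tables)})"
            )
        return tables[config.cancer_type]
    if config.signatures and config.weights:
        matrix = read_signature_matrix(config.signatures)
        weights = read_signature_weights(config.weights)
        if config.cancer_type not in weights:
            raise KeyError(
                f"cancer type {config.cancer_type!r} not in weights file "
                f"(available: {sorted(weights)})"
            )
        return compute_pspm(matrix, weights[config.cancer_type])
    logger.warning("no signature inputs configured; relP unavailable")
    return None


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full cascade and (optionally) write all outputs."""
    drug_records = _stage("read_drug_table")(read_kstar_table)(
        config.drug_table, "drug"
    )
    endo_records = []
    for path in config.endogenous_tables:
        endo_records.extend(
            _stage("read_endogenous_table")(read_kstar_table)(path, "endogenous")
        )
    records = drug_records + endo_records

    excluded = set(config.excluded_residues)
    if excluded:
        n_before = len(records)
        records = [r for r in records if r.is_wt or r.position not in excluded]
        logger.info(
            "excluded residues %s: %d records removed",
            sorted(excluded), n_before - len(records),
        )

    drug_ids = sorted({r.ligand_id for r in records if r.ligand_role == "drug"})
    if len(drug_ids) != 1:
        raise PipelineError(
            f"stage 'roles': expected exactly one drug ligand, got {drug_ids}"
        )
    drug_id = drug_ids[0]
    target_ids = sorted({r.target_id for r in records})
    target_id = target_ids[0]

    wt = _stage("wt_stats")(compute_wt_stats)(records)
    cutoffs = _stage("cutoff")(compute_cutoffs)(wt, drug_id)
    mutants = _stage("his_aggregation")(aggregate_his_variants)(records)
    if not mutants:
        raise PipelineError("stage 'his_aggregation': no mutant records")

    # avwt substitution for mutants evaluated against only one ligand
    ligand_ids = [drug_id] + sorted(cutoffs)
    for mutant in mutants.values():
        for scores in mutant.variant_scores.values():
            for ligand in ligand_ids:
                scores.setdefault(ligand, wt.stats[ligand].avwt)

    verdicts = {
        key: _stage("classify")(classify_mutant)(mut, cutoffs, drug_id)
        for key, mut in sorted(mutants.items())
    }

    cds = _stage("read_cds")(_read_single_fasta)(config.cds_fasta)
    feasibility: dict[tuple[int, str, str], Feasibility] = {}
    contexts = {}
    for key in sorted(mutants):
        position, wt_aa, mut_aa = key
        ctx = _stage("codon_context")(extract_codon_context)(
            cds, position, config.residue_offset, wt_aa
        )
        contexts[key] = ctx
        path_set = enumerate_paths(ctx, mut_aa)
        feasibility[key] = classify_feasibility(path_set.min_changes)

    cascade = _stage("cascade")(apply_cascade)(verdicts, feasibility)

    pspm = _stage("pspm")(_load_pspm)(config)
    relp_results: dict[tuple[int, str, str], RelPResult] | None
    if pspm is None:
        relp_results = None
    else:
        relp_results = {
            key: _stage("relp")(compute_relp)(
                contexts[key],
                key[2],
                pspm,
                context_mode=config.dpm_context_mode,
                minimal_only=config.minimal_paths_only,
            )
            for key in cascade.survivors
        }

    hotspot_list = identify_hotspots(cascade.survivors)
    report = prioritize(
        hotspot_list,
        relp_results,
        drug_id=drug_id,
        target_id=target_id,
        cancer_type=config.cancer_type,
        k=config.k,
        m=config.m,
    )

    result = PipelineResult(
        report=report,
        cascade=cascade,
        verdicts=verdicts,
        feasibility=feasibility,
        relp_results=relp_results,
        cutoffs=cutoffs,
        wt=wt,
        mutants=mutants,
    )
    if config.out_dir:
        _write_outputs(config, result)
    return result


def _read_single_fasta(path: str | Path) -> str:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"{path}: expected exactly one FASTA record, got {len(records)}")
    return str(records[0].seq).upper()


def _write_outputs(config: RunConfig, result: PipelineResult) -> None:
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    with (outdir / "mutants.tsv").open("w", encoding="utf-8") as fh:
        endo_ids = sorted(result.cutoffs)
        cols = ["position", "wt_aa", "mut_aa", "log_kstar_ratio", "fit",
                "affinity_resistant", "feasibility", "filter_stage_removed"]
        cols += [f"ratio_{e}" for e in endo_ids]
        fh.write("\t".join(cols) + "\n")
        for key in sorted(result.verdicts):
            v = result.verdicts[key]
            stage = result.cascade.stage_removed[key]
            row = [
                str(v.position), v.wt_aa, v.mut_aa,
                f"{v.log_kstar_ratio:.6g}", str(v.fit).lower(),
                str(v.affinity_resistant).lower(),
                result.feasibility[key].name, stage,
            ]
            row += [f"{v.per_endogenous[e][0]:.6g}" for e in endo_ids]
            fh.write("\t".join(row) + "\n")

    with (outdir / "attrition.json").open("w", encoding="utf-8") as fh:
        json.dump(result.cascade.summary.as_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")

    with (outdir / "hotspots.json").open("w", encoding="utf-8") as fh:
        json.dump(result.report.as_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")

    with (outdir / "hotspots.tsv").open("w", encoding="utf-8") as fh:
        fh.write("rank\tposition\twt_aa\tn_mutations\tmutation\trelp\trelp_rank\n")
        for h in result.report.hotspots:
            for m in h.mutations:
                relp = "" if m.relp is None else f"{m.relp:.6g}"
                rrank = "" if m.relp_rank is None else str(m.relp_rank)
                fh.write(
                    f"{h.rank}\t{h.position}\t{h.wt_aa}\t"
                    f"{h.n_resistant_mutants}\t{m.label}\t{relp}\t{rrank}\n"
                )

    manifest = {
        "package": "resmut",
        "version": __version__,
        "config_hash": config.content_hash(),
        "config": asdict(config),
        "n_mutants": len(result.verdicts),
        "n_survivors": len(result.cascade.survivors),
        "cutoffs": {
            e: {"cutoff": c.cutoff, "log_ratio_avwt": c.log_ratio_avwt,
                "range_wt": c.range_wt}
            for e, c in result.cutoffs.items()
        },
    }
    with (outdir / "manifest.json").open("w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_labels_tsv(path: str | Path) -> dict[tuple[int, str, str], bool]:
    """Read a binary label TSV (columns: position, wt_aa, mut_aa, resistant)."""
    labels: dict[tuple[int, str, str], bool] = {}
    with Path(path).open(encoding="utf-8") as fh:
        header = fh.readline().strip().split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for col in ("position", "wt_aa", "mut_aa", "resistant"):
            if col not in idx:
                raise ValueError(f"{path}: missing column {col!r}")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            key = (int(parts[idx["position"]]), parts[idx["wt_aa"]],
                   parts[idx["mut_aa"]])
            value = parts[idx["resistant"]].strip().lower()
            labels[key] = value in ("1", "true", "yes", "r")
    return labels


def evaluate_run(
    result: PipelineResult, labels: dict[tuple[int, str, str], bool]
) -> ConfusionMatrix:
    """Score a finished run against experimental resistance labels."""
    return evaluate_against_labels(result.predictions(), labels)
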