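"""Synthetic, fully self-consistent input bundles with planted ground truth.

The generator emulates the complete input stack of the triage workflow:
per-mutant affinity score tables for a drug and an endogenous ligand
(wild-type replicate scores with a controlled log-ratio variation range,
mutant scores planted as resistant / sensitive / unfit), a coding sequence
consistent with the mutant list, and a synthetic mutational-signature mix
with known normalization.  Planted resistant mutants receive score pairs
whose log K* ratio exceeds the fixture's own cutoff by a configurable
margin; unfit mutants get an endogenous score of 0; triple-point plants get
wild-type codons at Hamming distance 3 from every codon of the target amino
acid.  Everything is drawn from a single seeded generator, so a given seed
reproduces the bundle byte for byte.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codons import AA_TO_CODONS, CODON_TO_AA, SENSE_CODONS
from .kstar import KStarRecord, write_kstar_table
from .signatures import CLASS_LABELS, SUBSTITUTIONS

__all__ = ["FixtureSpec", "Fixture", "generate_fixture", "tpm_pairs"]

HIS_TAGS = ("HID", "HIE", "HIP")  # delta/epsilon/doubly protonated


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _min_changes(codon: str, aa: str) -> int:
    return min(_hamming(codon, c) for c in AA_TO_CODONS[aa])


_TPM_PAIRS: list[tuple[str, str]] | None = None


def tpm_pairs() -> list[tuple[str, str]]:
    """All (wild-type codon, target amino acid) pairs requiring three base
    exchanges, e.g. ATG (Met) -> His."""
    global _TPM_PAIRS
    if _TPM_PAIRS is None:
        _TPM_PAIRS = [
            (codon, aa)
            for codon in SENSE_CODONS
            for aa in sorted(AA_TO_CODONS)
            if aa != CODON_TO_AA[codon] and _min_changes(codon, aa) == 3
        ]
    return _TPM_PAIRS


def _feasible_aas(codon: str) -> list[str]:
    """Amino acids reachable from ``codon`` in 1 or 2 base exchanges.

    Pro is excluded: the upstream affinity estimator cannot score mutations
    to Pro, so real score tables never contain such rows and the fixture
    mirrors that.
    """
    wt = CODON_TO_AA[codon]
    return sorted(
        aa
        for aa in AA_TO_CODONS
        if aa != wt and aa != "P" and _min_changes(codon, aa) <= 2
    )


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions of one synthetic bundle.

    Defaults: 20 evaluated binding-site residues, 3 wild-type evaluation
    runs whose log-ratio spread is bounded by 0.3 log units (a typical
    replicate-to-replicate variation allowance), 5 planted resistant, 2
    planted unfit, 1 planted triple-point mutant, and a plant margin of 1
    log unit beyond the cutoff so planted classes are unambiguous relative
    to the wild-type noise.
    """

    seed: int = 0
    n_positions: int = 20
    wt_runs: int = 3
    wt_noise_log_range: float = 0.3
    n_resistant: int = 5
    n_unfit: int = 2
    n_tpm: int = 1
    margin: float = 1.0
    n_signatures: int = 3
    #: explicit per-hotspot resistant counts, e.g. (4, 3, 3); overrides
    #: n_resistant (which then equals the sum)
    resistant_layout: tuple[int, ...] | None = None
    his_variants: bool = True
    target_id: str = "TARGET1"
    drug_id: str = "drug1"
    endogenous_id: str = "ATP"
    cancer_type: str = "synthetic_cancer"


@dataclass
class Fixture:
    """An in-memory bundle plus its planted truth."""

    spec: FixtureSpec
    drug_records: list[KStarRecord]
    endogenous_records: list[KStarRecord]
    cds: str
    residue_offset: int
    signature_values: "np.ndarray"  # (96, n_signatures)
    signature_ids: list[str]
    weights: dict[str, float]
    truth: dict

    def write(self, outdir: str | Path) -> Path:
        """Write the bundle directory: drug.tsv, endogenous.tsv, cds.fasta,
        signatures.tsv, weights.tsv, truth.json, config.yaml."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_kstar_table(self.drug_records, outdir / "drug.tsv")
        write_kstar_table(self.endogenous_records, outdir / "endogenous.tsv")
        rec = SeqRecord(
            Seq(self.cds), id=self.spec.target_id, description="synthetic CDS"
        )
        SeqIO.write([rec], str(outdir / "cds.fasta"), "fasta")
        with (outdir / "signatures.tsv").open("w", encoding="utf-8") as fh:
            header = ["Substitution Type", "Trinucleotide", "Somatic Mutation Type"]
            fh.write("\t".join(header + self.signature_ids) + "\n")
            for i, label in enumerate(CLASS_LABELS):
                sub = label[2:5]
                tri = label[0] + label[2] + label[6]
                row = [sub, tri, label] + [
                    repr(float(v)) for v in self.signature_values[i]
                ]
                fh.write("\t".join(row) + "\n")
        with (outdir / "weights.tsv").open("w", encoding="utf-8") as fh:
            fh.write("cancer_type\tsignature_id\tc_s\n")
            for sig in self.signature_ids:
                fh.write(
                    f"{self.spec.cancer_type}\t{sig}\t{repr(self.weights[sig])}\n"
                )
        with (outdir / "truth.json").open("w", encoding="utf-8") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)
            fh.write("\n")
        config = {
            "drug_table": "drug.tsv",
            "endogenous_tables": ["endogenous.tsv"],
            "cds_fasta": "cds.fasta",
            "residue_offset": self.residue_offset,
            "signatures": "signatures.tsv",
            "weights": "weights.tsv",
            "cancer_type": self.spec.cancer_type,
            "excluded_residues": [],
            "k": 3,
            "m": 3,
            "out_dir": "out",
        }
        with (outdir / "config.yaml").open("w", encoding="utf-8") as fh:
            yaml.safe_dump(config, fh, sort_keys=True)
        return outdir


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Build a deterministic synthetic bundle from the study conditions.

    Raises
    ------
    ValueError
        The plant counts do not fit in ``n_positions`` residues, or a
        requested plant is infeasible.
    """
    rng = np.random.default_rng(spec.seed)
    layout = spec.resistant_layout
    if layout is not None and any(c < 1 for c in layout):
        raise ValueError("resistant_layout counts must be >= 1")
    n_res_positions = len(layout) if layout is not None else spec.n_resistant
    n_needed = spec.n_tpm + spec.n_unfit + n_res_positions
    if n_needed > spec.n_positions:
        raise ValueError(
            f"{n_needed} planted positions do not fit in "
            f"{spec.n_positions} evaluated residues"
        )

    # residues 1 .. n_positions + 2; positions 2 .. n_positions+1 are
    # evaluated (interior, so each codon has both flanking bases)
    positions = list(range(2, spec.n_positions + 2))
    order = [positions[i] for i in rng.permutation(len(positions))]
    tpm_positions = sorted(order[: spec.n_tpm])
    unfit_positions = sorted(order[spec.n_tpm : spec.n_tpm + spec.n_unfit])
    res_positions = sorted(
        order[spec.n_tpm + spec.n_unfit : spec.n_tpm + spec.n_unfit + n_res_positions]
    )
    sensitive_positions = sorted(order[n_needed:])

    # codon assignment; TPM positions draw from the distance-3 pair list
    pairs = [p for p in tpm_pairs() if p[1] != "P"]  # no Pro rows in real tables
    codons: dict[int, str] = {}
    tpm_targets: dict[int, str] = {}
    for pos in tpm_positions:
        codon, aa = pairs[int(rng.integers(len(pairs)))]
        codons[pos] = codon
        tpm_targets[pos] = aa
    for pos in positions:
        if pos not in codons:
            codons[pos] = SENSE_CODONS[int(rng.integers(len(SENSE_CODONS)))]

    cds_codons = ["ATG"]  # residue 1: start codon
    for pos in range(2, spec.n_positions + 2):
        cds_codons.append(codons[pos])
    # trailing residue so the last evaluated codon has a 3' flank
    cds_codons.append(SENSE_CODONS[int(rng.integers(len(SENSE_CODONS)))])
    cds = "".join(cds_codons)

    # wild-type runs: endogenous score fixed, drug score absorbs the drawn
    # per-run log-ratio; the spread of the draws is bounded by the noise range
    run_ids = [f"r{i + 1:02d}" for i in range(spec.wt_runs)]
    half = spec.wt_noise_log_range / 2.0
    wt_ratios = {run: float(rng.uniform(-half, half)) for run in run_ids}
    endo_wt = {run: 100.0 for run in run_ids}
    drug_wt = {run: 100.0 * 10 ** (-wt_ratios[run]) for run in run_ids}
    avwt_endo = sum(endo_wt.values()) / len(endo_wt)
    avwt_drug = sum(drug_wt.values()) / len(drug_wt)
    log_ratio_avwt = math.log10(avwt_endo / avwt_drug)
    range_wt = max(wt_ratios.values()) - min(wt_ratios.values())
    cutoff = log_ratio_avwt + range_wt

    def run_for(pos: int) -> str:
        return run_ids[pos % len(run_ids)]

    drug_records: list[KStarRecord] = []
    endo_records: list[KStarRecord] = []
    for run in run_ids:
        drug_records.append(
            KStarRecord(
                spec.target_id, spec.drug_id, "drug", run, 0, "X", "WT", "",
                drug_wt[run],
            )
        )
        endo_records.append(
            KStarRecord(
                spec.target_id, spec.endogenous_id, "endogenous", run, 0, "X",
                "WT", "", endo_wt[run],
            )
        )

    def emit(pos: int, mut_aa: str, endo_score: float, drug_score: float,
             tag: str = "") -> None:
        wt_aa = CODON_TO_AA[codons[pos]]
        run = run_for(pos)
        drug_records.append(
            KStarRecord(
                spec.target_id, spec.drug_id, "drug", run, pos, wt_aa, mut_aa,
                tag, drug_score,
            )
        )
        endo_records.append(
            KStarRecord(
                spec.target_id, spec.endogenous_id, "endogenous", run, pos,
                wt_aa, mut_aa, tag, endo_score,
            )
        )

    def resistant_scores() -> tuple[float, float]:
        log_ratio = cutoff + spec.margin + float(rng.uniform(0.0, 0.5))
        return 100.0, 100.0 * 10 ** (-log_ratio)

    def sensitive_scores() -> tuple[float, float]:
        log_ratio = cutoff - spec.margin - float(rng.uniform(0.0, 0.5))
        return 100.0, 100.0 * 10 ** (-log_ratio)

    truth_resistant: list[list] = []
    truth_unfit: list[list] = []
    truth_tpm: list[list] = []
    truth_sensitive: list[list] = []

    # planted resistant mutants (optionally several per hotspot position)
    counts = list(layout) if layout is not None else [1] * spec.n_resistant
    his_planted = False
    for pos, count in zip(res_positions, counts):
        wt_aa = CODON_TO_AA[codons[pos]]
        feas = _feasible_aas(codons[pos])
        if len(feas) < count:
            raise ValueError(
                f"position {pos} (codon {codons[pos]}) admits only "
                f"{len(feas)} feasible exchanges, {count} requested"
            )
        chosen = [feas[i] for i in rng.choice(len(feas), size=count, replace=False)]
        if spec.his_variants and not his_planted and "H" in feas and "H" not in chosen:
            chosen[0] = "H"
        for mut_aa in sorted(chosen):
            if mut_aa == "H" and spec.his_variants and not his_planted:
                his_planted = True
                for tag in HIS_TAGS:
                    e, d = resistant_scores()
                    emit(pos, mut_aa, e, d, tag=tag)
            else:
                e, d = resistant_scores()
                emit(pos, mut_aa, e, d)
            truth_resistant.append([pos, wt_aa, mut_aa])

    for pos in unfit_positions:
        wt_aa = CODON_TO_AA[codons[pos]]
        feas = _feasible_aas(codons[pos])
        mut_aa = feas[int(rng.integers(len(feas)))]
        emit(pos, mut_aa, 0.0, 100.0 * float(rng.uniform(0.5, 2.0)))
        truth_unfit.append([pos, wt_aa, mut_aa])

    for pos in tpm_positions:
        wt_aa = CODON_TO_AA[codons[pos]]
        mut_aa = tpm_targets[pos]
        e, d = resistant_scores()  # passes affinity+fitness, removed as TPM
        emit(pos, mut_aa, e, d)
        truth_tpm.append([pos, wt_aa, mut_aa])

    for pos in sensitive_positions:
        wt_aa = CODON_TO_AA[codons[pos]]
        feas = _feasible_aas(codons[pos])
        mut_aa = feas[int(rng.integers(len(feas)))]
        e, d = sensitive_scores()
        emit(pos, mut_aa, e, d)
        truth_sensitive.append([pos, wt_aa, mut_aa])

    # synthetic signature mix with known normalization
    signature_ids = [f"SigSynth{i + 1}" for i in range(spec.n_signatures)]
    signature_values = rng.dirichlet(np.ones(96), size=spec.n_signatures).T
    raw_weights = rng.uniform(0.2, 1.0, size=spec.n_signatures)
    raw_weights /= raw_weights.sum()
    weights = {sig: float(w) for sig, w in zip(signature_ids, raw_weights)}

    n_mutants = (
        len(truth_resistant) + len(truth_unfit) + len(truth_tpm)
        + len(truth_sensitive)
    )
    truth = {
        "spec": {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in asdict(spec).items()},
        "cutoff": cutoff,
        "log_ratio_avwt": log_ratio_avwt,
        "range_wt": range_wt,
        "resistant": sorted(map(tuple, truth_resistant)),
        "unfit": sorted(map(tuple, truth_unfit)),
        "tpm": sorted(map(tuple, truth_tpm)),
        "sensitive": sorted(map(tuple, truth_sensitive)),
        "n_mutants": n_mutants,
        "fractions": {
            "affinity": len(truth_sensitive) / n_mutants,
            "fitness": len(truth_unfit) / n_mutants,
            "tpm": len(truth_tpm) / n_mutants,
            "surviving": len(truth_resistant) / n_mutants,
        },
    }
    return Fixture(
        spec=spec,
        drug_records=drug_records,
        endogenous_records=endo_records,
        cds=cds,
        residue_offset=1,
        signature_values=signature_values,
        signature_ids=signature_ids,
        weights=weights,
        truth=truth,
    )
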