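"""Mutational-signature matrices and cancer-type base-exchange probabilities.

A mutational signature is a probability distribution over the 96 trinucleotide
substitution classes (pyrimidine-centered, e.g. ``A[C>A]A``).  A cancer type
carries a weighted mixture of signatures; mixing the signature distributions
with per-cancer weights ``c_s`` (renormalized to sum to 1) gives the overall
probability of each specific base exchange in that cancer type:

    pSPM(class) = sum_s  c_s * x_s(class)

Purine-centered queries are folded onto the pyrimidine strand by reverse
complement before lookup, following the standard signature convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "SignatureMatrix",
    "SignatureWeights",
    "PSPMTable",
    "SignatureFormatError",
    "CLASS_LABELS",
    "canonical_class",
    "read_signature_matrix",
    "read_signature_weights",
    "build_signature_weights",
    "compute_pspm",
    "lookup_pspm",
    "read_pspm_table",
    "write_pspm_table",
]

logger = logging.getLogger(__name__)

PYRIMIDINES = "CT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: canonical order of the 96 trinucleotide substitution classes
CLASS_LABELS: tuple[str, ...] = tuple(
    f"{f5}[{sub}]{f3}"
    for sub in SUBSTITUTIONS
    for f5 in "ACGT"
    for f3 in "ACGT"
)


class SignatureFormatError(ValueError):
    """Malformed signature or probability file."""


def _revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def canonical_class(tri_context: str, alt: str) -> str:
    """Canonical pyrimidine-centered class label for a base exchange.

    ``tri_context`` is the 3-base wild-type context centered on the reference
    base; purine-centered contexts are reverse complemented (which also
    complements the alternative base).
    """
    tri_context = tri_context.upper()
    alt = alt.upper()
    if len(tri_context) != 3 or any(b not in COMPLEMENT for b in tri_context):
        raise ValueError(f"invalid trinucleotide context {tri_context!r}")
    if alt not in COMPLEMENT:
        raise ValueError(f"invalid alternative base {alt!r}")
    ref = tri_context[1]
    if ref == alt:
        raise ValueError(f"reference and alternative base are both {ref!r}")
    if ref not in PYRIMIDINES:
        tri_context = _revcomp(tri_context)
        ref = tri_context[1]
        alt = COMPLEMENT[alt]
    return f"{tri_context[0]}[{ref}>{alt}]{tri_context[2]}"


def _canonicalize_label(label: str) -> str:
    """Normalize a class label (possibly purine-centered) to canonical form."""
    label = label.strip().upper()
    if len(label) != 7 or label[1] != "[" or label[3] != ">" or label[5] != "]":
        raise SignatureFormatError(f"unrecognized class label {label!r}")
    tri = label[0] + label[2] + label[6]
    return canonical_class(tri, label[4])


def _validate_96(labels: list[str], source: str) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise SignatureFormatError(f"{source}: duplicate class {lab!r}")
        seen.add(lab)
    if seen != set(CLASS_LABELS):
        raise SignatureFormatError(
            f"{source}: expected 96 classes, got {len(seen)} "
            f"(missing e.g. {sorted(set(CLASS_LABELS) - seen)[:3]})"
        )


@dataclass
class SignatureMatrix:
    """Signature distributions over the 96 classes, one column per signature.

    ``values`` is indexed by canonical class label in :data:`CLASS_LABELS`
    order; every column sums to 1.
    """

    values: pd.DataFrame

    @property
    def signature_ids(self) -> list[str]:
        return list(self.values.columns)


def _normalize_columns(df: pd.DataFrame, source: str, tol: float) -> pd.DataFrame:
    if (df.values < 0).any():
        raise SignatureFormatError(f"{source}: negative probability values")
    sums = df.sum(axis=0)
    if (sums <= 0).any():
        bad = list(sums.index[sums <= 0])
        raise SignatureFormatError(f"{source}: column(s) {bad} sum to zero")
    off = sums[(sums - 1.0).abs() > tol]
    if len(off):
        logger.warning(
            "%s: renormalizing column(s) %s (sums %s)",
            source,
            list(off.index),
            [float(v) for v in off.values],
        )
    return df.div(sums, axis=1)


def read_signature_matrix(path: str | Path) -> SignatureMatrix:
    """Read a signature TSV in the standard 96-class layout.

    The file carries the label columns ``Substitution Type``,
    ``Trinucleotide`` and ``Somatic Mutation Type`` followed by one numeric
    column per signature; rows may be in any order.  Columns off a sum of 1
    by more than 1e-6 are renormalized with a logged warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    label_cols = [
        c
        for c in df.columns
        if c.strip().lower()
        in ("substitution type", "trinucleotide", "somatic mutation type")
    ]
    if "Somatic Mutation Type" in df.columns:
        raw_labels = df["Somatic Mutation Type"].astype(str)
    elif {"Substitution Type", "Trinucleotide"} <= set(df.columns):
        raw_labels = [
            f"{t[0]}[{s}]{t[2]}"
            for s, t in zip(df["Substitution Type"], df["Trinucleotide"])
        ]
    else:
        raise SignatureFormatError(
            f"{path}: need 'Somatic Mutation Type' or "
            f"'Substitution Type'+'Trinucleotide' columns"
        )
    labels = [_canonicalize_label(l) for l in raw_labels]
    _validate_96(labels, str(path))
    sig_cols = [c for c in df.columns if c not in label_cols]
    if not sig_cols:
        raise SignatureFormatError(f"{path}: no signature columns")
    values = df[sig_cols].astype(float)
    values.index = labels
    values = values.reindex(list(CLASS_LABELS))
    values = _normalize_columns(values, str(path), tol=1e-6)
    return SignatureMatrix(values=values)


@dataclass
class SignatureWeights:
    """Renormalized signature weights ``c_s`` for one cancer type."""

    cancer_type: str
    weights: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if not self.weights or total <= 0:
            raise ValueError(
                f"weights for {self.cancer_type!r} must be non-empty with "
                f"positive sum"
            )
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be non-negative")
        if abs(total - 1.0) > 1e-9:
            self.weights = {s: w / total for s, w in self.weights.items()}


def read_signature_weights(path: str | Path) -> dict[str, SignatureWeights]:
    """Read a weights TSV (columns cancer_type, signature_id, c_s).

    Returns one :class:`SignatureWeights` per cancer type, renormalized so
    the weights of the signatures operating in that cancer type sum to 1.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"cancer_type", "signature_id", "c_s"}
    if not required <= set(df.columns):
        raise SignatureFormatError(
            f"{path}: missing column(s) {sorted(required - set(df.columns))}"
        )
    out: dict[str, SignatureWeights] = {}
    for cancer, group in df.groupby("cancer_type", sort=True):
        weights = dict(zip(group["signature_id"], group["c_s"].astype(float)))
        out[str(cancer)] = SignatureWeights(cancer_type=str(cancer), weights=weights)
    return out


def build_signature_weights(
    cancer_type: str,
    sample_fraction: Mapping[str, float],
    mean_contribution: Mapping[str, float],
) -> SignatureWeights:
    """Construct c_s from detection prevalence and mutational-load share.

    ``c_s = (fraction of samples in which signature s is detected) x
    (mean contribution of s to the mutational load)``, renormalized over the
    signatures operating in the cancer type.
    """
    if set(sample_fraction) != set(mean_contribution):
        raise ValueError("sample_fraction and mean_contribution must share keys")
    weights = {
        s: sample_fraction[s] * mean_contribution[s] for s in sample_fraction
    }
    return SignatureWeights(cancer_type=cancer_type, weights=weights)


@dataclass
class PSPMTable:
    """Cancer-type probability of each of the 96 base-exchange classes."""

    cancer_type: str
    pspm: pd.Series  # indexed by canonical class label, sums to 1

    def __post_init__(self) -> None:
        if list(self.pspm.index) != list(CLASS_LABELS):
            self.pspm = self.pspm.reindex(list(CLASS_LABELS))
        if self.pspm.isna().any():
            raise ValueError("pSPM table is missing classes")
        if (self.pspm < 0).any():
            raise ValueError("pSPM values must be non-negative")
        total = float(self.pspm.sum())
        if total <= 0:
            raise ValueError("pSPM values sum to zero")
        if abs(total - 1.0) > 1e-9:
            if abs(total - 1.0) > 1e-6:
                logger.warning(
                    "pSPM table for %s sums to %g; renormalizing",
                    self.cancer_type,
                    total,
                )
            self.pspm = self.pspm / total


def compute_pspm(matrix: SignatureMatrix, weights: SignatureWeights) -> PSPMTable:
    """Mix the signatures operating in a cancer type into its pSPM table."""
    unknown = set(weights.weights) - set(matrix.signature_ids)
    if unknown:
        raise ValueError(f"weights reference unknown signature(s) {sorted(unknown)}")
    pspm = sum(
        w * matrix.values[sig] for sig, w in sorted(weights.weights.items())
    )
    return PSPMTable(cancer_type=weights.cancer_type, pspm=pspm)


def lookup_pspm(table: PSPMTable, tri_context: str, ref: str, alt: str) -> float:
    """Probability of the base exchange ref>alt in its trinucleotide context.

    ``ref`` must be the center base of ``tri_context``; purine-centered
    queries are folded by reverse complement before lookup.
    """
    if tri_context[1].upper() != ref.upper():
        raise ValueError(
            f"ref {ref!r} is not the center of context {tri_context!r}"
        )
    return float(table.pspm[canonical_class(tri_context, alt)])


def read_pspm_table(path: str | Path) -> dict[str, PSPMTable]:
    """Read a precomputed pSPM TSV: one row per class, one column per cancer
    type, class labels in a ``Somatic Mutation Type`` (or first) column."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    label_col = (
        "Somatic Mutation Type"
        if "Somatic Mutation Type" in df.columns
        else df.columns[0]
    )
    labels = [_canonicalize_label(l) for l in df[label_col].astype(str)]
    _validate_96(labels, str(path))
    out: dict[str, PSPMTable] = {}
    for col in df.columns:
        if col == label_col:
            continue
        series = pd.Series(df[col].astype(float).values, index=labels)
        series = series.reindex(list(CLASS_LABELS))
        out[col] = PSPMTable(cancer_type=col, pspm=series)
    if not out:
        raise SignatureFormatError(f"{path}: no cancer-type columns")
    return out


def write_pspm_table(tables: Mapping[str, PSPMTable], path: str | Path) -> None:
    """Write pSPM tables as a TSV round-trippable by :func:`read_pspm_table`."""
    df = pd.DataFrame({"Somatic Mutation Type": list(CLASS_LABELS)})
    for name in sorted(tables):
        df[name] = tables[name].pspm.values
    df.to_csv(path, sep="\t", index=False)
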