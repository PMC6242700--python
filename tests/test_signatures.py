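"""Signature matrices, weight normalization, pSPM mixing and strand folding."""

import numpy as np
import pandas as pd
import pytest

from resmut.signatures import (
    CLASS_LABELS,
    PSPMTable,
    SignatureFormatError,
    SignatureWeights,
    build_signature_weights,
    canonical_class,
    compute_pspm,
    lookup_pspm,
    read_pspm_table,
    read_signature_matrix,
    read_signature_weights,
    write_pspm_table,
)


def write_signature_file(path, columns: dict[str, np.ndarray], drop_rows=0):
    rows = list(CLASS_LABELS)[: 96 - drop_rows]
    with path.open("w") as fh:
        names = list(columns)
        fh.write(
            "Substitution Type\tTrinucleotide\tSomatic Mutation Type\t"
            + "\t".join(names) + "\n"
        )
        for i, label in enumerate(rows):
            sub = label[2:5]
            tri = label[0] + label[2] + label[6]
            vals = "\t".join(repr(float(columns[n][i])) for n in names)
            fh.write(f"{sub}\t{tri}\t{label}\t{vals}\n")


class TestMatrixIO:
    def test_canonical_file_with_two_signatures(self, tmp_path):
        path = tmp_path / "sig.tsv"
        rng = np.random.default_rng(1)
        cols = {
            "Signature 1": rng.dirichlet(np.ones(96)),
            "Signature 2": rng.dirichlet(np.ones(96)),
        }
        write_signature_file(path, cols)
        m = read_signature_matrix(path)
        assert m.signature_ids == ["Signature 1", "Signature 2"]
        assert list(m.values.index) == list(CLASS_LABELS)
        np.testing.assert_allclose(m.values.sum(axis=0), 1.0)

    def test_95_rows_rejected(self, tmp_path):
        path = tmp_path / "sig.tsv"
        write_signature_file(path, {"S1": np.full(96, 1 / 96)}, drop_rows=1)
        with pytest.raises(SignatureFormatError, match="96 classes"):
            read_signature_matrix(path)

    def test_column_summing_to_two_is_halved_with_warning(self, tmp_path, caplog):
        path = tmp_path / "sig.tsv"
        write_signature_file(path, {"S1": np.full(96, 2 / 96)})
        with caplog.at_level("WARNING"):
            m = read_signature_matrix(path)
        assert "renormalizing" in caplog.text
        np.testing.assert_allclose(m.values["S1"].values, 1 / 96)

    def test_duplicate_class_rejected(self, tmp_path):
        path = tmp_path / "sig.tsv"
        write_signature_file(path, {"S1": np.full(96, 1 / 96)})
        lines = path.read_text().splitlines()
        lines[2] = lines[1]  # duplicate first data row
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(SignatureFormatError, match="duplicate"):
            read_signature_matrix(path)


class TestWeights:
    def test_weights_tsv_renormalized_per_cancer_type(self, tmp_path):
        path = tmp_path / "w.tsv"
        path.write_text(
            "cancer_type\tsignature_id\tc_s\n"
            "stomach\tS1\t2.0\nstomach\tS2\t6.0\nlung\tS1\t5.0\n"
        )
        weights = read_signature_weights(path)
        assert weights["stomach"].weights == {"S1": 0.25, "S2": 0.75}
        assert weights["lung"].weights == {"S1": 1.0}

    def test_builder_combines_prevalence_and_contribution(self):
        w = build_signature_weights(
            "lung", {"S1": 0.5, "S2": 1.0}, {"S1": 0.4, "S2": 0.2}
        )
        # raw: 0.2 and 0.2 -> equal weights
        assert w.weights == pytest.approx({"S1": 0.5, "S2": 0.5})

    def test_negative_or_empty_weights_rejected(self):
        with pytest.raises(ValueError):
            SignatureWeights("x", {})
        with pytest.raises(ValueError):
            SignatureWeights("x", {"S1": -1.0, "S2": 2.0})


def matrix_from(columns: dict[str, np.ndarray]):
    from resmut.signatures import SignatureMatrix

    df = pd.DataFrame(columns, index=list(CLASS_LABELS))
    return SignatureMatrix(values=df)


class TestPSPM:
    def test_single_signature_identity(self):
        rng = np.random.default_rng(2)
        x = rng.dirichlet(np.ones(96))
        m = matrix_from({"S1": x})
        t = compute_pspm(m, SignatureWeights("c", {"S1": 1.0}))
        np.testing.assert_allclose(t.pspm.values, x)

    def test_mixture_arithmetic(self):
        x1 = np.full(96, (1 - 0.02) / 95)
        x2 = np.full(96, (1 - 0.04) / 95)
        x1[0], x2[0] = 0.02, 0.04
        t = compute_pspm(
            matrix_from({"S1": x1, "S2": x2}),
            SignatureWeights("c", {"S1": 0.25, "S2": 0.75}),
        )
        assert t.pspm.iloc[0] == pytest.approx(0.25 * 0.02 + 0.75 * 0.04)
        assert float(t.pspm.sum()) == pytest.approx(1.0, abs=1e-9)

    def test_any_normalized_mixture_sums_to_one(self):
        rng = np.random.default_rng(3)
        m = matrix_from(
            {f"S{i}": rng.dirichlet(np.ones(96)) for i in range(4)}
        )
        w = rng.uniform(0.1, 1.0, 4)
        weights = SignatureWeights("c", {f"S{i}": w[i] for i in range(4)})
        t = compute_pspm(m, weights)
        assert float(t.pspm.sum()) == pytest.approx(1.0, abs=1e-9)

    def test_weight_scaling_then_renormalizing_is_identity(self):
        rng = np.random.default_rng(4)
        m = matrix_from({"S1": rng.dirichlet(np.ones(96)),
                         "S2": rng.dirichlet(np.ones(96))})
        t1 = compute_pspm(m, SignatureWeights("c", {"S1": 0.3, "S2": 0.7}))
        t2 = compute_pspm(m, SignatureWeights("c", {"S1": 3.0, "S2": 7.0}))
        np.testing.assert_allclose(t1.pspm.values, t2.pspm.values)

    def test_unknown_signature_in_weights_rejected(self):
        m = matrix_from({"S1": np.full(96, 1 / 96)})
        with pytest.raises(ValueError, match="unknown signature"):
            compute_pspm(m, SignatureWeights("c", {"S9": 1.0}))


class TestLookup:
    def test_purine_center_folds_by_reverse_complement(self, random_pspm):
        # T[G>A]C reverse-complements to G[C>T]A
        v = lookup_pspm(random_pspm, "TGC", "G", "A")
        assert v == float(random_pspm.pspm["G[C>T]A"])

    def test_pyrimidine_center_is_direct(self, random_pspm):
        v = lookup_pspm(random_pspm, "ACG", "C", "T")
        assert v == float(random_pspm.pspm["A[C>T]G"])

    def test_ref_equal_alt_rejected(self, random_pspm):
        with pytest.raises(ValueError):
            lookup_pspm(random_pspm, "ACG", "C", "C")

    def test_ref_must_be_center(self, random_pspm):
        with pytest.raises(ValueError, match="center"):
            lookup_pspm(random_pspm, "ACG", "G", "T")

    def test_folding_is_an_involution(self):
        for f5 in "ACGT":
            for ref, alts in (("G", "ACT"), ("A", "CGT")):
                for f3 in "ACGT":
                    for alt in alts:
                        label = canonical_class(f5 + ref + f3, alt)
                        # canonical labels are already pyrimidine-centered
                        tri = label[0] + label[2] + label[6]
                        assert canonical_class(tri, label[4]) == label


class TestPSPMTableIO:
    def test_round_trip_within_1e12(self, tmp_path, random_pspm):
        path = tmp_path / "pspm.tsv"
        write_pspm_table({"random": random_pspm}, path)
        back = read_pspm_table(path)["random"]
        np.testing.assert_allclose(
            back.pspm.values, random_pspm.pspm.values, atol=1e-12
        )

    def test_rows_summing_to_half_are_renormalized_with_warning(
        self, tmp_path, caplog
    ):
        path = tmp_path / "pspm.tsv"
        df = pd.DataFrame(
            {"Somatic Mutation Type": list(CLASS_LABELS), "c": 0.5 / 96}
        )
        df.to_csv(path, sep="\t", index=False)
        with caplog.at_level("WARNING"):
            t = read_pspm_table(path)["c"]
        assert "renormalizing" in caplog.text
        assert float(t.pspm.sum()) == pytest.approx(1.0, abs=1e-9)

    def test_negative_values_rejected(self):
        values = pd.Series(1.0 / 96, index=list(CLASS_LABELS))
        values.iloc[0] = -0.1
        with pytest.raises(ValueError, match="non-negative"):
            PSPMTable("c", values)
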