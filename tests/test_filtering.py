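"""Cutoff model, affinity/fitness classification, and the filter cascade."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from resmut.codons import Feasibility
from resmut.filtering import (
    AffinityVerdict,
    CutoffModel,
    apply_cascade,
    classify_mutant,
    compute_cutoff,
)
from resmut.kstar import LogicalMutant, compute_wt_stats

from conftest import make_record
from test_kstar import wt_pair_records


def make_cutoff(cutoff, endo="ATP", drug="drug1", range_wt=0.0):
    return CutoffModel(
        drug_id=drug,
        endogenous_id=endo,
        log_ratio_avwt=cutoff - range_wt,
        range_wt=range_wt,
        cutoff=cutoff,
    )


class TestCutoff:
    def test_two_run_example(self):
        wt = compute_wt_stats(
            wt_pair_records({"r1": 100.0, "r2": 100.0}, {"r1": 100.0, "r2": 50.0})
        )
        model = compute_cutoff(wt, "ATP", "drug1")
        assert model.log_ratio_avwt == pytest.approx(0.12494, abs=1e-5)
        assert model.range_wt == pytest.approx(0.30103, abs=1e-5)
        assert model.cutoff == pytest.approx(0.42597, abs=1e-5)

    def test_single_run_cutoff_is_zero(self):
        wt = compute_wt_stats(wt_pair_records({"r1": 10.0}, {"r1": 10.0}))
        model = compute_cutoff(wt, "ATP", "drug1")
        assert model.cutoff == 0.0 and model.range_wt == 0.0

    def test_range_is_max_minus_min(self):
        # ratios {-0.2, +0.1} with equal avwt: cutoff = 0 + 0.3
        wt = compute_wt_stats(
            wt_pair_records(
                {"r1": 100.0 * 10**-0.1, "r2": 100.0 * 10**0.05},
                {"r1": 100.0 * 10**0.1, "r2": 100.0 * 10**-0.05},
            )
        )
        model = compute_cutoff(wt, "ATP", "drug1")
        assert model.range_wt == pytest.approx(0.3)
        assert model.cutoff == pytest.approx(model.log_ratio_avwt + 0.3)

    def test_invariant_enforced_on_construction(self):
        with pytest.raises(ValueError):
            CutoffModel("d", "e", 0.1, 0.2, cutoff=0.5)
        with pytest.raises(ValueError):
            CutoffModel("d", "e", 0.1, -0.1, cutoff=0.0)


class TestClassify:
    CUTOFFS = {"ATP": make_cutoff(0.42597)}

    def classify(self, endo, drug, cutoffs=None):
        return classify_mutant(
            {"ATP": endo, "drug1": drug}, cutoffs or self.CUTOFFS, "drug1"
        )

    def test_ratio_above_cutoff_is_resistant(self):
        v = self.classify(endo=100.0, drug=10.0)
        assert v.fit and v.affinity_resistant
        assert v.log_kstar_ratio == pytest.approx(1.0)

    def test_zero_endogenous_score_is_unfit_never_resistant(self):
        v = self.classify(endo=0.0, drug=50.0)
        assert not v.fit and not v.affinity_resistant

    def test_tie_at_cutoff_is_sensitive(self):
        v = self.classify(endo=100.0, drug=100.0)
        assert v.fit and not v.affinity_resistant
        v2 = self.classify(endo=100.0, drug=100.0 * 10**-0.42597)
        assert not v2.affinity_resistant  # exactly at the cutoff: sensitive

    def test_zero_drug_score_with_fit_clone_is_resistant(self):
        v = self.classify(endo=100.0, drug=0.0)
        assert v.fit and v.affinity_resistant
        assert math.isinf(v.log_kstar_ratio)

    def test_his_variants_require_all_states_resistant(self):
        cutoffs = {"ATP": make_cutoff(0.4)}

        def his(ratios):
            mutant = LogicalMutant(
                position=10,
                wt_aa="A",
                mut_aa="H",
                variant_scores={
                    tag: {"ATP": 100.0, "drug1": 100.0 * 10**-r}
                    for tag, r in zip(("HID", "HIE", "HIP"), ratios)
                },
                n_variants=3,
            )
            return classify_mutant(mutant, cutoffs, "drug1")

        assert his((0.9, 0.5, 1.1)).affinity_resistant
        assert not his((0.9, 0.3, 1.1)).affinity_resistant

    def test_multiple_endogenous_ligands_all_must_exceed_cutoff(self):
        cutoffs = {"EGF": make_cutoff(0.2), "TGFA": make_cutoff(0.2)}
        scores = {"EGF": 100.0, "TGFA": 100.0, "drug1": 10.0}
        assert classify_mutant(scores, cutoffs, "drug1").affinity_resistant
        # abrogated EGF binding: unfit even though TGFA tolerates the mutant
        scores = {"EGF": 0.0, "TGFA": 100.0, "drug1": 10.0}
        v = classify_mutant(scores, cutoffs, "drug1")
        assert not v.fit and not v.affinity_resistant
        # resistant vs TGFA only: overall sensitive
        scores = {"EGF": 120.0, "TGFA": 100.0, "drug1": 80.0}
        assert not classify_mutant(scores, cutoffs, "drug1").affinity_resistant

    def test_missing_score_raises(self):
        with pytest.raises(KeyError):
            classify_mutant({"ATP": 1.0}, self.CUTOFFS, "drug1")

    @given(
        endo=st.floats(0.01, 1e4),
        drug=st.floats(0.01, 1e4),
        lower=st.floats(0.01, 0.99),
    )
    def test_monotone_in_drug_score(self, endo, drug, lower):
        """Decreasing the drug score never flips resistant -> sensitive."""
        v1 = self.classify(endo=endo, drug=drug)
        v2 = self.classify(endo=endo, drug=drug * lower)
        if v1.affinity_resistant:
            assert v2.affinity_resistant

    @given(
        endo=st.floats(0.01, 1e4),
        drug=st.floats(0.01, 1e4),
        scale=st.floats(0.001, 1e3),
    )
    def test_scale_invariance(self, endo, drug, scale):
        """Multiplying every K* score by one positive constant changes nothing."""
        v1 = self.classify(endo=endo, drug=drug)
        v2 = self.classify(endo=endo * scale, drug=drug * scale)
        assert v1.affinity_resistant == v2.affinity_resistant
        assert v1.log_kstar_ratio == pytest.approx(v2.log_kstar_ratio, abs=1e-9)

    def test_swapping_roles_negates_cutoff_log_ratio(self):
        wt = compute_wt_stats(
            wt_pair_records({"r1": 100.0, "r2": 100.0}, {"r1": 100.0, "r2": 50.0})
        )
        fwd = compute_cutoff(wt, "ATP", "drug1")
        swapped_wt = compute_wt_stats(
            [make_record("ATP", "drug", r, s) for r, s in
             {"r1": 100.0, "r2": 100.0}.items()]
            + [make_record("drug1", "endogenous", r, s) for r, s in
               {"r1": 100.0, "r2": 50.0}.items()]
        )
        rev = compute_cutoff(swapped_wt, "drug1", "ATP")
        assert rev.log_ratio_avwt == pytest.approx(-fwd.log_ratio_avwt)
        assert rev.range_wt == pytest.approx(fwd.range_wt)


def verdict(pos, mut, fit, resistant):
    return AffinityVerdict(
        position=pos, wt_aa="A", mut_aa=mut, log_kstar_ratio=0.0,
        fit=fit, affinity_resistant=resistant,
    )


class TestCascade:
    def test_ten_mutant_pool_attrition(self):
        """6 fail affinity, 1 unfit, 1 TPM, 2 survive -> 0.6/0.1/0.1/0.2."""
        verdicts, feas = {}, {}
        muts = "CDEFGIKLMN"
        for i in range(6):
            key = (i, "A", muts[i])
            verdicts[key] = verdict(i, muts[i], fit=True, resistant=False)
            feas[key] = Feasibility.SPM
        key = (6, "A", muts[6])
        verdicts[key] = verdict(6, muts[6], fit=False, resistant=False)
        feas[key] = Feasibility.SPM
        key = (7, "A", muts[7])
        verdicts[key] = verdict(7, muts[7], fit=True, resistant=True)
        feas[key] = Feasibility.TPM
        for i in (8, 9):
            key = (i, "A", muts[i])
            verdicts[key] = verdict(i, muts[i], fit=True, resistant=True)
            feas[key] = Feasibility.DPM if i == 8 else Feasibility.SPM
        result = apply_cascade(verdicts, feas)
        s = result.summary
        assert (s.frac_affinity_removed, s.frac_unfit_removed,
                s.frac_tpm_removed, s.frac_surviving) == (0.6, 0.1, 0.1, 0.2)
        assert s.dpm_share_of_survivors == 0.5
        assert len(result.survivors) == 2

    def test_all_survive(self):
        verdicts = {(i, "A", "V"): verdict(i, "V", True, True) for i in range(4)}
        feas = {k: Feasibility.SPM for k in verdicts}
        s = apply_cascade(verdicts, feas).summary
        assert (s.frac_affinity_removed, s.frac_unfit_removed,
                s.frac_tpm_removed, s.frac_surviving) == (0.0, 0.0, 0.0, 1.0)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            apply_cascade({}, {})

    def test_key_mismatch_lists_offenders(self):
        verdicts = {(1, "A", "V"): verdict(1, "V", True, True)}
        with pytest.raises(KeyError, match=r"\(1, 'A', 'V'\)"):
            apply_cascade(verdicts, {})

    @given(
        st.lists(
            st.tuples(st.booleans(), st.booleans(), st.sampled_from(list(Feasibility))),
            min_size=1,
            max_size=40,
        )
    )
    def test_fractions_sum_to_one(self, pool):
        verdicts, feas = {}, {}
        for i, (fit, resistant, f) in enumerate(pool):
            key = (i, "A", "V")
            verdicts[key] = verdict(i, "V", fit, fit and resistant)
            feas[key] = f
        s = apply_cascade(verdicts, feas).summary
        total = (s.frac_affinity_removed + s.frac_unfit_removed
                 + s.frac_tpm_removed + s.frac_surviving)
        assert total == pytest.approx(1.0, abs=1e-12)
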