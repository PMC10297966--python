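"""Readouts: per-arm tables, genome summary identities, the Welch test
against an independent oracle, and the five-readout ALT caller."""

import numpy as np
import pytest
from scipy import stats

from telomap.errors import InsufficientDataError
from telomap.model import ALTThresholds, Category, ClassifiedMolecule, ReadoutSummary
from telomap.readouts import (
    arm_stats,
    call_alt,
    compare_cell_lines,
    compute_arm_tables,
    genome_summary,
    welch_t_test,
)


def _cm(i, category, arm="3q", kb=0.0):
    arms = () if category in (Category.ECTR, Category.UNCLASSIFIED) else (arm,)
    return ClassifiedMolecule(i, category, arms, kb)


class TestArmStats:
    def test_all_fusion_its_minus_and_tfe_arm(self):
        """A 23-molecule arm of 16 ITS- fusions and 7 TFEs: 69.6% / 30.4%,
        overall mean 0, undefined CV."""
        sightings = [_cm(i, Category.FUSION_ITS_MINUS) for i in range(16)]
        sightings += [_cm(16 + i, Category.TFE) for i in range(7)]
        row = arm_stats("3q", sightings)
        assert row.overall_count == 23
        assert round(row.its_minus_pct, 1) == 69.6
        assert round(row.tfe_pct, 1) == 30.4
        assert row.overall_mean_kb == 0.0
        assert row.cv is None

    def test_constant_end_telomeres(self):
        row = arm_stats("1p", [_cm(i, Category.END_TEL, "1p", 5.0) for i in range(10)])
        assert row.overall_mean_kb == pytest.approx(5.0)
        assert row.overall_sd_kb == 0.0
        assert row.endtel_pct == 100.0
        assert row.tfe_pct == row.its_plus_pct == row.its_minus_pct == 0.0

    def test_hand_computed_moments_with_zero_convention(self):
        """Lengths {0, 0, 5, 10} (2 TFE + 2 end telomeres): mean 3.75,
        sample sd 4.787."""
        sightings = [_cm(0, Category.TFE), _cm(1, Category.TFE),
                     _cm(2, Category.END_TEL, kb=5.0), _cm(3, Category.END_TEL, kb=10.0)]
        row = arm_stats("3q", sightings)
        assert row.overall_mean_kb == pytest.approx(3.75)
        assert row.overall_sd_kb == pytest.approx(4.787, abs=1e-3)
        assert row.overall_max_kb == 10.0

    def test_empty_arm_is_dropped(self):
        assert arm_stats("9p", []) is None

    def test_percentage_partition_sums_to_100(self, run_cache):
        _, result = run_cache("U2OS", 42)
        for row in result.arm_tables.values():
            total = row.endtel_pct + row.tfe_pct + row.its_plus_pct + row.its_minus_pct
            assert total == pytest.approx(100.0, abs=0.05)


class TestGenomeSummary:
    def test_constant_lengths_give_zero_cv(self):
        cms = [_cm(i, Category.END_TEL, kb=4.0) for i in range(8)]
        assert genome_summary(cms).cv == 0.0

    def test_cv_scale_invariance(self):
        rng = np.random.default_rng(0)
        kbs = rng.lognormal(1.0, 0.8, 50)
        base = [_cm(i, Category.END_TEL, kb=k) for i, k in enumerate(kbs)]
        scaled = [_cm(i, Category.END_TEL, kb=3 * k) for i, k in enumerate(kbs)]
        assert genome_summary(scaled).cv == pytest.approx(genome_summary(base).cv)

    def test_zeros_only_lower_the_mean(self, run_cache):
        _, result = run_cache("U2OS", 42)
        s = result.summary
        measured = [cm.telomere_length_kb for cm in result.classified
                    if cm.category in (Category.END_TEL, Category.FUSION_ITS_PLUS)]
        assert s.overall_mean_kb <= np.mean(measured)

    def test_pooled_weighted_mean_identity(self, run_cache):
        """overall mean == (n_end * end mean + n_its+ * its+ mean) / n exactly
        (TFE/ITS- contribute zeros)."""
        _, result = run_cache("U2OS", 42)
        s = result.summary
        n_end = round(s.endtel_pct / 100 * s.n_molecules)
        n_its = round(s.its_plus_pct / 100 * s.n_molecules)
        expected = (n_end * s.endtel_mean_kb + n_its * s.its_plus_mean_kb) / s.n_molecules
        assert s.overall_mean_kb == pytest.approx(expected, rel=1e-9)

    def test_all_arms_empty_raises(self):
        with pytest.raises(InsufficientDataError):
            genome_summary([_cm(1, Category.ECTR, kb=11.0)])


class TestWelch:
    def test_identical_samples(self):
        r = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t_statistic == 0.0
        assert r.p_value_two_tailed == 1.0

    def test_antisymmetry(self):
        a, b = [1.0, 2.0, 4.0], [2.0, 5.0, 6.0, 9.0]
        r1, r2 = welch_t_test(a, b), welch_t_test(b, a)
        assert r1.t_statistic == pytest.approx(-r2.t_statistic)
        assert r1.p_value_two_tailed == pytest.approx(r2.p_value_two_tailed)

    def test_formula_example(self):
        """{1,2,3} vs {2,3,4}: t = -1.2247, df = 4, p = 0.2878."""
        r = welch_t_test([1, 2, 3], [2, 3, 4])
        assert r.t_statistic == pytest.approx(-1.2247, abs=1e-4)
        assert r.degrees_of_freedom == pytest.approx(4.0)
        assert r.p_value_two_tailed == pytest.approx(0.2878, abs=1e-4)

    def test_matches_scipy_on_random_pairs(self):
        """Implementation agrees with scipy's Welch test to 1e-10 on 1000
        random sample pairs."""
        rng = np.random.default_rng(7)
        for _ in range(1000):
            a = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), rng.integers(2, 30))
            b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), rng.integers(2, 30))
            r = welch_t_test(a, b)
            t_ref, p_ref = stats.ttest_ind(a, b, equal_var=False)
            assert r.t_statistic == pytest.approx(t_ref, abs=1e-10)
            assert r.p_value_two_tailed == pytest.approx(p_ref, abs=1e-10)

    def test_degenerate_equal_zero_variance(self):
        r = welch_t_test([2.0, 2.0, 2.0], [2.0, 2.0])
        assert r.t_statistic == 0.0
        assert r.p_value_two_tailed == 1.0

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            welch_t_test([1.0], [1.0, 2.0])


class TestCompareCellLines:
    def test_self_comparison_p_is_one(self, run_cache):
        _, result = run_cache("U2OS", 42)
        tables = {"a": result.arm_tables, "b": result.arm_tables}
        out = compare_cell_lines(tables, "its_plus_pct_by_arm")
        assert out[("a", "b")].p_value_two_tailed == pytest.approx(1.0)

    def test_tel_positive_replicates_are_null(self, run_cache):
        """Two TEL+ replicates have all-zero TFE percentages on every arm:
        the degenerate-equal rule reports p = 1."""
        _, r1 = run_cache("LNCaP", 1)
        _, r2 = run_cache("LNCaP", 2)
        out = compare_cell_lines({"r1": r1.arm_tables, "r2": r2.arm_tables}, "its_plus_pct_by_arm")
        assert out[("r1", "r2")].p_value_two_tailed == pytest.approx(1.0)

    def test_alt_vs_tel_its_plus_is_significant(self, run_cache):
        """Fusion/ITS+ per-arm percentages separate an ALT+ from a TEL+
        simulation decisively."""
        _, alt = run_cache("U2OS", 42)
        _, tel = run_cache("LNCaP", 1)
        out = compare_cell_lines({"alt": alt.arm_tables, "tel": tel.arm_tables},
                                 "its_plus_pct_by_arm")
        r = out[("alt", "tel")]
        assert r.t_statistic > 0
        assert r.p_value_two_tailed < 1e-6

    def test_too_few_shared_arms(self, run_cache):
        _, result = run_cache("U2OS", 42)
        arm = next(iter(result.arm_tables))
        tables = {"a": result.arm_tables, "b": {arm: result.arm_tables[arm]}}
        out = compare_cell_lines(tables, "tfe_pct_by_arm")
        assert out[("a", "b")] is None


def _summary(its_plus=0.0, its_minus=0.0, tfe=0.0, cv=0.0, frac15=0.0):
    endtel = 100.0 - its_plus - its_minus - tfe
    return ReadoutSummary(
        n_molecules=1000, overall_mean_kb=3.0, overall_sd_kb=cv * 3.0,
        endtel_mean_kb=4.0, endtel_sd_kb=2.0, its_plus_mean_kb=None, its_plus_sd_kb=None,
        cv=cv, endtel_pct=endtel, tfe_pct=tfe, its_plus_pct=its_plus,
        its_minus_pct=its_minus, frac_gt_15kb=frac15, n_measured_telomeres=900,
        frac_arms_max_gt_10kb=0.0, per_arm_cvs={}, median_cv=None,
        ectr_count=0, n_unclassified=0,
    )


class TestALTCaller:
    def test_u2os_readouts_fire_all_five_flags(self):
        call = call_alt(_summary(its_plus=23.1, its_minus=12.2, tfe=6.4, cv=1.4, frac15=0.041))
        assert call.n_positive == 5
        assert call.call == "ALT_positive"

    def test_lncap_readouts_fire_no_flags(self):
        call = call_alt(_summary(cv=0.5, frac15=0.004))
        assert call.n_positive == 0
        assert call.call == "ALT_negative"

    def test_all_zero_summary_is_negative(self):
        assert call_alt(_summary()).call == "ALT_negative"

    def test_vote_threshold_is_configurable(self):
        s = _summary(its_plus=2.0, its_minus=0.5, cv=0.5)
        assert call_alt(s).call == "ALT_negative"          # 2 of 5 flags
        assert call_alt(s, ALTThresholds(votes_required=2)).call == "ALT_positive"
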