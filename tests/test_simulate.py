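"""Simulator: reference generation, profile transcription, tail calibration,
and the statistical structure of simulated molecule populations."""

import dataclasses

import numpy as np
import pytest

from telomap.errors import CalibrationError, InvalidParameterError, UnknownArmError, UnknownProfileError
from telomap.model import Category, LengthDistribution
from telomap.simulate import (
    SUPER_LONG_KB,
    build_worked_fixture,
    calibrate_tail,
    make_reference,
    profile_from_table1,
    simulate_cell_line,
)


class TestMakeReference:
    def test_single_arm_count_and_ascending_labels(self):
        ref = make_reference(n_arms=1, seed=5)
        assert len(ref) == 1
        arm = ref[ref.arm_ids()[0]]
        assert np.all(np.diff(arm.label_positions) > 0)

    def test_seeded_reproducibility(self):
        a = make_reference(n_arms=10, seed=3)
        b = make_reference(n_arms=10, seed=3)
        for arm_id in a.arm_ids():
            np.testing.assert_array_equal(a[arm_id].label_positions, b[arm_id].label_positions)

    def test_mean_label_spacing_recovered(self):
        """Empirical mean inter-label spacing within 3 SE of the requested mean."""
        ref = make_reference(n_arms=41, mean_label_spacing_bp=9000, map_length_bp=300_000, seed=1)
        gaps = np.concatenate([np.diff(a.label_positions) for a in ref.arms.values()])
        se = gaps.std(ddof=1) / np.sqrt(gaps.size)
        assert abs(gaps.mean() - 9000) < 3 * se

    def test_min_spacing_respected(self):
        ref = make_reference(n_arms=20, min_spacing_bp=1500, seed=2)
        gaps = np.concatenate([np.diff(a.label_positions) for a in ref.arms.values()])
        assert gaps.min() >= 1500

    def test_acrocentric_p_arms_never_generated(self):
        ref = make_reference(n_arms=41, seed=0)
        assert not set(ref.arm_ids()) & {"13p", "14p", "15p", "21p", "22p"}
        assert {"3q", "19q", "21q"} <= set(ref.arm_ids())

    @pytest.mark.parametrize("kwargs", [
        {"mean_label_spacing_bp": -1}, {"map_length_bp": 0},
        {"min_spacing_bp": 0}, {"map_length_bp": 50_000},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            make_reference(**kwargs)


class TestCalibrateTail:
    def test_zero_target_needs_no_tail(self):
        dist = LengthDistribution(body_mean_kb=3.0, body_sd_kb=1.0)
        assert calibrate_tail(dist, 0.0).tail_weight == 0.0

    def test_saos2_tail_mass_by_monte_carlo(self):
        """Calibrated Saos-2-like body hits P(>15 kb) = 0.043 within MC error."""
        dist = calibrate_tail(LengthDistribution(body_mean_kb=4.5, body_sd_kb=5.6), 0.043)
        rng = np.random.default_rng(0)
        frac = (dist.sample_kb(rng, 100_000) > SUPER_LONG_KB).mean()
        assert abs(frac - 0.043) < 0.003

    def test_tail_weight_monotone_in_target(self):
        dist = LengthDistribution(body_mean_kb=5.0, body_sd_kb=2.2)
        targets = [0.01, 0.03, 0.05, 0.10, 0.20]
        weights = [calibrate_tail(dist, t).tail_weight for t in targets]
        assert all(a < b for a, b in zip(weights, weights[1:]))

    def test_unreachable_target_raises(self):
        heavy = LengthDistribution(body_mean_kb=10.0, body_sd_kb=10.0)  # intrinsic mass >> 1e-3
        with pytest.raises(CalibrationError):
            calibrate_tail(heavy, 0.001)


class TestProfiles:
    def test_u2os_category_fractions(self):
        p = profile_from_table1("U2OS")
        assert p.frac_its_plus == pytest.approx(0.231)
        assert p.frac_its_minus == pytest.approx(0.122)
        assert p.frac_tfe == pytest.approx(0.064)
        assert p.frac_endtel == pytest.approx(0.583)

    def test_tel_positive_line_is_pure_end_telomeres(self):
        p = profile_from_table1("LNCaP")
        assert p.frac_its_plus == p.frac_its_minus == p.frac_tfe == 0.0
        assert p.frac_endtel == 1.0
        assert p.ectr_per_100_molecules == 0.0

    def test_u2os_endtel_body_moments(self):
        """The end-telomere body reproduces the 5.0 +/- 2.2 kb moments to 1%."""
        body = profile_from_table1("U2OS").endtel_len.with_tail_weight(0.0)
        x = body.sample_kb(np.random.default_rng(1), 100_000)
        assert x.mean() == pytest.approx(5.0, rel=0.01)
        assert x.std(ddof=1) == pytest.approx(2.2, rel=0.01)

    def test_pooled_super_long_mass_is_calibrated(self):
        """Measured-telomere mixture (end + internal telomeres) carries the
        configured >15 kb mass for a line whose target is reachable."""
        p = profile_from_table1("Saos-2")
        w_end = p.frac_endtel / (p.frac_endtel + p.frac_its_plus)
        pooled = w_end * p.endtel_len.sf_kb(15.0) + (1 - w_end) * p.its_plus_len.sf_kb(15.0)
        assert pooled == pytest.approx(0.043, abs=2e-3)

    def test_unknown_profile_raises(self):
        with pytest.raises(UnknownProfileError):
            profile_from_table1("HeLa")

    def test_name_lookup_is_forgiving(self):
        assert profile_from_table1("saos2").name == "Saos-2"


class TestSimulateCellLine:
    def test_seeded_determinism(self, reference, profiles):
        a = simulate_cell_line(profiles["U2OS"], reference, seed=9)
        b = simulate_cell_line(profiles["U2OS"], reference, seed=9)
        assert len(a) == len(b)
        for x, y in zip(a, b):
            assert x.length_bp == y.length_bp
            np.testing.assert_array_equal(x.nick_labels, y.nick_labels)
            np.testing.assert_array_equal(x.tel_intensities, y.tel_intensities)

    def test_truth_fractions_match_profile(self, reference, profiles):
        """Simulated category mix converges to the profile fractions
        (3-SE binomial bound at n ~ 2000)."""
        prof = dataclasses.replace(profiles["U2OS"], mean_molecules_per_arm=50)
        mols = simulate_cell_line(prof, reference, seed=42, apply_noise=False)
        anchored = [m for m in mols if m.truth.category is not Category.ECTR]
        n = len(anchored)
        for cat, frac in prof.category_fractions.items():
            got = sum(1 for m in anchored if m.truth.category is cat) / n
            se = np.sqrt(frac * (1 - frac) / n)
            assert abs(got - frac) < 3 * se, f"{cat}: {got:.4f} vs {frac}"

    def test_degenerate_pure_endtel_mixture(self, reference, profiles):
        prof = dataclasses.replace(
            profiles["LNCaP"], frac_endtel=1.0, frac_tfe=0.0,
            frac_its_plus=0.0, frac_its_minus=0.0,
        )
        mols = simulate_cell_line(prof, reference, seed=3, apply_noise=False)
        for m in mols:
            if m.truth.category is Category.ECTR:
                continue
            assert m.truth.category is Category.END_TEL
            assert m.tel_positions.size == 1          # exactly one terminal telomere label
            assert m.tel_positions[0] in (0.0, m.length_bp)

    def test_ectr_length_distribution(self, profiles):
        """ECTR lengths average ~11 kb (the U2OS default)."""
        x = profiles["U2OS"].ectr_len.sample_kb(np.random.default_rng(2), 10_000, 0.1)
        se = x.std(ddof=1) / np.sqrt(x.size)
        assert abs(x.mean() - 11.0) < 3 * se

    def test_intensity_proportional_to_true_length(self, reference, profiles):
        """Origin regression of telomere-label intensity on true length
        recovers the calibration constant within 2% at zero intensity noise."""
        mols = simulate_cell_line(profiles["U2OS"], reference, seed=5, apply_noise=False)
        pairs = [(m.truth.telomere_kb, m.tel_intensities.sum())
                 for m in mols if m.truth.category is Category.END_TEL]
        t = np.array([p[0] for p in pairs])
        i = np.array([p[1] for p in pairs])
        k_hat = (t @ i) / (t @ t)
        assert k_hat == pytest.approx(1000.0, rel=0.02)

    def test_empty_reference_rejected(self, profiles):
        from telomap.model import ReferenceSet
        with pytest.raises(InvalidParameterError):
            simulate_cell_line(profiles["U2OS"], ReferenceSet(arms={}), seed=0)


class TestWorkedFixture:
    def test_fusion_composition_counts(self, reference):
        mols = build_worked_fixture(
            "3q",
            [(Category.FUSION_ITS_PLUS, 3, 2.0), (Category.FUSION_ITS_MINUS, 3, 0.0)],
            reference,
        )
        assert len(mols) == 6

    def test_19q_composition_counts(self, reference):
        mols = build_worked_fixture(
            "19q",
            [(Category.FUSION_ITS_PLUS, 25, 1.8), (Category.END_TEL, 1, 5.0)],
            reference,
        )
        assert len(mols) == 26

    def test_empty_composition(self, reference):
        assert build_worked_fixture("3q", [], reference) == []

    def test_unknown_arm_raises(self, reference):
        with pytest.raises(UnknownArmError):
            build_worked_fixture("13p", [(Category.TFE, 1, 0.0)], reference)

    def test_ectr_not_an_arm_category(self, reference):
        with pytest.raises(InvalidParameterError):
            build_worked_fixture("3q", [(Category.ECTR, 1, 11.0)], reference)
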