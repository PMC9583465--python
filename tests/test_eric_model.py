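"""Forward eRIC model, closed-form resonance and cohort simulation."""

import numpy as np
import pytest
from scipy.optimize import brentq

from oscml import (
    CohortConfig, ERICParameters, ImpedanceSpectrum, cohort_to_frames,
    eric_impedance, read_cohort, resonant_frequency_analytic, simulate_cohort,
    write_cohort,
)
from oscml.eric_model import GROUP_ALTERED, GROUP_CONTROL, GROUP_NORMAL


def _oracle_impedance(p: ERICParameters, f: float) -> complex:
    """Independent series-parallel complex-arithmetic evaluation."""
    w = 2 * np.pi * f
    z_c = 1.0 / (1j * w * p.C)
    z_par = (p.Rp * z_c) / (p.Rp + z_c)
    return p.R + 1j * w * p.I + z_par


class TestForwardModel:
    def test_matches_complex_arithmetic_oracle(self):
        p = ERICParameters(R=2, Rp=3, I=0.01, C=0.02)
        for f in (4.0, 8.0, 20.0, 32.0):
            z = eric_impedance(p, [f]).impedance[0]
            assert z == pytest.approx(_oracle_impedance(p, f), abs=1e-12)

    def test_vanishing_compliance_limit(self):
        p = ERICParameters(R=2, Rp=3, I=0.01, C=1e-12)
        spec = eric_impedance(p, np.arange(4.0, 33.0, 2.0))
        w = 2 * np.pi * spec.frequencies
        assert spec.resistance == pytest.approx(np.full(15, p.R + p.Rp), rel=1e-9)
        assert spec.reactance == pytest.approx(w * p.I, rel=1e-9)

    def test_no_peripheral_branch(self):
        p = ERICParameters(R=2, Rp=0, I=0.01, C=0.02)
        spec = eric_impedance(p, [4.0, 16.0])
        assert spec.resistance == pytest.approx([2.0, 2.0])
        assert spec.reactance == pytest.approx(2 * np.pi * np.array([4.0, 16.0]) * 0.01)

    def test_rejects_nonpositive_frequency_and_compliance(self):
        p = ERICParameters(R=2, Rp=3, I=0.01, C=0.02)
        with pytest.raises(ValueError, match="-4"):
            eric_impedance(p, [-4.0])
        with pytest.raises(ValueError, match="compliance"):
            ERICParameters(R=2, Rp=3, I=0.01, C=0.0)

    def test_real_part_monotone_and_bounded(self):
        rng = np.random.default_rng(0)
        f = np.linspace(1.0, 200.0, 400)
        for _ in range(50):
            p = ERICParameters(R=rng.uniform(0.5, 5), Rp=rng.uniform(0.5, 8),
                               I=rng.uniform(0.002, 0.05), C=rng.uniform(0.005, 0.1))
            re = eric_impedance(p, f).resistance
            assert np.all(np.diff(re) <= 1e-12)
            assert np.all(re <= p.R + p.Rp + 1e-12)
            assert np.all(re >= p.R - 1e-12)

    def test_high_frequency_reactance_is_inertive(self):
        """X -> w*I as w -> inf; the peripheral term decays as 1/(w*C).

        At w = 10*w_r the relative residual is exactly
        1/(100*(1 - I/(Rp^2*C))), marginally above 1% for any valid
        parameters, so the bound tested is that closed form.
        """
        p = ERICParameters(R=2, Rp=3, I=0.01, C=0.02)
        fr = resonant_frequency_analytic(p)
        for mult, bound in ((10, 1.0 / (100 * (1 - p.I / (p.Rp**2 * p.C))) + 1e-6),
                            (30, 0.0012)):
            f = mult * fr
            x = eric_impedance(p, [f]).reactance[0]
            assert x == pytest.approx(2 * np.pi * f * p.I, rel=bound)


class TestResonantFrequency:
    def _bracketed_root(self, p: ERICParameters) -> float:
        def imag(f):
            return eric_impedance(p, [f]).reactance[0]
        return brentq(imag, 1e-3, 1e4, xtol=1e-12)

    def test_agrees_with_root_bracketing_over_random_draws(self):
        rng = np.random.default_rng(1)
        checked = 0
        while checked < 1000:
            p = ERICParameters(R=rng.uniform(0.5, 5), Rp=rng.uniform(0.5, 8),
                               I=rng.uniform(0.002, 0.05), C=rng.uniform(0.005, 0.1))
            fr = resonant_frequency_analytic(p)
            if fr is None:
                assert p.Rp**2 * p.C <= p.I
                continue
            assert fr == pytest.approx(self._bracketed_root(p), rel=1e-9)
            checked += 1

    def test_zero_reactance_at_analytic_root(self):
        p = ERICParameters(R=2, Rp=3, I=0.01, C=0.02)
        fr = resonant_frequency_analytic(p)
        assert abs(eric_impedance(p, [fr]).reactance[0]) < 1e-9

    def test_none_when_no_crossing_exists(self):
        # Rp^2*C = 0.002 <= I = 0.01: reactance positive everywhere
        assert resonant_frequency_analytic(ERICParameters(R=1, Rp=1, I=0.01, C=0.002)) is None

    def test_joint_scaling_of_inertance_and_compliance(self):
        p = ERICParameters(R=2, Rp=3, I=0.01, C=0.02)
        for k in (0.5, 2.0):
            q = ERICParameters(R=p.R, Rp=p.Rp, I=p.I * k, C=p.C * k)
            fr = resonant_frequency_analytic(q)
            assert fr == pytest.approx(self._bracketed_root(q), rel=1e-9)


class TestCohortSimulation:
    def test_zero_noise_average_equals_forward_model(self):
        cfg = CohortConfig(noise=0.0, replicates=3, seed=5)
        rec = simulate_cohort(cfg)[0]
        clean = eric_impedance(rec.true_params, cfg.frequencies)
        assert rec.spectrum.resistance == pytest.approx(clean.resistance, abs=1e-12)
        assert rec.spectrum.reactance == pytest.approx(clean.reactance, abs=1e-12)

    def test_average_is_mean_of_replicates(self, default_cohort):
        rec = default_cohort[0]
        stacked = np.mean([s.resistance for s in rec.replicate_spectra], axis=0)
        assert rec.spectrum.resistance == pytest.approx(stacked, abs=1e-12)

    def test_same_seed_reproduces_cohort(self):
        a = simulate_cohort(CohortConfig(seed=9))
        b = simulate_cohort(CohortConfig(seed=9))
        for ra, rb in zip(a, b):
            assert ra.group == rb.group
            assert ra.spectrum.resistance == pytest.approx(rb.spectrum.resistance, abs=0)

    def test_default_group_sizes_and_labels(self, default_cohort):
        groups = [r.group for r in default_cohort]
        assert groups.count(GROUP_CONTROL) == 25
        assert groups.count(GROUP_NORMAL) == 24
        assert groups.count(GROUP_ALTERED) == 23
        assert {r.label for r in default_cohort} == {0, 1}

    def test_disease_shifts_rt_fr_up_and_cdyn_down(self):
        """Median Rt and Fr higher, Cdyn lower in disease (1000-subject draw)."""
        cfg = CohortConfig(n_control=500, n_normal=250, n_altered=250, seed=3)
        by_group = {GROUP_CONTROL: [], GROUP_NORMAL: [], GROUP_ALTERED: []}
        for rec in simulate_cohort(cfg):
            p = rec.true_params
            fr = resonant_frequency_analytic(p)
            x4 = rec.spectrum.reactance[0]
            by_group[rec.group].append((p.Rt, fr, -1 / (2 * np.pi * 4 * x4)))
        med = {g: np.median(np.array(v), axis=0) for g, v in by_group.items()}
        for g in (GROUP_NORMAL, GROUP_ALTERED):
            assert med[g][0] > med[GROUP_CONTROL][0]  # Rt up
            assert med[g][1] > med[GROUP_CONTROL][1]  # Fr up
            assert med[g][2] < med[GROUP_CONTROL][2]  # Cdyn down

    def test_rejects_degenerate_config(self):
        with pytest.raises(ValueError, match="noise"):
            CohortConfig(noise=-0.1)
        with pytest.raises(ValueError, match="n_control"):
            CohortConfig(n_control=0)

    def test_cohort_csv_round_trip(self, default_cohort, tmp_path):
        write_cohort(default_cohort, tmp_path / "s.csv", tmp_path / "l.csv")
        back = read_cohort(tmp_path / "s.csv", tmp_path / "l.csv")
        assert len(back) == len(default_cohort)
        for ra, rb in zip(default_cohort, back):
            assert ra.subject_id == rb.subject_id
            assert ra.group == rb.group
            np.testing.assert_allclose(ra.spectrum.resistance, rb.spectrum.resistance)

    def test_spectra_frame_layout(self, default_cohort):
        spectra, labels = cohort_to_frames(default_cohort)
        assert list(spectra.columns) == ["subject_id", "replicate", "frequency_hz",
                                         "resistance", "reactance"]
        assert set(spectra["replicate"]) == {0, 1, 2, 3}
        assert len(labels) == 72


def test_spectrum_rejects_bad_grids():
    with pytest.raises(ValueError, match="length"):
        ImpedanceSpectrum(np.array([4.0, 6.0]), np.array([1.0]), np.array([0.0, 0.1]))
    with pytest.raises(ValueError, match="increasing"):
        ImpedanceSpectrum(np.array([6.0, 4.0]), np.array([1.0, 1.0]), np.array([0.0, 0.1]))
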