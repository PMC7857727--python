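"""Profile I/O, logarithmic rebinning and Guinier analysis."""

import numpy as np
import pytest

from conftest import make_sphere_profile, make_two_point_profile
from ringfit.saxs_io import (GuinierError, ProfileFormatError, ScatteringProfile,
                             guinier_fit, read_profile, rebin_log, write_profile)


class TestProfileValidation:
    def test_arrays_must_match_and_be_long_enough(self):
        with pytest.raises(ProfileFormatError):
            ScatteringProfile([0.1, 0.2], [1, 2], [0.1, 0.1])
        with pytest.raises(ProfileFormatError):
            ScatteringProfile([0.1] * 5, [1] * 5, [0.1] * 4)

    def test_non_monotone_q_names_first_offending_index(self):
        q = [0.1, 0.2, 0.15, 0.3, 0.4]
        with pytest.raises(ProfileFormatError, match="index 2"):
            ScatteringProfile(q, np.ones(5), np.ones(5))

    def test_sigma_must_be_positive(self):
        with pytest.raises(ProfileFormatError, match="sigma"):
            ScatteringProfile([0.1, 0.2, 0.3, 0.4, 0.5], np.ones(5),
                              [0.1, 0.1, 0.0, 0.1, 0.1])


class TestReadWrite:
    def test_header_lines_skipped(self, tmp_path):
        path = tmp_path / "p.dat"
        path.write_text("# a header\nq I err\n"
                        + "".join(f"{0.01 * i} {1.0 / i} {0.01}\n"
                                  for i in range(1, 6)))
        prof = read_profile(path)
        assert len(prof) == 5

    def test_zero_sigma_rows_dropped_with_warning(self, tmp_path, caplog):
        path = tmp_path / "p.dat"
        rows = [f"{0.01 * i} 1.0 0.01\n" for i in range(1, 7)]
        rows.insert(2, "0.015 -0.2 0.0\n")
        path.write_text("".join(rows))
        with caplog.at_level("WARNING"):
            prof = read_profile(path)
        assert len(prof) == 6
        assert any("sigma" in rec.message for rec in caplog.records)

    def test_too_few_rows_is_format_error(self, tmp_path):
        path = tmp_path / "p.dat"
        path.write_text("0.1 1.0 0.1\n0.2 0.9 0.1\n")
        with pytest.raises(ProfileFormatError):
            read_profile(path)

    def test_round_trip_six_significant_digits(self, tmp_path, sphere50_profile):
        path = tmp_path / "out.dat"
        write_profile(path, sphere50_profile)
        back = read_profile(path)
        for a, b in ((sphere50_profile.q, back.q),
                     (sphere50_profile.intensity, back.intensity),
                     (sphere50_profile.sigma, back.sigma)):
            np.testing.assert_allclose(a, b, rtol=1e-6, atol=1e-300)


class TestRebinLog:
    def test_reduces_to_at_most_n_bins_with_increasing_q(self):
        prof = make_sphere_profile(50.0, n_q=800)
        out = rebin_log(prof, 180)
        assert len(out) <= 180
        assert np.all(np.diff(out.q) > 0)

    def test_identity_when_bins_exceed_points(self):
        prof = make_sphere_profile(50.0, n_q=100)
        out = rebin_log(prof, 100)
        assert out is prof

    def test_inverse_variance_combination_hand_computed(self):
        # two points in one bin with sigma 1 and 2:
        # I = (I1/1 + I2/4) / (1 + 1/4), sigma = 1/sqrt(1 + 1/4)
        q = np.array([1.0, 1.05, 2.0, 3.0, 4.5, 6.0, 8.0, 9.5])
        intensity = np.array([2.0, 4.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0])
        sigma = np.array([1.0, 2.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0])
        out = rebin_log(ScatteringProfile(q, intensity, sigma), 7)
        expected_i = (2.0 / 1.0 + 4.0 / 4.0) / (1.0 + 0.25)
        expected_s = 1.0 / np.sqrt(1.25)
        assert out.intensity[0] == pytest.approx(expected_i)
        assert out.sigma[0] == pytest.approx(expected_s)

    def test_combined_sigma_never_exceeds_member_sigma(self):
        rng = np.random.default_rng(1)
        n, n_bins = 300, 40
        q = np.sort(rng.uniform(0.01, 0.5, n))
        q += np.arange(n) * 1e-6  # enforce strict monotonicity
        prof = ScatteringProfile(q, rng.uniform(0.5, 2.0, n),
                                 rng.uniform(0.01, 0.1, n))
        out = rebin_log(prof, n_bins)
        # recompute the bin assignment and compare bin by occupied bin
        edges = np.geomspace(prof.q[0], prof.q[-1] * (1 + 1e-12), n_bins + 1)
        idx = np.clip(np.searchsorted(edges, prof.q, side="right") - 1,
                      0, n_bins - 1)
        occupied = [b for b in range(n_bins) if np.any(idx == b)]
        assert len(occupied) == len(out)
        for j, b in enumerate(occupied):
            assert out.sigma[j] <= prof.sigma[idx == b].min() + 1e-12


class TestGuinier:
    @pytest.mark.parametrize("radius", [20.0, 50.0, 100.0])
    def test_sphere_rg_within_one_percent(self, radius):
        prof = make_sphere_profile(radius, n_q=1500)
        result = guinier_fit(prof)
        expected = np.sqrt(3.0 / 5.0) * radius
        assert result.rg == pytest.approx(expected, rel=0.01)
        assert result.i0 == pytest.approx(1.0, rel=0.02)
        assert result.q_max * result.rg <= result.qrg_limit * 1.01

    def test_two_point_rg_is_half_separation(self):
        prof = make_two_point_profile(60.0)
        result = guinier_fit(prof)
        assert result.rg == pytest.approx(30.0, rel=0.02)

    def test_flat_curve_is_degenerate(self):
        q = np.linspace(0.01, 0.3, 100)
        prof = ScatteringProfile(q, np.ones(100), np.full(100, 1e-3))
        with pytest.raises(GuinierError):
            guinier_fit(prof)

    def test_aggregation_flag_on_low_q_upturn(self):
        from conftest import sphere_form_factor
        prof = make_sphere_profile(30.0, n_q=800)
        # a small admixture of large aggregates lifts the lowest-q points
        aggregate = 0.05 * sphere_form_factor(prof.q, 150.0)
        flagged = guinier_fit(ScatteringProfile(prof.q,
                                                prof.intensity + aggregate,
                                                prof.sigma))
        clean = guinier_fit(prof)
        assert flagged.aggregation_flag
        assert not clean.aggregation_flag
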