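import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import ndtr

from memfrac import imaging_io, profiles, synthetic
from memfrac.profiles import (
    Profile,
    align_and_average,
    bootstrap_ci,
    correct_pm_marker,
    default_axis,
    estimate_from_set,
    line_scan,
    normalize_profiles,
    pm_association,
    realign_on_pm,
    unmix_profile,
)
from memfrac.roiset import LineRoi

from helpers import grid_search_nnls

ROLES = imaging_io.ROLES
AXIS = default_axis(0.14)


def _edge(x, sigma=0.18):
    return ndtr(-x / sigma)


def _gauss(x, sigma=0.18):
    return np.exp(-0.5 * (x / sigma) ** 2)


def _profile(values, role="POI", axis=AXIS):
    return Profile(axis, np.asarray(values, dtype=float), role)


class TestLineScan:
    def test_constant_field(self):
        img = np.full((40, 40), 7.25)
        prof = line_scan(img, LineRoi(5, 20, 35, 20, width=10), pixel_size=0.14)
        np.testing.assert_allclose(prof.intensities, 7.25)

    def test_linear_ramp_slope(self):
        # bilinear interpolation reproduces linear fields exactly
        img = np.tile(np.arange(50.0), (50, 1))
        prof = line_scan(img, LineRoi(5, 25, 45, 25, width=5), pixel_size=1.0)
        slopes = np.diff(prof.intensities) / np.diff(prof.positions)
        np.testing.assert_allclose(slopes, 1.0, atol=1e-6)

    def test_width_averaging_matches_supersampled_oracle(
        self, noiseless_spec, noiseless_stack
    ):
        stack, _ = noiseless_stack
        img = stack.image("PM_marker")
        roi = synthetic.radial_line_rois(noiseless_spec, 8, seed=5)[3]
        prof = line_scan(img, roi, pixel_size=0.14)
        # oracle: brute-force 16x supersampling of the width average (16
        # sub-offsets per 1-px perpendicular sample)
        from scipy import ndimage

        p0 = np.array([roi.x1, roi.y1])
        p1 = np.array([roi.x2, roi.y2])
        length = np.linalg.norm(p1 - p0)
        u = (p1 - p0) / length
        perp = np.array([-u[1], u[0]])
        t = np.arange(0.0, length + 1e-9, 1.0)
        fine = (np.arange(roi.width * 16) - (roi.width * 16 - 1) / 2) / 16.0
        xs = p0[0] + t[None, :] * u[0] + fine[:, None] * perp[0]
        ys = p0[1] + t[None, :] * u[1] + fine[:, None] * perp[1]
        oracle = ndimage.map_coordinates(img, [ys, xs], order=1).mean(axis=0)
        scale = np.ptp(oracle)
        assert np.abs(prof.intensities - oracle).max() < 0.005 * scale

    def test_roi_exiting_image_errors(self):
        img = np.zeros((20, 20))
        with pytest.raises(ValueError, match="exits"):
            line_scan(img, LineRoi(2, 10, 40, 10, width=3), pixel_size=0.14)


class TestAlignAndAverage:
    def _triple(self, offset=0.0, flip=False, n=100, step=0.14):
        x = np.arange(n) * step
        center = x[n // 2] + offset
        pm = 3 * _gauss(x - center) + _edge(x - center)
        cp = _edge(x - center)
        poi = _edge(x - center)
        if flip:
            pm, cp, poi = pm[::-1], cp[::-1], poi[::-1]
        return {
            "PM_marker": Profile(x, pm, "PM_marker"),
            "CP_marker": Profile(x, cp, "CP_marker"),
            "POI": Profile(x, poi, "POI"),
        }

    def test_centered_inputs_get_common_shift(self):
        # identical lines get identical shifts, close to the marker peak
        # (which sits slightly cytoplasm-side of the membrane because the
        # marker's own cytoplasmic pool tilts the Gaussian)
        triples = [self._triple() for _ in range(3)]
        pset = align_and_average(triples, axis=AXIS)
        mid = triples[0]["PM_marker"].positions[50]
        assert np.ptp(pset.line_shifts) < 1e-12
        np.testing.assert_allclose(pset.line_shifts, mid, atol=0.05)
        # peak of the average lands at 0
        assert abs(pset.axis[np.nanargmax(pset.averages[0])]) < 0.14

    def test_random_offsets_recovered(self):
        rng = np.random.default_rng(0)
        offsets = rng.uniform(-1.0, 1.0, size=20)
        triples = [self._triple(offset=o) for o in offsets]
        pset = align_and_average(triples, axis=AXIS)
        # all shifts recover the injected offsets up to a common constant
        mid = triples[0]["PM_marker"].positions[50]
        np.testing.assert_allclose(pset.line_shifts - mid, offsets, atol=0.07)
        peak_pos = pset.axis[np.nanargmax(pset.averages[0])]
        assert abs(peak_pos) < 0.07  # within half a step

    def test_cytoplasm_right_line_is_flipped(self):
        pset = align_and_average([self._triple(flip=True)], axis=AXIS)
        assert pset.line_flipped[0]
        cp = pset.averages[1]
        left = np.nanmean(cp[pset.axis < -1])
        right = np.nanmean(cp[pset.axis > 1])
        assert left > right

    def test_peakless_line_rejected(self):
        flat = self._triple()
        flat["PM_marker"] = Profile(
            flat["PM_marker"].positions,
            np.ones_like(flat["PM_marker"].intensities),
            "PM_marker",
        )
        with pytest.warns(UserWarning, match="rejected"):
            pset = align_and_average([self._triple(), flat], axis=AXIS)
        assert pset.n_lines == 1
        assert pset.rejected == [1]


class TestNormalize:
    def _pset(self, scale=2.0, bg=0.1):
        triples = []
        x = AXIS
        vals = scale * (_edge(x) + bg / scale)
        rows = np.stack([np.stack([vals, vals, vals])] * 3)
        pset = profiles.ProfileSet(axis=x, aligned=rows)
        return pset

    def test_windows_forced_by_definition(self):
        pset = normalize_profiles(self._pset())
        for ch in range(3):
            avg = pset.averages[ch]
            assert np.nanmean(avg[AXIS > 2.0]) == pytest.approx(0.0, abs=1e-9)
            cyt = (AXIS >= -2.5) & (AXIS <= -1.5)
            assert np.nanmean(avg[cyt]) == pytest.approx(1.0, abs=1e-9)

    def test_idempotence(self):
        once = normalize_profiles(self._pset())
        twice = normalize_profiles(once)
        np.testing.assert_allclose(twice.averages, once.averages, atol=1e-6)

    def test_erf_edge_plateau(self):
        pset = normalize_profiles(self._pset(scale=5.0, bg=0.3))
        avg = pset.averages[2]
        assert np.nanmean(avg[AXIS < -2.0]) == pytest.approx(1.0, abs=1e-3)
        assert np.nanmax(avg) <= 1.0 + 1e-6

    def test_degenerate_normalization_errors(self):
        pset = self._pset()
        pset.aligned = -pset.aligned
        with pytest.raises(profiles.NormalizationError):
            normalize_profiles(pset)


class TestCorrectPmMarker:
    def test_self_cancellation(self):
        f = _profile(_edge(AXIS), "PM_marker")
        g = _profile(_edge(AXIS), "CP_marker")
        np.testing.assert_allclose(correct_pm_marker(f, g).intensities, 0.0)

    def test_additivity_recovers_gaussian(self):
        peak = 3 * _gauss(AXIS)
        f = _profile(_edge(AXIS) + peak, "PM_marker")
        g = _profile(_edge(AXIS), "CP_marker")
        np.testing.assert_allclose(
            correct_pm_marker(f, g).intensities, peak, atol=1e-12
        )


class TestUnmix:
    def test_exact_basis_member(self):
        cp = _profile(_edge(AXIS), "CP_marker")
        pm = _profile(3 * _gauss(AXIS), "PM_basis")
        res = unmix_profile(_profile(_edge(AXIS)), cp, pm)
        assert res.a_cp == pytest.approx(1.0, abs=1e-10)
        assert res.a_pm == pytest.approx(0.0, abs=1e-10)

    def test_constructed_mixture_recovered(self):
        cp = _profile(_edge(AXIS), "CP_marker")
        pm = _profile(3 * _gauss(AXIS), "PM_basis")
        poi = _profile(0.8 * cp.intensities + 0.2 * pm.intensities)
        res = unmix_profile(poi, cp, pm)
        assert res.a_cp == pytest.approx(0.8, abs=1e-8)
        assert res.a_pm == pytest.approx(0.2, abs=1e-8)
        # independent dense grid-search oracle agrees
        w = (AXIS >= -2.25) & (AXIS <= 2.25)
        g1, g2 = grid_search_nnls(
            cp.intensities[w], pm.intensities[w], poi.intensities[w]
        )
        assert abs(g1 - res.a_cp) < 2e-3 and abs(g2 - res.a_pm) < 2e-3

    def test_unphysical_negative_membrane_clamps_to_boundary(self):
        cp = _profile(_edge(AXIS), "CP_marker")
        pm = _profile(3 * _gauss(AXIS), "PM_basis")
        poi = _profile(cp.intensities - 0.3 * pm.intensities)
        res = unmix_profile(poi, cp, pm)
        assert res.a_pm == 0.0
        w = (AXIS >= -2.25) & (AXIS <= 2.25)
        g1, g2 = grid_search_nnls(
            cp.intensities[w], pm.intensities[w], poi.intensities[w]
        )
        assert g2 == 0.0
        assert res.a_cp == pytest.approx(g1, abs=2e-3)

    def test_collinear_bases_rejected(self):
        cp = _profile(_edge(AXIS), "CP_marker")
        pm = _profile(2.0 * _edge(AXIS), "PM_basis")
        with pytest.raises(profiles.UnmixError, match="collinear"):
            unmix_profile(_profile(_edge(AXIS)), cp, pm)

    def test_component_sum_reproduces_fit(self):
        cp = _profile(_edge(AXIS), "CP_marker")
        pm = _profile(3 * _gauss(AXIS), "PM_basis")
        poi = _profile(0.5 * cp.intensities + 0.1 * pm.intensities)
        res = unmix_profile(poi, cp, pm)
        np.testing.assert_allclose(
            res.cp_component + res.pm_component, poi.intensities, atol=1e-9
        )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        a_cp=st.floats(0.0, 2.0),
        a_pm=st.floats(-0.5, 1.5),
        noise=st.floats(0.0, 0.05),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_solver_matches_grid_oracle(self, a_cp, a_pm, noise, seed):
        rng = np.random.default_rng(seed)
        cp_v = _edge(AXIS)
        pm_v = 3 * _gauss(AXIS)
        target = a_cp * cp_v + a_pm * pm_v + noise * rng.normal(size=AXIS.size)
        res = unmix_profile(
            _profile(target), _profile(cp_v, "CP_marker"), _profile(pm_v, "PM_basis")
        )
        w = (AXIS >= -2.25) & (AXIS <= 2.25)
        g1, g2 = grid_search_nnls(cp_v[w], pm_v[w], target[w])
        assert abs(res.a_cp - g1) < 2e-3
        assert abs(res.a_pm - g2) < 2e-3


class TestVectorizedNnls:
    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_closed_form_matches_scipy_nnls(self, seed):
        from scipy.optimize import nnls

        from memfrac.profiles import _nnls2

        rng = np.random.default_rng(seed)
        x1 = rng.normal(size=30)
        x2 = rng.normal(size=30)
        b = rng.normal(size=30)
        coef, _ = nnls(np.column_stack([x1, x2]), b)
        a1, a2 = _nnls2(
            np.array([x1 @ x1]),
            np.array([x1 @ x2]),
            np.array([x2 @ x2]),
            np.array([x1 @ b]),
            np.array([x2 @ b]),
        )
        assert a1[0] == pytest.approx(coef[0], abs=1e-8)
        assert a2[0] == pytest.approx(coef[1], abs=1e-8)


class TestRealign:
    def _set_and_result(self, offset):
        x = np.arange(100) * 0.14
        center = x[50] + offset
        triples = []
        for _ in range(4):
            pm = 3 * _gauss(x - center) + _edge(x - center)
            cp = _edge(x - center)
            poi = _edge(x - center) + 0.6 * _gauss(x - center)
            triples.append(
                {
                    "PM_marker": Profile(x, pm, "PM_marker"),
                    "CP_marker": Profile(x, cp, "CP_marker"),
                    "POI": Profile(x, poi, "POI"),
                }
            )
        pset = align_and_average(triples, axis=AXIS)
        return estimate_from_set(pset)

    def test_realignment_is_a_fixed_point(self):
        # a second realignment pass changes essentially nothing: the PM
        # component peak is already centered on the axis origin
        pset, res = self._set_and_result(0.0)
        pset2, res2 = realign_on_pm(pset, res)
        assert res2.realigned
        peak_pos = pset2.axis[np.nanargmax(res2.pm_component)]
        assert abs(peak_pos) < 1e-9
        _, res3 = realign_on_pm(pset2, res2)
        assert abs(res3.pm_peak_percent - res2.pm_peak_percent) < 0.01 * max(
            res2.pm_peak_percent, 1.0
        )

    def test_cytoplasm_only_poi_flagged_unchanged(self):
        x = np.arange(100) * 0.14
        center = x[50]
        triples = [
            {
                "PM_marker": Profile(x, 3 * _gauss(x - center) + _edge(x - center), "PM_marker"),
                "CP_marker": Profile(x, _edge(x - center), "CP_marker"),
                "POI": Profile(x, _edge(x - center), "POI"),
            }
            for _ in range(3)
        ]
        pset = align_and_average(triples, axis=AXIS)
        pset, res = estimate_from_set(pset)
        assert res.a_pm == pytest.approx(0.0, abs=1e-8)
        _, res2 = realign_on_pm(pset, res)
        assert res2.degenerate_pm
        assert res2.pm_peak_percent == res.pm_peak_percent


class TestBootstrap:
    def _identical_lines(self, n=6):
        x = np.arange(100) * 0.14
        center = x[50]
        t = {
            "PM_marker": Profile(x, 3 * _gauss(x - center) + _edge(x - center), "PM_marker"),
            "CP_marker": Profile(x, _edge(x - center), "CP_marker"),
            "POI": Profile(x, _edge(x - center) + 0.6 * _gauss(x - center), "POI"),
        }
        return [dict(t) for _ in range(n)]

    def test_identical_lines_zero_width(self):
        pset = align_and_average(self._identical_lines(), axis=AXIS)
        pset, res = estimate_from_set(pset)
        ci = bootstrap_ci(pset, res, n_boot=200, seed=0)
        assert ci.pm_peak_sd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(ci.pm_lo, ci.pm_hi, atol=1e-9)

    def test_seed_stability(self):
        rng = np.random.default_rng(9)
        lines = self._identical_lines(12)
        # perturb each line with noise so the CI has nonzero width
        noisy = []
        for t in lines:
            noisy.append(
                {
                    role: Profile(
                        p.positions,
                        p.intensities + rng.normal(0, 0.02, p.intensities.size),
                        role,
                    )
                    for role, p in t.items()
                }
            )
        pset = align_and_average(noisy, axis=AXIS)
        pset, res = estimate_from_set(pset)
        ci_a = bootstrap_ci(pset, res, n_boot=1000, seed=1)
        ci_b = bootstrap_ci(pset, res, n_boot=1000, seed=2)
        width = ci_a.pm_peak_hi - ci_a.pm_peak_lo
        assert abs(ci_a.pm_peak_sd - ci_b.pm_peak_sd) < 0.1 * width

    def test_too_few_lines_errors(self):
        pset = align_and_average(self._identical_lines(1), axis=AXIS)
        pset, res = estimate_from_set(pset)
        with pytest.raises(ValueError, match="at least 2"):
            bootstrap_ci(pset, res, n_boot=100, seed=0)

    def test_small_n_boot_warns(self):
        pset = align_and_average(self._identical_lines(4), axis=AXIS)
        pset, res = estimate_from_set(pset)
        with pytest.warns(UserWarning, match="n_boot"):
            bootstrap_ci(pset, res, n_boot=50, seed=0)


class TestPipeline:
    def test_scale_invariance_of_coefficients(self, noiseless_spec):
        stack, _ = synthetic.make_cell_stack(noiseless_spec)
        pre = imaging_io.preprocess(stack)
        rois = synthetic.radial_line_rois(noiseless_spec, 12, seed=3)
        res = pm_association(pre, rois, n_boot=100, seed=0)
        scaled = imaging_io.ChannelStack(
            {
                "PM_marker": pre.channels["PM_marker"] * 7.0,
                "CP_marker": pre.channels["CP_marker"] * 0.3,
                "POI": pre.channels["POI"] * 2.5,
            },
            pixel_size=pre.pixel_size,
            registered=True,
            background_corrected=True,
        )
        res2 = pm_association(scaled, rois, n_boot=100, seed=0)
        assert res2.a_cp == pytest.approx(res.a_cp, rel=1e-6)
        assert res2.a_pm == pytest.approx(res.a_pm, rel=1e-6)

    def test_monotonic_in_membrane_density(self):
        peaks = []
        for level in (3.0, 10.0, 20.0, 100.0, 300.0):
            spec = (
                synthetic.SyntheticSpec(
                    seed=1, poisson=False, frames=1,
                    background={r: 0.0 for r in ROLES},
                )
                .matched_psfs()
                .with_pm_peak("POI", level)
            )
            stack, _ = synthetic.make_cell_stack(spec)
            pre = imaging_io.preprocess(stack)
            rois = synthetic.radial_line_rois(spec, 8, seed=3)
            res = pm_association(pre, rois, n_boot=100, seed=0)
            peaks.append(res.pm_peak_percent)
        assert all(b > a for a, b in zip(peaks, peaks[1:]))

    def test_noiseless_recovery_is_multiplicative_transfer(self):
        # bilinear sampling attenuates the imaged membrane peak by a
        # constant factor, so relative recovery error is the same at
        # every ground-truth level and stays below 10%
        rel = []
        for level in (3.0, 100.0):
            spec = (
                synthetic.SyntheticSpec(
                    seed=1, poisson=False, frames=1,
                    background={r: 0.0 for r in ROLES},
                )
                .matched_psfs()
                .with_pm_peak("POI", level)
            )
            stack, _ = synthetic.make_cell_stack(spec)
            pre = imaging_io.preprocess(stack)
            rois = synthetic.radial_line_rois(spec, 12, seed=3)
            res = pm_association(pre, rois, n_boot=100, seed=0)
            rel.append(res.pm_peak_percent / level)
        assert rel[0] == pytest.approx(rel[1], rel=0.01)
        assert 0.90 < rel[0] < 1.02

    def test_unregistered_stack_rejected(self, noiseless_spec):
        stack, _ = synthetic.make_cell_stack(noiseless_spec)
        rois = synthetic.radial_line_rois(noiseless_spec, 4, seed=3)
        with pytest.raises(ValueError, match="registered"):
            pm_association(stack, rois)
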