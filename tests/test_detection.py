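import numpy as np
import pytest
from scipy import integrate, stats

import ppscr
from ppscr.detection import (
    DetectionParams,
    baseline_intensities,
    expected_detections,
    integral_matrix,
    kernel_value,
    log_detection_pp,
    log_discrete_detector,
    log_single_detection,
    window_kernel_integral,
)

TWO_PI = 2 * np.pi


def test_kernel_basic_values():
    s = np.array([3.0, 4.0])
    assert kernel_value(s, s, 0.5) == 1.0
    y = s + np.array([0.5, 0.0])
    assert kernel_value(y, s, 0.5) == pytest.approx(np.exp(-0.5), rel=1e-12)


def test_kernel_radial_symmetry(rng):
    s = np.zeros(2)
    angles = rng.uniform(0, 2 * np.pi, size=20)
    pts = 1.3 * np.column_stack([np.cos(angles), np.sin(angles)])
    vals = kernel_value(pts, s, 0.7)
    assert np.allclose(vals, vals[0], rtol=1e-12)


def test_window_integral_whole_plane_and_quadrant():
    assert window_kernel_integral((0, 0), 1.0, (-8, -8, 8, 8)) == pytest.approx(
        TWO_PI, rel=1e-9
    )
    assert window_kernel_integral((0, 0), 1.0, (0, 0, 8, 8)) == pytest.approx(
        TWO_PI / 4, rel=1e-9
    )


def test_window_integral_unit_square_reference():
    val = window_kernel_integral((0.0, 0.0), 1.0, (0, 0, 1, 1))
    ref, _ = integrate.dblquad(
        lambda y, x: np.exp(-(x**2 + y**2) / 2.0), 0, 1, 0, 1, epsabs=1e-12
    )
    assert val == pytest.approx(ref, abs=1e-10)
    assert val == pytest.approx(0.73209, abs=1e-5)


def test_degenerate_window_warns_and_returns_zero():
    with pytest.warns(UserWarning, match="degenerate"):
        assert window_kernel_integral((0, 0), 1.0, (1, 1, 1, 2)) == 0.0


def test_window_integral_matches_2d_quadrature(rng):
    """Closed-form Gaussian rectangle integral vs adaptive 2-D quadrature."""
    for _ in range(6):
        s = rng.uniform(-2, 2, size=2)
        sigma = rng.uniform(0.3, 2.0)
        x0, y0 = rng.uniform(-2, 0, size=2)
        x1, y1 = x0 + rng.uniform(0.5, 3), y0 + rng.uniform(0.5, 3)
        ref, err = integrate.dblquad(
            lambda y, x: np.exp(-((x - s[0]) ** 2 + (y - s[1]) ** 2) / (2 * sigma**2)),
            x0, x1, y0, y1, epsabs=1e-12,
        )
        ours = window_kernel_integral(s, sigma, (x0, y0, x1, y1))
        assert abs(ours - ref) <= 1e-8


def test_separable_fast_path_matches_per_window_integrals(rng, detgrid_with_cov):
    """On a regular lattice the separable evaluation must equal the
    window-by-window closed form."""
    assert detgrid_with_cov.is_regular
    pts = rng.uniform(0, 10, size=(50, 2))
    fast = integral_matrix(pts, 0.8, detgrid_with_cov)
    slow = np.array(
        [
            [window_kernel_integral(p, 0.8, w.bounds) for w in detgrid_with_cov.windows]
            for p in pts
        ]
    )
    np.testing.assert_allclose(fast, slow, rtol=1e-12, atol=1e-15)


def test_expected_detections_limits(detgrid_with_cov):
    # vanishing baseline -> no detections expected
    params = DetectionParams(theta0=-1e9, theta=[0.0], sigma=1.0)
    assert expected_detections(np.array([5.0, 5.0]), params, detgrid_with_cov) == 0.0
    # single huge window, flat baseline of 1: whole-plane Gaussian integral
    big = ppscr.build_grid((-20, -20, 20, 20), 40.0, role="detection")
    params = DetectionParams(theta0=0.0, sigma=1.0)
    assert expected_detections(np.zeros(2), params, big) == pytest.approx(
        TWO_PI, rel=1e-9
    )


def test_expected_detections_matches_midpoint_quadrature(rng, detgrid_with_cov):
    """Lambda(o|s) equals a fine midpoint-rule quadrature of b(y) tau(y|s)."""
    params = DetectionParams(theta0=0.3, theta=[0.7], sigma=0.9)
    b = baseline_intensities(params, detgrid_with_cov)
    k = 240  # fine sub-lattice per 2 km window
    ref_total = 0.0
    for l in range(detgrid_with_cov.n_windows):
        lo, up = detgrid_with_cov.lower[l], detgrid_with_cov.upper[l]
        xs = lo[0] + (np.arange(k) + 0.5) * (up[0] - lo[0]) / k
        ys = lo[1] + (np.arange(k) + 0.5) * (up[1] - lo[1]) / k
        gx, gy = np.meshgrid(xs, ys)
        cell = (up[0] - lo[0]) * (up[1] - lo[1]) / k**2
        tau = np.exp(-((gx - 4.2) ** 2 + (gy - 5.1) ** 2) / (2 * params.sigma**2))
        ref_total += b[l] * tau.sum() * cell
    ours = expected_detections(np.array([4.2, 5.1]), params, detgrid_with_cov)
    assert ours == pytest.approx(ref_total, rel=1e-6)


def test_local_truncation_approaches_exact(detgrid_with_cov):
    params = DetectionParams(theta0=0.0, theta=[0.5], sigma=0.4)
    s = np.array([3.3, 6.1])
    exact = expected_detections(s, params, detgrid_with_cov)
    truncated = expected_detections(s, params, detgrid_with_cov, max_range_sigmas=6.0)
    assert truncated == pytest.approx(exact, rel=1e-6)
    assert expected_detections(
        s, params, detgrid_with_cov, max_range_sigmas=np.inf
    ) == pytest.approx(exact, rel=1e-15)


def test_lambda_decreases_along_ray(detgrid_with_cov):
    """Expected detections fall off monotonically as the AC moves away from
    the detection region along a ray."""
    params = DetectionParams(theta0=0.0, theta=[0.0], sigma=0.8)
    t = np.linspace(0.0, 6.0, 25)
    pts = np.column_stack([9.0 + t, 9.0 + t])  # walking away from the corner
    lam = expected_detections(pts, params, detgrid_with_cov)
    assert np.all(np.diff(lam) < 0)


def test_log_detection_pp_zero_and_centered(detgrid_with_cov):
    s = np.array([5.0, 5.0])
    params = DetectionParams(theta0=0.4, theta=[-0.3], sigma=0.7)
    Lam = expected_detections(s, params, detgrid_with_cov)
    # no detections: the conditional void probability
    assert log_detection_pp(np.zeros((0, 2)), s, params, detgrid_with_cov) == (
        pytest.approx(-Lam, rel=1e-12)
    )
    # one detection exactly at the AC with flat unit baseline
    flat = ppscr.build_grid((1, 1, 9, 9), 2.0, role="detection")
    p0 = DetectionParams(theta0=0.0, sigma=0.7)
    Lam0 = expected_detections(s, p0, flat)
    assert log_detection_pp(s.reshape(1, 2), s, p0, flat) == pytest.approx(
        -Lam0, rel=1e-12
    )


def test_log_detection_pp_against_independent_reimplementation(
    rng, detgrid_with_cov
):
    """Sum over detections of log lambda(y|s) minus Lambda, rebuilt from
    scalar primitives."""
    params = DetectionParams(theta0=0.2, theta=[0.9], sigma=0.6)
    s = rng.uniform(2, 8, size=2)
    locs = rng.uniform(1.5, 8.5, size=(5, 2))
    ours = log_detection_pp(locs, s, params, detgrid_with_cov)
    b = baseline_intensities(params, detgrid_with_cov)
    ref = -sum(
        b[l] * window_kernel_integral(s, params.sigma, w.bounds)
        for l, w in enumerate(detgrid_with_cov.windows)
    )
    for y in locs:
        l = int(detgrid_with_cov.locate(y))
        ref += np.log(b[l]) + np.log(kernel_value(y, s, params.sigma))
    assert ours == pytest.approx(ref, rel=1e-10)


def test_log_detection_pp_rejects_stray_location(detgrid_with_cov):
    params = DetectionParams(theta0=0.0, theta=[0.0], sigma=1.0)
    with pytest.raises(ValueError, match="outside every detection window"):
        log_detection_pp(
            np.array([[0.1, 0.1]]), np.array([5.0, 5.0]), params, detgrid_with_cov
        )


def test_single_detection_flat_baseline_value():
    """With b = 1 over an effectively infinite region, Lambda = 2 pi sigma^2
    and the density at the AC is 1 / (2 pi sigma^2)."""
    big = ppscr.build_grid((-20, -20, 20, 20), 40.0, role="detection")
    params = DetectionParams(theta0=0.0, sigma=1.0)
    s = np.zeros(2)
    assert log_single_detection(s, s, params, big) == pytest.approx(
        -np.log(TWO_PI), rel=1e-9
    )


def test_single_detection_integrates_to_one(detgrid_with_cov):
    params = DetectionParams(theta0=0.5, theta=[0.8], sigma=1.1)
    s = np.array([4.0, 6.0])
    k = 40
    total = 0.0
    for l in range(detgrid_with_cov.n_windows):
        lo, up = detgrid_with_cov.lower[l], detgrid_with_cov.upper[l]
        xs = lo[0] + (np.arange(k) + 0.5) * (up[0] - lo[0]) / k
        ys = lo[1] + (np.arange(k) + 0.5) * (up[1] - lo[1]) / k
        cell = (up[0] - lo[0]) * (up[1] - lo[1]) / k**2
        for x in xs:
            pts = np.column_stack([np.full(k, x), ys])
            vals = [
                np.exp(log_single_detection(p, s, params, detgrid_with_cov))
                for p in pts
            ]
            total += np.sum(vals) * cell
    assert total == pytest.approx(1.0, abs=1e-4)


def test_single_detection_invariant_to_baseline_rescale(detgrid_with_cov):
    s, y = np.array([4.0, 4.0]), np.array([4.5, 4.3])
    a = log_single_detection(y, s, DetectionParams(0.0, [0.6], 0.8), detgrid_with_cov)
    b = log_single_detection(y, s, DetectionParams(2.5, [0.6], 0.8), detgrid_with_cov)
    assert a == pytest.approx(b, rel=1e-12)


def test_discrete_detector_against_poisson_pmf(rng):
    detectors = rng.uniform(0, 4, size=(9, 2))
    cov = rng.uniform(-1, 1, size=(9, 1))
    params = DetectionParams(theta0=-0.5, theta=[0.4], sigma=1.2)
    s = np.array([2.0, 2.0])
    counts = rng.poisson(1.0, size=9)
    rates = np.exp(-0.5 + cov[:, 0] * 0.4) * np.exp(
        -np.sum((detectors - s) ** 2, axis=1) / (2 * 1.2**2)
    )
    ref = stats.poisson.logpmf(counts, rates).sum()
    ours = log_discrete_detector(counts, s, params, detectors, cov)
    assert ours == pytest.approx(ref, rel=1e-10)
    # all-zero counts reduce to minus the total rate
    assert log_discrete_detector(
        np.zeros(9, dtype=int), s, params, detectors, cov
    ) == pytest.approx(-rates.sum(), rel=1e-10)
    # single detector at the AC with unit baseline and one count
    one = log_discrete_detector(
        np.array([1]), s, DetectionParams(0.0, [], 1.0), s.reshape(1, 2)
    )
    assert one == pytest.approx(-1.0, rel=1e-12)
    with pytest.raises(ValueError, match="nonnegative"):
        log_discrete_detector(np.array([-1]), s, params, detectors, cov)
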