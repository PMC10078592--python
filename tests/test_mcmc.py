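import numpy as np
import pytest
from scipy import stats

import ppscr
from ppscr.density import DensityParams
from ppscr.detection import DetectionParams
from ppscr.diagnostics import Chains, ess, rhat, summarize
from ppscr.mcmc import (
    BlockRWSampler,
    DAState,
    MCMCConfig,
    ModelSpec,
    Priors,
    da_log_posterior,
    run_mcmc,
    sample_ac_block,
)


# ---------------------------------------------------------------------------
# block random-walk AC sampler
# ---------------------------------------------------------------------------


def test_block_sampler_recovers_gaussian_target(rng):
    """Sampling a known bivariate normal reproduces its mean and covariance
    within Monte-Carlo error."""
    mean = np.array([1.0, -2.0])
    cov = np.array([[1.0, 0.6], [0.6, 2.0]])
    prec = np.linalg.inv(cov)

    def log_target(x):
        d = x - mean
        return -0.5 * d @ prec @ d

    sampler = BlockRWSampler(log_target, init=mean.copy(), scale=1.0)
    draws = np.array([sampler.step(rng).copy() for _ in range(40_000)])
    kept = draws[5000:]
    np.testing.assert_allclose(kept.mean(axis=0), mean, atol=0.1)
    np.testing.assert_allclose(np.cov(kept.T), cov, atol=0.25)
    assert 0.15 <= sampler.acceptance_rate <= 0.35


def test_block_sampler_adapts_acceptance(rng):
    sampler = BlockRWSampler(
        lambda x: -0.5 * np.sum(x**2), init=np.zeros(2), scale=50.0
    )
    for _ in range(5000):
        sampler.step(rng)
    # reset counts, freeze adaptation, measure long-run acceptance
    sampler.adapting = False
    sampler.n_steps = sampler.n_accepted = 0
    for _ in range(5000):
        sampler.step(rng)
    assert 0.15 <= sampler.acceptance_rate <= 0.35


def test_proposal_into_minus_inf_region_is_rejected(rng):
    """A -inf target (e.g. outside the habitat) keeps the chain in place."""

    def log_target(x):
        return 0.0 if np.all(np.abs(x) < 1e-9) else -np.inf

    cur = np.zeros(2)
    for _ in range(50):
        new, accepted = sample_ac_block(cur, log_target, 0.5 * np.eye(2), rng)
        assert not accepted
        np.testing.assert_array_equal(new, cur)


# ---------------------------------------------------------------------------
# DA posterior density
# ---------------------------------------------------------------------------


def _tiny_model(rng):
    hab = ppscr.build_grid(
        (0, 0, 6, 6), 3.0,
        covariates=rng.uniform(-1, 1, size=(4, 1)), covariate_names=("h",),
    )
    det = ppscr.build_grid(
        (1, 1, 5, 5), 2.0,
        covariates=rng.uniform(-1, 1, size=(4, 1)), covariate_names=("d",),
        role="detection",
    )
    data = ppscr.DetectionData(
        ["a", "b"],
        [np.array([[2.0, 2.5], [3.1, 2.2]]), np.array([[4.0, 4.2]])],
    )
    return ModelSpec(hab, det, data)


def test_da_posterior_observed_individual_needs_z_one(rng):
    m = _tiny_model(rng)
    dp = DensityParams(0.0, [0.3])
    op = DetectionParams(-0.5, [0.2], 0.8)
    s = np.array([[2.5, 2.3], [4.1, 4.1], [1.5, 1.5]])
    good = DAState(M=3, z=np.array([1, 1, 0]), psi=0.4, s=s)
    bad = DAState(M=3, z=np.array([1, 0, 0]), psi=0.4, s=s)
    assert np.isfinite(da_log_posterior(good, dp, op, m.data, m.habitat, m.detgrid))
    assert da_log_posterior(bad, dp, op, m.data, m.habitat, m.detgrid) == -np.inf


def test_da_posterior_excluded_individual_contribution(rng):
    """Flipping an augmented individual's z from 0 to 1 changes the posterior
    by log(psi/(1-psi)) - Lambda(o|s): the AC prior stays, the detection
    branch switches to the all-zero history."""
    m = _tiny_model(rng)
    dp = DensityParams(0.0, [0.3])
    op = DetectionParams(-0.5, [0.2], 0.8)
    s = np.array([[2.5, 2.3], [4.1, 4.1], [1.5, 1.5]])
    off = DAState(M=3, z=np.array([1, 1, 0]), psi=0.4, s=s)
    on = DAState(M=3, z=np.array([1, 1, 1]), psi=0.4, s=s)
    lp_off = da_log_posterior(off, dp, op, m.data, m.habitat, m.detgrid)
    lp_on = da_log_posterior(on, dp, op, m.data, m.habitat, m.detgrid)
    Lam = ppscr.expected_detections(s[2], op, m.detgrid)
    expected = np.log(0.4 / 0.6) - Lam
    assert lp_on - lp_off == pytest.approx(expected, rel=1e-10)


def test_psi_gibbs_full_conditional(rng):
    """With z fixed, repeated psi draws follow Beta(1 + N, 1 + M - N)."""
    sc = ppscr.preset("sim3", habitat_resolution=6.0, detection_resolution=4.0, seed=3)
    ds = ppscr.simulate_dataset(sc)
    model = ModelSpec(ds["habitat"], ds["detgrid"], ds["detections"])
    cfg = MCMCConfig(mode="da", iterations=4000, burn_in=0, seed=8,
                     sigma_init=1.0, fix_all_z=True)
    ch = run_mcmc(model, cfg)
    n = len(ds["detections"])
    psi = ch.flat("psi")  # all z fixed at 1, M = n -> Beta(1 + n, 1)
    _, p = stats.kstest(psi, stats.beta(1 + n, 1).cdf)
    assert p > 0.001


# ---------------------------------------------------------------------------
# run_mcmc behaviour
# ---------------------------------------------------------------------------


def test_zero_iteration_config_is_rejected(sim3_dataset):
    model = ModelSpec(
        sim3_dataset["habitat"], sim3_dataset["detgrid"], sim3_dataset["detections"]
    )
    with pytest.raises(ValueError, match="iterations"):
        run_mcmc(model, MCMCConfig(iterations=0))
    with pytest.raises(ValueError, match="burn-in|burn_in"):
        run_mcmc(model, MCMCConfig(iterations=100, burn_in=100))
    with pytest.raises(ValueError, match="mode"):
        run_mcmc(model, MCMCConfig(mode="vb"))


def test_nonfinite_initial_posterior_reports_components(sim3_dataset):
    model = ModelSpec(
        sim3_dataset["habitat"], sim3_dataset["detgrid"], sim3_dataset["detections"],
        priors=Priors(sigma_upper=0.5),
    )
    with pytest.raises(ValueError, match="sigma prior"):
        run_mcmc(
            model,
            MCMCConfig(mode="da", iterations=100, burn_in=10, sigma_init=2.0),
        )


def test_identical_seed_gives_bit_identical_draws(sim3_dataset):
    model = ModelSpec(
        sim3_dataset["habitat"], sim3_dataset["detgrid"], sim3_dataset["detections"]
    )
    cfg = MCMCConfig(mode="da", iterations=300, burn_in=50, seed=77, sigma_init=1.0)
    a = run_mcmc(model, cfg)
    b = run_mcmc(model, cfg)
    for name in a.parameter_names:
        np.testing.assert_array_equal(a.draws[name], b.draws[name])
    c = run_mcmc(
        model,
        MCMCConfig(mode="da", iterations=300, burn_in=50, seed=78, sigma_init=1.0),
    )
    assert not np.array_equal(a.draws["sigma"], c.draws["sigma"])


def test_da_fixed_z_matches_scdl_fixed_u(sim3_dataset):
    """With the population fixed at the observed sample (all z = 1, M = n
    under DA; u = 0 under SCDL) the two fitting routes target the same
    posterior of (theta, sigma)."""
    model = ModelSpec(
        sim3_dataset["habitat"], sim3_dataset["detgrid"], sim3_dataset["detections"]
    )
    da = run_mcmc(
        model,
        MCMCConfig(mode="da", iterations=4000, burn_in=1000, seed=5,
                   sigma_init=1.0, fix_all_z=True),
    )
    # uniform N-prior so the N=n conditioning carries no extra beta
    # information (the Poisson prior's -Lambda term would)
    scdl = run_mcmc(
        model,
        MCMCConfig(mode="scdl", iterations=4000, burn_in=1000, seed=6,
                   sigma_init=1.0, fix_u_zero=True, n_prior="uniform"),
    )
    for name in ("theta0", "theta[0]", "sigma", "beta[0]"):
        x, y = da.flat(name), scdl.flat(name)
        se = np.sqrt(
            x.var() / ess(da.posterior(name)) + y.var() / ess(scdl.posterior(name))
        )
        assert abs(x.mean() - y.mean()) < 4 * se + 0.02, name


def test_scdl_uniform_prior_integer_sampler_mixes(sim3_dataset):
    """Under the discrete-uniform N-prior, u moves by an integer random walk
    and the N chain explores a plausible range."""
    model = ModelSpec(
        sim3_dataset["habitat"], sim3_dataset["detgrid"], sim3_dataset["detections"]
    )
    ch = run_mcmc(
        model,
        MCMCConfig(mode="scdl", iterations=3000, burn_in=1000, seed=4,
                   sigma_init=1.0, n_prior="uniform"),
    )
    N = ch.flat("N")
    n = len(sim3_dataset["detections"])
    assert N.min() >= n
    assert N.std() > 1.0  # the integer sampler actually moves
    assert ess(ch.posterior("N")) > 50


def test_categorical_ac_cost_grows_with_window_count():
    """The categorical AC sampler iterates over habitat cells, so its
    per-iteration operation count grows with the number of windows; the
    point-process sampler's does not."""
    ops = {}
    for res, label in ((6.0, "coarse"), (2.0, "fine")):
        sc = ppscr.preset("sim3", habitat_resolution=res, seed=12)
        ds = ppscr.simulate_dataset(sc)
        model = ModelSpec(ds["habitat"], ds["detgrid"], ds["detections"])
        for ac_model in ("pp", "categorical"):
            ch = run_mcmc(
                model,
                MCMCConfig(mode="da", iterations=50, burn_in=10, seed=1,
                           sigma_init=1.0, ac_model=ac_model),
            )
            ops[label, ac_model] = ch.meta["op_counts"][0]["ac_intensity_evals"]
    assert ops["fine", "categorical"] == 9 * ops["coarse", "categorical"]  # 36 vs 4
    assert ops["fine", "pp"] == ops["coarse", "pp"]


def test_categorical_and_pp_ac_models_agree_when_cells_are_small():
    """With habitat cells no larger than the kernel scale the centroid
    approximation is mild and the two AC models give compatible abundance
    posteriors (they diverge on coarse cells, which is the point of the
    continuous model)."""
    sc = ppscr.preset("sim3", habitat_resolution=1.0, detection_resolution=1.0,
                      seed=21)
    ds = ppscr.simulate_dataset(sc)
    model = ModelSpec(ds["habitat"], ds["detgrid"], ds["detections"])
    means = {}
    for ac_model in ("pp", "categorical"):
        ch = run_mcmc(
            model,
            MCMCConfig(mode="da", iterations=4000, burn_in=1000, seed=2,
                       sigma_init=1.0, ac_model=ac_model),
        )
        post = ch.flat("N")
        means[ac_model] = (post.mean(), post.std())
    diff = abs(means["pp"][0] - means["categorical"][0])
    scale = max(means["pp"][1], means["categorical"][1])
    assert diff < 2.0 * scale


def test_discrete_detector_mode_runs_and_inflates_sigma():
    """Collapsing 4 km detection cells to point detectors is a coarse
    approximation; the fit still runs and returns a usable N posterior."""
    sc = ppscr.preset("sim3", habitat_resolution=2.0, detection_resolution=4.0,
                      seed=31)
    ds = ppscr.simulate_dataset(sc)
    model = ModelSpec(ds["habitat"], ds["detgrid"], ds["detections"])
    ch = run_mcmc(
        model,
        MCMCConfig(mode="da", iterations=2000, burn_in=500, seed=3,
                   sigma_init=1.0, detection_model="discrete"),
    )
    N = ch.flat("N")
    assert len(ds["detections"]) <= N.mean() <= 2 * 100


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def test_ess_of_iid_draws(rng):
    x = rng.standard_normal(1000)
    assert 600 <= ess(x) <= 1400


def test_ess_of_ar1_matches_closed_form(rng):
    rho, n = 0.9, 40_000
    x = np.empty(n)
    x[0] = rng.standard_normal()
    innov = rng.standard_normal(n) * np.sqrt(1 - rho**2)
    for t in range(1, n):
        x[t] = rho * x[t - 1] + innov[t]
    expected = n * (1 - rho) / (1 + rho)
    assert abs(ess(x) - expected) / expected < 0.3


def test_rhat_of_identical_chains(rng):
    x = rng.standard_normal(2000)
    value = rhat(np.stack([x, x]))
    assert value == pytest.approx(1.0, abs=0.01)


def test_constant_chain_diagnostics_warn(rng):
    with pytest.warns(UserWarning, match="constant"):
        assert np.isnan(ess(np.ones(100)))
    with pytest.warns(UserWarning, match="constant"):
        assert np.isnan(rhat(np.ones((2, 100))))


def test_ess_requires_enough_draws():
    with pytest.raises(ValueError, match="more than 10"):
        ess(np.arange(5.0))
    with pytest.raises(ValueError, match="two chains"):
        rhat(np.arange(100.0))


def test_summarize_table(rng):
    draws = {
        "a": rng.standard_normal((2, 500)) + 3.0,
        "b": rng.standard_normal((2, 500)) * 2.0,
    }
    ch = Chains(draws=draws, burn_in=100)
    table = summarize(ch)
    assert list(table.index) == ["a", "b"]
    assert table.loc["a", "mean"] == pytest.approx(3.0, abs=0.2)
    assert table.loc["a", "q2.5"] < table.loc["a", "median"] < table.loc["a", "q97.5"]
    assert table.loc["b", "rhat"] == pytest.approx(1.0, abs=0.05)


def test_chains_round_trip_and_truncation(tmp_path, rng):
    draws = {"a": rng.standard_normal((2, 100))}
    ch = Chains(draws=draws, burn_in=10, meta={"seed": 1})
    path = tmp_path / "chains.csv"
    ch.to_csv(path)
    back = Chains.from_csv(path, burn_in=10)
    np.testing.assert_allclose(back.draws["a"], draws["a"])
    # drop a few rows of one chain -> unequal lengths must be detected
    import pandas as pd

    df = pd.read_csv(path).iloc[:-3]
    bad = tmp_path / "trunc.csv"
    df.to_csv(bad, index=False)
    with pytest.raises(ValueError, match="unequal"):
        Chains.from_csv(bad)
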