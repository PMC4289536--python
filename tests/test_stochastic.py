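"""Random environments, growth-rate metrics, and the exact recursion."""

import numpy as np
import pytest

from streamide import (
    CoinFlipSpec,
    ExponentialSumState,
    FixedSpec,
    Habitat,
    LognormalVelocitySpec,
    StageParams,
    build_nystrom,
    derive_rates,
    estimate_Lambda,
    exact_advance,
    exact_lambda_series,
    exact_lambda_t,
    iterate_linear,
    make_environment,
    operator_norm_product,
    principal_eigenpair,
    redistribution,
)
from streamide.stochastic import lognormal_underlying_params


def cfk_spec():
    return CoinFlipSpec(
        StageParams(derive_rates(0.1, 1.0, 1.0), 1.2),
        StageParams(derive_rates(1.0, 1.0, 1.0), 1.5),
    )


def test_environments_are_reproducible_and_iid():
    env1 = make_environment(cfk_spec(), 42, 200)
    env2 = make_environment(cfk_spec(), 42, 200)
    assert np.array_equal(env1.atom_indices, env2.atom_indices)
    env3 = make_environment(cfk_spec(), 43, 200)
    assert not np.array_equal(env1.atom_indices, env3.atom_indices)


def test_coinflip_frequency_matches_probability():
    env = make_environment(cfk_spec(), 7, 100_000)
    freq = np.mean(env.atom_indices == 0)
    assert freq == pytest.approx(0.5, abs=0.005)


def test_lognormal_moment_matching():
    m, nu = 0.95, 1.5
    mu, sigma = lognormal_underlying_params(m, nu)
    assert np.exp(mu + sigma**2 / 2) == pytest.approx(m, rel=1e-12)
    env = make_environment(LognormalVelocitySpec(m, nu), 11, 1_000_000)
    vs = np.array([s.kernel.v for s in env.stages])
    assert np.mean(vs) == pytest.approx(m, rel=0.01)
    assert np.var(vs) == pytest.approx(nu, rel=0.05)


def test_fixed_environment_draws_identical():
    st = StageParams(derive_rates(0.5, 1.0, 1.0), 1.3)
    env = make_environment(FixedSpec(st), 0, 50)
    assert all(s is st for s in env.stages)


def test_invalid_lognormal_spec_rejected():
    with pytest.raises(ValueError):
        LognormalVelocitySpec(-1.0, 1.0)
    with pytest.raises(ValueError):
        LognormalVelocitySpec(1.0, 0.0)


def test_fixed_environment_growth_converges_to_eigenvalue(habitat20):
    st = StageParams(derive_rates(0.95, 1.0, 1.0), 1.2)
    lam1 = principal_eigenpair(build_nystrom(st, habitat20), habitat20).lambda1
    env = make_environment(FixedSpec(st), 0, 4000)
    res = iterate_linear(env, habitat20)
    assert res.Lambda_hat == pytest.approx(lam1, rel=1.5e-3)
    # every step loses mass relative to the intrinsic growth rate
    assert np.all(res.log_increments <= np.log(st.R))


def test_growth_rate_independent_of_initial_state(habitat20):
    env = make_environment(cfk_spec(), 5, 3000)
    flat = iterate_linear(env, habitat20, n0=lambda x: np.full_like(x, 1 / 20))
    sine = iterate_linear(
        env, habitat20, n0=lambda x: (np.pi / 20) * np.sin(np.pi * x / 20)
    )
    assert flat.Lambda_hat == pytest.approx(sine.Lambda_hat, abs=5e-3)


def test_lambda_invariant_under_translation_and_refinement():
    env_seed, T = 9, 1500
    vals = []
    for h in (Habitat(0.0, 20.0, 201), Habitat(-10.0, 10.0, 201), Habitat(0.0, 20.0, 401)):
        env = make_environment(cfk_spec(), env_seed, T)
        vals.append(iterate_linear(env, h).Lambda_hat)
    assert np.ptp(vals) < 0.01


def test_estimate_lambda_deterministic_and_near_reference(habitat20):
    est1 = estimate_Lambda(cfk_spec(), habitat20, T=1200, replicates=3, seed=3)
    est2 = estimate_Lambda(cfk_spec(), habitat20, T=1200, replicates=3, seed=3)
    assert est1.value == est2.value
    assert est1.se < 0.02
    assert est1.value == pytest.approx(1.22, abs=0.03)
    with pytest.raises(ValueError):
        estimate_Lambda(cfk_spec(), habitat20, T=50)


def test_lambda_monotone_in_velocity_variance_and_mean(habitat20):
    h = Habitat(0.0, 20.0, 201)
    lams = [
        estimate_Lambda(LognormalVelocitySpec(0.95, nu), h, T=1500, replicates=3,
                        seed=17).value
        for nu in (0.1, 0.5, 1.0, 1.5)
    ]
    assert np.all(np.diff(lams) > 0)
    lams_mean = [
        estimate_Lambda(LognormalVelocitySpec(m, 1.0), h, T=1500, replicates=3,
                        seed=17).value
        for m in (0.9, 0.95, 1.0)
    ]
    assert np.all(np.diff(lams_mean) < 0)


def test_operator_norm_product_single_step(habitat20):
    st = StageParams(derive_rates(0.95, 1.0, 1.0), 1.2)
    env = make_environment(FixedSpec(st), 0, 5)
    r1 = operator_norm_product(env, habitat20, 1)
    ref = st.R * float(np.max(redistribution(st.kernel, habitat20, habitat20.nodes)))
    assert r1 == pytest.approx(ref, rel=1e-3)


def test_gelfand_limit_and_norm_equivalence(habitat20):
    st = StageParams(derive_rates(0.95, 1.0, 1.0), 1.2)
    lam1 = principal_eigenpair(build_nystrom(st, habitat20), habitat20).lambda1
    env = make_environment(FixedSpec(st), 0, 5)
    rs = [operator_norm_product(env, habitat20, t) for t in (1, 64, 4096)]
    assert all(r >= lam1 - 1e-12 for r in rs)
    assert np.all(np.diff(rs) < 0)
    assert rs[-1] == pytest.approx(lam1, rel=2e-3)
    r_l1 = operator_norm_product(env, habitat20, 4096, norm="l1")
    assert r_l1 == pytest.approx(rs[-1], rel=1e-3)


def test_spectral_radius_and_growth_rate_agree_for_random_environment(habitat20):
    h = Habitat(0.0, 20.0, 201)
    env = make_environment(cfk_spec(), 21, 600)
    r_t = operator_norm_product(env, h, 600)
    lam_t = iterate_linear(env, h).Lambda_t[-1]
    assert r_t == pytest.approx(lam_t, rel=0.02)
    assert r_t >= lam_t - 1e-9  # norm dominates any growth realization


def test_one_exact_step_reproduces_redistribution(habitat20):
    st = StageParams(derive_rates(1.0, 1.0, 1.0), 1.5)
    state = exact_advance(ExponentialSumState.uniform(1.0), st, habitat20)
    x = np.linspace(0.0, 20.0, 9)
    ref = st.R * redistribution(st.kernel, habitat20, x)
    np.testing.assert_allclose(
        np.exp(state.log_R_prod) * state.density(x), ref, rtol=1e-12
    )
    # Lambda_1 from a uniform unit start equals R * mean dispersal success
    from streamide import dispersal_success_approx

    assert exact_lambda_t(state, habitat20) / habitat20.L == pytest.approx(
        dispersal_success_approx(st, habitat20), rel=1e-10
    )


def test_exact_term_count_grows_linearly():
    env = make_environment(LognormalVelocitySpec(0.95, 1.5), 13, 8)
    h = Habitat(-10.0, 10.0, 101)
    state = ExponentialSumState.uniform(1.0)
    for t in range(8):
        state = exact_advance(state, env.draws(t), h)
        assert state.n_exponential_terms == 2 * (t + 1)


def test_exact_series_matches_quadrature_then_degrades():
    env = make_environment(LognormalVelocitySpec(0.95, 1.5), 7, 40)
    h = Habitat(-10.0, 10.0, 1601)
    exact, quad, unstable = exact_lambda_series(env, h, 40)
    rel = np.abs(exact[:15] - quad[:15]) / quad[:15]
    assert np.nanmax(rel) < 1e-4
    assert not unstable[:15].any()
    # double precision exhausts the closed form by t around 20
    assert unstable[25:].all()


def test_exact_series_handles_repeating_kernels():
    env = make_environment(cfk_spec(), 3, 10)
    h = Habitat(-10.0, 10.0, 1601)
    exact, quad, unstable = exact_lambda_series(env, h, 10)
    assert not unstable.any()
    np.testing.assert_allclose(exact, quad, rtol=2e-4)
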