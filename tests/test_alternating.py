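"""Alternating kernel model: quartic, boundary determinant, critical length."""

import numpy as np
import pytest

from streamide import (
    Habitat,
    StageParams,
    TwoStageProblem,
    boundary_determinant,
    characteristic_quartic,
    compose_kernels,
    critical_domain,
    critical_velocity,
    derive_rates,
    eigen_bvp_single,
    infinite_domain_factor,
    principal_eigenpair,
    twostep_approx,
    twostep_eigenvalue,
    NO_FINITE_CRITICAL_LENGTH,
)
from streamide.alternating import reconstruct_intermediate, twostep_radius_nystrom


def stage(v, R, D=1.0, beta=1.0):
    return StageParams(derive_rates(v, D, beta), R)


def example1_problem(n=401, L=20.0):
    """The recurring two-stage example: R1=1.2, R2=1.5, D=beta=1."""
    return TwoStageProblem(
        stage(0.1, 1.2), stage(1.0, 1.5), Habitat(0.0, L, n)
    )


def test_composition_of_identical_stages_is_the_square(habitat20, slow_stage):
    p = TwoStageProblem(slow_stage, slow_stage, habitat20)
    from streamide import build_nystrom

    M1 = build_nystrom(slow_stage, habitat20)
    np.testing.assert_allclose(compose_kernels(p), M1 @ M1, rtol=1e-13)


def test_composite_spectral_radius_bounded_by_growth_product():
    for (v1, v2, R1, R2) in [(0.1, 1.0, 1.2, 1.5), (2.0, 0.3, 1.8, 1.1)]:
        p = TwoStageProblem(stage(v1, R1), stage(v2, R2), Habitat(0.0, 20.0, 301))
        lam = principal_eigenpair(compose_kernels(p), p.habitat).lambda1
        assert lam <= R1 * R2


def test_quartic_roots_satisfy_vieta():
    p = example1_problem(101)
    lam = 1.3
    roots = characteristic_quartic(p, lam)
    assert len(roots) == 4
    k1, k2 = p.stage1.kernel, p.stage2.kernel
    c0 = (k1.beta * k2.beta / (k1.D * k2.D)) * (1.0 - p.R / lam)
    assert np.prod(roots) == pytest.approx(c0, rel=1e-10)
    assert np.sum(roots) == pytest.approx(p.B, rel=1e-10)


def test_quartic_constant_term_vanishes_at_growth_product():
    p = example1_problem(101)
    roots = characteristic_quartic(p, p.R)
    assert np.min(np.abs(roots)) < 1e-8


def test_symmetric_stages_give_paired_roots():
    p = TwoStageProblem(stage(0.0, 1.2), stage(0.0, 1.5), Habitat(0.0, 20.0, 101))
    roots = np.sort_complex(characteristic_quartic(p, 1.1))
    np.testing.assert_allclose(roots, -roots[::-1], atol=1e-9)


def test_boundary_determinant_vanishes_only_at_the_eigenvalue():
    p = example1_problem(801)
    res = twostep_eigenvalue(p)
    assert abs(boundary_determinant(p, res.lambda1)) < 1e-8
    assert abs(boundary_determinant(p, 0.9 * res.lambda1)) > 1e-8
    # sign change across the root
    d_lo = boundary_determinant(p, res.lambda1 * 0.995)
    d_hi = boundary_determinant(p, res.lambda1 * 1.005)
    assert np.sign(d_lo) != np.sign(d_hi)


def test_intermediate_stage_conditions_are_implied():
    """The mid-cycle density reconstructed at the root satisfies its own
    Robin conditions even though only the phi-conditions were imposed."""
    p = example1_problem(401)
    lam = twostep_eigenvalue(p).lambda1
    psi, dpsi = reconstruct_intermediate(p, lam)
    a11, a21 = p.stage1.kernel.a1, p.stage1.kernel.a2
    x0, y0 = p.habitat.x0, p.habitat.y0
    scale = float(np.max(np.abs(psi(np.linspace(x0, y0, 50)))))
    assert abs(float(dpsi(x0)[0] - a11 * psi(x0)[0])) < 1e-6 * scale
    assert abs(float(dpsi(y0)[0] - a21 * psi(y0)[0])) < 1e-6 * scale


def test_identical_stages_square_the_single_eigenvalue():
    st = stage(1.3, 1.2)
    h = Habitat(0.0, 20.0, 801)
    single = eigen_bvp_single(st, h).lambda1
    lam2 = twostep_eigenvalue(TwoStageProblem(st, st, h)).lambda1
    assert lam2 == pytest.approx(single**2, rel=1e-6)


def test_twostep_matches_nystrom_and_respects_bound():
    p = example1_problem(1601)
    res = twostep_eigenvalue(p)
    assert res.lambda1 == pytest.approx(twostep_radius_nystrom(p), rel=1e-4)
    assert res.lambda1 <= p.R
    assert np.all(res.phi > 0)


def test_stage_order_does_not_change_the_eigenvalue():
    # spectral radius of L2 L1 equals that of L1 L2 (similarity), so the
    # alternating-year growth rate cannot depend on which year comes first
    h = Habitat(0.0, 20.0, 401)
    f = twostep_eigenvalue(TwoStageProblem(stage(0.1, 1.2), stage(1.0, 1.5), h)).lambda1
    b = twostep_eigenvalue(TwoStageProblem(stage(1.0, 1.5), stage(0.1, 1.2), h)).lambda1
    assert f == pytest.approx(b, rel=1e-8)


def test_randomized_bvp_nystrom_sweep(rng):
    for _ in range(4):
        v1, v2 = rng.uniform(0.0, 3.0, size=2)
        L = rng.uniform(5.0, 25.0)
        R1, R2 = rng.uniform(1.0, 2.0, size=2)
        n = int(np.ceil(L / 0.0125)) // 2 * 2 + 1
        p = TwoStageProblem(stage(v1, R1), stage(v2, R2), Habitat(0.0, L, n))
        res = twostep_eigenvalue(p)
        assert res.lambda1 == pytest.approx(twostep_radius_nystrom(p), rel=1e-4)
        assert res.lambda1 <= R1 * R2


def test_eigenvalue_monotone_in_flow_statistics():
    h = Habitat(0.0, 20.0, 301)

    def lam(v1, v2):
        p = TwoStageProblem(stage(v1, 1.2), stage(v2, 1.5), h)
        return twostep_radius_nystrom(p)

    # decreasing in the mean for equal flows
    means = [lam(v, v) for v in (0.5, 1.0, 1.5, 2.5)]
    assert np.all(np.diff(means) < 0)
    # increasing in |v1 - v2| at fixed mean 1.3
    spreads = [lam(1.3 - d / 2, 1.3 + d / 2) for d in (0.0, 0.8, 1.6, 2.4)]
    assert np.all(np.diff(spreads) > 0)
    # decreasing in v2 at fixed v1 = 0.1
    v2s = [lam(0.1, v2) for v2 in (0.2, 1.0, 2.0, 3.0)]
    assert np.all(np.diff(v2s) < 0)


def test_twostep_approximation_quality_and_symmetric_reduction():
    p = example1_problem(801)
    approx = twostep_approx(p)
    lam = twostep_eigenvalue(p).lambda1
    assert approx > 0
    assert abs(approx - lam) / lam < 0.15  # regression guard
    # symmetric identical stages: reduces to (R^2/L) * integral s^2
    st = stage(0.0, 1.2)
    h = Habitat(0.0, 20.0, 801)
    ps = TwoStageProblem(st, st, h)
    from streamide import dispersal_success

    s = dispersal_success(st.kernel, h, h.nodes)
    ref = st.R**2 * float(h.weights @ (s * s)) / h.L
    assert twostep_approx(ps) == pytest.approx(ref, rel=1e-5)


def test_critical_domain_increases_with_flow_and_diverges():
    s1 = stage(0.1, 1.2)
    lcs = [critical_domain(s1, stage(v2, 1.5)) for v2 in (0.5, 1.5, 2.5)]
    assert np.all(np.diff(lcs) > 0)
    # two-step eigenvalue at the critical length is one
    s2 = stage(1.5, 1.5)
    Lc = critical_domain(s1, s2)
    n = int(np.ceil(Lc / 0.0125)) // 2 * 2 + 1
    p = TwoStageProblem(s1, s2, Habitat(0.0, Lc, n))
    assert twostep_eigenvalue(p).lambda1 == pytest.approx(1.0, abs=2e-4)


def test_no_finite_critical_length_beyond_the_asymptote():
    s1 = stage(0.1, 1.2)
    assert critical_domain(s1, stage(5.0, 1.5)) is NO_FINITE_CRITICAL_LENGTH
    factor, _ = infinite_domain_factor(s1, stage(5.0, 1.5))
    assert factor < 1.0


def test_critical_velocity_near_three():
    s1 = stage(0.1, 1.2)
    vstar = critical_velocity(s1, lambda v: stage(v, 1.5), (1.0, 5.0))
    assert vstar == pytest.approx(3.0, rel=0.05)
    # consistent with where finite critical lengths stop existing
    assert critical_domain(s1, stage(vstar - 0.1, 1.5)) < np.inf
    assert critical_domain(s1, stage(vstar + 0.1, 1.5)) == np.inf
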