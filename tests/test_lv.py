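"""Lotka-Volterra copy-number dynamics: construction, closed forms,
equilibria, classification and invariances."""

import numpy as np
import pytest

from oricompat.lv import (
    LVParams,
    classify_outcome,
    derivatives,
    from_copy_numbers,
    integrate_copy_numbers,
    interior_equilibrium,
    jacobian,
    load_params,
    pairwise_closed_form,
    save_params,
    simulate,
)


def logistic(t, K, r, x0):
    return K * x0 * np.exp(r * t) / (K + x0 * (np.exp(r * t) - 1.0))


# ---------------------------------------------------------------------------
# construction

def test_from_copy_numbers_reciprocal():
    p = from_copy_numbers([100.0])
    assert p.self_lim[0] == pytest.approx(0.01)
    assert p.r[0] == 5.0


def test_from_copy_numbers_defaults_zero_interaction():
    p = from_copy_numbers([100.0, 50.0])
    assert np.all(p.interaction == 0)
    assert p.K == pytest.approx([100.0, 50.0])


@pytest.mark.parametrize(
    "K, interaction",
    [
        ([0.0, 100.0], None),                       # zero copy number
        ([100.0, 100.0], [[0, 0.01], [0, 0]]),      # positive cross term
        ([100.0, 100.0], [[0.01, 0], [0, 0]]),      # non-zero diagonal
    ],
)
def test_parameter_validation_rejects(K, interaction):
    with pytest.raises(ValueError):
        from_copy_numbers(K, interaction)


def test_params_yaml_round_trip(tmp_path):
    p = from_copy_numbers(
        [100, 50], [[0, -0.002], [-0.001, 0]], origin_ids=("wt", "alpha")
    )
    path = tmp_path / "params.yaml"
    save_params(p, path)
    q = load_params(path)
    assert q.origin_ids == ("wt", "alpha")
    assert np.allclose(q.K, p.K)
    assert np.allclose(q.interaction, p.interaction)


# ---------------------------------------------------------------------------
# vector field

def test_derivatives_zero_state_is_absorbing():
    p = from_copy_numbers([100, 50])
    assert np.all(derivatives([0, 0], p) == 0)


def test_derivatives_zero_at_carrying_capacity():
    p = from_copy_numbers([100.0])
    assert derivatives([100.0], p)[0] == pytest.approx(0.0)


def test_derivatives_hand_value():
    # X=[50,50], K=[100,100], symmetric interaction -0.005, r=5:
    # dX1/dt = 5*50*(1 - 0.5 - 0.25) = 62.5
    p = from_copy_numbers([100, 100], [[0, -0.005], [-0.005, 0]])
    d = derivatives([50.0, 50.0], p)
    assert d == pytest.approx([62.5, 62.5])


def test_derivatives_rejects_negative_state():
    with pytest.raises(ValueError):
        derivatives([-1.0], from_copy_numbers([100.0]))


# ---------------------------------------------------------------------------
# integration

def test_single_origin_matches_logistic_closed_form():
    p = from_copy_numbers([100.0])
    traj = simulate(p, [1.0], 5.0)
    expected = logistic(traj.t, 100.0, 5.0, 1.0)
    rel = np.abs(traj.x[:, 0] - expected) / expected
    assert rel.max() < 1e-6


def test_trajectory_constant_at_interior_equilibrium():
    p = from_copy_numbers([100, 100], [[0, -0.005], [-0.005, 0]])
    eq = interior_equilibrium(p)
    traj = simulate(p, eq, 10.0)
    assert np.allclose(traj.x, eq, rtol=1e-6)


def test_zero_interaction_separates_into_single_origin_runs():
    p2 = from_copy_numbers([100.0, 40.0])
    traj2 = simulate(p2, [2.0, 5.0], 4.0, n_points=50)
    for i, (K, x0) in enumerate([(100.0, 2.0), (40.0, 5.0)]):
        expected = logistic(traj2.t, K, 5.0, x0)
        assert np.allclose(traj2.x[:, i], expected, rtol=1e-6)


def test_trajectories_stay_non_negative():
    p = from_copy_numbers([100, 100], [[0, -0.03], [-0.001, 0]])
    traj = simulate(p, [1.0, 90.0], 50.0)
    assert np.all(traj.x >= 0)


def test_simulate_rejects_bad_inputs():
    p = from_copy_numbers([100.0])
    with pytest.raises(ValueError):
        simulate(p, [-1.0], 1.0)
    with pytest.raises(ValueError):
        simulate(p, [1.0, 2.0], 1.0)


def test_fixed_step_population_integrator_matches_adaptive():
    p = from_copy_numbers([100, 60], [[0, -0.004], [-0.002, 0]])
    x0 = np.array([[5.0, 5.0], [80.0, 10.0]])
    fixed = integrate_copy_numbers(x0, p, 3.0, dt=0.02)
    for row_in, row_out in zip(x0, fixed):
        exact = simulate(p, row_in, 3.0).x[-1]
        assert np.allclose(row_out, exact, rtol=1e-4)


# ---------------------------------------------------------------------------
# equilibria

def test_zero_interaction_equilibrium_is_K():
    p = from_copy_numbers([100, 50, 20])
    assert interior_equilibrium(p) == pytest.approx([100, 50, 20])


def test_symmetric_interaction_closed_form():
    p = from_copy_numbers([100, 100], [[0, -0.005], [-0.005, 0]])
    eq = interior_equilibrium(p)
    # X* = (a + c) / (a^2 - c^2) = 0.005 / 7.5e-5 = 66.66...
    assert eq == pytest.approx([200.0 / 3.0, 200.0 / 3.0])
    assert np.linalg.norm(derivatives(eq, p)) < 1e-8


def test_asymmetric_strong_interaction_has_no_interior():
    # c12 = -0.02 pushes X1* = (a2 + c12)/det = -100 < 0
    p = from_copy_numbers([100, 100], [[0, -0.02], [0, 0]])
    assert interior_equilibrium(p) is None


def test_symmetric_strong_interaction_interior_is_saddle():
    # both components positive (33.3) but det < 0: a saddle, not absence
    p = from_copy_numbers([100, 100], [[0, -0.02], [-0.02, 0]])
    eq = interior_equilibrium(p)
    assert eq == pytest.approx([100.0 / 3.0, 100.0 / 3.0])
    eigs = np.linalg.eigvals(jacobian(eq, p)).real
    assert eigs.max() > 0


def test_degenerate_singular_system_returns_absent():
    # duplicated origin sharing one pool: c = -1/K both ways -> singular
    p = from_copy_numbers([100, 100], [[0, -0.01], [-0.01, 0]])
    assert interior_equilibrium(p) is None
    assert classify_outcome(p).label == "degenerate"


# ---------------------------------------------------------------------------
# outcome classification

def test_zero_interaction_coexistence_at_K():
    p = from_copy_numbers([100, 50])
    out = classify_outcome(p)
    assert out.label == "coexistence"
    assert out.interior_state == pytest.approx([100, 50])


def test_symmetric_strong_inhibition_is_bistable():
    p = from_copy_numbers([100, 100], [[0, -0.02], [-0.02, 0]])
    assert classify_outcome(p).label == "bistable"
    # verified by integration from starts on either side of the diagonal
    hi_lo = integrate_copy_numbers(np.array([[90.0, 10.0]]), p, 100.0)[0]
    lo_hi = integrate_copy_numbers(np.array([[10.0, 90.0]]), p, 100.0)[0]
    assert hi_lo[0] > 99 and hi_lo[1] < 1e-3
    assert lo_hi[1] > 99 and lo_hi[0] < 1e-3


def test_asymmetric_exclusion_matches_long_run_integration():
    p = from_copy_numbers([100, 100], [[0, 0], [-0.02, 0]])
    out = classify_outcome(p)
    assert out.label == "exclusion"
    assert out.excluded == (1,)
    end = integrate_copy_numbers(np.array([[50.0, 50.0]]), p, 100.0)[0]
    assert end[0] == pytest.approx(100, rel=1e-3)
    assert end[1] < 1e-3


def test_zero_interaction_settles_at_K_within_tenth_percent():
    p = from_copy_numbers([100, 50])
    end = simulate(p, [1.0, 1.0], 20.0).x[-1]
    assert np.allclose(end, [100, 50], rtol=1e-3)


def test_permuting_origin_labels_permutes_outputs():
    K = [120.0, 40.0, 80.0]
    C = np.array([[0, -0.001, -0.003], [-0.002, 0, 0], [0, -0.004, 0]])
    perm = [2, 0, 1]
    p = from_copy_numbers(K, C)
    pp = from_copy_numbers(
        [K[i] for i in perm], C[np.ix_(perm, perm)]
    )
    x = np.array([30.0, 20.0, 10.0])
    d = derivatives(x, p)
    dp = derivatives(x[perm], pp)
    assert dp == pytest.approx(d[perm])
    eq, eqp = interior_equilibrium(p), interior_equilibrium(pp)
    assert eqp == pytest.approx(eq[perm])


def test_closed_form_agrees_with_jacobian_classification(rng):
    """Closed-form n=2 criteria vs the numerical-Jacobian classifier on a
    random parameter sweep (outside the marginal band)."""
    checked = 0
    for _ in range(300):
        K = rng.uniform(20, 200, size=2)
        C = np.zeros((2, 2))
        C[0, 1] = -rng.uniform(0, 2.0 / K.min())
        C[1, 0] = -rng.uniform(0, 2.0 / K.min())
        a = 1.0 / K
        det = a[0] * a[1] - C[0, 1] * C[1, 0]
        margins = [abs(det), abs(a[1] + C[0, 1]), abs(a[0] + C[1, 0])]
        if min(margins) < 1e-6:
            continue  # declared marginal band
        p = from_copy_numbers(K, C)
        analytic = pairwise_closed_form(p)
        numeric = classify_outcome(p)
        if analytic == "coexistence":
            assert numeric.label == "coexistence"
        elif analytic == "bistable":
            assert numeric.label == "bistable"
        elif analytic.startswith("exclusion_of_"):
            assert numeric.label == "exclusion"
            assert numeric.excluded == (int(analytic[-1]),)
        checked += 1
    assert checked > 250
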