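"""Geometry primitives against an independent commuting-matrix oracle.

For simultaneously diagonalizable (here: diagonal) SPD matrices the
affine-invariant geometry reduces to scalar formulas on the eigenvalues:
log-ratio distance, elementwise geometric interpolation, and the geometric
mean.  Those closed forms are implemented here from scratch and frozen as
the oracle for distance, geodesic and Karcher mean.
"""

import numpy as np
import pytest

from riemanneeg import manifold
from riemanneeg.datatypes import ConvergenceWarning
from riemanneeg.manifold import (
    MeanSettings,
    geodesic,
    incremental_mean,
    inverse_tangent_map,
    karcher_mean,
    recenter,
    riemannian_distance,
    tangent_map,
)

from conftest import random_spd


# --- independent scalar oracle for commuting (diagonal) inputs ---------------


def oracle_distance(a: np.ndarray, b: np.ndarray) -> float:
    """delta(diag(a), diag(b)) = sqrt(sum ln^2 (b_i / a_i))."""
    return float(np.sqrt(np.sum(np.log(b / a) ** 2)))


def oracle_geodesic(a: np.ndarray, b: np.ndarray, t: float) -> np.ndarray:
    """Elementwise geometric interpolation a^(1-t) b^t."""
    return a ** (1 - t) * b**t


def oracle_mean(diags: np.ndarray) -> np.ndarray:
    """Elementwise geometric mean (the commuting Karcher mean)."""
    return np.exp(np.mean(np.log(diags), axis=0))


@pytest.fixture
def diag_batch(rng):
    return np.exp(rng.uniform(-2, 2, size=(6, 5)))  # 6 diagonal 5x5 SPDs


def test_distance_matches_commuting_oracle(diag_batch):
    for a in diag_batch:
        for b in diag_batch:
            assert riemannian_distance(np.diag(a), np.diag(b)) == pytest.approx(
                oracle_distance(a, b), abs=1e-8
            )


def test_distance_closed_form_example():
    # delta(2I, 8I) in 2 dimensions = sqrt(2) ln 4
    d = riemannian_distance(2 * np.eye(2), 8 * np.eye(2))
    assert d == pytest.approx(np.sqrt(2) * np.log(4), abs=1e-10)
    assert riemannian_distance(np.eye(3), np.eye(3)) == 0.0


def test_geodesic_matches_commuting_oracle(diag_batch):
    a, b = diag_batch[0], diag_batch[1]
    for t in (0.0, 0.25, 0.5, 0.9, 1.0):
        G = geodesic(np.diag(a), np.diag(b), t)
        assert np.allclose(G, np.diag(oracle_geodesic(a, b, t)), atol=1e-8)


def test_geodesic_commuting_midpoint():
    G = geodesic(np.diag([1.0, 4.0]), np.diag([4.0, 1.0]), 0.5)
    assert np.allclose(G, 2 * np.eye(2), atol=1e-10)


def test_karcher_mean_matches_commuting_oracle(diag_batch):
    M = karcher_mean(np.stack([np.diag(d) for d in diag_batch]))
    assert np.allclose(M, np.diag(oracle_mean(diag_batch)), atol=1e-8)


def test_karcher_mean_two_point_and_single():
    assert np.allclose(
        karcher_mean([np.diag([1.0, 4.0]), np.diag([4.0, 1.0])]), 2 * np.eye(2), atol=1e-8
    )
    A = np.diag([2.0, 3.0])
    assert np.allclose(karcher_mean([A]), A)


# --- metric and invariance properties ----------------------------------------


def test_distance_metric_properties(spd_batch):
    for A in spd_batch:
        assert riemannian_distance(A, A) == pytest.approx(0.0, abs=1e-9)
    for A in spd_batch[:4]:
        for B in spd_batch[4:]:
            dab = riemannian_distance(A, B)
            assert dab > 0
            assert dab == pytest.approx(riemannian_distance(B, A), abs=1e-9)


def test_distance_congruence_invariance(rng, spd_batch):
    W = rng.standard_normal((4, 4))
    assert abs(np.linalg.det(W)) > 1e-6
    for A, B in zip(spd_batch[:4], spd_batch[4:]):
        d0 = riemannian_distance(A, B)
        d1 = riemannian_distance(W @ A @ W.T, W @ B @ W.T)
        assert d1 == pytest.approx(d0, rel=1e-8)


def test_geodesic_distance_proportionality(spd_batch):
    A, B = spd_batch[0], spd_batch[1]
    d = riemannian_distance(A, B)
    for t in (0.25, 0.5, 0.75):
        assert riemannian_distance(A, geodesic(A, B, t)) == pytest.approx(t * d, abs=1e-8)


def test_geodesic_rejects_t_outside_unit_interval(spd_batch):
    with pytest.raises(ValueError):
        geodesic(spd_batch[0], spd_batch[1], 1.5)


def test_karcher_mean_equivariance(rng, spd_batch):
    W = rng.standard_normal((4, 4))
    M = karcher_mean(spd_batch)
    Mw = karcher_mean(np.einsum("ij,kjl,ml->kim", W, spd_batch, W))
    assert np.allclose(Mw, W @ M @ W.T, atol=1e-6 * np.linalg.norm(Mw))


def test_karcher_mean_gradient_condition(spd_batch):
    settings = MeanSettings(tol=1e-9, max_iter=100)
    M = karcher_mean(spd_batch, settings)
    Mis = manifold.invsqrtm(M)
    logs = manifold.logm(Mis @ spd_batch @ Mis)
    assert np.linalg.norm(logs.mean(axis=0), "fro") < settings.tol


def test_karcher_mean_tolerance_insensitivity(spd_batch):
    """Converged means agree across tolerances 1e-6..1e-10."""
    loose = karcher_mean(spd_batch, MeanSettings(tol=1e-6))
    tight = karcher_mean(spd_batch, MeanSettings(tol=1e-10, max_iter=200))
    assert riemannian_distance(loose, tight) < 1e-5


def test_karcher_mean_convergence_warning(spd_batch):
    with pytest.warns(ConvergenceWarning):
        karcher_mean(spd_batch, MeanSettings(tol=1e-15, max_iter=2))


def test_karcher_mean_empty_rejected():
    with pytest.raises(ValueError):
        karcher_mean(np.empty((0, 3, 3)))


# --- tangent space -----------------------------------------------------------


def test_tangent_map_zero_at_reference(spd_batch):
    v = tangent_map(spd_batch[0], spd_batch[0])
    assert np.allclose(v, 0, atol=1e-9)


def test_tangent_round_trip(spd_batch):
    ref = spd_batch[0]
    for C in spd_batch[1:]:
        back = inverse_tangent_map(tangent_map(C, ref), ref)
        assert np.allclose(back, C, atol=1e-8 * np.linalg.norm(C))


def test_tangent_norm_equals_distance(spd_batch):
    ref = spd_batch[0]
    for C in spd_batch[1:]:
        assert np.linalg.norm(tangent_map(C, ref)) == pytest.approx(
            riemannian_distance(ref, C), abs=1e-8
        )


def test_tangent_dimension_mismatch_rejected(rng):
    with pytest.raises(ValueError):
        inverse_tangent_map(np.zeros(5), np.eye(3))


# --- recentering and incremental mean ----------------------------------------


def test_recenter_identities(spd_batch):
    C, R = spd_batch[0], spd_batch[1]
    assert np.allclose(recenter(C, np.eye(4)), C, atol=1e-12)
    assert np.allclose(recenter(R, R), np.eye(4), atol=1e-10)


def test_recenter_is_isometry(spd_batch):
    A, B, R = spd_batch[0], spd_batch[1], spd_batch[2]
    assert riemannian_distance(recenter(A, R), recenter(B, R)) == pytest.approx(
        riemannian_distance(A, B), rel=1e-8
    )


def test_recentering_set_at_own_mean_gives_identity_mean(spd_batch):
    M = karcher_mean(spd_batch, MeanSettings(tol=1e-10, max_iter=200))
    shifted = recenter(spd_batch, M)
    M2 = karcher_mean(shifted, MeanSettings(tol=1e-10, max_iter=200))
    assert riemannian_distance(M2, np.eye(4)) < 1e-7


def test_incremental_mean_midpoint_and_fixed_point(spd_batch):
    A, B = spd_batch[0], spd_batch[1]
    assert np.allclose(incremental_mean(A, B, 1), geodesic(A, B, 0.5))
    for n in (1, 5, 100):
        assert np.allclose(incremental_mean(A, A, n), A, atol=1e-9)
    with pytest.raises(ValueError):
        incremental_mean(A, B, 0)


def test_incremental_mean_reproduces_batch_geometric_mean(rng):
    """Sequential updates over commuting diagonals equal the batch geometric mean."""
    diags = np.exp(rng.uniform(-1, 1, size=(7, 3)))
    M = np.diag(diags[0])
    for n, d in enumerate(diags[1:], start=1):
        M = incremental_mean(M, np.diag(d), n)
    expected = np.diag(np.exp(np.mean(np.log(diags), axis=0)))
    assert np.allclose(M, expected, atol=1e-10)


def test_distance_dimension_mismatch_rejected():
    with pytest.raises(ValueError):
        riemannian_distance(np.eye(3), np.eye(4))


# --- hypothesis property checks on the commuting closed form -----------------

from hypothesis import given, settings, strategies as st

pos = st.floats(min_value=1e-3, max_value=1e3, allow_nan=False, allow_infinity=False)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(a1=pos, a2=pos, b1=pos, b2=pos)
def test_distance_properties_on_diagonal_spds(a1, a2, b1, b2):
    A, B = np.diag([a1, a2]), np.diag([b1, b2])
    d = riemannian_distance(A, B)
    assert d >= 0
    assert d == pytest.approx(oracle_distance(np.array([a1, a2]), np.array([b1, b2])), rel=1e-6, abs=1e-8)
    assert d == pytest.approx(riemannian_distance(B, A), rel=1e-6, abs=1e-9)
    # scale invariance of the affine-invariant metric
    assert riemannian_distance(3.5 * A, 3.5 * B) == pytest.approx(d, rel=1e-6, abs=1e-9)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(a=pos, b=pos, t=st.floats(min_value=0.0, max_value=1.0))
def test_geodesic_endpoint_interpolation_scalar(a, b, t):
    G = geodesic(np.diag([a, a]), np.diag([b, b]), t)
    assert G[0, 0] == pytest.approx(a ** (1 - t) * b**t, rel=1e-6)
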