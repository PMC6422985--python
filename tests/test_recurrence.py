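"""Recurrence core: embedding, k-NN thresholds, matrix, rendering.

Brute-force oracles (explicit double loops over pairwise distances) are
kept deliberately independent of the library implementation.
"""

import hashlib

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctgrp.records import FHRRecord
from ctgrp.recurrence import (EmbeddingParams, PhaseTrajectory, embed, knn_epsilon,
                              recurrence_matrix, render_rp, signal_to_rp)
from ctgrp.synthetic import generate_fhr, normal_preset


# ---------------------------------------------------------------------- oracles
#
# Exact rational arithmetic on squared distances: for the given float
# coordinates these oracles are mathematically exact, so they are immune
# to the ulp-level kernel differences (BLAS FMA vs plain sums) that can
# flip a strict comparison exactly at the k-th-neighbour boundary, where
# the FAN rule places every threshold. d < eps  <=>  d^2 < eps^2.

from fractions import Fraction


def _sqdist_exact(p, q):
    return sum((Fraction(a) - Fraction(b)) ** 2 for a, b in zip(p, q))


def brute_knn_sq_epsilon(points, k):
    """Exact squared k-th-neighbour distances (self excluded)."""
    n = len(points)
    out = []
    for i in range(n):
        d = sorted(_sqdist_exact(points[i], points[j]) for j in range(n) if j != i)
        out.append(d[k - 1])
    return out


def brute_matrix_fan(points, k):
    """Exact FAN recurrence matrix (strict Heaviside) for neighbour count k."""
    n = len(points)
    eps_sq = brute_knn_sq_epsilon(points, k)
    R = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            R[i, j] = 1 if _sqdist_exact(points[i], points[j]) < eps_sq[i] else 0
    return R


def brute_matrix_global(points, eps):
    """Exact recurrence matrix for one scalar float threshold."""
    n = len(points)
    eps_sq = Fraction(float(eps)) ** 2
    R = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            R[i, j] = 1 if _sqdist_exact(points[i], points[j]) < eps_sq else 0
    return R


# ---------------------------------------------------------------------- embed

def test_embed_direct_expansion():
    traj = embed([1, 2, 3, 4, 5], EmbeddingParams(m=2, tau=1, k=1))
    np.testing.assert_array_equal(traj.points,
                                  [[1, 2], [2, 3], [3, 4], [4, 5]])
    assert traj.n_points == 4


def test_embed_point_count():
    traj = embed(np.arange(10.0), EmbeddingParams(m=3, tau=2, k=1))
    assert traj.n_points == 10 - 2 * 2


def test_embed_too_short():
    with pytest.raises(ValueError, match="at least"):
        embed(np.arange(4.0), EmbeddingParams(m=3, tau=2, k=1))


def test_params_invariants():
    for bad in (dict(m=1), dict(tau=0), dict(k=0)):
        with pytest.raises(ValueError):
            EmbeddingParams(**{**dict(m=2, tau=1, k=1), **bad})


@settings(max_examples=30, deadline=None)
@given(L=st.integers(6, 200), m=st.integers(2, 4), tau=st.integers(1, 5))
def test_embed_count_formula(L, m, tau):
    n = L - (m - 1) * tau
    if n < 2:
        return
    traj = embed(np.sin(np.arange(L)), EmbeddingParams(m=m, tau=tau, k=1))
    assert traj.n_points == n
    assert traj.points.shape == (n, m)


# ----------------------------------------------------------------- knn_epsilon

def test_knn_identical_points_zero_threshold():
    traj = PhaseTrajectory(points=np.zeros((6, 2)), source_length=7)
    np.testing.assert_array_equal(knn_epsilon(traj, 3), np.zeros(6))


def test_knn_collinear_k1():
    traj = PhaseTrajectory(points=np.array([[0, 0], [1, 0], [2, 0], [3, 0]], float),
                           source_length=5)
    np.testing.assert_allclose(knn_epsilon(traj, 1), [1, 1, 1, 1])


def test_knn_collinear_k3():
    traj = PhaseTrajectory(points=np.array([[0, 0], [1, 0], [2, 0], [3, 0]], float),
                           source_length=5)
    np.testing.assert_allclose(knn_epsilon(traj, 3), [3, 2, 2, 3])


def test_knn_k_too_large():
    traj = PhaseTrajectory(points=np.zeros((4, 2)), source_length=5)
    with pytest.raises(ValueError, match="k=4"):
        knn_epsilon(traj, 4)


@pytest.mark.parametrize("seed", range(5))
def test_knn_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    pts = rng.random((30, 2)) * 10
    traj = PhaseTrajectory(points=pts, source_length=31)
    for k in (1, 3, 7):
        expected = [float(s) ** 0.5 for s in brute_knn_sq_epsilon(pts, k)]
        np.testing.assert_allclose(knn_epsilon(traj, k), expected, rtol=1e-12)


# ------------------------------------------------------------ recurrence matrix

def test_identical_points_all_zero_matrix():
    """Zero thresholds with a strict step give an all-zero R, diagonal included."""
    traj = PhaseTrajectory(points=np.zeros((5, 2)), source_length=6)
    mat = recurrence_matrix(traj, knn_epsilon(traj, 2))
    assert mat.R.sum() == 0


def test_collinear_k1_gives_identity():
    traj = PhaseTrajectory(points=np.array([[0, 0], [1, 0], [2, 0], [3, 0]], float),
                           source_length=5)
    mat = recurrence_matrix(traj, knn_epsilon(traj, 1))
    np.testing.assert_array_equal(mat.R, np.eye(4, dtype=np.uint8))


def test_global_epsilon_symmetric():
    rng = np.random.default_rng(3)
    traj = PhaseTrajectory(points=rng.random((40, 3)), source_length=43)
    mat = recurrence_matrix(traj, 0.4)
    np.testing.assert_array_equal(mat.R, mat.R.T)


def test_epsilon_shape_mismatch():
    traj = PhaseTrajectory(points=np.zeros((5, 2)), source_length=6)
    with pytest.raises(ValueError, match="shape"):
        recurrence_matrix(traj, np.ones(4))


@pytest.mark.parametrize("seed", range(10))
def test_matrix_matches_brute_force_per_point(seed):
    rng = np.random.default_rng(100 + seed)
    n = int(rng.integers(10, 50))
    pts = rng.random((n, 2)) * 50
    traj = PhaseTrajectory(points=pts, source_length=n + 1)
    k = int(rng.integers(1, min(8, n - 1)))
    eps = knn_epsilon(traj, k)
    np.testing.assert_array_equal(recurrence_matrix(traj, eps).R,
                                  brute_matrix_fan(pts, k))


@pytest.mark.parametrize("seed", range(5))
def test_matrix_matches_brute_force_global(seed):
    rng = np.random.default_rng(200 + seed)
    n = int(rng.integers(20, 100))
    pts = rng.random((n, 2))
    traj = PhaseTrajectory(points=pts, source_length=n + 1)
    eps = float(rng.uniform(0.1, 0.5))
    np.testing.assert_array_equal(recurrence_matrix(traj, eps).R,
                                  brute_matrix_global(pts, eps))


@pytest.mark.parametrize("seed", range(5))
def test_rows_hold_exactly_k_ones_for_distinct_distances(seed):
    rng = np.random.default_rng(300 + seed)
    pts = rng.random((40, 2)) * 100  # random reals: distances distinct a.s.
    traj = PhaseTrajectory(points=pts, source_length=41)
    for k in (1, 4, 9):
        R = recurrence_matrix(traj, knn_epsilon(traj, k)).R
        np.testing.assert_array_equal(R.sum(axis=1), np.full(40, k))
        np.testing.assert_array_equal(np.diag(R), np.ones(40, dtype=np.uint8))


# -------------------------------------------------------------------- rendering

def make_matrix(R):
    from ctgrp.recurrence import RecurrenceMatrix
    R = np.asarray(R, dtype=np.uint8)
    return RecurrenceMatrix(R=R, epsilon=np.ones(R.shape[0]),
                            params=EmbeddingParams())


def test_render_all_ones_is_white():
    img = render_rp(make_matrix(np.ones((64, 64))), size=64)
    assert (img.pixels == 1.0).all()


def test_render_same_size_is_pixel_exact():
    rng = np.random.default_rng(0)
    R = (rng.random((64, 64)) < 0.3).astype(np.uint8)
    for mode in ("raster", "mean"):
        img = render_rp(make_matrix(R), size=64, mode=mode)
        np.testing.assert_array_equal(img.pixels, R.astype(float))


def test_render_checkerboard_area_mean():
    R = np.indices((128, 128)).sum(axis=0) % 2
    img = render_rp(make_matrix(R), size=64, mode="mean")
    np.testing.assert_allclose(img.pixels, 0.5)


def test_render_checkerboard_raster_is_white():
    R = np.indices((128, 128)).sum(axis=0) % 2
    img = render_rp(make_matrix(R), size=64, mode="raster")
    np.testing.assert_allclose(img.pixels, 1.0)


@pytest.mark.parametrize("n", [50, 64, 100, 137])
def test_mean_rendering_preserves_recurrence_rate(n):
    rng = np.random.default_rng(n)
    R = (rng.random((n, n)) < 0.2).astype(np.uint8)
    mat = make_matrix(R)
    img = render_rp(mat, size=64, mode="mean")
    assert img.pixels.mean() == pytest.approx(mat.recurrence_rate, abs=1e-9)


def test_render_rejects_bad_args():
    with pytest.raises(ValueError):
        render_rp(make_matrix(np.ones((4, 4))), size=0)
    with pytest.raises(ValueError):
        render_rp(make_matrix(np.ones((4, 4))), size=8, mode="nearest")


def test_channel_replication():
    img = render_rp(make_matrix(np.eye(10)), size=10)
    stack = img.as_channels(3)
    assert stack.shape == (10, 10, 3)
    np.testing.assert_array_equal(stack[..., 0], stack[..., 2])


# ------------------------------------------------------------------ end to end

def test_constant_record_renders_black(flat_record):
    img = signal_to_rp(flat_record, EmbeddingParams(2, 1, 6), size=64)
    assert (img.pixels == 0.0).all()


def test_signal_to_rp_contract(clean_record):
    img = signal_to_rp(clean_record, EmbeddingParams(2, 3, 4), size=64)
    assert img.pixels.shape == (64, 64)
    assert img.pixels.min() >= 0.0 and img.pixels.max() <= 1.0


def test_signal_to_rp_regression_fixture():
    """Frozen digest of the figure-style RP (m=2, tau=1, k=6) of a fixed record.

    Guards the full embed -> threshold -> matrix -> raster chain against
    silent numerical drift; the digest was generated once by this
    implementation.
    """
    rec = generate_fhr(normal_preset(duration_s=120.0, dropout_rate=0.0,
                                     spike_rate=0.0, seed=77))
    img = signal_to_rp(rec, EmbeddingParams(2, 1, 6), size=64)
    u8 = np.clip(np.rint(img.pixels * 255), 0, 255).astype(np.uint8)
    digest = hashlib.sha256(u8.tobytes()).hexdigest()
    assert digest == "6d3d9a5996640b3e7143196a417fbb72e544b3e68aeb9a8a4251690681f7d3d3"
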