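"""Recurrence-plot construction from FHR time series.

A scalar series :math:`u_1, \\dots, u_L` is embedded into an
m-dimensional phase space with delay :math:`\\tau` (Takens delay
coordinates), giving :math:`N = L - (m-1)\\tau` points
:math:`x_i = (u_i, u_{i+\\tau}, \\dots, u_{i+(m-1)\\tau})`. The recurrence
matrix marks pairs of points closer than a threshold:

.. math:: R_{i,j} = \\Theta(\\varepsilon_i - \\lVert x_i - x_j \\rVert),

with the Heaviside step defined strictly (:math:`\\Theta(0) = 0`) and the
Euclidean norm. The threshold is chosen per point by the fixed amount of
nearest neighbours (FAN) rule: :math:`\\varepsilon_i` is the distance
from :math:`x_i` to its k-th nearest neighbour (self excluded), so with
all pairwise distances distinct every row of R holds exactly k ones
(k-1 neighbours plus the diagonal). A global-threshold mode (the mean of
the per-point thresholds) is available for sensitivity checks; it yields
a symmetric R.

The N x N binary matrix is rendered to a fixed-size grayscale image
(default 64 x 64) with recurrences white (1.0) on a black (0.0)
background. The default rendering rasterizes the matrix the way a
plotting device draws an RP figure (a pixel is white when any recurrence
falls in its block); an exact area-average mode that preserves the
recurrence rate as the mean intensity is available for density analysis
(see :func:`render_rp`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import FHRRecord

__all__ = [
    "EmbeddingParams",
    "PhaseTrajectory",
    "RecurrenceMatrix",
    "RPImage",
    "embed",
    "knn_epsilon",
    "recurrence_matrix",
    "render_rp",
    "signal_to_rp",
]


@dataclass(frozen=True)
class EmbeddingParams:
    """Embedding dimension m (>= 2), delay tau (samples), neighbour count k."""
    m: int = 2
    tau: int = 1
    k: int = 6

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError(f"embedding dimension m must be >= 2, got {self.m}")
        if self.tau < 1:
            raise ValueError(f"delay tau must be >= 1, got {self.tau}")
        if self.k < 1:
            raise ValueError(f"neighbour count k must be >= 1, got {self.k}")

    @property
    def min_length(self) -> int:
        """Shortest series length giving at least 2 phase points."""
        return (self.m - 1) * self.tau + 2


@dataclass
class PhaseTrajectory:
    points: np.ndarray        # (N, m)
    source_length: int        # L

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass
class RecurrenceMatrix:
    R: np.ndarray             # (N, N) uint8 in {0, 1}
    epsilon: np.ndarray       # per-point thresholds, length N
    params: EmbeddingParams

    @property
    def recurrence_rate(self) -> float:
        return float(self.R.mean())


@dataclass
class RPImage:
    """Square intensity grid in [0, 1]; 1 = white = recurrence."""
    pixels: np.ndarray        # (H, W)

    def as_channels(self, n_channels: int = 3) -> np.ndarray:
        """(H, W, C) array with the grayscale plane replicated."""
        return np.repeat(self.pixels[:, :, None], n_channels, axis=2)


def embed(series, params: EmbeddingParams) -> PhaseTrajectory:
    """Delay-embed a scalar series into m-dimensional phase space."""
    u = np.asarray(series, dtype=float).ravel()
    L = u.size
    n = L - (params.m - 1) * params.tau
    if n < 2:
        raise ValueError(
            f"series of length {L} too short for (m={params.m}, tau={params.tau}); "
            f"need at least {params.min_length} samples")
    cols = [u[j * params.tau: j * params.tau + n] for j in range(params.m)]
    return PhaseTrajectory(points=np.column_stack(cols), source_length=L)


def _distance_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Euclidean distances between every row of ``a`` and every row of ``b``.

    Plain difference-square-sum-sqrt, summing coordinates in order, so the
    result agrees bit-for-bit with ``np.linalg.norm(a[i] - b[j])``. The
    FAN construction puts each point's k-th neighbour exactly on the
    strict threshold boundary, so the threshold and matrix stages must
    share one distance arithmetic (a fancier kernel — e.g. the BLAS
    ||a||^2+||b||^2-2ab expansion — can differ by an ulp and flip the
    Heaviside step). Squared coordinate differences are accumulated in
    coordinate order, exactly as ``linalg.norm`` sums them.
    """
    d2 = (a[:, 0, None] - b[None, :, 0]) ** 2
    for j in range(1, a.shape[1]):
        d2 += (a[:, j, None] - b[None, :, j]) ** 2
    return np.sqrt(d2)


def _row_chunk(n: int, m: int) -> int:
    # bound the (chunk, n, m) broadcast temporary to ~100 MB
    return max(1, int(1.5e6) // max(n * m // 8, 1))


def knn_epsilon(traj: PhaseTrajectory, k: int) -> np.ndarray:
    """Per-point thresholds: distance to the k-th nearest neighbour.

    The point itself is excluded from the ranking; ties are broken by
    sorted distance order, so the threshold is the k-th smallest distance
    to any other point (the row's (k+1)-th smallest entry, counting the
    zero self-distance).
    """
    n = traj.n_points
    if k >= n:
        raise ValueError(f"k={k} must be < number of phase points N={n}")
    pts = traj.points
    eps = np.empty(n)
    chunk = _row_chunk(n, pts.shape[1])
    for s in range(0, n, chunk):
        e = min(s + chunk, n)
        d = _distance_rows(pts[s:e], pts)
        eps[s:e] = np.partition(d, k, axis=1)[:, k]
    return eps


def recurrence_matrix(traj: PhaseTrajectory, epsilon,
                      params: EmbeddingParams | None = None) -> RecurrenceMatrix:
    """Binary recurrence matrix: R[i, j] = 1 iff ||x_i - x_j|| < eps_i.

    The comparison is strict (Heaviside of a non-positive argument is 0),
    so a zero threshold yields an all-zero row including the diagonal.
    ``epsilon`` may be a scalar (global threshold, symmetric R) or a
    length-N vector of per-point thresholds.
    """
    n = traj.n_points
    eps = np.asarray(epsilon, dtype=float)
    if eps.ndim == 0:
        eps = np.full(n, float(eps))
    if eps.shape != (n,):
        raise ValueError(f"epsilon has shape {eps.shape}, expected ({n},)")
    pts = traj.points
    R = np.empty((n, n), dtype=np.uint8)
    chunk = _row_chunk(n, pts.shape[1])
    for s in range(0, n, chunk):
        e = min(s + chunk, n)
        d = _distance_rows(pts[s:e], pts)
        R[s:e] = d < eps[s:e, None]
    if params is None:
        params = EmbeddingParams(m=max(pts.shape[1], 2), tau=1, k=1)
    return RecurrenceMatrix(R=R, epsilon=eps, params=params)


def _resample_weights(n_in: int, n_out: int) -> np.ndarray:
    """(n_out, n_in) exact area-overlap averaging weights; rows sum to 1."""
    w = np.zeros((n_out, n_in))
    scale = n_in / n_out
    for a in range(n_out):
        lo, hi = a * scale, (a + 1) * scale
        i0, i1 = int(np.floor(lo)), int(np.ceil(hi))
        for i in range(i0, min(i1, n_in)):
            overlap = min(hi, i + 1) - max(lo, i)
            if overlap > 0:
                w[a, i] = overlap / scale
    return w


def render_rp(matrix: RecurrenceMatrix, size: int = 64, mode: str = "raster") -> RPImage:
    """Render a recurrence matrix to a size x size grayscale image.

    An N x N matrix with N == size maps pixel-for-pixel (1 -> white) in
    either mode. Otherwise:

    * ``mode="raster"`` (default) emulates a plotting device: a pixel is
      white when *any* recurrence point falls inside its block. With
      per-point k-NN thresholds every matrix row holds exactly k ones, so
      the recurrence *rate* carries no information; the discriminative
      content is how recurrences clump (diagonal line segments for
      smooth, low-complexity traces vs scattered dots for noisy ones),
      which rasterization preserves and averaging washes out.
    * ``mode="mean"`` resamples by exact area averaging (both down- and
      upsampling), keeping the mean pixel intensity equal to the
      recurrence rate — the right choice when densities matter.
    """
    if size < 1:
        raise ValueError(f"image size must be >= 1, got {size}")
    if mode not in ("raster", "mean"):
        raise ValueError(f"unknown render mode {mode!r}")
    R = matrix.R.astype(float)
    n = R.shape[0]
    if n == size:
        return RPImage(pixels=R)
    if mode == "mean":
        w = _resample_weights(n, size)
        return RPImage(pixels=w @ R @ w.T)
    # raster: block-OR via an integral image (blocks of unequal size when
    # size does not divide N; upsampling replicates pixels)
    edges = np.floor(np.arange(size + 1) * n / size).astype(int)
    if n < size:
        idx = np.minimum(edges[:-1], n - 1)
        return RPImage(pixels=R[np.ix_(idx, idx)])
    cs = np.zeros((n + 1, n + 1))
    cs[1:, 1:] = np.cumsum(np.cumsum(matrix.R, axis=0), axis=1)
    block = (cs[edges[1:], :][:, edges[1:]] - cs[edges[:-1], :][:, edges[1:]]
             - cs[edges[1:], :][:, edges[:-1]] + cs[edges[:-1], :][:, edges[:-1]])
    return RPImage(pixels=(block > 0).astype(float))


def signal_to_rp(record: FHRRecord, params: EmbeddingParams = EmbeddingParams(),
                 size: int = 64, global_epsilon: bool = False,
                 render_mode: str = "raster") -> RPImage:
    """Full chain: embed -> k-NN thresholds -> recurrence matrix -> image.

    The per-point (FAN) mode computes each chunk of distance rows once,
    deriving the thresholds and the binary rows from the same arithmetic;
    the result is identical to composing :func:`knn_epsilon` and
    :func:`recurrence_matrix`.
    """
    traj = embed(record.samples, params)
    if global_epsilon:
        eps = float(knn_epsilon(traj, params.k).mean())
        mat = recurrence_matrix(traj, eps, params=params)
        return render_rp(mat, size=size, mode=render_mode)
    pts = traj.points
    n = traj.n_points
    if params.k >= n:
        raise ValueError(f"k={params.k} must be < number of phase points N={n}")
    R = np.empty((n, n), dtype=np.uint8)
    eps = np.empty(n)
    chunk = _row_chunk(n, pts.shape[1])
    for s in range(0, n, chunk):
        e = min(s + chunk, n)
        d = _distance_rows(pts[s:e], pts)
        eps[s:e] = np.partition(d, params.k, axis=1)[:, params.k]
        R[s:e] = d < eps[s:e, None]
    mat = RecurrenceMatrix(R=R, epsilon=eps, params=params)
    return render_rp(mat, size=size, mode=render_mode)
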