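"""Rigid and nonrigid Coherent Point Drift (CPD) point-set registration.

CPD treats the moving point set as the centroids of a Gaussian mixture fitted
to the fixed set by expectation-maximization, with a uniform component of
weight ``w`` absorbing outliers.  The rigid variant estimates a rotation and
translation (no scale: for symmetry analysis a size difference *is*
asymmetry); the nonrigid variant estimates a smooth displacement field
``v(y) = sum_j exp(-||y - y_j||^2 / (2 beta^2)) W_j`` regularized by the
motion-coherence penalty ``lambda/2 * tr(W' G W)``.

Both variants record a per-iteration trace (sigma^2, objective, posterior
entropy) and guarantee a non-increasing objective up to floating-point slack:
the objective is the observed-data negative log-likelihood (plus the coherence
penalty in the nonrigid case), which exact EM cannot increase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

#: floor on sigma^2 (mm^2) to avoid division blowup near perfect fits
SIGMA2_FLOOR = 1e-8


class RegistrationError(RuntimeError):
    """Raised for degenerate geometry or numerically failed solves."""


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------


@dataclass
class RigidTransform:
    """Proper rigid motion ``y -> R y + t`` (R orthonormal, det +1; t in mm)."""

    R: np.ndarray
    t: np.ndarray

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=np.float64).reshape(3, 3)
        self.t = np.asarray(self.t, dtype=np.float64).reshape(3)
        if np.abs(self.R.T @ self.R - np.eye(3)).max() > 1e-9:
            raise ValueError("R is not orthonormal within 1e-9")
        if abs(np.linalg.det(self.R) - 1.0) > 1e-9:
            raise ValueError("det(R) != +1 within 1e-9")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=np.float64) @ self.R.T + self.t

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first, then
        ``self``."""
        return RigidTransform(self.R @ other.R, self.R @ other.t + self.t)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.R.T, -self.R.T @ self.t)

    def rotation_angle_deg(self) -> float:
        """Geodesic rotation magnitude in degrees."""
        c = (np.trace(self.R) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    def to_dict(self) -> dict:
        return {"R": self.R.tolist(), "t": self.t.tolist()}


@dataclass
class CpdParams:
    """Hyperparameters of the CPD EM loop.

    w: outlier mixture weight in [0, 1).
    beta: Gaussian kernel width (mm) of the nonrigid motion-coherence prior;
        10 mm is smooth at bone scale.
    lam: regularization weight of the coherence penalty.
    tolerance: relative objective change declaring convergence.
    subsample_cap: maximum points used per set during fitting; seeded uniform
        subsampling keeps cost bounded, the fitted field is then evaluated at
        every vertex.
    """

    w: float = 0.1
    beta: float = 10.0
    lam: float = 2.0
    max_iterations: int = 150
    tolerance: float = 1e-6
    subsample_cap: int = 2000
    seed: int = 0
    sigma2_floor: float = SIGMA2_FLOOR

    def __post_init__(self) -> None:
        if not (0.0 <= self.w < 1.0):
            raise ValueError("w must be in [0, 1)")
        if self.beta <= 0 or self.lam <= 0 or self.tolerance <= 0:
            raise ValueError("beta, lam and tolerance must be positive")
        if self.sigma2_floor < SIGMA2_FLOOR:
            self.sigma2_floor = SIGMA2_FLOOR

    def to_dict(self) -> dict:
        return {
            "w": self.w,
            "beta": self.beta,
            "lam": self.lam,
            "max_iterations": self.max_iterations,
            "tolerance": self.tolerance,
            "subsample_cap": self.subsample_cap,
            "seed": self.seed,
            "sigma2_floor": self.sigma2_floor,
        }


@dataclass
class CpdTrace:
    """Per-iteration diagnostics of the EM loop."""

    sigma2: list[float] = field(default_factory=list)
    objective: list[float] = field(default_factory=list)
    entropy: list[float] = field(default_factory=list)
    converged: bool = False
    iterations: int = 0

    def to_rows(self) -> list[dict]:
        return [
            {"iteration": i, "sigma2": s, "objective": o, "entropy": e}
            for i, (s, o, e) in enumerate(
                zip(self.sigma2, self.objective, self.entropy)
            )
        ]


@dataclass
class DeformationField:
    """Kernel-parameterized displacement field from nonrigid CPD.

    ``displacement(y) = sum_j exp(-||y - y_j||^2/(2 beta^2)) W_j`` over the
    control points ``source_points``; smooth by construction and evaluable at
    arbitrary points, so a field fitted on a subsample deforms a full mesh.
    """

    source_points: np.ndarray
    W: np.ndarray
    beta: float

    def displacement(self, points: np.ndarray, chunk: int = 4096) -> np.ndarray:
        points = np.asarray(points, dtype=np.float64)
        out = np.empty_like(points)
        for lo in range(0, len(points), chunk):
            block = points[lo : lo + chunk]
            d2 = cdist(block, self.source_points, "sqeuclidean")
            G = np.exp(-d2 / (2.0 * self.beta**2))
            out[lo : lo + chunk] = G @ self.W
        return out

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=np.float64) + self.displacement(points)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def apply_rigid(points: np.ndarray, transform: RigidTransform) -> np.ndarray:
    """Apply ``y -> R y + t`` to an (N, 3) array."""
    return transform.apply(points)


def apply_deformation(points: np.ndarray, field_: DeformationField) -> np.ndarray:
    """Displace points by the kernel-evaluated deformation field."""
    return field_.apply(points)


def _subsample(points: np.ndarray, cap: int, rng: np.random.Generator) -> np.ndarray:
    if cap is None or len(points) <= cap:
        return points
    idx = np.sort(rng.choice(len(points), size=cap, replace=False))
    return points[idx]


def _check_nondegenerate(points: np.ndarray, name: str) -> None:
    if len(points) == 0:
        raise RegistrationError(f"{name} point set is empty")
    centered = points - points.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[0] < 1e-12 or (len(sv) > 1 and sv[1] < 1e-9 * sv[0]):
        raise RegistrationError(
            f"{name} point set is degenerate (coincident or collinear points)"
        )


def _e_step(X: np.ndarray, T: np.ndarray, sigma2: float, w: float):
    """Posterior matrix P (N, M), observed-data NLL, and mean row entropy.

    Log-sum-exp stabilized.  The mixture density is
    ``p(x) = (1 - w)/M sum_m N(x; t_m, sigma2 I) + w/N``.
    """
    N, M = len(X), len(T)
    d2 = cdist(X, T, "sqeuclidean")
    log_norm = -1.5 * np.log(2.0 * np.pi * sigma2)
    log_comp = -d2 / (2.0 * sigma2) + log_norm + np.log((1.0 - w) / M)
    row_max = log_comp.max(axis=1)
    s = np.exp(log_comp - row_max[:, None])
    row_sum = s.sum(axis=1)
    if w > 0:
        log_mix = np.logaddexp(row_max + np.log(row_sum), np.log(w / N))
    else:
        log_mix = row_max + np.log(row_sum)
    P = np.exp(log_comp - log_mix[:, None])
    nll = float(-log_mix.sum())
    # entropy of the per-point correspondence distribution over mixture
    # components (outlier mass excluded), averaged over fixed points
    with np.errstate(divide="ignore", invalid="ignore"):
        q = P / np.maximum(P.sum(axis=1, keepdims=True), 1e-300)
        ent = -np.nansum(np.where(q > 0, q * np.log(q), 0.0), axis=1)
    return P, nll, float(ent.mean())


# ---------------------------------------------------------------------------
# rigid CPD
# ---------------------------------------------------------------------------


def _pca_axes(points: np.ndarray) -> np.ndarray:
    centered = points - points.mean(axis=0)
    cov = centered.T @ centered / len(points)
    _, vecs = np.linalg.eigh(cov)
    return vecs.T[::-1]  # rows: axes by decreasing variance


def _init_candidates(X: np.ndarray, Y: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic starting poses: identity plus the four proper rotations
    aligning the principal axes of the moving cloud to the fixed cloud.

    EM from identity can stall in a local optimum for initial rotations beyond
    roughly 20 degrees; principal-axes pre-alignment puts at least one
    candidate near the basin of the global optimum."""
    mu_x = X.mean(axis=0)
    mu_y = Y.mean(axis=0)
    cands = [(np.eye(3), np.zeros(3)), (np.eye(3), mu_x - mu_y)]
    Ax = _pca_axes(X)
    Ay = _pca_axes(Y)
    for s1 in (1.0, -1.0):
        for s2 in (1.0, -1.0):
            S = np.diag([s1, s2, s1 * s2])  # proper sign combinations
            R = Ax.T @ S @ Ay
            if np.linalg.det(R) < 0:  # numerical guard; S keeps det +1
                continue
            cands.append((R, mu_x - R @ mu_y))
    return cands


def _select_init(
    X: np.ndarray, Y: np.ndarray, cands: list[tuple[np.ndarray, np.ndarray]]
) -> tuple[np.ndarray, np.ndarray, float]:
    """Pick the candidate pose minimizing the mean squared nearest-neighbour
    residual of the transformed moving cloud.  Strict improvement required,
    so the identity wins all ties (already-aligned inputs stay put).

    Returns (R, t, cost); the cost also calibrates the initial sigma^2 — a
    spread-based initialization would let the first high-entropy E-steps pull
    the estimate away from the selected basin."""
    from scipy.spatial import cKDTree

    tree = cKDTree(X)
    best = cands[0]
    best_cost = np.inf
    for R, t in cands:
        d, _ = tree.query(Y @ R.T + t, workers=-1)
        cost = float((d**2).mean())
        if cost < best_cost * (1.0 - 1e-9):
            best = (R, t)
            best_cost = cost
    return best[0], best[1], best_cost


def rigid_cpd(
    moving: np.ndarray,
    fixed: np.ndarray,
    params: CpdParams | None = None,
) -> tuple[RigidTransform, CpdTrace]:
    """Estimate the rigid motion mapping ``moving`` onto ``fixed``.

    EM over a Gaussian mixture whose centroids are the transformed moving
    points; each M-step solves the rotation from the SVD of the
    posterior-weighted cross-covariance (with determinant correction), then
    the translation and sigma^2 in closed form.  Pure rigid: no scale factor.
    The EM loop starts from the best of a deterministic set of candidate
    poses (identity and principal-axes alignments).
    """
    params = params or CpdParams()
    X = np.asarray(fixed, dtype=np.float64)
    Y = np.asarray(moving, dtype=np.float64)
    _check_nondegenerate(X, "fixed")
    _check_nondegenerate(Y, "moving")
    rng = np.random.default_rng(params.seed)
    X = _subsample(X, params.subsample_cap, rng)
    Y = _subsample(Y, params.subsample_cap, rng)

    R, t, init_cost = _select_init(X, Y, _init_candidates(X, Y))
    sigma2 = max(3.0 * init_cost, params.sigma2_floor)
    trace = CpdTrace()
    prev_obj = np.inf

    for it in range(params.max_iterations):
        T = Y @ R.T + t
        P, nll, ent = _e_step(X, T, sigma2, params.w)
        trace.sigma2.append(sigma2)
        trace.objective.append(nll)
        trace.entropy.append(ent)
        trace.iterations = it + 1

        Np = P.sum()
        if Np < 1e-12:
            raise RegistrationError("all correspondences assigned to outliers")
        Pt1 = P.sum(axis=1)  # (N,)
        P1 = P.sum(axis=0)  # (M,)
        mu_x = (Pt1 @ X) / Np
        mu_y = (P1 @ Y) / Np
        Xc = X - mu_x
        Yc = Y - mu_y
        A = Xc.T @ (P @ Yc)
        U, S, Vt = np.linalg.svd(A)
        C = np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))])
        R = U @ C @ Vt
        t = mu_x - R @ mu_y
        trAR = np.trace(A.T @ R)
        sxx = Pt1 @ np.einsum("ij,ij->i", Xc, Xc)
        syy = P1 @ np.einsum("ij,ij->i", Yc, Yc)
        sigma2 = max((sxx + syy - 2.0 * trAR) / (3.0 * Np), params.sigma2_floor)

        if it > 0 and abs(prev_obj - nll) / max(1.0, abs(prev_obj)) < params.tolerance:
            trace.converged = True
            break
        prev_obj = nll

    if not trace.converged:
        logger.warning(
            "rigid CPD did not converge in %d iterations", params.max_iterations
        )
    return RigidTransform(R, t), trace


# ---------------------------------------------------------------------------
# nonrigid CPD
# ---------------------------------------------------------------------------


def nonrigid_cpd(
    moving: np.ndarray,
    fixed: np.ndarray,
    params: CpdParams | None = None,
) -> tuple[DeformationField, CpdTrace]:
    """Estimate a smooth displacement field deforming ``moving`` onto ``fixed``.

    The deformed positions are ``T(Y) = Y + G W`` with the Gaussian Gram
    matrix ``G_ij = exp(-||y_i - y_j||^2/(2 beta^2))``; each M-step solves
    ``(diag(P1) G + lam sigma2 I) W = P X - diag(P1) Y`` and updates sigma^2
    in closed form.  When the moving set exceeds ``subsample_cap``, a seeded
    uniform subsample forms the control points; the fitted kernel field is
    then evaluable at all vertices.
    """
    params = params or CpdParams()
    X = np.asarray(fixed, dtype=np.float64)
    Y_full = np.asarray(moving, dtype=np.float64)
    _check_nondegenerate(X, "fixed")
    _check_nondegenerate(Y_full, "moving")
    rng = np.random.default_rng(params.seed)
    X = _subsample(X, params.subsample_cap, rng)
    Y = _subsample(Y_full, params.subsample_cap, rng)

    M = len(Y)
    G = np.exp(-cdist(Y, Y, "sqeuclidean") / (2.0 * params.beta**2))
    W = np.zeros((M, 3))
    # moving and fixed are already rigidly aligned when this runs in the
    # pipeline; a nearest-neighbour residual scale starts EM at the relevant
    # annealing stage instead of the full cloud spread
    from scipy.spatial import cKDTree

    nn = cKDTree(X).query(Y, workers=-1)[0]
    sigma2 = max(3.0 * float((nn**2).mean()), params.sigma2_floor)
    trace = CpdTrace()
    prev_obj = np.inf

    for it in range(params.max_iterations):
        T = Y + G @ W
        P, nll, ent = _e_step(X, T, sigma2, params.w)
        penalty = 0.5 * params.lam * float(np.einsum("ij,ij->", W, G @ W))
        obj = nll + penalty
        trace.sigma2.append(sigma2)
        trace.objective.append(obj)
        trace.entropy.append(ent)
        trace.iterations = it + 1

        Np = P.sum()
        if Np < 1e-12:
            raise RegistrationError("all correspondences assigned to outliers")
        P1 = P.sum(axis=0)  # (M,)
        Pt1 = P.sum(axis=1)  # (N,)
        PX = P.T @ X  # (M, 3)

        A = G * P1[:, None] + params.lam * sigma2 * np.eye(M)
        B = PX - P1[:, None] * Y
        try:
            W = scipy.linalg.solve(A, B)
        except scipy.linalg.LinAlgError as exc:
            raise RegistrationError(
                "nonrigid CPD linear solve is ill-conditioned; "
                "increase the regularization weight lam"
            ) from exc
        if not np.all(np.isfinite(W)):
            raise RegistrationError(
                "nonrigid CPD solve produced non-finite coefficients; "
                "increase the regularization weight lam"
            )

        T = Y + G @ W
        sxx = Pt1 @ np.einsum("ij,ij->i", X, X)
        stt = P1 @ np.einsum("ij,ij->i", T, T)
        cross = np.einsum("ij,ij->", PX, T)
        sigma2 = max((sxx - 2.0 * cross + stt) / (3.0 * Np), params.sigma2_floor)

        if it > 0 and abs(prev_obj - obj) / max(1.0, abs(prev_obj)) < params.tolerance:
            trace.converged = True
            break
        prev_obj = obj

    if not trace.converged:
        logger.warning(
            "nonrigid CPD did not converge in %d iterations", params.max_iterations
        )
    return DeformationField(Y.copy(), W, params.beta), trace
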