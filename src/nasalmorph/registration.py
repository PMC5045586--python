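"""Thin-plate-spline deformation and deformable robust point matching (RPM).

A 2-D thin-plate spline is the deformation f minimizing the squared
control-point matching error plus lambda times the integrated squared second
derivatives (the bending energy).  It decomposes into an affine part plus
radial-basis warping weights anchored at the control points, with kernel
U(r) = r^2 log r^2 and U(0) = 0.

Registration of a reference skeleton onto a target skeleton uses deterministic
annealing: soft correspondences m_ab ~ exp(-||t_b - f(r_a)||^2 / 2T) with an
outlier cluster, alternated with a TPS refit, while the temperature T is
reduced geometrically.  No random numbers are used anywhere, so results are
reproducible bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import LinAlgError, solve

from .io_alignment import ConfigError, PipelineError

__all__ = [
    "TPSTransform",
    "RPMConfig",
    "RegistrationResult",
    "tps_fit",
    "tps_apply",
    "bending_energy",
    "rpm_register",
]


def tps_kernel(r2: np.ndarray) -> np.ndarray:
    """U as a function of squared radius: U = r^2 log r^2, with U(0) = 0."""
    out = np.zeros_like(r2, dtype=float)
    pos = r2 > 0
    out[pos] = r2[pos] * np.log(r2[pos])
    return out


def _kernel_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    d2 = np.sum((a[:, None, :] - b[None, :, :]) ** 2, axis=2)
    return tps_kernel(d2)


def _lambda_scale(x: np.ndarray) -> float:
    """Dimensional scale for lambda: n times the squared mean pairwise
    distance of the source points, so lambda is dimensionless."""
    n = len(x)
    if n < 2:
        return float(n)
    d = np.sqrt(np.sum((x[:, None, :] - x[None, :, :]) ** 2, axis=2))
    dbar = d[np.triu_indices(n, 1)].mean()
    return n * dbar**2


@dataclass
class TPSTransform:
    """f(p) = offset + affine @ p + sum_i w_i U(||p - x_i||)."""

    source: np.ndarray  # (K, 2) control points x_i, mm
    weights: np.ndarray  # (K, 2) warping weights w_i
    affine: np.ndarray  # (2, 2)
    offset: np.ndarray  # (2,)
    stiffness: float = 0.0

    def __post_init__(self):
        self.source = np.asarray(self.source, dtype=float).reshape(-1, 2)
        self.weights = np.asarray(self.weights, dtype=float).reshape(-1, 2)
        self.affine = np.asarray(self.affine, dtype=float).reshape(2, 2)
        self.offset = np.asarray(self.offset, dtype=float).reshape(2)

    @classmethod
    def identity(cls, source=None) -> "TPSTransform":
        src = np.zeros((0, 2)) if source is None else source
        return cls(src, np.zeros_like(np.asarray(src, float)), np.eye(2), np.zeros(2))

    def __call__(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        single = p.ndim == 1
        p = p.reshape(-1, 2)
        out = p @ self.affine.T + self.offset
        if len(self.source):
            out = out + _kernel_matrix(p, self.source) @ self.weights
        return out[0] if single else out

    def to_json(self) -> dict:
        return {
            "source_pts": self.source.tolist(),
            "weights": self.weights.tolist(),
            "affine": self.affine.tolist(),
            "offset": self.offset.tolist(),
            "lambda": self.stiffness,
        }

    @classmethod
    def from_json(cls, doc: dict) -> "TPSTransform":
        return cls(
            np.array(doc["source_pts"], float),
            np.array(doc["weights"], float),
            np.array(doc["affine"], float),
            np.array(doc["offset"], float),
            float(doc.get("lambda", 0.0)),
        )


def tps_fit(x: np.ndarray, y: np.ndarray, lam: float = 0.0) -> TPSTransform:
    """Fit the TPS mapping control points x onto y with stiffness lambda.

    Solves the regularized linear system
    ``(K + lam_hat I) w + P a = y,  P^T w = 0`` where P = [1, x]; at lambda=0
    the spline interpolates exactly.  lambda is made dimensionless by scaling
    with n and the squared mean inter-point distance.
    """
    x = np.asarray(x, dtype=float).reshape(-1, 2)
    y = np.asarray(y, dtype=float).reshape(-1, 2)
    if x.shape != y.shape:
        raise ConfigError("source and target control points must pair up")
    n = len(x)
    if n < 3:
        raise ConfigError("TPS needs at least 3 control points")
    if lam < 0:
        raise ConfigError("lambda must be >= 0")
    d2 = np.sum((x[:, None, :] - x[None, :, :]) ** 2, axis=2)
    if np.min(d2[np.triu_indices(n, 1)]) < 1e-16:
        raise ConfigError("duplicate source control points")
    centered = x - x.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(x).max())) < 2:
        raise ConfigError("collinear source control points (rank-deficient TPS)")
    # solve in centered/scaled coordinates (conditioning); the similarity
    # converts back exactly - the kernel's log-scale term is a constant under
    # the boundedness constraints and folds into the offset
    mu = x.mean(axis=0)
    sc = float(np.sqrt(np.mean(np.sum(centered**2, axis=1))))
    sc = sc if sc > 1e-9 else 1.0
    xn = (x - mu) / sc
    yn = (y - mu) / sc
    Kmat = tps_kernel(d2 / sc**2)
    P = np.column_stack([np.ones(n), xn])
    A = np.zeros((n + 3, n + 3))
    A[:n, :n] = Kmat + lam * _lambda_scale(xn) * np.eye(n)
    A[:n, n:] = P
    A[n:, :n] = P.T
    rhs = np.zeros((n + 3, 2))
    rhs[:n] = yn
    try:
        sol = solve(A, rhs)
    except LinAlgError as exc:  # pragma: no cover - guarded above
        raise ConfigError(f"degenerate TPS system: {exc}") from exc
    wn = sol[:n]
    offset_n = sol[n]
    affine = sol[n + 1 :].T
    w = wn / sc
    kappa = (wn * np.sum(centered**2, axis=1)[:, None]).sum(axis=0) / sc
    offset = mu + sc * offset_n - affine @ mu - np.log(sc**2) * kappa
    return TPSTransform(x, w, affine, offset, lam)


def tps_apply(transform: TPSTransform, points: np.ndarray) -> np.ndarray:
    """Evaluate f at the given points (convenience wrapper)."""
    return transform(points)


def bending_energy(transform: TPSTransform) -> float:
    """w^T K w, proportional to the integrated squared curvature of f."""
    if not len(transform.source):
        return 0.0
    K = _kernel_matrix(transform.source, transform.source)
    return float(np.sum(transform.weights * (K @ transform.weights)))


# ---------------------------------------------------------------------------
# Robust point matching
# ---------------------------------------------------------------------------


@dataclass
class RPMConfig:
    """Deterministic-annealing schedule for TPS-RPM.

    stiffness : the user's (final) dimensionless lambda.
    t_init : start temperature, mm^2; default (half the target point set's
        bounding-box diagonal)^2, set at run time when None.
    t_final : final temperature, mm^2; default one pixel squared.
    anneal_rate : geometric temperature factor per outer iteration.
    outlier_weight : constant weight of the outlier row/column.
    inner_iterations : correspondence/TPS alternations per temperature.
    lambda_anneal : extra stiffness annealed down proportionally to T.
    """

    stiffness: float = 0.1
    t_init: float | None = None
    t_final: float = 0.43**2
    anneal_rate: float = 0.93
    outlier_weight: float = 0.01
    inner_iterations: int = 3
    sinkhorn_iterations: int = 5
    lambda_anneal: float = 5.0

    def __post_init__(self):
        if not (0 < self.anneal_rate < 1):
            raise ConfigError("anneal_rate must be in (0, 1)")
        if self.t_final <= 0 or (self.t_init is not None and self.t_init <= self.t_final):
            raise ConfigError("need t_init > t_final > 0")
        if self.stiffness < 0:
            raise ConfigError("stiffness must be >= 0")


@dataclass
class RegistrationResult:
    control_points: np.ndarray  # (K, 2) final images Y_i = f(X_i), mm
    transform: TPSTransform
    iterations: int
    converged: bool
    correspondence_entropy: float

    def to_json(self) -> dict:
        return {
            "control_points": self.control_points.tolist(),
            "transform": self.transform.to_json(),
            "iterations": self.iterations,
            "converged": self.converged,
            "correspondence_entropy": self.correspondence_entropy,
        }


def _sinkhorn(M: np.ndarray, iterations: int) -> np.ndarray:
    """Alternating row/column normalization of the outlier-augmented matrix.

    The last row and column are the outlier bins; they take part in the
    normalization but are never renormalized themselves (standard softassign).
    """
    M = M.copy()
    for _ in range(iterations):
        M[:-1] /= M[:-1].sum(axis=1, keepdims=True) + 1e-300
        M[:, :-1] /= M[:, :-1].sum(axis=0, keepdims=True) + 1e-300
    return M


def _fit_weighted_tps(
    ref: np.ndarray,
    targets: np.ndarray,
    weights: np.ndarray,
    control: np.ndarray,
    lam: float,
) -> TPSTransform:
    """Weighted least-squares TPS with basis anchored at ``control``.

    Minimizes sum_a s_a ||y_a - f(r_a)||^2 + lam_hat w^T K_cc w subject to the
    usual boundedness constraints sum w = 0, sum w x^T = 0.
    """
    K = len(control)
    n = len(ref)
    # work in centered, scaled coordinates for conditioning; the TPS kernel
    # transforms exactly under a similarity (the log-scale term is constant
    # by the boundedness constraints), so the fit converts back losslessly
    mu = control.mean(axis=0)
    sc = float(np.sqrt(np.mean(np.sum((control - mu) ** 2, axis=1))))
    sc = sc if sc > 1e-9 else 1.0
    refn = (ref - mu) / sc
    ctrn = (control - mu) / sc
    tgtn = (targets - mu) / sc
    Phi = _kernel_matrix(refn, ctrn)
    P = np.column_stack([np.ones(n), refn])
    # eliminate the constraints P_c^T w = 0 through a null-space basis
    Pc = np.column_stack([np.ones(K), ctrn])
    _, _, vt = np.linalg.svd(Pc.T, full_matrices=True)
    N = vt[3:].T  # (K, K-3)
    D = np.column_stack([Phi @ N, P])  # unknowns: gamma (K-3), then a (3)
    Kcc = _kernel_matrix(ctrn, ctrn)
    lam_hat = lam * _lambda_scale(ctrn)
    B = np.zeros((K, K))
    B[: K - 3, : K - 3] = N.T @ Kcc @ N
    A = D.T @ (D * weights[:, None]) + lam_hat * B
    A += 1e-10 * max(1.0, np.trace(A) / K) * np.eye(K)
    rhs = D.T @ (tgtn * weights[:, None])

    def _solve(pen: float):
        A2, rhs2 = A, rhs
        if pen > 0:
            A2 = A.copy()
            rhs2 = rhs.copy()
            A2[K - 2 :, K - 2 :] += pen * np.eye(2)
            rhs2[K - 2 :, :] += pen * np.eye(2)
        try:
            return solve(A2, rhs2, assume_a="sym")
        except LinAlgError:
            return np.linalg.lstsq(A2, rhs2, rcond=None)[0]

    sol = _solve(0.0)
    # anatomical deformations are orientation-preserving: a reflected affine
    # (det <= 0) is a spurious optimum of near-mirror-symmetric sections;
    # pull the affine toward identity until orientation is restored
    pen = 0.1 * float(weights.sum())
    for _ in range(12):
        if np.linalg.det(sol[K - 2 :].T) > 0.05:
            break
        sol = _solve(pen)
        pen *= 3.0
    wn = N @ sol[: K - 3]
    offset_n = sol[K - 3]
    affine = sol[K - 2 :].T
    # convert back to mm: w = wn / sc; the kernel's log-scale term reduces to
    # a constant kappa = sum_i w_i ||x_i||^2 absorbed into the offset
    w = wn / sc
    kappa = (wn * np.sum((control - mu) ** 2, axis=1)[:, None]).sum(axis=0) / sc
    offset = mu + sc * (offset_n - affine @ (mu / sc)) - np.log(sc**2) * kappa
    return TPSTransform(control, w, affine, offset, lam)


def rpm_register(
    reference_points: np.ndarray,
    target_points: np.ndarray,
    control_points: np.ndarray | None = None,
    config: RPMConfig | None = None,
) -> RegistrationResult:
    """Deformable robust point matching of a reference skeleton onto a target.

    The deformation is parameterized by the (small) control point set; soft
    correspondences are estimated for the full reference point set and the
    TPS refit to the correspondence-weighted target estimates.  Deterministic:
    initialization aligns the two centroids, and no randomness is used.
    """
    config = config or RPMConfig()
    ref = np.asarray(reference_points, dtype=float).reshape(-1, 2)
    tgt = np.asarray(target_points, dtype=float).reshape(-1, 2)
    if not len(ref) or not len(tgt):
        raise PipelineError("empty point set in registration")
    control = ref if control_points is None else np.asarray(control_points, float).reshape(-1, 2)
    if len(control) < 3:
        raise ConfigError("need at least 3 control points")

    bbox = tgt.max(axis=0) - tgt.min(axis=0)
    t_init = config.t_init if config.t_init is not None else (0.5 * np.hypot(*bbox)) ** 2
    t_final = config.t_final
    if t_init <= t_final:
        t_init = 4.0 * t_final

    shift = tgt.mean(axis=0) - ref.mean(axis=0)
    transform = TPSTransform(control, np.zeros_like(control), np.eye(2), shift)
    T = t_init
    iterations = 0
    entropy = 0.0
    while T > t_final:
        lam_T = config.stiffness + config.lambda_anneal * (T / t_init)
        for _ in range(config.inner_iterations):
            fr = transform(ref)
            d2 = np.sum((fr[:, None, :] - tgt[None, :, :]) ** 2, axis=2)
            M = np.empty((len(ref) + 1, len(tgt) + 1))
            M[:-1, :-1] = np.exp(-d2 / (2.0 * T))
            M[-1, :] = config.outlier_weight
            M[:, -1] = config.outlier_weight
            M = _sinkhorn(M, config.sinkhorn_iterations)
            m = M[:-1, :-1]
            s = m.sum(axis=1)
            good = s > 1e-12
            if good.sum() < 3:
                break
            y_hat = np.zeros_like(ref)
            y_hat[good] = (m[good] @ tgt) / s[good, None]
            y_hat[~good] = fr[~good]
            transform = _fit_weighted_tps(ref, y_hat, s, control, lam_T)
            iterations += 1
        with np.errstate(divide="ignore", invalid="ignore"):
            p = m / (m.sum() + 1e-300)
            entropy = float(-np.sum(p[p > 0] * np.log(p[p > 0])))
        T *= config.anneal_rate
    converged = iterations > 0
    return RegistrationResult(transform(control), transform, iterations, converged, entropy)


def write_registration(path, result: RegistrationResult) -> None:
    with open(path, "w") as fh:
        json.dump(result.to_json(), fh, indent=1)
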