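"""Reference-tissue kinetic models for regional TACs.

Implements the simplified reference tissue model solved by basis functions
(SRTM), its two-parameter variant with fixed reference efflux (SRTM2), the
multilinear reference tissue models (MRTM, MRTM2), the Logan graphical
reference method, AIC model comparison, and the SUVR-1 ratio shortcut.

Conventions
-----------
* All rates are min^-1, times minutes; BPND and R1 are unitless.
* The reference TAC is resampled to a 1-s grid (linear interpolation from
  frame midpoints, anchored at (0, 0)) for the convolution integrals, and
  model predictions are frame-averaged before computing residuals. This
  mirrors how the measured TAC itself arises from a continuous curve and
  removes discretization asymmetry between simulation and fitting.
* Cumulative integrals for the multilinear/graphical models use exact
  frame-duration quadrature: because a TAC value is the average of the
  underlying curve over its frame, sum(value*dt) is the exact integral to
  a frame end; subtracting half a frame reaches the midpoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import linregress

from .synth import C11_HALFLIFE_MIN, expconv
from .tac import TAC, FrameSchedule

__all__ = [
    "KineticFit",
    "LoganFit",
    "SUVRResult",
    "SRTMBasis",
    "fit_srtm",
    "fit_srtm2",
    "fit_mrtm",
    "fit_mrtm2",
    "fit_logan_ref",
    "fit_model",
    "aic",
    "suvr_minus_1",
    "DEFAULT_K2A_GRID",
]

#: Default basis grid for the apparent efflux rate k2a (min^-1).
DEFAULT_K2A_GRID = np.geomspace(0.01, 1.0, 128)

_FINE_DT_S = 1.0


@dataclass(frozen=True)
class KineticFit:
    """Estimated reference-tissue parameters plus fit diagnostics.

    ``se_pct`` maps parameter name to 100*SE/|estimate| where a standard
    error is available. ``flags`` carries non-fatal warnings such as a
    basis-grid boundary hit or a degenerate (target==reference) fit.
    """

    model: str
    r1: float
    k2: float
    k2a: float
    bpnd: float
    k2_prime: float
    rss: float
    n_frames_used: int
    n_params: int
    aic: float
    se_pct: dict = field(default_factory=dict)
    flags: tuple = ()


@dataclass(frozen=True)
class LoganFit:
    """Graphical reference-region fit: DVR slope of the late linear phase."""

    dvr: float
    intercept: float
    bpnd: float
    t_star: float
    n_points_used: int
    r2: float
    flags: tuple = ()


@dataclass(frozen=True)
class SUVRResult:
    window: tuple
    suvr_minus_1: float


# ---------------------------------------------------------------------------
# shared plumbing


def _weights(schedule: FrameSchedule, scheme: str) -> np.ndarray:
    if scheme == "uniform":
        return np.ones(schedule.n_frames)
    if scheme == "duration-decay":
        lam = math.log(2.0) / C11_HALFLIFE_MIN
        return schedule.durations_min * np.exp(-lam * schedule.mid_min)
    raise ValueError(f"unknown weighting scheme {scheme!r}")


class _FrameAverager:
    """Frame-averages a fine-grid curve; frame edges must lie on the grid."""

    def __init__(self, schedule: FrameSchedule, dt_s: float = _FINE_DT_S):
        self.dt_min = dt_s / 60.0
        idx_s = schedule.start_s / dt_s
        idx_e = schedule.end_s / dt_s
        if not (np.allclose(idx_s, np.round(idx_s)) and np.allclose(idx_e, np.round(idx_e))):
            raise ValueError("frame boundaries must align with the fine grid")
        self.i_start = np.round(idx_s).astype(int)
        self.i_end = np.round(idx_e).astype(int)
        self.dur_min = schedule.durations_min

    def __call__(self, curve: np.ndarray) -> np.ndarray:
        cum = np.concatenate(
            [[0.0], np.cumsum((curve[1:] + curve[:-1]) * 0.5 * self.dt_min)]
        )
        return (cum[self.i_end] - cum[self.i_start]) / self.dur_min


class SRTMBasis:
    """Reference-curve basis for SRTM-type fitting, reusable across targets.

    Resamples the reference TAC onto the fine grid and caches, for each
    candidate k2a, the frame-averaged convolution (C_R * exp(-k2a t)).
    Building this once and sharing it across thousands of voxel fits is
    what makes parametric mapping tractable.
    """

    def __init__(self, ref: TAC, k2a_grid: np.ndarray | None = None,
                 dt_s: float = _FINE_DT_S):
        if np.allclose(ref.values, 0.0):
            raise ValueError("reference TAC is identically zero")
        self.schedule = ref.schedule
        self.ref_frames = ref.values
        self.k2a_grid = np.asarray(
            DEFAULT_K2A_GRID if k2a_grid is None else k2a_grid, dtype=float
        )
        n_fine = int(round(ref.schedule.duration_s / dt_s))
        self.t_fine = np.arange(n_fine + 1) * (dt_s / 60.0)
        self.ref_fine = np.interp(
            self.t_fine,
            np.concatenate([[0.0], ref.schedule.mid_min]),
            np.concatenate([[0.0], ref.values]),
        )
        self._avg = _FrameAverager(ref.schedule, dt_s)
        self._dt_min = dt_s / 60.0
        self._cache: dict[float, np.ndarray] = {}
        self.B = np.column_stack([self.conv_frames(k) for k in self.k2a_grid])

    def conv_frames(self, k2a: float) -> np.ndarray:
        """Frame-averaged (C_R * exp(-k2a t)) for one candidate rate."""
        key = float(k2a)
        hit = self._cache.get(key)
        if hit is None:
            hit = self._avg(expconv(self.ref_fine, key, self._dt_min))
            self._cache[key] = hit
    # unbounded cache is fine: one basis object serves one reference curve
        return hit


def _wls2(r, b, y, w):
    """Weighted LS for y ~ th1*r + th2*b; returns (th1, th2, rss)."""
    a11 = np.dot(w * r, r)
    a12 = np.dot(w * r, b)
    a22 = np.dot(w * b, b)
    c1 = np.dot(w * r, y)
    c2 = np.dot(w * b, y)
    det = a11 * a22 - a12 * a12
    if det <= 0 or not np.isfinite(det):
        return np.nan, np.nan, np.inf
    th1 = (a22 * c1 - a12 * c2) / det
    th2 = (a11 * c2 - a12 * c1) / det
    resid = y - th1 * r - th2 * b
    return th1, th2, float(np.dot(w * resid, resid))


def aic(rss: float, n: int, k: int) -> float:
    """Gaussian-residual Akaike information criterion, n*ln(RSS/n) + 2k.

    Returns -inf when RSS is exactly zero (a perfect fit dominates any
    comparison); no small-sample correction, matching common kinetic
    modelling practice where only differences between models matter.
    """
    if n <= k:
        raise ValueError(f"need n > k, got n={n}, k={k}")
    if rss < 0:
        raise ValueError("negative RSS")
    if rss == 0:
        return -math.inf
    return n * math.log(rss / n) + 2 * k


def _se_pct(cov: np.ndarray, grads: dict, values: dict) -> dict:
    out = {}
    for name, g in grads.items():
        g = np.asarray(g, dtype=float)
        var = float(g @ cov @ g)
        v = values[name]
        if var >= 0 and np.isfinite(var) and v != 0:
            out[name] = 100.0 * math.sqrt(var) / abs(v)
    return out


# ---------------------------------------------------------------------------
# SRTM / SRTM2 (basis functions)


def _check_pair(target: TAC, ref: TAC) -> None:
    if target.schedule != ref.schedule:
        raise ValueError("target and reference must share a frame schedule")


def fit_srtm(target: TAC, ref: TAC, basis: SRTMBasis | None = None,
             k2a_grid: np.ndarray | None = None,
             weights: str = "uniform") -> KineticFit:
    """Three-parameter SRTM fit by basis functions with local refinement.

    For each candidate apparent efflux rate k2a on a log-spaced grid the
    model C_T = th1*C_R + th2*(C_R * exp(-k2a t)) is linear; the best grid
    point is polished by bounded scalar minimization between its
    neighbours. Reported parameters: R1 = th1, k2 = th2 + th1*k2a,
    BPND = k2/k2a - 1 (and k2' = k2/R1, exact only for one-tissue-like
    reference kinetics).
    """
    _check_pair(target, ref)
    if basis is None:
        basis = SRTMBasis(ref, k2a_grid)
    y = target.values
    r = basis.ref_frames
    w = _weights(target.schedule, weights)
    grid = basis.k2a_grid

    rss_grid = np.array([_wls2(r, basis.B[:, j], y, w)[2] for j in range(grid.size)])
    j = int(np.argmin(rss_grid))
    flags = []
    if j in (0, grid.size - 1):
        flags.append("k2a-grid-boundary")
        k2a_hat = grid[j]
    else:
        lo, hi = math.log(grid[j - 1]), math.log(grid[j + 1])

        def obj(logk):
            return _wls2(r, basis.conv_frames(math.exp(logk)), y, w)[2]

        res = minimize_scalar(obj, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-6})
        k2a_hat = math.exp(res.x)

    b = basis.conv_frames(k2a_hat)
    th1, th2, rss = _wls2(r, b, y, w)
    r1 = th1
    k2 = th2 + th1 * k2a_hat
    bpnd = k2 / k2a_hat - 1.0
    n = y.size

    se = {}
    if n > 3 and np.isfinite(rss):
        db = (basis.conv_frames(k2a_hat * 1.001) - basis.conv_frames(k2a_hat * 0.999)) / (
            0.002 * k2a_hat
        )
        J = np.column_stack([r, b, th2 * db]) * np.sqrt(w)[:, None]
        try:
            cov = np.linalg.inv(J.T @ J) * (rss / (n - 3))
            se = _se_pct(
                cov,
                {
                    "r1": [1.0, 0.0, 0.0],
                    "k2": [k2a_hat, 1.0, th2],
                    "bpnd": [1.0, 1.0 / k2a_hat, -th2 / k2a_hat**2],
                    "k2_prime": [-th2 / th1**2, 1.0 / th1, 1.0],
                },
                {"r1": r1, "k2": k2, "bpnd": bpnd, "k2_prime": k2 / r1},
            )
        except np.linalg.LinAlgError:
            flags.append("singular-covariance")

    return KineticFit(
        model="srtm", r1=r1, k2=k2, k2a=k2a_hat, bpnd=bpnd,
        k2_prime=k2 / r1 if r1 != 0 else math.nan,
        rss=rss, n_frames_used=n, n_params=3, aic=aic(rss, n, 3),
        se_pct=se, flags=tuple(flags),
    )


def fit_srtm2(target: TAC, ref: TAC, k2_prime: float,
              basis: SRTMBasis | None = None,
              k2a_grid: np.ndarray | None = None,
              weights: str = "uniform") -> KineticFit:
    """Two-parameter SRTM with the reference efflux k2' fixed.

    C_T = R1*C_R + R1*(k2' - k2a)*(C_R * exp(-k2a t)); for each k2a the
    single coefficient R1 is solved in closed form. BPND = R1*k2'/k2a - 1.
    """
    if k2_prime <= 0:
        raise ValueError("k2_prime must be positive")
    _check_pair(target, ref)
    if basis is None:
        basis = SRTMBasis(ref, k2a_grid)
    y = target.values
    r = basis.ref_frames
    w = _weights(target.schedule, weights)
    grid = basis.k2a_grid

    def solve(k2a, b):
        z = r + (k2_prime - k2a) * b
        denom = np.dot(w * z, z)
        if denom <= 0:
            return np.nan, np.inf, z
        th1 = np.dot(w * z, y) / denom
        resid = y - th1 * z
        return th1, float(np.dot(w * resid, resid)), z

    rss_grid = np.array(
        [solve(grid[j], basis.B[:, j])[1] for j in range(grid.size)]
    )
    j = int(np.argmin(rss_grid))
    flags = []
    if j in (0, grid.size - 1):
        flags.append("k2a-grid-boundary")
        k2a_hat = grid[j]
    else:
        lo, hi = math.log(grid[j - 1]), math.log(grid[j + 1])
        res = minimize_scalar(
            lambda lk: solve(math.exp(lk), basis.conv_frames(math.exp(lk)))[1],
            bounds=(lo, hi), method="bounded", options={"xatol": 1e-6},
        )
        k2a_hat = math.exp(res.x)

    b = basis.conv_frames(k2a_hat)
    r1, rss, z = solve(k2a_hat, b)
    bpnd = r1 * k2_prime / k2a_hat - 1.0
    k2 = r1 * k2_prime
    n = y.size

    se = {}
    if n > 2 and np.isfinite(rss) and np.isfinite(r1):
        db = (basis.conv_frames(k2a_hat * 1.001) - basis.conv_frames(k2a_hat * 0.999)) / (
            0.002 * k2a_hat
        )
        dz = -b + (k2_prime - k2a_hat) * db
        J = np.column_stack([z, r1 * dz]) * np.sqrt(w)[:, None]
        try:
            cov = np.linalg.inv(J.T @ J) * (rss / (n - 2))
            se = _se_pct(
                cov,
                {
                    "r1": [1.0, 0.0],
                    "bpnd": [k2_prime / k2a_hat, -r1 * k2_prime / k2a_hat**2],
                },
                {"r1": r1, "bpnd": bpnd},
            )
        except np.linalg.LinAlgError:
            flags.append("singular-covariance")

    return KineticFit(
        model="srtm2", r1=r1, k2=k2, k2a=k2a_hat, bpnd=bpnd, k2_prime=k2_prime,
        rss=rss, n_frames_used=n, n_params=2, aic=aic(rss, n, 2),
        se_pct=se, flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# MRTM / MRTM2 / Logan


def _cumint_mid(values: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    """Integral of the underlying curve from 0 to each frame midpoint.

    Exact when values are frame averages: the integral to a frame end is
    the cumulative sum of value*duration, minus half a frame to step back
    to the midpoint.
    """
    d = schedule.durations_min
    return np.cumsum(values * d) - 0.5 * values * d


def _mrtm_error_covariance(X, g, resid, target: TAC, ref: TAC, use) -> np.ndarray:
    """Coefficient covariance for the multilinear fit, noise-propagation aware.

    Plain OLS covariance underestimates the multilinear model's parameter
    variability because frame noise enters the regressors too: the
    cumulative integrals carry the accumulated noise of both TACs, and the
    reference curve appears directly. Here each frame's noise is propagated
    through the quadrature matrix into every term of the operational
    equation, with the frame variance profile taken from count statistics
    (value * e^{lambda t} / dt) and its overall scale estimated from the
    residual sum of squares after removing the regression projection.
    """
    sched = target.schedule
    d = sched.durations_min
    n_all = sched.n_frames
    lam = math.log(2.0) / C11_HALFLIFE_MIN
    g1, g2, g3 = g
    # quadrature: integral at midpoint m = sum_{j<m} d_j v_j + (d_m/2) v_m
    W = np.tril(np.ones((n_all, n_all))) * d[None, :]
    np.fill_diagonal(W, d / 2.0)
    W = W[use, :]
    E = np.eye(n_all)[use, :]
    decay = np.exp(lam * sched.mid_min) / d
    v_t = np.maximum(target.values, 1e-6) * decay
    v_r = np.maximum(ref.values, 1e-6) * decay
    A_t = E - g2 * W          # noise of the target TAC: response + its integral
    A_r = -g1 * W - g3 * E    # noise of the reference TAC: integral + direct term
    S = (A_t * v_t[None, :]) @ A_t.T + (A_r * v_r[None, :]) @ A_r.T
    XtXi = np.linalg.inv(X.T @ X)
    H = X @ XtXi @ X.T
    denom = np.trace((np.eye(S.shape[0]) - H) @ S)
    scale = float(resid @ resid) / denom if denom > 0 else 0.0
    return XtXi @ (X.T @ (scale * S) @ X) @ XtXi


def fit_mrtm(target: TAC, ref: TAC, t_star: float = 0.0,
             _degenerate_ok: bool = True) -> KineticFit:
    """Three-coefficient multilinear reference-tissue fit (OLS).

    Regresses C_T(T) on [int_0^T C_R, int_0^T C_T, C_R(T)] over frames
    with midpoint >= t_star. BPND = -(g1/g2 + 1), k2' = g1/g3, R1 = g3,
    k2 = -g2; the k2' standard error comes from the coefficient covariance
    by the delta method.
    """
    _check_pair(target, ref)
    if np.allclose(target.values, 0.0):
        raise ValueError("target TAC is identically zero")
    sched = target.schedule
    mids = sched.mid_min
    use = mids >= t_star
    if use.sum() < 4:
        raise ValueError(f"need >= 4 frames past t*={t_star} min, got {use.sum()}")
    I_R = _cumint_mid(ref.values, sched)
    I_T = _cumint_mid(target.values, sched)
    X = np.column_stack([I_R[use], I_T[use], ref.values[use]])
    y = target.values[use]

    sv = np.linalg.svd(X, compute_uv=False)
    if sv[-1] < 1e-10 * sv[0]:
        if _degenerate_ok and np.allclose(target.values, ref.values):
            # target == reference: DVR = 1 by construction, coefficients
            # unidentifiable; report the degenerate solution, flagged.
            return KineticFit(
                model="mrtm", r1=1.0, k2=math.nan, k2a=math.nan, bpnd=0.0,
                k2_prime=math.nan, rss=0.0, n_frames_used=int(use.sum()),
                n_params=3, aic=-math.inf, flags=("degenerate-identical-tacs",),
            )
        raise ValueError("singular design matrix: regressors are collinear")

    g, res, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ g
    rss = float(resid @ resid)
    n = int(use.sum())
    g1, g2, g3 = g
    bpnd = -(g1 / g2 + 1.0)
    k2p = g1 / g3
    # -g2 = -1/b is the apparent efflux rate (b is the graphical-plot
    # intercept); the target efflux follows as k2 = k2a*(1+BPND).
    k2a_hat = -g2
    k2 = k2a_hat * (1.0 + bpnd)
    r1 = g3

    se = {}
    flags = []
    if n > 3:
        try:
            cov = _mrtm_error_covariance(X, g, resid, target, ref, use)
            se = _se_pct(
                cov,
                {
                    "k2_prime": [1.0 / g3, 0.0, -g1 / g3**2],
                    "bpnd": [-1.0 / g2, g1 / g2**2, 0.0],
                    "r1": [0.0, 0.0, 1.0],
                    "k2a": [0.0, -1.0, 0.0],
                },
                {"k2_prime": k2p, "bpnd": bpnd, "r1": r1, "k2a": k2a_hat},
            )
        except np.linalg.LinAlgError:
            flags.append("singular-covariance")

    return KineticFit(
        model="mrtm", r1=r1, k2=k2, k2a=k2a_hat, bpnd=bpnd,
        k2_prime=k2p, rss=rss, n_frames_used=n, n_params=3,
        aic=aic(rss, n, 3), se_pct=se, flags=tuple(flags),
    )


def fit_mrtm2(target: TAC, ref: TAC, k2_prime: float,
              t_star: float = 0.0) -> KineticFit:
    """Two-coefficient multilinear fit with the reference efflux k2' fixed.

    C_T(T) = g1*(int_0^T C_R + C_R(T)/k2') + g2*int_0^T C_T;
    BPND = -(g1/g2 + 1), R1 = g1/k2'.
    """
    if k2_prime <= 0:
        raise ValueError("k2_prime must be positive")
    _check_pair(target, ref)
    if np.allclose(target.values, 0.0):
        raise ValueError("target TAC is identically zero")
    sched = target.schedule
    use = sched.mid_min >= t_star
    if use.sum() < 3:
        raise ValueError(f"need >= 3 frames past t*={t_star} min")
    I_R = _cumint_mid(ref.values, sched)
    I_T = _cumint_mid(target.values, sched)
    X = np.column_stack(
        [I_R[use] + ref.values[use] / k2_prime, I_T[use]]
    )
    y = target.values[use]
    sv = np.linalg.svd(X, compute_uv=False)
    if sv[-1] < 1e-10 * sv[0]:
        raise ValueError("singular design matrix: regressors are collinear")
    g, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ g
    rss = float(resid @ resid)
    n = int(use.sum())
    g1, g2 = g
    bpnd = -(g1 / g2 + 1.0)
    r1 = g1 / k2_prime
    k2a_hat = -g2  # as in the three-coefficient fit, -g2 is 1/|intercept| = k2a
    k2 = k2a_hat * (1.0 + bpnd)
    se = {}
    if n > 2:
        cov = np.linalg.inv(X.T @ X) * (rss / (n - 2))
        se = _se_pct(
            cov,
            {"bpnd": [-1.0 / g2, g1 / g2**2], "r1": [1.0 / k2_prime, 0.0]},
            {"bpnd": bpnd, "r1": r1},
        )
    return KineticFit(
        model="mrtm2", r1=r1, k2=k2, k2a=k2a_hat, bpnd=bpnd,
        k2_prime=k2_prime, rss=rss, n_frames_used=n, n_params=2,
        aic=aic(rss, n, 2), se_pct=se,
    )


def fit_logan_ref(target: TAC, ref: TAC, k2_prime: float,
                  t_star: float = 15.0) -> LoganFit:
    """Logan graphical analysis with a reference region.

    OLS of y(T) = int_0^T C_T / C_T(T) on x(T) = (int_0^T C_R +
    C_R(T)/k2') / C_T(T) over frames with midpoint >= t_star (default
    15 min). DVR is the slope; BPND = DVR - 1. Frames with non-positive
    C_T(T) are dropped with a flag.
    """
    if k2_prime <= 0:
        raise ValueError("k2_prime must be positive")
    _check_pair(target, ref)
    sched = target.schedule
    use = sched.mid_min >= t_star
    flags = []
    ct = target.values
    bad = use & (ct <= 0)
    if bad.any():
        flags.append(f"dropped-{int(bad.sum())}-nonpositive-frames")
        use = use & (ct > 0)
    if use.sum() < 3:
        raise ValueError(
            f"need >= 3 usable frames past t*={t_star} min, got {use.sum()}"
        )
    I_R = _cumint_mid(ref.values, sched)
    I_T = _cumint_mid(ct, sched)
    x = (I_R[use] + ref.values[use] / k2_prime) / ct[use]
    y = I_T[use] / ct[use]
    if np.ptp(x) == 0:
        raise ValueError("degenerate Logan plot: no spread in x")
    reg = linregress(x, y)
    dvr = float(reg.slope)
    return LoganFit(
        dvr=dvr, intercept=float(reg.intercept), bpnd=dvr - 1.0,
        t_star=t_star, n_points_used=int(use.sum()),
        r2=float(reg.rvalue**2), flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# dispatch + SUVR


def fit_model(name: str, target: TAC, ref: TAC, *, k2_prime: float | None = None,
              t_star: float | None = None, basis: SRTMBasis | None = None,
              weights: str = "uniform"):
    """Fit one named model; 'logan'/'srtm2'/'mrtm2' take k2' from ``k2_prime``
    or, when it is None, from a preliminary MRTM fit of the same pair."""
    name = name.lower()
    if name in ("srtm2", "mrtm2", "logan") and k2_prime is None:
        k2_prime = fit_mrtm(target, ref).k2_prime
    if name == "srtm":
        return fit_srtm(target, ref, basis=basis, weights=weights)
    if name == "srtm2":
        return fit_srtm2(target, ref, k2_prime, basis=basis, weights=weights)
    if name == "mrtm":
        return fit_mrtm(target, ref, t_star=0.0 if t_star is None else t_star)
    if name == "mrtm2":
        return fit_mrtm2(target, ref, k2_prime,
                         t_star=0.0 if t_star is None else t_star)
    if name == "logan":
        return fit_logan_ref(target, ref, k2_prime,
                             t_star=15.0 if t_star is None else t_star)
    raise ValueError(f"unknown model {name!r}")


def suvr_minus_1(target: TAC, ref: TAC, window: tuple) -> SUVRResult:
    """Target/reference uptake ratio minus one over a late time window.

    Uses the duration-weighted mean over frames lying fully inside
    [t0, t1] minutes; a cheap surrogate for BPND when the ratio has
    reached pseudo-equilibrium.
    """
    _check_pair(target, ref)
    t0, t1 = window
    sched = target.schedule
    if t0 < 0 or t1 * 60.0 > sched.duration_s + 1e-9:
        raise ValueError(f"window {window} outside scan duration")
    inside = (sched.start_s >= t0 * 60.0 - 1e-9) & (sched.end_s <= t1 * 60.0 + 1e-9)
    if not inside.any():
        raise ValueError(f"no frames fully inside window {window}")
    d = sched.durations_min[inside]
    num = float(np.sum(target.values[inside] * d) / d.sum())
    den = float(np.sum(ref.values[inside] * d) / d.sum())
    if den <= 0:
        raise ValueError("reference mean over window is non-positive")
    return SUVRResult(window=(t0, t1), suvr_minus_1=num / den - 1.0)
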