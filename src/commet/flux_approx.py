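"""First- and second-moment approximation of the uniform flux distribution.

The steady-state flux polytope ``P = {v : S v = 0, lb <= v <= ub}`` carries
the uniform density; its per-reaction means/variances and the full
reaction-by-reaction covariance are the raw material for the downstream
PCA decomposition. Two routes are provided:

* :func:`ep_moments` — Expectation Propagation: a multivariate Gaussian is
  fitted to the uniform density by iterative moment matching. The mass
  balance ``S v = 0`` enters as a soft Gaussian likelihood with precision
  ``beta`` (default 1e8, effectively exact) and each box constraint is
  approximated by a univariate Gaussian site whose parameters are updated
  so the Gaussian marginal matches the moments of the truncated-Gaussian
  tilted marginal. Deterministic, O(sweeps * n^3).
* :func:`sample_moments` — uniform hit-and-run sampling in null-space
  coordinates of ``S``; the empirical moments serve as an independent
  Monte-Carlo oracle for EP.

Fluxes are affinely rescaled to the unit box per reaction before EP and
back-transformed afterwards, which keeps the site updates well conditioned
regardless of the spread of the FVA ranges.

Fully coupled reactions — reactions whose null-space directions are
collinear, so their fluxes are affine images of one another everywhere in
the polytope (enzyme subsets being the canonical case) — are detected and
their box constraints merged into a single site on one representative
before EP. Placing several sites on the same one-dimensional projection
is exactly the duplicate-factor situation in which EP is known to
underestimate variances; merging the boxes (their intersection on the
representative) leaves the target density unchanged while removing the
bias.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.optimize import linprog
from scipy.stats import truncnorm

from .preprocess import ReducedFluxSpace

__all__ = ["EpConfig", "FluxMoments", "ep_moments", "sample_moments"]

_FIXED_WIDTH = 1e-12  # below this a reaction is treated as fixed-flux


@dataclass(frozen=True)
class EpConfig:
    """Expectation-propagation settings.

    max_iterations: sweep budget; precision: convergence threshold on the
    largest change in any site parameter; beta: precision of the soft
    mass-balance likelihood; damping: weight kept on the old site natural
    parameters each update; variance_floor: smallest reported variance.
    """

    max_iterations: int = 1000
    precision: float = 1e-5
    beta: float = 1e8
    damping: float = 0.9
    variance_floor: float = 1e-10

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.precision <= 0 or self.beta <= 0:
            raise ValueError("precision and beta must be positive")
        if not 0 <= self.damping < 1:
            raise ValueError("damping must lie in [0, 1)")


@dataclass
class FluxMoments:
    reaction_ids: list[str]
    mean: np.ndarray
    variance: np.ndarray
    covariance: np.ndarray
    method: str  # "ep" | "sampling"
    convergence: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "reaction_id": self.reaction_ids,
                "mean": self.mean,
                "variance": self.variance,
                "sd": np.sqrt(np.maximum(self.variance, 0.0)),
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _psd_repair(C: np.ndarray) -> np.ndarray:
    """Symmetrise and clip negative eigenvalues at zero."""
    C = 0.5 * (C + C.T)
    w, V = np.linalg.eigh(C)
    if w[0] >= 0:
        return C
    w = np.clip(w, 0.0, None)
    C = (V * w) @ V.T
    return 0.5 * (C + C.T)


# ---------------------------------------------------------------------------
# Expectation propagation
# ---------------------------------------------------------------------------

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(24)


def _truncnorm_mv(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean and variance of a standard normal truncated to [a, b].

    scipy's closed-form truncated moments lose all precision when the
    standardized interval is narrow (the variance is a difference of O(1)
    terms of size (b - a)^2): that regime arises whenever an EP cavity is
    nearly flat over the box. Narrow intervals are therefore integrated by
    Gauss-Legendre quadrature in a centred coordinate, which is free of
    cancellation; wide intervals use scipy's formulas.
    """
    a = np.atleast_1d(np.asarray(a, float))
    b = np.atleast_1d(np.asarray(b, float))
    mean = np.empty_like(a)
    var = np.empty_like(a)
    narrow = (b - a) < 1e-3
    if np.any(~narrow):
        m, v = truncnorm.stats(a[~narrow], b[~narrow], moments="mv")
        mean[~narrow] = np.asarray(m, float)
        var[~narrow] = np.asarray(v, float)
    if np.any(narrow):
        an, bn = a[narrow], b[narrow]
        mid = 0.5 * (an + bn)
        half = 0.5 * (bn - an)
        # nodes u in [-half, half] around mid; density ratio exp(-mid*u - u^2/2)
        u = half[:, None] * _GL_NODES[None, :]
        logw = -(mid[:, None] * u + 0.5 * u**2)
        logw -= logw.max(axis=1, keepdims=True)
        wgt = np.exp(logw) * _GL_WEIGHTS[None, :]
        z = wgt.sum(axis=1)
        m_u = (wgt * u).sum(axis=1) / z
        v_u = (wgt * u**2).sum(axis=1) / z - m_u**2
        mean[narrow] = mid + m_u
        var[narrow] = np.clip(v_u, 0.0, None)
    return mean, var


def _collinear_groups(N: np.ndarray, tol: float = 1e-9):
    """Group row indices of the null-space basis by collinear directions.

    Returns (groups, zero_rows): ``groups`` is a list of index lists, each
    sharing a common direction up to sign; ``zero_rows`` are rows with
    (numerically) zero norm, i.e. reactions fixed everywhere on the
    polytope's affine hull.
    """
    norms = np.linalg.norm(N, axis=1)
    scale = max(norms.max(initial=0.0), 1.0)
    zero_rows = [int(i) for i in np.flatnonzero(norms <= tol * scale)]
    live = np.flatnonzero(norms > tol * scale)
    groups: list[list[int]] = []
    reps: list[np.ndarray] = []
    for i in live:
        u = N[i] / norms[i]
        placed = False
        for g, ug in enumerate(reps):
            if abs(float(u @ ug)) >= 1.0 - tol:
                groups[g].append(int(i))
                placed = True
                break
        if not placed:
            groups.append([int(i)])
            reps.append(u)
    return groups, zero_rows


def ep_moments(space: ReducedFluxSpace, cfg: EpConfig | None = None) -> FluxMoments:
    """Gaussian EP approximation of the uniform density on the polytope.

    Returns per-reaction truncated-Gaussian (tilted) means/variances and a
    covariance matrix whose correlation structure comes from the global
    Gaussian and whose diagonal equals the reported variances. Raises on an
    infeasible space; non-convergence is recorded in ``convergence`` and
    surfaced as a warning, never silently.
    """
    cfg = cfg or EpConfig()
    S, lb, ub = space.S, np.asarray(space.lb, float), np.asarray(space.ub, float)
    n = S.shape[1]
    width = ub - lb
    if np.any(width < 0):
        raise ValueError("lb > ub")
    free = width > _FIXED_WIDTH
    fixed_vals = lb[~free]

    mean = lb.astype(float).copy()
    var = np.zeros(n)
    cov = np.zeros((n, n))

    if not free.any():
        if n and np.max(np.abs(S @ mean)) > 1e-6:
            raise ValueError("flux polytope is infeasible (fixed fluxes violate S v = 0)")
        var[:] = np.minimum(var, cfg.variance_floor)
        return FluxMoments(
            list(space.reaction_ids), mean, var, cov, "ep",
            {"iterations": 0, "final_change": 0.0, "converged": True},
        )

    ix_free = np.flatnonzero(free)
    Sf = S[:, free]
    b = -(S[:, ~free] @ fixed_vals) if (~free).any() else np.zeros(S.shape[0])
    lo_f, hi_f = lb[free], ub[free]
    m = Sf.shape[1]

    # geometry of the affine hull {Sf v = b}: particular solution + null space
    vp, residual, *_ = np.linalg.lstsq(Sf, b, rcond=None)
    if np.linalg.norm(Sf @ vp - b) > 1e-6 * max(1.0, np.linalg.norm(b)):
        raise ValueError("flux polytope is infeasible (mass balance unsatisfiable)")
    N = linalg.null_space(Sf)
    groups, zero_rows = _collinear_groups(N)

    # reactions fixed by the geometry (zero null-space direction)
    geo_fixed = np.zeros(m, bool)
    for i in zero_rows:
        geo_fixed[i] = True

    # Merge collinear box constraints onto one representative per group:
    # for members i of a group with directions n_i = c_i * n_rep,
    # v_i = vp_i + (c_i / c_rep) * (v_rep - vp_rep) everywhere.
    rep_of = np.full(m, -1, int)
    coef = np.zeros(m)       # c_i / c_rep per member
    box_lo = lo_f.copy()
    box_hi = hi_f.copy()
    sited = np.zeros(m, bool)
    for members in groups:
        norms = np.linalg.norm(N[members], axis=1)
        rep = members[int(np.argmax(norms))]
        u_rep = N[rep] / np.linalg.norm(N[rep])
        lo_r, hi_r = -np.inf, np.inf
        for i in members:
            c = float(N[i] @ u_rep) / float(N[rep] @ u_rep)
            rep_of[i], coef[i] = rep, c
            # member box -> interval for v_rep
            a1 = vp[rep] + (lo_f[i] - vp[i]) / c
            a2 = vp[rep] + (hi_f[i] - vp[i]) / c
            lo_r = max(lo_r, min(a1, a2))
            hi_r = min(hi_r, max(a1, a2))
        if hi_r < lo_r - 1e-9 * max(1.0, abs(lo_r)):
            raise ValueError("flux polytope is infeasible (coupled boxes are disjoint)")
        if hi_r - lo_r <= _FIXED_WIDTH:  # coupling pins the whole group
            mid = 0.5 * (lo_r + hi_r)
            for i in members:
                geo_fixed[i] = True
                vp[i] = vp[i] + coef[i] * (mid - vp[rep])
            continue
        box_lo[rep], box_hi[rep] = lo_r, hi_r
        sited[rep] = True

    # rescale every free variable to unit width for conditioning
    w = np.where(sited, box_hi - box_lo, np.maximum(hi_f - lo_f, 1.0))
    off = np.where(sited, box_lo, lo_f)
    A = Sf * w
    b_eff = b - Sf @ off
    # equilibrate the equality system: row scaling leaves {A x = b}
    # unchanged but keeps beta's effective precision independent of the
    # flux scale (wide boxes would otherwise inflate A and push the
    # normal matrix past float64 conditioning)
    row_norms = np.linalg.norm(A, axis=1)
    keep_rows = row_norms > 1e-300
    A = A[keep_rows] / row_norms[keep_rows, None]
    b_eff = b_eff[keep_rows] / row_norms[keep_rows]

    mt_x, vt_x, Sigma_x, conv = _ep_core(A, b_eff, sited, cfg)

    # representative moments in flux units
    mean_f = np.empty(m)
    var_f = np.empty(m)
    rep_mean = off + w * mt_x
    rep_var = w**2 * vt_x
    for i in range(m):
        if geo_fixed[i]:
            mean_f[i], var_f[i] = vp[i], cfg.variance_floor
        else:
            r = rep_of[i]
            mean_f[i] = vp[i] + coef[i] * (rep_mean[r] - vp[r])
            var_f[i] = max(coef[i] ** 2 * rep_var[r], cfg.variance_floor)

    # correlation structure from the global Gaussian, diagonal pinned to
    # the reported variances (a pure rescaling, PSD-preserving)
    Cx = (w[:, None] * Sigma_x) * w[None, :]
    d = np.sqrt(var_f / np.maximum(np.diag(Cx), 1e-300))
    Cx = (d[:, None] * Cx) * d[None, :]
    cov[np.ix_(ix_free, ix_free)] = _psd_repair(Cx)
    mean[free] = mean_f
    var[free] = var_f
    var[~free] = np.minimum(var[~free], cfg.variance_floor)

    if not conv["converged"]:
        warnings.warn(
            f"EP did not converge in {cfg.max_iterations} sweeps "
            f"(final change {conv['final_change']:.3g})",
            RuntimeWarning,
            stacklevel=2,
        )
    return FluxMoments(list(space.reaction_ids), mean, var, cov, "ep", conv)


def _ep_core(A: np.ndarray, b: np.ndarray, sited: np.ndarray, cfg: EpConfig):
    """EP on {A x = b (soft, precision beta)} with unit-box sites.

    Sited variables carry a Gaussian site exp(-(x_j - a_j)^2 / (2 d_j))
    approximating the box indicator 1[0 <= x_j <= 1]; unsited variables are
    constrained only through the soft mass balance (their boxes having been
    merged onto a sited representative). Parallel sweeps with damping on
    the site natural parameters (r = 1/d, q = a/d); convergence when the
    largest change in any site mean or variance drops below
    ``cfg.precision``. Returns tilted means/variances (sited entries;
    others carry the Gaussian marginal), the global Gaussian covariance and
    a convergence record.
    """
    beta, floor = cfg.beta, cfg.variance_floor
    n = A.shape[1]
    AtA = A.T @ A
    Atb = A.T @ b
    s_ix = np.flatnonzero(sited)

    r = np.where(sited, 1.0, 0.0)    # site precisions 1/d
    q = np.where(sited, 0.5, 0.0)    # site precision-means a/d

    def gaussian(r, q):
        P = beta * AtA + np.diag(r)
        h = beta * Atb + q
        cho = linalg.cho_factor(P, lower=True)
        Sigma = linalg.cho_solve(cho, np.eye(n))
        return Sigma, Sigma @ h

    def tilted(Sigma, mu, r, q):
        s = np.clip(np.diag(Sigma)[s_ix], 1e-300, None)
        rc = np.clip(1.0 / s - r[s_ix], 1e-11, None)
        qc = mu[s_ix] / s - q[s_ix]
        vc = 1.0 / rc
        mc = qc * vc
        sd = np.sqrt(vc)
        mt, vt = _truncnorm_mv((0.0 - mc) / sd, (1.0 - mc) / sd)
        return (
            mc + sd * mt,
            np.clip(vc * vt, floor, None),
            rc,
            qc,
        )

    max_change = np.inf
    it = 0
    Sigma, mu = gaussian(r, q)
    for it in range(1, cfg.max_iterations + 1):
        mt, vt, rc, qc = tilted(Sigma, mu, r, q)
        r_new = np.clip(1.0 / vt - rc, 1e-11, None)
        q_new = mt / vt - qc
        r_next, q_next = r.copy(), q.copy()
        r_next[s_ix] = cfg.damping * r[s_ix] + (1 - cfg.damping) * r_new
        q_next[s_ix] = cfg.damping * q[s_ix] + (1 - cfg.damping) * q_new
        max_change = max(
            np.max(np.abs(1.0 / r_next[s_ix] - 1.0 / r[s_ix])),
            np.max(np.abs(q_next[s_ix] / r_next[s_ix] - q[s_ix] / r[s_ix])),
        )
        r, q = r_next, q_next
        Sigma, mu = gaussian(r, q)
        if max_change < cfg.precision:
            break

    mt_all = mu.copy()
    vt_all = np.clip(np.diag(Sigma).copy(), floor, None)
    mt, vt, _, _ = tilted(Sigma, mu, r, q)
    mt_all[s_ix] = np.clip(mt, 0.0, 1.0)
    vt_all[s_ix] = vt
    conv = {
        "iterations": it,
        "final_change": float(max_change),
        "converged": bool(max_change < cfg.precision),
    }
    return mt_all, vt_all, Sigma, conv


# ---------------------------------------------------------------------------
# Hit-and-run sampling oracle
# ---------------------------------------------------------------------------

def _interior_point(S, lb, ub):
    """Strictly interior feasible point by maximising the box slack (LP)."""
    n = S.shape[1]
    width = ub - lb
    smax = 0.5 * np.min(width[width > _FIXED_WIDTH], initial=1.0)
    # variables (v, s): maximise s with lb + s <= v <= ub - s where width > 0
    c = np.zeros(n + 1)
    c[-1] = -1.0
    A_eq = np.hstack([S, np.zeros((S.shape[0], 1))])
    rows_lo, rows_hi = [], []
    for j in range(n):
        if width[j] <= _FIXED_WIDTH:
            continue
        row = np.zeros(n + 1)
        row[j], row[-1] = -1.0, 1.0  # s - v <= -lb
        rows_lo.append((row, -lb[j]))
        row = np.zeros(n + 1)
        row[j], row[-1] = 1.0, 1.0  # v + s <= ub
        rows_hi.append((row, ub[j]))
    A_ub = np.array([r for r, _ in rows_lo + rows_hi])
    b_ub = np.array([v for _, v in rows_lo + rows_hi])
    bounds = [(lb[j], ub[j]) for j in range(n)] + [(0.0, smax)]
    res = linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=np.zeros(S.shape[0]),
        bounds=bounds, method="highs",
    )
    if res.status == 2 or not res.success:
        raise ValueError("flux polytope is infeasible")
    return res.x[:n]


def sample_moments(
    space: ReducedFluxSpace,
    n_samples: int = 100_000,
    seed: int = 0,
    warmup_factor: int = 10,
    thinning_factor: int = 1,
) -> FluxMoments:
    """Empirical moments from uniform hit-and-run samples of the polytope.

    The chain runs in null-space coordinates of ``S`` (so every state is
    exactly mass balanced), with ``warmup_factor * dim`` warm-up steps and
    ``thinning_factor * dim`` steps between retained samples. Deterministic
    for a fixed seed. A zero-dimensional space returns point-mass moments.
    """
    S, lb, ub = space.S, np.asarray(space.lb, float), np.asarray(space.ub, float)
    n = S.shape[1]
    rng = np.random.default_rng(seed)

    N = linalg.null_space(S) if S.size else np.eye(n)
    dim = N.shape[1]
    if np.all(ub - lb <= _FIXED_WIDTH):  # zero-width box: a single point
        dim = 0
    if dim == 0:
        mean = lb.copy()
        if np.max(np.abs(S @ mean)) > 1e-6:
            raise ValueError("flux polytope is infeasible")
        return FluxMoments(
            list(space.reaction_ids), mean, np.zeros(n), np.zeros((n, n)),
            "sampling", {"n_samples": 0, "dim": 0},
        )

    v = _interior_point(S, lb, ub)
    warmup = warmup_factor * dim
    thin = max(1, thinning_factor * dim)
    total = warmup + n_samples * thin

    samples = np.empty((n_samples, n))
    kept = 0
    tol = 1e-12
    for step in range(total):
        d = rng.standard_normal(dim)
        d /= np.linalg.norm(d)
        u = N @ d
        # line segment {v + t u} within the box
        with np.errstate(divide="ignore", invalid="ignore"):
            t_lo = (lb - v) / u
            t_hi = (ub - v) / u
        t_min = np.where(u > tol, t_lo, np.where(u < -tol, t_hi, -np.inf))
        t_max = np.where(u > tol, t_hi, np.where(u < -tol, t_lo, np.inf))
        tmin, tmax = np.max(t_min), np.min(t_max)
        if not np.isfinite(tmin) or not np.isfinite(tmax) or tmax < tmin:
            continue  # numerically degenerate direction; keep current state
        v = v + rng.uniform(tmin, tmax) * u
        v = np.clip(v, lb, ub)
        if step >= warmup and (step - warmup) % thin == 0 and kept < n_samples:
            samples[kept] = v
            kept += 1
    samples = samples[:kept]

    mean = samples.mean(axis=0)
    cov = np.cov(samples, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    return FluxMoments(
        list(space.reaction_ids), mean, np.diag(cov).copy(), cov,
        "sampling", {"n_samples": int(kept), "dim": int(dim), "seed": int(seed)},
    )
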