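"""Bi-exponential intravoxel-incoherent-motion (IVIM) model and fitters.

The fractional DWI signal at diffusion weighting ``b`` is modelled as a
two-compartment decay

    S(b)/S(0) = (1 - v_bw) exp(-b D) + v_bw exp(-b (D + D*))

where ``D`` is the diffusion coefficient of water in bulk tissue (mm^2/s),
``D*`` is the effective (pseudo-)diffusion coefficient of blood water in
randomly oriented microvessels, and ``v_bw`` is the fraction of voxel water
in blood.  The derived product ``D* x v_bw`` indexes microvascular blood
flow.  The fast-compartment rate is ``D + D*`` by default
(``fast_rate_convention="sum"``); much IVIM literature uses ``D*`` alone,
available as ``"dstar_only"`` — the two conventions differ in reported
``D*`` by exactly ``D``.

Two estimators are provided per voxel:

* ``segmented`` — ``D`` from a log-linear fit to the high-b tail
  (``b >= b_cut``), then ``(v_bw, D*)`` by bounded least squares on the full
  curve with ``D`` held fixed;
* ``full_nls`` — simultaneous bounded least squares on all three
  parameters, started from the segmented solution.

``fit_ivim_volume`` additionally offers a vectorized segmented path
(closed-form ``v_bw`` given ``D*``, golden-section search on ``D*``) for
cohort-scale maps.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .preprocess import DWISeries

PARAM_NAMES = ("vbw", "d", "dstar", "flow")


@dataclass(frozen=True)
class IVIMParams:
    """Per-voxel IVIM parameter triple plus the derived flow product."""

    vbw: float
    d: float
    dstar: float

    @property
    def flow(self) -> float:
        return self.dstar * self.vbw

    def validate(self) -> None:
        if not 0.0 <= self.vbw <= 1.0:
            raise ValueError(f"v_bw={self.vbw} outside [0, 1]")
        if self.d < 0:
            raise ValueError(f"D={self.d} must be non-negative")
        if self.dstar < self.d:
            raise ValueError(f"D*={self.dstar} must be >= D={self.d}")


@dataclass(frozen=True)
class FitOptions:
    """Bounds, tolerances and conventions shared by all fitters.

    Bounds are physiological brain ranges and prevent the two compartments
    from swapping roles.  The D* >= D constraint is imposed by fitting the
    gap ``D* - D`` with a non-negative box bound.
    """

    b_cut: float = 200.0                      # s/mm^2, start of mono-exp tail
    vbw_max: float = 0.3
    d_max: float = 3e-3                       # mm^2/s
    dstar_max: float = 0.1                    # mm^2/s
    fast_rate_convention: str = "sum"         # "sum" | "dstar_only"
    ftol: float = 1e-14
    xtol: float = 1e-14
    gtol: float = 1e-14
    max_nfev: int = 200
    min_identifiable_vbw: float = 0.005
    dstar_grid_size: int = 48                 # vectorized path: coarse D* grid
    golden_iters: int = 40                    # vectorized path: refinement steps

    def __post_init__(self) -> None:
        if self.fast_rate_convention not in ("sum", "dstar_only"):
            raise ValueError(f"unknown fast_rate_convention {self.fast_rate_convention!r}")


@dataclass
class FitResult:
    params: IVIMParams
    residual_norm: float
    converged: bool
    method: str
    n_iter: int
    identifiable: bool = True


def _fast_rate(d, dstar, convention: str):
    return d + dstar if convention == "sum" else dstar


def ivim_signal(params: IVIMParams, b, convention: str = "sum") -> np.ndarray:
    """Fractional signal S(b)/S(0) of the bi-exponential model; 1 at b=0."""
    b = np.asarray(b, dtype=float)
    fast = _fast_rate(params.d, params.dstar, convention)
    return (1.0 - params.vbw) * np.exp(-b * params.d) + params.vbw * np.exp(-b * fast)


def fit_monoexp_tail(
    signal: np.ndarray, b_values: np.ndarray, b_cut: float = 200.0
) -> tuple[float, float]:
    """Log-linear fit of the high-b tail: returns (D, tissue amplitude).

    The slope magnitude estimates the tissue diffusion coefficient; the
    exponentiated intercept estimates the tissue-compartment amplitude
    (``1 - v_bw``).
    """
    signal = np.asarray(signal, dtype=float)
    b = np.asarray(b_values, dtype=float)
    sel = (b >= b_cut) & (signal > 0) & np.isfinite(signal)
    if np.count_nonzero(sel) < 2:
        raise ValueError("need at least 2 positive signal values at b >= b_cut")
    slope, intercept = np.polyfit(b[sel], np.log(signal[sel]), 1)
    return max(-float(slope), 0.0), float(np.exp(intercept))


def _invalid_result(method: str) -> FitResult:
    return FitResult(
        params=IVIMParams(np.nan, np.nan, np.nan),
        residual_norm=np.nan,
        converged=False,
        method=method,
        n_iter=0,
        identifiable=False,
    )


def _model_vgap(v, d, gap, b, convention):
    dstar = d + gap
    fast = _fast_rate(d, dstar, convention)
    return (1.0 - v) * np.exp(-b * d) + v * np.exp(-b * fast)


def fit_ivim_voxel(
    signal: np.ndarray,
    b_values: np.ndarray,
    method: str = "segmented",
    options: FitOptions | None = None,
) -> FitResult:
    """Estimate (v_bw, D, D*) for one voxel from its fractional decay curve.

    Non-convergence and degenerate inputs are flagged in the returned
    ``FitResult`` rather than raised; downstream maps exclude flagged voxels.
    """
    opts = options or FitOptions()
    if method not in ("segmented", "full_nls"):
        raise ValueError(f"unknown fit method {method!r}")
    y = np.asarray(signal, dtype=float)
    b = np.asarray(b_values, dtype=float)
    if y.shape != b.shape:
        raise ValueError("signal and b-value schedule have different lengths")
    valid = np.isfinite(y)
    if np.count_nonzero(valid) < 4:
        return _invalid_result(method)
    y, b = y[valid], b[valid]

    # --- stage 1: tissue D from the mono-exponential tail
    try:
        d_seg, amp = fit_monoexp_tail(y, b, opts.b_cut)
        d_seg = min(d_seg, opts.d_max)
        seg_start_ok = True
    except ValueError:
        if method == "segmented":
            return _invalid_result(method)
        d_seg, amp, seg_start_ok = 0.5 * opts.d_max, 0.85, False

    # --- stage 2: (v_bw, gap) with D fixed
    gap_ub = max(opts.dstar_max - d_seg, 1e-6)
    v0 = float(np.clip(1.0 - amp, 1e-4, opts.vbw_max - 1e-4))
    gap0 = float(np.clip(1e-2 - d_seg, 1e-4, gap_ub - 1e-7))

    def resid_seg(x):
        return _model_vgap(x[0], d_seg, x[1], b, opts.fast_rate_convention) - y

    sol_seg = least_squares(
        resid_seg,
        x0=[v0, gap0],
        bounds=([0.0, 0.0], [opts.vbw_max, gap_ub]),
        method="trf",
        x_scale=[0.1, 1e-2],
        ftol=opts.ftol,
        xtol=opts.xtol,
        gtol=opts.gtol,
        max_nfev=opts.max_nfev,
    )
    v_seg, gap_seg = sol_seg.x
    if method == "segmented":
        params = IVIMParams(float(v_seg), float(d_seg), float(d_seg + gap_seg))
        return FitResult(
            params=params,
            residual_norm=float(np.linalg.norm(sol_seg.fun)),
            converged=bool(sol_seg.success),
            method=method,
            n_iter=int(sol_seg.nfev),
            identifiable=v_seg >= opts.min_identifiable_vbw,
        )

    # --- full NLS on (v_bw, D, gap), started from the segmented solution
    if seg_start_ok and sol_seg.success:
        x0 = [float(np.clip(v_seg, 0, opts.vbw_max)), d_seg, float(gap_seg)]
    else:  # bound midpoints
        x0 = [opts.vbw_max / 2, opts.d_max / 2, opts.dstar_max / 2]

    def resid_full(x):
        return _model_vgap(x[0], x[1], x[2], b, opts.fast_rate_convention) - y

    sol = least_squares(
        resid_full,
        x0=x0,
        bounds=([0.0, 0.0, 0.0], [opts.vbw_max, opts.d_max, opts.dstar_max]),
        method="trf",
        x_scale=[0.1, 1e-3, 1e-2],
        ftol=opts.ftol,
        xtol=opts.xtol,
        gtol=opts.gtol,
        max_nfev=opts.max_nfev,
    )
    v, d, gap = sol.x
    cost = sol.cost
    nfev = sol.nfev
    # trf can stall a hair short of the optimum when the truth sits on a box
    # bound; an unconstrained LM polish is accepted if it stays in bounds and
    # lowers the cost.
    try:
        polish = least_squares(
            resid_full, x0=sol.x, method="lm",
            ftol=opts.ftol, xtol=opts.xtol, gtol=opts.gtol, max_nfev=opts.max_nfev,
        )
        tol = 1e-9
        within = (
            -tol <= polish.x[0] <= opts.vbw_max + tol
            and -tol <= polish.x[1] <= opts.d_max + tol
            and -tol <= polish.x[2] <= opts.dstar_max + tol
        )
        if within and polish.cost <= cost:
            v, d, gap = np.clip(
                polish.x, 0.0, [opts.vbw_max, opts.d_max, opts.dstar_max]
            )
            cost = polish.cost
            nfev += polish.nfev
    except Exception:  # pragma: no cover - LM can fail on degenerate curves
        pass
    params = IVIMParams(float(v), float(d), float(d + gap))
    return FitResult(
        params=params,
        residual_norm=float(math.sqrt(2.0 * cost)),
        converged=bool(sol.success),
        method="full_nls",
        n_iter=int(nfev),
        identifiable=v >= opts.min_identifiable_vbw,
    )


@dataclass
class ParameterMaps:
    """One scalar field per IVIM parameter, NaN outside the validity mask."""

    maps: dict[str, np.ndarray]
    mask: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    residual_norm: np.ndarray | None = None
    method: str = "segmented"
    n_invalid: int = 0

    def __getitem__(self, name: str) -> np.ndarray:
        return self.maps[name]


# ----------------------------------------------------------------------------
# vectorized segmented fitting over a whole volume
# ----------------------------------------------------------------------------

def _tail_loglinear_batch(Y: np.ndarray, b: np.ndarray, opts: FitOptions):
    """Vectorized high-b log-linear fit.  Voxels with any non-positive tail
    sample are marked invalid (smoothed magnitude data essentially never is)."""
    sel = b >= opts.b_cut
    if np.count_nonzero(sel) < 2:
        raise ValueError("b schedule has fewer than 2 points at/above b_cut")
    bt = b[sel]
    T = Y[:, sel]
    ok = np.all(T > 0, axis=1) & np.all(np.isfinite(T), axis=1)
    logT = np.where(T > 0, np.log(np.maximum(T, 1e-300)), 0.0)
    bc = bt - bt.mean()
    denom = float(np.sum(bc * bc))
    slope = (logT @ bc) / denom
    intercept = logT.mean(axis=1) - slope * bt.mean()
    d = np.clip(-slope, 0.0, opts.d_max)
    amp = np.exp(intercept)
    return d, amp, ok


def _sse_given_dstar(Y, b, d, dstar, opts):
    """Closed-form optimal v_bw and SSE for fixed per-voxel (D, D*)."""
    fast = _fast_rate(d, dstar, opts.fast_rate_convention)
    A = np.exp(-np.outer(d, b))
    F = np.exp(-np.outer(fast, b))
    W = F - A
    R = Y - A
    denom = np.einsum("ij,ij->i", W, W)
    num = np.einsum("ij,ij->i", W, R)
    v = np.where(denom > 0, num / np.maximum(denom, 1e-300), 0.0)
    v = np.clip(v, 0.0, opts.vbw_max)
    E = R - v[:, None] * W
    sse = np.einsum("ij,ij->i", E, E)
    return v, sse


def _fit_segmented_batch(Y: np.ndarray, b: np.ndarray, opts: FitOptions):
    """Segmented fit for all voxels at once.

    D comes from the vectorized tail fit; D* is found per voxel by a coarse
    log-spaced grid followed by golden-section refinement, with v_bw solved in
    closed form at every candidate (the model is linear in v_bw given D, D*).
    """
    n = Y.shape[0]
    d, _amp, ok = _tail_loglinear_batch(Y, b, opts)

    gap_lo = 1e-5
    grid = np.geomspace(2e-4, opts.dstar_max, opts.dstar_grid_size)
    gap_ub = np.maximum(opts.dstar_max - d, 1e-6)

    best_sse = np.full(n, np.inf)
    best_idx = np.zeros(n, dtype=int)
    for i, g in enumerate(grid):
        gv = np.minimum(g, gap_ub)
        _v, sse = _sse_given_dstar(Y, b, d, d + gv, opts)
        better = sse < best_sse
        best_sse[better] = sse[better]
        best_idx[better] = i
    lo = np.where(best_idx > 0, grid[np.maximum(best_idx - 1, 0)], gap_lo)
    hi = np.where(
        best_idx < grid.size - 1, grid[np.minimum(best_idx + 1, grid.size - 1)], opts.dstar_max
    )
    lo = np.minimum(lo, gap_ub)
    hi = np.minimum(hi, gap_ub)

    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    x1 = hi - invphi * (hi - lo)
    x2 = lo + invphi * (hi - lo)
    _, f1 = _sse_given_dstar(Y, b, d, d + x1, opts)
    _, f2 = _sse_given_dstar(Y, b, d, d + x2, opts)
    for _ in range(opts.golden_iters):
        shrink_hi = f1 < f2  # minimum lies in [lo, x2]
        hi = np.where(shrink_hi, x2, hi)
        lo = np.where(shrink_hi, lo, x1)
        x1n = np.where(shrink_hi, hi - invphi * (hi - lo), x2)
        x2n = np.where(shrink_hi, x1, lo + invphi * (hi - lo))
        newx = np.where(shrink_hi, x1n, x2n)  # the one freshly placed point
        _, fn = _sse_given_dstar(Y, b, d, d + newx, opts)
        f1, f2 = np.where(shrink_hi, fn, f2), np.where(shrink_hi, f1, fn)
        x1, x2 = x1n, x2n
    gap = 0.5 * (lo + hi)
    v, sse = _sse_given_dstar(Y, b, d, d + gap, opts)
    return v, d, d + gap, np.sqrt(sse), ok


def _fit_full_batch(Y: np.ndarray, b: np.ndarray, opts: FitOptions, n_iter: int = 40):
    """Vectorized full bi-exponential fit: damped Gauss-Newton on
    (v_bw, D, gap) from the segmented start, projected onto the box bounds.

    Steps are only accepted where they lower the SSE, so the final residual
    never exceeds the segmented one.
    """
    v, d, dstar, rnorm, ok = _fit_segmented_batch(Y, b, opts)
    g = np.clip(dstar - d, 0.0, opts.dstar_max)
    d = d.copy()
    v = v.copy()
    sum_conv = opts.fast_rate_convention == "sum"
    scale = np.array([0.1, 1e-3, 1e-2])
    lo = np.zeros(3)
    hi = np.array([opts.vbw_max, opts.d_max, opts.dstar_max])

    def model_and_parts(v, d, g):
        E1 = np.exp(-np.outer(d, b))
        fast = (2.0 * d + g) if sum_conv else (d + g)
        E2 = np.exp(-np.outer(fast, b))
        m = (1.0 - v)[:, None] * E1 + v[:, None] * E2
        return m, E1, E2

    def sse_of(v, d, g):
        m, _, _ = model_and_parts(v, d, g)
        r = m - Y
        return np.einsum("ij,ij->i", r, r)

    sse = sse_of(v, d, g)
    lam = np.full(v.shape, 1e-3)
    for _ in range(n_iter):
        prev_sse = sse
        m, E1, E2 = model_and_parts(v, d, g)
        r = m - Y
        dfac = 2.0 if sum_conv else 1.0
        J = np.stack(
            [
                (E2 - E1) * scale[0],
                (-(1.0 - v)[:, None] * b * E1 - dfac * v[:, None] * b * E2) * scale[1],
                (-v[:, None] * b * E2) * scale[2],
            ],
            axis=2,
        )  # (N, B, 3), scaled parameterization
        JtJ = np.einsum("ibk,ibl->ikl", J, J)
        Jtr = np.einsum("ibk,ib->ik", J, r)
        accepted = np.zeros(v.shape, dtype=bool)
        for _try in range(4):
            A = JtJ + lam[:, None, None] * np.eye(3)
            try:
                delta = -np.linalg.solve(A, Jtr[:, :, None])[:, :, 0]
            except np.linalg.LinAlgError:  # pragma: no cover
                delta = -np.linalg.solve(A + 1e-8 * np.eye(3), Jtr[:, :, None])[:, :, 0]
            theta = np.stack([v, d, g], axis=1) + delta * scale * (~accepted)[:, None]
            theta = np.clip(theta, lo, hi)
            new_sse = sse_of(theta[:, 0], theta[:, 1], theta[:, 2])
            better = (new_sse < sse) & ~accepted
            v = np.where(better, theta[:, 0], v)
            d = np.where(better, theta[:, 1], d)
            g = np.where(better, theta[:, 2], g)
            sse = np.where(better, new_sse, sse)
            lam = np.where(better, lam / 3.0, np.where(accepted, lam, lam * 10.0))
            accepted |= better
            if accepted.all():
                break
        if np.max((prev_sse - sse) / np.maximum(prev_sse, 1e-300)) < 1e-12:
            break
    dstar = d + g
    return v, d, dstar, np.sqrt(sse), ok


def fit_ivim_volume(
    dwi: DWISeries,
    method: str = "segmented",
    options: FitOptions | None = None,
) -> ParameterMaps:
    """Voxel-wise IVIM fit over the brain mask of a normalized series.

    Input must be direction-averaged and normalized (b=0 entry equal to 1
    inside the mask).  ``segmented`` runs fully vectorized; ``full_nls``
    fits voxel by voxel with bounded nonlinear least squares.
    """
    opts = options or FitOptions()
    if dwi.has_directions:
        raise ValueError("average directions before fitting")
    mask = dwi.brain_mask
    if not mask.any():
        raise ValueError("empty brain mask")
    b0 = dwi.signal[..., 0][mask]
    if not np.allclose(b0, 1.0, atol=1e-6):
        raise ValueError("series is not normalized: b=0 entries differ from 1 inside mask")

    b = dwi.b_values
    Y = dwi.signal[mask]  # (N, B)
    shape = dwi.grid_shape

    if method == "segmented":
        v, d, dstar, rnorm, ok = _fit_segmented_batch(Y, b, opts)
    elif method == "full_nls":
        v, d, dstar, rnorm, ok = _fit_full_batch(Y, b, opts)
    else:
        raise ValueError(f"unknown fit method {method!r}")

    valid = np.zeros(shape, dtype=bool)
    valid[mask] = ok
    maps: dict[str, np.ndarray] = {}
    for name, vec in (("vbw", v), ("d", d), ("dstar", dstar), ("flow", dstar * v)):
        m = np.full(shape, np.nan)
        m[mask] = np.where(ok, vec, np.nan)
        maps[name] = m
    res_map = np.full(shape, np.nan)
    res_map[mask] = np.where(ok, rnorm, np.nan)
    return ParameterMaps(
        maps=maps,
        mask=valid,
        voxel_size_mm=dwi.voxel_size_mm,
        residual_norm=res_map,
        method=method,
        n_invalid=int(np.count_nonzero(mask) - np.count_nonzero(valid)),
    )
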