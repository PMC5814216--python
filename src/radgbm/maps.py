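"""Physiologic MR maps: ADC from a DWI b-value pair, and DSC perfusion indices.

The DSC chain is: signal S(t) -> relaxation-rate change ``dR2*(t)`` ->
(optional leakage correction) -> gamma-variate first-pass fit -> perfusion
indices (CBV, CBF, MTT, TTP) defined in closed form on the fitted curve.
No arterial input function is used: indices are *relative* quantities of the
fitted first-pass bolus curve, normalised afterwards to a reference
(normal-tissue) region, which is why the feature names carry an "r" prefix.

Gamma-variate model (the canonical first-pass bolus shape)::

    C(t) = K * (t - t0)**alpha * exp(-(t - t0) / beta)   for t > t0, else 0

with amplitude ``K``, bolus-arrival time ``t0`` (s), shape ``alpha``
(dimensionless) and scale ``beta`` (s). On this curve:

    CBV = K * beta**(alpha+1) * Gamma(alpha+1)      (area under curve)
    MTT = beta * (alpha + 1)                        (first moment / area, from t0)
    TTP = t0 + alpha * beta                         (time of the peak)
    CBF = CBV / MTT                                 (central volume principle)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

__all__ = [
    "DynamicSeries",
    "GammaVariateFit",
    "PerfusionMapSet",
    "gamma_variate",
    "compute_adc",
    "signal_to_relaxation",
    "fit_gamma_variate",
    "fit_gamma_variate_batch",
    "correct_leakage",
    "perfusion_indices",
    "normalize_relative",
]


@dataclass
class DynamicSeries:
    """A DSC-MRI acquisition: 4D signal, time axis and echo parameters.

    ``data`` is time-first: shape (n_timepoints, *spatial). ``baseline_window``
    indexes the pre-bolus timepoints used to estimate the baseline signal.
    """

    data: np.ndarray
    tr: float
    te: float
    baseline_window: slice = field(default_factory=lambda: slice(0, 5))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape[0] < 10:
            raise ValueError(
                f"dynamic series needs >=10 timepoints, got {self.data.shape[0]}"
            )
        if self.tr <= 0 or self.te <= 0:
            raise ValueError("TR and TE must be positive")
        n_base = len(range(*self.baseline_window.indices(self.data.shape[0])))
        if n_base < 1:
            raise ValueError("baseline window is empty")

    @property
    def times(self) -> np.ndarray:
        """Acquisition times (s) of each volume, starting at 0."""
        return np.arange(self.data.shape[0]) * self.tr


@dataclass
class GammaVariateFit:
    """Result of a gamma-variate least-squares fit to one dR2* curve."""

    k_amp: float
    t0: float
    alpha_g: float
    beta_g: float
    rss: float
    converged: bool


@dataclass
class PerfusionMapSet:
    """Voxelwise perfusion index maps sharing one grid.

    rCBV/rCBF are in relative units (after :func:`normalize_relative`);
    MTT and TTP are in seconds. ``fit_quality`` flags voxels whose
    gamma-variate fit converged; indices elsewhere are NaN.
    """

    rcbv: np.ndarray
    rcbf: np.ndarray
    mtt: np.ndarray
    ttp: np.ndarray
    fit_quality: np.ndarray


def gamma_variate(t, k_amp, t0, alpha_g, beta_g):
    """Evaluate K*(t-t0)^alpha*exp(-(t-t0)/beta), zero at and before t0.

    Broadcasts over both the time axis and stacked parameter arrays.
    """
    t = np.asarray(t, dtype=float)
    u = t - t0
    out = np.zeros(np.broadcast(u, k_amp * 1.0).shape, dtype=float)
    pos = u > 0
    u_pos = np.where(pos, u, 1.0)  # avoid log(<=0); masked out below
    with np.errstate(over="ignore"):
        val = k_amp * np.exp(alpha_g * np.log(u_pos) - u_pos / beta_g)
    return np.where(pos, val, out)


def compute_adc(s_b0, s_b1000, b=1000.0, mask=None):
    """Apparent diffusion coefficient from a two-point DWI acquisition.

    ADC = ln(S_b0 / S_b) / b per voxel (mm^2/s for b in s/mm^2). Negative
    estimates (noise pushing S_b above S_b0) are clamped to zero.

    Returns ``(adc, n_clamped)``. Raises if any signal inside ``mask``
    (default: everywhere) is non-positive.
    """
    s_b0 = np.asarray(s_b0, dtype=float)
    s_b1000 = np.asarray(s_b1000, dtype=float)
    if b <= 0:
        raise ValueError("b-value must be positive")
    if s_b0.shape != s_b1000.shape:
        raise ValueError("DWI volumes must share a grid")
    if mask is None:
        mask = np.ones(s_b0.shape, dtype=bool)
    bad = int(np.count_nonzero((s_b0[mask] <= 0) | (s_b1000[mask] <= 0)))
    if bad:
        raise ValueError(f"non-positive DWI signal at {bad} voxels inside mask")
    adc = np.full(s_b0.shape, np.nan)
    adc[mask] = np.log(s_b0[mask] / s_b1000[mask]) / b
    neg = mask & (adc < 0)
    n_clamped = int(np.count_nonzero(neg))
    adc[neg] = 0.0
    return adc, n_clamped


def signal_to_relaxation(series: DynamicSeries, mask=None) -> np.ndarray:
    """Convert DSC signal to the relaxation-rate change curve dR2*(t).

    dR2*(t) = -(1/TE) * ln(S(t)/S_base), with S_base the mean over the
    pre-bolus baseline window; the output baseline is ~0 by construction.
    With ``mask`` (boolean, spatial shape) only the masked voxels are
    converted and the result has shape (n_timepoints, n_masked).
    """
    s = series.data
    if mask is not None:
        s = s.reshape(s.shape[0], -1)[:, np.asarray(mask, dtype=bool).ravel()]
    s = np.asarray(s, dtype=float)
    s_base = s[series.baseline_window].mean(axis=0)
    if np.any(s_base <= 0):
        raise ValueError("non-positive baseline signal; cannot take log ratio")
    if np.any(s <= 0):
        raise ValueError("non-positive signal in dynamic series")
    return -np.log(s / s_base) / series.te


def _fit_window(curves: np.ndarray, cutoff_frac: float) -> np.ndarray:
    """Per-curve boolean window ending at the first post-peak drop below
    ``cutoff_frac`` of the peak — samples beyond it are dominated by
    recirculation and excluded from the first-pass fit."""
    n, t = curves.shape
    peak_idx = np.argmax(curves, axis=1)
    peak = curves[np.arange(n), peak_idx]
    after = np.arange(t)[None, :] > peak_idx[:, None]
    below = after & (curves < cutoff_frac * peak[:, None])
    # first index where below holds; t if never
    first_below = np.where(below.any(axis=1), below.argmax(axis=1), t)
    return np.arange(t)[None, :] <= first_below[:, None]


def _initial_params(curves, times, window):
    """Moment/log-linear initial values per curve (K, t0, alpha, beta).

    Given t0, ``ln y = ln K + alpha ln(t - t0) - (t - t0)/beta`` is linear;
    a masked weighted least-squares solve (batched 3x3 normal equations)
    yields the start point for the nonlinear refinement.
    """
    n, t = curves.shape
    peak_idx = np.argmax(curves, axis=1)
    peak = curves[np.arange(n), peak_idx]
    # t0: last time before the curve first exceeds 10% of peak
    above = curves > 0.1 * peak[:, None]
    first_above = above.argmax(axis=1)
    t0 = times[np.maximum(first_above - 1, 0)]
    t0 = np.minimum(t0, times[peak_idx] - 1e-6)

    sel = window & (curves > 0.02 * peak[:, None]) & (times[None, :] > t0[:, None])
    u = np.where(sel, times[None, :] - t0[:, None], 1.0)
    logy = np.where(sel & (curves > 0), np.log(np.maximum(curves, 1e-300)), 0.0)
    w = sel.astype(float)
    X = np.stack([np.ones_like(u), np.log(u), -u], axis=2)  # n x t x 3
    Xw = X * w[:, :, None]
    A = np.einsum("ntp,ntq->npq", Xw, X)
    b = np.einsum("ntp,nt->np", Xw, logy)
    ok = sel.sum(axis=1) >= 3
    coef = np.zeros((n, 3))
    if ok.any():
        # tiny ridge keeps near-singular windows solvable
        A_ok = A[ok] + 1e-10 * np.eye(3)[None]
        coef[ok] = np.linalg.solve(A_ok, b[ok][..., None])[..., 0]
    k0 = np.where(ok, np.exp(np.clip(coef[:, 0], -50, 50)), np.maximum(peak, 1e-6))
    a0 = np.where(ok, np.clip(coef[:, 1], 0.2, 20.0), 2.0)
    b0 = np.where(ok, 1.0 / np.clip(coef[:, 2], 1e-3, 1e3), 1.0)
    return k0, t0, a0, b0


def fit_gamma_variate_batch(
    curves: np.ndarray,
    times: np.ndarray,
    cutoff_frac: float = 0.2,
    snr_min: float = 3.0,
    max_iter: int = 60,
    tol: float = 1e-12,
):
    """Fit the gamma-variate model to many dR2* curves at once.

    A vectorised Levenberg-Marquardt pass over all curves simultaneously,
    fitted only on each curve's first-pass window (up to the first post-peak
    return below ``cutoff_frac`` of peak). A curve is flagged non-converged
    when its peak fails an SNR check against the baseline scatter or the
    optimiser does not reduce the residual to a stable point.

    Returns a dict of arrays: k_amp, t0, alpha_g, beta_g, rss, converged.
    """
    curves = np.atleast_2d(np.asarray(curves, dtype=float))
    times = np.asarray(times, dtype=float)
    n, t = curves.shape
    if t < 8:
        raise ValueError("need >=8 samples to fit a 4-parameter bolus model")
    peak = curves.max(axis=1)
    # SNR guard: noise proxied by the smaller of the pre-bolus scatter and a
    # second-difference estimate (the latter covers curves with no flat
    # baseline, where the early samples already ride the bolus upslope)
    n_base = max(3, t // 5)
    base_sd = curves[:, :n_base].std(axis=1, ddof=1)
    d2 = curves[:, 2:] - 2.0 * curves[:, 1:-1] + curves[:, :-2]
    hf_sd = np.std(d2, axis=1, ddof=1) / np.sqrt(6.0)
    noise_floor = np.maximum(np.minimum(base_sd, hf_sd), 1e-12)
    fittable = (peak > 0) & (peak / noise_floor >= snr_min) & np.isfinite(curves).all(axis=1)

    out = {
        "k_amp": np.zeros(n),
        "t0": np.zeros(n),
        "alpha_g": np.full(n, np.nan),
        "beta_g": np.full(n, np.nan),
        "rss": np.full(n, np.nan),
        "converged": np.zeros(n, dtype=bool),
    }
    idx = np.flatnonzero(fittable)
    if idx.size == 0:
        return out
    y = curves[idx]
    window = _fit_window(y, cutoff_frac)
    w = window.astype(float)
    k, t0, a, b = _initial_params(y, times, window)
    t_peak = times[np.argmax(y, axis=1)]

    lam = np.full(idx.size, 1e-3)
    params = np.stack([k, t0, a, b], axis=1)

    def cost(p, yy, ww):
        m = gamma_variate(times[None, :], p[:, 0:1], p[:, 1:2], p[:, 2:3], p[:, 3:4])
        r = (m - yy) * ww
        return m, r, (r * r).sum(axis=1)

    m, r, c = cost(params, y, w)
    active = np.ones(idx.size, dtype=bool)
    for _ in range(max_iter):
        ai = np.flatnonzero(active)
        if ai.size == 0:
            break
        p_a, m_a, r_a, w_a = params[ai], m[ai], r[ai], w[ai]
        kk, tt0, aa, bb = (p_a[:, i : i + 1] for i in range(4))
        u = times[None, :] - tt0
        pos = u > 0
        u_safe = np.where(pos, u, 1.0)
        dm_dk = np.where(pos, m_a / np.maximum(kk, 1e-300), 0.0)
        dm_dt0 = np.where(pos, m_a * (1.0 / bb - aa / u_safe), 0.0)
        dm_da = np.where(pos, m_a * np.log(u_safe), 0.0)
        dm_db = np.where(pos, m_a * u_safe / (bb * bb), 0.0)
        J = np.stack([dm_dk, dm_dt0, dm_da, dm_db], axis=2) * w_a[:, :, None]
        JTJ = np.einsum("ntp,ntq->npq", J, J)
        JTr = np.einsum("ntp,nt->np", J, r_a)
        diag = np.einsum("npp->np", JTJ).copy()
        diag[diag <= 0] = 1.0
        A = JTJ + lam[ai, None, None] * diag[:, None, :] * np.eye(4)[None]
        try:
            step = np.linalg.solve(A, -JTr[..., None])[..., 0]
        except np.linalg.LinAlgError:  # pragma: no cover
            step = np.stack([np.linalg.lstsq(Ai, -gi, rcond=None)[0] for Ai, gi in zip(A, JTr)])
        trial = p_a + step
        trial[:, 0] = np.maximum(trial[:, 0], 1e-12)  # K > 0
        trial[:, 1] = np.clip(trial[:, 1], 0.0, t_peak[ai] - 1e-9)  # 0 <= t0 < peak time
        trial[:, 2] = np.clip(trial[:, 2], 1e-3, 50.0)  # alpha > 0
        trial[:, 3] = np.clip(trial[:, 3], 1e-3, 1e4)  # beta > 0
        m_t, r_t, c_t = cost(trial, y[ai], w_a)
        better = c_t < c[ai]
        params[ai] = np.where(better[:, None], trial, p_a)
        m[ai] = np.where(better[:, None], m_t, m_a)
        r[ai] = np.where(better[:, None], r_t, r_a)
        rel_impr = np.where(better, (c[ai] - c_t) / np.maximum(c[ai], 1e-300), np.inf)
        c[ai] = np.where(better, c_t, c[ai])
        lam[ai] = np.clip(np.where(better, lam[ai] / 3.0, lam[ai] * 10.0), 1e-12, 1e12)
        # a curve leaves the active set once converged (tiny relative
        # improvement) or stalled (damping blown up without improvement)
        done = (better & (rel_impr < tol) & (lam[ai] < 1.0)) | (~better & (lam[ai] >= 1e10))
        active[ai[done]] = False

    scale = np.maximum((y * y * w).sum(axis=1), 1e-300)
    converged = c / scale < 0.5  # fit explains at least half the windowed energy
    out["k_amp"][idx] = params[:, 0]
    out["t0"][idx] = params[:, 1]
    out["alpha_g"][idx] = params[:, 2]
    out["beta_g"][idx] = params[:, 3]
    out["rss"][idx] = c
    out["converged"][idx] = converged
    return out


def fit_gamma_variate(curve, times, **kwargs) -> GammaVariateFit:
    """Fit one dR2* curve; see :func:`fit_gamma_variate_batch`.

    A flat or sub-SNR curve yields ``converged=False`` rather than raising.
    """
    curve = np.asarray(curve, dtype=float)
    if curve.ndim != 1:
        raise ValueError("expected a single 1-D curve")
    if not np.any(curve > 0):
        return GammaVariateFit(0.0, 0.0, np.nan, np.nan, np.nan, False)
    res = fit_gamma_variate_batch(curve[None, :], times, **kwargs)
    return GammaVariateFit(
        k_amp=float(res["k_amp"][0]),
        t0=float(res["t0"][0]),
        alpha_g=float(res["alpha_g"][0]),
        beta_g=float(res["beta_g"][0]),
        rss=float(res["rss"][0]),
        converged=bool(res["converged"][0]),
    )


def _cumtrapz(y: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Cumulative trapezoidal integral along the last axis, starting at 0."""
    dt = np.diff(times)
    mid = (y[..., 1:] + y[..., :-1]) / 2.0 * dt
    out = np.zeros_like(y)
    out[..., 1:] = np.cumsum(mid, axis=-1)
    return out


def correct_leakage(curve, reference_curve, times):
    """Boxerman-style two-parameter leakage correction of a dR2* curve.

    Models ``curve ~= k1 * reference - k2 * cumint(reference)`` by linear
    least squares; the corrected curve adds back ``k2 * cumint(reference)``,
    removing the T1-leakage droop so the tail returns to baseline.

    Returns ``(corrected_curve, k2)``. Vectorised: ``curve`` may be
    (n_voxels, T).
    """
    curve = np.asarray(curve, dtype=float)
    ref = np.asarray(reference_curve, dtype=float)
    if curve.shape[-1] != ref.shape[-1]:
        raise ValueError("curve and reference must share a time axis")
    if np.ptp(ref) == 0:
        raise ValueError("degenerate (constant) reference curve")
    cum = _cumtrapz(ref, np.asarray(times, dtype=float))
    X = np.column_stack([ref, -cum])
    coef, *_ = np.linalg.lstsq(X, np.atleast_2d(curve).T, rcond=None)
    k2 = coef[1]
    corrected = np.atleast_2d(curve) + k2[:, None] * cum[None, :]
    if curve.ndim == 1:
        return corrected[0], float(k2[0])
    return corrected, k2


def perfusion_indices(fit: GammaVariateFit):
    """Closed-form perfusion indices of a fitted first-pass curve.

    Returns ``(cbv, cbf, mtt, ttp)``; all NaN when the fit did not converge.
    """
    if not fit.converged:
        return (np.nan, np.nan, np.nan, np.nan)
    cbv = fit.k_amp * np.exp((fit.alpha_g + 1) * np.log(fit.beta_g) + gammaln(fit.alpha_g + 1))
    mtt = fit.beta_g * (fit.alpha_g + 1)
    ttp = fit.t0 + fit.alpha_g * fit.beta_g
    cbf = cbv / mtt
    return (float(cbv), float(cbf), float(mtt), float(ttp))


def perfusion_indices_batch(res: dict):
    """Vectorised :func:`perfusion_indices` on a batch-fit result dict."""
    conv = res["converged"]
    with np.errstate(invalid="ignore"):
        cbv = res["k_amp"] * np.exp(
            (res["alpha_g"] + 1) * np.log(res["beta_g"]) + gammaln(res["alpha_g"] + 1)
        )
        mtt = res["beta_g"] * (res["alpha_g"] + 1)
        ttp = res["t0"] + res["alpha_g"] * res["beta_g"]
        cbf = cbv / mtt
    for arr in (cbv, cbf, mtt, ttp):
        arr[~conv] = np.nan
    return cbv, cbf, mtt, ttp


def normalize_relative(voxel_map, reference_mask):
    """Divide a map by its median over a reference (normal-tissue) region.

    The output has median exactly 1 over the reference mask; this is the "r"
    of rCBV/rCBF/rADC. NaN voxels in the reference are ignored.
    """
    voxel_map = np.asarray(voxel_map, dtype=float)
    reference_mask = np.asarray(reference_mask, dtype=bool)
    if voxel_map.shape != reference_mask.shape:
        raise ValueError("map and reference mask must share a grid")
    vals = voxel_map[reference_mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("empty reference region")
    med = float(np.median(vals))
    if med <= 0:
        raise ValueError(f"non-positive reference median ({med}); cannot normalise")
    return voxel_map / med
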