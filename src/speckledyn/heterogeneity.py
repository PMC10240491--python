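"""Dynamical heterogeneity from two-time correlation matrices.

The normalized variance

    chi_T(dt) = ( <C(t, t+dt)^2>_t - <C(t, t+dt)>_t^2 ) / beta^2

is the variance of the TTC along its diagonal at fixed lag ``dt``,
normalized by the squared speckle contrast so that values are comparable
across temperatures and contrast modes.  It is an experimentally accessible
estimator of the four-point dynamic susceptibility: a homogeneous
stationary process gives only a finite-sampling noise floor, while
collective switching between dynamical states produces an interior peak.

Normalization is configurable (``"beta2"`` default, ``"mean2"`` or
``"none"``) and recorded in every result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .correlators import ContrastEstimate, G2Curve, TTCMatrix
from .exceptions import ConfigError, DegenerateInputError
from .kinetics import KWWFit, fit_kww


@dataclass
class ChiCurve:
    q: float
    dts: np.ndarray             # seconds, increasing
    chi: np.ndarray
    se: np.ndarray              # block-bootstrap SEs
    n_samples: np.ndarray       # diagonal samples per dt
    normalization: str = "beta2"
    meta: dict = field(default_factory=dict)


@dataclass
class Chi0Series:
    temperatures: np.ndarray
    chi0: np.ndarray
    dt_at_max: np.ndarray       # seconds
    se: np.ndarray
    t_peak: float               # K, from the Gaussian-bump fit
    t_peak_se: float
    significant: bool           # max/median >= 2


def compute_chi_T(ttc: TTCMatrix, contrast: ContrastEstimate, *,
                  dts: Optional[np.ndarray] = None,
                  normalization: str = "beta2",
                  min_samples: int = 20, n_blocks: int = 10,
                  n_boot: int = 200,
                  rng: Optional[np.random.Generator] = None) -> ChiCurve:
    """Normalized variance of the TTC along the diagonal, per lag ``dt``.

    The variance uses the n/(n-1) finite-sample correction; SEs come from a
    block bootstrap over contiguous diagonal segments (dynamical switching
    makes diagonal samples strongly correlated, which plain bootstrap would
    underestimate).
    """
    if normalization == "beta2":
        if contrast.beta <= 0:
            raise DegenerateInputError("contrast must be positive")
        norm = contrast.beta ** 2
    elif normalization == "mean2":
        norm = float(np.mean(np.diag(ttc.matrix))) ** 2
    elif normalization == "none":
        norm = 1.0
    else:
        raise ConfigError(f"unknown chi normalization {normalization!r}")
    if rng is None:
        rng = np.random.default_rng(0)

    n = len(ttc.times)
    dt_frame = ttc.dt
    if dts is None:
        max_k = n - min_samples
        ks = np.unique(np.round(np.geomspace(1, max(2, max_k), 40)).astype(int))
        ks = ks[ks <= max_k]
    else:
        ks = np.unique(np.round(np.asarray(dts) / dt_frame).astype(int))
        ks = ks[(ks >= 1) & (ks <= n - min_samples)]
    if ks.size == 0:
        raise ConfigError("TTC span too short for the requested dt grid")

    chi = np.empty(len(ks))
    se = np.empty(len(ks))
    n_samples = np.empty(len(ks), dtype=int)
    for i, k in enumerate(ks):
        d = np.diagonal(ttc.matrix, offset=int(k))
        m = len(d)
        n_samples[i] = m
        chi[i] = float(np.var(d, ddof=1)) / norm
        nb = min(n_blocks, m)
        blocks = np.array_split(d, nb)
        stats = np.empty(n_boot)
        for b in range(n_boot):
            pick = rng.integers(0, nb, nb)
            sample = np.concatenate([blocks[j] for j in pick])
            stats[b] = np.var(sample, ddof=1) / norm
        se[i] = float(stats.std(ddof=1))
    return ChiCurve(q=ttc.q, dts=ks * dt_frame, chi=chi, se=se,
                    n_samples=n_samples, normalization=normalization,
                    meta=dict(ttc.meta))


def chi_max(curve: ChiCurve):
    """Maximum of chi_T over dt: ``(chi0, dt_peak, flags)``.

    Ties resolve to the smaller dt; a maximum on the first or last grid
    point is flagged ``"boundary maximum"``.
    """
    if curve.chi.size == 0 or not np.any(np.isfinite(curve.chi)):
        raise DegenerateInputError("empty chi curve")
    i = int(np.nanargmax(curve.chi))   # first occurrence = smaller dt
    flags = ()
    if i == 0 or i == len(curve.chi) - 1:
        flags = ("boundary maximum",)
    return float(curve.chi[i]), float(curve.dts[i]), flags


def chi0_vs_temperature(series: Sequence) -> Chi0Series:
    """Assemble chi_0(T) and locate its peak temperature.

    ``series``: sequence of ``(T, ChiCurve)``; needs >= 5 temperatures.
    T_peak from a Gaussian-bump fit of chi_0(T) (baseline + peak), which is
    robust to uneven temperature grids; falls back to quadratic
    interpolation through the discrete argmax, then to the argmax itself.
    The SE comes from resampling the chi_0 values within their errors.
    A peak is flagged significant when max(chi0)/median(chi0) >= 2.
    """
    series = sorted(series, key=lambda x: x[0])
    if len(series) < 5:
        raise ConfigError("need >= 5 temperatures for a chi_0(T) peak")
    T = np.asarray([s[0] for s in series], float)
    chi0 = np.empty(len(series))
    dt_at = np.empty(len(series))
    se = np.empty(len(series))
    for i, (_, curve) in enumerate(series):
        c0, dtp, _ = chi_max(curve)
        chi0[i] = c0
        dt_at[i] = dtp
        k = int(np.nanargmax(curve.chi))
        se[i] = curve.se[k]

    def _quad_vertex(vals):
        j = int(np.argmax(vals))
        if j == 0 or j == len(vals) - 1:
            return T[j]
        x = T[j - 1:j + 2]
        y = vals[j - 1:j + 2]
        denom = (x[0] - x[1]) * (x[0] - x[2]) * (x[1] - x[2])
        a = (x[2] * (y[1] - y[0]) + x[1] * (y[0] - y[2])
             + x[0] * (y[2] - y[1])) / denom
        b = (x[2] ** 2 * (y[0] - y[1]) + x[1] ** 2 * (y[2] - y[0])
             + x[0] ** 2 * (y[1] - y[2])) / denom
        if a >= 0:          # not concave; fall back to the grid point
            return x[1]
        return float(np.clip(-b / (2 * a), x[0], x[2]))

    def vertex(vals):
        from scipy.optimize import curve_fit

        def bump(t, base, height, tc, w):
            return base + height * np.exp(-(t - tc) ** 2 / (2.0 * w ** 2))

        j = int(np.argmax(vals))
        p0 = [float(np.median(vals)),
              max(float(vals[j] - np.median(vals)), 1e-12), float(T[j]), 8.0]
        try:
            popt, _ = curve_fit(
                bump, T, vals, p0=p0,
                bounds=([0.0, 0.0, T[0], 1.0],
                        [np.inf, np.inf, T[-1], T[-1] - T[0]]),
                maxfev=20000)
            return float(popt[2])
        except (RuntimeError, ValueError):
            return _quad_vertex(vals)

    t_peak = float(vertex(chi0))
    rng = np.random.default_rng(12345)
    boots = [vertex(chi0 + rng.normal(0.0, np.where(se > 0, se, 0.0)))
             for _ in range(400)]
    t_peak_se = float(np.std(boots, ddof=1))
    significant = bool(np.max(chi0) / max(np.median(chi0), 1e-30) >= 2.0)
    return Chi0Series(temperatures=T, chi0=chi0, dt_at_max=dt_at, se=se,
                      t_peak=t_peak, t_peak_se=t_peak_se,
                      significant=significant)


def timescale_at_chi_peak(ttc: TTCMatrix, curve: ChiCurve,
                          contrast: Optional[ContrastEstimate] = None,
                          window_factor: float = 4.0,
                          min_windows: int = 3):
    """Mean local relaxation time of the epochs driving the chi_T peak.

    Construction: slide non-overlapping diagonal windows of width
    ``window_factor × dt_peak`` along the TTC.  The epochs that drive the
    variance peak on its fast side are those whose local correlation at
    ``dt_peak`` has already decayed *below* the diagonal mean, so windows
    are ranked by their negative deviation ``mean_w C(t, t+dt_peak) - <C>``
    and the most strongly decorrelated half of those is kept.  Within each
    kept window, C(t, t+dt) averaged over the window gives a local g2 curve
    which is fitted with a KWW decay (baseline fixed at 1).  Returns the
    median of the window time constants (robust against windows straddling
    an episode boundary) together with the per-window values:
    ``(tau_fast, per_window_taus)``.
    """
    chi0, dt_peak, _ = chi_max(curve)
    dtf = ttc.dt
    k_peak = max(1, int(round(dt_peak / dtf)))
    wlen = max(int(round(window_factor * k_peak)), k_peak + 6)
    n = len(ttc.times)
    if n < wlen + k_peak:
        raise ConfigError("TTC too short for sub-window analysis")
    d_peak = np.diagonal(ttc.matrix, offset=k_peak)
    d_mean = d_peak.mean()

    starts = list(range(0, n - wlen - k_peak, wlen))
    if len(starts) < min_windows:
        raise ConfigError(
            f"only {len(starts)} sub-windows available (< {min_windows})")
    deviation = np.array([np.mean(d_peak[s:s + wlen]) - d_mean
                          for s in starts])
    order = np.argsort(deviation)           # most negative first
    n_fast = max(min_windows, int(np.sum(deviation < 0) // 2))
    keep = [starts[i] for i in order[:n_fast]]

    taus = []
    lags = np.arange(1, wlen + 1)
    for s in keep:
        g_local = np.array([np.diagonal(ttc.matrix, offset=int(k))
                            [s:s + wlen].mean() for k in lags])
        local = G2Curve(q=ttc.q, lags=lags * dtf, g2=g_local,
                        se=np.full(len(lags), np.nan), n_pixels=ttc.n_pixels,
                        n_frames=wlen, meta={"frame_interval": dtf})
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            try:
                f = fit_kww(local, fix_baseline=1.0)
            except Exception:
                continue
        if "unresolved decay" not in f.flags:
            taus.append(f.tau)
    if len(taus) < min_windows:
        raise ConfigError("too few usable sub-windows for a timescale")
    return float(np.median(taus)), np.asarray(taus)
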