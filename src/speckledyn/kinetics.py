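"""Model fits for speckle decorrelation kinetics.

* KWW (stretched/compressed exponential) fits of g2 curves,
  ``g2(t) = β exp[-2 (t/τ)^α] + c`` — the Siegert-consistent form in which
  the *field* correlation is ``exp[-(t/τ)^α]``; the factor 2 convention is
  applied consistently by the synthetic generators and the fitters, so a
  fitted τ is directly comparable with a generator τ.
* Q-dispersion of the decay rate (ballistic test: 1/τ linear in Q with zero
  intercept; AIC comparison against the diffusive 1/τ ∝ Q² alternative).
* Flux-coupling model ``1/τ = 1/τ0 + a F`` and the associated
  ``t / (1 + a F τ0)`` time-axis rescaling with a collapse score.
* Arrhenius temperature dependence ``τ(T) = A exp(E_a / (R T))`` with E_a
  reported in kJ/mol (R = 8.314462618 J/(mol K), energies per mole).
* Gaussian-dip localization of the KWW-exponent minimum α(T).

All fits are weighted (1/SE²) whenever standard errors are available;
otherwise an unweighted fall-back is used and flagged in the result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .correlators import G2Curve
from .exceptions import ConfigError, FitError
from .synthetic import R_GAS


def kww_g2(t, beta, c, tau, alpha):
    """g2 model: ``c + beta * exp(-2 (t/tau)^alpha)``."""
    t = np.asarray(t, dtype=float)
    return c + beta * np.exp(-2.0 * (t / tau) ** alpha)


# --------------------------------------------------------------------------
# KWW fit
# --------------------------------------------------------------------------

@dataclass
class KWWFit:
    beta: float
    c: float
    tau: float                  # s
    alpha: float
    cov: np.ndarray             # 4x4 in (beta, c, tau, alpha) order
    resid_norm: float
    n_points: int
    weighted: bool = True
    flags: tuple = ()

    @property
    def se(self):
        return tuple(np.sqrt(np.maximum(np.diag(self.cov), 0.0)))

    @property
    def beta_se(self):
        return self.se[0]

    @property
    def tau_se(self):
        return self.se[2]

    @property
    def alpha_se(self):
        return self.se[3]


def fit_kww(curve: G2Curve, bounds: Optional[dict] = None,
            init: Optional[dict] = None, fix_baseline: Optional[float] = None
            ) -> KWWFit:
    """Weighted least-squares KWW fit of a g2 curve.

    Defaults: init c = 1, β = g2(first lag) - 1, τ at the lag where the
    normalized decay is nearest e⁻², α = 1; bounds α ∈ (0.2, 3],
    τ ∈ (frame interval, 10⁴ × lag span).
    """
    t = np.asarray(curve.lags, dtype=float)
    y = np.asarray(curve.g2, dtype=float)
    se = np.asarray(curve.se, dtype=float)
    ok = np.isfinite(y) & (t > 0)
    t, y, se = t[ok], y[ok], se[ok]
    if len(t) < 6:
        raise ConfigError("need >= 6 lag points spanning the decay")
    weighted = bool(np.all(np.isfinite(se)) and np.all(se > 0))
    sigma = se if weighted else None
    if not weighted:
        warnings.warn("no usable errors on g2; unweighted KWW fit",
                      stacklevel=2)

    dt = curve.frame_interval
    span = t[-1] - t[0]
    b = dict(beta=(1e-6, 2.0), c=(0.0, 2.0),
             tau=(dt, 1e4 * span), alpha=(0.2, 3.0))
    if bounds:
        b.update(bounds)

    c0 = 1.0 if fix_baseline is None else fix_baseline
    beta0 = max(y[0] - c0, 1e-3)
    norm = np.clip((y - c0) / beta0, 1e-12, None)
    tau0 = t[int(np.argmin(np.abs(norm - np.exp(-2.0))))]
    tau0 = float(np.clip(tau0, b["tau"][0] * 1.0001, b["tau"][1] * 0.9999))
    p0 = dict(beta=beta0, c=c0, tau=tau0, alpha=1.0)
    if init:
        p0.update(init)

    if fix_baseline is not None:
        names = ("beta", "tau", "alpha")

        def model(tt, beta, tau, alpha):
            return kww_g2(tt, beta, fix_baseline, tau, alpha)
    else:
        names = ("beta", "c", "tau", "alpha")
        model = kww_g2

    lo = [b[n][0] for n in names]
    hi = [b[n][1] for n in names]
    start = [float(np.clip(p0[n], b[n][0], b[n][1])) for n in names]
    try:
        popt, pcov = curve_fit(model, t, y, p0=start, sigma=sigma,
                               absolute_sigma=weighted, bounds=(lo, hi),
                               maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"KWW fit did not converge: {exc}",
                       diagnostics={"init": p0, "n_points": len(t)}) from exc

    params = dict(zip(names, popt))
    cov = np.zeros((4, 4))           # (beta, c, tau, alpha) order
    if fix_baseline is not None:
        params["c"] = fix_baseline
        idx = [0, 2, 3]
        for i, ii in enumerate(idx):
            for j, jj in enumerate(idx):
                cov[ii, jj] = pcov[i, j]
    else:
        cov = pcov
    resid = y - kww_g2(t, params["beta"], params["c"], params["tau"],
                       params["alpha"])
    flags = []
    # honest parameter errors: nearby g2 lags share the underlying data, so
    # the curve_fit covariance (which assumes independent points) is
    # optimistic; when pixel-group jackknife replicates of the curve are
    # available, refit each delete-one-group curve and take the jackknife
    # covariance of the fitted parameters instead.
    if getattr(curve, "group_g2", None) is not None:
        reps = []
        for gy in curve.group_g2:
            gy = np.asarray(gy, dtype=float)[ok]
            try:
                gopt, _ = curve_fit(model, t, gy, p0=popt, sigma=sigma,
                                    absolute_sigma=weighted,
                                    bounds=(lo, hi), maxfev=5000)
                reps.append(gopt)
            except (RuntimeError, ValueError):
                continue
        if len(reps) >= 4:
            reps = np.asarray(reps)
            G = len(reps)
            dev = reps - reps.mean(axis=0)
            jcov = (G - 1) / G * (dev.T @ dev)
            if fix_baseline is not None:
                idx = [0, 2, 3]
                for i, ii in enumerate(idx):
                    for j, jj in enumerate(idx):
                        cov[ii, jj] = jcov[i, j]
            else:
                cov = jcov
            flags.append("jackknife errors")
    if (params["tau"] <= b["tau"][0] * 1.01
            or params["tau"] >= b["tau"][1] * 0.99):
        flags.append("unresolved decay")
    return KWWFit(beta=params["beta"], c=params["c"], tau=params["tau"],
                  alpha=params["alpha"], cov=cov,
                  resid_norm=float(np.sqrt(np.mean(resid ** 2))),
                  n_points=len(t), weighted=weighted, flags=tuple(flags))


# --------------------------------------------------------------------------
# weighted linear regression helper
# --------------------------------------------------------------------------

def _wls(x, y, w, absolute=True):
    """Weighted least squares ``y = b0 + b1 x``; returns ``(b0, b1, cov)``.

    With ``absolute=True`` the weights are treated as 1/σ² and the parameter
    covariance is ``(X' W X)⁻¹``; otherwise it is scaled by the reduced χ².
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    X = np.column_stack([np.ones_like(x), x])
    A = X.T @ (X * w[:, None])
    coef = np.linalg.solve(A, X.T @ (w * y))
    cov = np.linalg.inv(A)
    if not absolute and len(x) > 2:
        resid = y - X @ coef
        cov = cov * float(np.sum(w * resid ** 2)) / (len(x) - 2)
    return coef[0], coef[1], cov


# --------------------------------------------------------------------------
# Q dispersion
# --------------------------------------------------------------------------

@dataclass
class DispersionFit:
    slope: float                # (1/s)/(1/nm)
    intercept: float            # 1/s
    slope_se: float
    intercept_se: float
    qs: np.ndarray
    rates: np.ndarray           # 1/tau
    rate_ses: np.ndarray
    is_ballistic: bool
    aic_linear: float
    aic_quadratic: float


def fit_q_dispersion(fits_by_q: Sequence) -> DispersionFit:
    """Weighted linear regression of the decay rate 1/τ on Q.

    ``fits_by_q``: sequence of ``(q, KWWFit)`` or ``(q, tau, tau_se)``.
    ``is_ballistic`` is true when the linear (in Q) model is AIC-preferred
    over the quadratic (in Q²) alternative and the intercept is consistent
    with zero (|intercept| < 2 SE).
    """
    qs, rates, ses = [], [], []
    for item in fits_by_q:
        if len(item) == 2:
            q, f = item
            tau, tse = f.tau, f.tau_se
        else:
            q, tau, tse = item
        qs.append(float(q))
        rates.append(1.0 / tau)
        ses.append(tse / tau ** 2 if np.isfinite(tse) and tse > 0 else np.nan)
    qs = np.asarray(qs)
    rates = np.asarray(rates)
    ses = np.asarray(ses)
    if len(qs) < 3:
        raise ConfigError("need >= 3 q bins for a dispersion fit")
    have_se = bool(np.all(np.isfinite(ses)))
    w = 1.0 / ses ** 2 if have_se else np.ones_like(rates)

    def aic_for(x):
        b0, b1, cov = _wls(x, rates, w, absolute=have_se)
        resid = rates - (b0 + b1 * x)
        chi2 = float(np.sum(w * resid ** 2))
        n = len(x)
        # Gaussian AIC with known per-point sigmas, 2 parameters
        return chi2 + 2 * 2, b0, b1, cov

    aic_lin, b0, b1, cov = aic_for(qs)
    aic_quad, _, _, _ = aic_for(qs ** 2)
    se0 = float(np.sqrt(cov[0, 0]))
    se1 = float(np.sqrt(cov[1, 1]))
    ballistic = bool(aic_lin <= aic_quad and abs(b0) < 2 * se0)
    return DispersionFit(slope=b1, intercept=b0, slope_se=se1,
                         intercept_se=se0, qs=qs, rates=rates, rate_ses=ses,
                         is_ballistic=ballistic, aic_linear=aic_lin,
                         aic_quadratic=aic_quad)


# --------------------------------------------------------------------------
# flux coupling
# --------------------------------------------------------------------------

@dataclass
class FluxCouplingFit:
    tau0: float                 # s
    a: float                    # um^2/ph
    tau0_se: float
    a_se: float
    fluxes: np.ndarray
    taus: np.ndarray
    tau_ses: np.ndarray


def fit_flux_coupling(taus: Sequence) -> FluxCouplingFit:
    """Weighted regression of 1/τ on flux density F: ``1/τ = 1/τ0 + a F``.

    ``taus``: sequence of ``(F, tau, tau_se)``.  τ0 SE by the delta method.
    """
    taus = list(taus)
    F = np.asarray([x[0] for x in taus], float)
    tau = np.asarray([x[1] for x in taus], float)
    tse = np.asarray([x[2] for x in taus], float)
    if len(np.unique(F)) < 3:
        raise ConfigError("need >= 3 distinct flux densities")
    rate = 1.0 / tau
    rse = tse / tau ** 2
    have_se = bool(np.all(np.isfinite(rse) & (rse > 0)))
    w = 1.0 / rse ** 2 if have_se else np.ones_like(rate)
    b0, b1, cov = _wls(F, rate, w, absolute=have_se)
    if b0 <= 0:
        raise FitError("no finite equilibrium time constant resolvable "
                       f"(intercept {b0:.3g} <= 0)")
    tau0 = 1.0 / b0
    tau0_se = float(np.sqrt(cov[0, 0]) / b0 ** 2)   # delta method
    return FluxCouplingFit(tau0=tau0, a=b1, tau0_se=tau0_se,
                           a_se=float(np.sqrt(cov[1, 1])),
                           fluxes=F, taus=tau, tau_ses=tse)


def rescale_time_axis(curves: Sequence[G2Curve], fit: FluxCouplingFit,
                      kww_fits: Optional[Sequence[KWWFit]] = None,
                      n_grid: int = 40):
    """Rescale each curve's lag axis by ``(1 + a F τ0)`` and score collapse.

    Under the coupling model ``τ(F) = τ0 / (1 + a F τ0)``, so
    ``t (1 + a F τ0)`` equals ``t/τ(F)`` up to the constant τ0 and the
    whole flux family falls on a single master decay; an unstimulated
    (F = 0) curve keeps its axis unchanged.

    The collapse score is the maximum over a common (log-spaced, overlapping)
    rescaled-lag grid of the spread across curves of the normalized decay
    ``(g2 - c)/β``; it is returned together with the pooled interpolated SE
    so callers can compare (a good collapse has score ≲ 3× pooled SE).
    """
    if kww_fits is None:
        kww_fits = [fit_kww(c) for c in curves]
    rescaled = []
    for c in curves:
        F = c.meta.get("flux_density") or 0.0
        factor = 1.0 + fit.a * F * fit.tau0
        rescaled.append(replace(c, lags=np.asarray(c.lags) * factor))
    lo = max(r.lags[0] for r in rescaled)
    hi = min(r.lags[-1] for r in rescaled)
    if hi <= lo:
        raise ConfigError("rescaled curves do not overlap in lag")
    grid = np.geomspace(lo, hi, n_grid)
    vals = []
    errs = []
    for r, kf in zip(rescaled, kww_fits):
        yn = (r.g2 - kf.c) / kf.beta
        en = r.se / kf.beta
        vals.append(np.interp(grid, r.lags, yn))
        errs.append(np.interp(grid, r.lags, en))
    vals = np.asarray(vals)
    errs = np.asarray(errs)
    spread = vals.max(axis=0) - vals.min(axis=0)
    score = float(spread.max())
    pooled_se = float(np.sqrt((errs ** 2).mean(axis=0)).max()) * np.sqrt(2.0)
    return rescaled, score, pooled_se


# --------------------------------------------------------------------------
# Arrhenius
# --------------------------------------------------------------------------

@dataclass
class ArrheniusFit:
    amplitude: float            # A, s
    activation_energy: float    # E_a, kJ/mol
    amplitude_se: float
    activation_energy_se: float
    temperatures: np.ndarray
    taus: np.ndarray


def fit_arrhenius(taus: Sequence) -> ArrheniusFit:
    """Weighted regression of ln τ on 1/T: ``τ(T) = A exp(E_a/(R T))``.

    ``taus``: sequence of ``(T [K], tau [s], tau_se [s])``.
    """
    taus = list(taus)
    T = np.asarray([x[0] for x in taus], float)
    tau = np.asarray([x[1] for x in taus], float)
    tse = np.asarray([x[2] for x in taus], float)
    if len(T) < 4:
        raise ConfigError("need >= 4 temperatures for an Arrhenius fit")
    if np.any(tau <= 0):
        raise ConfigError("non-positive relaxation time in Arrhenius input")
    x = 1.0 / T
    y = np.log(tau)
    yse = tse / tau
    have_se = bool(np.all(np.isfinite(yse) & (yse > 0)))
    w = 1.0 / yse ** 2 if have_se else np.ones_like(y)
    b0, b1, cov = _wls(x, y, w, absolute=have_se)
    ea = b1 * R_GAS / 1e3                      # kJ/mol
    ea_se = float(np.sqrt(cov[1, 1]) * R_GAS / 1e3)
    A = float(np.exp(b0))
    A_se = float(A * np.sqrt(cov[0, 0]))
    return ArrheniusFit(amplitude=A, activation_energy=float(ea),
                        amplitude_se=A_se, activation_energy_se=ea_se,
                        temperatures=T, taus=tau)


def correct_rate_for_flux(taus: Sequence, a: float, flux_density: float):
    """Unwind beam-stimulated coupling: ``1/τ0 = 1/τ - a F``.

    ``taus``: sequence of ``(T, tau, tau_se)``.  Returns the equivalent
    list with equilibrium ``tau0`` and delta-method SEs; temperatures whose
    corrected rate is non-positive (decay indistinguishable from the purely
    beam-driven limit) are dropped with a warning.
    """
    out = []
    aF = a * flux_density
    for T, tau, tse in taus:
        r0 = 1.0 / tau - aF
        if r0 <= 0:
            warnings.warn(f"T = {T} K: corrected rate non-positive; dropped",
                          stacklevel=2)
            continue
        r_se = tse / tau ** 2
        out.append((T, 1.0 / r0, r_se / r0 ** 2))
    return out


# --------------------------------------------------------------------------
# KWW-exponent minimum
# --------------------------------------------------------------------------

@dataclass
class MinimumFit:
    t_min: float                # K
    depth: float
    width: float                # K
    baseline: float             # alpha far from the dip
    t_min_se: float
    depth_se: float
    significant: bool
    fallback: bool = False      # argmin fallback used


def locate_kww_minimum(alphas: Sequence) -> MinimumFit:
    """Gaussian-dip fit ``α(T) = α_base - depth exp[-(T-T_min)²/(2 w²)]``.

    ``alphas``: sequence of ``(T, alpha, alpha_se)``.  On non-convergence
    falls back to the discrete argmin (ties toward lower temperature) with
    ``significant=False``.
    """
    alphas = sorted(alphas)
    T = np.asarray([x[0] for x in alphas], float)
    al = np.asarray([x[1] for x in alphas], float)
    se = np.asarray([x[2] for x in alphas], float)
    if len(T) < 5:
        raise ConfigError("need >= 5 temperatures spanning the minimum")
    weighted = np.all(np.isfinite(se) & (se > 0))
    sigma = se if weighted else None

    def model(t, base, depth, tmin, w):
        return base - depth * np.exp(-(t - tmin) ** 2 / (2.0 * w ** 2))

    # argmin with ties resolved toward lower temperature
    i_min = int(np.flatnonzero(al == al.min())[0])
    base0 = float(np.median(al))
    depth0 = max(base0 - al[i_min], 1e-3)
    p0 = [base0, depth0, float(T[i_min]), 10.0]
    lo = [0.0, 0.0, T[0], 1.0]
    hi = [3.0, 3.0, T[-1], (T[-1] - T[0])]
    try:
        popt, pcov = curve_fit(model, T, al, p0=p0, sigma=sigma,
                               absolute_sigma=weighted, bounds=(lo, hi),
                               maxfev=20000)
        base, depth, tmin, w = popt
        tmin_se = float(np.sqrt(pcov[2, 2]))
        depth_se = float(np.sqrt(pcov[1, 1]))
        # significance: the dip must both resolve its depth (>2 SE) and be
        # decisively preferred over a flat alpha(T) by AIC (delta > 10)
        wts = 1.0 / se ** 2 if weighted else np.ones_like(al)
        chi2_dip = float(np.sum(wts * (al - model(T, *popt)) ** 2))
        flat = float(np.sum(wts * al) / np.sum(wts))
        chi2_flat = float(np.sum(wts * (al - flat) ** 2))
        significant = bool(depth > 2.0 * depth_se
                           and (chi2_flat + 2.0) - (chi2_dip + 8.0) > 10.0)
        return MinimumFit(t_min=float(tmin), depth=float(depth),
                          width=float(w), baseline=float(base),
                          t_min_se=tmin_se, depth_se=depth_se,
                          significant=significant)
    except (RuntimeError, ValueError):
        return MinimumFit(t_min=float(T[i_min]), depth=depth0, width=np.nan,
                          baseline=base0, t_min_se=np.nan, depth_se=np.nan,
                          significant=False, fallback=True)
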