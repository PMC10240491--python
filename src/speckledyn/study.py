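"""Canonical synthetic-study runs: the recovery experiments of the package.

Each function generates synthetic speckle under the study conditions —
ground truths set to the reported experimental estimates (equilibrium time
constant 336 s and beam coupling 1.1e-8 um^2/ph for the flux family;
Arrhenius amplitude 1.8 s and activation energy 9.4 kJ/mol with
F = 1.5e6 ph/s/um^2 for the temperature scan; anomaly temperature 227 K;
fast/slow pair 26 s / 220 s at 230 K) — runs the full analysis chain and
returns the recovered quantities.  The problem sizes are chosen so each run
completes in well under a minute on a single core while leaving the
estimators comfortably inside their asymptotic regime.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .correlators import G2Curve, LagScheme, g2_from_series
from .kinetics import fit_kww, fit_q_dispersion
from .pipeline import AnalysisConfig, run_flux_experiment, \
    run_temperature_scan
from .synthetic import HeterogeneitySchedule, SimConfig, \
    render_two_state_stack
from . import correlators, heterogeneity
from .geometry import build_q_map

#: study ground truths (experimental estimates used as generator settings)
TAU0_TRUE_S = 336.0
COUPLING_A_TRUE = 1.1e-8          # um^2/ph
ARRHENIUS_A_TRUE_S = 1.8
ACTIVATION_ENERGY_TRUE = 9.4      # kJ/mol
SCAN_FLUX = 1.5e6                 # (ph/s)/um^2
T_ANOMALY = 227.0                 # K
FAST_TAU_TRUE_S = 26.0
SLOW_TAU_TRUE_S = 220.0


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(n)]


def flux_recovery(seed: int, out_dir, n_seeds: int = 5,
                  n_frames: int = 4000, n_pixels: int = 100) -> dict:
    """Recover (tau0, a) from synthetic flux families over several seeds.

    Six flux densities spanning 0-90% attenuation of the unattenuated
    4.4e6 (ph/s)/um^2 beam; one KWW fit per flux, then the weighted
    1/tau-vs-F regression.  Returns per-seed fits plus the across-seed
    mean and its standard error.
    """
    fits = []
    for s in _child_seeds(seed, n_seeds):
        cfg = AnalysisConfig(
            sim={"kind": "flux", "n_frames": n_frames, "n_pixels": n_pixels,
                 "tau0": TAU0_TRUE_S, "coupling_a": COUPLING_A_TRUE},
            q_targets=(0.08,), q_interest=0.08, seed=s)
        bundle = run_flux_experiment(cfg, f"{out_dir}/seed{s}")
        fits.append(bundle.results["flux_coupling"])
    # pool at the rate level: tau0 = 1/intercept is a skewed nonlinear
    # transform, so seeds are combined on the (linear, unbiased) intercept
    # before inverting
    rates0 = np.array([1.0 / f.tau0 for f in fits])
    rate_ses = np.array([f.tau0_se / f.tau0 ** 2 for f in fits])
    a_vals = np.array([f.a for f in fits])
    a_ses = np.array([f.a_se for f in fits])
    b_mean = rates0.mean()
    # SE of the pooled mean: the larger of the across-seed scatter estimate
    # (chi^2-noisy at 5 seeds) and the propagated per-fit jackknife errors
    b_se = max(rates0.std(ddof=1), float(np.sqrt(np.mean(rate_ses ** 2)))) \
        / np.sqrt(len(rates0))
    a_se = max(a_vals.std(ddof=1), float(np.sqrt(np.mean(a_ses ** 2)))) \
        / np.sqrt(len(a_vals))
    return {
        "fits": fits,
        "tau0_mean": float(1.0 / b_mean),
        "tau0_se": float(b_se / b_mean ** 2),
        "a_mean": float(a_vals.mean()),
        "a_se": float(a_se),
        "n": n_seeds * 6 * n_frames * n_pixels,
    }


def arrhenius_recovery(seed: int, out_dir, n_frames: int = 6000,
                       n_pixels: int = 150):
    """Temperature scan without heterogeneity; flux-corrected Arrhenius fit."""
    cfg = AnalysisConfig(
        sim={"kind": "tscan", "n_frames": n_frames, "n_pixels": n_pixels,
             "protocol": {}, "heterogeneity": None},
        q_targets=(0.1,), q_interest=0.1, seed=seed)
    bundle = run_temperature_scan(cfg, out_dir)
    return bundle.results["arrhenius"], bundle


def arrhenius_recovery_pooled(seed: int, out_dir, n_seeds: int = 3,
                              n_frames: int = 6000,
                              n_pixels: int = 150) -> dict:
    """Arrhenius recovery pooled over several independent scans.

    The flux correction amplifies tau noise by (tau0/tau)^2 at the lowest
    temperatures, so a single scan occasionally lands a 2-3 sigma slope
    excursion; pooling the regression coefficients (E_a is linear in the
    slope, ln A in the intercept) across seeds averages that out.  SEs take
    the larger of the across-seed scatter and the propagated per-fit errors.
    """
    fits = []
    for s in _child_seeds(seed, n_seeds):
        arr, _ = arrhenius_recovery(s, f"{out_dir}/seed{s}",
                                    n_frames=n_frames, n_pixels=n_pixels)
        fits.append(arr)
    ea = np.array([f.activation_energy for f in fits])
    ea_ses = np.array([f.activation_energy_se for f in fits])
    lnA = np.array([np.log(f.amplitude) for f in fits])
    lnA_ses = np.array([f.amplitude_se / f.amplitude for f in fits])
    ea_se = max(ea.std(ddof=1), float(np.sqrt(np.mean(ea_ses ** 2)))) \
        / np.sqrt(n_seeds)
    lnA_se = max(lnA.std(ddof=1), float(np.sqrt(np.mean(lnA_ses ** 2)))) \
        / np.sqrt(n_seeds)
    A = float(np.exp(lnA.mean()))
    return {"fits": fits,
            "activation_energy": float(ea.mean()),
            "activation_energy_se": float(ea_se),
            "amplitude": A,
            "amplitude_se": float(A * lnA_se),
            "n": n_seeds * 10 * n_frames * n_pixels}


def ballistic_exponent(seed: int, n_frames: int = 20000,
                       n_pixels: int = 200,
                       qs=(0.05, 0.08, 0.1, 0.15), q_report: float = 0.08):
    """KWW exponent and Q dispersion of the ballistic Lévy generator.

    mu = 1.5, no intermittency; independent pixel ensembles per q; reports
    the fitted alpha at ``q_report`` plus the dispersion fit over all q.
    """
    cfg = SimConfig(seed=seed, n_frames=n_frames, n_pixels=n_pixels,
                    q_targets=tuple(qs),
                    velocity_scale=SimConfig.velocity_for_tau(300.0, q_report))
    seeds = _child_seeds(seed, len(qs))
    lags = LagScheme().lags(n_frames)
    fits = []
    alpha_report = None
    fit_report = None
    from .synthetic import simulate_ballistic_series
    for q, s in zip(qs, seeds):
        rng = np.random.default_rng(s)
        series = simulate_ballistic_series(cfg, q, rng=rng)
        lag_s, g2, se, groups = g2_from_series(series, lags)
        curve = G2Curve(q=q, lags=lag_s, g2=g2, se=se, n_pixels=n_pixels,
                        n_frames=n_frames, meta={"frame_interval": 1.0},
                        group_g2=groups)
        f = fit_kww(curve)
        fits.append((q, f))
        if np.isclose(q, q_report):
            alpha_report = f.alpha
            fit_report = f
    dispersion = fit_q_dispersion(fits)
    return {"alpha": float(alpha_report), "fit": fit_report,
            "dispersion": dispersion, "fits": fits,
            "n": n_frames * n_pixels * len(qs)}


def anomaly_scan(seed: int, out_dir, n_frames: int = 6000,
                 n_pixels: int = 100):
    """Temperature scan with the heterogeneity schedule peaked at 227 K.

    Returns the Gaussian-dip fit of alpha(T), the chi_0(T) series with its
    peak temperature, and the full report bundle.
    """
    cfg = AnalysisConfig(
        sim={"kind": "tscan", "n_frames": n_frames, "n_pixels": n_pixels,
             "protocol": {}, "heterogeneity": {"t_star": T_ANOMALY}},
        q_targets=(0.1,), q_interest=0.1, seed=seed)
    bundle = run_temperature_scan(cfg, out_dir)
    return (bundle.results["kww_minimum"], bundle.results["chi0_series"],
            bundle)


def anomaly_scan_pooled(seed: int, out_dir, n_seeds: int = 3,
                        n_frames: int = 6000, n_pixels: int = 100) -> dict:
    """Anomaly localization averaged over several independent scans.

    Single-scan T_min / T_peak estimates scatter by ~2 K (the dip is
    sampled by only three grid temperatures); averaging unbiased estimates
    over seeds halves that without touching the study conditions.
    """
    t_mins, t_peaks, runs = [], [], []
    for s in _child_seeds(seed, n_seeds):
        minimum, chi0, _ = anomaly_scan(s, f"{out_dir}/seed{s}",
                                        n_frames=n_frames,
                                        n_pixels=n_pixels)
        t_mins.append(minimum.t_min)
        t_peaks.append(chi0.t_peak)
        runs.append((minimum, chi0))
    return {"t_min": float(np.mean(t_mins)),
            "t_min_se": float(np.std(t_mins, ddof=1) / np.sqrt(n_seeds)),
            "t_peak": float(np.mean(t_peaks)),
            "t_peak_se": float(np.std(t_peaks, ddof=1) / np.sqrt(n_seeds)),
            "runs": runs,
            "n": n_seeds * 10 * n_frames * n_pixels}


def two_state_timescales(seed: int, n_frames: int = 6000,
                         frame_interval: float = 2.0,
                         n_pixels: int = 100) -> dict:
    """Fast-timescale extraction from telegraph speckle at 230 K.

    The two-state process switches between the study's 26 s and 220 s
    constants (fast episodes ~300 s, slow ~800 s on average); the TTC
    sub-window analysis at the chi_T peak recovers the fast constant while
    the global KWW fit sees the occupancy-weighted mixture.
    """
    het = HeterogeneitySchedule(rate_to_fast=1.0 / 800.0,
                                rate_to_slow=1.0 / 300.0,
                                fast_tau=FAST_TAU_TRUE_S,
                                slow_tau=SLOW_TAU_TRUE_S, t_star=230.0)
    base = SimConfig(seed=seed, n_frames=n_frames,
                     frame_interval=frame_interval, n_pixels=n_pixels)
    stack = render_two_state_stack(het, base, q=0.1, temperature_k=230.0)
    qmap = build_q_map(stack.geometry,
                       {"kind": "targets", "centers": [0.1],
                        "rel_width": 0.1})
    curve = correlators.compute_g2(stack, qmap, 0)
    global_fit = fit_kww(curve)
    contrast = correlators.estimate_contrast(stack, qmap, 0)
    ttc = correlators.compute_ttc(stack, qmap, 0)
    chi = heterogeneity.compute_chi_T(ttc, contrast,
                                      rng=np.random.default_rng(seed))
    chi0, dt_peak, _ = heterogeneity.chi_max(chi)
    tau_fast, window_taus = heterogeneity.timescale_at_chi_peak(ttc, chi)
    truth = stack.meta["truth"]
    return {"tau_fast": tau_fast, "window_taus": window_taus,
            "tau_global": global_fit.tau, "global_fit": global_fit,
            "mixture_mean": truth["mixture_mean_tau_s"],
            "chi0": chi0, "dt_peak": dt_peak,
            "n": n_frames * n_pixels}
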