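"""Synthetic speckle generators with known ground-truth dynamics.

Two independent generative routes are provided so each can validate the
other:

* a *physical* route (`simulate_ballistic_series`): a sum of point
  scatterers moving ballistically with velocities drawn from a symmetric
  Lévy-stable law of index μ.  The field correlation between stress-release
  events is the stable characteristic function, ``exp[-(c·q·t)^μ]``, so the
  KWW exponent recovered by the analysis equals μ and the decay rate
  ``1/τ = c·q`` is linear in q — ballistic dispersion by construction.
* a *statistical* route (`generate_kww_oracle_series`): a stationary complex
  Gaussian process with autocorrelation ``exp[-(t/τ)^α]`` drawn by circulant
  spectral embedding (the stretched exponential is positive definite for
  α ≤ 2).  Its g2 is ``1 + β·exp[-2(t/τ)^α]`` exactly, independent of any
  scatterer model.

Dynamical heterogeneity is modeled as a two-state telegraph process that
switches the relaxation time between a fast and a slow value, shared by all
pixels of a stack (the switching is a collective event, which is what makes
it visible as fluctuations of the two-time correlation and as a peak of the
dynamic susceptibility).  Its strength follows a temperature schedule peaked
at a configurable anomaly temperature.
"""

from __future__ import annotations

import functools
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.stats import levy_stable

from .exceptions import ConfigError, SpeckledynError
from .geometry import DetectorGeometry, build_q_map
from .stacks import FrameStack

#: molar gas constant [J/(mol K)] — activation energies are per mole
R_GAS = 8.314462618

#: Lévy draws are truncated at this two-sided tail probability to avoid
#: overflow from extreme excursions; a controlled, documented bias.
LEVY_TAIL_PROB = 1e-6


# --------------------------------------------------------------------------
# configuration types
# --------------------------------------------------------------------------

@dataclass
class HeterogeneitySchedule:
    """Two-state (telegraph) dynamical switching and its temperature profile.

    ``fast_tau``/``slow_tau`` are the state relaxation times realized at full
    intermittency strength; ``rate_to_fast`` (slow→fast) and ``rate_to_slow``
    (fast→slow) set the switching statistics, so the stationary fraction of
    time in the fast state is ``rate_to_fast/(rate_to_fast+rate_to_slow)``.
    The strength ``amplitude(T) ∈ [0, 1]`` is a Gaussian bump peaked at
    ``t_star`` — the simplest stationary profile with a unique maximum.
    """

    rate_to_fast: float = 1.0 / 500.0   # 1/s, slow -> fast
    rate_to_slow: float = 1.0 / 250.0   # 1/s, fast -> slow
    fast_tau: float = 26.0              # s
    slow_tau: float = 220.0             # s
    t_star: float = 227.0               # K
    width_k: float = 8.0                # K
    peak_amplitude: float = 1.0
    amplitude_fn: Optional[Callable[[float], float]] = None

    def __post_init__(self):
        if not (self.fast_tau < self.slow_tau):
            raise ConfigError("fast_tau must be smaller than slow_tau")
        if self.rate_to_fast <= 0 or self.rate_to_slow <= 0:
            raise ConfigError("switching rates must be positive")
        if not (0 <= self.peak_amplitude <= 1):
            raise ConfigError("peak amplitude must lie in [0, 1]")

    @property
    def p_fast(self) -> float:
        return self.rate_to_fast / (self.rate_to_fast + self.rate_to_slow)

    def amplitude(self, temperature_k: float) -> float:
        if self.amplitude_fn is not None:
            a = float(self.amplitude_fn(temperature_k))
        else:
            a = self.peak_amplitude * float(
                np.exp(-(temperature_k - self.t_star) ** 2
                       / (2.0 * self.width_k ** 2)))
        if not (0.0 <= a <= 1.0):
            raise ConfigError("amplitude_vs_T must lie in [0, 1]")
        return a


@dataclass
class TemperatureProtocol:
    """Ground-truth thermal and flux parameters of a temperature scan.

    ``tau0(T) = A exp(E_a / (R T))`` is the equilibrium (zero-flux) time
    constant; the observed constant under beam-stimulated relaxation is
    ``tau = 1 / (1/tau0 + a F)``.
    """

    temperatures: tuple = (290.0, 270.0, 250.0, 240.0, 230.0,
                           225.0, 220.0, 210.0, 195.0, 180.0)   # K
    flux_density: float = 1.5e6          # (ph/s)/um^2
    tau0_amplitude: float = 1.8          # s (A)
    activation_energy: float = 9.4       # kJ/mol (E_a)
    coupling_a: float = 1.1e-8           # um^2/ph

    def __post_init__(self):
        t = np.asarray(self.temperatures, dtype=float)
        d = np.diff(t)
        if len(t) >= 2 and not (np.all(d > 0) or np.all(d < 0)):
            raise ConfigError("temperatures must be strictly monotone")
        for name in ("flux_density", "tau0_amplitude", "activation_energy"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.coupling_a < 0:
            raise ConfigError("coupling_a must be non-negative")

    def tau0(self, temperature_k: float) -> float:
        return self.tau0_amplitude * float(
            np.exp(self.activation_energy * 1e3 / (R_GAS * temperature_k)))

    def tau_observed(self, temperature_k: float) -> float:
        return 1.0 / (1.0 / self.tau0(temperature_k)
                      + self.coupling_a * self.flux_density)


@dataclass
class SimConfig:
    """Full generative specification for one synthetic stack."""

    n_scatterers: int = 50
    levy_index: float = 1.5            # μ in (0, 2]
    velocity_scale: float = 1.0 / (0.1 * 50.0)   # nm/s (stable scale c)
    event_rate: float = 0.0            # 1/s per scatterer, velocity redraws
    n_modes: int = 2                   # M; speckle contrast β = 1/M
    mean_counts: float = 20.0          # photons/pixel/frame
    frame_interval: float = 1.0        # s
    n_frames: int = 4000
    q_targets: tuple = (0.05, 0.08, 0.1, 0.15)   # 1/nm
    seed: int = 0
    hydration_h: float = 0.28          # g water / g protein, metadata
    n_pixels: int = 100                # independent speckle realizations per q
    het_schedule: Optional[HeterogeneitySchedule] = None

    def __post_init__(self):
        if not (0 < self.levy_index <= 2):
            raise ConfigError("levy_index must lie in (0, 2]")
        if self.n_modes < 1:
            raise ConfigError("n_modes must be >= 1")
        if self.mean_counts <= 0:
            raise ConfigError("mean_counts must be positive")
        if self.frame_interval <= 0:
            raise ConfigError("frame_interval must be positive")
        if any(q <= 0 for q in self.q_targets):
            raise ConfigError("all q_targets must be positive")
        if self.n_scatterers < 2:
            raise ConfigError("need at least 2 scatterers")
        if self.event_rate < 0:
            raise ConfigError("event_rate must be non-negative")

    @property
    def beta(self) -> float:
        return 1.0 / self.n_modes

    def tau_at(self, q: float) -> float:
        """Ground-truth relaxation time at momentum transfer ``q`` [s]."""
        if self.velocity_scale == 0:
            return float("inf")
        return 1.0 / (self.velocity_scale * q)

    @staticmethod
    def velocity_for_tau(tau: float, q: float) -> float:
        """Stable scale parameter giving relaxation time ``tau`` at ``q``."""
        return 1.0 / (q * tau)


# --------------------------------------------------------------------------
# telegraph switching
# --------------------------------------------------------------------------

def telegraph_sequence(rng: np.random.Generator, n_frames: int, dt: float,
                       rate_to_fast: float, rate_to_slow: float) -> np.ndarray:
    """Boolean per-frame state sequence (True = fast), stationary start."""
    p_fast = rate_to_fast / (rate_to_fast + rate_to_slow)
    state = bool(rng.random() < p_fast)
    seq = np.empty(n_frames, dtype=bool)
    t = 0
    while t < n_frames:
        rate = rate_to_slow if state else rate_to_fast
        hold = max(1, int(np.ceil(rng.exponential(1.0 / rate) / dt)))
        seq[t:t + hold] = state
        t += hold
        state = not state
    return seq


# --------------------------------------------------------------------------
# physical route: ballistic Lévy scatterers
# --------------------------------------------------------------------------

@functools.lru_cache(maxsize=32)
def _levy_trunc_quantile(mu: float) -> float:
    """Two-sided truncation bound (unit scale) at total tail mass 1e-6."""
    return float(levy_stable.ppf(1.0 - LEVY_TAIL_PROB / 2.0, mu, 0.0))


def _draw_levy_velocities(rng, mu, scale, size):
    v = levy_stable.rvs(mu, 0.0, scale=scale, size=size, random_state=rng)
    bad = ~np.isfinite(v)
    if bad.any():
        warnings.warn(f"resampling {int(bad.sum())} non-finite Lévy draws",
                      stacklevel=2)
    bound = _levy_trunc_quantile(mu) * scale
    bad |= np.abs(v) > bound
    while bad.any():
        v[bad] = levy_stable.rvs(mu, 0.0, scale=scale, size=int(bad.sum()),
                                 random_state=rng)
        bad = (~np.isfinite(v)) | (np.abs(v) > bound)
    return v


def simulate_ballistic_series(cfg: SimConfig, q: float, *,
                              rng: Optional[np.random.Generator] = None,
                              state_seq: Optional[np.ndarray] = None,
                              tau_multipliers: tuple = (1.0, 1.0),
                              poisson: bool = True) -> np.ndarray:
    """Photon-count series for ``cfg.n_pixels`` independent speckles at ``q``.

    Each pixel is an independent realization of the complex field
    ``E(t) = Σ_j exp(i q x_j(t))`` over ``n_scatterers`` scatterers whose
    velocities are symmetric Lévy-stable draws of index ``levy_index``;
    positions advance ballistically between Poisson-timed velocity redraws
    (rate ``event_rate`` per scatterer).  The per-pixel intensity sums
    ``n_modes`` independent mode realizations (contrast β = 1/M) and is
    Poisson-sampled at ``mean_counts`` unless ``poisson=False``.

    ``state_seq`` (True = fast) with ``tau_multipliers = (m_fast, m_slow)``
    applies the telegraph time-warp: in a state with multiplier ``m`` the
    phases advance ``m`` times faster, i.e. the instantaneous relaxation
    time is ``tau/m``.

    Returns an array of shape ``(n_frames, n_pixels)``.
    """
    if q <= 0:
        raise ConfigError("q must be positive")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n_rows = cfg.n_pixels * cfg.n_modes
    shape = (n_rows, cfg.n_scatterers)

    if cfg.velocity_scale == 0:
        v = np.zeros(shape)
    else:
        v = _draw_levy_velocities(rng, cfg.levy_index, cfg.velocity_scale,
                                  shape)
    theta0 = rng.uniform(0.0, 2.0 * np.pi, shape)
    step = q * v * cfg.frame_interval          # phase advance per frame
    W = np.exp(1j * theta0)

    m_fast, m_slow = tau_multipliers
    if state_seq is not None and len(state_seq) != cfg.n_frames:
        raise ConfigError("state_seq length must equal n_frames")
    z_fast = np.exp(1j * step * m_fast)
    z_slow = np.exp(1j * step * m_slow) if m_slow != m_fast else z_fast

    p_event = cfg.event_rate * cfg.frame_interval
    n_events = (rng.binomial(v.size, min(p_event, 1.0), size=cfg.n_frames)
                if p_event > 0 else None)

    intens = np.empty((cfg.n_frames, cfg.n_pixels))
    for t in range(cfg.n_frames):
        E = W.reshape(cfg.n_pixels, cfg.n_modes, cfg.n_scatterers).sum(axis=2)
        intens[t] = (E.real ** 2 + E.imag ** 2).sum(axis=1)
        if n_events is not None and n_events[t]:
            flat = rng.integers(0, v.size, n_events[t])
            vv = _draw_levy_velocities(rng, cfg.levy_index,
                                       cfg.velocity_scale, n_events[t])
            v.ravel()[flat] = vv
            s = q * vv * cfg.frame_interval
            z_fast.ravel()[flat] = np.exp(1j * s * m_fast)
            if z_slow is not z_fast:
                z_slow.ravel()[flat] = np.exp(1j * s * m_slow)
        if state_seq is not None and state_seq[t]:
            W *= z_fast
        else:
            W *= z_slow if state_seq is not None else z_fast
    scale = cfg.mean_counts / (cfg.n_modes * cfg.n_scatterers)
    if poisson:
        return rng.poisson(intens * scale).astype(np.float64)
    return intens * scale


# --------------------------------------------------------------------------
# statistical route: Gaussian-field KWW oracle
# --------------------------------------------------------------------------

def embedding_eigenvalues(tau: float, alpha: float, n_frames: int,
                          frame_interval: float = 1.0,
                          factor: int = 4) -> np.ndarray:
    """Circulant-embedding eigenvalues of ``exp[-(t/tau)^alpha]``."""
    length = factor * n_frames
    k = np.arange(length)
    d = np.minimum(k, length - k) * frame_interval
    r = np.exp(-(d / tau) ** alpha) if np.isfinite(tau) else np.ones(length)
    return np.fft.fft(r).real


def generate_kww_oracle_series(tau: float, alpha: float, beta: float,
                               n_frames: int, frame_interval: float = 1.0,
                               seed: int = 0, *, n_pixels: int = 100,
                               mean_counts: Optional[float] = None,
                               poisson: bool = False,
                               rng: Optional[np.random.Generator] = None,
                               factor: int = 4) -> np.ndarray:
    """Intensity series whose expected g2 is ``1 + β exp[-2(t/τ)^α]`` exactly.

    Draws stationary circular complex Gaussian processes with autocorrelation
    ``exp[-(t/τ)^α]`` by circulant spectral embedding and averages
    ``M = round(1/β)`` squared-magnitude realizations per pixel.  This path
    never touches the scatterer model, so it serves as the independent
    oracle for the whole correlator/fitting chain.
    """
    if not (0 < alpha <= 2):
        raise ConfigError("alpha must lie in (0, 2] (positive definiteness)")
    if tau <= 0:
        raise ConfigError("tau must be positive")
    m_modes = int(round(1.0 / beta))
    if m_modes < 1 or abs(1.0 / m_modes - beta) > 1e-9:
        raise ConfigError("beta must equal 1/M for an integer mode count M")
    if rng is None:
        rng = np.random.default_rng(seed)

    lam = embedding_eigenvalues(tau, alpha, n_frames, frame_interval, factor)
    tol = -1e-10 * lam.max()
    if lam.min() < tol:
        lam = embedding_eigenvalues(tau, alpha, n_frames, frame_interval,
                                    2 * factor)
        if lam.min() < -1e-10 * lam.max():
            raise SpeckledynError(
                "circulant embedding not positive definite; "
                f"min eigenvalue {lam.min():.3e}")
    lam = np.maximum(lam, 0.0)
    length = len(lam)
    amp = np.sqrt(lam / 2.0)

    total_rows = n_pixels * m_modes
    out = np.zeros((n_frames, n_pixels))
    chunk = max(1, int(64e6 / (16 * length)))   # cap scratch memory
    row = 0
    while row < total_rows:
        nr = min(chunk, total_rows - row)
        x = amp * (rng.standard_normal((nr, length))
                   + 1j * rng.standard_normal((nr, length)))
        e = np.sqrt(length) * np.fft.ifft(x, axis=1)[:, :n_frames]
        ii = (e.real ** 2 + e.imag ** 2)
        # accumulate into the pixels these mode-rows belong to
        for j in range(nr):
            out[:, (row + j) // m_modes] += ii[j]
        row += nr
    out /= m_modes
    if mean_counts is not None:
        out *= mean_counts            # E|e|^2 = 1 already
        if poisson:
            out = rng.poisson(out).astype(np.float64)
    return out


def kww_g2_expected(t, tau, alpha, beta, baseline=1.0):
    """Analytic g2 of the oracle process (Siegert relation)."""
    t = np.asarray(t, dtype=float)
    return baseline + beta * np.exp(-2.0 * (t / tau) ** alpha)


# --------------------------------------------------------------------------
# frame-stack rendering
# --------------------------------------------------------------------------

def default_synthetic_geometry() -> DetectorGeometry:
    """Compact detector placing Q = 0.05–0.15 1/nm rings on a 96x96 grid.

    Not a beamline geometry: the distance is shortened so the analysis
    annuli fit a small detector, keeping synthetic stacks light.  The Q
    computation path is identical to the experimental-geometry one.
    """
    return DetectorGeometry(photon_energy_kev=12.4, sdd_m=1.2018,
                            pixel_size_um=75.0, beam_center=(48.0, 48.0),
                            shape=(96, 96))


def render_frame_stack(cfg: SimConfig, geometry: Optional[DetectorGeometry] = None,
                       *, temperature_k: Optional[float] = None,
                       flux_density: Optional[float] = None,
                       state_seq: Optional[np.ndarray] = None,
                       tau_multipliers: tuple = (1.0, 1.0),
                       truth_extra: Optional[dict] = None,
                       poisson: bool = True) -> FrameStack:
    """Render a FrameStack whose annulus pixels at each ``q_target`` carry
    independent realizations of the configured dynamics at that q.

    Ground-truth parameters are embedded in ``stack.meta['truth']`` for
    recovery tests; identical config + seed gives a bit-identical stack.
    """
    if geometry is None:
        geometry = default_synthetic_geometry()
    qmap = build_q_map(geometry, {"kind": "targets",
                                  "centers": list(cfg.q_targets),
                                  "rel_width": 0.1})
    q_sorted = np.sort(np.asarray(cfg.q_targets, dtype=float))
    qmax = geometry.q_of_radius(geometry.radius_m().max())
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(len(q_sorted))

    frames = np.zeros((cfg.n_frames,) + tuple(geometry.shape), dtype=np.uint32)
    mask = np.zeros(geometry.shape, dtype=bool)
    tau_per_q = {}
    for qi, (q, child) in enumerate(zip(q_sorted, children)):
        sel = qmap.pixels_in_bin(qi)
        n_avail = int(sel.sum())
        if n_avail < 50:
            raise ConfigError(
                f"q target {q:.4g} 1/nm maps to {n_avail} pixels (<50); "
                f"valid q interval on this detector is (0, {qmax:.4g}]")
        flat = np.flatnonzero(sel.ravel())
        if n_avail > cfg.n_pixels:
            keep = flat[np.linspace(0, n_avail - 1, cfg.n_pixels).astype(int)]
        else:
            keep = flat
        rng = np.random.default_rng(child)
        series = simulate_ballistic_series(
            cfg, q, rng=rng, state_seq=state_seq,
            tau_multipliers=tau_multipliers, poisson=poisson)
        series = series[:, :len(keep)] if series.shape[1] >= len(keep) else series
        rows, cols = np.unravel_index(keep[:series.shape[1]], geometry.shape)
        frames[:, rows, cols] = np.round(series).astype(np.uint32)
        mask[rows, cols] = True
        tau_per_q[float(q)] = cfg.tau_at(q)

    truth = {
        "levy_index": cfg.levy_index,
        "beta": cfg.beta,
        "mean_counts": cfg.mean_counts,
        "tau_per_q_s": {f"{k:.6g}": v for k, v in tau_per_q.items()},
        "event_rate": cfg.event_rate,
        "seed": cfg.seed,
        "tau_multipliers": list(tau_multipliers),
    }
    if truth_extra:
        truth.update(truth_extra)
    meta = {"sample_id": "synthetic-hydrated-protein",
            "hydration_h": cfg.hydration_h, "seed": cfg.seed, "truth": truth}
    timestamps = np.arange(cfg.n_frames, dtype=float) * cfg.frame_interval
    return FrameStack(images=frames, timestamps=timestamps, geometry=geometry,
                      mask=mask, temperature_k=temperature_k,
                      flux_density=flux_density, meta=meta)


def render_two_state_stack(het: HeterogeneitySchedule, base: SimConfig,
                           *, q: float = 0.1, temperature_k: float = 230.0,
                           geometry: Optional[DetectorGeometry] = None
                           ) -> FrameStack:
    """Stack with full-strength telegraph switching between the schedule's
    absolute fast/slow relaxation times at one temperature.

    The scatterer velocity scale is set so the *geometric mean* of the two
    state times is realized at ``q``; the telegraph multiplier
    ``g = sqrt(slow_tau/fast_tau)`` then makes the fast state relax at
    exactly ``fast_tau`` and the slow state at ``slow_tau``.
    """
    tau_c = float(np.sqrt(het.fast_tau * het.slow_tau))
    g = float(np.sqrt(het.slow_tau / het.fast_tau))
    cfg = replace(base, q_targets=(q,),
                  velocity_scale=SimConfig.velocity_for_tau(tau_c, q))
    ss = np.random.SeedSequence(cfg.seed)
    rng_state = np.random.default_rng(ss.spawn(1)[0])
    seq = telegraph_sequence(rng_state, cfg.n_frames, cfg.frame_interval,
                             het.rate_to_fast, het.rate_to_slow)
    truth = {"temperature_k": temperature_k, "fast_tau_s": het.fast_tau,
             "slow_tau_s": het.slow_tau, "p_fast": het.p_fast,
             "occupancy_fast": float(seq.mean()),
             "mixture_mean_tau_s": float(seq.mean() * het.fast_tau
                                         + (1 - seq.mean()) * het.slow_tau)}
    return render_frame_stack(cfg, geometry, temperature_k=temperature_k,
                              state_seq=seq, tau_multipliers=(g, 1.0 / g),
                              truth_extra=truth)


def generate_temperature_scan(protocol: TemperatureProtocol,
                              het: Optional[HeterogeneitySchedule],
                              base: SimConfig,
                              geometry: Optional[DetectorGeometry] = None
                              ) -> list[FrameStack]:
    """One FrameStack per protocol temperature with Arrhenius + flux-coupled
    ground truth and, optionally, telegraph heterogeneity.

    At each T the equilibrium constant is ``tau0(T) = A exp(E_a/(R T))`` and
    the observed constant ``tau = 1/(1/tau0 + a F)``; the scatterer velocity
    scale is set so that the first (reference) q target relaxes at that tau.
    With a schedule, the telegraph state multiplies the relaxation time by
    ``g^(±amplitude(T))`` with ``g = sqrt(slow_tau/fast_tau)``, preserving
    the geometric-mean tau while opening a fast/slow split whose full ratio
    matches the configured pair.
    """
    ss = np.random.SeedSequence(base.seed)
    children = ss.spawn(len(protocol.temperatures))
    q_ref = float(base.q_targets[0])
    stacks = []
    for temp, child in zip(protocol.temperatures, children):
        tau0 = protocol.tau0(temp)
        tau_obs = protocol.tau_observed(temp)
        seed_t = int(child.generate_state(1)[0] % (2 ** 31))
        cfg_t = replace(base, seed=seed_t,
                        velocity_scale=SimConfig.velocity_for_tau(tau_obs, q_ref))
        amp = het.amplitude(temp) if het is not None else 0.0
        state_seq = None
        mult = (1.0, 1.0)
        if het is not None and amp > 0:
            g = np.sqrt(het.slow_tau / het.fast_tau)
            mult = (g ** amp, g ** (-amp))     # (m_fast, m_slow)
            rng_state = np.random.default_rng(child.spawn(1)[0])
            state_seq = telegraph_sequence(rng_state, cfg_t.n_frames,
                                           cfg_t.frame_interval,
                                           het.rate_to_fast, het.rate_to_slow)
        truth_extra = {
            "temperature_k": temp, "tau0_s": tau0, "tau_observed_s": tau_obs,
            "arrhenius_A_s": protocol.tau0_amplitude,
            "activation_energy_kj_mol": protocol.activation_energy,
            "coupling_a_um2_per_ph": protocol.coupling_a,
            "flux_density": protocol.flux_density,
            "het_amplitude": amp,
            "het_p_fast": het.p_fast if het is not None else 0.0,
        }
        stacks.append(render_frame_stack(
            cfg_t, geometry, temperature_k=temp,
            flux_density=protocol.flux_density, state_seq=state_seq,
            tau_multipliers=mult, truth_extra=truth_extra))
    return stacks
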