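# speckledyn

XPCS (X-ray Photon Correlation Spectroscopy) analysis of beam-stimulated
nanoscale dynamics in soft, granular samples — built around the study of
hydrated protein powders, where the coherent X-ray beam itself stimulates
collective stress–relaxation and the speckle fluctuations encode its
kinetics down to deeply supercooled temperatures.

The package provides, as importable library code plus numbered analysis
drivers:

* **Correlators** — the intensity autocorrelation
  `g2(Q, t) = ⟨I(Q, t0) I(Q, t0+t)⟩ / (⟨I(Q, t0)⟩⟨I(Q, t0+t)⟩)`
  averaged over start times and the pixels of a Q annulus, with
  pixel-jackknife errors; the two-time correlation matrix
  `C(Q; t1, t2) = ⟨I(t1) I(t2)⟩_pix / (⟨I(t1)⟩_pix ⟨I(t2)⟩_pix)`;
  speckle-contrast estimators.
* **Kinetics fits** — the Kohlrausch–Williams–Watts model
  `g2(t) = β exp[−2 (t/τ)^α] + c` (compressed, α > 1, for ballistic
  stress-release dynamics); Q dispersion of the rate (ballistic test:
  `1/τ ∝ Q`); the flux-coupling model `1/τ = 1/τ0 + a·F` with time-axis
  rescaling and collapse scoring; the Arrhenius law
  `τ(T) = A·exp(E_a / R T)`; Gaussian-dip localization of the α(T)
  minimum.
* **Dynamic susceptibility** — the normalized variance of the two-time
  correlation along its diagonal,
  `χ_T(δt) = var_t[C(t, t+δt)] / β²`, its maximum χ₀, the χ₀(T) peak,
  and the local (sub-window) relaxation time of the epochs that drive the
  peak.
* **Synthetic speckle generators** with exactly known ground truth: a
  physical route (point scatterers with Lévy-stable velocities, giving a
  compressed exponential with exponent equal to the Lévy index and a decay
  rate linear in Q) and an independent statistical route (circulant-embedded
  complex Gaussian fields with prescribed `exp[−(t/τ)^α]` correlation).
  Detector geometry, Q maps, masking, azimuthal averaging and HDF5 I/O
  round out the chain.

## Worked example

Recover the flux-coupling constants from a synthetic six-flux family
(ground truths: τ0 = 336 s, a = 1.1×10⁻⁸ μm²/ph):

```python
from speckledyn.pipeline import AnalysisConfig, run_flux_experiment

cfg = AnalysisConfig(sim={"kind": "flux", "n_frames": 4000},
                     q_targets=(0.08,), q_interest=0.08, seed=1)
bundle = run_flux_experiment(cfg, "out/flux")
f = bundle.results["flux_coupling"]
print(f"tau0 = {f.tau0:.0f} +- {f.tau0_se:.0f} s, "
      f"a = {f.a:.3g} +- {f.a_se:.2g} um^2/ph")
```

prints

```
tau0 = 334 +- 33 s, a = 1.11e-08 +- 1.7e-10 um^2/ph
```

i.e. the equilibrium relaxation time extrapolated to zero flux and the
beam-coupling constant, both consistent with their generative values; the
rescaled curves collapse onto a single master decay (collapse score below
3× the pooled statistical error).

The numbered drivers run the full synthetic study and write their tables
under `results/`:

```
python analysis/01_flux_dependence.py        # tau0, a recovery
python analysis/02_temperature_scan.py       # Arrhenius E_a, A recovery
python analysis/03_heterogeneity_anomaly.py  # alpha(T) dip + chi_0(T) peak at 227 K
python analysis/04_fast_timescale.py         # 26 s fast constant from TTC windows
```

A `speckledyn` CLI (`simulate`, `analyze flux|tscan`, `demo`) wraps the
same pipeline for shell use.

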