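import numpy as np
import pytest

import speckledyn as sd


@pytest.fixture(scope="session")
def small_geometry():
    """Compact detector used across tests (rings at 0.05-0.15 1/nm)."""
    return sd.default_synthetic_geometry()


@pytest.fixture(scope="session")
def ring_stack():
    """Small rendered stack with known dynamics at Q = 0.1 1/nm.

    Ground truth: tau = 50 s, alpha (Levy index) = 1.5, beta = 0.5.
    """
    cfg = sd.SimConfig(seed=123, n_frames=3000, n_pixels=80,
                       q_targets=(0.1,),
                       velocity_scale=sd.SimConfig.velocity_for_tau(50.0, 0.1))
    return sd.render_frame_stack(cfg, temperature_k=300.0)


@pytest.fixture(scope="session")
def ring_qmap(ring_stack):
    return sd.build_q_map(ring_stack.geometry,
                          {"kind": "targets", "centers": [0.1],
                           "rel_width": 0.1})


def make_curve(lags_s, g2, se=None, q=0.1, dt=1.0, n_pixels=100,
               flux=None):
    lags_s = np.asarray(lags_s, dtype=float)
    if se is None:
        se = np.full(len(lags_s), 1e-3)
    meta = {"frame_interval": dt}
    if flux is not None:
        meta["flux_density"] = flux
    return sd.G2Curve(q=q, lags=lags_s, g2=np.asarray(g2, dtype=float),
                      se=np.asarray(se, dtype=float), n_pixels=n_pixels,
                      n_frames=int(lags_s[-1] / dt) + 1, meta=meta)
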