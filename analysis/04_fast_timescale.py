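"""Fast intrinsic timescale at the chi_T peak.

Simulates two-state telegraph speckle at 230 K switching between the 26 s
and 220 s relaxation constants, computes the TTC and chi_T, and extracts
the local relaxation time of the epochs that drive the variance peak.
The sub-window analysis should recover the fast constant while the global
KWW fit reports the occupancy-weighted mixture.

Writes a JSON summary under results/two_state/.
"""

import json
import sys
import warnings
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
warnings.filterwarnings("ignore")

from speckledyn import study          # noqa: E402

OUT = Path(__file__).resolve().parents[1] / "results" / "two_state"


def main(seed: int = 4):
    res = study.two_state_timescales(seed)
    print(f"chi_T peak at dt = {res['dt_peak']:.0f} s, chi_0 = "
          f"{res['chi0']:.2f}")
    print(f"fast timescale from TTC sub-windows: {res['tau_fast']:.1f} s "
          f"(ground truth {study.FAST_TAU_TRUE_S} s)")
    print(f"global KWW tau: {res['tau_global']:.0f} s "
          f"(occupancy-weighted mixture mean {res['mixture_mean']:.0f} s)")
    OUT.mkdir(parents=True, exist_ok=True)
    payload = {k: (float(res[k]) if k != "window_taus" else
                   [float(x) for x in res[k]])
               for k in ("tau_fast", "tau_global", "mixture_mean", "chi0",
                         "dt_peak", "window_taus")}
    with open(OUT / "two_state_summary.json", "w") as fh:
        json.dump(payload, fh, indent=1)
    print(f"artifacts under {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 4)
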