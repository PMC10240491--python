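"""Speckle intensity correlators: g2, two-time correlation, contrast.

Normalization convention: both g2 and the TTC use the *symmetric*
(two-time-mean) normalization,

    g2(t) = <I(t0) I(t0+t)> / (<I(t0)> <I(t0+t)>),

with averages over pixels of the Q bin and (for g2) over start times t0.
Under stationarity this reduces to the single-squared-mean form; under slow
drift it is markedly less biased, which is why it is the default here.

The multi-tau lag *grid* (16 channels per level, doubling spacing) is the
default lag scheme, but correlation values are always evaluated exactly at
those lags by an O(N·n_lags) sweep — no per-level intensity pre-averaging,
hence no pre-averaging bias and exact agreement with the brute-force
reference correlator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .exceptions import ConfigError, DegenerateInputError
from .geometry import QMap
from .stacks import FrameStack


# --------------------------------------------------------------------------
# lag schemes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LagScheme:
    """Lag grid specification.

    ``kind``: ``"multitau"`` (channels per level, doubling spacing),
    ``"linear"`` (every lag up to ``max_lag``), or ``"list"`` (explicit lags
    in frames).
    """

    kind: str = "multitau"
    channels: int = 16
    max_lag: Optional[int] = None
    lag_list: Optional[tuple] = None

    def lags(self, n_frames: int) -> np.ndarray:
        """Strictly increasing integer lags (frames), each < n_frames."""
        limit = self.max_lag or n_frames - 1
        limit = min(limit, n_frames - 1)
        if self.kind == "linear":
            out = np.arange(1, limit + 1)
        elif self.kind == "list":
            out = np.asarray(sorted(set(int(l) for l in self.lag_list)))
        elif self.kind == "multitau":
            ch = self.channels
            lags = list(range(1, ch + 1))
            step = 2
            while lags[-1] < limit:
                start = lags[-1] + step
                if start > limit:
                    break
                lags.extend(range(start,
                                  min(start + step * (ch // 2), limit + 1),
                                  step))
                step *= 2
            out = np.asarray(lags)
        else:
            raise ConfigError(f"unknown lag scheme kind {self.kind!r}")
        if np.any(out < 1):
            raise ConfigError("lags must be >= 1 frame")
        dropped = out[out >= n_frames]
        if dropped.size:
            warnings.warn(f"dropping {dropped.size} lags >= n_frames",
                          stacklevel=2)
        return out[out < n_frames]


# --------------------------------------------------------------------------
# result containers
# --------------------------------------------------------------------------

@dataclass
class G2Curve:
    q: float                    # 1/nm
    lags: np.ndarray            # seconds
    g2: np.ndarray
    se: np.ndarray              # jackknife standard errors
    n_pixels: int
    n_frames: int
    meta: dict = field(default_factory=dict)   # T, F, provenance
    group_g2: Optional[np.ndarray] = None      # jackknife replicates

    @property
    def frame_interval(self) -> float:
        return self.meta.get("frame_interval", float(self.lags[0]))


@dataclass
class TTCMatrix:
    q: float
    times: np.ndarray           # seconds, length n
    matrix: np.ndarray          # (n, n), symmetric by construction
    n_pixels: int
    meta: dict = field(default_factory=dict)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass
class ContrastEstimate:
    beta: float
    method: str
    se: float = float("nan")

    def __post_init__(self):
        if not (0 < self.beta <= 1.05):
            raise DegenerateInputError(
                f"contrast estimate {self.beta:.4g} outside (0, 1.05]; "
                "over-masking or pure noise?")


# --------------------------------------------------------------------------
# core estimators (array level)
# --------------------------------------------------------------------------

def _per_pixel_sums(I: np.ndarray, lags: np.ndarray):
    """Per-pixel lag accumulators: product, head and tail sums, each
    normalized by the number of start times.  Shapes (n_lags, n_pixels)."""
    n, p = I.shape
    num = np.empty((len(lags), p))
    s1 = np.empty((len(lags), p))
    s2 = np.empty((len(lags), p))
    for i, L in enumerate(lags):
        a = I[:-L]
        b = I[L:]
        m = n - L
        num[i] = np.einsum("ij,ij->j", a, b) / m
        s1[i] = a.sum(axis=0) / m
        s2[i] = b.sum(axis=0) / m
    return num, s1, s2


def g2_from_series(series: np.ndarray, lags: np.ndarray,
                   frame_interval: float = 1.0, n_groups: int = 10):
    """Symmetric-normalized g2 with pixel-jackknife errors.

    ``series``: (n_frames, n_pixels) intensities.  Returns
    ``(lags_s, g2, se, group_g2)`` where ``group_g2`` (shape
    ``(n_groups, n_lags)``, or None for few pixels) holds the
    delete-one-pixel-group jackknife replicates of the curve, used
    downstream to propagate honest errors into fitted parameters.
    """
    I = np.asarray(series, dtype=np.float64)
    n, p = I.shape
    if n < 2:
        raise ConfigError("need at least 2 frames")
    if I.mean() == 0:
        raise DegenerateInputError("zero mean intensity in bin")
    lags = np.asarray(lags, dtype=int)
    num_p, s1_p, s2_p = _per_pixel_sums(I, lags)
    num, s1, s2 = num_p.sum(1), s1_p.sum(1), s2_p.sum(1)
    with np.errstate(divide="ignore", invalid="ignore"):
        g2 = (num / p) / ((s1 / p) * (s2 / p))

    se = np.full(len(lags), np.nan)
    if p > 1:
        d1 = (s1[:, None] - s1_p) / (p - 1)
        d2 = (s2[:, None] - s2_p) / (p - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            jk = ((num[:, None] - num_p) / (p - 1)) / (d1 * d2)
        for i in range(len(lags)):
            row = jk[i][np.isfinite(jk[i])]
            if len(row) > 1:
                se[i] = np.sqrt((len(row) - 1) / len(row)
                                * np.sum((row - row.mean()) ** 2))

    group_g2 = None
    if p >= 2 * n_groups and n_groups >= 4:
        bounds = np.linspace(0, p, n_groups + 1).astype(int)
        group_g2 = np.empty((n_groups, len(lags)))
        for g in range(n_groups):
            sl = slice(bounds[g], bounds[g + 1])
            pg = p - (bounds[g + 1] - bounds[g])
            gn = num - num_p[:, sl].sum(1)
            g1 = s1 - s1_p[:, sl].sum(1)
            g2_ = s2 - s2_p[:, sl].sum(1)
            group_g2[g] = (gn / pg) / ((g1 / pg) * (g2_ / pg))
    return lags * frame_interval, g2, se, group_g2


def g2_reference(series: np.ndarray, lags, frame_interval: float = 1.0):
    """Brute-force loop implementation of the same estimator (oracle).

    Independent of :func:`g2_from_series` — plain Python accumulation, used
    only on small inputs to cross-check the vectorized path.
    """
    I = np.asarray(series, dtype=np.float64)
    n, p = I.shape
    out = []
    for L in lags:
        num = 0.0
        s1 = 0.0
        s2 = 0.0
        cnt = 0
        for j in range(p):
            for t in range(n - L):
                num += I[t, j] * I[t + L, j]
                s1 += I[t, j]
                s2 += I[t + L, j]
                cnt += 1
        out.append((num / cnt) / ((s1 / cnt) * (s2 / cnt)))
    return np.asarray(lags, dtype=float) * frame_interval, np.asarray(out)


def ttc_from_series(series: np.ndarray, frame_interval: float = 1.0,
                    max_frames: int = 4000):
    """Two-time correlation C(t1, t2) with pixel-only averaging.

    Frames are pre-averaged in windows when the stack exceeds
    ``max_frames`` (window size is recorded by the caller via the returned
    effective dt).  Returns ``(times, C, window)`` with C exactly symmetric.
    """
    I = np.asarray(series, dtype=np.float64)
    n, p = I.shape
    if I.mean() == 0:
        raise DegenerateInputError("zero mean intensity in bin")
    window = 1
    if n > max_frames:
        window = int(np.ceil(n / max_frames))
        nw = n // window
        I = I[:nw * window].reshape(nw, window, p).mean(axis=1)
        n = nw
    m = I.mean(axis=1)
    if np.any(m == 0):
        raise DegenerateInputError("zero pixel-mean intensity in some frames")
    C = (I @ I.T) / p / np.outer(m, m)
    C = 0.5 * (C + C.T)          # exact symmetry
    times = (np.arange(n) * window + 0.5 * (window - 1)) * frame_interval
    return times, C, window


# --------------------------------------------------------------------------
# stack-level operations
# --------------------------------------------------------------------------

def _bin_series(stack: FrameStack, qmap: QMap, qbin, min_pixels=10):
    if isinstance(qbin, float):
        qbin = qmap.bin_for_q(qbin)
    sel = qmap.pixels_in_bin(int(qbin), stack.mask)
    npx = int(sel.sum())
    if npx < min_pixels:
        raise ConfigError(f"Q bin {qbin} has {npx} unmasked pixels "
                          f"(minimum {min_pixels})")
    q = float(qmap.centers[int(qbin)])
    return stack.pixel_series(sel), q


def compute_g2(stack: FrameStack, qmap: QMap, qbin,
               scheme: Optional[LagScheme] = None) -> G2Curve:
    """g2 for one Q bin of a stack; averaging over start times and pixels."""
    scheme = scheme or LagScheme()
    series, q = _bin_series(stack, qmap, qbin)
    if stack.n_frames < 2:
        raise ConfigError("need at least 2 frames")
    lags = scheme.lags(stack.n_frames)
    dt = stack.frame_interval
    lag_s, g2, se, groups = g2_from_series(series, lags, dt)
    meta = {"frame_interval": dt,
            "temperature_k": stack.temperature_k,
            "flux_density": stack.flux_density}
    return G2Curve(q=q, lags=lag_s, g2=g2, se=se,
                   n_pixels=series.shape[1], n_frames=stack.n_frames,
                   meta=meta, group_g2=groups)


def compute_ttc(stack: FrameStack, qmap: QMap, qbin,
                max_frames: int = 4000) -> TTCMatrix:
    """Two-time correlation matrix for one Q bin (pixel-only averaging)."""
    series, q = _bin_series(stack, qmap, qbin)
    times, C, window = ttc_from_series(series, stack.frame_interval,
                                       max_frames)
    meta = {"window": window, "temperature_k": stack.temperature_k,
            "flux_density": stack.flux_density}
    return TTCMatrix(q=q, times=times, matrix=C,
                     n_pixels=series.shape[1], meta=meta)


def estimate_contrast(stack: FrameStack, qmap: QMap, qbin,
                      method: str = "short_lag") -> ContrastEstimate:
    """Speckle contrast β.

    ``short_lag`` (default): linear extrapolation of g2 - 1 from the first
    four lag channels to t = 0.  ``variance``: per-frame normalized pixel
    variance corrected for Poisson counting noise,
    ``var(I)/<I>^2 - 1/<I>``, averaged over frames.
    """
    series, q = _bin_series(stack, qmap, qbin)
    if method == "short_lag":
        lags = np.arange(1, 5)
        lags = lags[lags < stack.n_frames]
        _, g2, se, _ = g2_from_series(series, lags, stack.frame_interval)
        y = g2 - 1.0
        coef = np.polyfit(lags.astype(float), y, 1)
        beta = float(np.polyval(coef, 0.0))
        err = float(np.nanmean(se)) if np.isfinite(se).any() else float("nan")
        return ContrastEstimate(beta=beta, method="short_lag", se=err)
    if method == "variance":
        m = series.mean(axis=1)
        if np.any(m == 0):
            raise DegenerateInputError("zero pixel-mean in some frames")
        v = series.var(axis=1, ddof=1)
        per_frame = v / m ** 2 - 1.0 / m
        beta = float(per_frame.mean())
        se = float(per_frame.std(ddof=1) / np.sqrt(len(per_frame)))
        if beta <= 0 or beta < 2.0 * se:
            raise DegenerateInputError(
                f"contrast {beta:.3g} +- {se:.3g} not resolvable above the "
                "Poisson noise floor; over-masking or pure noise?")
        return ContrastEstimate(beta=beta, method="variance", se=se)
    raise ConfigError(f"unknown contrast method {method!r}")
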