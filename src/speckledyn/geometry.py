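"""Detector geometry, momentum-transfer maps, masking and azimuthal averaging.

Conventions (stated once, bit-exact everywhere):

* pixel indexing is 0-based ``(row, col)`` with the origin at the top-left;
* the beam center is given in the same ``(row, col)`` convention and may lie
  outside the detector (usual in USAXS geometries);
* Q is computed exactly, ``Q = (4*pi/lambda) * sin(theta)`` with
  ``2*theta = arctan(r / SDD)`` — no small-angle approximation;
* azimuth is measured in degrees counter-clockwise from the +col axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np

from .exceptions import ConfigError, DegenerateInputError

if TYPE_CHECKING:  # pragma: no cover
    from .stacks import FrameStack

#: keV <-> nm conversion constant (h*c in keV*nm)
HC_KEV_NM = 1.23984193


@dataclass(frozen=True)
class DetectorGeometry:
    """Flat area-detector geometry for small-angle scattering.

    Parameters
    ----------
    photon_energy_kev:
        Photon energy in keV. The wavelength follows from
        ``lambda = 1.23984193 / E`` in nm.
    sdd_m:
        Sample-detector distance in meters.
    pixel_size_um:
        Square pixel edge in micrometers.
    beam_center:
        Direct-beam position ``(row, col)`` in pixels; fractional values
        allowed; may lie outside the detector.
    shape:
        Detector shape ``(n_rows, n_cols)`` in pixels.
    """

    photon_energy_kev: float
    sdd_m: float
    pixel_size_um: float
    beam_center: tuple[float, float]
    shape: tuple[int, int]

    def __post_init__(self):
        if self.photon_energy_kev <= 0:
            raise ConfigError("photon energy must be positive")
        if self.sdd_m <= 0:
            raise ConfigError("sample-detector distance must be positive")
        if self.pixel_size_um <= 0:
            raise ConfigError("pixel size must be positive")
        if len(self.shape) != 2 or any(s <= 0 for s in self.shape):
            raise ConfigError("detector shape must be two positive integers")

    @property
    def wavelength_nm(self) -> float:
        return HC_KEV_NM / self.photon_energy_kev

    def radius_m(self) -> np.ndarray:
        """Per-pixel radial distance from the beam center in the detector plane [m]."""
        rows = np.arange(self.shape[0], dtype=float)[:, None]
        cols = np.arange(self.shape[1], dtype=float)[None, :]
        p = self.pixel_size_um * 1e-6
        dr = (rows - self.beam_center[0]) * p
        dc = (cols - self.beam_center[1]) * p
        return np.hypot(dr, dc)

    def azimuth_deg(self) -> np.ndarray:
        """Per-pixel azimuth in degrees in [0, 360), CCW from the +col axis."""
        rows = np.arange(self.shape[0], dtype=float)[:, None]
        cols = np.arange(self.shape[1], dtype=float)[None, :]
        # image row axis points down; negate so that angles are CCW
        ang = np.degrees(np.arctan2(-(rows - self.beam_center[0]),
                                    cols - self.beam_center[1]))
        return np.mod(ang, 360.0)

    def q_of_radius(self, r_m) -> np.ndarray:
        """Momentum transfer [1/nm] at detector-plane radius ``r_m`` [m]."""
        two_theta = np.arctan(np.asarray(r_m, dtype=float) / self.sdd_m)
        return (4.0 * np.pi / self.wavelength_nm) * np.sin(two_theta / 2.0)

    def q_map(self) -> np.ndarray:
        return self.q_of_radius(self.radius_m())


@dataclass
class QMap:
    """Per-pixel momentum transfer with a bin assignment.

    ``bin_index`` is ``-1`` for pixels outside every bin; masked pixels are
    excluded at use time by intersecting with a stack's pixel mask.  Bins are
    half-open intervals ``[edge_i, edge_{i+1})``.
    """

    q: np.ndarray                     # [1/nm], shape = detector shape
    edges: np.ndarray                 # [1/nm], strictly increasing
    bin_index: np.ndarray             # int, -1 = unbinned
    geometry: DetectorGeometry = None
    target_centers: Optional[np.ndarray] = None   # set for "targets" binning

    @property
    def n_bins(self) -> int:
        if self.target_centers is not None:
            return len(self.target_centers)
        return len(self.edges) - 1

    @property
    def centers(self) -> np.ndarray:
        if self.target_centers is not None:
            return self.target_centers
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def pixels_in_bin(self, b: int, mask: Optional[np.ndarray] = None) -> np.ndarray:
        """Boolean map of pixels assigned to bin ``b`` (optionally masked)."""
        sel = self.bin_index == b
        if mask is not None:
            sel &= mask
        return sel

    def bin_for_q(self, q: float) -> int:
        """Index of the bin containing or nearest to ``q``."""
        b = int(np.searchsorted(self.edges, q, side="right")) - 1
        b = min(max(b, 0), self.n_bins - 1)
        return b


def build_q_map(geometry: DetectorGeometry, binning) -> QMap:
    """Build a per-pixel Q map and bin assignment.

    ``binning`` is a mapping with a ``kind`` key:

    * ``{"kind": "log", "n": 30}`` — ``n`` log-spaced bins over the populated
      positive-Q range (the default analysis choice);
    * ``{"kind": "edges", "edges": [...]}`` — explicit edges in 1/nm;
    * ``{"kind": "targets", "centers": [...], "rel_width": 0.1}`` — disjoint
      annuli of fractional width ``rel_width`` around each center.
    """
    q = geometry.q_map()
    kind = binning.get("kind", "log")
    if kind == "log":
        n = int(binning.get("n", 30))
        positive = q[q > 0]
        if positive.size == 0:
            raise ConfigError("no pixels with Q > 0 on this detector")
        lo, hi = positive.min(), q.max()
        edges = np.geomspace(lo, hi * (1 + 1e-12), n + 1)
        idx = np.searchsorted(edges, q, side="right") - 1
        idx[(idx < 0) | (idx >= n)] = -1
    elif kind == "edges":
        edges = np.asarray(binning["edges"], dtype=float)
        if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
            raise ConfigError("bin edges must be strictly increasing, length >= 2")
        idx = np.searchsorted(edges, q, side="right") - 1
        idx[(idx < 0) | (idx >= len(edges) - 1)] = -1
    elif kind == "targets":
        centers = np.sort(np.asarray(binning["centers"], dtype=float))
        w = float(binning.get("rel_width", 0.1))
        if np.any(centers <= 0):
            raise ConfigError("target Q centers must be positive")
        lo = centers * (1 - w / 2)
        hi = centers * (1 + w / 2)
        if np.any(lo[1:] < hi[:-1]):
            raise ConfigError("target annuli overlap; reduce rel_width")
        # interleave into a single edge array; odd gaps are unbinned
        edges = np.empty(2 * len(centers))
        edges[0::2] = lo
        edges[1::2] = hi
        raw = np.searchsorted(edges, q, side="right") - 1
        idx = np.where((raw >= 0) & (raw % 2 == 0), raw // 2, -1)
        return QMap(q=q, edges=edges, bin_index=idx.astype(np.int32),
                    geometry=geometry, target_centers=centers)
    else:
        raise ConfigError(f"unknown binning kind {kind!r}")
    return QMap(q=q, edges=edges, bin_index=idx.astype(np.int32), geometry=geometry)


@dataclass
class RadialProfile:
    """Azimuthally averaged intensity vs Q.

    Bins with zero unmasked pixels carry ``nan`` intensity and
    ``n_pixels == 0`` — absent, never silently zero.
    """

    q: np.ndarray                 # bin centers [1/nm]
    intensity: np.ndarray         # mean counts/pixel/frame
    n_pixels: np.ndarray          # unmasked pixels per bin
    per_frame: Optional[np.ndarray] = None   # (n_frames, n_bins) if requested

    def to_csv(self, path):
        import pandas as pd
        df = pd.DataFrame({"q_nm^-1": self.q,
                           "intensity_counts_per_pixel": self.intensity,
                           "n_pixels": self.n_pixels})
        with open(path, "w") as fh:
            fh.write("# azimuthally averaged intensity; q in 1/nm, "
                     "intensity in photon counts/pixel/frame\n")
            df.to_csv(fh, index=False)


def azimuthal_average(stack: "FrameStack", qmap: QMap,
                      per_frame: bool = False) -> RadialProfile:
    """Per-Q-bin mean counts over unmasked pixels, averaged over frames."""
    nb = qmap.n_bins
    labels = qmap.bin_index.ravel().copy()
    labels[~stack.mask.ravel()] = -1
    counts = np.bincount(labels[labels >= 0], minlength=nb)
    frames = stack.images.reshape(stack.n_frames, -1)
    mean_img = frames.mean(axis=0)
    sums = np.bincount(labels[labels >= 0],
                       weights=mean_img[labels >= 0], minlength=nb)
    with np.errstate(invalid="ignore"):
        intensity = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    pf = None
    if per_frame:
        pf = np.full((stack.n_frames, nb), np.nan)
        sel = labels >= 0
        lab = labels[sel]
        for t in range(stack.n_frames):
            s = np.bincount(lab, weights=frames[t, sel], minlength=nb)
            pf[t] = np.where(counts > 0, s / np.maximum(counts, 1), np.nan)
    return RadialProfile(q=qmap.centers, intensity=intensity,
                         n_pixels=counts, per_frame=pf)


def build_mask(stack: "FrameStack", rules: Optional[dict] = None,
               qmap: Optional[QMap] = None) -> np.ndarray:
    """Combine static, hot-pixel and angular-sector masks.

    ``True`` marks a *valid* pixel.  ``rules`` keys (all optional):

    * ``static``: boolean array, ``True`` = keep;
    * ``hot_pixel_k``: mask pixels whose time-mean exceeds ``k`` times the
      median of their Q annulus (default 50 when the key is present);
    * ``sectors``: list of ``(lo_deg, hi_deg)`` azimuth intervals to remove
      (streaks from grain boundaries are typically masked this way);
    * ``required_bins``: Q-bin indices to check for over-masking.
    """
    rules = rules or {}
    mask = np.ones(stack.images.shape[1:], dtype=bool)
    if "static" in rules:
        static = np.asarray(rules["static"], dtype=bool)
        if static.shape != mask.shape:
            raise ConfigError("static mask shape does not match detector")
        mask &= static
    if "hot_pixel_k" in rules:
        k = float(rules["hot_pixel_k"] or 50.0)
        if qmap is None:
            qmap = build_q_map(stack.geometry, {"kind": "log", "n": 30})
        mean_img = stack.images.mean(axis=0)
        for b in range(qmap.n_bins):
            sel = qmap.pixels_in_bin(b, mask)
            if not sel.any():
                continue
            med = np.median(mean_img[sel])
            if med > 0:
                mask[sel & (mean_img > k * med)] = False
    for lo, hi in rules.get("sectors", ()):
        az = stack.geometry.azimuth_deg()
        lo, hi = float(lo) % 360.0, float(hi) % 360.0
        if lo <= hi:
            mask[(az >= lo) & (az <= hi)] = False
        else:  # wraps through 0
            mask[(az >= lo) | (az <= hi)] = False
    if qmap is not None:
        for b in rules.get("required_bins", ()):
            total = int((qmap.bin_index == b).sum())
            kept = int(qmap.pixels_in_bin(b, mask).sum())
            if total > 0 and kept < 0.1 * total:
                warnings.warn(
                    f"mask removes >90% of required Q-bin {b} "
                    f"({kept}/{total} pixels left)", stacklevel=2)
    return mask


def sector_profiles(stack: "FrameStack", qmap: QMap,
                    n_sectors: int = 4) -> list[RadialProfile]:
    """Azimuthal-sector radial profiles — the isotropy diagnostic.

    Splits the detector into ``n_sectors`` equal azimuth wedges and returns
    one radial profile per wedge; on isotropic input they agree within
    counting error.
    """
    az = stack.geometry.azimuth_deg()
    out = []
    width = 360.0 / n_sectors
    base_mask = stack.mask
    from .stacks import FrameStack as FS
    for s in range(n_sectors):
        sel = (az >= s * width) & (az < (s + 1) * width)
        sub = stack.with_mask(base_mask & sel)
        out.append(azimuthal_average(sub, qmap))
    return out
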