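"""Detector geometry, Q-mapping, masking, azimuthal averaging and I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import speckledyn as sd
from speckledyn.exceptions import ConfigError, SchemaError


def beamline_geometry(shape=(256, 256), center=(128.0, 128.0)):
    """The USAXS setup of the first experiment: 12.4 keV, SDD 21.2 m."""
    return sd.DetectorGeometry(photon_energy_kev=12.4, sdd_m=21.2,
                               pixel_size_um=75.0, beam_center=center,
                               shape=shape)


class TestQComputation:
    def test_q_zero_at_beam_center(self):
        g = beamline_geometry()
        assert g.q_of_radius(0.0) == 0.0

    def test_usaxs_analysis_bin(self):
        # independent trigonometry: r = 26.99 mm at 12.4 keV / 21.2 m gives
        # 2*theta = 1.27311e-3 rad and Q = 0.0800 1/nm, the paper-scale
        # analysis annulus
        g = beamline_geometry()
        lam = 1.23984193 / 12.4
        two_theta = np.arctan(26.99e-3 / 21.2)
        q_expected = 4 * np.pi / lam * np.sin(two_theta / 2)
        assert abs(two_theta - 1.27311e-3) < 1e-8
        assert abs(q_expected - 0.0800) < 2e-4
        assert np.isclose(g.q_of_radius(26.99e-3), q_expected, rtol=1e-12)

    def test_wavelength_from_energy(self):
        g = beamline_geometry()
        assert np.isclose(g.wavelength_nm, 1.23984193 / 12.4, rtol=1e-12)

    def test_small_angle_sdd_doubling(self):
        # at fixed radius, doubling SDD halves Q to first order
        g1 = beamline_geometry()
        g2 = sd.DetectorGeometry(photon_energy_kev=12.4, sdd_m=42.4,
                                 pixel_size_um=75.0,
                                 beam_center=(128.0, 128.0),
                                 shape=(256, 256))
        r = 26.99e-3
        ratio = g2.q_of_radius(r) / g1.q_of_radius(r)
        assert abs(ratio - 0.5) < 1e-5

    def test_negative_sdd_rejected(self):
        with pytest.raises(ConfigError):
            sd.DetectorGeometry(photon_energy_kev=12.4, sdd_m=-1.0,
                                pixel_size_um=75.0, beam_center=(0, 0),
                                shape=(16, 16))

    @settings(max_examples=20, deadline=None)
    @given(st.floats(min_value=1e-4, max_value=0.1))
    def test_q_monotone_in_radius(self, r):
        g = beamline_geometry()
        assert g.q_of_radius(r * 1.01) > g.q_of_radius(r)


class TestQMap:
    def test_bins_partition_pixels(self, small_geometry):
        qmap = sd.build_q_map(small_geometry, {"kind": "log", "n": 20})
        idx = qmap.bin_index
        assigned = idx >= 0
        # every assigned pixel belongs to exactly one bin and its q lies
        # inside that bin's half-open interval
        q = qmap.q[assigned]
        lo = qmap.edges[idx[assigned]]
        hi = qmap.edges[idx[assigned] + 1]
        assert np.all((q >= lo) & (q < hi))

    def test_target_annuli_disjoint_and_centered(self, small_geometry):
        qmap = sd.build_q_map(small_geometry,
                              {"kind": "targets",
                               "centers": [0.05, 0.1], "rel_width": 0.1})
        for b, c in enumerate([0.05, 0.1]):
            qs = qmap.q[qmap.bin_index == b]
            assert qs.size > 0
            assert np.all(np.abs(qs - c) <= 0.051 * c)

    def test_overlapping_targets_rejected(self, small_geometry):
        with pytest.raises(ConfigError):
            sd.build_q_map(small_geometry,
                           {"kind": "targets", "centers": [0.1, 0.101],
                            "rel_width": 0.1})


class TestAzimuthalAverage:
    def _uniform_stack(self, geometry, value=7.0, n_frames=3):
        imgs = np.full((n_frames,) + tuple(geometry.shape), value)
        return sd.FrameStack(images=imgs,
                             timestamps=np.arange(n_frames, dtype=float),
                             geometry=geometry,
                             mask=np.ones(geometry.shape, bool))

    def test_uniform_frames(self, small_geometry):
        stack = self._uniform_stack(small_geometry)
        qmap = sd.build_q_map(small_geometry, {"kind": "log", "n": 15})
        prof = sd.azimuthal_average(stack, qmap)
        pop = prof.n_pixels > 0
        assert np.allclose(prof.intensity[pop], 7.0)

    def test_power_law_profile_slope(self, small_geometry):
        qmap = sd.build_q_map(small_geometry, {"kind": "log", "n": 25})
        q = np.where(qmap.q > 0, qmap.q, np.nan)
        img = np.nan_to_num(q ** -3.0, nan=0.0, posinf=0.0)
        stack = sd.FrameStack(images=img[None],
                              timestamps=np.array([0.0]),
                              geometry=small_geometry,
                              mask=np.isfinite(q))
        prof = sd.azimuthal_average(stack, qmap)
        pop = (prof.n_pixels > 20) & np.isfinite(prof.intensity)
        slope = np.polyfit(np.log(prof.q[pop]),
                           np.log(prof.intensity[pop]), 1)[0]
        assert abs(slope + 3.0) < 0.05

    def test_empty_bins_absent_not_zero(self, small_geometry):
        stack = self._uniform_stack(small_geometry)
        # edges beyond the detector range give empty bins
        qmax = float(stack.geometry.q_map().max())
        qmap = sd.build_q_map(small_geometry,
                              {"kind": "edges",
                               "edges": [qmax * 2, qmax * 3, qmax * 4]})
        prof = sd.azimuthal_average(stack, qmap)
        assert np.all(prof.n_pixels == 0)
        assert np.all(np.isnan(prof.intensity))

    def test_isotropy_sector_agreement(self, small_geometry):
        # isotropic Poisson input: azimuthal sector profiles agree within
        # counting error
        rng = np.random.default_rng(8)
        imgs = rng.poisson(20.0, (40,) + tuple(small_geometry.shape))
        stack = sd.FrameStack(images=imgs,
                              timestamps=np.arange(40, dtype=float),
                              geometry=small_geometry,
                              mask=np.ones(small_geometry.shape, bool))
        qmap = sd.build_q_map(small_geometry,
                              {"kind": "targets", "centers": [0.1],
                               "rel_width": 0.2})
        profs = sd.sector_profiles(stack, qmap, n_sectors=4)
        vals = np.array([p.intensity[0] for p in profs])
        n_min = min(int(p.n_pixels[0]) for p in profs)
        counting = np.sqrt(20.0 / (n_min * 40))
        assert np.ptp(vals) < 6 * counting


class TestMask:
    def _noise_stack(self, geometry, seed=0):
        rng = np.random.default_rng(seed)
        imgs = rng.poisson(5.0, (4,) + tuple(geometry.shape))
        return sd.FrameStack(images=imgs,
                             timestamps=np.arange(4, dtype=float),
                             geometry=geometry,
                             mask=np.ones(geometry.shape, bool))

    def test_empty_rules_all_true(self, small_geometry):
        stack = self._noise_stack(small_geometry)
        assert sd.build_mask(stack).all()

    def test_hot_pixel_detected(self, small_geometry):
        stack = self._noise_stack(small_geometry)
        stack.images[:, 30, 60] = 50000
        qmap = sd.build_q_map(small_geometry, {"kind": "log", "n": 10})
        mask = sd.build_mask(stack, {"hot_pixel_k": 50}, qmap=qmap)
        assert not mask[30, 60]
        assert mask.sum() == mask.size - 1

    def test_sector_mask_area(self):
        geom = sd.DetectorGeometry(photon_energy_kev=12.4, sdd_m=21.2,
                                   pixel_size_um=75.0,
                                   beam_center=(100.0, 100.0),
                                   shape=(200, 200))
        imgs = np.ones((1, 200, 200))
        stack = sd.FrameStack(images=imgs, timestamps=np.array([0.0]),
                              geometry=geom, mask=np.ones((200, 200), bool))
        mask = sd.build_mask(stack, {"sectors": [(85.0, 95.0)]})
        r = geom.radius_m() / (75.0e-6)
        disc = r <= 90
        removed = disc & ~mask
        expected = (10.0 / 360.0) * disc.sum()
        assert abs(removed.sum() - expected) / expected < 0.02

    def test_overmasking_warns(self, ring_stack, ring_qmap):
        with pytest.warns(UserWarning, match="Q-bin 0"):
            sd.build_mask(ring_stack,
                          {"static": np.zeros(ring_stack.mask.shape, bool),
                           "required_bins": [0]},
                          qmap=ring_qmap)


class TestIO:
    def test_roundtrip_lossless(self, ring_stack, tmp_path):
        path = tmp_path / "stack.h5"
        sd.write_frame_stack(ring_stack, path)
        back = sd.read_frame_stack(path)
        assert np.array_equal(back.images, ring_stack.images)
        assert np.array_equal(back.timestamps, ring_stack.timestamps)
        assert np.array_equal(back.mask, ring_stack.mask)
        assert back.temperature_k == ring_stack.temperature_k
        assert back.meta["truth"] == ring_stack.meta["truth"]
        assert back.geometry == ring_stack.geometry
        # ground-truth sidecar written for synthetic stacks
        assert (tmp_path / "stack.h5.truth.json").exists()

    def test_non_monotone_timestamps_rejected(self, ring_stack, tmp_path):
        import h5py
        path = tmp_path / "bad.h5"
        sd.write_frame_stack(ring_stack, path)
        with h5py.File(path, "r+") as f:
            ts = f["timestamps"][...]
            ts[5] = ts[4]
            f["timestamps"][...] = ts
        with pytest.raises(ConfigError, match="strictly increasing"):
            sd.read_frame_stack(path)

    def test_foreign_file_schema_error(self, tmp_path):
        import h5py
        path = tmp_path / "foreign.h5"
        with h5py.File(path, "w") as f:
            f.create_dataset("whatever", data=np.arange(5))
        with pytest.raises(SchemaError) as err:
            sd.read_frame_stack(path)
        assert "frames" in err.value.missing
        assert "schema_version" in err.value.missing
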