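import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lutidose import phantom_sim as ps
from lutidose import voi_tools as vt
from conftest import make_phantom_spec


def uniform_sphere_volume(tumor_bq_ml=10_000.0, bg_bq_ml=1_000.0,
                          radius_mm=15.0, vox=5.08, n=40):
    """Hot sphere centered in a uniform warm box (no blur, no noise)."""
    idx = np.indices((n, n, n), dtype=float)
    centers = (idx + 0.5) * vox
    c = n * vox / 2.0
    d2 = sum((centers[a] - c) ** 2 for a in range(3))
    grid = np.full((n, n, n), bg_bq_ml)
    sphere = d2 <= radius_mm**2
    grid[sphere] = tumor_bq_ml
    return vt.ActivityVolume(grid, vox, 72.0), sphere


class TestEncloseTumor:
    def test_contains_tumor_with_margin(self, phantom_spec, tumor_seed_voxel):
        vols, truth = ps.generate_phantom_study(phantom_spec)
        voi = vt.enclose_tumor(vols[-1], tumor_seed_voxel, dilation_mm=10.0)
        assert voi.volume_ml > truth.volumes_ml["tumor"]
        assert np.all(voi.mask[truth.masks["tumor"]])

    def test_zero_activity_seed_errors(self):
        vol = vt.ActivityVolume(np.zeros((10, 10, 10)), 5.0, 72.0)
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="zero activity"):
                vt.enclose_tumor(vol, (5, 5, 5), 10.0)

    def test_deterministic(self, phantom_spec, tumor_seed_voxel):
        vols, _ = ps.generate_phantom_study(phantom_spec)
        a = vt.enclose_tumor(vols[-1], tumor_seed_voxel, 10.0)
        b = vt.enclose_tumor(vols[-1], tumor_seed_voxel, 10.0)
        assert np.array_equal(a.mask, b.mask)


class TestSeparateTumor:
    def test_recovers_sphere_within_one_voxel_shell(self):
        vol, sphere = uniform_sphere_volume()
        seed = (20, 20, 20)
        enc = vt.enclose_tumor(vol, seed, dilation_mm=15.0)
        sep = vt.separate_tumor(vol, enc)
        true_v = sphere.sum() * vol.voxel_volume_ml
        # within one voxel shell of the rasterized truth
        r_vox = (3 * sphere.sum() / (4 * np.pi)) ** (1 / 3)
        shell_vox = 4 * np.pi * (r_vox**2) * 1.0
        assert abs(sep.n_voxels - sphere.sum()) <= shell_vox
        assert sep.volume_ml == pytest.approx(true_v, rel=0.35)
        assert np.all(enc.mask[sep.mask])  # nested VOIs
        assert sep.activity_bq <= enc.activity_bq
        assert sep.volume_ml <= enc.volume_ml

    def test_tumor_touching_voi_edge_fails(self):
        # tumor occupies a full slab through the volume: every threshold
        # component touches the enclosing VOI boundary
        grid = np.ones((20, 20, 20)) * 100.0
        grid[:, 8:12, 8:12] = 10_000.0
        vol = vt.ActivityVolume(grid, 5.0, 72.0)
        enc = vt.VOI.from_mask(vol, np.ones_like(grid, dtype=bool))
        with pytest.raises(vt.SeparationFailure):
            vt.separate_tumor(vol, enc)

    def test_zero_background_gives_superzero_component(self):
        vol, sphere = uniform_sphere_volume(bg_bq_ml=0.0)
        enc = vt.enclose_tumor(vol, (20, 20, 20), dilation_mm=15.0)
        sep = vt.separate_tumor(vol, enc)
        assert sep.n_voxels == sphere.sum()


class TestBackgroundCorrectedActivity:
    def test_hand_example(self):
        m = vt.TumorMeasurement(A0_bq=120e3, V0_ml=100.0, A_spect_bq=100e3,
                                V_spect_ml=30.0, V_CT_ml=20.0)
        assert vt.background_corrected_activity(m) == pytest.approx(97_142.857, rel=1e-6)

    @pytest.mark.parametrize("a0, vspect, vct", [
        (100e3, 30.0, 30.0),   # V_spect == V_CT: correction vanishes
        (100e3, 30.0, 20.0),   # A0 == A_spect: zero background
    ])
    def test_correction_vanishes(self, a0, vspect, vct):
        m = vt.TumorMeasurement(a0, 100.0, 100e3, vspect, vct)
        assert vt.background_corrected_activity(m) == pytest.approx(100e3)

    def test_geometry_contract_errors(self):
        with pytest.raises(ValueError):
            vt.TumorMeasurement(120e3, 30.0, 100e3, 30.0, 20.0)  # V0 == V_spect
        with pytest.raises(ValueError):
            vt.TumorMeasurement(120e3, 100.0, 100e3, 30.0, 40.0)  # V_spect < V_CT

    @given(a0_extra=st.floats(0.0, 5e5), seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_monotone_nonincreasing_in_A0(self, a0_extra, seed):
        rng = np.random.default_rng(seed)
        a_spect = rng.uniform(1e4, 1e6)
        m1 = vt.TumorMeasurement(a_spect + 1.0, 100.0, a_spect, 30.0, 20.0)
        m2 = vt.TumorMeasurement(a_spect + 1.0 + a0_extra, 100.0, a_spect, 30.0, 20.0)
        assert (vt.background_corrected_activity(m2)
                <= vt.background_corrected_activity(m1) + 1e-9)

    @pytest.mark.parametrize("bg_frac", [0.0, 0.1, 0.25, 0.5])
    def test_recovers_truth_across_background_levels(self, bg_frac):
        tumor_c = 10_000.0
        vol, sphere = uniform_sphere_volume(tumor_bq_ml=tumor_c,
                                            bg_bq_ml=bg_frac * tumor_c)
        true_act = tumor_c * sphere.sum() * vol.voxel_volume_ml
        enc = vt.enclose_tumor(vol, (20, 20, 20), dilation_mm=15.0)
        sep = vt.separate_tumor(vol, enc)
        m = vt.TumorMeasurement(enc.activity_bq, enc.volume_ml, sep.activity_bq,
                                sep.volume_ml, sphere.sum() * vol.voxel_volume_ml)
        a4 = vt.background_corrected_activity(m)
        assert a4 == pytest.approx(true_act, rel=0.05)


class TestTacVoi:
    def test_three_ml_voxel_count(self):
        vol, _ = uniform_sphere_volume()
        voi = vt.tac_voi(vol, (20, 20, 20), 3.0)
        assert voi.n_voxels == 23  # round(3 / 0.13107) with 5.08 mm voxels
        assert voi.volume_ml == pytest.approx(23 * 5.08**3 / 1000.0)

    def test_uniform_image_mean_is_uniform_value(self):
        vol = vt.ActivityVolume(np.full((15, 15, 15), 42.0), 5.08, 1.0)
        voi = vt.tac_voi(vol, (3, 3, 3), 3.0)
        assert vol.voxels[voi.mask].mean() == pytest.approx(42.0)

    def test_single_voxel_target_is_hottest(self):
        vol, _ = uniform_sphere_volume()
        vox_ml = vol.voxel_volume_ml
        voi = vt.tac_voi(vol, (20, 20, 20), vox_ml)
        assert voi.n_voxels == 1
        assert vol.voxels[voi.mask].max() == vol.voxels.max()

    def test_grid_too_small(self):
        vol = vt.ActivityVolume(np.ones((2, 2, 2)), 5.08, 1.0)
        with pytest.raises(ValueError):
            vt.tac_voi(vol, (0, 0, 0), 5000.0)


class TestNiftiRoundTrip:
    def test_write_read(self, tmp_path, phantom_spec):
        vols, _ = ps.generate_phantom_study(phantom_spec)
        p = tmp_path / "a.nii.gz"
        vt.write_volume(vols[0], p)
        back = vt.read_volume(p)
        assert np.allclose(back.voxels, vols[0].voxels)
        assert back.voxel_size_mm == pytest.approx(5.08)
        assert back.time_post_injection_h == pytest.approx(1.0)
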