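import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from lutidose import nucdata
from lutidose.dose_engine import mc_voxel_energy
from lutidose.phantom_sim import PhantomSpec, Region


@pytest.fixture(scope="session")
def decay():
    return nucdata.load_decay_data()


@pytest.fixture(scope="session")
def kernel_508(decay):
    """Small-but-stable MC kernel for pipeline tests (se << 1%)."""
    return mc_voxel_energy(decay, 5.08, 200_000, seed=11)


def make_phantom_spec(seed: int = 7, *, psf_fwhm_mm: float = 0.0,
                      noise_model: str = "none",
                      tumor_Te_h: float = 30.0) -> PhantomSpec:
    """A 40^3-voxel (5.08 mm) phantom: one ellipsoidal tumor in warm background.

    Activities and half-lives are in the clinically observed range: ~1 MBq in
    the tumor at 72 h, effective half-lives of tens of hours, acquisition at
    1/4/24/72 h p.i.
    """
    vox = 5.08
    extent = 40 * vox
    c = extent / 2.0
    tumor = Region("tumor", center_mm=(c, c, c), semi_axes_mm=(12.0, 10.0, 14.0),
                   A_ref_bq=1e6, Te_true_h=tumor_Te_h, t_ref_h=72.0)
    background = Region("background", center_mm=(c, c, c),
                        semi_axes_mm=(90.0, 90.0, 90.0),
                        A_ref_bq=2e6, Te_true_h=60.0, t_ref_h=0.0)
    return PhantomSpec((40, 40, 40), vox, [tumor, background],
                       psf_fwhm_mm=psf_fwhm_mm, noise_model=noise_model,
                       seed=seed)


@pytest.fixture()
def phantom_spec():
    return make_phantom_spec()


@pytest.fixture()
def tumor_seed_voxel(phantom_spec):
    vox = phantom_spec.voxel_size_mm
    return tuple(int(c / vox) for c in phantom_spec.regions[0].center_mm)
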