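"""Synthetic phantom studies, chromatograms, and packaged clinical tables.

The phantom generator emulates *post-reconstruction* quantitative SPECT: it
rasterizes ellipsoidal regions with known mono-exponential kinetics into
activity-concentration volumes (Bq/ml) at the acquisition times (default
1, 4, 24, 72 h p.i.), optionally degrades them with a Gaussian PSF and
voxelwise Poisson noise on a counts scale, and returns a closed-form ground
truth (activities, volumes, disintegration counts, doses) so every
downstream stage can be validated without patient data.  Projection-domain
physics (attenuation, scatter, collimator response) is out of scope.

Coordinates: 0-based voxel indices; the world position of a voxel center is
``origin + (index + 0.5) * spacing``; volumes in ml are
``voxel_count * voxel_size^3 / 1000``.

All stochastic steps draw from one ``numpy.random.Generator`` seeded from the
spec's single integer seed, in a fixed order (noise fields time point by time
point), so outputs are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import ndimage

from .voi_tools import ActivityVolume

__all__ = [
    "Region",
    "PhantomSpec",
    "GroundTruth",
    "ChromatogramSpec",
    "Chromatogram",
    "generate_phantom_study",
    "generate_chromatogram",
    "sample_noisy_tac",
    "load_clinical_tables",
    "load_printed_summaries",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass
class Region:
    """Ellipsoidal phantom region with mono-exponential washout.

    ``A_ref_bq`` is the regional activity at ``t_ref_h``; activity at time t
    follows ``A(t) = A_ref * 2**((t_ref - t)/Te_true_h)``.  With the
    ``linear_rise`` uptake model the activity rises linearly from 0 to its
    mono-exponential value at the first acquisition time.
    """

    label: str
    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]
    A_ref_bq: float
    Te_true_h: float
    t_ref_h: float = 0.0
    uptake_model: str = "instantaneous"

    def __post_init__(self) -> None:
        if self.A_ref_bq < 0:
            raise ValueError("region activity must be non-negative")
        if self.Te_true_h <= 0:
            raise ValueError("effective half-life must be positive")
        if any(a <= 0 for a in self.semi_axes_mm):
            raise ValueError("ellipsoid semi-axes must be positive")
        if self.uptake_model not in ("instantaneous", "linear_rise"):
            raise ValueError(f"unknown uptake model {self.uptake_model!r}")

    def activity_at(self, t_h: float, t1_h: float | None = None) -> float:
        """True regional activity (Bq) at time t hours p.i."""
        a = self.A_ref_bq * 2.0 ** ((self.t_ref_h - t_h) / self.Te_true_h)
        if self.uptake_model == "linear_rise" and t1_h is not None and t_h < t1_h:
            a_t1 = self.A_ref_bq * 2.0 ** ((self.t_ref_h - t1_h) / self.Te_true_h)
            return a_t1 * t_h / t1_h
        return a


@dataclass
class PhantomSpec:
    """Full specification of a synthetic multi-time-point study."""

    grid_shape: tuple[int, int, int]
    voxel_size_mm: float
    regions: list[Region]
    acquisition_times_h: tuple[float, ...] = (1.0, 4.0, 24.0, 72.0)
    psf_fwhm_mm: float = 0.0
    noise_model: str = "none"  # "none" | "poisson"
    counts_per_bq: float = 1e-3  # scale for the Poisson counts domain
    seed: int = 0

    def __post_init__(self) -> None:
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be positive")
        t = np.asarray(self.acquisition_times_h)
        if np.any(np.diff(t) <= 0):
            raise ValueError("acquisition times must be strictly increasing")
        if self.noise_model not in ("none", "poisson"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")


@dataclass
class GroundTruth:
    """Closed-form truth for every region of a generated study."""

    times_h: tuple[float, ...]
    activities_bq: dict[str, list[float]]  # label -> activity per time point
    volumes_ml: dict[str, float]  # rasterized V_CT per region
    masks: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    def true_disintegrations(self, label: str, spec: PhantomSpec) -> float:
        """Analytic N for a region under the uptake-triangle + tail convention.

        N = A(t1) * (t1/2 + 1/lambda_e) with times in seconds — the same
        convention the kinetics stage estimates, so pipeline-vs-truth
        comparisons are apples to apples.
        """
        region = next(r for r in spec.regions if r.label == label)
        t1_h = spec.acquisition_times_h[0]
        a1 = region.activity_at(t1_h)
        lam = math.log(2.0) / (region.Te_true_h * 3600.0)
        return a1 * (t1_h * 3600.0 / 2.0 + 1.0 / lam)

    def true_dose_gy(self, label: str, spec: PhantomSpec,
                     e_center_j: float, rho_g_cm3: float = 1.0) -> float:
        """True absorbed dose D = N*E/(rho*V_CT) in Gy for a region."""
        n = self.true_disintegrations(label, spec)
        mass_kg = rho_g_cm3 * self.volumes_ml[label] * 1e-3
        return n * e_center_j / mass_kg


def _rasterize(spec: PhantomSpec) -> dict[str, np.ndarray]:
    """Voxel-center membership masks per region; background = surround."""
    shape = spec.grid_shape
    idx = np.indices(shape, dtype=float)
    centers = [(idx[a] + 0.5) * spec.voxel_size_mm for a in range(3)]
    masks: dict[str, np.ndarray] = {}
    for r in spec.regions:
        d2 = sum(
            ((centers[a] - r.center_mm[a]) / r.semi_axes_mm[a]) ** 2
            for a in range(3)
        )
        m = d2 <= 1.0
        if not m.any():
            raise ValueError(f"region {r.label!r} rasterizes to zero voxels")
        masks[r.label] = m
    # background encloses the others: carve out foreground regions
    fg = [l for l in masks if l != "background"]
    if "background" in masks:
        for l in fg:
            masks["background"] &= ~masks[l]
    for i, a in enumerate(fg):
        for b in fg[i + 1:]:
            if (masks[a] & masks[b]).any():
                raise ValueError(f"regions {a!r} and {b!r} overlap after rasterization")
    return masks


def generate_phantom_study(spec: PhantomSpec) -> tuple[list[ActivityVolume], GroundTruth]:
    """Generate one activity volume per acquisition time plus ground truth.

    Before blur/noise the voxel sum over each region equals the region's true
    activity at that time exactly (uniform concentration over the rasterized
    mask).  Blur is an isotropic Gaussian of the stated FWHM; Poisson noise is
    applied on a counts scale (``counts_per_bq``) and rescaled to Bq/ml.
    """
    masks = _rasterize(spec)
    rng = np.random.default_rng(spec.seed)
    t1 = spec.acquisition_times_h[0]
    vox_ml = spec.voxel_size_mm**3 / 1000.0

    truth = GroundTruth(
        times_h=tuple(spec.acquisition_times_h),
        activities_bq={r.label: [r.activity_at(t, t1) for t in spec.acquisition_times_h]
                       for r in spec.regions},
        volumes_ml={l: float(m.sum()) * vox_ml for l, m in masks.items()},
        masks=masks,
    )

    volumes = []
    for ti, t in enumerate(spec.acquisition_times_h):
        img = np.zeros(spec.grid_shape, dtype=float)
        for r in spec.regions:
            m = masks[r.label]
            img[m] = r.activity_at(t, t1) / (m.sum() * vox_ml)  # Bq/ml, uniform
        if spec.psf_fwhm_mm > 0:
            sigma_vox = spec.psf_fwhm_mm * _FWHM_TO_SIGMA / spec.voxel_size_mm
            img = ndimage.gaussian_filter(img, sigma_vox, mode="constant")
        if spec.noise_model == "poisson":
            counts = img * vox_ml * spec.counts_per_bq
            img = rng.poisson(counts).astype(float) / (vox_ml * spec.counts_per_bq)
        volumes.append(ActivityVolume(img, spec.voxel_size_mm, t))
    return volumes, truth


@dataclass
class ChromatogramSpec:
    """Synthetic radio-HPLC trace: baseline + Gaussian peaks + noise."""

    peaks: list[tuple[float, float, float]]  # (retention_time_min, area, sigma_min)
    baseline: float = 0.0
    noise_sd: float = 0.0
    rt_window_min: tuple[float, float] = (0.0, 16.0)
    dt_min: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.rt_window_min
        for rt, area, width in self.peaks:
            if area < 0:
                raise ValueError("peak area must be non-negative")
            if width <= 0:
                raise ValueError("peak width must be positive")
            if not (lo <= rt <= hi):
                raise ValueError("peak retention time outside acquisition window")


@dataclass
class Chromatogram:
    """Sampled radio-HPLC trace (retention time in min vs counts)."""

    retention_time_min: np.ndarray
    counts: np.ndarray
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rt_min": self.retention_time_min, "counts": self.counts}
        )


def generate_chromatogram(spec: ChromatogramSpec) -> Chromatogram:
    """Sample ``baseline + sum of Gaussian peaks + white noise`` on the rt grid."""
    lo, hi = spec.rt_window_min
    rt = np.arange(lo, hi + spec.dt_min / 2, spec.dt_min)
    trace = np.full_like(rt, float(spec.baseline))
    for mu, area, sigma in spec.peaks:
        trace += area / (sigma * math.sqrt(2 * math.pi)) * np.exp(
            -0.5 * ((rt - mu) / sigma) ** 2
        )
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        trace = trace + rng.normal(0.0, spec.noise_sd, rt.shape)
    return Chromatogram(rt, trace)


def sample_noisy_tac(times_h, A0_bq: float, Te_h: float,
                     noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Mono-exponential TAC samples with multiplicative lognormal noise.

    ``noise_sd`` is the standard deviation of the lognormal factor on the
    natural-log scale (0.1 = ~10% multiplicative noise).
    """
    t = np.asarray(times_h, dtype=float)
    clean = A0_bq * 2.0 ** (-t / Te_h)
    return clean * rng.lognormal(0.0, noise_sd, t.shape)


def _data_path(name: str):
    return resources.files("lutidose.data").joinpath(name)


def load_clinical_tables() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Packaged per-patient clinical tables (stability %, doses in Gy/GBq).

    Returns ``(stability, doses)`` DataFrames transcribed from the published
    trial: percent intact peptide for patients 1-8 at 5/15/30/60 min in both
    arms with non-evaluable entries flagged, and per-lesion/per-patient
    absorbed doses plus printed tumor-to-organ ratios.
    """
    with resources.as_file(_data_path("stability_table.csv")) as p:
        stab = pd.read_csv(p, comment="#")
    stab["evaluable"] = stab["evaluable"].astype(bool)
    with resources.as_file(_data_path("dose_table.csv")) as p:
        doses = pd.read_csv(p, comment="#")
    return stab, doses


def load_printed_summaries() -> dict:
    """Published summary rows (medians/IQRs/p-values) for report-layer comparison."""
    import json

    return json.loads(_data_path("printed_summaries.json").read_text())
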