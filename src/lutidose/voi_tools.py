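"""VOI construction and background-corrected tumor activity.

Implements the threshold-based volume-of-interest workflow used on the 72 h
post-injection image: an enclosing VOI (V0, A0) around tumor plus local
background, an upward threshold scan that separates the tumor component
(V_spect, A_spect) from background, the background-corrected tumor activity

    A4 = A_spect - (A0 - A_spect) / (V0 - V_spect) * (V_spect - V_CT),

and fixed-volume (default 3 ml) hottest-voxel VOIs for time-activity-curve
sampling.  Spill-in/out of activity across the tumor boundary is deliberately
not corrected.  Voxels are assigned to regions by voxel-center membership;
connectivity is 26-neighbor throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "ActivityVolume",
    "VOI",
    "TumorMeasurement",
    "SeparationFailure",
    "enclose_tumor",
    "separate_tumor",
    "background_corrected_activity",
    "tac_voi",
    "read_volume",
    "write_volume",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


class SeparationFailure(RuntimeError):
    """No threshold separates the tumor component from the enclosing VOI edge.

    The clinical analogue is a tumor whose activity cannot be discriminated
    from adjacent structures (e.g. blood-pool overlay), making it
    non-evaluable for dosimetry.
    """


@dataclass
class ActivityVolume:
    """Calibrated 3-D activity-concentration image at one time point.

    voxels are in Bq/ml on an isotropic grid; ``voxel_size_mm`` is the edge
    length.  Negative concentrations (possible after vendor reconstruction
    filters) are clipped to zero on construction.
    """

    voxels: np.ndarray
    voxel_size_mm: float
    time_post_injection_h: float
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be positive")
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("activity volume must be 3-D")
        if np.any(self.voxels < 0):
            self.voxels = np.clip(self.voxels, 0.0, None)

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_size_mm**3 / 1000.0

    def total_activity_bq(self) -> float:
        return float(self.voxels.sum() * self.voxel_volume_ml)


@dataclass
class VOI:
    """A set of voxels on a named volume's grid with derived volume/activity."""

    mask: np.ndarray  # boolean, same shape as the source volume
    volume_ml: float
    activity_bq: float
    threshold_bq_ml: float | None = field(default=None)

    @classmethod
    def from_mask(cls, vol: ActivityVolume, mask: np.ndarray,
                  threshold: float | None = None) -> "VOI":
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != vol.voxels.shape:
            raise ValueError("mask shape does not match volume grid")
        v = float(mask.sum()) * vol.voxel_volume_ml
        a = float(vol.voxels[mask].sum()) * vol.voxel_volume_ml
        return cls(mask=mask, volume_ml=v, activity_bq=a, threshold_bq_ml=threshold)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class TumorMeasurement:
    """The five measured tumor quantities and the derived corrected activity.

    A0/V0: enclosing VOI; A_spect/V_spect: separated tumor VOI; V_CT: the
    anatomical tumor volume (an input — CT segmentation is out of scope).
    """

    A0_bq: float
    V0_ml: float
    A_spect_bq: float
    V_spect_ml: float
    V_CT_ml: float

    def __post_init__(self) -> None:
        if not (self.V0_ml > self.V_spect_ml):
            raise ValueError("require V0 > V_spect")
        if not (self.V_spect_ml >= self.V_CT_ml > 0):
            raise ValueError("require V_spect >= V_CT > 0")
        if self.A0_bq < self.A_spect_bq:
            raise ValueError("require A0 >= A_spect")


def enclose_tumor(vol: ActivityVolume, seed_point: tuple[int, int, int],
                  dilation_mm: float, rel_threshold: float = 0.2) -> VOI:
    """Draw an enclosing VOI around the tumor and its local background.

    A deterministic surrogate for the manual enclosing VOI: the 26-connected
    component of voxels above ``rel_threshold`` x the seed intensity that
    contains the seed, morphologically dilated by ``dilation_mm``.
    """
    if dilation_mm <= 0:
        raise ValueError("dilation must be positive")
    seed = tuple(int(i) for i in seed_point)
    grid = vol.voxels
    for ax, i in enumerate(seed):
        if not (0 <= i < grid.shape[ax]):
            raise ValueError("seed point outside grid")
    if grid[seed] <= 0:
        warnings.warn("seed voxel has zero activity; no tumor blob found")
        raise ValueError("empty VOI: seed voxel has zero activity")

    blob = grid >= rel_threshold * grid[seed]
    labels, _ = ndimage.label(blob, structure=_STRUCT26)
    mask = labels == labels[seed]
    n_iter = max(1, int(round(dilation_mm / vol.voxel_size_mm)))
    ball = ndimage.generate_binary_structure(3, 3)
    mask = ndimage.binary_dilation(mask, structure=ball, iterations=n_iter)
    return VOI.from_mask(vol, mask)


def separate_tumor(vol: ActivityVolume, enclosing: VOI,
                   step: float = 0.01) -> VOI:
    """Raise the threshold until the hot component no longer touches the VOI edge.

    Scans thresholds upward in steps of ``step`` x the enclosing-VOI maximum
    and returns the first (smallest) threshold at which the 26-connected
    component containing the hottest voxel has no voxel 26-adjacent to the
    enclosing VOI's outer boundary.  Raises :class:`SeparationFailure` when no
    threshold separates the tumor.
    """
    if enclosing.n_voxels == 0:
        raise ValueError("enclosing VOI is empty")
    if not (0 < step < 1):
        raise ValueError("step must be a relative fraction in (0, 1)")
    grid = vol.voxels
    inside = enclosing.mask
    vmax = float(grid[inside].max())
    if vmax <= 0:
        raise SeparationFailure("enclosing VOI contains no activity")
    hot_flat = np.argmax(np.where(inside, grid, -np.inf))
    hot = np.unravel_index(hot_flat, grid.shape)
    # voxels outside the VOI that are 26-adjacent to it = outer boundary ring
    ring = ndimage.binary_dilation(inside, structure=_STRUCT26) & ~inside
    # a component "touches the edge" if it meets the VOI voxels adjacent to the
    # ring; where the VOI reaches the image border there is no outside, so the
    # border voxels themselves count as boundary
    edge_zone = ndimage.binary_dilation(ring, structure=_STRUCT26) & inside
    border = np.ones_like(inside)
    border[1:-1, 1:-1, 1:-1] = False
    edge_zone |= inside & border

    for k in range(1, int(round(1.0 / step)) + 1):
        thr = k * step * vmax
        super_thr = inside & (grid >= thr)
        if not super_thr[hot]:
            break
        labels, _ = ndimage.label(super_thr, structure=_STRUCT26)
        comp = labels == labels[hot]
        if not (comp & edge_zone).any():
            return VOI.from_mask(vol, comp, threshold=thr)
    raise SeparationFailure(
        "tumor component touches the enclosing VOI boundary at every threshold"
    )


def background_corrected_activity(m: TumorMeasurement) -> float:
    """Background-corrected tumor activity A4 (Bq) at the measurement time.

    The mean background concentration is estimated from the shell between the
    enclosing and the separated VOI, and the correction removes the background
    contribution of the non-tumor part of the separated VOI.  Negative results
    are clipped to zero with a warning.
    """
    denom = m.V0_ml - m.V_spect_ml
    if denom <= 0:
        raise ZeroDivisionError("V0 == V_spect: background shell is empty")
    a4 = m.A_spect_bq - (m.A0_bq - m.A_spect_bq) / denom * (m.V_spect_ml - m.V_CT_ml)
    if a4 < 0:
        warnings.warn("background correction produced negative activity; clipping to 0")
        return 0.0
    return float(a4)


def tac_voi(vol: ActivityVolume, seed_point: tuple[int, int, int],
            target_volume_ml: float = 3.0) -> VOI:
    """Connected hottest-voxel VOI of ~``target_volume_ml`` around the seed.

    Greedy region growing: start from the hottest voxel in the seed's
    immediate neighborhood and repeatedly absorb the hottest 26-neighbor
    until the voxel count closest to the target volume is reached.  The mean
    concentration over the returned VOI defines one TAC sample.
    """
    vox_ml = vol.voxel_volume_ml
    if target_volume_ml < vox_ml:
        raise ValueError("target volume smaller than one voxel")
    n_target = max(1, int(round(target_volume_ml / vox_ml)))
    grid = vol.voxels
    if n_target > grid.size:
        raise ValueError("grid too small for requested VOI volume")
    seed = tuple(int(i) for i in seed_point)
    for ax, i in enumerate(seed):
        if not (0 <= i < grid.shape[ax]):
            raise ValueError("seed point outside grid")

    # start at the hottest voxel within a one-voxel neighborhood of the seed
    lo = [max(0, s - 1) for s in seed]
    hi = [min(n, s + 2) for s, n in zip(seed, grid.shape)]
    sub = grid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    off = np.unravel_index(np.argmax(sub), sub.shape)
    start = tuple(l + o for l, o in zip(lo, off))

    mask = np.zeros(grid.shape, dtype=bool)
    mask[start] = True
    import heapq

    frontier: list[tuple[float, tuple[int, int, int]]] = []
    queued = np.zeros(grid.shape, dtype=bool)

    def push_neighbors(p: tuple[int, int, int]) -> None:
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for dk in (-1, 0, 1):
                    q = (p[0] + di, p[1] + dj, p[2] + dk)
                    if all(0 <= q[a] < grid.shape[a] for a in range(3)):
                        if not mask[q] and not queued[q]:
                            queued[q] = True
                            # max-heap on intensity; index tiebreak => deterministic
                            heapq.heappush(frontier, (-grid[q], q))

    push_neighbors(start)
    while mask.sum() < n_target and frontier:
        _, q = heapq.heappop(frontier)
        if mask[q]:
            continue
        mask[q] = True
        push_neighbors(q)
    return VOI.from_mask(vol, mask)


def read_volume(path) -> ActivityVolume:
    """Read a NIfTI activity volume (Bq/ml); time p.i. from the header extension
    is not used — pass it explicitly via the returned object if needed."""
    import nibabel as nib

    img = nib.load(str(path))
    # zooms are float32 in the header; round to nm precision so volumes
    # recomputed from the spacing match values derived before writing
    spacing = round(float(img.header.get_zooms()[0]), 6)
    t = float(img.header["cal_max"])  # stored by write_volume
    return ActivityVolume(np.asanyarray(img.dataobj, dtype=float), spacing, t)


def write_volume(vol: ActivityVolume, path) -> None:
    """Write an activity volume as NIfTI with spacing in the header (Bq/ml)."""
    import nibabel as nib

    affine = np.diag([vol.voxel_size_mm] * 3 + [1.0])
    img = nib.Nifti1Image(vol.voxels.astype(np.float64), affine)
    img.header.set_zooms((vol.voxel_size_mm,) * 3)
    img.header["cal_max"] = vol.time_post_injection_h  # stash acquisition time
    nib.save(img, str(path))
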