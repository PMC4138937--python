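"""Volumetric mode: ROI spheres painted into a voxel grid, NIfTI I/O.

The decoder itself consumes ROI-level features; this module exists so
the imaging path (voxelwise fALFF -> Gaussian smoothing -> global-mean
normalization -> sphere averaging) can be exercised end to end on
synthetic data.  Geometry is standard 3 mm isotropic MNI-like space:
world coordinates x = affine @ ijk, spheres of the template's radius
around each ROI centre.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .falff import SpectralBands, detrend_linear, falff_matrix, normalize_global_mean, smooth_gaussian
from .simulate import SimulationConfig, SubjectRecording, simulate_subject_timeseries
from .template import RoiTemplate


def default_affine(template: RoiTemplate, voxel_size: float = 3.0,
                   margin_mm: float = 9.0) -> tuple[tuple[int, int, int], np.ndarray]:
    """Smallest axis-aligned grid (shape, affine) covering the template.

    The affine maps voxel indices to MNI mm with isotropic voxels and a
    margin around the extreme ROI centres.
    """
    lo = template.coords.min(axis=0) - margin_mm - template.radius
    hi = template.coords.max(axis=0) + margin_mm + template.radius
    shape = np.ceil((hi - lo) / voxel_size).astype(int) + 1
    affine = np.diag([voxel_size] * 3 + [1.0])
    affine[:3, 3] = lo
    return tuple(int(s) for s in shape), affine


def sphere_masks(template: RoiTemplate, shape: tuple[int, int, int],
                 affine: np.ndarray) -> list[np.ndarray]:
    """Boolean voxel mask per ROI (template order)."""
    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    vox = np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1)
    world = vox @ affine.T  # (..., 4)
    masks = []
    for centre in template.coords:
        d2 = ((world[..., :3] - centre) ** 2).sum(axis=-1)
        masks.append(d2 <= template.radius**2)
    return masks


def paint_recording(recording: SubjectRecording, template: RoiTemplate,
                    shape: tuple[int, int, int] | None = None,
                    affine: np.ndarray | None = None,
                    noise_sigma: float = 0.0,
                    seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Paint an ROI-level recording into a 4-D grid (x, y, z, t).

    Each ROI's series fills its sphere; optional voxelwise white noise
    on top.  Returns ``(volume4d, affine)``.
    """
    if shape is None or affine is None:
        shape, affine = default_affine(template)
    masks = sphere_masks(template, shape, affine)
    n_t = recording.data.shape[0]
    vol = np.zeros(shape + (n_t,))
    for j, m in enumerate(masks):
        vol[m, :] = recording.data[:, j]
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        vol += rng.normal(0.0, noise_sigma, size=vol.shape)
    return vol, affine


def simulate_volumetric_recording(config: SimulationConfig, template: RoiTemplate,
                                  condition: str, subject_seed: int,
                                  voxel_noise_sigma: float = 0.5,
                                  subject_id: str | None = None
                                  ) -> tuple[np.ndarray, np.ndarray, SubjectRecording]:
    """ROI-level simulation painted into a volume with voxel noise."""
    rec = simulate_subject_timeseries(config, template, condition, subject_seed,
                                      subject_id=subject_id)
    vol, affine = paint_recording(rec, template, noise_sigma=voxel_noise_sigma,
                                  seed=subject_seed)
    return vol, affine, rec


def falff_volume(vol4d: np.ndarray, tr: float, bands: SpectralBands | None = None,
                 n_discard: int = 0, mask: np.ndarray | None = None,
                 fwhm_mm: float = 6.0, voxel_size_mm: float = 3.0,
                 normalize: bool = True) -> np.ndarray:
    """Voxelwise fALFF map: trim -> detrend -> fALFF -> smooth -> normalize.

    ``mask`` restricts the global-mean normalization (default: all
    voxels with defined fALFF).  Order of operations follows the
    modelled pipeline: the map is smoothed first, then divided by the
    global mean.
    """
    vol4d = np.asarray(vol4d, dtype=float)
    if vol4d.ndim != 4:
        raise ValueError("expected a 4-D (x, y, z, t) array")
    data = vol4d[..., n_discard:]
    flat = data.reshape(-1, data.shape[-1])
    detr = detrend_linear(flat)
    vals = falff_matrix(detr.T, tr, bands)
    fmap = vals.reshape(vol4d.shape[:3])
    fmap = smooth_gaussian(np.nan_to_num(fmap), fwhm_mm, voxel_size_mm)
    if normalize:
        if mask is None:
            mask = np.isfinite(fmap) & (fmap > 0)
        fmap = normalize_global_mean(fmap, mask)
    return fmap


def save_nifti(data: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def load_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine
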