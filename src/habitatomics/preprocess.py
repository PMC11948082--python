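"""Volume normalization before habitat analysis and feature extraction.

Fixed order: N4 bias-field correction → B-spline resampling to isotropic
1 mm³ voxels → piecewise-linear (Nyul-style) histogram standardization.
The standardization step is idempotent: re-running it moves the landmarks
by less than 1e-6.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .images import ImageVolume, TumorMask

__all__ = [
    "PreprocessConfig",
    "bias_field_correct",
    "resample_isotropic",
    "standardize_histogram",
    "tumor_landmarks",
    "preprocess_pair",
]

#: Decile landmark set (plus the 1st/99th tails) used for standardization,
#: computed inside the tumor mask.
DEFAULT_LANDMARK_PERCENTILES = (1, 10, 20, 30, 40, 50, 60, 70, 80, 90, 99)


@dataclass
class PreprocessConfig:
    """Knobs for the normalization pipeline.

    target_spacing : mm, isotropic resampling target (default 1.0)
    interpolation_order : spline degree for intensities (default 3);
        masks always go nearest-neighbour
    landmark_percentiles : strictly increasing percentiles in (0, 100)
    bias_correction : toggle N4
    n4_shrink : integer shrink factor applied before N4 fitting
    n4_iterations : iterations per fitting level
    """

    target_spacing: float = 1.0
    interpolation_order: int = 3
    landmark_percentiles: tuple = DEFAULT_LANDMARK_PERCENTILES
    bias_correction: bool = True
    n4_shrink: int = 2
    n4_iterations: tuple = (20, 20, 20)

    def __post_init__(self):
        if self.target_spacing <= 0:
            raise ValueError("target_spacing must be positive")
        p = np.asarray(self.landmark_percentiles, float)
        if np.any(np.diff(p) <= 0) or p[0] <= 0 or p[-1] >= 100:
            raise ValueError("landmark percentiles must be strictly increasing in (0,100)")


def _to_sitk(volume):
    img = sitk.GetImageFromArray(np.asarray(volume.voxels, np.float64))
    img.SetSpacing(tuple(volume.spacing[::-1]))  # sitk wants (x,y,z)
    img.SetOrigin(tuple(volume.origin[::-1]))
    return img


def bias_field_correct(volume: ImageVolume, mask: TumorMask, config=None) -> ImageVolume:
    """Remove a smooth multiplicative intensity field (N4 algorithm).

    The field is estimated on the tumor mask dilated by 3 voxels (the bias
    varies slowly, so a neighbourhood suffices) and applied to the whole
    volume.  Non-negative input stays non-negative.
    """
    config = config or PreprocessConfig()
    mask.check_aligned(volume)
    if not np.all(np.isfinite(volume.voxels)):
        raise ValueError("volume contains non-finite voxels")
    fit_region = ndimage.binary_dilation(mask.voxels, iterations=3)
    inside = volume.voxels[fit_region]
    scale = np.abs(inside).mean()
    if scale == 0 or inside.std() / scale < 1e-6:
        # (near-)constant region: nothing to correct, and N4's histogram
        # sharpening is degenerate on a delta histogram
        return volume.copy_with(volume.voxels.copy())
    img = _to_sitk(volume)
    m = sitk.GetImageFromArray(fit_region.astype(np.uint8))
    m.CopyInformation(img)
    shrink = max(1, int(config.n4_shrink))
    small = sitk.Shrink(img, [shrink] * 3)
    small_m = sitk.Shrink(m, [shrink] * 3)
    f = sitk.N4BiasFieldCorrectionImageFilter()
    f.SetMaximumNumberOfIterations(list(config.n4_iterations))
    f.Execute(sitk.Cast(small, sitk.sitkFloat32), small_m)
    logfield = sitk.GetArrayFromImage(f.GetLogBiasFieldAsImage(img))
    # normalize so the field has unit geometric mean over the fit region:
    # correction removes smooth variation without rescaling the volume
    logfield = logfield - logfield[fit_region].mean()
    corrected = volume.voxels / np.exp(logfield)
    return volume.copy_with(corrected)


def resample_isotropic(volume: ImageVolume, mask: TumorMask, config=None):
    """Resample to isotropic spacing (degree-3 B-spline; NN for the mask)."""
    config = config or PreprocessConfig()
    mask.check_aligned(volume)
    sp = np.asarray(volume.spacing, float)
    if sp.max() / sp.min() > 20:
        warnings.warn("anisotropy ratio exceeds 20; resampling may blur heavily")
    t = float(config.target_spacing)
    if np.allclose(sp, t):
        return volume, mask
    new_size_zyx = np.maximum(8, np.round(np.array(volume.shape) * sp / t).astype(int))

    def _resample(img, interp):
        r = sitk.ResampleImageFilter()
        r.SetOutputSpacing((t, t, t))
        r.SetSize([int(s) for s in new_size_zyx[::-1]])
        r.SetOutputOrigin(img.GetOrigin())
        r.SetOutputDirection(img.GetDirection())
        r.SetInterpolator(interp)
        return sitk.GetArrayFromImage(r.Execute(img))

    interp = sitk.sitkBSpline if config.interpolation_order == 3 else sitk.sitkLinear
    new_vox = _resample(_to_sitk(volume), interp)
    mask_img = _to_sitk(ImageVolume(mask.voxels.astype(float), mask.spacing, mask.origin))
    new_mask = _resample(mask_img, sitk.sitkNearestNeighbor) > 0.5
    # keep the mask a single component (NN resampling can shed slivers)
    lab, ncomp = ndimage.label(new_mask, structure=np.ones((3, 3, 3), bool))
    if ncomp > 1:
        new_mask = lab == (np.bincount(lab.ravel())[1:].argmax() + 1)
    return (
        ImageVolume(new_vox, (t, t, t), volume.origin),
        TumorMask(new_mask, (t, t, t), volume.origin),
    )


def tumor_landmarks(volume: ImageVolume, mask: TumorMask, percentiles=DEFAULT_LANDMARK_PERCENTILES):
    """Intensity landmarks (percentiles) computed inside the tumor mask."""
    vals = volume.voxels[mask.voxels]
    if np.unique(vals).size < 2:
        raise ValueError("fewer than 2 distinct intensities inside the mask")
    return np.percentile(vals, percentiles)


def standardize_histogram(
    volume: ImageVolume,
    mask: TumorMask,
    reference_landmarks,
    percentiles=DEFAULT_LANDMARK_PERCENTILES,
) -> ImageVolume:
    """Map the volume's mask-interior landmarks onto reference landmarks.

    Piecewise-linear and monotone, with linear extrapolation beyond the
    outermost landmarks.  A volume whose landmarks already equal the
    reference is a fixed point.
    """
    ref = np.asarray(reference_landmarks, float)
    if np.any(np.diff(ref) <= 0):
        raise ValueError("reference landmarks must be strictly increasing")
    own = tumor_landmarks(volume, mask, percentiles)
    if np.any(np.diff(own) <= 0):
        # merge ties by nudging: keeps the map monotone on degenerate histograms
        own = own + np.arange(own.size) * 1e-9 * max(1.0, abs(own[-1]))
    x = volume.voxels
    out = np.interp(x, own, ref)
    # linear extrapolation of the end segments
    lo_slope = (ref[1] - ref[0]) / (own[1] - own[0])
    hi_slope = (ref[-1] - ref[-2]) / (own[-1] - own[-2])
    out = np.where(x < own[0], ref[0] + (x - own[0]) * lo_slope, out)
    out = np.where(x > own[-1], ref[-1] + (x - own[-1]) * hi_slope, out)
    return volume.copy_with(out)


def preprocess_pair(volume, mask, reference_landmarks=None, config=None):
    """Full pipeline: N4 → isotropic resampling → histogram standardization.

    If ``reference_landmarks`` is None the volume's own landmarks are used
    (identity standardization) — appropriate when fitting the reference on a
    training cohort is handled by the caller.
    """
    config = config or PreprocessConfig()
    if config.bias_correction:
        volume = bias_field_correct(volume, mask, config)
    volume, mask = resample_isotropic(volume, mask, config)
    if reference_landmarks is None:
        reference_landmarks = tumor_landmarks(volume, mask, config.landmark_percentiles)
    volume = standardize_histogram(volume, mask, reference_landmarks, config.landmark_percentiles)
    return volume, mask
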