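"""Image filter bank: original + 8 wavelet sub-bands + 4 LoG channels.

The wavelet decomposition is a single-level stationary (undecimated) 3D
transform, so every sub-band stays voxel-aligned with the input.  Sub-bands
are named by per-axis low/high-pass selection, LLL..HHH in (z, y, x) order.
LoG channels use scale-space sigmas expressed in mm and converted to voxels
through the spacing.
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy import ndimage

__all__ = ["apply_transforms", "CHANNEL_NAMES"]

DEFAULT_WAVELET = "coif1"
DEFAULT_LOG_SIGMAS_MM = (2.0, 3.0, 4.0, 5.0)

_WAVELET_BANDS = ["LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH"]


def channel_names(log_sigmas=DEFAULT_LOG_SIGMAS_MM):
    return (
        ["original"]
        + [f"wavelet-{b}" for b in _WAVELET_BANDS]
        + [f"log-sigma-{s:g}mm" for s in log_sigmas]
    )


CHANNEL_NAMES = channel_names()


def _swt_subbands(voxels, wavelet):
    # stationary transform needs even dimensions: pad with edge values, crop back
    shape = voxels.shape
    pad = [(0, s % 2) for s in shape]
    arr = np.pad(voxels, pad, mode="edge")
    coeffs = pywt.swtn(arr, wavelet, level=1)[0]
    out = {}
    for key, sub in coeffs.items():
        name = "".join("L" if c == "a" else "H" for c in key)
        out[name] = sub[: shape[0], : shape[1], : shape[2]]
    return out


def apply_transforms(
    volume, wavelet=DEFAULT_WAVELET, log_sigmas_mm=DEFAULT_LOG_SIGMAS_MM
):
    """Return the 13 named filter channels of an :class:`ImageVolume`.

    Each channel is voxel-aligned with the input.  Raises if the volume is
    smaller than the wavelet filter support.
    """
    voxels = volume.voxels
    w = pywt.Wavelet(wavelet)
    if min(voxels.shape) < w.dec_len:
        raise ValueError(
            f"volume shape {voxels.shape} smaller than the {wavelet} filter support"
        )
    channels = {"original": voxels}
    sub = _swt_subbands(voxels, wavelet)
    for b in _WAVELET_BANDS:
        channels[f"wavelet-{b}"] = sub[b]
    spacing = np.asarray(volume.spacing, float)
    for s in log_sigmas_mm:
        sigma_vox = s / spacing
        channels[f"log-sigma-{s:g}mm"] = ndimage.gaussian_laplace(voxels, sigma=sigma_vox)
    return channels
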