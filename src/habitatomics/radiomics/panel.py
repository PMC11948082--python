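"""Feature panel assembly and the study's exact feature accounting.

Per region the panel is 14 shape features (geometry only, computed once)
plus 93 intensity/texture features (18 first-order + 24 GLCM + 16 GLRLM +
16 GLSZM + 14 GLDM + 5 NGTDM) on each of 13 filter channels:

    14 + 93 × 13 = 1223 per region
    3 habitats   → 3669 per timepoint of habitat features
    2 timepoints → 2 × (1223 + 3669) = 9784 per patient

Feature names carry full provenance: ``timepoint|region|channel|family|name``.
Regions below 8 voxels produce an explicitly *flagged* all-NaN vector, never
silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .firstorder import FIRST_ORDER_NAMES, first_order_features
from .shape import SHAPE_NAMES, shape_features
from .texture import (
    GLCM_NAMES,
    GLDM_NAMES,
    GLRLM_NAMES,
    GLSZM_NAMES,
    NGTDM_NAMES,
    discretize,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)
from .transforms import DEFAULT_LOG_SIGMAS_MM, DEFAULT_WAVELET, apply_transforms, channel_names

MIN_REGION_VOXELS = 8

_FAMILY_EXTRACTORS = {
    "firstorder": None,  # handled separately (needs raw values + voxel volume)
    "glcm": (GLCM_NAMES, glcm_features),
    "glrlm": (GLRLM_NAMES, glrlm_features),
    "glszm": (GLSZM_NAMES, glszm_features),
    "gldm": (GLDM_NAMES, gldm_features),
    "ngtdm": (NGTDM_NAMES, ngtdm_features),
}

ALL_FAMILIES = ("firstorder", "glcm", "glrlm", "glszm", "gldm", "ngtdm")


@dataclass
class FeaturePanelConfig:
    """Which families/channels to extract and how to discretize.

    The default configuration reproduces the full 1223-feature accounting.
    ``bin_width`` applies to post-standardization intensities (default 25
    units).  A reduced config (e.g. ``families=("firstorder",),
    use_transforms=False``) is useful for large simulation studies.
    """

    families: tuple = ALL_FAMILIES
    include_shape: bool = True
    use_transforms: bool = True
    wavelet: str = DEFAULT_WAVELET
    log_sigmas_mm: tuple = DEFAULT_LOG_SIGMAS_MM
    bin_width: float = 25.0
    gldm_alpha: int = 0

    @property
    def channels(self):
        if self.use_transforms:
            return channel_names(self.log_sigmas_mm)
        return ["original"]

    def intensity_feature_names(self):
        names = []
        for fam in self.families:
            fam_names = (
                FIRST_ORDER_NAMES if fam == "firstorder" else _FAMILY_EXTRACTORS[fam][0]
            )
            names.extend((fam, n) for n in fam_names)
        return names

    @property
    def n_per_region(self):
        n = len(SHAPE_NAMES) if self.include_shape else 0
        return n + len(self.intensity_feature_names()) * len(self.channels)


def region_feature_names(config=None, prefix=""):
    """Ordered feature names for one region (optionally provenance-prefixed)."""
    config = config or FeaturePanelConfig()
    names = []
    if config.include_shape:
        names += [f"{prefix}original|shape|{n}" for n in SHAPE_NAMES]
    for ch in config.channels:
        for fam, n in config.intensity_feature_names():
            names.append(f"{prefix}{ch}|{fam}|{n}")
    return names


def extract_region_features(channels, region_mask, spacing, config=None):
    """Feature vector of one region given precomputed filter channels.

    Parameters
    ----------
    channels : dict name → 3D array (from :func:`apply_transforms`)
    region_mask : 3D bool array
    spacing : (mm, mm, mm)

    Returns
    -------
    values : ndarray, ordered as :func:`region_feature_names`
    flagged : bool — True when the region was degenerate (< 8 voxels)
    """
    config = config or FeaturePanelConfig()
    region = np.asarray(region_mask, bool)
    n = int(region.sum())
    n_expected = config.n_per_region
    if n < MIN_REGION_VOXELS:
        return np.full(n_expected, np.nan), True
    voxel_vol = float(np.prod(spacing))
    out = []
    if config.include_shape:
        sf = shape_features(region, spacing)
        out.extend(sf[k] for k in SHAPE_NAMES)
    fam_list = config.intensity_feature_names()
    for ch in config.channels:
        vol = channels[ch]
        vals = vol[region]
        levels_flat = discretize(vals, config.bin_width)
        levels = np.zeros(region.shape, np.int64)
        levels[region] = levels_flat
        ng = int(levels_flat.max())
        cache = {}
        for fam, name in fam_list:
            if fam not in cache:
                if fam == "firstorder":
                    cache[fam] = first_order_features(vals, voxel_vol, levels_flat)
                elif fam == "gldm":
                    cache[fam] = gldm_features(levels, region, config.gldm_alpha, ng)
                else:
                    cache[fam] = _FAMILY_EXTRACTORS[fam][1](levels, region, ng)
            out.append(cache[fam][name])
    return np.asarray(out, float), False


REGIONS = ("TR", "habitat1", "habitat2", "habitat3")


def extract_patient_features(
    pre_volume,
    pre_mask,
    pre_habitats,
    mid_volume,
    mid_mask,
    mid_habitats,
    config=None,
):
    """One patient's full feature row across both timepoints.

    Concatenates the whole-tumor (TR) panel and the three habitat (SHR)
    panels at each timepoint.  With the default config this is exactly
    2 × (1223 + 3·1223) = 9784 named values.  Empty habitats are flagged
    (NaN block) but the row is retained.

    Returns a pandas Series indexed by provenance-tagged names.
    """
    config = config or FeaturePanelConfig()
    values, names = [], []
    for tp, vol, msk, hab in (
        ("pre", pre_volume, pre_mask, pre_habitats),
        ("mid", mid_volume, mid_mask, mid_habitats),
    ):
        if config.use_transforms:
            channels = apply_transforms(vol, config.wavelet, config.log_sigmas_mm)
        else:
            channels = {"original": vol.voxels}
        regions = [("TR", msk.voxels)]
        regions += [
            (f"habitat{j}", hab.region_mask(j)) for j in range(1, hab.k + 1)
        ]
        for rname, rmask in regions:
            vec, _ = extract_region_features(channels, rmask, vol.spacing, config)
            values.append(vec)
            names.extend(region_feature_names(config, prefix=f"{tp}|{rname}|"))
    return pd.Series(np.concatenate(values), index=names)


def build_feature_table(patient_rows: dict) -> pd.DataFrame:
    """Stack per-patient Series (patients × features), names verified stable."""
    table = pd.DataFrame(patient_rows).T
    table.index.name = "patient_id"
    return table
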