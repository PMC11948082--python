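"""Synthetic phantoms, cohorts, reader perturbations, and omics tables.

The study conditions this package is tested under: breast tumors imaged at two
timepoints (pre- and mid-treatment) whose voxels belong to three latent
perfusion classes — high-enhancement, transitional, and hypoxic/necrotic —
with spatial composition that shifts under therapy.  Outcome labels (pCR vs
non-pCR) are drawn from a logistic model whose signal lives in *subregional*
image statistics (mid-treatment high-enhancement volume fraction and class
contrast) plus clinical covariates, while the whole-tumor mean intensity is
matched across outcomes by construction, so whole-tumor first-order averages
carry no outcome signal.

Everything here is a pure function of its parameters and a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import brentq

from .images import CONNECTIVITY_26, ImageVolume, TumorMask

__all__ = [
    "PhantomTruth",
    "PatientPhantom",
    "generate_phantom_pair",
    "generate_cohort",
    "perturb_mask",
    "dice",
    "generate_expression",
    "generate_celltype_table",
]

# Default intensity scale (arbitrary DCE-MR enhancement units): class 1 is the
# high-enhancement habitat, class 3 the marginal/necrotic one.  The classes
# differ in dispersion as well as mean — vascular, actively perfused tissue is
# texturally heterogeneous, the transitional rim relatively uniform, necrotic
# cores intermediate — so habitats are separable in (mean, SD, entropy) space,
# not merely along a single intensity axis.
DEFAULT_CLASS_MEANS = (300.0, 200.0, 100.0)
DEFAULT_CLASS_SDS = (20.0, 8.0, 14.0)
DEFAULT_NOISE_SD = 10.0
BACKGROUND_MEAN = 30.0

CELL_TYPES = ("epithelial", "basal", "endothelial", "fibroblast", "myeloid", "T", "B")
_CELL_BASE_PROBS = np.array([0.40, 0.08, 0.07, 0.15, 0.12, 0.13, 0.05])


@dataclass
class PhantomTruth:
    """Planted ground truth for one phantom pair.

    ``latent_class_map_pre/mid`` hold 0 outside the tumor and 1..3 inside;
    class means are strictly decreasing from class 1 to class 3.
    """

    latent_class_map_pre: np.ndarray
    latent_class_map_mid: np.ndarray
    class_means: tuple[float, float, float]
    class_sds: tuple[float, float, float]
    volume_fractions_pre: np.ndarray
    volume_fractions_mid: np.ndarray
    class_means_mid: tuple[float, float, float] = None

    def __post_init__(self):
        for fr in (self.volume_fractions_pre, self.volume_fractions_mid):
            fr = np.asarray(fr, float)
            if np.any(fr < -1e-12) or abs(fr.sum() - 1.0) > 1e-9:
                raise ValueError("volume fractions must lie in [0,1] and sum to 1")
        if self.class_means_mid is None:
            self.class_means_mid = self.class_means
        for m in (self.class_means, self.class_means_mid):
            if not (m[0] > m[1] > m[2]):
                raise ValueError("class means must be strictly decreasing")

    def empirical_fractions(self, timepoint: str = "pre") -> np.ndarray:
        cmap = self.latent_class_map_pre if timepoint == "pre" else self.latent_class_map_mid
        counts = np.array([(cmap == c).sum() for c in (1, 2, 3)], float)
        return counts / counts.sum()


@dataclass
class PatientPhantom:
    """Image+mask pair at both timepoints with its planted truth."""

    pre_volume: ImageVolume
    pre_mask: TumorMask
    mid_volume: ImageVolume
    mid_mask: TumorMask
    truth: PhantomTruth


def _ellipsoid_mask(shape, center, semi_axes, jitter_field=None):
    zz, yy, xx = np.indices(shape, dtype=float)
    r = (
        ((zz - center[0]) / semi_axes[0]) ** 2
        + ((yy - center[1]) / semi_axes[1]) ** 2
        + ((xx - center[2]) / semi_axes[2]) ** 2
    )
    level = np.ones(shape) if jitter_field is None else 1.0 + jitter_field
    return r <= level


def _smooth_field(rng, shape, sigma_vox, amplitude):
    f = ndimage.gaussian_filter(rng.normal(size=shape), sigma=sigma_vox)
    sd = f.std()
    return f * (amplitude / sd) if sd > 0 else f


def _farthest_point_seeds(coords, k, rng):
    """Greedy farthest-point sampling of k seed voxels (spatial spread)."""
    seeds = [coords[rng.integers(len(coords))]]
    for _ in range(k - 1):
        d = np.min(
            [np.sum((coords - s) ** 2, axis=1) for s in seeds], axis=0
        )
        seeds.append(coords[int(np.argmax(d))])
    return np.array(seeds, float)


def _plant_classes(mask, fractions, rng, rim_weight=0.0):
    """Partition a mask into spatially coherent blobs with target fractions.

    Seeded competitive assignment: voxels start at their nearest seed
    (Voronoi), then quota repair moves voxels between classes until the
    class volumes match the requested fractions exactly (up to rounding);
    moves are ordered by distance regret so each class stays a coherent blob
    around its seed for convex-ish masks.

    ``rim_weight`` controls the spatial arrangement of class 1 (the
    high-enhancement habitat): 0 grows it as a compact blob around a seed
    point, 1 as a peripheral rim along the tumor boundary (peripherally
    enhancing morphology), intermediate values interpolate.  Arrangement
    changes the habitat's geometry without touching the intensity histogram.
    """
    fractions = np.asarray(fractions, float)
    coords = np.argwhere(mask).astype(float)
    n = len(coords)
    k = len(fractions)
    cmap = np.zeros(mask.shape, dtype=np.int16)
    active = np.where(fractions > 1e-12)[0]
    if len(active) == 1:
        cmap[mask] = active[0] + 1
        return cmap
    seeds = _farthest_point_seeds(coords, len(active), rng)
    dist = np.stack([np.sqrt(np.sum((coords - s) ** 2, axis=1)) for s in seeds], axis=1)
    if rim_weight > 0 and 0 in active:
        depth = ndimage.distance_transform_edt(mask)[tuple(coords.astype(int).T)]
        scale = max(dist[:, 0].std(), 1e-9) / max(depth.std(), 1e-9)
        j = int(np.where(active == 0)[0][0])
        dist[:, j] = (1 - rim_weight) * dist[:, j] + rim_weight * scale * depth * 3.0
    # integer quotas by largest remainder
    raw = fractions[active] * n
    target = np.floor(raw).astype(int)
    for j in np.argsort(raw - np.floor(raw))[::-1][: n - target.sum()]:
        target[j] += 1
    assign = np.argmin(dist, axis=1)
    # quota repair: bulk-move minimum-regret voxels from over- to under-full
    # classes (voxels closest to the receiving seed move first, keeping the
    # blobs spatially coherent)
    for _ in range(3 * len(active) ** 2):
        counts = np.bincount(assign, minlength=len(active))
        excess = counts - target
        if np.all(excess == 0):
            break
        o = int(np.argmax(excess))
        u = int(np.argmin(excess))
        need = min(excess[o], -excess[u])
        cand = np.where(assign == o)[0]
        regret = dist[cand, u] - dist[cand, o]
        assign[cand[np.argsort(regret, kind="stable")[:need]]] = u
    labels = active[assign] + 1
    cmap[tuple(coords.astype(int).T)] = labels
    return cmap


def _render_intensities(rng, shape, cmap, class_means, class_sds, noise_sd):
    vol = rng.normal(BACKGROUND_MEAN, max(noise_sd, 1e-9), size=shape)
    for c in (1, 2, 3):
        sel = cmap == c
        if sel.any():
            vol[sel] = rng.normal(class_means[c - 1], max(class_sds[c - 1], 1e-9), sel.sum())
    return vol


def generate_phantom_pair(
    size=(32, 32, 32),
    fractions_pre=(0.45, 0.30, 0.25),
    fractions_mid=(0.25, 0.30, 0.45),
    class_means=DEFAULT_CLASS_MEANS,
    class_sds=DEFAULT_CLASS_SDS,
    noise_sd=DEFAULT_NOISE_SD,
    shrink=0.75,
    boundary_jitter=0.10,
    spacing=(1.0, 1.0, 1.0),
    class_means_mid=None,
    rim_weight_pre=0.0,
    rim_weight_mid=0.0,
    seed=0,
):
    """Generate a paired pre/mid phantom with three planted perfusion classes.

    Parameters
    ----------
    size : tuple of int
        Grid shape (z, y, x); must admit a ≥64-voxel tumor.
    fractions_pre, fractions_mid : 3 proportions each summing to 1
        Planted class volume fractions at the two timepoints.
    class_means, class_sds : 3 intensities each
        Per-class Gaussian intensity model; means strictly decreasing.
    noise_sd : float
        Background noise SD.
    shrink : float
        Linear shrink factor of the mid-treatment ellipsoid (≈ treatment
        response; volume shrinks by ``shrink**3``).
    boundary_jitter : float
        Relative amplitude of the smooth boundary perturbation (0 = exact
        ellipsoid).
    """
    fractions_pre = np.asarray(fractions_pre, float)
    fractions_mid = np.asarray(fractions_mid, float)
    for fr in (fractions_pre, fractions_mid):
        if abs(fr.sum() - 1.0) > 1e-9 or np.any(fr < -1e-12):
            raise ValueError("fractions must be non-negative and sum to 1")
    if np.any(np.asarray(class_sds) < 0):
        raise ValueError("class_sds must be non-negative")
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in size)
    center = np.array(shape, float) / 2.0 - 0.5
    semi = np.array(shape, float) * 0.33
    jit = (
        _smooth_field(rng, shape, sigma_vox=4.0, amplitude=boundary_jitter)
        if boundary_jitter > 0
        else None
    )

    if class_means_mid is None:
        class_means_mid = class_means

    def _make(axes, fractions, means, rim_weight):
        m = _ellipsoid_mask(shape, center, axes, jit)
        lab, ncomp = ndimage.label(m, structure=CONNECTIVITY_26)
        if ncomp > 1:  # keep the largest lump if jitter split the boundary
            m = lab == (np.bincount(lab.ravel())[1:].argmax() + 1)
        if m.sum() < 64:
            raise ValueError("tumor smaller than 64 voxels; increase size")
        cmap = _plant_classes(m, fractions, rng, rim_weight)
        vol = _render_intensities(rng, shape, cmap, means, class_sds, noise_sd)
        return m, cmap, vol

    m_pre, cmap_pre, vol_pre = _make(semi, fractions_pre, class_means, rim_weight_pre)
    m_mid, cmap_mid, vol_mid = _make(semi * shrink, fractions_mid, class_means_mid, rim_weight_mid)
    truth = PhantomTruth(
        cmap_pre, cmap_mid, tuple(class_means), tuple(class_sds),
        fractions_pre, fractions_mid, tuple(class_means_mid),
    )
    return (
        ImageVolume(vol_pre, spacing),
        TumorMask(m_pre, spacing),
        ImageVolume(vol_mid, spacing),
        TumorMask(m_mid, spacing),
        truth,
    )


# ---------------------------------------------------------------------------
# cohort generation


_CT_LEVELS = ("cT1", "cT2", "cT3", "cT4")
# marginal frequencies roughly matching a locally-advanced NAT population
_CT_PROBS = (0.07, 0.66, 0.18, 0.09)
_P_HER2 = 0.42
_P_ER = 0.60


#: Whole-tumor moment targets enforced on every phantom: the signal is
#: strictly subregional, so first- and second-moment whole-tumor summaries
#: are matched across patients by construction.
WHOLE_TUMOR_MEAN = 200.0
WHOLE_TUMOR_VARIANCE = 10000.0


def _pinned_class_means(fractions, d1, sds, mean=WHOLE_TUMOR_MEAN, var=WHOLE_TUMOR_VARIANCE):
    """Class means (m2+d1, m2, m2−d3) with whole-tumor mean and variance
    pinned to fixed targets.

    Given the class fractions, the class-1 contrast d1, and the class SDs,
    m2 follows from the mean constraint and the class-3 contrast d3 is
    solved from the variance constraint (clamped to [30, 300] when the
    targets are unattainable for extreme draws).
    """
    f1, f2, f3 = fractions
    s2 = f1 * sds[0] ** 2 + f2 * sds[1] ** 2 + f3 * sds[2] ** 2

    def excess(d3):
        m2 = mean - f1 * d1 + f3 * d3
        mu = (m2 + d1, m2, m2 - d3)
        return (
            s2
            + f1 * mu[0] ** 2 + f2 * mu[1] ** 2 + f3 * mu[2] ** 2
            - mean**2
            - var
        )

    lo, hi = 30.0, 300.0
    if excess(lo) >= 0:
        d3 = lo
    elif excess(hi) <= 0:
        d3 = hi
    else:
        d3 = brentq(excess, lo, hi)
    m2 = mean - f1 * d1 + f3 * d3
    return (m2 + d1, m2, m2 - d3)


def _subtype(er, her2):
    if her2 == "pos":
        return "HER2+"
    if er == "pos":
        return "HR+/HER2-"
    return "TN"


def generate_cohort(
    n_patients=80,
    effect=2.5,
    clinical_log_odds=(0.9, 0.8, 0.7),
    pcr_base_rate=0.396,
    size=(28, 28, 28),
    class_sds=DEFAULT_CLASS_SDS,
    noise_sd=DEFAULT_NOISE_SD,
    generate_images=True,
    seed=0,
):
    """Generate a cohort of phantom pairs with causally-linked outcomes.

    The linear predictor of the outcome logistic model is::

        b0 + effect * (z(f1_mid) + 0.5*z(rim_mid) + 0.25*z(contrast_mid))
           + b_cT1*[cT1] + b_HER2*[HER2+] + b_ERneg*[ER-]

    where ``f1_mid`` is the planted mid-treatment class-1 (high-enhancement)
    volume fraction, ``rim_mid`` its spatial arrangement (compact core → 0,
    peripheral rim → 1), and ``contrast_mid`` the planted class-1/class-2
    intensity gap.  Per-patient class means are chosen so every tumor has the
    same whole-tumor mean *and* variance (moment pinning), and arrangement
    never alters the histogram at all: the outcome signal lives in the
    subregional decomposition, not in whole-tumor summaries.

    Returns
    -------
    cohort : DataFrame
        One row per patient: patient_id, cT_stage, ER, HER2, subtype, outcome,
        plus the planted fractions (columns prefixed ``true_``).
    phantoms : list of PatientPhantom
    """
    if n_patients < 20:
        raise ValueError("n_patients must be >= 20")
    if not 0 < pcr_base_rate < 1:
        raise ValueError("pcr_base_rate must be in (0,1)")
    if effect < 0:
        raise ValueError("effect must be non-negative")
    rng = np.random.default_rng(seed)
    b_ct1, b_her2, b_erneg = clinical_log_odds

    for attempt in range(10):
        ct = rng.choice(_CT_LEVELS, size=n_patients, p=_CT_PROBS)
        her2 = np.where(rng.random(n_patients) < _P_HER2, "pos", "neg")
        er = np.where(rng.random(n_patients) < _P_ER, "pos", "neg")

        frac_pre = rng.dirichlet((8.0, 6.0, 5.0), size=n_patients)
        frac_mid = rng.dirichlet((4.0, 5.0, 7.0), size=n_patients)
        # per-patient class-contrast: the class1-class2 intensity gap at
        # mid-treatment (enters the outcome model); the pre-treatment gap and
        # the per-class dispersions are outcome-independent nuisance
        # heterogeneity
        contrast = 100.0 * np.clip(1.0 + 0.35 * rng.standard_normal(n_patients), 0.4, 1.8)
        contrast_pre = 100.0 * np.clip(1.0 + 0.35 * rng.standard_normal(n_patients), 0.4, 1.8)
        sd_jitter = np.clip(1.0 + 0.25 * rng.standard_normal((n_patients, 3)), 0.5, 1.6)
        # spatial arrangement of the high-enhancement habitat at each
        # timepoint: 0 = compact core, 1 = peripheral rim.  The mid-treatment
        # arrangement enters the outcome model; the whole-tumor histogram is
        # blind to it by construction.
        rim_mid = rng.uniform(0.0, 1.0, n_patients)
        rim_pre = rng.uniform(0.0, 1.0, n_patients)

        def z(v):
            return (v - v.mean()) / v.std()

        lp_covariates = (
            effect * (z(frac_mid[:, 0]) + 0.5 * z(rim_mid) + 0.25 * z(contrast))
            + b_ct1 * (ct == "cT1")
            + b_her2 * (her2 == "pos")
            + b_erneg * (er == "neg")
        )

        def mean_rate(b0, lp=lp_covariates):
            return float(np.mean(1.0 / (1.0 + np.exp(-(b0 + lp))))) - pcr_base_rate

        b0 = brentq(mean_rate, -30, 30)
        p = 1.0 / (1.0 + np.exp(-(b0 + lp_covariates)))
        outcome = rng.random(n_patients) < p
        if 0 < outcome.sum() < n_patients:
            break
        warnings.warn("degenerate all-one-outcome draw; re-drawing cohort")
    else:
        raise RuntimeError("could not draw a two-class cohort in 10 attempts")

    phantoms = []
    base_sds = np.asarray(class_sds, float)
    for i in range(n_patients if generate_images else 0):
        sds_i = base_sds * sd_jitter[i]
        means_pre = _pinned_class_means(frac_pre[i], contrast_pre[i], sds_i)
        means_mid = _pinned_class_means(frac_mid[i], contrast[i], sds_i)
        pv, pm, mv, mm, truth = generate_phantom_pair(
            size=size,
            fractions_pre=frac_pre[i],
            fractions_mid=frac_mid[i],
            class_means=means_pre,
            class_means_mid=means_mid,
            class_sds=tuple(sds_i),
            noise_sd=noise_sd,
            rim_weight_pre=rim_pre[i],
            rim_weight_mid=rim_mid[i],
            seed=rng.integers(2**31 - 1),
        )
        phantoms.append(PatientPhantom(pv, pm, mv, mm, truth))

    cohort = pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(n_patients)],
            "cT_stage": ct,
            "ER": er,
            "HER2": her2,
            "subtype": [_subtype(e, h) for e, h in zip(er, her2)],
            "outcome": np.where(outcome, "pCR", "non-pCR"),
            "true_f1_mid": frac_mid[:, 0],
            "true_contrast": contrast,
            "true_rim_mid": rim_mid,
        }
    )
    return cohort, phantoms


# ---------------------------------------------------------------------------
# reader-perturbation simulation


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    return 2.0 * np.logical_and(a, b).sum() / denom if denom else 1.0


def perturb_mask(mask: TumorMask, magnitude: float, seed=0) -> TumorMask:
    """Simulate a re-delineation: jitter the mask boundary by ``magnitude`` mm.

    A smooth Gaussian random field (unit SD, correlation length ≈ 4 voxels) is
    compared against the signed Euclidean distance to the boundary; voxels
    whose inside-distance exceeds the field value stay in the mask.  At
    magnitude 0 the mask is returned unchanged; expected Dice against the
    original decreases monotonically in magnitude.
    """
    if magnitude < 0:
        raise ValueError("magnitude must be non-negative")
    if magnitude == 0:
        return TumorMask(mask.voxels.copy(), mask.spacing, mask.origin)
    rng = np.random.default_rng(seed)
    m = mask.voxels
    d_in = ndimage.distance_transform_edt(m, sampling=mask.spacing)
    d_out = ndimage.distance_transform_edt(~m, sampling=mask.spacing)
    signed = np.where(m, d_in, -d_out)  # mm, positive inside
    for _ in range(10):
        g = _smooth_field(rng, m.shape, sigma_vox=4.0, amplitude=magnitude)
        new = signed > g
        lab, ncomp = ndimage.label(new, structure=CONNECTIVITY_26)
        if ncomp >= 1:
            sizes = np.bincount(lab.ravel())[1:]
            new = lab == (sizes.argmax() + 1)
            if new.sum() >= 64:
                return TumorMask(new, mask.spacing, mask.origin)
    raise RuntimeError("perturbation emptied the mask in 10 attempts")


# ---------------------------------------------------------------------------
# expression + cell-type tables


def generate_expression(
    n_genes=2000,
    n_samples=60,
    group=None,
    marker_sets=None,
    shift=2.0,
    mean_log=4.0,
    sd_log=1.5,
    dispersion=0.15,
    seed=0,
):
    """Negative-binomial count matrix with group-dependent marker shifts.

    Gene baselines are lognormal; genes in ``marker_sets`` are multiplied by
    ``2**shift`` in ``group == 1`` ("high") samples.  Gene lengths (kb) are
    attached for downstream TPM normalization.

    Returns an :class:`habitatomics.immune.ExpressionMatrix` holding raw
    counts.
    """
    from .immune import ExpressionMatrix

    if n_samples < 6:
        raise ValueError("n_samples must be >= 6")
    rng = np.random.default_rng(seed)
    if group is None:
        group = (np.arange(n_samples) % 2).astype(int)
    group = np.asarray(group, int)
    if group.size != n_samples or len(np.unique(group)) < 2:
        raise ValueError("group must label both classes across n_samples samples")
    genes = np.array([f"G{i:05d}" for i in range(n_genes)])
    universe = set(genes)
    marker_sets = dict(marker_sets or {})
    for name, members in marker_sets.items():
        unknown = [g for g in members if g not in universe]
        if unknown:
            raise KeyError(f"marker gene(s) not in universe for set '{name}': {unknown}")

    base = rng.lognormal(mean_log, sd_log, size=n_genes)
    lengths_kb = rng.lognormal(0.7, 0.4, size=n_genes)  # ≈ 2 kb median
    mu = np.tile(base[:, None], (1, n_samples))
    marker_idx = sorted(
        {int(np.where(genes == g)[0][0]) for members in marker_sets.values() for g in members}
    )
    if marker_idx:
        mu[np.ix_(marker_idx, np.where(group == 1)[0])] *= 2.0**shift
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu / shape)
    counts = rng.poisson(lam).astype(float)
    return ExpressionMatrix(
        values=pd.DataFrame(counts, index=genes, columns=[f"S{j:03d}" for j in range(n_samples)]),
        gene_lengths_kb=pd.Series(lengths_kb, index=genes),
        groups=pd.Series(group, index=[f"S{j:03d}" for j in range(n_samples)]),
        is_tpm=False,
    )


def generate_celltype_table(
    n_patients=20, group=None, b_cell_enrichment=5.0, cells_per_patient=2000, seed=0
):
    """Multinomial per-patient cell counts over 7 types.

    The B-cell probability is multiplied by ``b_cell_enrichment`` for
    group-1 ("high") patients, then renormalized.

    Returns
    -------
    counts : DataFrame, cell types × patients
    groups : Series, per-patient 0/1 labels
    """
    if b_cell_enrichment <= 0:
        raise ValueError("b_cell_enrichment must be positive")
    rng = np.random.default_rng(seed)
    if group is None:
        group = (np.arange(n_patients) % 2).astype(int)
    group = np.asarray(group, int)
    cols = [f"P{i:03d}" for i in range(n_patients)]
    out = np.zeros((len(CELL_TYPES), n_patients), dtype=int)
    for j in range(n_patients):
        p = _CELL_BASE_PROBS.copy()
        if group[j] == 1:
            p[CELL_TYPES.index("B")] *= b_cell_enrichment
        p /= p.sum()
        out[:, j] = rng.multinomial(cells_per_patient, p)
    return (
        pd.DataFrame(out, index=list(CELL_TYPES), columns=cols),
        pd.Series(group, index=cols, name="group"),
    )


# ---------------------------------------------------------------------------
# on-disk export (NIfTI pairs + CSV/TSV/GMT)


def write_cohort(outdir, cohort: pd.DataFrame, phantoms) -> None:
    """Write per-patient NIfTI volume/mask pairs and the cohort CSV."""
    from pathlib import Path

    from .images import write_volume

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for pid, ph in zip(cohort["patient_id"], phantoms):
        pdir = outdir / pid
        pdir.mkdir(exist_ok=True)
        write_volume(pdir / "pre_image.nii.gz", ph.pre_volume)
        write_volume(pdir / "pre_mask.nii.gz", ph.pre_mask)
        write_volume(pdir / "mid_image.nii.gz", ph.mid_volume)
        write_volume(pdir / "mid_mask.nii.gz", ph.mid_mask)
    cohort.to_csv(outdir / "cohort.csv", index=False)


def write_gmt(path, gene_sets: dict) -> None:
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            fh.write("\t".join([name, "synthetic"] + list(members)) + "\n")
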