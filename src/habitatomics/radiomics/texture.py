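"""Grey-level matrix textures on fixed-bin-width discretized intensities.

Conventions:

* discretization: level = floor((x − min(region)) / bin_width) + 1, so levels
  run 1..Ng within the region;
* GLCM: distance 1, the 13 unique 3D directions, symmetric; features are
  computed per direction and averaged;
* GLRLM: runs of identical level along the same 13 directions, features
  averaged over directions;
* GLSZM: 26-connected iso-level zones (single matrix, no directions);
* GLDM: dependence = 1 + number of 26-neighbours within ``alpha`` (=0) grey
  levels of the centre voxel;
* NGTDM: absolute difference between each voxel's level and the mean level of
  its in-region 26-neighbourhood.

Degenerate regions (a single grey level) yield the defined limiting values
rather than NaN.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

EPS = np.finfo(float).eps

GLCM_NAMES = [
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "JointEnergy", "JointEntropy",
    "Imc1", "Imc2", "Idm", "Idmn", "Id", "Idn", "InverseVariance",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares", "MCC",
]
GLRLM_NAMES = [
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
]
GLSZM_NAMES = [
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
    "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
]
GLDM_NAMES = [
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
]
NGTDM_NAMES = ["Coarseness", "Contrast", "Busyness", "Complexity", "Strength"]

#: 13 unique direction offsets (dz, dy, dx) of the 26-neighbourhood (one of
#: each ± pair).
DIRECTIONS_13 = [
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1),
    (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]

CONNECTIVITY_26 = np.ones((3, 3, 3), bool)


def discretize(values, bin_width):
    """Fixed-bin-width grey-level binning: levels 1..Ng."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    v = np.asarray(values, float)
    return (np.floor((v - v.min()) / bin_width)).astype(np.int64) + 1


def _shifted_views(arr, d):
    """Return aligned (source, destination) views for offset d."""
    sl_src, sl_dst = [], []
    for o in d:
        if o > 0:
            sl_src.append(slice(0, -o))
            sl_dst.append(slice(o, None))
        elif o < 0:
            sl_src.append(slice(-o, None))
            sl_dst.append(slice(0, o))
        else:
            sl_src.append(slice(None))
            sl_dst.append(slice(None))
    return arr[tuple(sl_src)], arr[tuple(sl_dst)]


# ---------------------------------------------------------------------------
# matrices


def glcm_matrices(levels, region, ng=None):
    """Symmetric co-occurrence matrix per direction: list of Ng×Ng counts."""
    ng = ng or int(levels[region].max())
    g = np.where(region, levels, 0)
    mats = []
    for d in DIRECTIONS_13:
        a, b = _shifted_views(g, d)
        valid = (a > 0) & (b > 0)
        i, j = a[valid] - 1, b[valid] - 1
        m = np.bincount(i * ng + j, minlength=ng * ng).reshape(ng, ng).astype(float)
        mats.append(m + m.T)
    return mats


def glrlm_matrices(levels, region, ng=None):
    """Run-length matrix per direction: list of Ng×Lmax counts."""
    ng = ng or int(levels[region].max())
    g = np.where(region, levels, 0)
    lmax = max(g.shape)
    mats = []
    for d in DIRECTIONS_13:
        # cont[v] = 1 if the run continues from v to v+d
        cont = np.zeros(g.shape, bool)
        a, b = _shifted_views(g, d)
        cont_sub = (a > 0) & (a == b)
        src, _ = _shifted_views(cont, d)
        src[...] = cont_sub
        # L[v] = length of the run starting at v (recurrence L = 1 + cont*L(v+d))
        L = (g > 0).astype(np.int64)
        for _ in range(lmax):
            shifted = np.zeros_like(L)
            s_view, d_view = _shifted_views(shifted, d)
            _, L_dst = _shifted_views(L, d)
            s_view[...] = L_dst
            newL = np.where(g > 0, 1 + np.where(cont, shifted, 0), 0)
            if np.array_equal(newL, L):
                break
            L = newL
        # run starts: no continuation arrives from v-d
        arrives = np.zeros(g.shape, bool)
        _, arr_dst = _shifted_views(arrives, d)
        arr_dst[...] = cont_sub
        starts = (g > 0) & ~arrives
        gl = g[starts] - 1
        rl = L[starts] - 1
        m = (
            np.bincount(gl * lmax + rl, minlength=ng * lmax)
            .reshape(ng, lmax)
            .astype(float)
        )
        mats.append(m[:, : max(1, int(rl.max()) + 1)] if rl.size else m[:, :1])
    return mats


def glszm_matrix(levels, region, ng=None):
    """Size-zone matrix: Ng × Smax counts of 26-connected iso-level zones."""
    ng = ng or int(levels[region].max())
    g = np.where(region, levels, 0)
    rows, sizes_all = [], []
    for level in range(1, ng + 1):
        lab, ncomp = ndimage.label(g == level, structure=CONNECTIVITY_26)
        if ncomp:
            sizes = np.bincount(lab.ravel())[1:]
            rows.extend([level - 1] * ncomp)
            sizes_all.extend(sizes.tolist())
    if not rows:
        return np.zeros((ng, 1))
    smax = max(sizes_all)
    m = np.zeros((ng, smax))
    for r, s in zip(rows, sizes_all):
        m[r, s - 1] += 1
    return m


def gldm_matrix(levels, region, alpha=0, ng=None):
    """Dependence matrix: Ng × Dmax; dependence = 1 + similar 26-neighbours."""
    ng = ng or int(levels[region].max())
    g = np.where(region, levels, 0)
    dep = np.zeros(g.shape, np.int64)
    for d in DIRECTIONS_13:
        a, b = _shifted_views(g, d)
        hit = (a > 0) & (b > 0) & (np.abs(a - b) <= alpha)
        av, _ = _shifted_views(dep, d)
        av += hit
        _, bv = _shifted_views(dep, d)
        bv += hit
    dep = np.where(g > 0, dep + 1, 0)
    gl = g[region] - 1
    dp = dep[region] - 1
    dmax = int(dp.max()) + 1
    return (
        np.bincount(gl * dmax + dp, minlength=ng * dmax).reshape(ng, dmax).astype(float)
    )


def ngtdm_table(levels, region, ng=None):
    """Per-level (n_i, p_i, s_i) of the neighbourhood grey-tone difference."""
    ng = ng or int(levels[region].max())
    g = np.where(region, levels, 0).astype(float)
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0
    nb_sum = ndimage.convolve(g * region, kernel, mode="constant")
    nb_cnt = ndimage.convolve(region.astype(float), kernel, mode="constant")
    valid = region & (nb_cnt > 0)
    diff = np.zeros(g.shape)
    diff[valid] = np.abs(g[valid] - nb_sum[valid] / nb_cnt[valid])
    gl = (levels[valid] - 1).astype(int)
    n_i = np.bincount(gl, minlength=ng).astype(float)
    s_i = np.bincount(gl, weights=diff[valid], minlength=ng)
    n_total = n_i.sum()
    p_i = n_i / n_total if n_total else n_i
    return n_i, p_i, s_i


# ---------------------------------------------------------------------------
# features


def _glcm_features_single(m):
    p = m / m.sum()
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float((ii * p).sum())
    sig = np.sqrt(((ii - mu) ** 2 * p).sum())
    # diagonal (difference) and cross-diagonal (sum) distributions
    k_diff = np.arange(ng)
    p_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in k_diff])
    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.array([p[(ii + jj) == k].sum() for k in k_sum])
    da = float((k_diff * p_diff).sum())
    nz = p > 0
    hxy = float(-(p[nz] * np.log2(p[nz])).sum())
    px_nz = px[px > 0]
    hx = float(-(px_nz * np.log2(px_nz)).sum())
    pxy = np.outer(px, px)
    both = nz & (pxy > 0)
    hxy1 = float(-(p[both] * np.log2(pxy[both])).sum())
    pq = pxy[pxy > 0]
    hxy2 = float(-(pq * np.log2(pq)).sum())
    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1 - np.exp(-2 * (hxy2 - hxy))))) if hxy2 >= hxy else 0.0
    corr = float(((ii * jj * p).sum() - mu * mu) / (sig * sig)) if sig > 0 else 1.0
    off = np.abs(ii - jj) > 0
    inv_var = float((p[off] / (ii - jj)[off] ** 2).sum()) if off.any() else 0.0
    if ng > 1:
        # Q_ij = sum_k p(i,k) p(j,k) / (px_i px_k)
        q = np.einsum("ik,jk->ij", p / np.maximum(px, EPS)[:, None], p / np.maximum(px, EPS)[None, :])
        ev = np.sort(np.real(np.linalg.eigvals(q)))
        mcc = float(np.sqrt(max(0.0, ev[-2]))) if ev.size > 1 else 1.0
    else:
        mcc = 1.0
    dnz = p_diff > 0
    snz = p_sum > 0
    return dict(
        zip(
            GLCM_NAMES,
            [
                float((ii * jj * p).sum()),
                mu,
                float(((ii + jj - 2 * mu) ** 4 * p).sum()),
                float(((ii + jj - 2 * mu) ** 3 * p).sum()),
                float(((ii + jj - 2 * mu) ** 2 * p).sum()),
                float(((ii - jj) ** 2 * p).sum()),
                corr,
                da,
                float(-(p_diff[dnz] * np.log2(p_diff[dnz])).sum()),
                float(((k_diff - da) ** 2 * p_diff).sum()),
                float((p**2).sum()),
                hxy,
                imc1,
                imc2,
                float((p / (1 + (ii - jj) ** 2)).sum()),
                float((p / (1 + ((ii - jj) / ng) ** 2)).sum()),
                float((p / (1 + np.abs(ii - jj))).sum()),
                float((p / (1 + np.abs(ii - jj) / ng)).sum()),
                inv_var,
                float(p.max()),
                float((k_sum * p_sum).sum()),
                float(-(p_sum[snz] * np.log2(p_sum[snz])).sum()),
                float(((ii - mu) ** 2 * p).sum()),
                mcc,
            ],
        )
    )


def glcm_features(levels, region, ng=None):
    """Direction-averaged GLCM features (24)."""
    mats = glcm_matrices(levels, region, ng)
    per_dir = [_glcm_features_single(m) for m in mats if m.sum() > 0]
    if not per_dir:
        return dict.fromkeys(GLCM_NAMES, 0.0)
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLCM_NAMES}


def _sz_style_features(m, n_voxels, names):
    """Shared formula set of GLRLM/GLSZM (matrix rows=grey level, cols=size)."""
    nr = m.sum()
    ng, nl = m.shape
    i = np.arange(1, ng + 1)[:, None]
    j = np.arange(1, nl + 1)[None, :]
    p = m / nr
    pg = m.sum(axis=1)
    pl = m.sum(axis=0)
    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    nzp = p[p > 0]
    return dict(
        zip(
            names,
            [
                float((m / j**2).sum() / nr),
                float((m * j**2).sum() / nr),
                float((pg**2).sum() / nr),
                float((pg**2).sum() / nr**2),
                float((pl**2).sum() / nr),
                float((pl**2).sum() / nr**2),
                float(nr / n_voxels),
                float(((i - mu_i) ** 2 * p).sum()),
                float(((j - mu_j) ** 2 * p).sum()),
                float(-(nzp * np.log2(nzp)).sum()),
                float((m / i**2).sum() / nr),
                float((m * i**2).sum() / nr),
                float((m / (i**2 * j**2)).sum() / nr),
                float((m * i**2 / j**2).sum() / nr),
                float((m * j**2 / i**2).sum() / nr),
                float((m * i**2 * j**2).sum() / nr),
            ],
        )
    )


def glrlm_features(levels, region, ng=None):
    """Direction-averaged run-length features (16)."""
    mats = glrlm_matrices(levels, region, ng)
    n_voxels = int(region.sum())
    per_dir = [_sz_style_features(m, n_voxels, GLRLM_NAMES) for m in mats if m.sum() > 0]
    if not per_dir:
        return dict.fromkeys(GLRLM_NAMES, 0.0)
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLRLM_NAMES}


def glszm_features(levels, region, ng=None):
    """Size-zone features (16)."""
    m = glszm_matrix(levels, region, ng)
    if m.sum() == 0:
        return dict.fromkeys(GLSZM_NAMES, 0.0)
    return _sz_style_features(m, int(region.sum()), GLSZM_NAMES)


def gldm_features(levels, region, alpha=0, ng=None):
    """Dependence features (14)."""
    m = gldm_matrix(levels, region, alpha, ng)
    nz_total = m.sum()
    if nz_total == 0:
        return dict.fromkeys(GLDM_NAMES, 0.0)
    ng_, nd = m.shape
    i = np.arange(1, ng_ + 1)[:, None]
    j = np.arange(1, nd + 1)[None, :]
    p = m / nz_total
    pg = m.sum(axis=1)
    pd = m.sum(axis=0)
    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    nzp = p[p > 0]
    return dict(
        zip(
            GLDM_NAMES,
            [
                float((m / j**2).sum() / nz_total),
                float((m * j**2).sum() / nz_total),
                float((pg**2).sum() / nz_total),
                float((pd**2).sum() / nz_total),
                float((pd**2).sum() / nz_total**2),
                float(((i - mu_i) ** 2 * p).sum()),
                float(((j - mu_j) ** 2 * p).sum()),
                float(-(nzp * np.log2(nzp)).sum()),
                float((m / i**2).sum() / nz_total),
                float((m * i**2).sum() / nz_total),
                float((m / (i**2 * j**2)).sum() / nz_total),
                float((m * i**2 / j**2).sum() / nz_total),
                float((m * j**2 / i**2).sum() / nz_total),
                float((m * i**2 * j**2).sum() / nz_total),
            ],
        )
    )


def ngtdm_features(levels, region, ng=None):
    """Neighbourhood grey-tone difference features (5)."""
    n_i, p_i, s_i = ngtdm_table(levels, region, ng)
    n_total = n_i.sum()
    nz = p_i > 0
    ngp = int(nz.sum())
    i = np.arange(1, len(p_i) + 1, dtype=float)
    ps = float((p_i * s_i).sum())
    coarseness = 1.0 / ps if ps > 0 else 1e6
    if ngp > 1:
        iv, jv = np.meshgrid(i[nz], i[nz], indexing="ij")
        pv, qv = np.meshgrid(p_i[nz], p_i[nz], indexing="ij")
        sv, tv = np.meshgrid(s_i[nz], s_i[nz], indexing="ij")
        contrast = float(
            (pv * qv * (iv - jv) ** 2).sum() / (ngp * (ngp - 1)) * s_i.sum() / n_total
        )
        denom = np.abs(iv * pv - jv * qv).sum()
        busyness = ps / denom if denom > 0 else 0.0
        complexity = float((np.abs(iv - jv) * (pv * sv + qv * tv) / (pv + qv)).sum() / n_total)
        s_sum = s_i.sum()
        strength = float(((pv + qv) * (iv - jv) ** 2).sum() / s_sum) if s_sum > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0
    return dict(zip(NGTDM_NAMES, [coarseness, contrast, busyness, complexity, strength]))
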