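"""Group inference on contrast maps.

One-sample and two-sample t maps, sign-preserving t-to-Z conversion,
threshold-free cluster enhancement (TFCE; Smith & Nichols 2009 form with
E = 0.5, H = 2, dh = 0.1 and 6-connectivity), and family-wise error control
by max-statistic permutation (sign flipping for one-sample designs, group
label permutation for two-sample designs) within a region-of-interest mask.

Two significance conventions are carried through: a contrast-wise alpha
(default 0.05) and a stricter experiment-wise alpha dividing it by the
number of contrasts examined (0.05 / 6 = 0.008333 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from scipy import ndimage, stats

#: default enhancement parameters
TFCE_E = 0.5
TFCE_H = 2.0
TFCE_DH = 0.1

_STRUCT6 = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


class EmptyResultError(RuntimeError):
    """No suprathreshold voxels where some were required."""


@dataclass
class StatMap:
    data: np.ndarray  # (n_voxels,) within-mask values or full 3D volume
    df: int
    kind: str  # one_sample_t | two_sample_t | regression_t | z
    zero_variance: np.ndarray | None = None


@dataclass
class ROIMask:
    """Labeled integer volume (0 = background) with a name -> label table."""

    volume: np.ndarray
    labels: dict[str, int]

    def mask(self, name: str | None = None) -> np.ndarray:
        if name is None:
            return self.volume > 0
        return self.volume == self.labels[name]

    @property
    def names(self) -> list[str]:
        return list(self.labels)


@dataclass
class GroupResult:
    p_corrected: np.ndarray  # within-mask corrected p values
    tfce_observed: np.ndarray  # within-mask signed TFCE scores
    zmap: np.ndarray  # within-mask Z values
    mask: np.ndarray  # 3D boolean analysis mask
    alpha_cw: float
    alpha_ew: float
    supra_cw: np.ndarray = field(init=False)
    supra_ew: np.ndarray = field(init=False)
    cluster_table: pd.DataFrame | None = None
    subject_means: np.ndarray | None = None
    n_perm: int = 0
    exact: bool = False

    def __post_init__(self):
        self.supra_cw = self.p_corrected < self.alpha_cw
        self.supra_ew = self.p_corrected < self.alpha_ew


def to_volume(values: np.ndarray, mask: np.ndarray, fill=np.nan) -> np.ndarray:
    vol = np.full(mask.shape, fill, dtype=float)
    vol[mask] = values
    return vol


def _as_masked(maps, mask: np.ndarray | None) -> np.ndarray:
    maps = np.asarray(maps, dtype=float)
    if maps.ndim == 2:
        return maps
    if maps.ndim == 4:
        if mask is None:
            raise ValueError("4D subject maps require a mask")
        return maps[:, mask]
    raise ValueError("maps must be (n_subjects, n_voxels) or (n_subjects, x, y, z)")


# ----------------------------------------------------------------------
# t statistics


def one_sample_t(maps, mask: np.ndarray | None = None) -> StatMap:
    """Voxelwise one-sample t against 0; df = n - 1.

    Zero-variance voxels get t = +/-inf (sign of the mean) and are flagged.
    """
    m = _as_masked(maps, mask)
    n = m.shape[0]
    if n < 3:
        raise ValueError("one-sample t requires at least 3 subjects")
    mean = m.mean(axis=0)
    sd = m.std(axis=0, ddof=1)
    zero = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[zero] = np.sign(mean[zero]) * np.inf
    t[zero & (mean == 0)] = 0.0
    return StatMap(data=t, df=n - 1, kind="one_sample_t", zero_variance=zero)


def two_sample_t(
    maps_g1, maps_g2, mask: np.ndarray | None = None, welch: bool = False
) -> StatMap:
    """Independent-samples t (pooled variance by default; Welch optional)."""
    a = _as_masked(maps_g1, mask)
    b = _as_masked(maps_g2, mask)
    n1, n2 = a.shape[0], b.shape[0]
    if min(n1, n2) < 2:
        raise ValueError("two-sample t requires at least 2 subjects per group")
    d = a.mean(axis=0) - b.mean(axis=0)
    v1 = a.var(axis=0, ddof=1)
    v2 = b.var(axis=0, ddof=1)
    if welch:
        se2 = v1 / n1 + v2 / n2
        with np.errstate(divide="ignore", invalid="ignore"):
            df_v = se2**2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
        df = int(np.nanmedian(df_v)) if np.isfinite(df_v).any() else n1 + n2 - 2
    else:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se2 = sp2 * (1.0 / n1 + 1.0 / n2)
        df = n1 + n2 - 2
    zero = se2 == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = d / np.sqrt(se2)
    t[zero] = np.sign(d[zero]) * np.inf
    t[zero & (d == 0)] = 0.0
    return StatMap(data=t, df=df, kind="two_sample_t", zero_variance=zero)


def t_to_z(stat: StatMap) -> StatMap:
    """Sign-preserving conversion: Z carries the same two-sided p as t."""
    z = _t_to_z_values(stat.data, stat.df)
    return StatMap(data=z, df=stat.df, kind="z", zero_variance=stat.zero_variance)


def _t_to_z_values(t: np.ndarray, df: int) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    with np.errstate(over="ignore", invalid="ignore"):
        logp = stats.t.logsf(np.abs(t), df)  # log one-sided p
    z = stats.norm.isf(np.minimum(np.exp(logp), 0.5))
    tiny = (logp < -690) & np.isfinite(logp)  # exp underflow: asymptotic tail
    if np.any(tiny):
        u = -2.0 * logp[tiny]
        z[tiny] = np.sqrt(u - np.log(u) - np.log(2.0 * np.pi))
    z = np.where(np.isfinite(z), z, 39.0)
    return np.sign(t) * z


# ----------------------------------------------------------------------
# TFCE


def tfce(
    volume: np.ndarray,
    E: float = TFCE_E,
    H: float = TFCE_H,
    dh: float = TFCE_DH,
    two_sided: bool = True,
) -> np.ndarray:
    """Threshold-free cluster enhancement of a 3D map.

    Per voxel, sum over heights h (step dh) of extent(h)^E * h^H * dh where
    extent(h) is the size of the 6-connected cluster supporting the voxel at
    threshold h.  Negative values are enhanced on the negated map and
    re-signed.
    """
    if volume.ndim != 3:
        raise ValueError("tfce expects a 3D volume")
    if min(E, H, dh) <= 0:
        raise ValueError("E, H and dh must be positive")
    out = _tfce_onesided(np.maximum(volume, 0.0), E, H, dh)
    if two_sided:
        out -= _tfce_onesided(np.maximum(-volume, 0.0), E, H, dh)
    return out


def _tfce_onesided(pos: np.ndarray, E: float, H: float, dh: float) -> np.ndarray:
    out = np.zeros_like(pos, dtype=float)
    vmax = float(pos.max(initial=0.0))
    if vmax <= 0:
        return out
    heights = np.arange(dh, vmax + dh / 2, dh)
    for h in heights:
        supra = pos >= h
        if not supra.any():
            break
        labels, n_lab = ndimage.label(supra, structure=_STRUCT6)
        if n_lab == 0:
            continue
        sizes = np.bincount(labels.ravel())
        contrib = (sizes.astype(float) ** E) * (h**H) * dh
        contrib[0] = 0.0
        out += contrib[labels]
    return out


def _tfce_masked(values: np.ndarray, mask: np.ndarray, bbox, E, H, dh) -> np.ndarray:
    """TFCE of within-mask values, computed on the mask's bounding box."""
    sub = np.zeros([s.stop - s.start for s in bbox])
    sub[mask[bbox]] = values
    enh = tfce(sub, E, H, dh)
    return enh[mask[bbox]]


# ----------------------------------------------------------------------
# permutation FWE


def _bbox(mask: np.ndarray) -> tuple[slice, slice, slice]:
    sl = ndimage.find_objects(mask.astype(np.int8))[0]
    return sl


def _sign_matrix(n: int, n_perm: int, rng: np.random.Generator):
    """Sign-flip matrix; exact enumeration when 2^n <= n_perm."""
    if n <= 30 and 2**n <= n_perm:
        bits = np.arange(2**n)[:, None] >> np.arange(n)[None, :] & 1
        return np.where(bits == 1, 1.0, -1.0), True
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    signs[0] = 1.0  # identity permutation included
    return signs, False


def _label_perms(n1: int, n2: int, n_perm: int, rng: np.random.Generator):
    n = n1 + n2
    if comb(n, n1) <= n_perm:
        from itertools import combinations

        perms = []
        for idx in combinations(range(n), n1):
            g1 = np.zeros(n, dtype=bool)
            g1[list(idx)] = True
            perms.append(g1)
        return np.array(perms), True
    perms = np.zeros((n_perm, n), dtype=bool)
    perms[0, :n1] = True  # identity
    for i in range(1, n_perm):
        perms[i, rng.choice(n, size=n1, replace=False)] = True
    return perms, False


def permutation_fwe(
    maps,
    groups=None,
    n_perm: int = 1000,
    seed: int = 0,
    mask: np.ndarray | ROIMask | None = None,
    E: float = TFCE_E,
    H: float = TFCE_H,
    dh: float = TFCE_DH,
    alpha_cw: float = 0.05,
    n_contrasts: int = 6,
    subject_values: np.ndarray | None = None,
) -> GroupResult:
    """Max-TFCE permutation FWE correction within a mask.

    ``maps`` is (n_subjects, n_voxels) within-mask data (or 4D with a mask).
    ``groups`` is None for a one-sample (sign-flipping) test, else a boolean
    or two-level label vector for a two-sample (label-permutation) test.
    Corrected p per voxel is the proportion of permutations whose image-wide
    maximum TFCE score meets or exceeds the observed score (the identity
    permutation is always a member of the null set, so p >= 1/n_perm).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if isinstance(mask, ROIMask):
        mask = mask.mask()
    m = _as_masked(maps, mask)
    if mask is None:
        raise ValueError("permutation_fwe requires a 3D mask")
    if m.shape[1] != int(mask.sum()):
        raise ValueError("maps do not match mask voxel count")
    rng = np.random.default_rng(seed)
    bbox = _bbox(mask)
    n = m.shape[0]

    if groups is None:
        stat = one_sample_t(m)
        signs, exact = _sign_matrix(n, n_perm, rng)
        n_eff = signs.shape[0]
        msq = (m**2).mean(axis=0)
        mean = signs @ m / n
        var = np.maximum((msq[None, :] - mean**2) * n / (n - 1), 1e-300)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_all = mean / np.sqrt(var / n)
    else:
        g = np.asarray(groups)
        if g.dtype != bool:
            levels = pd.unique(g)
            if len(levels) != 2:
                raise ValueError("two-sample design requires exactly 2 groups")
            g = g == levels[0]
        n1 = int(g.sum())
        n2 = n - n1
        stat = two_sample_t(m[g], m[~g])
        # reorder so the identity permutation (first n1 rows) matches g
        m2 = np.vstack([m[g], m[~g]])
        perms, exact = _label_perms(n1, n2, n_perm, rng)
        n_eff = perms.shape[0]
        pmat = perms.astype(float)
        s_tot = m2.sum(axis=0)
        ss_tot = (m2**2).sum(axis=0)
        sum1 = pmat @ m2
        ssq1 = pmat @ (m2**2)
        mean1 = sum1 / n1
        mean2 = (s_tot[None, :] - sum1) / n2
        v1 = (ssq1 - n1 * mean1**2) / (n1 - 1)
        v2 = ((ss_tot[None, :] - ssq1) - n2 * mean2**2) / (n2 - 1)
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se2 = np.maximum(sp2 * (1.0 / n1 + 1.0 / n2), 1e-300)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_all = (mean1 - mean2) / np.sqrt(se2)

    z_obs = _t_to_z_values(stat.data, stat.df)
    tfce_obs = _tfce_masked(z_obs, mask, bbox, E, H, dh)

    z_all = _t_to_z_values(t_all, stat.df)
    max_null = np.empty(n_eff)
    for i in range(n_eff):
        enh = _tfce_masked(z_all[i], mask, bbox, E, H, dh)
        max_null[i] = np.abs(enh).max()

    exceed = (max_null[None, :] >= np.abs(tfce_obs)[:, None]).sum(axis=1)
    p_corr = exceed / n_eff

    result = GroupResult(
        p_corrected=p_corr,
        tfce_observed=tfce_obs,
        zmap=z_obs,
        mask=mask,
        alpha_cw=alpha_cw,
        alpha_ew=alpha_cw / n_contrasts,
        n_perm=n_eff,
        exact=exact,
    )
    result.cluster_table = _cluster_table(result, bbox)
    if subject_values is not None and result.supra_cw.any():
        result.subject_means = extract_suprathreshold_means(subject_values, result)
    return result


def _cluster_table(result: GroupResult, bbox) -> pd.DataFrame:
    rows = []
    mask = result.mask
    supra_vol = np.zeros(mask.shape, dtype=bool)
    supra_vol[mask] = result.supra_cw
    z_vol = to_volume(result.zmap, mask, fill=0.0)
    for sign in (1, -1):
        signed = supra_vol & ((z_vol > 0) if sign > 0 else (z_vol < 0))
        labels, n_lab = ndimage.label(signed[bbox], structure=_STRUCT6)
        for lab in range(1, n_lab + 1):
            idx = np.argwhere(labels == lab)
            zvals = np.array([z_vol[bbox][tuple(i)] for i in idx])
            peak_local = idx[np.argmax(np.abs(zvals))]
            peak = tuple(
                int(p + s.start) for p, s in zip(peak_local, bbox)
            )
            rows.append(
                {
                    "label": f"{'pos' if sign > 0 else 'neg'}_{lab}",
                    "size": len(idx),
                    "peak_x": peak[0],
                    "peak_y": peak[1],
                    "peak_z": peak[2],
                    "peak_z_value": float(zvals[np.argmax(np.abs(zvals))]),
                }
            )
    return pd.DataFrame(
        rows, columns=["label", "size", "peak_x", "peak_y", "peak_z", "peak_z_value"]
    )


def extract_suprathreshold_means(
    subject_maps, result: GroupResult, which: str = "cw"
) -> np.ndarray:
    """Per-subject mean contrast value over suprathreshold voxels."""
    supra = result.supra_cw if which == "cw" else result.supra_ew
    if not supra.any():
        raise EmptyResultError("no suprathreshold voxels to average over")
    m = _as_masked(subject_maps, result.mask)
    return m[:, supra].mean(axis=1)
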