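"""Brain-symptom association: Spearman correlations, Bonferroni scheme, and
a voxelwise symptom-regression map with TFCE permutation correction.

Regional contrast summaries (per-subject mean percent signal change over an
ROI or suprathreshold set) are correlated with clinical measures (SHAPS-C
anhedonia, CAPS emotional-numbing items, TEPS anticipatory/consummatory
pleasure) within the clinical group, with Bonferroni correction across
measures x regions (0.05 / (4 x 5) = 0.0025 by default).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .group import (
    GroupResult,
    ROIMask,
    StatMap,
    _as_masked,
    _bbox,
    _t_to_z_values,
    _tfce_masked,
    TFCE_DH,
    TFCE_E,
    TFCE_H,
)

DEFAULT_MEASURES = ("SHAPS_C", "CAPS_numbing", "TEPS_A", "TEPS_C")


def spearman_assoc(values, scores) -> tuple[float, float, int]:
    """Spearman rank correlation with average ranks for ties.

    Returns (rho, two-sided p via the t approximation, df = n - 2).
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(scores, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("values and scores must be paired 1D arrays")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 paired observations")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values are not supported")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p), n - 2


def bonferroni_threshold(
    alpha: float, n_measures: int, n_regions: int = 1
) -> float:
    """alpha / (n_measures * n_regions)."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if n_measures <= 0 or n_regions <= 0:
        raise ValueError("counts must be positive")
    return alpha / (n_measures * n_regions)


def associate(
    region_values: dict[str, np.ndarray],
    symptoms: pd.DataFrame,
    measures=DEFAULT_MEASURES,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Region x measure Spearman association table.

    ``region_values`` maps region name -> per-subject values aligned with the
    rows of ``symptoms``.  The Bonferroni threshold uses the number of
    measures times the number of regions.
    """
    thr = bonferroni_threshold(alpha, len(measures), len(region_values))
    rows = []
    for region, vals in region_values.items():
        for meas in measures:
            rho, p, df = spearman_assoc(vals, symptoms[meas].to_numpy())
            rows.append(
                {
                    "region": region,
                    "measure": meas,
                    "rho": rho,
                    "df": df,
                    "p": p,
                    "corrected_alpha": thr,
                    "significant": p < thr,
                }
            )
    return pd.DataFrame(rows)


def symptom_regression_map(
    subject_maps,
    scores,
    mask: np.ndarray | ROIMask,
    n_perm: int = 1000,
    seed: int = 0,
    E: float = TFCE_E,
    H: float = TFCE_H,
    dh: float = TFCE_DH,
    alpha: float = 0.05,
) -> tuple[StatMap, np.ndarray]:
    """Voxelwise simple regression of contrast on symptom score.

    Returns the slope t map (within mask) and TFCE permutation-corrected p
    values obtained by shuffling scores across subjects.
    """
    if isinstance(mask, ROIMask):
        mask = mask.mask()
    m = _as_masked(subject_maps, mask)
    s = np.asarray(scores, dtype=float)
    n = len(s)
    if n < 5:
        raise ValueError("need at least 5 subjects")
    if np.ptp(s) == 0:
        raise ValueError("constant scores: regression undefined")
    rng = np.random.default_rng(seed)
    bbox = _bbox(mask)
    df = n - 2

    def slope_t(svec: np.ndarray) -> np.ndarray:
        sc = svec - svec.mean()
        ssx = float(sc @ sc)
        b = sc @ m / ssx
        fitted = np.outer(svec, b) + (m.mean(axis=0) - svec.mean() * b)
        rss = ((m - fitted) ** 2).sum(axis=0)
        se = np.sqrt(np.maximum(rss / df / ssx, 1e-300))
        return b / se

    t_obs = slope_t(s)
    z_obs = _t_to_z_values(t_obs, df)
    tfce_obs = _tfce_masked(z_obs, mask, bbox, E, H, dh)
    max_null = np.empty(n_perm)
    for i in range(n_perm):
        sp = s if i == 0 else rng.permutation(s)
        z_i = _t_to_z_values(slope_t(sp), df)
        max_null[i] = np.abs(_tfce_masked(z_i, mask, bbox, E, H, dh)).max()
    p_corr = (max_null[None, :] >= np.abs(tfce_obs)[:, None]).mean(axis=1)
    return (
        StatMap(data=t_obs, df=df, kind="regression_t"),
        p_corr,
    )
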