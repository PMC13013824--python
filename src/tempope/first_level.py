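"""First-level voxelwise GLMs: designs, fitting, and the contrast set.

Two design families are supported.  The *traditional* design models the five
event classes (cue, expected/unexpected outcome, expected/unexpected
absence) separately for the juice and visual conditions — up to 10 task
regressors, each a boxcar at the stated onsets/durations convolved with a
canonical double-gamma HRF.  The *model-based* design carries, per
condition, a parametric cue regressor (cue events scaled by the TD
prediction error sampled at cue onset) and a parametric outcome regressor
(expected deliveries, unexpected deliveries and unexpected absences scaled
by their PE samples), alongside unmodulated main-effect regressors for the
same events.  Modulators are mean-centered within run before convolution
(no serial orthogonalization).

Data are expected in percent-signal-change-compatible scaling (run mean
100); with the HRF kernel peak-normalized to 1, a unit-amplitude 1 s event
then yields a beta approximately equal to the percent signal change.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist
from sklearn.base import BaseEstimator

from .task import CONDITIONS, EVENT_CLASSES

logger = logging.getLogger(__name__)

#: outcome-locked event classes pooled into the parametric outcome regressor
OUTCOME_POOL = ("expected_outcome", "unexpected_outcome", "unexpected_absence")


@dataclass
class HRFSpec:
    """Canonical double-gamma haemodynamic response, peak-normalized to 1."""

    model: str = "double_gamma"
    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    duration: float = 32.0
    oversampling: int = 16

    def kernel(self, dt: float) -> np.ndarray:
        if self.model != "double_gamma":
            raise ValueError(f"unknown HRF model {self.model!r}")
        t = np.arange(0, self.duration + dt, dt)
        peak = gamma_dist.pdf(
            t, self.peak_delay / self.peak_dispersion, scale=self.peak_dispersion
        )
        under = gamma_dist.pdf(
            t,
            self.undershoot_delay / self.undershoot_dispersion,
            scale=self.undershoot_dispersion,
        )
        h = peak - self.undershoot_ratio * under
        return h / h.max()


@dataclass
class DesignMatrix:
    """Time x regressor matrix with labeled columns and run structure."""

    matrix: np.ndarray
    columns: list[str]
    tr: float
    design_kind: str
    run_slices: list[slice]
    modulator_centering: dict[str, list[float]] = field(default_factory=dict)
    n_truncated_events: int = 0

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.columns)

    def column(self, label: str) -> np.ndarray:
        return self.matrix[:, self.columns.index(label)]

    @property
    def task_columns(self) -> list[str]:
        return [
            c
            for c in self.columns
            if not c.startswith(("drift", "intercept", "nuisance"))
        ]

    def condition_number(self) -> float:
        """Condition number of the column-normalized design."""
        x = self.matrix / np.linalg.norm(self.matrix, axis=0, keepdims=True)
        return float(np.linalg.cond(x))


@dataclass
class ContrastSpec:
    name: str
    weights: dict[str, float]
    family: str = "traditional"

    def vector(self, columns: list[str]) -> np.ndarray:
        v = np.zeros(len(columns))
        for label, w in self.weights.items():
            if label not in columns:
                raise KeyError(
                    f"contrast {self.name!r}: column {label!r} not in design"
                )
            v[columns.index(label)] = w
        return v


# ----------------------------------------------------------------------
# design construction


def _as_run_lengths(n_volumes, run_indices) -> dict[int, int]:
    runs = sorted(int(r) for r in run_indices)
    if np.isscalar(n_volumes):
        if len(runs) != 1:
            raise ValueError(
                "scalar n_volumes with multi-run events; pass one value per run"
            )
        return {runs[0]: int(n_volumes)}
    if len(n_volumes) != len(runs):
        raise ValueError("n_volumes must have one entry per run")
    return dict(zip(runs, (int(v) for v in n_volumes)))


def _convolve_run(
    onsets: np.ndarray,
    durations: np.ndarray,
    amplitudes: np.ndarray,
    n_vol: int,
    tr: float,
    hrf: HRFSpec,
) -> tuple[np.ndarray, int]:
    """HRF-convolved regressor sampled at volume times; returns truncation count."""
    dt = tr / hrf.oversampling
    n_hr = int(np.ceil(n_vol * tr / dt)) + 1
    x = np.zeros(n_hr)
    n_trunc = 0
    for o, d, a in zip(onsets, durations, amplitudes):
        if o >= n_vol * tr:
            n_trunc += 1
            continue
        i0 = int(np.round(o / dt))
        i1 = max(i0 + 1, int(np.round((o + d) / dt)))
        x[i0 : min(i1, n_hr)] += a
    from scipy.signal import fftconvolve

    conv = fftconvolve(x, hrf.kernel(dt))[:n_hr]
    vol_idx = np.round(np.arange(n_vol) * tr / dt).astype(int)
    return conv[vol_idx], n_trunc


def cosine_drift(n_vol: int, tr: float, cutoff: float = 128.0) -> np.ndarray:
    """Discrete cosine drift basis (excluding the constant), DCT-II style."""
    t = (np.arange(n_vol) + 0.5) / n_vol
    order = int(np.floor(2.0 * n_vol * tr / cutoff))
    return np.column_stack(
        [np.cos(np.pi * k * t) for k in range(1, order + 1)]
    ) if order >= 1 else np.empty((n_vol, 0))


def _assemble(
    per_run_task: dict[int, dict[str, np.ndarray]],
    task_labels: list[str],
    run_lengths: dict[int, int],
    tr: float,
    drift_cutoff: float,
    design_kind: str,
    centering: dict[str, list[float]],
    n_trunc: int,
    nuisance: dict[int, np.ndarray] | None = None,
) -> DesignMatrix:
    runs = sorted(run_lengths)
    blocks = []
    run_slices = []
    start = 0
    drift_labels: list[str] = []
    # determine drift widths per run
    drifts = {r: cosine_drift(run_lengths[r], tr, drift_cutoff) for r in runs}
    for r in runs:
        n_vol = run_lengths[r]
        cols = [
            per_run_task[r].get(lbl, np.zeros(n_vol)) for lbl in task_labels
        ]
        block = [np.column_stack(cols)] if cols else []
        block.append(np.ones((n_vol, 1)))
        block.append(drifts[r])
        if nuisance and r in nuisance:
            block.append(np.atleast_2d(nuisance[r]))
        blocks.append(np.column_stack(block) if len(block) > 1 else block[0])
        run_slices.append(slice(start, start + n_vol))
        start += n_vol
    # task columns are shared across runs; intercept/drift/nuisance are per run
    n_task = len(task_labels)
    total = sum(run_lengths[r] for r in runs)
    extra_width = sum(b.shape[1] - n_task for b in blocks)
    mat = np.zeros((total, n_task + extra_width))
    labels = list(task_labels)
    col = n_task
    for r, b, sl in zip(runs, blocks, run_slices):
        mat[sl, :n_task] = b[:, :n_task]
        w = b.shape[1] - n_task
        mat[sl, col : col + w] = b[:, n_task:]
        labels.append(f"intercept_run{r}")
        n_drift = drifts[r].shape[1]
        labels.extend(f"drift{k+1}_run{r}" for k in range(n_drift))
        labels.extend(
            f"nuisance{k+1}_run{r}" for k in range(w - 1 - n_drift)
        )
        col += w
    # drop all-zero task columns (event class absent from these runs)
    keep = [i for i in range(len(labels)) if np.any(mat[:, i] != 0)]
    dropped = [labels[i] for i in range(len(labels)) if i not in keep]
    if dropped:
        logger.info("dropping empty design columns: %s", dropped)
    dm = DesignMatrix(
        matrix=mat[:, keep],
        columns=[labels[i] for i in keep],
        tr=tr,
        design_kind=design_kind,
        run_slices=run_slices,
        modulator_centering=centering,
        n_truncated_events=n_trunc,
    )
    logger.info(
        "%s design: %d columns, condition number %.1f",
        design_kind,
        len(dm.columns),
        dm.condition_number(),
    )
    return dm


def build_traditional_design(
    events: pd.DataFrame,
    tr: float,
    n_volumes,
    hrf: HRFSpec | None = None,
    drift_cutoff: float = 128.0,
    nuisance: dict[int, np.ndarray] | None = None,
) -> DesignMatrix:
    """Five event classes x two conditions as separate HRF-convolved boxcars."""
    if events.empty:
        raise ValueError("empty event table: no estimable design")
    hrf = hrf or HRFSpec()
    run_lengths = _as_run_lengths(n_volumes, events["run_index"].unique())
    task_labels = [
        f"{cls}_{cond}" for cls in EVENT_CLASSES for cond in CONDITIONS
    ]
    per_run: dict[int, dict[str, np.ndarray]] = {}
    n_trunc = 0
    for r, n_vol in run_lengths.items():
        ev_r = events[events["run_index"] == r]
        per_run[r] = {}
        for lbl in task_labels:
            sel = ev_r[ev_r["trial_type"] == lbl]
            if sel.empty:
                continue
            col, tr_ct = _convolve_run(
                sel["onset"].to_numpy(),
                sel["duration"].to_numpy(),
                np.ones(len(sel)),
                n_vol,
                tr,
                hrf,
            )
            n_trunc += tr_ct
            per_run[r][lbl] = col
    if n_trunc:
        warnings.warn(f"{n_trunc} events beyond scan end were truncated")
    return _assemble(
        per_run, task_labels, run_lengths, tr, drift_cutoff, "traditional", {}, n_trunc,
        nuisance,
    )


def build_modelbased_design(
    events: pd.DataFrame,
    pes: pd.DataFrame,
    tr: float,
    n_volumes,
    hrf: HRFSpec | None = None,
    drift_cutoff: float = 128.0,
    nuisance: dict[int, np.ndarray] | None = None,
) -> DesignMatrix:
    """Four parametric PE regressors plus unmodulated main effects.

    ``pes`` must contain a PE sample for every cue, expected/unexpected
    outcome and unexpected-absence event (columns as produced by
    :func:`tempope.td.sample_pes`, both conditions concatenated).
    """
    if events.empty:
        raise ValueError("empty event table: no estimable design")
    hrf = hrf or HRFSpec()
    run_lengths = _as_run_lengths(n_volumes, events["run_index"].unique())
    merged = events.merge(
        pes[["event_class", "condition", "run_index", "trial_index", "pe_value"]],
        on=["event_class", "condition", "run_index", "trial_index"],
        how="left",
    )
    modeled = merged["event_class"].isin(("cue",) + OUTCOME_POOL)
    if merged.loc[modeled, "pe_value"].isna().any():
        missing = merged.loc[modeled & merged["pe_value"].isna()]
        raise ValueError(
            f"{len(missing)} modeled events lack a PE sample "
            f"(first: {missing.iloc[0][['trial_type', 'run_index', 'trial_index']].to_dict()})"
        )

    main_labels, par_labels = [], []
    for cond in CONDITIONS:
        main_labels += [f"cue_main_{cond}", f"outcome_main_{cond}"]
        par_labels += [f"cue_pe_{cond}", f"outcome_pe_{cond}"]
    task_labels = main_labels + par_labels

    per_run: dict[int, dict[str, np.ndarray]] = {}
    centering: dict[str, list[float]] = {lbl: [] for lbl in par_labels}
    n_trunc = 0
    groups = {"cue": ("cue",), "outcome": OUTCOME_POOL}
    for r, n_vol in run_lengths.items():
        ev_r = merged[merged["run_index"] == r]
        per_run[r] = {}
        for cond in CONDITIONS:
            for gname, classes in groups.items():
                sel = ev_r[
                    (ev_r["condition"] == cond)
                    & (ev_r["event_class"].isin(classes))
                ]
                if sel.empty:
                    continue
                onsets = sel["onset"].to_numpy()
                durs = sel["duration"].to_numpy()
                col, ct = _convolve_run(
                    onsets, durs, np.ones(len(sel)), n_vol, tr, hrf
                )
                n_trunc += ct
                per_run[r][f"{gname}_main_{cond}"] = col
                mod = sel["pe_value"].to_numpy(dtype=float)
                mu = float(mod.mean())
                centering[f"{gname}_pe_{cond}"].append(mu)
                col_p, _ = _convolve_run(onsets, durs, mod - mu, n_vol, tr, hrf)
                per_run[r][f"{gname}_pe_{cond}"] = col_p
    # drop zero-variance parametric columns
    for lbl in list(par_labels):
        sd = max(
            float(np.std(per_run[r][lbl])) if lbl in per_run[r] else 0.0
            for r in per_run
        )
        if sd < 1e-10:
            warnings.warn(
                f"parametric modulator {lbl!r} has zero variance; column dropped"
            )
            for r in per_run:
                per_run[r].pop(lbl, None)
            task_labels.remove(lbl)
    if n_trunc:
        warnings.warn(f"{n_trunc} events beyond scan end were truncated")
    return _assemble(
        per_run, task_labels, run_lengths, tr, drift_cutoff, "model_based",
        centering, n_trunc, nuisance,
    )


# ----------------------------------------------------------------------
# GLM fitting


@dataclass
class GLMResult:
    betas: np.ndarray  # (n_regressors, n_voxels)
    sigma2: np.ndarray  # (n_voxels,)
    df: int
    columns: list[str]
    design: DesignMatrix
    ar_rho: float = 0.0

    def beta(self, label: str) -> np.ndarray:
        return self.betas[self.columns.index(label)]


def scale_percent_signal(data: np.ndarray, run_slices: list[slice]) -> np.ndarray:
    """Scale each voxel's time series to mean 100 within each run."""
    out = np.empty_like(data)
    for sl in run_slices:
        mean = data[sl].mean(axis=0, keepdims=True, dtype=np.float64)
        out[sl] = 100.0 * data[sl] / mean.astype(data.dtype)
    return out


def _check_rank(x: np.ndarray, columns: list[str]) -> int:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        corr = np.corrcoef(x, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise np.linalg.LinAlgError(
            f"rank-deficient design (rank {rank} < {x.shape[1]}); most "
            f"collinear pair: {columns[i]!r} / {columns[j]!r} "
            f"(r = {corr[i, j]:.3f})"
        )
    return int(rank)


def _ar1_transform(a: np.ndarray, rho: float, run_slices: list[slice]) -> np.ndarray:
    out = a.copy()
    r = a.dtype.type(rho) if np.issubdtype(a.dtype, np.floating) else rho
    for sl in run_slices:
        seg = a[sl]
        np.subtract(seg[1:], r * seg[:-1], out=out[sl][1:])
        out[sl][0] = seg[0] * np.sqrt(1.0 - rho**2)
    return out


def fit_glm(
    data: np.ndarray,
    design: DesignMatrix,
    prewhiten: bool = True,
) -> GLMResult:
    """Voxelwise OLS (optionally Cochrane-Orcutt AR(1) prewhitened).

    ``data`` is (n_volumes, n_voxels); returns betas, residual variance and
    residual degrees of freedom ``n_volumes - rank(design)``.
    """
    x = design.matrix
    if data.shape[0] != x.shape[0]:
        raise ValueError(
            f"data has {data.shape[0]} volumes but design has {x.shape[0]} rows"
        )
    rank = _check_rank(x, design.columns)
    # heavy matmuls run in the data's dtype (float32 for synthetic volumes)
    x = x.astype(data.dtype, copy=False)

    def ols(xm, ym):
        return np.linalg.solve(
            (xm.T @ xm).astype(np.float64), (xm.T @ ym).astype(np.float64)
        ).astype(ym.dtype)

    beta = ols(x, data)
    rho = 0.0
    if prewhiten:
        # pooled lag-1 autocorrelation of first-pass residuals; a voxel
        # subsample suffices for the single global estimate
        step = max(1, data.shape[1] // 512)
        resid_sub = data[:, ::step] - x @ beta[:, ::step]
        num = den = 0.0
        for sl in design.run_slices:
            seg = resid_sub[sl]
            num += float(np.sum(seg[1:] * seg[:-1], dtype=np.float64))
            den += float(np.sum(seg[:-1] ** 2, dtype=np.float64))
        rho = float(np.clip(num / den if den > 0 else 0.0, -0.95, 0.95))
        xw = _ar1_transform(x, rho, design.run_slices)
        yw = _ar1_transform(data, rho, design.run_slices)
        beta = ols(xw, yw)
        resid = yw - xw @ beta
    else:
        resid = data - x @ beta
    df = data.shape[0] - rank
    sigma2 = np.sum(resid**2, axis=0) / df
    return GLMResult(
        betas=beta,
        sigma2=sigma2,
        df=int(df),
        columns=list(design.columns),
        design=design,
        ar_rho=rho,
    )


def compute_contrast(result: GLMResult, contrast: ContrastSpec) -> np.ndarray:
    """Voxelwise weighted sum of betas for a contrast (percent signal change)."""
    v = contrast.vector(result.columns)
    return v @ result.betas


# ----------------------------------------------------------------------
# contrast registry


def _within(cls_a: str, cls_b: str, cond: str) -> dict[str, float]:
    return {f"{cls_a}_{cond}": 1.0, f"{cls_b}_{cond}": -1.0}


def component_contrasts() -> dict[str, ContrastSpec]:
    """Within-condition temporal-PE component contrasts (non-registry helpers)."""
    out = {}
    for cond in CONDITIONS:
        out[f"pos_tpe_{cond}"] = ContrastSpec(
            f"pos_tpe_{cond}",
            _within("unexpected_outcome", "expected_outcome", cond),
        )
        out[f"neg_tpe_{cond}"] = ContrastSpec(
            f"neg_tpe_{cond}",
            _within("unexpected_absence", "expected_absence", cond),
        )
    return out


def contrast_registry() -> list[ContrastSpec]:
    """The six contrasts examined for group differences.

    Four traditional (juice vs visual cue, outcome, positive temporal PE,
    negative temporal PE) and two model-based (TD-PE modulation of the juice
    cue and of juice delivery, each examined on its own).
    """
    reg = [
        ContrastSpec(
            "cue_juice_vs_visual",
            {"cue_juice": 1.0, "cue_visual": -1.0},
        ),
        ContrastSpec(
            "outcome_juice_vs_visual",
            {"expected_outcome_juice": 1.0, "expected_outcome_visual": -1.0},
        ),
        ContrastSpec(
            "pos_tpe_juice_vs_visual",
            {
                "unexpected_outcome_juice": 1.0,
                "expected_outcome_juice": -1.0,
                "unexpected_outcome_visual": -1.0,
                "expected_outcome_visual": 1.0,
            },
        ),
        ContrastSpec(
            "neg_tpe_juice_vs_visual",
            {
                "unexpected_absence_juice": 1.0,
                "expected_absence_juice": -1.0,
                "unexpected_absence_visual": -1.0,
                "expected_absence_visual": 1.0,
            },
        ),
        ContrastSpec("cue_pe_juice", {"cue_pe_juice": 1.0}, family="model_based"),
        ContrastSpec(
            "outcome_pe_juice", {"outcome_pe_juice": 1.0}, family="model_based"
        ),
    ]
    return reg


# ----------------------------------------------------------------------
# estimator facade


class FirstLevelGLM(BaseEstimator):
    """Subject-level GLM over one or both task runs.

    design_kind : "traditional", "model_based" or "combined" (traditional
        event-class columns plus the four parametric PE columns; the
        generating model of the synthetic cohort).
    """

    def __init__(
        self,
        tr: float = 1.0,
        design_kind: str = "traditional",
        hrf: HRFSpec | None = None,
        prewhiten: bool = True,
        drift_cutoff: float = 128.0,
        scale_psc: bool = True,
    ):
        self.tr = tr
        self.design_kind = design_kind
        self.hrf = hrf
        self.prewhiten = prewhiten
        self.drift_cutoff = drift_cutoff
        self.scale_psc = scale_psc

    def build_design(self, events, n_volumes, pes=None, nuisance=None) -> DesignMatrix:
        hrf = self.hrf or HRFSpec()
        if self.design_kind == "traditional":
            return build_traditional_design(
                events, self.tr, n_volumes, hrf, self.drift_cutoff, nuisance
            )
        if self.design_kind == "model_based":
            if pes is None:
                raise ValueError("model-based design requires PE samples")
            return build_modelbased_design(
                events, pes, self.tr, n_volumes, hrf, self.drift_cutoff, nuisance
            )
        if self.design_kind == "combined":
            trad = build_traditional_design(
                events, self.tr, n_volumes, hrf, self.drift_cutoff, nuisance
            )
            mb = build_modelbased_design(
                events, pes, self.tr, n_volumes, hrf, self.drift_cutoff
            )
            par = [c for c in mb.columns if "_pe_" in c]
            mat = np.column_stack(
                [trad.matrix] + [mb.column(c) for c in par]
            )
            return DesignMatrix(
                matrix=mat,
                columns=trad.columns + par,
                tr=self.tr,
                design_kind="combined",
                run_slices=trad.run_slices,
                modulator_centering=mb.modulator_centering,
            )
        raise ValueError(f"unknown design_kind {self.design_kind!r}")

    def fit(
        self,
        data: np.ndarray,
        events: pd.DataFrame,
        n_volumes,
        pes=None,
        nuisance=None,
    ):
        design = self.build_design(events, n_volumes, pes=pes, nuisance=nuisance)
        y = (
            scale_percent_signal(data, design.run_slices)
            if self.scale_psc
            else np.asarray(data, dtype=float)
        )
        self.design_ = design
        res = fit_glm(y, design, prewhiten=self.prewhiten)
        self.result_ = res
        self.betas_ = res.betas
        self.sigma2_ = res.sigma2
        self.df_ = res.df
        return self

    def contrast(self, contrast: ContrastSpec | str) -> np.ndarray:
        if isinstance(contrast, str):
            all_specs = {c.name: c for c in contrast_registry()}
            all_specs.update(component_contrasts())
            contrast = all_specs[contrast]
        return compute_contrast(self.result_, contrast)
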