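"""Synthetic study generator with known ground truth.

Builds a two-group cohort (PTP: post-trauma psychopathology; TEHC:
trauma-exposed healthy comparison; 45 subjects each by default) whose BOLD
data contain HRF-convolved event responses and TD-PE-modulated components
with group-specific regional effects, AR(1)-plus-drift noise, and symptom
scores rank-coupled to the left-amygdala negative temporal-PE contrast.

The injected group differences mirror the qualitative pattern the analysis
is meant to detect: the PTP group has attenuated juice positive/negative
temporal-PE responses and attenuated outcome-PE modulation in amygdala /
putamen / pallidum / midbrain, and exaggerated cue-PE modulation in insula
and putamen.  Magnitudes default to a between-group Cohen's d of about 0.7
per voxel in affected regions under the default noise model.

Geometry is a small 20 x 24 x 20 grid at 3 mm isotropic with spherical ROI
blobs standing in for anatomical regions; data are synthesised only inside
an analysis mask (the dilated ROI union), which is also the mask all group
inference is restricted to.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation
from scipy.signal import lfilter

from .first_level import DesignMatrix, FirstLevelGLM, HRFSpec, cosine_drift
from .group import ROIMask
from .task import ScheduleConfig, TaskSchedule, generate_schedule, schedule_to_events
from .td import TDParams, sample_pes, simulate_td

GRID_SHAPE = (20, 24, 20)
VOXEL_SIZE = 3.0

#: ROI blob layout: name -> (center voxel, radius in voxels)
ROI_LAYOUT = {
    "amygdala_L": ((4, 7, 5), 2.5),
    "putamen_L": ((4, 14, 9), 3.0),
    "pallidum_L": ((7, 10, 7), 2.0),
    "midbrain": ((10, 6, 5), 2.5),
    "caudate": ((10, 14, 13), 3.0),
    "pgACC": ((10, 20, 8), 2.5),
    "insula_L": ((3, 19, 13), 2.5),
    "insula_R": ((16, 19, 13), 2.5),
    "putamen_R": ((15, 14, 9), 3.0),
}

#: generating-design task regressors
GEN_LABELS = [
    "cue_juice",
    "cue_visual",
    "expected_outcome_juice",
    "expected_outcome_visual",
    "expected_absence_juice",
    "expected_absence_visual",
    "unexpected_absence_juice",
    "unexpected_absence_visual",
    "unexpected_outcome_juice",
    "unexpected_outcome_visual",
    "cue_pe_juice",
    "cue_pe_visual",
    "outcome_pe_juice",
    "outcome_pe_visual",
]

_POS_TPE_ROIS = (
    "putamen_L", "putamen_R", "pallidum_L", "midbrain", "caudate",
    "insula_L", "insula_R", "amygdala_L",
)
_NEG_TPE_ROIS = (
    "amygdala_L", "putamen_L", "pallidum_L", "midbrain", "caudate", "pgACC",
)


@dataclass
class CohortConfig:
    n_per_group: int = 45
    grid_shape: tuple[int, int, int] = GRID_SHAPE
    voxel_size: float = VOXEL_SIZE
    tr: float = 1.0
    noise_sd: float = 1.0  # marginal sd of AR(1) noise, % signal units
    ar_rho: float = 0.3
    drift_sd: float = 0.3  # sd of random cosine drift amplitudes
    mask_dilation: int = 2
    symptom_rho: float = -0.50  # target Spearman: amygdala neg-TPE vs SHAPS-C
    subject_sd: float = 0.2  # between-subject sd of varying betas
    # between-group mean shifts in affected ROIs (percent signal change),
    # calibrated so the observed per-voxel effect size is d ~ 0.7
    delta_pos_tpe: float = 0.20
    delta_neg_tpe: float = 0.30
    delta_cue_pe: float = 0.15
    delta_outcome_pe: float = 0.16
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    td: TDParams = field(default_factory=TDParams)
    hrf: HRFSpec = field(default_factory=lambda: HRFSpec(oversampling=8))
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("need at least 2 subjects per group")
        if not (abs(self.symptom_rho) < 1):
            raise ValueError("|symptom_rho| must be < 1")


def build_roi_mask(
    shape=GRID_SHAPE, layout: dict | None = None
) -> ROIMask:
    """Labeled spherical ROI blobs on the synthetic grid."""
    layout = layout or ROI_LAYOUT
    vol = np.zeros(shape, dtype=np.int16)
    labels = {}
    grids = np.indices(shape)
    for i, (name, (center, radius)) in enumerate(layout.items(), start=1):
        d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
        sphere = d2 <= radius**2
        if (vol[sphere] != 0).any():
            raise ValueError(f"ROI {name!r} overlaps an earlier ROI")
        vol[sphere] = i
        labels[name] = i
    return ROIMask(volume=vol, labels=labels)


def _mean_effects(config: CohortConfig) -> dict[str, pd.DataFrame]:
    """Group-mean true betas per (ROI, regressor), percent signal change."""
    rois = list(ROI_LAYOUT)
    base = pd.DataFrame(0.0, index=rois, columns=GEN_LABELS)
    base["cue_juice"] = 0.3
    base["cue_visual"] = 0.3
    base["expected_outcome_juice"] = 0.5
    base["expected_outcome_visual"] = 0.3
    # visual condition: no temporal-PE effect (unexpected == expected)
    base["unexpected_outcome_visual"] = 0.3
    # juice positive temporal PE: unexpected delivery exceeds expected
    for r in _POS_TPE_ROIS:
        base.loc[r, "unexpected_outcome_juice"] = 0.9
    # juice negative temporal PE: deactivation at unexpected absence
    for r in _NEG_TPE_ROIS:
        base.loc[r, "unexpected_absence_juice"] = -0.4
    # TD-PE parametric modulation
    for r in ("caudate", "insula_L", "insula_R"):
        base.loc[r, "cue_pe_juice"] = 0.3
    base.loc["pgACC", "cue_pe_juice"] = -0.3
    base.loc["caudate", "cue_pe_visual"] = 0.1
    for r in ("amygdala_L", "putamen_L", "putamen_R", "pallidum_L",
              "midbrain", "insula_L", "insula_R", "caudate"):
        base.loc[r, "outcome_pe_juice"] = 0.4
    base.loc["pgACC", "outcome_pe_juice"] = 0.3
    base.loc["caudate", "outcome_pe_visual"] = 0.1

    tehc = base.copy()
    ptp = base.copy()
    for r in ("putamen_L", "pallidum_L", "midbrain", "amygdala_L"):
        ptp.loc[r, "unexpected_outcome_juice"] -= config.delta_pos_tpe
    for r in ("amygdala_L", "putamen_L", "pallidum_L"):
        ptp.loc[r, "unexpected_absence_juice"] += config.delta_neg_tpe
    for r in ("insula_L", "insula_R", "putamen_L", "putamen_R"):
        ptp.loc[r, "cue_pe_juice"] += config.delta_cue_pe
    for r in ("amygdala_L", "putamen_L"):
        ptp.loc[r, "outcome_pe_juice"] -= config.delta_outcome_pe
    return {"TEHC": tehc, "PTP": ptp}


#: regressors whose true betas vary across subjects (sd = subject_sd);
#: expected-absence baselines are held fixed so the amygdala coupling latent
#: is the sole subject-level source of true neg-TPE contrast variance
VARYING_LABELS = (
    "unexpected_outcome_juice",
    "unexpected_outcome_visual",
    "unexpected_absence_juice",
    "unexpected_absence_visual",
    "cue_pe_juice",
    "cue_pe_visual",
    "outcome_pe_juice",
    "outcome_pe_visual",
)


def _subject_sd_table(config: CohortConfig) -> pd.DataFrame:
    """Between-subject sd of each varying regressor per ROI.

    In the left amygdala all sds except the coupled unexpected-absence beta
    are shrunk: unmodeled leakage of other varying components into the
    estimated unexpected-absence beta would add subject-level variance
    unrelated to the coupling latent and attenuate the brain-symptom rank
    correlation, which the generator is constructed to keep small.
    """
    rois = list(ROI_LAYOUT)
    tbl = pd.DataFrame(config.subject_sd, index=rois, columns=list(VARYING_LABELS))
    tbl.loc["amygdala_L"] = 0.05
    tbl.loc["amygdala_L", "unexpected_absence_juice"] = config.subject_sd
    return tbl


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    schedule_seed: int
    noise_seed: int
    schedule: TaskSchedule
    events: pd.DataFrame
    pes: pd.DataFrame
    symptoms: dict[str, float]
    beta_table: pd.DataFrame  # (ROI x regressor) true betas


@dataclass
class GroundTruth:
    config: CohortConfig
    roi: ROIMask
    analysis_mask: np.ndarray
    labels: list[str]
    symptom_latents: pd.DataFrame

    def beta_matrix(
        self, record: SubjectRecord, voxels: np.ndarray | None = None
    ) -> np.ndarray:
        """Expand a subject's ROI beta table to (n_regressors, n_voxels).

        ``voxels`` optionally restricts to a boolean subset of mask voxels.
        """
        v = self.roi.volume[self.analysis_mask]
        if voxels is not None:
            v = v[voxels]
        out = np.zeros((len(self.labels), v.size))
        for name, lab in self.roi.labels.items():
            sel = v == lab
            out[:, sel] = record.beta_table.loc[name, self.labels].to_numpy()[
                :, None
            ]
        return out

    def roi_selector(
        self, name: str, voxels: np.ndarray | None = None
    ) -> np.ndarray:
        v = self.roi.volume[self.analysis_mask]
        if voxels is not None:
            v = v[voxels]
        return v == self.roi.labels[name]


@dataclass
class Cohort:
    records: list[SubjectRecord]
    ground_truth: GroundTruth

    def by_group(self, group: str) -> list[SubjectRecord]:
        return [r for r in self.records if r.group == group]

    @property
    def symptom_table(self) -> pd.DataFrame:
        rows = [
            {"subject_id": r.subject_id, "group": r.group, **r.symptoms}
            for r in self.records
        ]
        return pd.DataFrame(rows)


def _symptom_scores(
    rng: np.random.Generator, group: str, z_couple: float
) -> dict[str, float]:
    """Monotone integer mappings of the symptom latents (plausible ranges)."""
    e1, e2, e3 = rng.standard_normal(3)
    if group == "PTP":
        shaps = np.clip(np.round(33 + 7 * z_couple), 14, 56)
        caps = np.clip(np.round(10 + 3 * (0.6 * z_couple + 0.8 * e1)), 0, 20)
        teps_a = np.clip(np.round(38 - 5 * (0.5 * z_couple + 0.87 * e2)), 10, 60)
        teps_c = np.clip(np.round(36 - 5 * (0.5 * z_couple + 0.87 * e3)), 10, 60)
    else:
        shaps = np.clip(np.round(18 + 3 * z_couple), 14, 56)
        caps = np.clip(np.round(2 + 1.5 * e1), 0, 20)
        teps_a = np.clip(np.round(46 - 4 * e2), 10, 60)
        teps_c = np.clip(np.round(44 - 4 * e3), 10, 60)
    return {
        "SHAPS_C": float(shaps),
        "CAPS_numbing": float(caps),
        "TEPS_A": float(teps_a),
        "TEPS_C": float(teps_c),
    }


def generate_cohort(config: CohortConfig | None = None, seed: int = 0) -> Cohort:
    """Generate the full synthetic study; deterministic per (config, seed).

    Per subject: a two-run schedule (subject-specific seed), TD traces and
    PE samples for both conditions, a ground-truth beta table, and symptom
    scores.  Within the PTP group the left-amygdala unexpected-absence beta
    and the SHAPS-C score share a Gaussian copula whose latent Pearson
    correlation 2*sin(pi*rho_s/6) yields the configured population Spearman
    rho between the true negative-temporal-PE contrast and SHAPS-C.
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    roi = build_roi_mask(config.grid_shape)
    analysis_mask = binary_dilation(
        roi.mask(), iterations=config.mask_dilation
    )
    effects = _mean_effects(config)
    # latent Pearson correlation reproducing the target Spearman rho between
    # the true amygdala contrast and SHAPS-C.  The pipeline-estimated
    # correlation is additionally attenuated by the ROI-mean measurement
    # error (~0.005 % signal change per unit noise sd under the default
    # design); warn when the target cannot survive that attenuation.
    r_lat = 2.0 * np.sin(np.pi * config.symptom_rho / 6.0)
    se_roi = 0.0053 * config.noise_sd
    atten = config.subject_sd / float(np.hypot(config.subject_sd, se_roi))
    if abs(r_lat) / atten > 1.0:
        achievable = np.sign(config.symptom_rho) * (6.0 / np.pi) * np.arcsin(
            atten / 2.0
        )
        warnings.warn(
            f"symptom_rho {config.symptom_rho:+.2f} is not reachable after "
            f"measurement attenuation at noise_sd {config.noise_sd}; the "
            f"estimated correlation will saturate near {achievable:+.2f}"
        )
        r_lat = float(np.sign(r_lat))

    records: list[SubjectRecord] = []
    latents = []
    for group in ("PTP", "TEHC"):
        for i in range(config.n_per_group):
            sid = f"sub-{group}{i + 1:03d}"
            schedule_seed = int(rng.integers(0, 2**31 - 1))
            noise_seed = int(rng.integers(0, 2**31 - 1))
            z1 = float(rng.standard_normal())  # amygdala contrast latent
            z2 = float(
                r_lat * z1 + np.sqrt(1.0 - r_lat**2) * rng.standard_normal()
            )
            symptoms = _symptom_scores(rng, group, z2 if group == "PTP" else z1)

            beta = effects[group].copy()
            sd_tbl = _subject_sd_table(config)
            for lbl in VARYING_LABELS:
                dev = rng.standard_normal(len(beta)) * sd_tbl[lbl].to_numpy()
                beta[lbl] = beta[lbl] + dev
            # the coupled latent drives the amygdala unexpected-absence beta
            beta.loc["amygdala_L", "unexpected_absence_juice"] = (
                effects[group].loc["amygdala_L", "unexpected_absence_juice"]
                + config.subject_sd * z1
            )

            schedule = generate_schedule(
                config.schedule, seed=schedule_seed, subject_id=sid
            )
            events = schedule_to_events(schedule)
            pes = pd.concat(
                [
                    sample_pes(simulate_td(schedule, cond, config.td), events)
                    for cond in ("juice", "visual")
                ],
                ignore_index=True,
            )
            records.append(
                SubjectRecord(
                    subject_id=sid,
                    group=group,
                    schedule_seed=schedule_seed,
                    noise_seed=noise_seed,
                    schedule=schedule,
                    events=events,
                    pes=pes,
                    symptoms=symptoms,
                    beta_table=beta,
                )
            )
            latents.append(
                {"subject_id": sid, "group": group, "z_brain": z1, "z_symptom": z2}
            )

    gt = GroundTruth(
        config=replace(config, seed=seed),
        roi=roi,
        analysis_mask=analysis_mask,
        labels=GEN_LABELS,
        symptom_latents=pd.DataFrame(latents),
    )
    return Cohort(records=records, ground_truth=gt)


# ----------------------------------------------------------------------
# BOLD synthesis


def run_volumes(schedule: TaskSchedule, tr: float) -> list[int]:
    return [int(np.ceil(d / tr)) for d in schedule.run_durations]


def generating_design(
    record: SubjectRecord, config: CohortConfig
) -> DesignMatrix:
    """The combined (event classes + parametric PE) generating design."""
    glm = FirstLevelGLM(
        tr=config.tr, design_kind="combined", hrf=config.hrf
    )
    return glm.build_design(
        record.events, run_volumes(record.schedule, config.tr), pes=record.pes
    )


def synthesize_bold(
    record: SubjectRecord,
    ground_truth: GroundTruth,
    design: DesignMatrix | None = None,
    voxels: np.ndarray | None = None,
    dtype=np.float32,
) -> tuple[np.ndarray, DesignMatrix]:
    """BOLD = 100 + design x true betas + cosine drift + AR(1) noise.

    Returns (data, generating design); data is (n_volumes, n_voxels) in
    percent-signal-change-compatible units (baseline 100).  ``voxels`` can
    restrict synthesis to a boolean subset of mask voxels (voxel noise is
    independent, so any subset is a marginal of the full-grid simulation in
    distribution).
    """
    cfg = ground_truth.config
    design = design or generating_design(record, cfg)
    b = ground_truth.beta_matrix(record, voxels=voxels)
    n_vox = b.shape[1]
    task_cols = [c for c in design.columns if c in ground_truth.labels]
    x = np.column_stack([design.column(c) for c in task_cols]).astype(dtype)
    b_used = b[[ground_truth.labels.index(c) for c in task_cols]].astype(dtype)
    signal = x @ b_used

    rng = np.random.default_rng(record.noise_seed)
    data = np.full(signal.shape, 100.0, dtype=dtype)
    data += signal
    innov_sd = cfg.noise_sd * np.sqrt(1.0 - cfg.ar_rho**2)
    for sl in design.run_slices:
        n_vol = sl.stop - sl.start
        w = rng.standard_normal((n_vol, n_vox), dtype=np.float32).astype(
            dtype, copy=False
        ) * dtype(innov_sd)
        b_coef = np.array([1.0], dtype=dtype)
        a_coef = np.array([1.0, -cfg.ar_rho], dtype=dtype)
        noise = lfilter(b_coef, a_coef, w, axis=0)
        data[sl] += noise
        drift_basis = cosine_drift(n_vol, cfg.tr)
        if drift_basis.size:
            amps = rng.standard_normal(
                (drift_basis.shape[1], n_vox), dtype=np.float32
            ).astype(dtype, copy=False) * cfg.drift_sd
            data[sl] += (drift_basis.astype(dtype) @ amps)
    return data, design


def traditional_subdesign(design: DesignMatrix) -> DesignMatrix:
    """Traditional-family columns (event classes + nuisance) of a combined design."""
    keep = [i for i, c in enumerate(design.columns) if "_pe_" not in c]
    return DesignMatrix(
        matrix=design.matrix[:, keep],
        columns=[design.columns[i] for i in keep],
        tr=design.tr,
        design_kind="traditional",
        run_slices=design.run_slices,
    )
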