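"""Synthetic cohort: geometry, ground truth, recovery, and symptom coupling."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from tempope.cohort import (
    CohortConfig,
    ROI_LAYOUT,
    build_roi_mask,
    generate_cohort,
    generating_design,
    run_volumes,
    synthesize_bold,
    traditional_subdesign,
)
from tempope.first_level import (
    component_contrasts,
    compute_contrast,
    fit_glm,
    scale_percent_signal,
)
from tempope.task import ScheduleConfig


@pytest.fixture(scope="module")
def tiny_config():
    """Two subjects per group with a shortened schedule: fast plumbing tests."""
    return CohortConfig(
        n_per_group=2,
        schedule=ScheduleConfig(
            run1_normal_per_condition=6,
            run2_normal_per_condition=8,
            run2_catch_per_condition=2,
        ),
    )


def test_roi_blobs_disjoint_and_labeled():
    roi = build_roi_mask()
    assert set(roi.labels) == set(ROI_LAYOUT)
    sizes = {n: int(roi.mask(n).sum()) for n in roi.names}
    assert all(s >= 20 for s in sizes.values())
    total = sum(sizes.values())
    assert int(roi.mask().sum()) == total  # no overlap


def test_default_cohort_size_and_groups():
    cohort = generate_cohort(CohortConfig(), seed=2)
    assert len(cohort.records) == 90
    assert len(cohort.by_group("PTP")) == 45
    assert len(cohort.by_group("TEHC")) == 45
    tbl = cohort.symptom_table
    assert set(tbl.columns) >= {"SHAPS_C", "CAPS_numbing", "TEPS_A", "TEPS_C"}
    # anhedonia scores are elevated in the clinical group
    assert (
        tbl[tbl.group == "PTP"]["SHAPS_C"].mean()
        > tbl[tbl.group == "TEHC"]["SHAPS_C"].mean()
    )


def test_cohort_determinism(tiny_config):
    a = generate_cohort(tiny_config, seed=9)
    b = generate_cohort(tiny_config, seed=9)
    ra, rb = a.records[0], b.records[0]
    assert ra.schedule.to_dict() == rb.schedule.to_dict()
    assert ra.beta_table.equals(rb.beta_table)
    assert ra.symptoms == rb.symptoms
    da, _ = synthesize_bold(ra, a.ground_truth)
    db, _ = synthesize_bold(rb, b.ground_truth)
    np.testing.assert_array_equal(da, db)


def test_group_effects_injected_in_expected_directions(tiny_config):
    cohort = generate_cohort(CohortConfig(), seed=4)
    eff_ptp = np.mean(
        [r.beta_table.loc["putamen_L", "unexpected_outcome_juice"]
         for r in cohort.by_group("PTP")]
    )
    eff_tehc = np.mean(
        [r.beta_table.loc["putamen_L", "unexpected_outcome_juice"]
         for r in cohort.by_group("TEHC")]
    )
    assert eff_ptp < eff_tehc  # attenuated positive temporal PE response
    cue_ptp = np.mean(
        [r.beta_table.loc["insula_L", "cue_pe_juice"]
         for r in cohort.by_group("PTP")]
    )
    cue_tehc = np.mean(
        [r.beta_table.loc["insula_L", "cue_pe_juice"]
         for r in cohort.by_group("TEHC")]
    )
    assert cue_ptp > cue_tehc  # exaggerated cue-PE modulation


def test_noiseless_recovery_to_1e6(tiny_config):
    cfg = CohortConfig(
        n_per_group=2, noise_sd=0.0, drift_sd=0.0,
        schedule=tiny_config.schedule,
    )
    cohort = generate_cohort(cfg, seed=5)
    gt = cohort.ground_truth
    rec = cohort.records[0]
    gen = generating_design(rec, cfg)
    data, _ = synthesize_bold(rec, gt, design=gen, dtype=np.float64)
    res = fit_glm(data, gen, prewhiten=False)
    true = gt.beta_matrix(rec)
    for i, lbl in enumerate(gt.labels):
        if lbl in res.columns:
            np.testing.assert_allclose(
                res.beta(lbl), true[i], atol=1e-6,
                err_msg=f"beta mismatch for {lbl}",
            )


def test_injected_effects_recovered_within_2se():
    """At default noise, voxelwise contrast estimates in the affected ROIs
    sit within 2 standard errors of the generator's true contrast values
    (expected coverage ~95%; the percent-signal scaling convention carries a
    small known multiplicative factor well inside that band)."""
    from tempope.first_level import _ar1_transform

    cfg = CohortConfig(n_per_group=2)
    cohort = generate_cohort(cfg, seed=6)
    gt = cohort.ground_truth
    rec = cohort.records[0]
    gen = generating_design(rec, cfg)
    data, _ = synthesize_bold(rec, gt, design=gen)
    data = scale_percent_signal(data, gen.run_slices)
    res = fit_glm(data, gen, prewhiten=True)
    spec = component_contrasts()["neg_tpe_juice"]
    est = compute_contrast(res, spec)
    cvec = spec.vector(res.columns)
    xw = _ar1_transform(gen.matrix, res.ar_rho, gen.run_slices)
    xtxinv = np.linalg.inv(xw.T @ xw)
    for roi in ("amygdala_L", "putamen_L"):
        sel = gt.roi_selector(roi)
        se_vox = np.sqrt(cvec @ xtxinv @ cvec * res.sigma2[sel].astype(float))
        true_c = (
            rec.beta_table.loc[roi, "unexpected_absence_juice"]
            - rec.beta_table.loc[roi, "expected_absence_juice"]
        )
        covered = np.abs(est[sel] - true_c) < 2 * se_vox
        assert covered.mean() > 0.85, f"{roi}: coverage {covered.mean():.2f}"


def test_true_symptom_coupling_matches_target():
    """Across replicate cohorts the true amygdala negative-temporal-PE
    contrast and SHAPS-C have the configured Spearman correlation."""
    rhos = []
    for seed in range(1, 13):
        cohort = generate_cohort(CohortConfig(), seed=seed)
        ptp = cohort.by_group("PTP")
        ua = [
            r.beta_table.loc["amygdala_L", "unexpected_absence_juice"]
            for r in ptp
        ]
        sh = [r.symptoms["SHAPS_C"] for r in ptp]
        rhos.append(spearmanr(ua, sh).statistic)
    mean_rho = np.mean(rhos)
    # population value -0.50; SE of the 12-seed mean is ~0.033
    assert mean_rho == pytest.approx(-0.50, abs=0.10)


def test_association_survives_contrast_differencing():
    """The coupling is injected in the juice condition, so both the
    juice-only and the juice-minus-visual negative-temporal-PE contrasts
    carry the symptom association."""
    from tempope.symptom import spearman_assoc

    cohort = generate_cohort(CohortConfig(), seed=11)
    ptp = cohort.by_group("PTP")
    shaps = [r.symptoms["SHAPS_C"] for r in ptp]
    ua_j = np.array(
        [r.beta_table.loc["amygdala_L", "unexpected_absence_juice"] for r in ptp]
    )
    ua_v = np.array(
        [r.beta_table.loc["amygdala_L", "unexpected_absence_visual"] for r in ptp]
    )
    rho_j, p_j, _ = spearman_assoc(ua_j, shaps)
    rho_jv, p_jv, _ = spearman_assoc(ua_j - ua_v, shaps)
    assert rho_j < 0 and p_j < 0.01
    assert rho_jv < 0 and p_jv < 0.01


def test_symptom_regression_slope_sign_in_amygdala():
    """Voxelwise regression of the true contrast maps on SHAPS-C within the
    clinical group recovers the injected negative amygdala coupling."""
    from tempope.symptom import symptom_regression_map

    cohort = generate_cohort(CohortConfig(), seed=12)
    gt = cohort.ground_truth
    ptp = cohort.by_group("PTP")
    ua_idx = gt.labels.index("unexpected_absence_juice")
    ea_idx = gt.labels.index("expected_absence_juice")
    maps = np.array(
        [
            gt.beta_matrix(r)[ua_idx] - gt.beta_matrix(r)[ea_idx]
            for r in ptp
        ]
    )
    scores = np.array([r.symptoms["SHAPS_C"] for r in ptp])
    stat, p_corr = symptom_regression_map(
        maps, scores, gt.analysis_mask, n_perm=200, seed=0
    )
    amyg = gt.roi_selector("amygdala_L")
    assert stat.data[amyg].mean() < 0
    assert (p_corr[amyg] < 0.05).any()


def test_voxel_subset_is_consistent_marginal(tiny_config):
    cohort = generate_cohort(tiny_config, seed=8)
    gt = cohort.ground_truth
    rec = cohort.records[0]
    vox = gt.roi_selector("amygdala_L")
    b_full = gt.beta_matrix(rec)
    b_sub = gt.beta_matrix(rec, voxels=vox)
    np.testing.assert_array_equal(b_full[:, vox], b_sub)
    data, _ = synthesize_bold(rec, gt, voxels=vox)
    assert data.shape[1] == int(vox.sum())


def test_unreachable_symptom_coupling_warns(tiny_config):
    cfg = CohortConfig(
        n_per_group=2, noise_sd=200.0, schedule=tiny_config.schedule
    )
    with pytest.warns(UserWarning, match="saturate"):
        generate_cohort(cfg, seed=1)


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        CohortConfig(n_per_group=1).validate()
    with pytest.raises(ValueError):
        CohortConfig(symptom_rho=1.5).validate()


def test_run_volumes_cover_schedule(tiny_config):
    cohort = generate_cohort(tiny_config, seed=3)
    rec = cohort.records[0]
    n_vol = run_volumes(rec.schedule, tiny_config.tr)
    assert len(n_vol) == 2
    last = rec.schedule.runs[1][-1]
    assert n_vol[1] * tiny_config.tr >= last.trial_end
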