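"""Design construction, HRF convolution, GLM fitting and the contrast set."""

import numpy as np
import pandas as pd
import pytest

from tempope.cohort import run_volumes
from tempope.first_level import (
    ContrastSpec,
    FirstLevelGLM,
    HRFSpec,
    build_modelbased_design,
    build_traditional_design,
    component_contrasts,
    compute_contrast,
    contrast_registry,
    fit_glm,
)
from tempope.td import TDParams, sample_pes, simulate_td


@pytest.fixture(scope="module")
def small_setup(small_schedule, small_events):
    pes = pd.concat(
        [
            sample_pes(simulate_td(small_schedule, c, TDParams()), small_events)
            for c in ("juice", "visual")
        ],
        ignore_index=True,
    )
    n_vol = run_volumes(small_schedule, 1.0)
    return small_schedule, small_events, pes, n_vol


def test_traditional_design_has_ten_task_columns(small_setup):
    _, events, _, n_vol = small_setup
    dm = build_traditional_design(events, 1.0, n_vol)
    assert len(dm.task_columns) == 10
    expected = {
        f"{cls}_{cond}"
        for cls in (
            "cue", "expected_outcome", "expected_absence",
            "unexpected_absence", "unexpected_outcome",
        )
        for cond in ("juice", "visual")
    }
    assert set(dm.task_columns) == expected


def test_empty_events_error():
    with pytest.raises(ValueError, match="empty"):
        build_traditional_design(pd.DataFrame(columns=["onset"]), 1.0, 100)


def test_single_event_matches_direct_convolution_oracle():
    """A lone cue regressor equals boxcar * HRF computed independently."""
    events = pd.DataFrame(
        {
            "onset": [0.0],
            "duration": [1.0],
            "trial_type": ["cue_juice"],
            "event_class": ["cue"],
            "condition": ["juice"],
            "run_index": [1],
            "trial_index": [0],
            "modulator": [np.nan],
        }
    )
    tr, n_vol = 1.0, 60
    hrf = HRFSpec(oversampling=16)
    dm = build_traditional_design(events, tr, n_vol, hrf)
    col = dm.column("cue_juice")
    # independent direct convolution on the oversampled grid
    dt = tr / hrf.oversampling
    kernel = hrf.kernel(dt)
    box = np.zeros(n_vol * hrf.oversampling + 1)
    box[: int(round(1.0 / dt))] = 1.0
    ref = np.convolve(box, kernel)[: len(box)][:: hrf.oversampling][:n_vol]
    np.testing.assert_allclose(col, ref, atol=1e-10)


def test_hrf_kernel_peak_normalized():
    k = HRFSpec().kernel(0.1)
    assert k.max() == pytest.approx(1.0)
    assert abs(k[-1]) < 0.01  # decays to ~0 by 32 s


def test_modelbased_design_four_parametric_columns(small_setup):
    _, events, pes, n_vol = small_setup
    dm = build_modelbased_design(events, pes, 1.0, n_vol)
    par = [c for c in dm.columns if "_pe_" in c]
    assert sorted(par) == [
        "cue_pe_juice", "cue_pe_visual", "outcome_pe_juice", "outcome_pe_visual",
    ]
    assert dm.design_kind == "model_based"
    assert dm.modulator_centering["cue_pe_juice"]  # per-run means recorded


def test_constant_modulator_dropped_with_warning(small_setup):
    _, events, pes, n_vol = small_setup
    flat = pes.copy()
    flat["pe_value"] = 1.0
    with pytest.warns(UserWarning, match="zero variance"):
        dm = build_modelbased_design(events, flat, 1.0, n_vol)
    assert not any("_pe_" in c for c in dm.columns)


def test_missing_pe_sample_raises(small_setup):
    _, events, pes, n_vol = small_setup
    with pytest.raises(ValueError, match="lack a PE sample"):
        build_modelbased_design(events, pes.iloc[:5], 1.0, n_vol)


def test_two_event_parametric_column_matches_hand_construction():
    """Outcome events with centered PEs +1/-1 give the difference of their
    individual HRF responses."""
    base = {
        "duration": 1.0,
        "condition": "juice",
        "run_index": 1,
        "modulator": np.nan,
    }
    events = pd.DataFrame(
        [
            {"onset": 5.0, "trial_type": "expected_outcome_juice",
             "event_class": "expected_outcome", "trial_index": 0, **base},
            {"onset": 30.0, "trial_type": "unexpected_outcome_juice",
             "event_class": "unexpected_outcome", "trial_index": 1, **base},
        ]
    )
    pes = pd.DataFrame(
        {
            "event_class": ["expected_outcome", "unexpected_outcome"],
            "condition": ["juice", "juice"],
            "run_index": [1, 1],
            "trial_index": [0, 1],
            "time": [5.0, 30.0],
            "pe_value": [2.0, 4.0],  # centered: -1, +1
        }
    )
    tr, n_vol = 1.0, 70
    dm = build_modelbased_design(events, pes, tr, n_vol)
    hrf = HRFSpec()
    resp = {}
    for onset in (5.0, 30.0):
        e = pd.DataFrame(
            {"onset": [onset], "duration": [1.0], "trial_type": ["cue_juice"],
             "event_class": ["cue"], "condition": ["juice"], "run_index": [1],
             "trial_index": [0], "modulator": [np.nan]}
        )
        resp[onset] = build_traditional_design(e, tr, n_vol, hrf).column("cue_juice")
    np.testing.assert_allclose(
        dm.column("outcome_pe_juice"), resp[30.0] - resp[5.0], atol=1e-10
    )


def test_parametric_main_decorrelated(small_setup):
    """Mean-centering keeps parametric and main-effect columns weakly
    correlated without orthogonalization."""
    _, events, pes, n_vol = small_setup
    dm = build_modelbased_design(events, pes, 1.0, n_vol)
    for cond in ("juice", "visual"):
        for g in ("cue", "outcome"):
            a = dm.column(f"{g}_main_{cond}")
            b = dm.column(f"{g}_pe_{cond}")
            assert abs(np.corrcoef(a, b)[0, 1]) < 0.3


def test_design_condition_number(small_setup):
    _, events, pes, n_vol = small_setup
    for dm in (
        build_traditional_design(events, 1.0, n_vol),
        build_modelbased_design(events, pes, 1.0, n_vol),
    ):
        assert dm.condition_number() < 30


# ----------------------------------------------------------------------
# GLM


def test_noiseless_recovery(small_setup):
    _, events, _, n_vol = small_setup
    dm = build_traditional_design(events, 1.0, n_vol)
    rng = np.random.default_rng(0)
    beta_true = rng.normal(size=(len(dm.columns), 5))
    data = dm.matrix @ beta_true
    res = fit_glm(data, dm, prewhiten=False)
    np.testing.assert_allclose(res.betas, beta_true, atol=1e-8)
    assert res.df == data.shape[0] - len(dm.columns)


def test_white_noise_beta_variance_matches_ols_theory(small_setup):
    """Empirical beta variance across simulated voxels tracks (X'X)^-1 s2."""
    _, events, _, n_vol = small_setup
    dm = build_traditional_design(events, 1.0, n_vol)
    rng = np.random.default_rng(1)
    sigma = 2.0
    data = rng.normal(scale=sigma, size=(dm.matrix.shape[0], 200))
    res = fit_glm(data, dm, prewhiten=False)
    j = dm.columns.index("cue_juice")
    theory = sigma**2 * np.linalg.inv(dm.matrix.T @ dm.matrix)[j, j]
    emp = res.betas[j].var()
    assert abs(res.betas[j].mean()) < 3 * np.sqrt(theory / 200)
    assert emp == pytest.approx(theory, rel=0.15)


def test_prewhitening_reduces_beta_se(small_setup):
    """Under AR(1) noise, Cochrane-Orcutt prewhitened betas are no more
    variable on average than plain OLS betas."""
    from scipy.signal import lfilter

    _, events, _, n_vol = small_setup
    dm = build_traditional_design(events, 1.0, n_vol)
    rng = np.random.default_rng(2)
    rho = 0.3
    w = rng.normal(size=(dm.matrix.shape[0], 300))
    noise = lfilter([1.0], [1.0, -rho], w, axis=0)
    res_w = fit_glm(noise, dm, prewhiten=True)
    res_o = fit_glm(noise, dm, prewhiten=False)
    assert 0.15 < res_w.ar_rho < 0.45
    j = dm.columns.index("cue_juice")
    assert res_w.betas[j].var() <= res_o.betas[j].var() * 1.05


def test_rank_deficient_design_names_collinear_columns(small_setup):
    _, events, _, n_vol = small_setup
    dm = build_traditional_design(events, 1.0, n_vol)
    dm.matrix[:, 1] = dm.matrix[:, 0]
    dm.columns[1] = "duplicate_of_first"
    with pytest.raises(np.linalg.LinAlgError, match="duplicate_of_first"):
        fit_glm(np.zeros((dm.matrix.shape[0], 3)), dm)


def test_mismatched_volumes_error(small_setup):
    _, events, _, n_vol = small_setup
    dm = build_traditional_design(events, 1.0, n_vol)
    with pytest.raises(ValueError, match="volumes"):
        fit_glm(np.zeros((10, 3)), dm)


# ----------------------------------------------------------------------
# contrasts


def test_contrast_arithmetic(small_setup):
    _, events, _, n_vol = small_setup
    dm = build_traditional_design(events, 1.0, n_vol)
    res = fit_glm(np.zeros((dm.matrix.shape[0], 2)), dm, prewhiten=False)
    res.betas[res.columns.index("cue_juice")] = 3.0
    res.betas[res.columns.index("cue_visual")] = 1.0
    spec = ContrastSpec("cue", {"cue_juice": 1.0, "cue_visual": -1.0})
    np.testing.assert_allclose(compute_contrast(res, spec), [2.0, 2.0])


def test_registry_has_six_contrasts():
    reg = contrast_registry()
    assert len(reg) == 6
    names = [c.name for c in reg]
    assert names == [
        "cue_juice_vs_visual", "outcome_juice_vs_visual",
        "pos_tpe_juice_vs_visual", "neg_tpe_juice_vs_visual",
        "cue_pe_juice", "outcome_pe_juice",
    ]


def test_traditional_registry_weights_sum_to_zero():
    for spec in contrast_registry():
        if spec.family == "traditional":
            assert sum(spec.weights.values()) == 0


def test_pos_tpe_contrast_equals_component_difference():
    reg = {c.name: c for c in contrast_registry()}
    comp = component_contrasts()
    combined = {}
    for lbl, w in comp["pos_tpe_juice"].weights.items():
        combined[lbl] = combined.get(lbl, 0) + w
    for lbl, w in comp["pos_tpe_visual"].weights.items():
        combined[lbl] = combined.get(lbl, 0) - w
    assert combined == reg["pos_tpe_juice_vs_visual"].weights


def test_unknown_contrast_column_errors(small_setup):
    _, events, _, n_vol = small_setup
    dm = build_traditional_design(events, 1.0, n_vol)
    res = fit_glm(np.zeros((dm.matrix.shape[0], 1)), dm, prewhiten=False)
    with pytest.raises(KeyError, match="nonexistent"):
        compute_contrast(res, ContrastSpec("bad", {"nonexistent": 1.0}))


def test_estimator_facade(small_setup):
    schedule, events, pes, n_vol = small_setup
    rng = np.random.default_rng(5)
    glm = FirstLevelGLM(tr=1.0, design_kind="model_based", scale_psc=False)
    data = rng.normal(100.0, 1.0, size=(sum(n_vol), 4))
    glm.fit(data, events, n_vol, pes=pes)
    assert glm.betas_.shape[1] == 4
    vals = glm.contrast("cue_pe_juice")
    assert vals.shape == (4,)
    assert glm.get_params()["design_kind"] == "model_based"
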