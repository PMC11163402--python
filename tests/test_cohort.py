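"""Synthetic cohort generator: responder rule, determinism, analytic oracle."""

import numpy as np
import pandas as pd
import pytest

import fcdecomp as f
from fcdecomp.cohort import (
    ConfigurationError,
    classify_responder,
    nearest_correlation,
    target_correlation_from_latent,
    unit_metadata,
)


@pytest.mark.parametrize(
    "baseline, week8, expected",
    [
        (28, 8, "responder"),  # 71.4% decrease
        (30, 16, "nonresponder"),  # 46.7% decrease
        (30, 15, "nonresponder"),  # exactly 50%: strict ">" required
    ],
)
def test_responder_rule(baseline, week8, expected):
    assert classify_responder(baseline, week8) == expected


def test_cohort_counts_and_label_consistency(tiny_config, tiny_cohort):
    co = tiny_cohort
    assert (co.diagnosis == "MD").sum() == tiny_config.n_patients
    assert (co.diagnosis == "control").sum() == tiny_config.n_controls
    assert (co.responder == "responder").sum() == tiny_config.n_responders
    # controls never carry a response label or MADRS scores
    controls = co[co.diagnosis == "control"]
    assert (controls.responder == "not_applicable").all()
    assert controls.madrs_baseline.isna().all()
    # the label column is reproducible from the MADRS columns
    patients = co[co.diagnosis == "MD"]
    relabel = [
        classify_responder(b, w8)
        for b, w8 in zip(patients.madrs_baseline, patients.madrs_week8)
    ]
    assert list(patients.responder) == relabel
    assert (patients.madrs_baseline >= 24).all()  # entry criterion


def test_study_sized_defaults():
    cfg = f.SimulationConfig()
    co = f.generate_cohort(cfg)
    assert len(co) == 107
    assert (co.diagnosis == "MD").sum() == 68
    assert (co.responder == "responder").sum() == 33
    assert (co.responder == "nonresponder").sum() == 35
    assert ((co.diagnosis == "control") & (co.sex == "F")).sum() == 21


def test_infeasible_counts_rejected():
    with pytest.raises(ConfigurationError):
        f.SimulationConfig(n_patients_f=1, n_patients_m=0, n_responders=2)
    with pytest.raises(ConfigurationError):
        f.SimulationConfig(weights={"common": -1.0})
    with pytest.raises(ConfigurationError):
        f.SimulationConfig(n_rois=2)


def test_seed_determinism(tiny_config, tiny_cohort):
    co2 = f.generate_cohort(tiny_config)
    pd.testing.assert_frame_equal(tiny_cohort, co2)
    c1 = f.generate_latent_components(tiny_config, tiny_cohort)
    c2 = f.generate_latent_components(tiny_config, tiny_cohort)
    for k in c1.patterns:
        assert np.array_equal(c1[k], c2[k])
    v1 = f.generate_fc_vectors(c1, tiny_cohort, tiny_config)
    v2 = f.generate_fc_vectors(c2, tiny_cohort, tiny_config)
    assert all(np.array_equal(a.values, b.values) for a, b in zip(v1, v2))


def test_latent_component_shapes(tiny_cohort):
    cfg = f.SimulationConfig(
        n_controls_f=2, n_controls_m=2, n_patients_f=2, n_patients_m=2,
        n_responders=2, n_rois=4, seed=99,
        weights={**f.DEFAULT_WEIGHTS, "individual": 0.0},
    )
    comps = f.generate_latent_components(cfg, tiny_cohort)
    # P = R(R-1)/2 for every pattern
    assert comps.n_pairs == 6
    assert all(p.shape == (6,) for p in comps.patterns.values())
    # zero weight -> zero pattern
    for sub in tiny_cohort.subject_id:
        assert np.all(comps[("individual", sub)] == 0)


def test_fc_vector_expected_correlations_monte_carlo():
    """common=individual=noise=1 at large P: within-subject r ~ 2/3, across ~ 1/3."""
    weights = {c: 0.0 for c in f.DEFAULT_WEIGHTS}
    weights.update(common=1.0, individual=1.0, noise=1.0)
    cfg = f.SimulationConfig(
        n_controls_f=1, n_controls_m=1, n_patients_f=0, n_patients_m=0,
        n_responders=0, n_rois=450, weights=weights, seed=5,
    )  # P = 101_025
    co = f.generate_cohort(cfg)
    comps = f.generate_latent_components(cfg, co)
    vecs = f.generate_fc_vectors(comps, co, cfg)
    by = {(v.meta.subject_id, v.meta.session): v.values for v in vecs}
    subs = sorted({k[0] for k in by})
    within = np.corrcoef(by[(subs[0], "baseline")], by[(subs[0], "week2")])[0, 1]
    across = np.corrcoef(by[(subs[0], "baseline")], by[(subs[1], "week2")])[0, 1]
    assert within == pytest.approx(2 / 3, abs=0.02)
    assert across == pytest.approx(1 / 3, abs=0.02)


def test_degenerate_weight_configurations(tiny_cohort):
    # only noise: vectors essentially uncorrelated
    w = {c: 0.0 for c in f.DEFAULT_WEIGHTS}
    cfg = f.SimulationConfig(
        n_controls_f=2, n_controls_m=2, n_patients_f=2, n_patients_m=2,
        n_responders=2, n_rois=60, weights={**w, "noise": 1.0}, seed=1,
    )
    gt = f.expected_ground_truth(cfg, "all", cohort=tiny_cohort)
    assert all(e.expected_r == 0 for e in gt.values())
    # only common: all units share one vector, expected r = 1 everywhere
    cfg2 = f.SimulationConfig(
        n_controls_f=2, n_controls_m=2, n_patients_f=2, n_patients_m=2,
        n_responders=2, n_rois=12, weights={**w, "common": 1.0}, seed=1,
    )
    comps = f.generate_latent_components(cfg2, tiny_cohort)
    vecs = f.generate_fc_vectors(comps, tiny_cohort, cfg2)
    assert all(np.array_equal(v.values, vecs[0].values) for v in vecs)
    gt2 = f.expected_ground_truth(cfg2, "all", cohort=tiny_cohort)
    assert all(e.expected_r == 1 for e in gt2.values())


def test_expected_similarity_against_brute_force_simulation():
    """Mask-average oracle matches Monte-Carlo mask averages at large P."""
    weights = {c: 0.0 for c in f.DEFAULT_WEIGHTS}
    weights.update(common=1.0, individual=1.0, noise=1.0)
    cfg = f.SimulationConfig(
        n_controls_f=2, n_controls_m=1, n_patients_f=0, n_patients_m=0,
        n_responders=0, n_rois=450, weights=weights, seed=17,
    )
    co = f.generate_cohort(cfg)
    comps = f.generate_latent_components(cfg, co)
    vecs = f.generate_fc_vectors(comps, co, cfg)
    _, _, table, _ = f.decompose(vecs, sample="controls", mode="pooled")
    gt = f.expected_ground_truth(cfg, "controls", cohort=co)
    # individual pair-class correlation is exactly 2/3 here
    assert gt["individual"].expected_r == pytest.approx(2 / 3)
    for eff, obs in zip(table.effect, table.raw_mean_z):
        assert obs == pytest.approx(gt[eff].expected_z, abs=0.01)


def test_expected_effect_similarity_unknown_name(tiny_config):
    with pytest.raises(KeyError):
        f.expected_effect_similarity(tiny_config, "zodiac")


def test_unit_grain_controls_unit_count(tiny_config, tiny_cohort):
    assert len(unit_metadata(tiny_config, tiny_cohort, "session")) == 8 * 3
    assert len(unit_metadata(tiny_config, tiny_cohort, "session_task")) == 8 * 9


def test_nearest_correlation_properties(rng):
    A = rng.standard_normal((8, 8))
    C = nearest_correlation((A + A.T) / 4)
    assert np.allclose(C, C.T)
    assert np.allclose(np.diag(C), 1.0)
    assert np.linalg.eigvalsh(C).min() > 0
    # an already-valid correlation matrix passes through (up to tolerance)
    X = rng.standard_normal((500, 8))
    C0 = np.corrcoef(X, rowvar=False)
    assert np.allclose(nearest_correlation(C0), C0, atol=1e-8)


def test_target_correlation_rejects_nonfinite():
    v = np.full(6, np.nan)
    with pytest.raises(ValueError):
        target_correlation_from_latent(v, 4)


def test_timeseries_recovers_target_correlation():
    """Sampling from the target structure reproduces it within sampling error."""
    rng = np.random.default_rng(2)
    v = rng.standard_normal(45) * 0.8
    C = target_correlation_from_latent(v, 10)
    L = np.linalg.cholesky(C)
    X = rng.standard_normal((20000, 10)) @ L.T
    emp = np.corrcoef(X, rowvar=False)
    assert np.abs(emp - C).max() < 0.05
    # identity target: off-diagonal FC ~ 0
    Xi = rng.standard_normal((20000, 10))
    ei = np.corrcoef(Xi, rowvar=False)
    assert np.abs(ei - np.eye(10)).max() < 0.03


def test_timeseries_dataset_layout(tmp_path, tiny_cohort):
    cfg = f.SimulationConfig(
        n_controls_f=2, n_controls_m=2, n_patients_f=2, n_patients_m=2,
        n_responders=2, n_rois=8, mode="timeseries", seed=99,
    )
    comps = f.generate_latent_components(cfg, tiny_cohort)
    runs, manifest, events = f.generate_timeseries_dataset(
        comps, tiny_cohort, cfg, out_dir=tmp_path
    )
    assert len(runs) == 8 * 3 * 3
    # run lengths follow floor(duration / TR)
    lengths = {ts.task: ts.n_timepoints for ts in runs}
    assert lengths == {"rest": 294, "gonogo": 294, "anhedonia": 345}
    assert (tmp_path / "manifest.csv").exists()
    assert (tmp_path / "ground_truth.json").exists()
    for _, row in manifest.iterrows():
        assert (tmp_path / row["path"]).exists()
    # event tables per the task designs: 5 go/no-go types, 7 anhedonia types
    ev_g = events[(manifest.subject_id[0], "baseline", "gonogo")]
    ev_a = events[(manifest.subject_id[0], "baseline", "anhedonia")]
    assert ev_g.trial_type.nunique() == 5
    assert ev_a.trial_type.nunique() == 7
    assert len(events[(manifest.subject_id[0], "baseline", "rest")]) == 0
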