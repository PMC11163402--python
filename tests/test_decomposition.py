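"""Similarity matrix, effect masks, baselines and normalized magnitudes."""

import itertools

import numpy as np
import pandas as pd
import pytest

from fcdecomp.connectivity import FcVector, UnitMetadata, Z_CLIP, fisher_z
from fcdecomp.decomposition import (
    SimilarityMatrix,
    baseline_for,
    build_similarity_matrix,
    effect_average,
    make_effect_masks,
    normalized_magnitudes,
    participant_effect_averages,
    participant_table,
    roi_effect_magnitudes,
)


def meta(sub, sess, task="pooled", diagnosis="control", sex="F", responder="not_applicable"):
    return UnitMetadata(sub, sess, task, diagnosis, sex, responder)


def vec(values, m):
    values = np.asarray(values, dtype=float)
    # infer R from P = R(R-1)/2
    R = int((1 + np.sqrt(1 + 8 * len(values))) / 2)
    return FcVector(values=values, n_rois=R, meta=m)


def grid_units(n_sub=2, sessions=("baseline", "week2"), tasks=("pooled",), **kw):
    units = []
    for i in range(n_sub):
        for s in sessions:
            for t in tasks:
                units.append(meta(f"sub{i}", s, task=t, **kw))
    return units


class TestSimilarityMatrix:
    def test_identical_vectors_all_clip(self, rng):
        v = rng.standard_normal(6)
        units = grid_units(1, ("baseline", "week2", "week8"))
        sm = build_similarity_matrix([vec(v, m) for m in units])
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(sm.values[off], Z_CLIP)

    def test_two_units_symmetric(self, rng):
        vs = [vec(rng.standard_normal(6), m) for m in grid_units(2, ("baseline",))]
        sm = build_similarity_matrix(vs)
        assert sm.values[0, 1] == sm.values[1, 0]

    def test_matches_pairwise_pearson_loop(self, rng):
        vs = [vec(rng.standard_normal(6), m) for m in grid_units(3, ("baseline",))]
        sm = build_similarity_matrix(vs)
        for i, j in itertools.combinations(range(3), 2):
            r = np.corrcoef(vs[i].values, vs[j].values)[0, 1]
            assert sm.values[i, j] == pytest.approx(np.arctanh(r))

    def test_zero_variance_vector_named(self, rng):
        vs = [
            vec(rng.standard_normal(6), meta("a", "baseline")),
            vec(np.zeros(6), meta("b", "baseline")),
        ]
        with pytest.raises(ValueError, match="b/baseline"):
            build_similarity_matrix(vs)


class TestMasks:
    def test_session_mask_cell_count(self):
        units = grid_units(2, ("baseline", "week2"))
        masks = make_effect_masks(units, sample="controls", mode="pooled")
        # 2 subjects x 2 sessions: 2 symmetric cells per session
        assert masks["session"].sum() == 4

    def test_individual_mask_one_subject(self):
        units = grid_units(1, ("baseline", "week2", "week8"))
        masks = {"individual": make_effect_masks(units, "controls", "pooled")["individual"]}
        assert masks["individual"].sum() == 6  # 3 x 2 ordered cells

    def test_common_mask_all_offdiagonal(self):
        units = grid_units(2, ("baseline", "week2"))
        masks = make_effect_masks(units, "controls", "pooled")
        assert masks["common"].sum() == 4 * 3

    def test_session_mask_never_within_subject(self):
        units = grid_units(4, ("baseline", "week2", "week8"))
        masks = make_effect_masks(units, "controls", "pooled")
        subj = np.array([u.subject_id for u in units])
        within = subj[:, None] == subj[None, :]
        assert not (masks["session"] & within).any()

    def test_single_level_factor_omitted_with_warning(self):
        units = grid_units(2, ("baseline",), sex="F")
        with pytest.warns(UserWarning, match="single level"):
            masks = make_effect_masks(units, "controls", "pooled")
        assert "sex" not in masks and "session" not in masks

    def test_per_task_within_subject_partition(self):
        units = grid_units(
            3, ("baseline", "week2", "week8"), tasks=("rest", "gonogo", "anhedonia")
        )
        masks = make_effect_masks(units, "controls", "per-task")
        subj = np.array([u.subject_id for u in units])
        within = (subj[:, None] == subj[None, :]) & ~np.eye(len(units), dtype=bool)
        trio = ["individual", "individual_x_session", "individual_x_task"]
        for a, b in itertools.combinations(trio, 2):
            assert not (masks[a] & masks[b]).any()
        union = masks[trio[0]] | masks[trio[1]] | masks[trio[2]]
        assert np.array_equal(union, within)

    def test_group_masks_match_predicate_enumeration(self):
        units = grid_units(4, ("baseline", "week2"), diagnosis="MD", responder="responder")
        units += grid_units(4, ("baseline", "week2"), diagnosis="control")
        # rename control subjects to be distinct; two sexes per diagnosis group
        units = [
            meta(f"{u.diagnosis}_{u.subject_id}", u.session,
                 diagnosis=u.diagnosis,
                 sex="F" if int(u.subject_id[-1]) % 2 == 0 else "M",
                 responder=u.responder)
            for u in units
        ]
        masks = make_effect_masks(units, sample="all", mode="pooled")
        n = len(units)
        for name, pred in {
            "diagnosis": lambda a, b: a.diagnosis == b.diagnosis,
            "diagnosis_x_session": lambda a, b: a.diagnosis == b.diagnosis
            and a.session == b.session,
            "diagnosis_x_sex": lambda a, b: a.diagnosis == b.diagnosis and a.sex == b.sex,
        }.items():
            expected = np.zeros((n, n), dtype=bool)
            for i, j in itertools.product(range(n), repeat=2):
                if i != j and units[i].subject_id != units[j].subject_id:
                    expected[i, j] = pred(units[i], units[j])
            assert np.array_equal(masks[name], expected), name


class TestEffectAverages:
    def test_constant_matrix(self):
        units = grid_units(2, ("baseline", "week2"))
        sm = SimilarityMatrix(values=np.full((4, 4), 0.7), units=units)
        masks = make_effect_masks(units, "controls", "pooled")
        for m in masks.values():
            assert effect_average(sm, m) == pytest.approx(0.7)
            for u in ("sub0", "sub1"):
                assert participant_effect_averages(sm, m, u) == pytest.approx(0.7)

    def test_hand_built_matrix_session_mask(self):
        units = grid_units(2, ("baseline", "week2"))
        vals = np.zeros((4, 4))
        # units: (sub0,b),(sub0,w2),(sub1,b),(sub1,w2)
        vals[0, 2] = vals[2, 0] = 0.4  # same session baseline
        vals[1, 3] = vals[3, 1] = 0.6  # same session week2
        sm = SimilarityMatrix(values=vals, units=units)
        masks = make_effect_masks(units, "controls", "pooled")
        assert effect_average(sm, masks["session"]) == pytest.approx(0.5)
        assert participant_effect_averages(sm, masks["session"], "sub0") == pytest.approx(0.5)

    def test_permutation_invariance(self, rng):
        units = grid_units(3, ("baseline", "week2"))
        vals = rng.standard_normal((6, 6))
        vals = (vals + vals.T) / 2
        sm = SimilarityMatrix(values=vals, units=units)
        masks = make_effect_masks(units, "controls", "pooled")
        perm = rng.permutation(6)
        sm2 = SimilarityMatrix(
            values=vals[np.ix_(perm, perm)], units=[units[i] for i in perm]
        )
        masks2 = make_effect_masks(sm2.units, "controls", "pooled")
        for name in masks:
            assert effect_average(sm, masks[name]) == pytest.approx(
                effect_average(sm2, masks2[name])
            )

    def test_empty_mask_rejected(self):
        units = grid_units(2, ("baseline",))
        sm = SimilarityMatrix(values=np.zeros((2, 2)), units=units)
        with pytest.raises(ValueError, match="empty"):
            effect_average(sm, np.zeros((2, 2), dtype=bool))

    def test_double_loop_oracle_equivalence(self, rng):
        """Every effect average equals an explicit loop over unordered unit pairs."""
        units = grid_units(3, ("baseline", "week2"), diagnosis="MD", responder="responder")
        units = [
            meta(u.subject_id if i < 2 else f"c{u.subject_id}", u.session,
                 diagnosis="MD" if i < 2 else "control",
                 sex="F" if i % 2 else "M",
                 responder=u.responder if i < 2 else "not_applicable")
            for i, u in enumerate(units)
            for _ in [0]
        ]
        vals = rng.standard_normal((len(units), len(units)))
        vals = (vals + vals.T) / 2
        sm = SimilarityMatrix(values=vals, units=units)
        masks = make_effect_masks(units, "all", "pooled")
        for name, m in masks.items():
            cells = [
                vals[i, j]
                for i in range(len(units))
                for j in range(i + 1, len(units))
                if m[i, j]
            ]
            if cells:
                assert effect_average(sm, m) == pytest.approx(np.mean(cells)), name

    def test_participant_mean_aggregates_to_matrix_mean_when_balanced(self, rng):
        """On a balanced design the subject-mean of participant averages is the matrix average."""
        units = grid_units(4, ("baseline", "week2", "week8"))
        vals = rng.standard_normal((12, 12))
        vals = (vals + vals.T) / 2
        sm = SimilarityMatrix(values=vals, units=units)
        masks = make_effect_masks(units, "controls", "pooled")
        for name in ("session", "individual"):
            per = [
                participant_effect_averages(sm, masks[name], f"sub{i}") for i in range(4)
            ]
            assert np.mean(per) == pytest.approx(effect_average(sm, masks[name]))


class TestNormalizedMagnitudes:
    def test_ladder_worked_example(self):
        raw = {"common": 0.30, "session": 0.28, "sex": 0.32, "individual": 0.58}
        tab = normalized_magnitudes(raw).set_index("effect")
        assert tab.loc["common", "corrected"] == pytest.approx(0.30)
        assert tab.loc["session", "corrected"] == 0.0
        assert tab.loc["sex", "corrected"] == pytest.approx(0.02)
        assert tab.loc["individual", "corrected"] == pytest.approx(0.26)
        assert tab.loc["common", "normalized_pct"] == pytest.approx(100 * 0.30 / 0.58)
        assert tab.loc["individual", "normalized_pct"] == pytest.approx(100 * 0.26 / 0.58)
        assert tab["normalized_pct"].sum() == pytest.approx(100.0)

    def test_single_effect_above_zero_baseline(self):
        tab = normalized_magnitudes({"common": 0.4}).set_index("effect")
        assert tab.loc["common", "normalized_pct"] == pytest.approx(100.0)

    def test_below_baseline_floored_to_zero(self):
        raw = {"common": 0.5, "session": 0.3, "individual": 0.9}
        tab = normalized_magnitudes(raw).set_index("effect")
        assert tab.loc["session", "corrected"] == 0.0
        assert tab.loc["session", "normalized_pct"] == 0.0

    def test_interaction_baseline_is_max_of_mains(self):
        raw = {
            "common": 0.2, "session": 0.25, "sex": 0.30, "diagnosis": 0.28,
            "diagnosis_x_sex": 0.33, "diagnosis_x_session": 0.27, "individual": 0.6,
        }
        assert baseline_for("diagnosis_x_sex", raw) == pytest.approx(0.30)
        assert baseline_for("diagnosis_x_session", raw) == pytest.approx(0.28)
        # individual's baseline is the max over all group/session effects
        assert baseline_for("individual", raw) == pytest.approx(0.33)

    def test_exploratory_effects_baseline_on_individual(self):
        raw = {
            "common": 0.2, "session": 0.25, "sex": 0.3, "individual": 0.6,
            "individual_x_session": 0.65, "individual_x_task": 0.7,
        }
        assert baseline_for("individual_x_session", raw) == pytest.approx(0.6)
        assert baseline_for("individual_x_task", raw) == pytest.approx(0.6)

    def test_all_zero_corrected_reported_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            tab = normalized_magnitudes({"common": 0.0, "session": 0.0, "individual": 0.0})
        assert tab["normalized_pct"].isna().all()


class TestRoiMagnitudes:
    def test_matches_manual_profile_pipeline(self, rng):
        from fcdecomp.connectivity import matrix_from_vector, roi_profile

        units = grid_units(2, ("baseline", "week2"))
        mats = []
        for m in units:
            z = rng.standard_normal((3, 3))
            z = (z + z.T) / 2
            np.fill_diagonal(z, 0.0)
            mats.append(matrix_from_vector(vec(z[np.triu_indices(3, 1)], m)))
        tab = roi_effect_magnitudes(mats, sample="controls", mode="pooled")
        # manual pipeline for ROI 0
        profiles = np.vstack([roi_profile(m, 0) for m in mats])
        sim = fisher_z(np.corrcoef(profiles))
        masks = make_effect_masks(units, "controls", "pooled")
        sm = SimilarityMatrix(values=sim, units=units)
        raw = {e: effect_average(sm, mk) for e, mk in masks.items()}
        manual = normalized_magnitudes(raw).set_index("effect")
        got = tab[tab.roi_index == 0].set_index("effect")
        for e in manual.index:
            assert got.loc[e, "normalized_pct"] == pytest.approx(
                manual.loc[e, "normalized_pct"], nan_ok=True
            )

    def test_constant_profiles_rejected(self):
        from fcdecomp.connectivity import ConnectivityMatrix

        units = grid_units(2, ("baseline", "week2"))
        mats = [
            ConnectivityMatrix(values=np.zeros((3, 3)), meta=m) for m in units
        ]
        with pytest.raises(ValueError, match="constant profile"):
            roi_effect_magnitudes(mats, sample="controls", mode="pooled")


def test_participant_table_shape(rng):
    units = grid_units(3, ("baseline", "week2"))
    vals = rng.standard_normal((6, 6))
    vals = (vals + vals.T) / 2
    sm = SimilarityMatrix(values=vals, units=units)
    masks = make_effect_masks(units, "controls", "pooled")
    tab = participant_table(sm, masks)
    assert tab.shape == (3, len(masks))
    assert list(tab.index) == ["sub0", "sub1", "sub2"]
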