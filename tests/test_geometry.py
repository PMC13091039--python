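"""Distance observables, 2D maps, state calls and representatives."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ensemblefp import (
    DistancePairSpec,
    DistanceSeries,
    Ensemble,
    EnsembleFPError,
    ResolutionError,
    StructureModel,
    classify_states,
    ensemble_distances,
    histogram2d,
    measure_pair,
    select_representative,
)
from ensemblefp.model_io import ATOM_COLUMNS
from ensemblefp.synthetic import par1_preset, template_distances

from oracles import random_rigid_transform

ROLES = {"receptor": "A", "barr2": "B"}


def two_atom_model(pos_a, pos_b, model_id="m"):
    rows = [
        ("A", 1, "GLY", "CA", "", *pos_a, 1.0, 0.0),
        ("A", 2, "GLY", "CA", "", *pos_b, 1.0, 0.0),
    ]
    return StructureModel(model_id, pd.DataFrame(rows, columns=ATOM_COLUMNS))


def series(name, values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"m{i}" for i in range(len(values))]
    return DistanceSeries(name=name, model_ids=list(ids), values=values)


class TestMeasurePair:
    def test_three_four_five_triangle(self):
        model = two_atom_model((0, 0, 0), (3, 4, 0))
        spec = DistancePairSpec.from_strings("1/ca", "2/ca")
        assert measure_pair(model, spec, ROLES) == pytest.approx(5.0)

    def test_coincident_positions_zero(self):
        model = two_atom_model((1, 1, 1), (1, 1, 1))
        spec = DistancePairSpec.from_strings("1/ca", "2/ca")
        assert measure_pair(model, spec, ROLES) == 0.0

    def test_same_atom_rejected(self):
        model = two_atom_model((0, 0, 0), (1, 0, 0))
        spec = DistancePairSpec.from_strings("1/ca", "1/ca")
        with pytest.raises(ResolutionError, match="same atom"):
            measure_pair(model, spec, ROLES)

    def test_matches_generator_ground_truth(self, small_spec, small_ensemble):
        """With the generator's noise present, measured distances sit near
        the recorded pre-noise truth; regenerating noise-free recovers the
        template values to format precision."""
        ens, truth = small_ensemble
        specs = small_spec.pair_specs()
        got = {
            s.name: measure_pair(ens.models[0], s, ROLES) for s in specs
        }
        want = truth.true_distances[ens.model_ids[0]]
        for name in want:
            assert got[name] == pytest.approx(want[name], abs=6 * small_spec.noise_sigma)


class TestEnsembleDistances:
    def test_one_series_per_spec_ordered(self, toy_ensemble, preset_spec):
        ens, _ = toy_ensemble
        out = ensemble_distances(ens, preset_spec.pair_specs(), ROLES)
        assert len(out) == 8
        for s in out:
            assert len(s) == 100
            assert s.model_ids == ens.model_ids

    def test_empty_spec_list(self, small_ensemble):
        ens, _ = small_ensemble
        assert ensemble_distances(ens, [], ROLES) == []

    def test_rigid_invariance(self, small_ensemble, small_spec):
        """Distances are unchanged (within 1e-9 Å) when each model moves by
        its own random global rigid transform."""
        ens, _ = small_ensemble
        specs = small_spec.pair_specs()
        before = ensemble_distances(ens, specs, ROLES)
        rng = np.random.default_rng(5)
        moved = []
        for m in ens.models:
            R, t = random_rigid_transform(rng)
            moved.append(m.with_coords(m.coords @ R.T + t))
        after = ensemble_distances(
            Ensemble(label="moved", models=moved), specs, ROLES
        )
        for sa, sb in zip(before, after):
            assert np.abs(sa.values - sb.values).max() <= 1e-9

    def test_skip_policy_records_models(self, small_ensemble):
        ens, _ = small_ensemble
        bad = DistancePairSpec.from_strings("1/ca", "9999/ca")
        with pytest.raises(ResolutionError):
            ensemble_distances(ens, [bad], ROLES)
        out = ensemble_distances(ens, [bad], ROLES, skip_unresolvable=True)
        assert out[0].skipped == ens.model_ids
        assert len(out[0]) == 0


class TestHistogram2D:
    def test_single_model_single_cell(self):
        m = histogram2d(series("x", [2.0]), series("y", [3.0]), 1.0)
        assert m.counts.sum() == 1
        assert (m.counts == 1).sum() == 1

    def test_hand_binned_three_points(self):
        """xs {1.0, 1.1, 3.0}, ys {2.0, 2.1, 4.0}, width 1: two points share
        one cell, the third sits alone."""
        m = histogram2d(series("x", [1.0, 1.1, 3.0]), series("y", [2.0, 2.1, 4.0]), 1.0)
        flat = sorted(m.counts.ravel(), reverse=True)
        assert flat[:2] == [2, 1] and sum(flat) == 3

    def test_edges_pad_one_bin_each_side(self):
        m = histogram2d(series("x", [5.0, 6.0]), series("y", [5.0, 6.0]), 0.5)
        assert m.x_edges[0] == pytest.approx(4.5)
        assert m.x_edges[-1] == pytest.approx(6.5)
        assert np.allclose(np.diff(m.x_edges), 0.5)

    def test_mismatched_series_rejected(self):
        with pytest.raises(ValueError, match="model order"):
            histogram2d(series("x", [1.0, 2.0]), series("y", [1.0]))

    @given(
        data=st.lists(
            st.tuples(
                st.floats(0.0, 80.0, allow_nan=False),
                st.floats(0.0, 80.0, allow_nan=False),
            ),
            min_size=1,
            max_size=60,
        ),
        width=st.sampled_from([0.25, 0.5, 1.0, 2.0]),
    )
    @settings(max_examples=60, derandomize=True)
    def test_counts_conserved(self, data, width):
        xs = series("x", [d[0] for d in data])
        ys = series("y", [d[1] for d in data])
        m = histogram2d(xs, ys, width)
        assert m.counts.sum() == len(data)


class TestClassifyStates:
    def test_fixed_threshold(self):
        calls = classify_states(
            {"pocket": [series("p", [10.0, 11.0, 13.0])]},
            method="fixed-threshold",
            thresholds={"pocket": 12.0},
            labels={"pocket": ("below", "above")},
        )
        assert [c.states["pocket"] for c in calls] == ["below", "below", "above"]

    def test_identical_models_single_state(self):
        calls = classify_states({"a": [series("p", [7.0] * 6)]})
        assert len({c.states["a"] for c in calls}) == 1
        assert calls[0].params["per_axis"]["a"]["separation"] == 0.0

    def test_two_cluster_recovers_planted_mixture(self):
        """Means 8 Å vs 16 Å with σ 0.8: labels match the planted states for
        at least 99% of models."""
        rng = np.random.default_rng(7)
        truth = rng.random(200) < 0.5
        vals = np.where(truth, rng.normal(8.0, 0.8, 200), rng.normal(16.0, 0.8, 200))
        calls = classify_states(
            {"pocket": [series("p", vals)]}, labels={"pocket": ("lo", "hi")}
        )
        got = np.array([c.states["pocket"] == "lo" for c in calls])
        assert (got == truth).mean() >= 0.99
        assert calls[0].params["per_axis"]["pocket"]["separation"] > 5.0

    def test_insufficient_models(self):
        with pytest.raises(EnsembleFPError, match=">= 4"):
            classify_states({"a": [series("p", [1.0, 2.0, 3.0])]})

    def test_axis_label_assignment_by_cluster_mean(self):
        vals = [1.0, 1.1, 20.0, 20.1]
        calls = classify_states(
            {"a": [series("p", vals)]}, labels={"a": ("narrow", "extended")}
        )
        assert [c.states["a"] for c in calls] == [
            "narrow",
            "narrow",
            "extended",
            "extended",
        ]


class TestSelectRepresentative:
    def test_single_model(self):
        xs, ys = series("x", [2.0]), series("y", [3.0])
        assert select_representative(histogram2d(xs, ys, 1.0), xs, ys) == "m0"

    def test_member_of_modal_bin(self):
        xs = series("x", [1.1, 1.2, 5.0])
        ys = series("y", [1.1, 1.2, 5.0])
        rep = select_representative(histogram2d(xs, ys, 1.0), xs, ys)
        assert rep in ("m0", "m1")

    def test_tie_breaks_by_model_order(self):
        # two singly-occupied bins, symmetric: the earlier model wins
        xs = series("x", [1.5, 3.5])
        ys = series("y", [1.5, 3.5])
        rep = select_representative(histogram2d(xs, ys, 1.0), xs, ys)
        assert rep == "m0"


class TestPresetObservables:
    def test_two_state_templates_differ_on_designated_pairs(self):
        """The preset's state-B displacement opens the pocket and widens the
        effector surface by several Å; the stable pair stays put."""
        spec = par1_preset()
        da = template_distances(spec, "A")
        db = template_distances(spec, "B")
        assert db["D256^45.52/cg-Y350^7.32/oh"] - da["D256^45.52/cg-Y350^7.32/oh"] > 5
        assert db["R200^3.50/ca-L314^6.36/ca"] - da["R200^3.50/ca-L314^6.36/ca"] > 5
        assert db["Y290^5.58/ca-S375^8.47/ca"] - da["Y290^5.58/ca-S375^8.47/ca"] > 5
        stable = "Y267^5.35/cb-L101^1.31/cb"
        assert da[stable] == pytest.approx(db[stable])
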