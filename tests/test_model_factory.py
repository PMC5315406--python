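import numpy as np
import pytest

from aspasia.model_factory import (
    AUTO,
    FactoryError,
    Intervention,
    apply_interventions,
    generate_models,
    intervention_sweep,
    snapshot_from_trajectory,
    write_ensemble,
)
from aspasia.sampling import lhs_sample
from aspasia.sbml_io import parse_model, write_model
from aspasia.settings import ParameterRange
from aspasia.solver import solve
from conftest import make_decay_model, make_random_linear_model, make_reversible_model


class TestGenerateModels:
    def test_count_matches_rows(self, reversible_model):
        design = lhs_sample([ParameterRange("kf", 0.1, 5.0),
                             ParameterRange("A", 0.0, 2.0)], n=20, seed=0)
        docs, manifest = generate_models(reversible_model, design)
        assert len(docs) == 20
        assert len(manifest) == 20
        for i, doc in enumerate(docs):
            assert doc.get_parameter("kf") == design.rows[i, 0]
            assert doc.get_species("A").initial_concentration == design.rows[i, 1]
            # untouched fields
            assert doc.get_parameter("kr") == 1.0

    def test_empty_design(self, reversible_model):
        design = lhs_sample([ParameterRange("kf", 0.1, 5.0)], n=2, seed=0)
        from dataclasses import replace
        empty = replace(design, rows=design.rows[:0])
        docs, manifest = generate_models(reversible_model, empty)
        assert docs == [] and len(manifest) == 0

    def test_unresolvable_column_atomic(self, reversible_model, tmp_path):
        design = lhs_sample([ParameterRange("zz", 0.0, 1.0)], n=5, seed=0)
        with pytest.raises(FactoryError, match="zz"):
            generate_models(reversible_model, design)
        assert list(tmp_path.iterdir()) == []  # nothing written

    def test_write_ensemble(self, reversible_model, tmp_path):
        design = lhs_sample([ParameterRange("kf", 0.1, 5.0)], n=7, seed=1)
        docs, manifest = generate_models(reversible_model, design)
        paths = write_ensemble(docs, manifest, tmp_path)
        assert len(paths) == 7
        assert (tmp_path / "manifest.csv").exists()
        reread = parse_model(paths[3].read_text())
        assert reread == docs[3]


class TestSnapshot:
    def test_auto_takes_last_row(self, decay_model):
        traj = solve(decay_model, t_end=10.0, step=1.0)
        snap = snapshot_from_trajectory(decay_model, traj, AUTO)
        assert snap.get_species("S").initial_concentration == traj.series["S"][-1]
        assert ("snapshot_time", repr(10.0)) in snap.annotations

    def test_explicit_time(self, reversible_model):
        traj = solve(reversible_model, t_end=4.0, step=0.5)
        snap = snapshot_from_trajectory(reversible_model, traj, at_time=2.0)
        i = int(np.where(traj.times == 2.0)[0][0])
        assert snap.get_species("A").initial_concentration == traj.series["A"][i]

    def test_time_outside_span(self, decay_model):
        traj = solve(decay_model, t_end=1.0, step=0.5)
        with pytest.raises(ValueError, match="span"):
            snapshot_from_trajectory(decay_model, traj, at_time=5.0)

    def test_missing_species_named(self, reversible_model):
        traj = solve(reversible_model, t_end=1.0, step=0.5)
        del traj.series["B"]
        with pytest.raises(FactoryError, match="B"):
            snapshot_from_trajectory(reversible_model, traj)

    def test_continuation_matches_uninterrupted(self, reversible_model):
        t1, t2 = 3.0, 2.0
        full = solve(reversible_model, t_end=t1 + t2, step=0.5)
        first = solve(reversible_model, t_end=t1, step=0.5)
        snap = snapshot_from_trajectory(reversible_model, first)
        cont = solve(snap, t_end=t2, step=0.5)
        offset = int(round(t1 / 0.5))
        for s in ("A", "B"):
            np.testing.assert_allclose(
                cont.series[s], full.series[s][offset:], rtol=1e-6, atol=1e-9
            )


class TestInterventions:
    def test_set_changes_only_target(self, reversible_model):
        traj = solve(reversible_model, 2.0, 0.5)
        snap = snapshot_from_trajectory(reversible_model, traj)
        out = apply_interventions(snap, [Intervention("A", "SET", 100.0)])
        assert out.get_species("A").initial_concentration == 100.0
        assert out.get_species("B") == snap.get_species("B")
        assert out.parameters == snap.parameters

    def test_scale_identity(self, reversible_model):
        traj = solve(reversible_model, 2.0, 0.5)
        snap = snapshot_from_trajectory(reversible_model, traj)
        out = apply_interventions(snap, [Intervention("A", "SCALE", 1.0)],
                                  traj.final_state())
        assert (out.get_species("A").initial_concentration
                == snap.get_species("A").initial_concentration)

    def test_scale_arithmetic(self, decay_model):
        snap = apply_interventions(decay_model, [Intervention("S", "SET", 3.5)])
        out = apply_interventions(snap, [Intervention("S", "SCALE", 2.0)],
                                  {"S": 3.5})
        assert out.get_species("S").initial_concentration == 7.0

    def test_scale_without_final_state(self, decay_model):
        with pytest.raises(FactoryError, match="final-state"):
            apply_interventions(decay_model, [Intervention("S", "SCALE", 2.0)])

    def test_serialised_diff_touches_only_target(self, reversible_model):
        traj = solve(reversible_model, 2.0, 0.5)
        snap = snapshot_from_trajectory(reversible_model, traj)
        out = apply_interventions(snap, [Intervention("kf", "SET", 9.0)])
        strip = lambda xml: [l for l in xml.splitlines() if "asp:" not in l]
        before = strip(write_model(snap))
        after = strip(write_model(out))
        assert len(before) == len(after)
        changed = [(a, b) for a, b in zip(before, after) if a != b]
        assert len(changed) == 1
        assert 'id="kf"' in changed[0][1] and 'value="9.0"' in changed[0][1]

    def test_invalid_mode(self):
        with pytest.raises(FactoryError):
            Intervention("S", "BUMP", 1.0)


class TestInterventionSweep:
    def test_log_spaced_values(self, decay_model):
        values = np.logspace(1, 4, 10)
        docs = intervention_sweep(decay_model, "S", values)
        assert len(docs) == 10
        got = [d.get_species("S").initial_concentration for d in docs]
        np.testing.assert_array_equal(got, values)

    def test_single_value(self, decay_model):
        assert len(intervention_sweep(decay_model, "S", [5.0])) == 1

    def test_empty_values(self, decay_model):
        with pytest.raises(FactoryError):
            intervention_sweep(decay_model, "S", [])
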