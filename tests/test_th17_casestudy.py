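import numpy as np
import pytest

from aspasia.sbml_io import parse_model, write_model
from aspasia.solver import Trajectory, solve
from aspasia.th17_casestudy import (
    CX_STIMULUS,
    DEFAULT_PARAMS,
    DOUBLE_POSITIVE,
    EX_TH17,
    INHIBIT_RORGT,
    PROMOTE_TBET,
    TH1,
    TH17,
    UNPOLARISED,
    CaseStudyError,
    PhenotypeCall,
    build_th17_model,
    classify_phenotype,
    receptor_block_ranges,
    robustness_sweep,
    run_single_switch,
    run_switching_experiment,
)

# The three solve stages per model make these the slowest tests in the
# suite; ensembles are kept small here (acceptance covers n=50).


@pytest.fixture(scope="module")
def promote_model():
    return build_th17_model(variant=PROMOTE_TBET)


@pytest.fixture(scope="module")
def promote_switch():
    return run_single_switch(None, PROMOTE_TBET)


class TestBuild:
    def test_species_and_parameters(self, promote_model):
        assert set(promote_model.species_ids()) == {
            "T", "R", "C1", "C17", "X", "XC", "CX"}
        assert promote_model.get_parameter("a6") == DEFAULT_PARAMS["a6"]

    def test_round_trips_as_sbml(self, promote_model):
        assert parse_model(write_model(promote_model)) == promote_model

    def test_variants_differ_only_in_modulation(self):
        pro = build_th17_model(variant=PROMOTE_TBET)
        inh = build_th17_model(variant=INHIBIT_RORGT)
        pro_ids = {r.id for r in pro.reactions}
        inh_ids = {r.id for r in inh.reactions}
        assert inh_ids - pro_ids == {"rorgt_inhibition"}

    def test_nonpositive_parameter_rejected(self):
        with pytest.raises(CaseStudyError, match="a5"):
            build_th17_model({"a5": 0.0})

    def test_unknown_parameter_rejected(self):
        with pytest.raises(CaseStudyError, match="zz"):
            build_th17_model({"zz": 1.0})

    def test_unknown_variant(self):
        with pytest.raises(CaseStudyError):
            build_th17_model(variant="SIDEWAYS")

    def test_no_cytokine_fixed_point(self, promote_model):
        base = {s.id: s.initial_concentration for s in promote_model.species}
        traj = solve(promote_model, t_end=144.0, step=0.5)
        for sid, x0 in base.items():
            drift = abs(traj.series[sid][-1] - x0) / max(abs(x0), 1e-9)
            assert drift < 1e-6, sid

    def test_receptor_block_ranges_tenfold(self):
        ranges = receptor_block_ranges()
        assert len(ranges) == 8
        for r in ranges:
            assert r.max / r.min == pytest.approx(100.0)
            assert r.baseline == pytest.approx(np.sqrt(r.min * r.max))


class TestClassify:
    def _traj(self, T, R):
        t = np.arange(0.0, 21.0, 1.0)
        return Trajectory(times=t, series={"T": np.full_like(t, T),
                                           "R": np.full_like(t, R)})

    def test_unpolarised(self):
        call = classify_phenotype(self._traj(0.1, 0.1), (0.1, 0.1))
        assert call.label == UNPOLARISED

    def test_th17(self):
        assert classify_phenotype(self._traj(0.1, 1.0), (0.1, 0.1)).label == TH17

    def test_th1_without_history(self):
        assert classify_phenotype(self._traj(1.0, 0.1), (0.1, 0.1)).label == TH1

    def test_ex_th17_with_history(self):
        prior = PhenotypeCall(TH17, 0.1, 1.0, (0.1, 0.1))
        call = classify_phenotype(self._traj(1.0, 0.1), (0.1, 0.1), history=[prior])
        assert call.label == EX_TH17

    def test_double_positive(self):
        assert (classify_phenotype(self._traj(1.0, 1.0), (0.1, 0.1)).label
                == DOUBLE_POSITIVE)

    def test_scale_invariance(self):
        for f in (0.01, 1.0, 250.0):
            call = classify_phenotype(self._traj(1.0 * f, 0.1 * f),
                                      (0.1 * f, 0.1 * f))
            assert call.label == TH1

    def test_nonpositive_baseline(self):
        with pytest.raises(CaseStudyError, match="baseline"):
            classify_phenotype(self._traj(1.0, 1.0), (0.0, 0.1))

    def test_unsettled_trajectory_warns(self):
        t = np.arange(0.0, 21.0, 1.0)
        traj = Trajectory(times=t, series={"T": 0.1 + 0.2 * t, "R": np.full_like(t, 0.1)})
        with pytest.warns(UserWarning, match="steady state"):
            classify_phenotype(traj, (0.1, 0.1))


class TestSwitching:
    def test_default_promote_switches(self, promote_switch):
        assert promote_switch["th17_polarised"]
        assert promote_switch["switched"]
        assert promote_switch["final_label"] == EX_TH17
        assert 0 < promote_switch["time_to_switch"] < 144.0

    def test_default_inhibit_returns_to_th17(self):
        r = run_single_switch(None, INHIBIT_RORGT)
        assert r["th17_polarised"]
        assert not r["switched"]
        assert r["final_label"] == TH17

    def test_th17_stable_under_c1(self, promote_model):
        """Polarised Th17 cell does not switch on a later C1 stimulus."""
        from aspasia.th17_casestudy import _stimulate_and_solve, C1_STIMULUS, C17_STIMULUS
        import warnings as w

        t0 = promote_model.get_species("T").initial_concentration
        r0 = promote_model.get_species("R").initial_concentration
        with w.catch_warnings():
            w.simplefilter("ignore")
            settle = solve(promote_model, 144.0, 0.12)
            th17 = _stimulate_and_solve(promote_model, settle, "C17",
                                        C17_STIMULUS, 144.0, 0.12)
            after_c1 = _stimulate_and_solve(promote_model, th17, "C1",
                                            C1_STIMULUS, 144.0, 0.12)
            call = classify_phenotype(after_c1, (t0, r0))
        assert call.label == TH17

    def test_empty_report(self):
        report = run_switching_experiment(0, PROMOTE_TBET)
        assert report.n_switched == 0 and report.frame.empty

    def test_small_ensembles_show_mechanism_asymmetry(self):
        # n kept small for speed; the n=50 version is an acceptance criterion
        pro = run_switching_experiment(8, PROMOTE_TBET, seed=1, step=0.5)
        inh = run_switching_experiment(8, INHIBIT_RORGT, seed=1, step=0.5)
        assert pro.n_switched > 0
        assert inh.n_switched == 0
        assert pro.n_failed == 0 and inh.n_failed == 0


class TestRobustness:
    def test_single_reference_dose(self):
        ok, trajs = robustness_sweep(cx_values=[CX_STIMULUS], step=0.5)
        assert ok and len(trajs) == 1

    def test_no_stimulus_no_switch(self):
        r = run_single_switch(None, PROMOTE_TBET, cx=1e-12, step=0.5)
        assert not r["switched"]
        assert r["final_label"] == TH17
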