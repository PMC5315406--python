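"""Th17/Th1 phenotype-switching case study.

A seven-species ODE model of the T-bet / RORgamma-t transcription-factor
circuit in a polarising CD4+ T cell, extended with a hypothetical receptor
(X) whose ligand (the cytokine CX) drives phenotype switching. The core is
a mutual-inhibition + autoactivation Hill circuit with saturating
cytokine-driven induction; the receptor block is formation of X driven by
RORgamma-t, mass-action ligand binding, and a saturating complex-driven
modulation term of rate ``a6`` that either promotes T-bet
(``PROMOTE_TBET``) or enhances RORgamma-t turnover (``INHIBIT_RORGT``).

The rate laws built here are the normative reconstruction for this
package; the shipped default parameter set (``DEFAULT_PARAMS``, tuned by
``scripts/tune_defaults.py``) exhibits:

* a stable unpolarised fixed point in the absence of cytokines;
* stable RORgamma-t expression after a decaying C17 pulse, resistant to a
  later C1 pulse (Th17 lock-in);
* under PROMOTE_TBET, a CX pulse at the Th17 steady state can flip the
  cell to a stable T-bet-expressing (ex-Th17) state, robustly across CX
  doses from 10 to 10000;
* under INHIBIT_RORGT, CX causes at most a transient RORgamma-t dip — a
  switch to a T-bet-expressing state is structurally impossible because
  nothing in that variant raises T-bet.

Every simulated stimulus goes through the snapshot + intervention pipeline
(new model files at steady state), never through SBML events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import fsolve

from .expr import parse_infix
from .model_factory import Intervention, apply_interventions, intervention_sweep, snapshot_from_trajectory
from .sbml_io import ModelDocument, ReactionRecord, SpeciesRecord
from .settings import ParameterRange
from .solver import Trajectory, compile_rhs, detect_steady_state, solve

PROMOTE_TBET = "PROMOTE_TBET"
INHIBIT_RORGT = "INHIBIT_RORGT"
VARIANTS = (PROMOTE_TBET, INHIBIT_RORGT)

#: Receptor-block parameter names (the ensemble perturbation targets).
RECEPTOR_BLOCK = ("a5", "a6", "k9", "k10", "mu7", "mu8", "mu9", "b1")

#: Normative default parameter set (arbitrary concentration units, hours).
DEFAULT_PARAMS: dict[str, float] = {
    # basal transcription-factor production
    "b0": 0.01,
    # autoactivation: max rate / Hill half-max for T-bet (a1,k1) and
    # RORgamma-t (a2,k3); cross-inhibition constants k2 (R on T), k4 (T on R)
    "a1": 0.6, "k1": 2.0, "k2": 0.25,
    "a2": 1.2, "k3": 3.0, "k4": 0.25,
    # cytokine-driven induction: C1 -> T (a3,k5), C17 -> R (a4,k6),
    # each suppressed by the opposing factor (k7, k8)
    "a3": 0.5, "k5": 1.0, "k7": 0.1,
    "a4": 0.5, "k6": 1.0, "k8": 0.1,
    # first-order decay: T, R, C1, C17
    "mu1": 0.1, "mu2": 0.1, "mu3": 0.05, "mu4": 0.05,
    # receptor block: X upregulation by R (a5, half-max k9), modulation
    # rate a6 (half-max k10 in XC), decays of X / XC / CX, binding rate b1
    "a5": 0.1, "a6": 0.035, "k9": 1.0, "k10": 0.5,
    "mu7": 0.1, "mu8": 0.01, "mu9": 0.01, "b1": 0.1,
}

#: Stimulus magnitudes (SET interventions on initial concentrations).
C17_STIMULUS = 10.0
C1_STIMULUS = 10.0
CX_STIMULUS = 100.0

#: Paper-scale solve horizon and output step.
T_END = 144.0
STEP = 0.12

SPECIES_ORDER = ("T", "R", "C1", "C17", "X", "XC", "CX")


class CaseStudyError(ValueError):
    pass


# ---------------------------------------------------------------------------
# model construction


def _core_rate_laws(variant: str) -> list[tuple[str, tuple, tuple, str]]:
    """(reaction id, reactants, products, infix rate law) for the system."""
    promote = " + a6 * XC / (k10 + XC)" if variant == PROMOTE_TBET else ""
    laws = [
        ("tbet_production", (), (("T", 1.0),),
         "b0 + a1 * T**2 / (k1**2 + T**2) / (1 + R / k2)"
         " + a3 * C1 / (k5 + C1) / (1 + R / k7)" + promote),
        ("tbet_decay", (("T", 1.0),), (), "mu1 * T"),
        ("rorgt_production", (), (("R", 1.0),),
         "b0 + a2 * R**2 / (k3**2 + R**2) / (1 + T / k4)"
         " + a4 * C17 / (k6 + C17) / (1 + T / k8)"),
        ("rorgt_decay", (("R", 1.0),), (), "mu2 * R"),
        ("c1_decay", (("C1", 1.0),), (), "mu3 * C1"),
        ("c17_decay", (("C17", 1.0),), (), "mu4 * C17"),
        ("receptor_formation", (), (("X", 1.0),), "a5 * R / (k9 + R)"),
        ("receptor_decay", (("X", 1.0),), (), "mu7 * X"),
        ("ligand_binding", (("X", 1.0), ("CX", 1.0)), (("XC", 1.0),),
         "b1 * X * CX"),
        ("complex_decay", (("XC", 1.0),), (), "mu8 * XC"),
        ("ligand_decay", (("CX", 1.0),), (), "mu9 * CX"),
    ]
    if variant == INHIBIT_RORGT:
        laws.append(
            ("rorgt_inhibition", (("R", 1.0),), (),
             "a6 * (XC / (k10 + XC)) * R")
        )
    return laws


def build_th17_model(
    params: Optional[dict[str, float]] = None,
    variant: str = PROMOTE_TBET,
) -> ModelDocument:
    """Build the case-study model as an SBML ModelDocument, with initial
    concentrations placed at the cytokine-free fixed point."""
    if variant not in VARIANTS:
        raise CaseStudyError(f"variant must be one of {VARIANTS}, got {variant!r}")
    p = dict(DEFAULT_PARAMS)
    if params:
        unknown = set(params) - set(DEFAULT_PARAMS)
        if unknown:
            raise CaseStudyError(f"unknown parameter(s): {sorted(unknown)}")
        p.update(params)
    bad = [k for k, v in p.items() if not (v > 0)]
    if bad:
        raise CaseStudyError(f"parameters must be > 0: {sorted(bad)}")

    reactions = tuple(
        ReactionRecord(rid, reactants, products, parse_infix(law))
        for rid, reactants, products, law in _core_rate_laws(variant)
    )
    # provisional initials; replaced by the computed fixed point below
    doc = ModelDocument(
        model_id=f"th17_{'promote' if variant == PROMOTE_TBET else 'inhibit'}",
        level_version="L3V2",
        compartments=(("cell", 1.0),),
        species=tuple(
            SpeciesRecord(sid, "cell", 0.0) for sid in SPECIES_ORDER
        ),
        parameters=tuple((k, v, True) for k, v in sorted(p.items())),
        reactions=reactions,
        annotations=(("variant", variant),),
    )
    t0, r0, x0 = _cytokine_free_fixed_point(doc, p)
    species = tuple(
        SpeciesRecord(sid, "cell", {"T": t0, "R": r0, "X": x0}.get(sid, 0.0))
        for sid in SPECIES_ORDER
    )
    from dataclasses import replace
    return replace(doc, species=species)


def _cytokine_free_fixed_point(
    doc: ModelDocument, p: dict[str, float]
) -> tuple[float, float, float]:
    """Solve for the unpolarised steady state (C1=C17=CX=XC=0)."""
    rhs, order = compile_rhs(doc)
    idx = {sid: i for i, sid in enumerate(order)}

    def residual(v):
        y = [0.0] * len(order)
        y[idx["T"]], y[idx["R"]], y[idx["X"]] = v
        d = rhs(0.0, y)
        return [d[idx["T"]], d[idx["R"]], d[idx["X"]]]

    guess = [p["b0"] / p["mu1"], p["b0"] / p["mu2"],
             p["a5"] * (p["b0"] / p["mu2"]) / (p["k9"] * p["mu7"])]
    sol, info, ok, msg = fsolve(residual, guess, full_output=True, xtol=1e-13)
    if ok != 1 or np.any(sol < 0):
        raise CaseStudyError(f"could not locate the cytokine-free fixed point: {msg}")
    return float(sol[0]), float(sol[1]), float(sol[2])


def receptor_block_ranges(
    params: Optional[dict[str, float]] = None, fold: float = 10.0
) -> list[ParameterRange]:
    """Receptor-block perturbation ranges, *fold* above and below defaults."""
    p = dict(DEFAULT_PARAMS)
    if params:
        p.update(params)
    return [
        ParameterRange(target_id=name, min=p[name] / fold, max=p[name] * fold,
                       baseline=p[name])
        for name in RECEPTOR_BLOCK
    ]


# ---------------------------------------------------------------------------
# phenotype classification

UNPOLARISED = "UNPOLARISED"
TH1 = "TH1"
TH17 = "TH17"
DOUBLE_POSITIVE = "DOUBLE_POSITIVE"
EX_TH17 = "EX_TH17"


@dataclass(frozen=True)
class PhenotypeCall:
    label: str
    T_level: float
    R_level: float
    baselines: tuple[float, float]


def classify_phenotype(
    traj: Trajectory,
    baselines: tuple[float, float],
    fold_threshold: float = 2.0,
    history: Sequence[PhenotypeCall] = (),
    steady_window: float = 10.0,
    steady_rel_tol: float = 1e-3,
) -> PhenotypeCall:
    """Classify the cell state at the end of *traj*.

    A transcription factor counts as expressed when it exceeds
    ``fold_threshold`` times its baseline. T-bet-only expression reads as
    TH1, or as EX_TH17 when the history contains a TH17 call. If the
    trajectory has not settled (windowed sup-norm criterion) a warning is
    emitted and the final time point is used regardless.
    """
    t0, r0 = baselines
    if t0 <= 0 or r0 <= 0:
        raise CaseStudyError("baselines must be positive")
    if detect_steady_state(traj, steady_window, steady_rel_tol) is None:
        warnings.warn(
            "trajectory has not reached steady state; classifying at t_end",
            stacklevel=2,
        )
    state = traj.final_state()
    t_level, r_level = state["T"], state["R"]
    above_t = t_level > fold_threshold * t0
    above_r = r_level > fold_threshold * r0
    if above_t and above_r:
        label = DOUBLE_POSITIVE
    elif above_r:
        label = TH17
    elif above_t:
        label = EX_TH17 if any(c.label == TH17 for c in history) else TH1
    else:
        label = UNPOLARISED
    return PhenotypeCall(label, t_level, r_level, (t0, r0))


# ---------------------------------------------------------------------------
# the switching experiment


@dataclass
class SwitchReport:
    variant: str
    n_requested: int
    frame: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_switched(self) -> int:
        if self.frame.empty:
            return 0
        return int(self.frame["switched"].fillna(False).sum())

    @property
    def n_failed(self) -> int:
        if self.frame.empty:
            return 0
        return int((self.frame["error"] != "").sum())

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def _stimulate_and_solve(
    base: ModelDocument,
    traj: Trajectory,
    target: str,
    magnitude: float,
    t_end: float,
    step: float,
) -> Trajectory:
    """Technique 4 + 5: snapshot the trajectory end state, SET a stimulus,
    re-solve."""
    snap = snapshot_from_trajectory(base, traj)
    stim = apply_interventions(snap, [Intervention(target, "SET", magnitude)])
    return solve(stim, t_end, step)


def run_single_switch(
    params: Optional[dict[str, float]],
    variant: str,
    cx: float = CX_STIMULUS,
    t_end: float = T_END,
    step: float = STEP,
    fold_threshold: float = 2.0,
) -> dict:
    """Polarise one parameter set to Th17, stimulate with CX, classify.

    Returns a record with the phenotype call sequence, whether the model
    switched (ended EX_TH17), and the time from CX addition to the first
    stable switch call.
    """
    model = build_th17_model(params, variant)
    t0 = model.get_species("T").initial_concentration
    r0 = model.get_species("R").initial_concentration
    baselines = (t0, r0)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        settle = solve(model, t_end, step)
        th17_traj = _stimulate_and_solve(model, settle, "C17", C17_STIMULUS,
                                         t_end, step)
        th17_call = classify_phenotype(th17_traj, baselines, fold_threshold)
        post_cx = _stimulate_and_solve(model, th17_traj, "CX", cx, t_end, step)
        final_call = classify_phenotype(
            post_cx, baselines, fold_threshold, history=[th17_call]
        )
    switched = final_call.label == EX_TH17
    return {
        "th17_polarised": th17_call.label == TH17,
        "final_label": final_call.label,
        "switched": switched,
        "time_to_switch": _time_to_switch(post_cx, baselines, fold_threshold)
        if switched else np.nan,
        "T_final": final_call.T_level,
        "R_final": final_call.R_level,
        "baseline_T": t0,
        "baseline_R": r0,
        "post_cx_trajectory": post_cx,
    }


def _time_to_switch(
    traj: Trajectory, baselines: tuple[float, float], fold_threshold: float
) -> float:
    """Earliest time (from CX addition) after which the ex-Th17 condition —
    T above threshold, R below — holds for the rest of the trajectory."""
    t0, r0 = baselines
    above_t = traj.series["T"] > fold_threshold * t0
    below_r = traj.series["R"] <= fold_threshold * r0
    ok = above_t & below_r
    # last index where the condition fails; switch time is the next grid point
    bad = np.where(~ok)[0]
    if len(bad) == 0:
        return float(traj.times[0])
    if bad[-1] == len(ok) - 1:
        return float("nan")
    return float(traj.times[bad[-1] + 1])


def run_switching_experiment(
    n_sets: int,
    variant: str,
    ranges: Optional[Sequence[ParameterRange]] = None,
    seed: Optional[int] = None,
    cx: float = CX_STIMULUS,
    t_end: float = T_END,
    step: float = STEP,
    fold_threshold: float = 2.0,
) -> SwitchReport:
    """Latin-hypercube the receptor block (10-fold up/down by default),
    run the full polarise -> stimulate pipeline per set, count switches.

    Per-model failures are recorded in the report, not raised.
    """
    from .sampling import lhs_sample

    if variant not in VARIANTS:
        raise CaseStudyError(f"variant must be one of {VARIANTS}")
    if n_sets == 0:
        return SwitchReport(variant, 0)
    if ranges is None:
        ranges = receptor_block_ranges()
    design = lhs_sample(ranges, n_sets, seed=seed)
    records = []
    for i in range(design.n_rows):
        overrides = {c: float(design.rows[i, j]) for j, c in enumerate(design.columns)}
        rec = {"model_index": i, **overrides}
        try:
            result = run_single_switch(
                overrides, variant, cx=cx, t_end=t_end, step=step,
                fold_threshold=fold_threshold,
            )
            result.pop("post_cx_trajectory")
            rec.update(result)
            rec["error"] = ""
        except Exception as exc:  # per-model failure is data, not fatal
            rec.update({"switched": False, "final_label": "ERROR",
                        "error": f"{type(exc).__name__}: {exc}"})
        records.append(rec)
    return SwitchReport(variant, n_sets, pd.DataFrame(records))


def robustness_sweep(
    params: Optional[dict[str, float]] = None,
    variant: str = PROMOTE_TBET,
    cx_values: Optional[Sequence[float]] = None,
    t_end: float = T_END,
    step: float = STEP,
    fold_threshold: float = 2.0,
) -> tuple[bool, list[Trajectory]]:
    """Re-run the CX intervention at each dose (default 10 log-spaced values
    in [10, 10000]) for one parameter set; returns (all switched?, post-CX
    trajectories). The sweep goes through :func:`intervention_sweep`, i.e.
    one intervention model file per dose."""
    if cx_values is None:
        cx_values = np.logspace(1.0, 4.0, 10)
    model = build_th17_model(params, variant)
    t0 = model.get_species("T").initial_concentration
    r0 = model.get_species("R").initial_concentration
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        settle = solve(model, t_end, step)
        th17_traj = _stimulate_and_solve(model, settle, "C17", C17_STIMULUS,
                                         t_end, step)
        th17_call = classify_phenotype(th17_traj, (t0, r0), fold_threshold)
        snap = snapshot_from_trajectory(model, th17_traj)
        docs = intervention_sweep(snap, "CX", list(cx_values))
        trajectories = []
        all_switched = True
        for doc in docs:
            traj = solve(doc, t_end, step)
            call = classify_phenotype(traj, (t0, r0), fold_threshold,
                                      history=[th17_call])
            all_switched &= call.label == EX_TH17
            trajectories.append(traj)
    return all_switched, trajectories
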