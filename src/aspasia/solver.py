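"""Deterministic ODE integration of a ModelDocument.

The reaction network is compiled to a single Python right-hand side
function and integrated with an adaptive, stiffness-capable method
(LSODA, rtol 1e-8 / atol 1e-10). The *output* grid is fixed —
``{0, step, 2*step, ..., t_end}`` — mirroring fixed-step solver output
while retaining adaptive error control internally.

Species dynamics: for each non-boundary species ``s``,
``dc_s/dt = (1/vol(s)) * sum_r nu_{s,r} * v_r`` where ``v_r`` is the
reaction's kinetic law evaluated on current concentrations, parameters,
and compartment sizes. Boundary species are held constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .sbml_io import ModelDocument


class IntegrationError(RuntimeError):
    pass


@dataclass
class Trajectory:
    """A solved time course: shared time grid plus one series per species."""

    times: np.ndarray
    series: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.times)
        if any(len(v) != n for v in self.series.values()):
            raise ValueError("all series must match the time grid length")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        for name, v in self.series.items():
            if not np.all(np.isfinite(v)):
                raise ValueError(f"series {name!r} contains non-finite values")

    @property
    def species(self) -> list[str]:
        return list(self.series)

    def at_time(self, t: float) -> dict[str, float]:
        """State at the grid point nearest to *t* (t must be within span)."""
        if t < self.times[0] or t > self.times[-1]:
            raise ValueError(
                f"time {t} outside trajectory span [{self.times[0]}, {self.times[-1]}]"
            )
        i = int(np.argmin(np.abs(self.times - t)))
        return {k: float(v[i]) for k, v in self.series.items()}

    def final_state(self) -> dict[str, float]:
        return {k: float(v[-1]) for k, v in self.series.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, **self.series})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Trajectory":
        df = pd.read_csv(path)
        if df.columns[0] != "time":
            raise ValueError("trajectory CSV must start with a 'time' column")
        return cls(
            times=df["time"].to_numpy(float),
            series={c: df[c].to_numpy(float) for c in df.columns[1:]},
        )


# ---------------------------------------------------------------------------


def compile_rhs(doc: ModelDocument):
    """Compile *doc*'s reactions into ``f(t, y) -> dy/dt`` plus the species
    order used for the state vector (non-boundary species only)."""
    doc.validate()
    dynamic = [s for s in doc.species if not s.boundary]
    order = [s.id for s in dynamic]
    index = {sid: i for i, sid in enumerate(order)}

    consts: dict[str, float] = {}
    for pid, value, _ in doc.parameters:
        consts[pid] = value
    for cid, size in doc.compartments:
        consts[cid] = size
    for s in doc.species:
        if s.boundary:
            consts[s.id] = s.initial_concentration

    vol = {s.id: doc.compartment_size(s.compartment) for s in doc.species}

    lines = ["def _rhs(t, y):"]
    for sid, i in index.items():
        lines.append(f"    {sid} = y[{i}]")
    rate_names = []
    for r_i, rxn in enumerate(doc.reactions):
        name = f"_v{r_i}"
        rate_names.append(name)
        lines.append(f"    {name} = {rxn.kinetic_law.to_infix()}")
    terms: dict[int, list[str]] = {i: [] for i in index.values()}
    for r_i, rxn in enumerate(doc.reactions):
        for sid, stoich in rxn.reactants:
            if sid in index:
                terms[index[sid]].append(f"- {stoich / vol[sid]!r} * _v{r_i}")
        for sid, stoich in rxn.products:
            if sid in index:
                terms[index[sid]].append(f"+ {stoich / vol[sid]!r} * _v{r_i}")
    body = ", ".join(" ".join(terms[i]) if terms[i] else "0.0" for i in range(len(order)))
    lines.append(f"    return [{body}]")
    namespace = dict(consts)
    exec("\n".join(lines), namespace)  # noqa: S102 - generated from validated ids
    return namespace["_rhs"], order


def solve(
    doc: ModelDocument,
    t_end: float,
    step: float,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate *doc* from its initial concentrations to *t_end*, reporting
    on the fixed grid with spacing *step* (grid length floor(t_end/step)+1)."""
    if t_end <= 0 or step <= 0:
        raise ValueError("t_end and step must be > 0")
    rhs, order = compile_rhs(doc)
    y0 = [doc.get_species(sid).initial_concentration for sid in order]
    n_pts = int(math.floor(t_end / step + 1e-9)) + 1
    t_eval = np.arange(n_pts) * step

    _DIVERGE = 1e12

    def guarded(t, y):  # abort early on blow-up instead of grinding
        if not np.all(np.isfinite(y)) or np.max(np.abs(y)) > _DIVERGE:
            raise IntegrationError(f"non-finite or diverging state at t={t}")
        return rhs(t, y)

    sol = solve_ivp(
        guarded, (0.0, float(t_eval[-1])), y0, method="LSODA",
        t_eval=t_eval, rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"integration failed: {sol.message}")
    if not np.all(np.isfinite(sol.y)):
        bad = np.argwhere(~np.isfinite(sol.y))
        t_bad = t_eval[bad[0][1]]
        raise IntegrationError(f"non-finite state at t={t_bad}")
    series = {sid: sol.y[i] for i, sid in enumerate(order)}
    # boundary species are constant but still reported
    for s in doc.species:
        if s.boundary:
            series[s.id] = np.full(n_pts, s.initial_concentration)
    return Trajectory(
        times=t_eval,
        series=series,
        meta={"step": step, "method": "LSODA", "model_id": doc.model_id},
    )


def detect_steady_state(
    traj: Trajectory,
    window: float,
    rel_tol: float,
    floor: float = 1e-9,
) -> Optional[float]:
    """Earliest grid time ``t*`` such that within ``[t*, t*+window]`` every
    species stays within ``rel_tol * max(|x(t*)|, floor)`` of ``x(t*)``.
    Returns None if no such time exists."""
    times = traj.times
    span = times[-1] - times[0]
    if window >= span:
        raise ValueError("window must be smaller than the trajectory span")
    n = len(times)
    w_pts = int(np.searchsorted(times, times[0] + window, side="left"))
    w_pts = max(w_pts, 1)
    mat = np.column_stack([traj.series[s] for s in traj.species])
    for i in range(n - w_pts):
        ref = mat[i]
        seg = mat[i : i + w_pts + 1]
        tol = rel_tol * np.maximum(np.abs(ref), floor)
        if np.all(np.abs(seg - ref) <= tol):
            return float(times[i])
    return None
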