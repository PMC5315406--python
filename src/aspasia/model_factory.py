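"""Turn designs and solver output into SBML files.

Three production paths:

* :func:`generate_models` — one perturbed model per design row
  (local / LHS / eFAST ensembles);
* :func:`snapshot_from_trajectory` — re-initialise a model from a solved
  time course at a chosen (or automatically detected final) time point;
* :func:`apply_interventions` / :func:`intervention_sweep` — discrete SET or
  final-state SCALE changes applied to a snapshot.

Interventions are deliberately *not* encoded as SBML events: every change
is materialised as a fresh, self-contained model file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .sampling import SampleSet
from .sbml_io import ModelDocument, set_value, with_annotation, write_model
from .solver import Trajectory

AUTO = "AUTO"


class FactoryError(ValueError):
    pass


@dataclass(frozen=True)
class Intervention:
    """A discrete change applied to a snapshotted model.

    SET assigns ``magnitude`` verbatim; SCALE multiplies the target's
    final-state value by ``magnitude``.
    """

    target_id: str
    mode: str  # SET | SCALE
    magnitude: float
    target_kind: str = "species_initial"

    def __post_init__(self) -> None:
        if self.mode not in ("SET", "SCALE"):
            raise FactoryError(f"mode must be SET or SCALE, got {self.mode!r}")
        if not math.isfinite(self.magnitude):
            raise FactoryError("magnitude must be finite")
        if self.mode == "SCALE" and self.magnitude <= 0:
            raise FactoryError("SCALE magnitude must be > 0")


def generate_models(
    base: ModelDocument, design: SampleSet
) -> tuple[list[ModelDocument], pd.DataFrame]:
    """One model per design row; each differs from *base* only in the
    designed targets. Fails atomically if any column does not resolve."""
    known = set(base.parameter_ids()) | set(base.species_ids())
    missing = [c for c in design.columns if c not in known]
    if missing:
        raise FactoryError(
            f"design column(s) {missing} do not resolve in model "
            f"{base.model_id!r}; no models generated"
        )
    docs = []
    records = []
    stem = base.model_id
    for i in range(design.n_rows):
        doc = base
        for j, col in enumerate(design.columns):
            doc = set_value(doc, col, float(design.rows[i, j]))
        filename = f"{stem}_{design.technique.lower()}_{i}.xml"
        docs.append(doc)
        records.append({"filename": filename,
                        **{c: design.rows[i, j] for j, c in enumerate(design.columns)}})
    manifest = pd.DataFrame(records, columns=["filename", *design.columns])
    return docs, manifest


def write_ensemble(
    docs: Sequence[ModelDocument],
    manifest: pd.DataFrame,
    out_dir: Union[str, Path],
) -> list[Path]:
    """Write every model (named per the manifest) plus ``manifest.csv``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for doc, filename in zip(docs, manifest["filename"]):
        p = out / filename
        p.write_text(write_model(doc), encoding="utf-8")
        paths.append(p)
    manifest.to_csv(out / "manifest.csv", index=False)
    return paths


def snapshot_from_trajectory(
    base: ModelDocument,
    traj: Trajectory,
    at_time: Union[float, str] = AUTO,
) -> ModelDocument:
    """Copy *base* with species initial concentrations (and any parameters
    present as trajectory columns) set to the trajectory values at
    *at_time*; AUTO selects the final time row. The selected time is
    recorded in the model annotations."""
    non_boundary = [s.id for s in base.species if not s.boundary]
    missing = [sid for sid in non_boundary if sid not in traj.series]
    if missing:
        raise FactoryError(
            f"trajectory lacks column(s) for species: {', '.join(missing)}"
        )
    if at_time == AUTO:
        t_sel = float(traj.times[-1])
        state = traj.final_state()
    else:
        t_sel = float(at_time)
        state = traj.at_time(t_sel)

    doc = base
    for sid in non_boundary:
        doc = set_value(doc, sid, state[sid])
    for pid in base.parameter_ids():
        if pid in state:
            doc = set_value(doc, pid, state[pid])
    return with_annotation(doc, "snapshot_time", repr(t_sel))


def apply_interventions(
    snapshot: ModelDocument,
    interventions: Sequence[Intervention],
    final_state: Optional[Mapping[str, float]] = None,
) -> ModelDocument:
    """Apply SET/SCALE interventions to a snapshot; SCALE needs the
    final-state row the snapshot was taken from."""
    doc = snapshot
    for iv in interventions:
        if iv.mode == "SET":
            value = iv.magnitude
        else:
            if final_state is None or iv.target_id not in final_state:
                raise FactoryError(
                    f"SCALE intervention on {iv.target_id!r} requires a "
                    "final-state value for that target"
                )
            value = final_state[iv.target_id] * iv.magnitude
        doc = set_value(doc, iv.target_id, value)
        doc = with_annotation(
            doc, "intervention", f"{iv.mode} {iv.target_id} {value!r}"
        )
    return doc


def intervention_sweep(
    snapshot: ModelDocument, target: str, values: Sequence[float]
) -> list[ModelDocument]:
    """One SET-intervention model per value (e.g. 10 log-spaced stimulus
    concentrations)."""
    if len(values) == 0:
        raise FactoryError("intervention sweep needs at least one value")
    return [
        apply_interventions(snapshot, [Intervention(target, "SET", float(v))])
        for v in values
    ]
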