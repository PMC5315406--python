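"""Run configuration: the XML settings file and its in-memory form.

The tag vocabulary is defined by this package (see ``docs/settings.xsd``);
an annotated example lives in the README. A settings document names the
technique, the model file, the output directory, the parameter/species
ranges to perturb, and — for intervention runs — the targets to change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence
from xml.etree import ElementTree as ET

TECHNIQUES = ("LOCAL", "LHS", "EFAST", "SNAPSHOT", "INTERVENTION")

DEFAULT_EFAST_CURVES = 3
DEFAULT_EFAST_SAMPLES = 65
DEFAULT_LOCAL_INCREMENTS = 10


class SettingsError(ValueError):
    pass


@dataclass(frozen=True)
class ParameterRange:
    """A perturbation range for one parameter or species initial value."""

    target_id: str
    min: float
    max: float
    target_kind: str = "parameter"  # parameter | species_initial
    baseline: Optional[float] = None

    def __post_init__(self) -> None:
        if self.target_kind not in ("parameter", "species_initial"):
            raise SettingsError(
                f"{self.target_id!r}: unknown target kind {self.target_kind!r}"
            )
        if not (self.min < self.max):
            raise SettingsError(
                f"range for {self.target_id!r}: min ({self.min}) must be < max "
                f"({self.max})"
            )
        if self.baseline is not None and not (self.min <= self.baseline <= self.max):
            raise SettingsError(
                f"range for {self.target_id!r}: baseline {self.baseline} outside "
                f"[{self.min}, {self.max}]"
            )


@dataclass(frozen=True)
class InterventionSpec:
    target_id: str
    mode: str                       # SET | SCALE
    magnitude: float
    target_kind: str = "species_initial"

    def __post_init__(self) -> None:
        if self.mode not in ("SET", "SCALE"):
            raise SettingsError(f"intervention mode must be SET or SCALE, got {self.mode!r}")
        if not math.isfinite(self.magnitude):
            raise SettingsError("intervention magnitude must be finite")
        if self.mode == "SCALE" and self.magnitude <= 0:
            raise SettingsError("SCALE magnitude must be > 0")


@dataclass(frozen=True)
class Settings:
    technique: str
    model_path: Path
    output_dir: Path
    ranges: tuple[ParameterRange, ...] = ()
    lhs_samples: int = 2
    efast_curves: int = DEFAULT_EFAST_CURVES
    efast_samples_per_curve: int = DEFAULT_EFAST_SAMPLES
    local_increments: int = DEFAULT_LOCAL_INCREMENTS
    interventions: tuple[InterventionSpec, ...] = ()
    t_end: float = 100.0
    step: float = 0.1
    seed: Optional[int] = None
    applied_defaults: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "model_path", Path(self.model_path))
        object.__setattr__(self, "output_dir", Path(self.output_dir))
        if self.technique not in TECHNIQUES:
            raise SettingsError(
                f"unknown technique {self.technique!r}; one of {TECHNIQUES}"
            )
        if self.technique == "LHS" and self.lhs_samples < 2:
            raise SettingsError("lhs_samples must be >= 2 for technique LHS")
        if self.technique == "EFAST":
            if self.efast_samples_per_curve % 2 == 0 or self.efast_samples_per_curve < 65:
                raise SettingsError(
                    "efast_samples_per_curve must be odd and >= 65"
                )
            if self.efast_curves < 1:
                raise SettingsError("efast_curves must be >= 1")
        if self.local_increments < 1:
            raise SettingsError("local_increments must be >= 1")
        if self.t_end <= 0 or self.step <= 0:
            raise SettingsError("solver tEnd and step must be > 0")


# ---------------------------------------------------------------------------


def _req(parent: ET.Element, tag: str) -> ET.Element:
    el = parent.find(tag)
    if el is None:
        raise SettingsError(f"{tag} required")
    return el


def parse_settings(xml_text: str) -> Settings:
    """Parse a settings XML document into a :class:`Settings` object.

    Missing optional tags take the documented defaults; each applied
    default is recorded in ``Settings.applied_defaults``.
    """
    try:
        root = ET.fromstring(xml_text)
    except ET.ParseError as exc:
        raise SettingsError(f"malformed settings XML: {exc}") from None
    if root.tag != "aspasia":
        raise SettingsError(f"root element must be <aspasia>, got <{root.tag}>")

    technique = (_req(root, "technique").text or "").strip().upper()
    model_path = Path((_req(root, "modelPath").text or "").strip())
    output_dir = Path((_req(root, "outputDir").text or "").strip())

    applied = []

    def opt_attr(el: Optional[ET.Element], name: str, default, cast):
        if el is None or el.get(name) is None:
            applied.append(f"{name}={default}")
            return default
        return cast(el.get(name))

    solver = root.find("solver")
    t_end = opt_attr(solver, "tEnd", 100.0, float)
    step = opt_attr(solver, "step", 0.1, float)
    lhs_samples = opt_attr(root.find("lhs"), "samples", 2, int)
    efast_el = root.find("efast")
    efast_curves = opt_attr(efast_el, "curves", DEFAULT_EFAST_CURVES, int)
    efast_samples = opt_attr(efast_el, "samplesPerCurve", DEFAULT_EFAST_SAMPLES, int)
    local_increments = opt_attr(root.find("local"), "increments",
                                DEFAULT_LOCAL_INCREMENTS, int)
    seed_el = root.find("seed")
    seed = int(seed_el.text.strip()) if seed_el is not None and seed_el.text else None

    ranges = []
    for p in root.iterfind("parameters/parameter"):
        if p.get("id") is None:
            raise SettingsError("<parameter> requires an id attribute")
        if p.get("min") is None or p.get("max") is None:
            raise SettingsError(f"<parameter id={p.get('id')!r}> requires min and max")
        baseline = p.get("baseline")
        ranges.append(
            ParameterRange(
                target_id=p.get("id"),
                target_kind=p.get("kind", "parameter"),
                min=float(p.get("min")),
                max=float(p.get("max")),
                baseline=float(baseline) if baseline is not None else None,
            )
        )

    interventions = []
    for iv in root.iterfind("interventions/intervention"):
        if iv.get("target") is None or iv.get("magnitude") is None:
            raise SettingsError("<intervention> requires target and magnitude")
        interventions.append(
            InterventionSpec(
                target_id=iv.get("target"),
                target_kind=iv.get("kind", "species_initial"),
                mode=iv.get("mode", "SET").upper(),
                magnitude=float(iv.get("magnitude")),
            )
        )

    return Settings(
        technique=technique,
        model_path=model_path,
        output_dir=output_dir,
        ranges=tuple(ranges),
        lhs_samples=lhs_samples,
        efast_curves=efast_curves,
        efast_samples_per_curve=efast_samples,
        local_increments=local_increments,
        interventions=tuple(interventions),
        t_end=t_end,
        step=step,
        seed=seed,
        applied_defaults=tuple(applied),
    )


def serialise_settings(settings: Settings) -> str:
    """Inverse of :func:`parse_settings` (round-trip safe)."""
    root = ET.Element("aspasia")
    ET.SubElement(root, "technique").text = settings.technique
    ET.SubElement(root, "modelPath").text = str(settings.model_path)
    ET.SubElement(root, "outputDir").text = str(settings.output_dir)
    ET.SubElement(root, "solver", {"tEnd": repr(settings.t_end),
                                   "step": repr(settings.step)})
    ET.SubElement(root, "lhs", {"samples": str(settings.lhs_samples)})
    ET.SubElement(root, "efast", {
        "curves": str(settings.efast_curves),
        "samplesPerCurve": str(settings.efast_samples_per_curve),
    })
    ET.SubElement(root, "local", {"increments": str(settings.local_increments)})
    if settings.seed is not None:
        ET.SubElement(root, "seed").text = str(settings.seed)
    if settings.ranges:
        params = ET.SubElement(root, "parameters")
        for r in settings.ranges:
            attrs = {"id": r.target_id, "kind": r.target_kind,
                     "min": repr(r.min), "max": repr(r.max)}
            if r.baseline is not None:
                attrs["baseline"] = repr(r.baseline)
            ET.SubElement(params, "parameter", attrs)
    if settings.interventions:
        ivs = ET.SubElement(root, "interventions")
        for iv in settings.interventions:
            ET.SubElement(ivs, "intervention", {
                "target": iv.target_id, "kind": iv.target_kind,
                "mode": iv.mode, "magnitude": repr(iv.magnitude),
            })
    ET.indent(root)
    return '<?xml version="1.0" encoding="UTF-8"?>\n' + ET.tostring(root, encoding="unicode")


def load_settings(path: str | Path) -> Settings:
    return parse_settings(Path(path).read_text(encoding="utf-8"))
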