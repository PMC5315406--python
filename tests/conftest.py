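"""Shared fixtures: programmatically generated toy models."""

from __future__ import annotations

import numpy as np
import pytest

from aspasia.expr import parse_infix
from aspasia.sbml_io import ModelDocument, ReactionRecord, SpeciesRecord


def make_decay_model(k: float = 1.0, x0: float = 1.0) -> ModelDocument:
    """Single species, dX/dt = -k1*X."""
    return ModelDocument(
        model_id="decay",
        compartments=(("c", 1.0),),
        species=(SpeciesRecord("S", "c", x0),),
        parameters=(("k1", k, True),),
        reactions=(
            ReactionRecord("deg", (("S", 1.0),), (), parse_infix("k1 * S")),
        ),
    )


def make_reversible_model(kf: float = 2.0, kr: float = 1.0,
                          a0: float = 1.0, b0: float = 0.0) -> ModelDocument:
    """A <-> B mass action; A + B is conserved."""
    return ModelDocument(
        model_id="reversible",
        compartments=(("c", 1.0),),
        species=(SpeciesRecord("A", "c", a0), SpeciesRecord("B", "c", b0)),
        parameters=(("kf", kf, True), ("kr", kr, True)),
        reactions=(
            ReactionRecord("fwd", (("A", 1.0),), (("B", 1.0),), parse_infix("kf * A")),
            ReactionRecord("rev", (("B", 1.0),), (("A", 1.0),), parse_infix("kr * B")),
        ),
    )


def make_random_linear_model(rng: np.random.Generator,
                             n_species: int | None = None) -> ModelDocument:
    """Random stable linear network: constant production, first-order decay,
    and random first-order conversions. Trajectories stay finite and
    non-negative."""
    n = n_species or int(rng.integers(2, 5))
    species = tuple(
        SpeciesRecord(f"S{i}", "c", float(rng.uniform(0.5, 5.0))) for i in range(n)
    )
    params = []
    reactions = []
    for i in range(n):
        prod = float(rng.uniform(0.1, 1.0))
        dec = float(rng.uniform(0.2, 1.5))
        params += [(f"p{i}", prod, True), (f"d{i}", dec, True)]
        reactions.append(ReactionRecord(f"prod{i}", (), ((f"S{i}", 1.0),),
                                        parse_infix(f"p{i}")))
        reactions.append(ReactionRecord(f"dec{i}", ((f"S{i}", 1.0),), (),
                                        parse_infix(f"d{i} * S{i}")))
    n_conv = int(rng.integers(1, n + 1))
    for c in range(n_conv):
        i, j = rng.choice(n, size=2, replace=False)
        rate = float(rng.uniform(0.1, 0.8))
        params.append((f"c{c}", rate, True))
        reactions.append(
            ReactionRecord(f"conv{c}", ((f"S{i}", 1.0),), ((f"S{j}", 1.0),),
                           parse_infix(f"c{c} * S{i}"))
        )
    return ModelDocument(
        model_id=f"toy{int(rng.integers(0, 10**6))}",
        compartments=(("c", 1.0),),
        species=species,
        parameters=tuple(params),
        reactions=tuple(reactions),
    )


@pytest.fixture
def decay_model() -> ModelDocument:
    return make_decay_model()


@pytest.fixture
def reversible_model() -> ModelDocument:
    return make_reversible_model()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
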