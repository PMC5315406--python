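"""Parameter-value designs: local one-at-a-time sweeps, latin-hypercube
samples, and eFAST sinusoidal search-curve samples.

All designs are deterministic under a fixed seed and keep every emitted
value inside its declared ``[min, max]`` range.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .settings import ParameterRange

#: eFAST interference factor: number of higher harmonics of the driving
#: frequency attributed to a factor when partitioning variance.
EFAST_M = 4


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class EfastMeta:
    """Frequency bookkeeping needed to analyse an eFAST design.

    ``omega[i, j]`` is the frequency driving column j inside the block where
    column i is the factor of interest; ``phase[c, i, j]`` the random phase
    offset for resample curve c. Rows are laid out block-major:
    ``block(i, c) = rows[(i*curves + c)*ns : (i*curves + c + 1)*ns]``.
    """

    omega: np.ndarray          # (k, k) int
    phase: np.ndarray          # (curves, k, k) float
    curves: int
    samples_per_curve: int
    omega_max: int
    dummy_column: Optional[str] = None

    def block_rows(self, factor_index: int, curve: int) -> slice:
        ns = self.samples_per_curve
        start = (factor_index * self.curves + curve) * ns
        return slice(start, start + ns)


@dataclass(frozen=True)
class SampleSet:
    """A sampling design: value matrix plus the metadata to analyse it."""

    technique: str                      # LOCAL | LHS | EFAST
    columns: tuple[str, ...]
    rows: np.ndarray                    # (n_rows, n_columns) float
    seed: Optional[int] = None
    efast_meta: Optional[EfastMeta] = None
    local_meta: Optional[tuple[int, ...]] = field(default=None)  # factor index per row

    def __post_init__(self) -> None:
        if self.rows.ndim != 2 or self.rows.shape[1] != len(self.columns):
            raise DesignError("rows must be a (n, k) matrix matching columns")

    @property
    def n_rows(self) -> int:
        return self.rows.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=list(self.columns))

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)
        meta = {
            "technique": self.technique,
            "seed": self.seed,
            "columns": list(self.columns),
        }
        if self.efast_meta is not None:
            meta["efast"] = {
                "omega": self.efast_meta.omega.tolist(),
                "phase": self.efast_meta.phase.tolist(),
                "curves": self.efast_meta.curves,
                "samples_per_curve": self.efast_meta.samples_per_curve,
                "omega_max": self.efast_meta.omega_max,
                "dummy_column": self.efast_meta.dummy_column,
            }
        if self.local_meta is not None:
            meta["local_factor_index"] = list(self.local_meta)
        Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))


# ---------------------------------------------------------------------------
# Technique 1: local one-at-a-time sweep


def local_sweep(ranges: Sequence[ParameterRange], increments: int) -> SampleSet:
    """Sweep each target across [min, max] while holding the others at
    their baselines; ``increments`` evenly spaced values per target."""
    if increments < 1:
        raise DesignError("increments must be >= 1")
    if increments == 1:
        warnings.warn("increments=1 gives a degenerate single-point sweep (min only)")
    for r in ranges:
        if r.baseline is None:
            raise DesignError(f"range for {r.target_id!r} has no baseline value")
    columns = tuple(r.target_id for r in ranges)
    baselines = np.array([r.baseline for r in ranges])
    blocks = []
    factor_index = []
    for j, r in enumerate(ranges):
        sweep = np.linspace(r.min, r.max, increments) if increments > 1 else np.array([r.min])
        block = np.tile(baselines, (len(sweep), 1))
        block[:, j] = sweep
        blocks.append(block)
        factor_index.extend([j] * len(sweep))
    return SampleSet(
        technique="LOCAL",
        columns=columns,
        rows=np.vstack(blocks),
        local_meta=tuple(factor_index),
    )


# ---------------------------------------------------------------------------
# Technique 2: latin-hypercube sampling


def lhs_sample(
    ranges: Sequence[ParameterRange], n: int, seed: Optional[int] = None
) -> SampleSet:
    """Stratified latin-hypercube design: per column, exactly one value in
    each of the ``n`` equal-width strata, stratum order an independent
    random permutation, position within a stratum uniform."""
    if n < 2:
        raise DesignError("latin-hypercube sampling needs n >= 2")
    rng = np.random.default_rng(seed)
    k = len(ranges)
    unit = np.empty((n, k))
    for j in range(k):
        strata = rng.permutation(n)
        unit[:, j] = (strata + rng.uniform(size=n)) / n
    lo = np.array([r.min for r in ranges])
    hi = np.array([r.max for r in ranges])
    return SampleSet(
        technique="LHS",
        columns=tuple(r.target_id for r in ranges),
        rows=lo + unit * (hi - lo),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Technique 3: eFAST search-curve sampling


def _complementary_frequencies(k_minus_1: int, max_freq: int) -> np.ndarray:
    """Spread k-1 integer frequencies across [1, max_freq] (repeats allowed
    when k-1 exceeds the band — the canonical step schedule)."""
    if k_minus_1 <= 0:
        return np.array([], dtype=int)
    if max_freq <= 1:
        return np.ones(k_minus_1, dtype=int)
    return np.floor(np.linspace(1, max_freq, k_minus_1)).astype(int)


def efast_sample(
    ranges: Sequence[ParameterRange],
    samples_per_curve: int,
    curves: int,
    include_dummy: bool = True,
    seed: Optional[int] = None,
    dummy_name: str = "_dummy_",
) -> SampleSet:
    """eFAST design: one block per (factor of interest, resample curve).

    Within a block the factor of interest is driven along the search curve
    ``x(s) = min + (max-min) * (1/2 + arcsin(sin(w*s + phi))/pi)`` at the
    high frequency ``omega_max``; complementary factors follow low
    frequencies. ``s`` takes ``samples_per_curve`` equally spaced points in
    (-pi, pi]. Total rows = k * curves * samples_per_curve.
    """
    if samples_per_curve % 2 == 0 or samples_per_curve < 65:
        raise DesignError("samples_per_curve must be odd and >= 65")
    if curves < 1:
        raise DesignError("curves must be >= 1")
    rng = np.random.default_rng(seed)

    ranges = list(ranges)
    columns = [r.target_id for r in ranges]
    lo = [r.min for r in ranges]
    hi = [r.max for r in ranges]
    dummy_column = None
    if include_dummy:
        dummy_column = dummy_name
        columns.append(dummy_name)
        lo.append(0.0)
        hi.append(1.0)
    k = len(columns)
    lo_arr, hi_arr = np.array(lo), np.array(hi)

    omega_max = (samples_per_curve - 1) // (2 * EFAST_M)
    if omega_max < 1:
        raise DesignError("samples_per_curve too small for the interference factor")
    comp_band = max(1, omega_max // (2 * EFAST_M))

    omega = np.empty((k, k), dtype=int)
    for i in range(k):
        comp = _complementary_frequencies(k - 1, comp_band)
        row = np.empty(k, dtype=int)
        row[i] = omega_max
        row[[j for j in range(k) if j != i]] = comp
        omega[i] = row

    phase = rng.uniform(0.0, 2.0 * np.pi, size=(curves, k, k))
    ns = samples_per_curve
    s = -np.pi + 2.0 * np.pi * np.arange(1, ns + 1) / ns  # (-pi, pi]

    blocks = []
    for i in range(k):
        for c in range(curves):
            angle = np.outer(s, omega[i]) + phase[c, i]
            unit = 0.5 + np.arcsin(np.sin(angle)) / np.pi
            blocks.append(lo_arr + unit * (hi_arr - lo_arr))
    meta = EfastMeta(
        omega=omega,
        phase=phase,
        curves=curves,
        samples_per_curve=ns,
        omega_max=omega_max,
        dummy_column=dummy_column,
    )
    return SampleSet(
        technique="EFAST",
        columns=tuple(columns),
        rows=np.vstack(blocks),
        seed=seed,
        efast_meta=meta,
    )
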