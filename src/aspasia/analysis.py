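"""Sensitivity statistics over solver responses.

* :func:`prcc` — partial rank correlation coefficients with t-based
  significance for latin-hypercube ensembles;
* :func:`efast_indices` — first-order (Si) and total-order (STi) variance
  partitioning for eFAST designs, with a dummy-factor significance test;
* :func:`local_curves` — response-vs-value curves for one-at-a-time sweeps.

Inputs are a :class:`~aspasia.sampling.SampleSet` plus a response table
whose rows align one-to-one with the design rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .sampling import EFAST_M, SampleSet


class AnalysisError(ValueError):
    pass


@dataclass
class ResponseTable:
    """Named response measures, one row per design row."""

    frame: pd.DataFrame

    def column(self, name: str, n_expected: int) -> np.ndarray:
        if name not in self.frame.columns:
            raise AnalysisError(
                f"response {name!r} not found; available: {list(self.frame.columns)}"
            )
        if len(self.frame) != n_expected:
            raise AnalysisError(
                f"response table has {len(self.frame)} rows, design has {n_expected}"
            )
        return self.frame[name].to_numpy(float)


@dataclass
class SensitivityResult:
    technique: str
    response: str
    table: pd.DataFrame  # one row per target
    notes: dict = field(default_factory=dict)

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# PRCC


def _rank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x)


def _residuals(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Residuals of y after least-squares regression on [1, X]."""
    A = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return y - A @ coef


def prcc(
    design: SampleSet,
    responses: ResponseTable,
    response: str,
    bonferroni: bool = False,
) -> SensitivityResult:
    """Partial rank correlation of each design column with *response*,
    controlling for all other columns.

    Significance via ``t = r * sqrt(dof / (1 - r^2))`` with
    ``dof = n - 2 - (k - 1)`` controlled variables.
    """
    if design.technique != "LHS":
        raise AnalysisError(f"PRCC expects an LHS design, got {design.technique}")
    n, k = design.rows.shape
    if n < k + 3:
        raise AnalysisError(f"PRCC needs n >= k + 3 (n={n}, k={k})")
    y = responses.column(response, n)

    ranks = np.column_stack([_rank(design.rows[:, j]) for j in range(k)])
    ry = _rank(y)
    dof = n - 2 - (k - 1)

    records = []
    for j, target in enumerate(design.columns):
        if np.ptp(design.rows[:, j]) == 0:
            records.append({"target": target, "prcc": np.nan, "p_value": np.nan,
                            "note": "constant column: statistic undefined"})
            continue
        others = np.delete(ranks, j, axis=1)
        rx_res = _residuals(ranks[:, j], others)
        ry_res = _residuals(ry, others)
        denom = np.linalg.norm(rx_res) * np.linalg.norm(ry_res)
        if denom == 0:
            records.append({"target": target, "prcc": np.nan, "p_value": np.nan,
                            "note": "degenerate ranks"})
            continue
        r = float(np.dot(rx_res, ry_res) / denom)
        r = max(-1.0, min(1.0, r))
        if abs(r) == 1.0:
            p = 0.0
        else:
            t = r * np.sqrt(dof / (1.0 - r * r))
            p = 2.0 * stats.t.sf(abs(t), dof)
        if bonferroni:
            p = min(1.0, p * k)
        records.append({"target": target, "prcc": r, "p_value": p, "note": ""})
    return SensitivityResult(
        technique="LHS",
        response=response,
        table=pd.DataFrame(records),
        notes={"n": n, "k": k, "dof": dof, "bonferroni": bonferroni},
    )


# ---------------------------------------------------------------------------
# eFAST


def _spectrum_power(y: np.ndarray) -> np.ndarray:
    """Power at integer frequencies 1 .. (NS-1)/2 of a length-NS series."""
    ns = len(y)
    coeffs = np.fft.fft(y - y.mean())
    half = (ns - 1) // 2
    return (np.abs(coeffs[1 : half + 1]) ** 2) / (ns * ns) * 2.0


def efast_indices(
    design: SampleSet,
    responses: ResponseTable,
    response: str,
) -> SensitivityResult:
    """First-order and total-order eFAST indices per design column.

    Per factor block and resample curve: Si = power at the driving
    frequency's first ``EFAST_M`` harmonics over total variance; STi = 1
    minus the share of the low-frequency complementary band
    (frequencies <= omega_max / 2). Averaged over curves; the dummy
    column's per-curve indices give the significance floor (two-sample
    one-sided t test).
    """
    meta = design.efast_meta
    if design.technique != "EFAST" or meta is None:
        raise AnalysisError("eFAST analysis requires an EFAST design with metadata")
    y_all = responses.column(response, design.n_rows)

    w_max = meta.omega_max
    comp_cut = max(1, w_max // 2)
    harmonics = np.arange(1, EFAST_M + 1) * w_max

    per_curve_si: dict[str, list[float]] = {}
    per_curve_sti: dict[str, list[float]] = {}
    degenerate = []
    for i, target in enumerate(design.columns):
        si_list, sti_list = [], []
        for c in range(meta.curves):
            y = y_all[meta.block_rows(i, c)]
            power = _spectrum_power(y)
            total = power.sum()
            if total <= 0 or not np.isfinite(total):
                degenerate.append((target, c))
                continue
            vi = power[harmonics - 1].sum()
            vci = power[:comp_cut].sum()
            si_list.append(vi / total)
            sti_list.append(1.0 - vci / total)
        per_curve_si[target] = si_list
        per_curve_sti[target] = sti_list

    dummy = meta.dummy_column
    records = []
    for target in design.columns:
        si = per_curve_si[target]
        sti = per_curve_sti[target]
        rec = {
            "target": target,
            "Si": float(np.mean(si)) if si else np.nan,
            "STi": float(np.mean(sti)) if sti else np.nan,
            "Si_sd": float(np.std(si, ddof=1)) if len(si) > 1 else np.nan,
            "is_dummy": target == dummy,
        }
        if dummy is not None and target != dummy and si and per_curve_si[dummy]:
            if len(si) > 1 and len(per_curve_si[dummy]) > 1:
                rec["p_vs_dummy"] = float(
                    stats.ttest_ind(
                        si, per_curve_si[dummy], alternative="greater"
                    ).pvalue
                )
            else:
                rec["p_vs_dummy"] = np.nan
        else:
            rec["p_vs_dummy"] = np.nan
        records.append(rec)
    notes = {"omega_max": w_max, "harmonics": EFAST_M, "curves": meta.curves}
    if degenerate:
        notes["degenerate_blocks"] = [
            f"{t} curve {c}: zero total variance" for t, c in degenerate
        ]
    return SensitivityResult(
        technique="EFAST", response=response, table=pd.DataFrame(records), notes=notes
    )


# ---------------------------------------------------------------------------
# local sweeps


def local_curves(
    design: SampleSet,
    responses: ResponseTable,
    response: str,
    baseline_response: Optional[float] = None,
) -> dict[str, pd.DataFrame]:
    """Per target: sorted (value, response) pairs plus each point's absolute
    deviation from the baseline response (median response if not given)."""
    if design.technique != "LOCAL" or design.local_meta is None:
        raise AnalysisError("local-curve analysis requires a LOCAL design")
    y = responses.column(response, design.n_rows)
    factor = np.asarray(design.local_meta)
    out: dict[str, pd.DataFrame] = {}
    for j, target in enumerate(design.columns):
        rows = np.where(factor == j)[0]
        values = design.rows[rows, j]
        resp = y[rows]
        base = float(np.median(resp)) if baseline_response is None else baseline_response
        order = np.argsort(values)
        out[target] = pd.DataFrame({
            "value": values[order],
            "response": resp[order],
            "abs_deviation": np.abs(resp[order] - base),
        })
    return out


# ---------------------------------------------------------------------------
# plots (deliberately plain)


def plot_sensitivity(result: SensitivityResult, path: str | Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    t = result.table
    if result.technique == "LHS":
        ax.bar(t["target"], t["prcc"], color="steelblue")
        ax.set_ylabel("PRCC")
        ax.set_ylim(-1, 1)
    else:
        x = np.arange(len(t))
        ax.bar(x - 0.2, t["Si"], width=0.4, label="Si", color="steelblue")
        ax.bar(x + 0.2, t["STi"], width=0.4, label="STi", color="indianred")
        ax.set_xticks(x, t["target"])
        ax.set_ylabel("variance share")
        ax.legend()
    ax.set_title(f"{result.technique} sensitivity: {result.response}")
    ax.axhline(0, color="black", lw=0.5)
    plt.setp(ax.get_xticklabels(), rotation=45, ha="right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
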