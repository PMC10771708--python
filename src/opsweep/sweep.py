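"""Per-patient counterfactual SN-OP sweep and slope extraction.

For each patient the SN-OP angle is varied over an absolute grid (default
9 to 25 degrees in 1-degree steps, 17 points) while the nine remaining
skeletal inputs are frozen at the patient's measured values; the trained
surrogate predicts the outcome at every grid point and an ordinary
least-squares line through (grid, prediction) yields the patient's slope k
(outcome units per degree) and intercept b.  The grid is absolute, not
centred on the patient's own SN-OP, so sweeping may extrapolate beyond an
individual's plausible occlusion; reports label the result as model-based
sensitivity, not a treatment effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import tables
from .data import Cohort, SkeletalClass
from .exceptions import ConfigurationError
from .surrogate import SurrogateResults

__all__ = [
    "SweepGrid", "PatientSlope", "SweepResults",
    "build_sweep_matrix", "fit_patient_line", "run_sweep", "summarize_slopes",
]

#: per-patient fits with R^2 below this are flagged as non-linear responses
R2_FLAG_THRESHOLD = 0.95


@dataclass(frozen=True)
class SweepGrid:
    """Ascending SN-OP grid; both endpoints included when step divides the
    range (17 values at the 9..25 step-1 default)."""

    start: float = 9.0
    stop: float = 25.0
    step: float = 1.0

    def __post_init__(self):
        if not self.start < self.stop:
            raise ConfigurationError("grid requires start < stop")
        if not self.step > 0:
            raise ConfigurationError("grid requires step > 0")

    @property
    def values(self) -> np.ndarray:
        n = int(np.floor((self.stop - self.start) / self.step + 1e-9)) + 1
        vals = self.start + self.step * np.arange(n)
        return vals

    def __len__(self) -> int:
        return len(self.values)

    @classmethod
    def parse(cls, text: str) -> "SweepGrid":
        """Parse 'START:STOP:STEP' (STEP optional, default 1)."""
        parts = text.split(":")
        if len(parts) == 2:
            return cls(float(parts[0]), float(parts[1]))
        if len(parts) == 3:
            return cls(float(parts[0]), float(parts[1]), float(parts[2]))
        raise ConfigurationError(f"cannot parse grid {text!r}")


@dataclass(frozen=True)
class PatientSlope:
    """Least-squares line of predicted outcome vs swept SN-OP."""

    id: str
    outcome: str
    k: float      # outcome units per degree
    b: float      # outcome units
    r2: float
    n_grid: int
    degenerate: bool = False  # constant response: k = 0, r2 defined as 0


def build_sweep_matrix(record, grid: SweepGrid = SweepGrid()) -> pd.DataFrame:
    """Counterfactual input table: one row per grid value; the SN_OP column
    runs over the grid, every other input is frozen at the record's value.
    The record's own SN-OP need not lie inside the grid."""
    vals = grid.values
    base = {f: getattr(record, f) for f in tables.INPUT_FEATURES}
    df = pd.DataFrame({f: np.full(len(vals), base[f])
                       for f in tables.INPUT_FEATURES})
    df["SN_OP"] = vals
    return df


def fit_patient_line(grid_values: np.ndarray, predictions: np.ndarray,
                     record_id: str = "", outcome: str = "") -> PatientSlope:
    """Closed-form OLS of predictions on grid values (no iteration).

    k = sum((x-xbar)(y-ybar)) / sum((x-xbar)^2), b = ybar - k xbar.
    R^2 of a constant response is defined as 0 with a degenerate flag.
    """
    x = np.asarray(grid_values, float).ravel()
    y = np.asarray(predictions, float).ravel()
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need equal-length vectors of at least 2 points")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        raise ConfigurationError("degenerate design: constant grid")
    syy = float(np.sum((y - y.mean()) ** 2))
    k = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    b = float(y.mean() - k * x.mean())
    if syy == 0.0:
        return PatientSlope(record_id, outcome, 0.0, float(y.mean()), 0.0,
                            len(x), degenerate=True)
    ss_res = syy - k * k * sxx
    r2 = float(np.clip(1.0 - ss_res / syy, 0.0, 1.0))
    return PatientSlope(record_id, outcome, k, b, r2, len(x))


@dataclass
class SweepResults:
    """Per-patient slopes for one outcome, with summaries and exports."""

    outcome: str
    slopes: pd.DataFrame  # id, outcome, k, b, r2, n_grid, degenerate
    grid: SweepGrid

    def __len__(self) -> int:
        return len(self.slopes)

    @property
    def k(self) -> np.ndarray:
        return self.slopes["k"].to_numpy()

    @property
    def b(self) -> np.ndarray:
        return self.slopes["b"].to_numpy()

    def low_r2(self, threshold: float = R2_FLAG_THRESHOLD) -> pd.DataFrame:
        """Patients whose response deviates from linearity (r2 < threshold);
        the per-patient line is assumed linear, so these warrant review."""
        return self.slopes[self.slopes["r2"] < threshold]

    def summarize(self, labels: list[SkeletalClass]) -> pd.DataFrame:
        return summarize_slopes(self, labels)

    def with_labels(self, labels: list[SkeletalClass]) -> pd.DataFrame:
        df = self.slopes.copy()
        df["sagittal"] = [l.sagittal for l in labels]
        df["vertical"] = [l.vertical for l in labels]
        return df

    def plot_cells(self, labels: list[SkeletalClass], ax=None):
        """Box plot of k by skeletal cell (needs matplotlib)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        df = self.with_labels(labels)
        groups, names = [], []
        for s in tables.SAGITTAL:
            for v in tables.VERTICAL:
                sub = df[(df.sagittal == s) & (df.vertical == v)]
                if len(sub):
                    groups.append(sub["k"].to_numpy())
                    names.append(f"{s}-{v}")
        ax.boxplot(groups, tick_labels=names)
        ax.set_ylabel(f"k ({self.outcome} per degree SN-OP)")
        ax.tick_params(axis="x", rotation=45)
        return ax


def run_sweep(results: SurrogateResults, cohort: Cohort,
              grid: SweepGrid = SweepGrid(),
              outcome: str | None = None) -> SweepResults:
    """Sweep every record through the surrogate; one PatientSlope each.

    Per-record independent by construction: each record's predictions come
    from its own frozen-feature matrix.
    """
    outcome = outcome or results.out_bounds.names[0]
    if results.out_bounds.names[0] != outcome:
        raise ConfigurationError(
            f"model predicts {results.out_bounds.names[0]!r}, not {outcome!r}")
    vals = grid.values
    g = len(vals)
    n = len(cohort)
    # one stacked prediction call: n blocks of g rows
    X = np.repeat(cohort.inputs().to_numpy(float), g, axis=0)
    op_col = list(tables.INPUT_FEATURES).index("SN_OP")
    X[:, op_col] = np.tile(vals, n)
    preds = results.predict(X).reshape(n, g)
    rows = []
    for rec, y in zip(cohort, preds):
        ps = fit_patient_line(vals, y, record_id=rec.id, outcome=outcome)
        rows.append({"id": ps.id, "outcome": outcome, "k": ps.k, "b": ps.b,
                     "r2": ps.r2, "n_grid": ps.n_grid,
                     "degenerate": ps.degenerate})
    return SweepResults(outcome=outcome, slopes=pd.DataFrame(rows), grid=grid)


def summarize_slopes(sweep: SweepResults | pd.DataFrame,
                     labels: list[SkeletalClass]) -> pd.DataFrame:
    """Per-cell mean, SD and count of k and b, plus row/column totals.

    Slope units: FHR slopes in percentage points per degree, FA slopes in
    degrees per degree.  Empty cells are reported with n = 0 and NaN
    moments, not raised.
    """
    df = sweep.slopes if isinstance(sweep, SweepResults) else sweep
    if len(df) != len(labels):
        raise ConfigurationError("labels do not cover the slope records")
    work = df.copy()
    work["sagittal"] = [l.sagittal for l in labels]
    work["vertical"] = [l.vertical for l in labels]
    rows = []
    sag_groups = list(tables.SAGITTAL) + ["Total"]
    vert_groups = list(tables.VERTICAL) + ["Total"]
    for s in sag_groups:
        for v in vert_groups:
            sub = work
            if s != "Total":
                sub = sub[sub.sagittal == s]
            if v != "Total":
                sub = sub[sub.vertical == v]
            rows.append({
                "sagittal": s, "vertical": v, "n": len(sub),
                "k_mean": sub["k"].mean() if len(sub) else np.nan,
                "k_sd": sub["k"].std(ddof=1) if len(sub) > 1 else np.nan,
                "b_mean": sub["b"].mean() if len(sub) else np.nan,
                "b_sd": sub["b"].std(ddof=1) if len(sub) > 1 else np.nan,
            })
    return pd.DataFrame(rows)
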