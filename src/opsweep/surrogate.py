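"""Feedforward surrogate models for the two aesthetic indices.

A :class:`SurrogateRegression` is a single-hidden-layer (default 10 tanh
units, linear output) network mapping the ten skeletal inputs to one
outcome.  Inputs and outcome are min-max normalized to [-1, 1] on the
training split only (the mapminmax convention); the data are split
70:15:15 into training / validation / test; full-batch Levenberg-Marquardt
(one damped Gauss-Newton step per epoch; L-BFGS available as an
alternative) minimizes the mean-squared error in normalized space, with
early stopping after ``patience`` epochs without validation improvement;
the returned weights are those of the best validation epoch.

``fit`` returns a :class:`SurrogateResults` carrying the weights, the
normalization bounds, the per-epoch train/validation/test MSE trace and
agreement diagnostics (Pearson r, paired t, Bland-Altman limits).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from . import tables
from .exceptions import ConfigurationError, DegenerateFeatureError

__all__ = [
    "NormalizationBounds", "SurrogateRegression", "SurrogateResults",
    "AgreementReport", "fit_bounds", "split_dataset", "train_surrogate",
    "predict", "evaluate_agreement",
]


@dataclass(frozen=True)
class NormalizationBounds:
    """Per-feature min/max for the affine map to [-1, 1] (no clipping)."""

    minimum: np.ndarray
    maximum: np.ndarray
    names: tuple[str, ...]

    @classmethod
    def fit(cls, X: np.ndarray, names: Sequence[str]) -> "NormalizationBounds":
        X = np.atleast_2d(np.asarray(X, float))
        lo, hi = X.min(axis=0), X.max(axis=0)
        for j, name in enumerate(names):
            if not hi[j] > lo[j]:
                raise DegenerateFeatureError(name)
        return cls(lo, hi, tuple(names))

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        return 2.0 * (X - self.minimum) / (self.maximum - self.minimum) - 1.0

    def inverse(self, Z: np.ndarray) -> np.ndarray:
        Z = np.asarray(Z, float)
        return (Z + 1.0) / 2.0 * (self.maximum - self.minimum) + self.minimum


def fit_bounds(inputs: np.ndarray, outputs: np.ndarray,
               feature_names: Sequence[str] | None = None,
               outcome_name: str = "y"
               ) -> tuple[NormalizationBounds, NormalizationBounds]:
    """Training-split normalization bounds for inputs and outcome."""
    inputs = np.atleast_2d(np.asarray(inputs, float))
    names = tuple(feature_names) if feature_names is not None else tuple(
        f"x{j}" for j in range(inputs.shape[1]))
    in_b = NormalizationBounds.fit(inputs, names)
    out_b = NormalizationBounds.fit(np.asarray(outputs, float).reshape(-1, 1),
                                    (outcome_name,))
    return in_b, out_b


def split_dataset(n: int, ratios: Sequence[float] = (0.70, 0.15, 0.15),
                  seed: int | None = None
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random disjoint exhaustive train/validation/test index sets.

    Sizes follow largest-remainder rounding of the normalized ratios; equal
    remainders are resolved in favour of the later split (903 with 70:15:15
    gives 632/135/136).
    """
    ratios = np.asarray(ratios, float)
    if len(ratios) != 3 or np.any(ratios <= 0):
        raise ConfigurationError("need three positive split ratios")
    ratios = ratios / ratios.sum()
    quotas = ratios * n
    sizes = np.floor(quotas).astype(int)
    frac = quotas - sizes
    for _ in range(n - sizes.sum()):
        j = max(range(3), key=lambda i: (frac[i], i))
        sizes[j] += 1
        frac[j] = -1.0
    perm = np.random.default_rng(seed).permutation(n)
    a, b = sizes[0], sizes[0] + sizes[1]
    return np.sort(perm[:a]), np.sort(perm[a:b]), np.sort(perm[b:])


# ---------------------------------------------------------------------------
# network internals


def _unpack(p: np.ndarray, d: int, h: int):
    i = 0
    W1 = p[i:i + d * h].reshape(d, h); i += d * h
    b1 = p[i:i + h]; i += h
    w2 = p[i:i + h]; i += h
    b2 = p[i]
    return W1, b1, w2, b2


def _forward(p: np.ndarray, Xn: np.ndarray, d: int, h: int) -> np.ndarray:
    W1, b1, w2, b2 = _unpack(p, d, h)
    return np.tanh(Xn @ W1 + b1) @ w2 + b2


def _loss_grad(p: np.ndarray, Xn: np.ndarray, yn: np.ndarray,
               d: int, h: int) -> tuple[float, np.ndarray]:
    W1, b1, w2, b2 = _unpack(p, d, h)
    H = np.tanh(Xn @ W1 + b1)
    r = H @ w2 + b2 - yn
    n = len(yn)
    loss = float(r @ r) / n
    dy = 2.0 * r / n
    dw2 = H.T @ dy
    db2 = dy.sum()
    dZ = np.outer(dy, w2) * (1.0 - H * H)
    dW1 = Xn.T @ dZ
    db1 = dZ.sum(axis=0)
    return loss, np.concatenate([dW1.ravel(), db1, dw2, [db2]])


def _residual_jacobian(p: np.ndarray, Xn: np.ndarray, yn: np.ndarray,
                       d: int, h: int) -> tuple[np.ndarray, np.ndarray]:
    """Residuals and their Jacobian wrt the packed parameter vector."""
    W1, b1, w2, b2 = _unpack(p, d, h)
    H = np.tanh(Xn @ W1 + b1)
    r = H @ w2 + b2 - yn
    G = (1.0 - H * H) * w2          # n x h
    J = np.concatenate([
        np.einsum("ni,nj->nij", Xn, G).reshape(len(Xn), d * h),
        G, H, np.ones((len(Xn), 1))], axis=1)
    return r, J


@dataclass
class AgreementReport:
    """Prediction-vs-truth agreement diagnostics."""

    n: int
    pearson_r: float
    r_squared: float
    t_stat: float
    t_p: float
    mean_diff: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    frac_within_limits: float
    note: str = ""

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "n", "pearson_r", "r_squared", "t_stat", "t_p", "mean_diff",
            "sd_diff", "loa_lower", "loa_upper", "frac_within_limits",
            "note")}


def evaluate_agreement(predicted: np.ndarray,
                       actual: np.ndarray) -> AgreementReport:
    """Pearson r, paired t on the differences, Bland-Altman limits."""
    predicted = np.asarray(predicted, float).ravel()
    actual = np.asarray(actual, float).ravel()
    if predicted.shape != actual.shape:
        raise ValueError("predicted and actual must have equal length")
    n = len(predicted)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    note = ""
    if predicted.std() == 0 or actual.std() == 0:
        r = float("nan")
        note = "correlation undefined: zero variance"
    else:
        r = float(sps.pearsonr(predicted, actual).statistic)
    diff = predicted - actual
    d_mean = float(diff.mean())
    d_sd = float(diff.std(ddof=1))
    if d_sd == 0.0:
        t, p = (0.0, 1.0) if d_mean == 0.0 else \
            (float(np.sign(d_mean) * np.inf), 0.0)
    else:
        res = sps.ttest_rel(predicted, actual)
        t, p = float(res.statistic), float(res.pvalue)
    lo = d_mean - 1.96 * d_sd
    hi = d_mean + 1.96 * d_sd
    within = float(np.mean((diff >= lo) & (diff <= hi)))
    return AgreementReport(n=n, pearson_r=r, r_squared=r * r if np.isfinite(r)
                           else float("nan"), t_stat=t, t_p=p,
                           mean_diff=d_mean, sd_diff=d_sd, loa_lower=lo,
                           loa_upper=hi, frac_within_limits=within, note=note)


class SurrogateRegression:
    """Model object: data plus hyperparameters; ``fit`` trains the network."""

    def __init__(self, inputs, outcome, feature_names: Sequence[str] | None = None,
                 outcome_name: str = "y", hidden: int = 10,
                 ratios: Sequence[float] = (0.70, 0.15, 0.15),
                 max_epochs: int = 1000, patience: int = 20,
                 restarts: int = 3, optimizer: str = "lm"):
        if isinstance(inputs, pd.DataFrame):
            feature_names = feature_names or tuple(inputs.columns)
            inputs = inputs.to_numpy(float)
        self.X = np.atleast_2d(np.asarray(inputs, float))
        self.y = np.asarray(outcome, float).ravel()
        if len(self.X) != len(self.y):
            raise ValueError("inputs and outcome lengths differ")
        if len(self.X) < 50:
            raise ConfigurationError("need at least 50 records to train")
        self.feature_names = tuple(feature_names) if feature_names else tuple(
            f"x{j}" for j in range(self.X.shape[1]))
        self.outcome_name = outcome_name
        self.hidden = int(hidden)
        self.ratios = tuple(ratios)
        self.max_epochs = int(max_epochs)
        self.patience = int(patience)
        self.restarts = int(restarts)
        if optimizer not in ("lm", "lbfgs"):
            raise ConfigurationError(f"unknown optimizer {optimizer!r}")
        self.optimizer = optimizer

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, outcome: str,
                       features: Sequence[str] = tables.INPUT_FEATURES,
                       **kwargs) -> "SurrogateRegression":
        return cls(df[list(features)], df[outcome].to_numpy(float),
                   feature_names=tuple(features), outcome_name=outcome,
                   **kwargs)

    # ------------------------------------------------------------------
    def fit(self, seed: int = 0) -> "SurrogateResults":
        ss = np.random.SeedSequence(seed)
        split_seed = int(ss.generate_state(1)[0] % (2**31))
        train_idx, val_idx, test_idx = split_dataset(
            len(self.y), self.ratios, split_seed)
        in_b, out_b = fit_bounds(self.X[train_idx], self.y[train_idx],
                                 self.feature_names, self.outcome_name)
        Xn = {k: in_b.transform(self.X[idx]) for k, idx in
              (("train", train_idx), ("val", val_idx), ("test", test_idx))}
        yn = {k: out_b.transform(self.y[idx].reshape(-1, 1)).ravel()
              for k, idx in (("train", train_idx), ("val", val_idx),
                             ("test", test_idx))}
        d, h = self.X.shape[1], self.hidden

        best = None
        for child in ss.spawn(self.restarts):
            rng = np.random.default_rng(child)
            p0 = np.concatenate([
                rng.normal(0.0, 1.0 / np.sqrt(d), d * h),
                np.zeros(h),
                rng.normal(0.0, 1.0 / np.sqrt(h), h),
                [0.0]])
            run = self._train_once(p0, Xn, yn, d, h)
            if best is None or run["best_val"] < best["best_val"]:
                best = run

        results = SurrogateResults(
            model=self, params=best["params"], in_bounds=in_b,
            out_bounds=out_b, trace=best["trace"],
            best_epoch=best["best_epoch"], converged=best["converged"],
            seed=seed, split_indices=(train_idx, val_idx, test_idx))
        return results

    def _train_once(self, p0, Xn, yn, d, h) -> dict:
        trace: list[dict] = []
        state = {"best_val": np.inf, "best_p": p0.copy(), "stall": 0,
                 "stopped": False}

        def record(p):
            row = {}
            for k in ("train", "val", "test"):
                r = _forward(p, Xn[k], d, h) - yn[k]
                row[k] = float(r @ r) / len(r) if len(r) else float("nan")
            trace.append(row)
            return row

        def check_stop(p, row) -> bool:
            """Track the best validation epoch; True when patience runs out."""
            if row["val"] < state["best_val"] - 1e-15:
                state["best_val"] = row["val"]
                state["best_p"] = p.copy()
                state["stall"] = 0
                return False
            state["stall"] += 1
            if state["stall"] >= self.patience:
                state["stopped"] = True
                return True
            return False

        row0 = record(p0)
        state["best_val"] = row0["val"]
        if self.optimizer == "lm":
            self._run_lm(p0, Xn, yn, d, h, record, check_stop)
        else:
            self._run_lbfgs(p0, Xn, yn, d, h, record, check_stop)

        vals = np.array([row["val"] for row in trace])
        if not np.all(np.isfinite(vals)):
            raise ConfigurationError("training diverged to non-finite loss")
        best_epoch = int(np.argmin(vals))  # earliest minimum on ties
        return {"params": state["best_p"], "trace": pd.DataFrame(trace),
                "best_epoch": best_epoch, "best_val": float(vals.min()),
                "converged": state["stopped"] or len(trace) < self.max_epochs + 1}

    def _run_lm(self, p0, Xn, yn, d, h, record, check_stop) -> None:
        """Levenberg-Marquardt epochs: damped Gauss-Newton steps on the
        training residuals; one accepted step per epoch."""
        p = p0.copy()
        mu = 1e-3
        Xt, yt = Xn["train"], yn["train"]
        r, J = _residual_jacobian(p, Xt, yt, d, h)
        sse = float(r @ r)
        eye = np.eye(len(p))
        for _ in range(self.max_epochs):
            JtJ = J.T @ J
            Jtr = J.T @ r
            accepted = False
            for _ in range(40):
                try:
                    delta = np.linalg.solve(JtJ + mu * eye, -Jtr)
                except np.linalg.LinAlgError:
                    mu *= 10.0
                    continue
                cand = p + delta
                rc, Jc = _residual_jacobian(cand, Xt, yt, d, h)
                sse_c = float(rc @ rc)
                if np.isfinite(sse_c) and sse_c < sse:
                    p, r, J, sse = cand, rc, Jc, sse_c
                    mu = max(mu / 10.0, 1e-12)
                    accepted = True
                    break
                mu *= 10.0
                if mu > 1e12:
                    break
            if not accepted:
                break  # damping exhausted: converged on the training loss
            row = record(p)
            if check_stop(p, row):
                break

    def _run_lbfgs(self, p0, Xn, yn, d, h, record, check_stop) -> None:
        def callback(pk):
            if check_stop(pk, record(pk)):
                raise StopIteration

        try:
            optimize.minimize(
                _loss_grad, p0, args=(Xn["train"], yn["train"], d, h),
                jac=True, method="L-BFGS-B", callback=callback,
                options={"maxiter": self.max_epochs, "ftol": 1e-12,
                         "gtol": 1e-10})
        except StopIteration:
            pass


@dataclass
class SurrogateResults:
    """Fitted surrogate: weights, bounds, training trace, diagnostics."""

    model: SurrogateRegression | None
    params: np.ndarray
    in_bounds: NormalizationBounds
    out_bounds: NormalizationBounds
    trace: pd.DataFrame
    best_epoch: int
    converged: bool
    seed: int
    split_indices: tuple[np.ndarray, np.ndarray, np.ndarray]

    @property
    def hidden(self) -> int:
        d = len(self.in_bounds.names)
        return (len(self.params) - 1) // (d + 2)

    def predict(self, inputs) -> np.ndarray:
        """Normalize, forward pass, inverse-normalize (original units)."""
        if isinstance(inputs, pd.DataFrame):
            inputs = inputs[list(self.in_bounds.names)].to_numpy(float)
        X = np.atleast_2d(np.asarray(inputs, float))
        d = len(self.in_bounds.names)
        if X.shape[1] != d:
            raise ValueError(f"expected {d} input columns, got {X.shape[1]}")
        zn = _forward(self.params, self.in_bounds.transform(X), d, self.hidden)
        return self.out_bounds.inverse(zn.reshape(-1, 1)).ravel()

    def _split_xy(self, split: str):
        names = {"train": 0, "val": 1, "test": 2}
        idx = self.split_indices[names[split]]
        return self.model.X[idx], self.model.y[idx]

    def split_r(self, split: str = "test") -> float:
        X, y = self._split_xy(split)
        return float(sps.pearsonr(self.predict(X), y).statistic)

    def agreement(self, split: str = "test") -> AgreementReport:
        X, y = self._split_xy(split)
        return evaluate_agreement(self.predict(X), y)

    def summary(self) -> str:
        lines = [
            f"Surrogate regression results: {self.out_bounds.names[0]}",
            "=" * 58,
            f"inputs: {len(self.in_bounds.names)}  hidden units: {self.hidden}"
            f"  seed: {self.seed}",
            f"epochs run: {len(self.trace) - 1}  best epoch: {self.best_epoch}"
            f"  converged: {self.converged}",
            "split sizes: " + "/".join(str(len(i)) for i in self.split_indices),
        ]
        best = self.trace.iloc[self.best_epoch]
        lines.append(
            f"MSE (normalized) at best epoch: train {best['train']:.5f}"
            f"  val {best['val']:.5f}  test {best['test']:.5f}")
        if self.model is not None:
            for split in ("train", "val", "test"):
                rep = self.agreement(split)
                lines.append(
                    f"{split:>5}: r = {rep.pearson_r:.4f}  "
                    f"paired t = {rep.t_stat:+.3f} (p = {rep.t_p:.3f})  "
                    f"LoA [{rep.loa_lower:+.3f}, {rep.loa_upper:+.3f}]  "
                    f"within = {100 * rep.frac_within_limits:.1f}%")
        return "\n".join(lines)

    # ------------------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        d = {
            "outcome": self.out_bounds.names[0],
            "feature_names": list(self.in_bounds.names),
            "params": self.params.tolist(),
            "in_min": self.in_bounds.minimum.tolist(),
            "in_max": self.in_bounds.maximum.tolist(),
            "out_min": self.out_bounds.minimum.tolist(),
            "out_max": self.out_bounds.maximum.tolist(),
            "trace": self.trace.to_dict(orient="list"),
            "best_epoch": self.best_epoch,
            "converged": self.converged,
            "seed": self.seed,
            "splits": [idx.tolist() for idx in self.split_indices],
        }
        Path(path).write_text(json.dumps(d))

    @classmethod
    def from_json(cls, path: str | Path) -> "SurrogateResults":
        d = json.loads(Path(path).read_text())
        in_b = NormalizationBounds(np.array(d["in_min"]),
                                   np.array(d["in_max"]),
                                   tuple(d["feature_names"]))
        out_b = NormalizationBounds(np.array(d["out_min"]),
                                    np.array(d["out_max"]),
                                    (d["outcome"],))
        return cls(model=None, params=np.array(d["params"]), in_bounds=in_b,
                   out_bounds=out_b, trace=pd.DataFrame(d["trace"]),
                   best_epoch=d["best_epoch"], converged=d["converged"],
                   seed=d["seed"],
                   split_indices=tuple(np.array(i) for i in d["splits"]))

    def training_curves(self) -> pd.DataFrame:
        """Epoch-indexed train/val/test MSE table (exportable as CSV)."""
        df = self.trace.copy()
        df.insert(0, "epoch", np.arange(len(df)))
        return df

    def plot_training(self, ax=None):
        """MSE-vs-epoch curves for the three splits (needs matplotlib)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        for k, color in (("train", "C0"), ("val", "C2"), ("test", "C3")):
            ax.plot(self.trace[k], color=color, label=k)
        ax.axvline(self.best_epoch, ls=":", color="k", lw=0.8)
        ax.set_xlabel("epoch")
        ax.set_ylabel("MSE (normalized)")
        ax.set_yscale("log")
        ax.legend()
        return ax


def train_surrogate(inputs, outcome, seed: int = 0,
                    **hyperparams) -> SurrogateResults:
    """Functional wrapper: build a :class:`SurrogateRegression` and fit."""
    return SurrogateRegression(inputs, outcome, **hyperparams).fit(seed=seed)


def predict(results: SurrogateResults, inputs) -> np.ndarray:
    return results.predict(inputs)
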