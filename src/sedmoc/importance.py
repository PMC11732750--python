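"""ANN emulation of the ensemble and partial-derivative process importance.

A three-layer network (inputs → tanh hidden layer → linear output) is
trained on the (parameter, output) table produced by the Monte Carlo stage.
Sensitivity of the emulated output to each standardized input is the mean
absolute partial derivative over the sample, evaluated analytically through
the network by the chain rule (for a single linear neuron y = w·x + b the
derivative is exactly w).  Parameters are grouped into six processes; a
process's raw score is the maximum over its members' sensitivities, and
scores are normalized to sum to 100 %.  Confidence intervals come from
repeated trainings with different weight initializations and bootstrap
resamples of the rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neural_network import MLPRegressor

from .ensemble import PROCESSES, ParameterDistribution

__all__ = [
    "nash_sutcliffe",
    "Emulator",
    "train_emulator",
    "partial_derivative_sensitivity",
    "process_importance",
    "ImportanceResult",
    "importance_with_ci",
    "averaged_importance",
    "grouping_from_distributions",
]


def nash_sutcliffe(obs: np.ndarray, sim: np.ndarray) -> float:
    """Nash–Sutcliffe model efficiency, 1 − SSE/SST (1 perfect, ≤0 no skill)."""
    obs = np.asarray(obs, dtype=float)
    sim = np.asarray(sim, dtype=float)
    sst = ((obs - obs.mean()) ** 2).sum()
    if sst == 0:
        raise ValueError("degenerate target: zero variance")
    return 1.0 - ((obs - sim) ** 2).sum() / sst


def grouping_from_distributions(dists: list[ParameterDistribution]) -> dict[str, str]:
    """Parameter-name → process map, as shipped with the distribution table."""
    return {d.name: d.process for d in dists}


def _transforms_from_distributions(dists: list[ParameterDistribution]) -> dict[str, str]:
    return {d.name: d.transform for d in dists}


@dataclass
class Emulator:
    """Trained network plus the input standardization it was fitted under."""

    mlp: MLPRegressor
    feature_names: list[str]
    transforms: dict[str, str]
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    y_std: float
    nse: float  # held-out Nash–Sutcliffe efficiency
    hidden_size: int

    def standardize(self, X: pd.DataFrame) -> np.ndarray:
        cols = []
        for nm in self.feature_names:
            v = X[nm].to_numpy(dtype=float)
            if self.transforms.get(nm, "none") == "log":
                v = np.log(v)
            cols.append(v)
        Xs = np.column_stack(cols)
        return (Xs - self.x_mean) / self.x_std

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.mlp.predict(self.standardize(X)) * self.y_std + self.y_mean


def _standardize_fit(X: pd.DataFrame, transforms: dict[str, str]):
    names = list(X.columns)
    cols = []
    for nm in names:
        v = X[nm].to_numpy(dtype=float)
        if transforms.get(nm, "none") == "log":
            v = np.log(v)
        cols.append(v)
    Xt = np.column_stack(cols)
    mean = Xt.mean(axis=0)
    std = Xt.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    return names, (Xt - mean) / std, mean, std


def train_emulator(
    X: pd.DataFrame,
    y: np.ndarray,
    hidden_sizes: tuple[int, ...] = (4, 6, 8, 12),
    seed: int = 0,
    transforms: dict[str, str] | None = None,
    test_fraction: float = 0.25,
    max_iter: int = 3000,
) -> Emulator:
    """Fit the three-layer emulator, selecting the hidden-layer width by
    held-out Nash–Sutcliffe efficiency.

    Requires roughly ten rows per hidden neuron; widths violating that are
    skipped.  Inputs are standardized internally (log first where the
    distribution table says so); the target is standardized too.
    """
    y = np.asarray(y, dtype=float)
    if y.std() == 0:
        raise ValueError("degenerate target: zero variance")
    transforms = transforms or {}
    names, Xs, x_mean, x_std = _standardize_fit(X, transforms)
    n = len(y)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_test = max(2, int(round(test_fraction * n)))
    test, train = order[:n_test], order[n_test:]
    y_mean, y_std = float(y[train].mean()), float(y[train].std())
    ys = (y - y_mean) / y_std

    candidates = [h for h in hidden_sizes if len(train) >= 10 * h] or [min(hidden_sizes)]
    best = None
    for h in candidates:
        mlp = MLPRegressor(
            hidden_layer_sizes=(h,), activation="tanh", solver="lbfgs",
            alpha=1e-4, max_iter=max_iter,
            random_state=int(rng.integers(2**31 - 1)),
        )
        mlp.fit(Xs[train], ys[train])
        nse = nash_sutcliffe(ys[test], mlp.predict(Xs[test]))
        if best is None or nse > best[1]:
            best = (mlp, nse, h)
    mlp, nse, h = best
    return Emulator(mlp=mlp, feature_names=names, transforms=transforms,
                    x_mean=x_mean, x_std=x_std, y_mean=y_mean, y_std=y_std,
                    nse=float(nse), hidden_size=h)


def partial_derivative_sensitivity(emulator: Emulator,
                                   X: pd.DataFrame) -> pd.Series:
    """Mean absolute ∂ŷ/∂x_k over the sample, on standardized inputs.

    Chain rule through tanh hidden layer and linear output:
    ∂ŷ/∂x = W1 · diag(1 − h²) · w2.
    """
    mlp = emulator.mlp
    if not hasattr(mlp, "coefs_"):
        raise ValueError("emulator network is not trained")
    Xs = emulator.standardize(X)
    W1, w2 = mlp.coefs_  # (n_in, n_h), (n_h, 1)
    b1 = mlp.intercepts_[0]
    h = np.tanh(Xs @ W1 + b1)  # (n, n_h)
    grad = ((1.0 - h * h) * w2.ravel()) @ W1.T  # (n, n_in)
    scores = np.abs(grad).mean(axis=0)
    return pd.Series(scores, index=emulator.feature_names)


def process_importance(sensitivities: pd.Series,
                       grouping: dict[str, str]) -> pd.Series:
    """Max-over-members per process, normalized to sum to 100 %."""
    missing = [nm for nm in sensitivities.index if nm not in grouping]
    if missing:
        raise KeyError(f"parameters without a process assignment: {missing}")
    raw = {}
    for proc in PROCESSES:
        members = [nm for nm in sensitivities.index if grouping[nm] == proc]
        if members:
            raw[proc] = float(sensitivities[members].max())
    total = sum(raw.values())
    if total <= 0:
        raise ValueError("all sensitivities are zero; importance undefined")
    return pd.Series({p: 100.0 * v / total for p, v in raw.items()})


@dataclass
class ImportanceResult:
    """Per-process relative importance (%) with repeated-training CIs."""

    table: pd.DataFrame  # columns: process, mean, ci_lo, ci_hi
    nse: list[float] = field(default_factory=list)
    n_repeats: int = 0
    output_name: str = ""

    def ranked(self) -> pd.DataFrame:
        return self.table.sort_values("mean", ascending=False).reset_index(drop=True)

    def top_process(self) -> str:
        return self.ranked().iloc[0]["process"]


def importance_with_ci(
    X: pd.DataFrame,
    y: np.ndarray,
    grouping: dict[str, str],
    n_repeats: int = 20,
    seed: int = 0,
    transforms: dict[str, str] | None = None,
    hidden_sizes: tuple[int, ...] = (4, 6, 8, 12),
    output_name: str = "",
) -> ImportanceResult:
    """Repeat train → differentiate → group; report mean and percentile CI.

    Each repeat uses a fresh weight initialization and a bootstrap resample
    of the rows.  The hidden width is selected once on the full table and
    then held fixed across repeats.
    """
    if n_repeats < 2:
        raise ValueError("need at least two repeats for a confidence interval")
    y = np.asarray(y, dtype=float)
    base = train_emulator(X, y, hidden_sizes=hidden_sizes, seed=seed,
                          transforms=transforms)
    rng = np.random.default_rng(seed + 1)
    rows = []
    nses = [base.nse]
    n = len(y)
    for _ in range(n_repeats):
        idx = rng.integers(0, n, n)
        rep = train_emulator(
            X.iloc[idx].reset_index(drop=True), y[idx],
            hidden_sizes=(base.hidden_size,),
            seed=int(rng.integers(2**31 - 1)), transforms=transforms,
        )
        nses.append(rep.nse)
        sens = partial_derivative_sensitivity(rep, X)
        rows.append(process_importance(sens, grouping))
    reps = pd.DataFrame(rows)
    mean = reps.mean()
    mean = 100.0 * mean / mean.sum()
    table = pd.DataFrame({
        "process": mean.index,
        "mean": mean.to_numpy(),
        "ci_lo": reps.quantile(0.025).reindex(mean.index).to_numpy(),
        "ci_hi": reps.quantile(0.975).reindex(mean.index).to_numpy(),
    })
    return ImportanceResult(table=table, nse=nses, n_repeats=n_repeats,
                            output_name=output_name)


def averaged_importance(
    X: pd.DataFrame,
    outputs: pd.DataFrame,
    targets: list[str],
    grouping: dict[str, str],
    n_repeats: int = 10,
    seed: int = 0,
    transforms: dict[str, str] | None = None,
    log_targets: bool = True,
    floor: float = 1e-6,
) -> ImportanceResult:
    """Importance averaged over several related outputs.

    Used for mineral-phase OC preservation: importance is computed for each
    MOC fraction's formation rate separately and the per-process
    importances are averaged, so that small-magnitude fractions (GPS-MOC,
    lrDOC-MOC) weigh equally with the large (semi)labile fraction.  Rates
    spanning orders of magnitude are emulated on a log scale by default.
    """
    tables = []
    nses: list[float] = []
    for i, target in enumerate(targets):
        y = outputs[target].to_numpy(dtype=float)
        if log_targets:
            y = np.log(np.maximum(y, floor))
        res = importance_with_ci(X, y, grouping, n_repeats=n_repeats,
                                 seed=seed + i, transforms=transforms,
                                 output_name=target)
        tables.append(res.table.set_index("process"))
        nses.extend(res.nse)
    mean = sum(t["mean"] for t in tables) / len(tables)
    mean = 100.0 * mean / mean.sum()
    table = pd.DataFrame({
        "process": mean.index,
        "mean": mean.to_numpy(),
        "ci_lo": (sum(t["ci_lo"] for t in tables) / len(tables)).to_numpy(),
        "ci_hi": (sum(t["ci_hi"] for t in tables) / len(tables)).to_numpy(),
    })
    return ImportanceResult(table=table, nse=nses, n_repeats=n_repeats,
                            output_name="+".join(targets))
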