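"""Cell-blind splitting, cross-validated model selection, and regressors.

The central evaluation scenario is *cell-blind*: the train and test sets
contain disjoint cell lines, mimicking predictions for a new patient whose
tumour has never been screened.  An entry-level random split is available
as a contrast (known-cell-line scenario); it still keeps the two drug-order
representations (AB/BA) of the same entry on the same side of the split.

All regressors — random forest, elastic net, a small feed-forward network,
and two baselines — share one fit/predict contract, so benchmarking
algorithms-by-encodings is a loop over configurations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import ElasticNet
from sklearn.neural_network import MLPRegressor

from .featurize import (
    CellFeatureModel,
    Dataset,
    DrugEncodingConfig,
    build_dataset,
    fit_cell_features,
)
from .screen import ScreenTable, entry_key_strings

__all__ = [
    "SplitSpec",
    "RegressorSpec",
    "make_split",
    "assign_folds",
    "cross_validate",
    "make_regressor",
    "fit_predict",
    "MeanBaseline",
    "PerTreatmentBaseline",
]

ALGORITHMS = (
    "random_forest",
    "elastic_net",
    "neural_network",
    "mean_baseline",
    "per_treatment_baseline",
)

#: compact default hyperparameter grids, overridable per run
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "random_forest": {"n_estimators": [500], "min_samples_leaf": [1, 5]},
    "elastic_net": {"l1_ratio": [0.1, 0.5, 0.9], "alpha": [0.01, 0.1, 1.0]},
    "neural_network": {"hidden_layer_sizes": [(128,), (256, 128)]},
    "mean_baseline": {},
    "per_treatment_baseline": {},
}


@dataclass
class SplitSpec:
    """How to divide a screen into train and test."""

    mode: str = "cell_blind"      # or "random_entry"
    test_fraction: float = 0.2
    seed: int = 0
    fold_count: int = 5

    def __post_init__(self) -> None:
        if self.mode not in ("cell_blind", "random_entry"):
            raise ValueError(f"unknown split mode {self.mode!r}")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")


@dataclass
class RegressorSpec:
    """Algorithm plus hyperparameter grid and (after CV) the selection."""

    algorithm: str
    grid: dict[str, list] = field(default_factory=dict)
    selected: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if not self.grid:
            self.grid = {k: list(v) for k, v in DEFAULT_GRIDS[self.algorithm].items()}

    def candidates(self) -> list[dict]:
        if not self.grid:
            return [{}]
        names = list(self.grid)
        return [dict(zip(names, combo)) for combo in product(*(self.grid[n] for n in names))]


def make_split(table: ScreenTable, spec: SplitSpec) -> tuple[pd.Index, pd.Index]:
    """Split a screen table into train/test row indices.

    ``cell_blind`` assigns whole cell lines to one side; ``random_entry``
    splits at the level of canonical entry keys, so the AB and BA encodings
    of one combination entry can never straddle the split.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    df = table.df
    if spec.mode == "cell_blind":
        cells = np.array(sorted(df["cell_line"].unique()))
        if len(cells) < 2:
            raise ValueError("cell-blind split needs at least 2 cell lines")
        rng.shuffle(cells)
        n_test = max(1, round(spec.test_fraction * len(cells)))
        if n_test >= len(cells):
            n_test = len(cells) - 1
        test_cells = set(cells[:n_test])
        mask = df["cell_line"].isin(test_cells).to_numpy()
    else:
        keys = entry_key_strings(df).to_numpy()
        uniq = np.unique(keys)
        rng.shuffle(uniq)
        n_test = max(1, round(spec.test_fraction * len(uniq)))
        test_keys = set(uniq[:n_test])
        mask = np.array([k in test_keys for k in keys])
    return df.index[~mask], df.index[mask]


def assign_folds(cells, fold_count: int, seed: int) -> dict[str, int]:
    """Partition cell lines into ``fold_count`` disjoint folds."""
    cells = np.array(sorted(set(cells)))
    if fold_count < 2 or fold_count > len(cells):
        raise ValueError("fold_count must be in [2, n_cells]")
    rng = np.random.default_rng(seed)
    rng.shuffle(cells)
    return {c: i % fold_count for i, c in enumerate(cells)}


class MeanBaseline:
    """Predicts the global mean of the training targets."""

    def fit(self, X, y, provenance=None):
        self.mean_ = float(np.mean(y))
        return self

    def predict(self, X, provenance=None):
        return np.full(len(X), self.mean_)


class PerTreatmentBaseline:
    """Predicts the training-mean inhibition per drug / drug combination.

    Monotherapies get the mean over that drug's monotherapy entries;
    combinations the mean over that unordered pair's entries.  Treatments
    unseen in training fall back to the global mean (counted, not fatal).
    """

    def fit(self, X, y, provenance: pd.DataFrame = None):
        if provenance is None:
            raise ValueError("per-treatment baseline needs provenance (treatment labels)")
        self.global_mean_ = float(np.mean(y))
        self.means_ = (
            pd.Series(np.asarray(y), index=provenance["treatment"].to_numpy())
            .groupby(level=0)
            .mean()
            .to_dict()
        )
        return self

    def predict(self, X, provenance: pd.DataFrame = None):
        if provenance is None:
            raise ValueError("per-treatment baseline needs provenance (treatment labels)")
        self.n_fallback_ = 0
        out = np.empty(len(provenance))
        for i, t in enumerate(provenance["treatment"].to_numpy()):
            if t in self.means_:
                out[i] = self.means_[t]
            else:
                out[i] = self.global_mean_
                self.n_fallback_ += 1
        return out


def make_regressor(spec: RegressorSpec, params: dict | None = None):
    """Instantiate the backend regressor for one hyperparameter candidate."""
    p = dict(spec.selected or {})
    if params is not None:
        p = dict(params)
    alg = spec.algorithm
    if alg == "random_forest":
        return RandomForestRegressor(
            n_estimators=p.get("n_estimators", 500),
            min_samples_leaf=p.get("min_samples_leaf", 1),
            max_features=p.get("max_features", "sqrt"),
            random_state=spec.seed,
            n_jobs=1,
        )
    if alg == "elastic_net":
        return ElasticNet(
            alpha=p.get("alpha", 0.1),
            l1_ratio=p.get("l1_ratio", 0.5),
            max_iter=p.get("max_iter", 5000),
            random_state=spec.seed,
        )
    if alg == "neural_network":
        return MLPRegressor(
            hidden_layer_sizes=p.get("hidden_layer_sizes", (128,)),
            early_stopping=True,
            max_iter=p.get("max_iter", 300),
            random_state=spec.seed,
        )
    if alg == "mean_baseline":
        return MeanBaseline()
    return PerTreatmentBaseline()


def _fit(model, train: Dataset):
    if isinstance(model, (MeanBaseline, PerTreatmentBaseline)):
        model.fit(train.X, train.y, provenance=train.provenance)
    else:
        model.fit(train.X, train.y)
    return model


def _predict(model, data: Dataset) -> np.ndarray:
    if isinstance(model, (MeanBaseline, PerTreatmentBaseline)):
        return model.predict(data.X, provenance=data.provenance)
    return model.predict(data.X)


def fit_predict(spec: RegressorSpec, train: Dataset, test: Dataset) -> np.ndarray:
    """Fit the selected (or default) model on train, predict on test."""
    params = spec.selected if spec.selected is not None else (spec.candidates() or [{}])[0]
    model = make_regressor(spec, params)
    _fit(model, train)
    pred = _predict(model, test)
    if not np.all(np.isfinite(pred)):
        raise RuntimeError("model produced non-finite predictions")
    return pred


def cross_validate(
    train_table: ScreenTable,
    expression: pd.DataFrame,
    cfg: DrugEncodingConfig,
    spec: SplitSpec,
    reg: RegressorSpec,
    n_components: int,
    duplicate: bool = True,
) -> tuple[RegressorSpec, pd.DataFrame]:
    """Select hyperparameters by 5-fold cell-level CV minimizing MAE.

    Folds partition the *training cell lines*; every entry of a cell line
    lands in that cell's fold.  Within each fold the PCA cell-feature model
    is refit on the fold-training cells only, so no held-out cell leaks
    into the feature space.  The winner is the candidate with the smallest
    MAE averaged over folds; ties break by grid order.  Returns the spec
    with ``selected`` set, plus a tidy table of per-fold MAEs.
    """
    cells = sorted(train_table.df["cell_line"].unique())
    folds = assign_folds(cells, spec.fold_count, spec.seed)
    fold_ids = np.array([folds[c] for c in train_table.df["cell_line"]])
    candidates = reg.candidates()
    records = []
    for k in range(spec.fold_count):
        tr_rows = fold_ids != k
        va_rows = fold_ids == k
        if not va_rows.any() or not tr_rows.any():
            raise ValueError(f"fold {k} is empty")
        tr_tab = ScreenTable(train_table.df[tr_rows].reset_index(drop=True), train_table.scale)
        va_tab = ScreenTable(train_table.df[va_rows].reset_index(drop=True), train_table.scale)
        cell_model = fit_cell_features(
            expression, set(tr_tab.df["cell_line"]), n_components
        )
        dup = duplicate and cfg.order_sensitive
        tr = build_dataset(tr_tab, cell_model, cfg, expression, duplicate=dup)
        va = build_dataset(va_tab, cell_model, cfg, expression, duplicate=dup)
        for ci, params in enumerate(candidates):
            model = _fit(make_regressor(reg, params), tr)
            mae = float(np.mean(np.abs(_predict(model, va) - va.y)))
            records.append({"fold": k, "candidate": ci, "mae": mae, **params})
    table = pd.DataFrame(records)
    mean_mae = table.groupby("candidate")["mae"].mean()
    best = int(mean_mae.index[np.argmin(mean_mae.to_numpy())])
    out = RegressorSpec(reg.algorithm, grid=reg.grid, selected=candidates[best], seed=reg.seed)
    return out, table
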