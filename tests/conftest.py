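import numpy as np
import pandas as pd
import pytest

import combisens as cs
from combisens import modeling as md
from combisens.featurize import DrugEncodingConfig, build_dataset, fit_cell_features


@pytest.fixture(scope="session")
def tiny_world():
    """Small noiseless world for parameter-recovery checks."""
    cfg = cs.SyntheticWorldConfig(
        n_cells=5, n_drugs=6, n_combinations=5, noise_sd=0.0, seed=3
    )
    return cs.generate_world(cfg)


@pytest.fixture(scope="session")
def noisy_world():
    """Replicated world at the default replicate-noise level (sd 7)."""
    cfg = cs.SyntheticWorldConfig(
        n_cells=10, n_drugs=6, n_combinations=6, replicates=3, noise_sd=7.0, seed=11
    )
    return cs.generate_world(cfg)


@pytest.fixture(scope="session")
def benchmark_world():
    """The seeded world used for model-benchmark properties."""
    return cs.generate_world(cs.SyntheticWorldConfig(seed=7))


@pytest.fixture(scope="session")
def benchmark_run(benchmark_world):
    """One cell-blind MACCS train/test run: datasets, forest + baselines.

    Shared session-wide because random-forest training dominates suite
    runtime; all model-comparison properties read from this single run.
    """
    w = benchmark_world
    table = cs.preprocess_screen(
        w.screen, drug_min_entries=1, cells_with_expression=set(w.cells)
    )
    enc = DrugEncodingConfig.build("maccs", w.drugs, feature_table=w.fingerprints)
    spec = md.SplitSpec(seed=7)
    tr_idx, te_idx = md.make_split(table, spec)
    tr = cs.ScreenTable(table.df.loc[tr_idx].reset_index(drop=True), "log1p")
    te = cs.ScreenTable(table.df.loc[te_idx].reset_index(drop=True), "log1p")
    cell_model = fit_cell_features(w.expression, set(tr.df["cell_line"]), 10)
    ds_tr = build_dataset(tr, cell_model, enc, w.expression, duplicate=True)
    ds_tr_nodup = build_dataset(tr, cell_model, enc, w.expression, duplicate=False)
    ds_te = build_dataset(te, cell_model, enc, w.expression, duplicate=True)

    forest = md.RegressorSpec(
        "random_forest",
        grid={"n_estimators": [150], "min_samples_leaf": [5]},
        selected={"n_estimators": 150, "min_samples_leaf": 5},
        seed=7,
    )
    preds = {
        "forest_dup": md.fit_predict(forest, ds_tr, ds_te),
        "forest_nodup": md.fit_predict(forest, ds_tr_nodup, ds_te),
        "mean_baseline": md.fit_predict(md.RegressorSpec("mean_baseline"), ds_tr, ds_te),
        "per_treatment_baseline": md.fit_predict(
            md.RegressorSpec("per_treatment_baseline"), ds_tr, ds_te
        ),
    }
    return {
        "world": w,
        "table": table,
        "train": ds_tr,
        "train_nodup": ds_tr_nodup,
        "test": ds_te,
        "predictions": preds,
    }


@pytest.fixture()
def raw_screen_df():
    """Hand-built raw screen rows exercising every preprocessing branch."""
    rows = [
        # cell, drug_row, drug_col, conc_row, conc_col, inhibition
        ("C1", "A", "B", 1.0, 2.0, 30.0),
        ("C1", "B", "A", 2.0, 1.0, 40.0),      # replicate of the above, swapped
        ("C1", "A", "A", 1.0, 2.0, 30.0),      # same-drug pair -> mono at 3.0
        ("C1", "A", "B", 0.0, 2.0, 25.0),      # one zero conc -> mono of B
        ("C1", "A", None, 1.0, 0.0, 10.0),
        ("C1", "A", None, 1.0, 0.0, 20.0),     # replicate of the mono above
        ("C1", "A", "B", 5.0, 5.0, 250.0),     # quality-filtered (inh > 200)
        ("C1", "A", "B", 0.0, 0.0, 5.0),       # all-zero concentration
        ("C2", "A", None, 1.0, 0.0, 15.0),     # cell without expression
    ]
    return pd.DataFrame(
        rows,
        columns=["cell_line", "drug_row", "drug_col", "conc_row", "conc_col", "inhibition"],
    )
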