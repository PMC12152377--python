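import numpy as np
import pandas as pd
import pytest

import combisens as cs
from combisens.featurize import (
    DrugEncodingConfig,
    EncodingError,
    build_dataset,
    encode_entry,
    fit_cell_features,
)


@pytest.fixture()
def small_expression():
    rng = np.random.default_rng(0)
    return pd.DataFrame(
        rng.standard_normal((50, 8)),
        index=[f"G{i}" for i in range(50)],
        columns=[f"C{i}" for i in range(8)],
    )


class TestCellFeatures:
    def test_duplicate_cells_get_identical_scores(self, small_expression):
        expr = small_expression.copy()
        expr["C1"] = expr["C0"]
        model = fit_cell_features(expr, ["C0", "C1", "C2", "C3"], n_components=3)
        scores = model.transform(expr, ["C0", "C1"])
        assert np.allclose(scores.loc["C0"], scores.loc["C1"])

    def test_low_rank_structure_recovered(self, tiny_world):
        w = tiny_world
        k = w.config.latent_dim
        model = fit_cell_features(w.expression, w.cells, n_components=min(k, len(w.cells) - 1))
        scores = model.transform(w.expression, w.cells).to_numpy()
        total = ((w.expression - w.expression.mean(axis=1).to_numpy()[:, None]) ** 2).to_numpy().sum()
        explained = (scores**2).sum()
        assert explained / total >= 0.95

    def test_centering_independent_of_held_out_cells(self, small_expression):
        m1 = fit_cell_features(small_expression, ["C0", "C1", "C2"], n_components=2)
        m2 = fit_cell_features(
            small_expression[["C0", "C1", "C2", "C7"]], ["C0", "C1", "C2"], n_components=2
        )
        assert np.allclose(m1.gene_means, m2.gene_means)

    def test_too_many_components_rejected(self, small_expression):
        with pytest.raises(ValueError, match="n_components"):
            fit_cell_features(small_expression, ["C0", "C1"], n_components=5)

    def test_loadings_orthonormal(self, small_expression):
        m = fit_cell_features(small_expression, list(small_expression.columns), n_components=4)
        assert np.allclose(m.components @ m.components.T, np.eye(4), atol=1e-10)


@pytest.fixture()
def fp_table():
    return pd.DataFrame(
        [[1, 0, 1, 0], [0, 1, 1, 0], [1, 1, 0, 0]],
        index=["A", "B", "C"],
        columns=["b0", "b1", "b2", "b3"],
    )


class TestEncodings:
    def test_constant_fingerprint_columns_dropped(self, fp_table):
        cfg = DrugEncodingConfig.build("maccs", ["A", "B", "C"], feature_table=fp_table)
        assert cfg.block_width == 3  # b3 constant across drugs
        assert cfg.n_drug_features == 2 * 3 + 2

    def test_onehot_sets_log_concentration(self):
        cfg = DrugEncodingConfig.build("onehot", ["A", "B", "C"])
        cell = np.zeros(2)
        vec = encode_entry(cell, cfg, "A", "C", 0.7, 1.1)
        drug_block = vec[2:]
        assert drug_block.tolist() == [0.7, 0.0, 1.1]

    def test_onehottar_counts_shared_targets(self):
        cfg = DrugEncodingConfig.build(
            "onehottar",
            ["A", "B"],
            targets={"A": {"m1", "m2"}, "B": {"m1"}},
            min_target_degree=1,
        )
        vec = encode_entry(np.zeros(0), cfg, "A", "B", 0.5, 0.5)
        target_block = vec[2:]
        # m1 targeted by both drugs -> 2; m2 by one -> 1
        assert dict(zip(cfg.target_index, target_block)) == {"m1": 2.0, "m2": 1.0}

    def test_target_degree_threshold(self):
        cfg = DrugEncodingConfig.build(
            "onehottar",
            ["A", "B", "C"],
            targets={"A": {"m1"}, "B": {"m1"}, "C": {"m2"}},
            min_target_degree=2,
        )
        assert cfg.target_index == ["m1"]

    def test_maccs_monotherapy_zeroes_second_block(self, fp_table):
        cfg = DrugEncodingConfig.build("maccs", ["A", "B", "C"], feature_table=fp_table)
        vec = encode_entry(np.zeros(1), cfg, "A", None, 0.9, 0.0)
        w = cfg.block_width
        second = vec[1 + w + 1:]
        assert np.all(second == 0)

    def test_ab_ba_blocks_swapped(self, fp_table):
        cfg = DrugEncodingConfig.build("maccs", ["A", "B", "C"], feature_table=fp_table)
        ab = encode_entry(np.zeros(1), cfg, "A", "B", 0.5, 0.8, order="AB")
        ba = encode_entry(np.zeros(1), cfg, "A", "B", 0.5, 0.8, order="BA")
        w = cfg.block_width
        assert np.allclose(ab[1 : 1 + w + 1], ba[1 + w + 1 :])
        assert np.allclose(ab[1 + w + 1 :], ba[1 : 1 + w + 1])
        assert np.allclose(ab[:1], ba[:1])  # cell features identical

    def test_unknown_drug_named_in_error(self, fp_table):
        cfg = DrugEncodingConfig.build("maccs", ["A", "B", "C"], feature_table=fp_table)
        with pytest.raises(EncodingError, match="ZZZ"):
            encode_entry(np.zeros(1), cfg, "ZZZ", None, 0.5, 0.0)


class TestBuildDataset:
    @pytest.fixture()
    def world_bits(self, tiny_world):
        w = tiny_world
        table = cs.preprocess_screen(
            w.screen, drug_min_entries=1, cells_with_expression=set(w.cells)
        )
        model = fit_cell_features(w.expression, w.cells, n_components=4)
        return w, table, model

    def test_duplication_counts(self, world_bits):
        w, table, model = world_bits
        cfg = DrugEncodingConfig.build("maccs", w.drugs, feature_table=w.fingerprints)
        n_mono = int(table.is_mono.sum())
        n_combo = len(table) - n_mono
        dup = build_dataset(table, model, cfg, w.expression, duplicate=True)
        nodup = build_dataset(table, model, cfg, w.expression, duplicate=False)
        assert len(dup) == n_mono + 2 * n_combo
        assert len(nodup) == n_mono + n_combo

    def test_duplicate_pairs_share_target(self, world_bits):
        w, table, model = world_bits
        cfg = DrugEncodingConfig.build("maccs", w.drugs, feature_table=w.fingerprints)
        ds = build_dataset(table, model, cfg, w.expression, duplicate=True)
        prov = ds.provenance
        combos = prov[~prov["is_mono"]]
        y = pd.Series(ds.y[combos.index], index=combos["entry_key"].to_numpy())
        spread = y.groupby(level=0).agg(lambda s: s.max() - s.min())
        assert (spread == 0).all()

    def test_onehot_duplication_warns_and_noop(self, world_bits):
        w, table, model = world_bits
        cfg = DrugEncodingConfig.build("onehot", w.drugs)
        with pytest.warns(UserWarning, match="order-free"):
            ds = build_dataset(table, model, cfg, w.expression, duplicate=True)
        assert len(ds) == len(table)

    def test_requires_log1p_scale(self, world_bits):
        w, _, model = world_bits
        cfg = DrugEncodingConfig.build("onehot", w.drugs)
        with pytest.raises(EncodingError, match="log1p"):
            build_dataset(w.screen, model, cfg, w.expression, duplicate=False)
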