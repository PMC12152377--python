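"""Model inputs: PCA cell-line features and four drug/concentration encodings.

Cell lines are represented by principal-component scores of their gene
expression profile; the PCA is always fitted on training cells only so that
held-out (test) cell lines never influence the feature space — the contract
that makes cell-blind evaluation honest.

Drugs and concentrations enter the model through one of four encodings:

* ``onehot`` — one feature per known drug, set to the log1p-scaled
  concentration when that drug is part of the entry, else 0;
* ``onehottar`` — the onehot block plus one count feature per target
  molecule (how many drugs of the entry hit that target: 0, 1 or 2);
* ``maccs`` — two binary substructure-fingerprint blocks, each followed by
  its drug's concentration;
* ``physchem`` — like ``maccs`` but with numeric physico-chemical
  descriptor blocks.

The fingerprint/descriptor encodings are order-sensitive: the same
combination can be written drug-A-first or drug-B-first.  Such entries are
therefore duplicated in both orders when building datasets, so models learn
that the two representations mean the same treatment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .screen import ScreenTable, entry_key_strings

__all__ = [
    "CellFeatureModel",
    "DrugEncodingConfig",
    "EncodingError",
    "Dataset",
    "fit_cell_features",
    "encode_entry",
    "build_dataset",
]

SETTINGS = ("onehot", "onehottar", "maccs", "physchem")


class EncodingError(ValueError):
    """Raised when an entry cannot be encoded (unknown drug, wrong scale)."""


@dataclass
class CellFeatureModel:
    """PCA projection of gene expression, fitted on training cells only."""

    training_cell_ids: frozenset
    gene_index: pd.Index
    gene_means: np.ndarray          # per-gene centering vector, training cells only
    components: np.ndarray          # n_components x n_genes, orthonormal rows
    n_components: int

    def transform(self, expression: pd.DataFrame, cells=None) -> pd.DataFrame:
        """Project cells (columns of a genes x cells matrix) onto the PCs."""
        if cells is not None:
            expression = expression[list(cells)]
        mat = expression.loc[self.gene_index].to_numpy(dtype=float).T
        scores = (mat - self.gene_means) @ self.components.T
        return pd.DataFrame(
            scores,
            index=expression.columns,
            columns=[f"PC{i + 1}" for i in range(self.n_components)],
        )


def fit_cell_features(
    expression: pd.DataFrame,
    training_cells,
    n_components: int = 300,
) -> CellFeatureModel:
    """Fit the PCA cell-feature model on the training cell lines.

    ``expression`` is a genes x cells DataFrame.  Centering uses per-gene
    means over training cells only; no per-gene scaling is applied (the
    source expression data is assumed pre-normalized).

    Parameters
    ----------
    n_components:
        Number of principal components retained (default 300, suited to
        genome-wide expression; reduce for small synthetic inputs).
    """
    training_cells = sorted(set(training_cells))
    missing = [c for c in training_cells if c not in expression.columns]
    if missing:
        raise ValueError(f"training cells missing from expression matrix: {missing}")
    max_rank = min(len(training_cells), expression.shape[0])
    if n_components > max_rank:
        raise ValueError(
            f"n_components={n_components} exceeds min(n_training_cells, n_genes)={max_rank}"
        )
    train = expression[training_cells].to_numpy(dtype=float).T  # cells x genes
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(train)
    return CellFeatureModel(
        training_cell_ids=frozenset(training_cells),
        gene_index=expression.index,
        gene_means=train.mean(axis=0),
        components=pca.components_,
        n_components=n_components,
    )


@dataclass
class DrugEncodingConfig:
    """Frozen description of one drug-encoding setting.

    Feature layout for the fingerprint/descriptor settings is
    ``[drug1 block | conc1 | drug2 block | conc2]``; for the one-hot
    settings it is ``[per-drug concentration slots | target counts]``.
    """

    setting: str
    drug_index: list[str] = field(default_factory=list)
    target_index: list[str] = field(default_factory=list)
    targets: dict[str, frozenset] = field(default_factory=dict)  # drug -> molecules
    feature_table: pd.DataFrame | None = None  # drugs x features (maccs/physchem)
    min_target_degree: int = 5

    def __post_init__(self) -> None:
        if self.setting not in SETTINGS:
            raise ValueError(f"unknown setting {self.setting!r}; choose from {SETTINGS}")

    @property
    def order_sensitive(self) -> bool:
        return self.setting in ("maccs", "physchem")

    @property
    def block_width(self) -> int:
        """Width of one drug's feature block (excluding its concentration)."""
        if self.feature_table is None:
            raise ValueError(f"setting {self.setting!r} has no per-drug feature block")
        return self.feature_table.shape[1]

    @property
    def n_drug_features(self) -> int:
        if self.setting == "onehot":
            return len(self.drug_index)
        if self.setting == "onehottar":
            return len(self.drug_index) + len(self.target_index)
        return 2 * self.block_width + 2

    @classmethod
    def build(
        cls,
        setting: str,
        drugs,
        targets: dict | None = None,
        feature_table: pd.DataFrame | None = None,
        min_target_degree: int = 5,
    ) -> "DrugEncodingConfig":
        """Construct a config from raw annotation tables.

        For ``onehottar``, only molecules targeted by at least
        ``min_target_degree`` of the supplied drugs become features.  For
        ``maccs``/``physchem``, columns constant across the supplied drugs
        are dropped, so block widths are data-dependent.
        """
        drug_index = sorted(set(drugs))
        target_index: list[str] = []
        target_map: dict[str, frozenset] = {}
        table = None
        if setting == "onehottar":
            if targets is None:
                raise ValueError("onehottar requires a drug->targets mapping")
            target_map = {d: frozenset(targets.get(d, ())) for d in drug_index}
            degree: dict[str, int] = {}
            for mols in target_map.values():
                for m in mols:
                    degree[m] = degree.get(m, 0) + 1
            target_index = sorted(m for m, n in degree.items() if n >= min_target_degree)
        elif setting in ("maccs", "physchem"):
            if feature_table is None:
                raise ValueError(f"{setting} requires a drug feature table")
            table = feature_table.loc[
                [d for d in feature_table.index if d in set(drug_index)]
            ].astype(float)
            keep = table.columns[table.nunique() > 1]
            table = table[keep]
        return cls(
            setting=setting,
            drug_index=drug_index,
            target_index=target_index,
            targets=target_map,
            feature_table=table,
            min_target_degree=min_target_degree,
        )

    def drug_block(self, drug: str) -> np.ndarray:
        cache = self.__dict__.setdefault("_block_cache", {})
        if drug not in cache:
            try:
                cache[drug] = self.feature_table.loc[drug].to_numpy(dtype=float)
            except KeyError:
                raise EncodingError(f"no {self.setting} features for drug {drug!r}")
        return cache[drug]


def encode_entry(
    cell_features: np.ndarray,
    cfg: DrugEncodingConfig,
    drug_row: str,
    drug_col: str | None,
    conc_row: float,
    conc_col: float,
    order: str = "AB",
) -> np.ndarray:
    """Encode one entry as ``[cell PCs | drug features]``.

    Concentrations must already be log1p-scaled.  ``order="BA"`` swaps the
    two drug blocks (meaningful only for the order-sensitive settings).
    """
    if order not in ("AB", "BA"):
        raise ValueError("order must be 'AB' or 'BA'")
    if cfg.setting in ("onehot", "onehottar"):
        pos = {d: i for i, d in enumerate(cfg.drug_index)}
        vec = np.zeros(cfg.n_drug_features)
        for drug, conc in ((drug_row, conc_row), (drug_col, conc_col)):
            if drug is None:
                continue
            if drug not in pos:
                raise EncodingError(f"drug {drug!r} not in the one-hot drug index")
            vec[pos[drug]] = conc
        if cfg.setting == "onehottar":
            tpos = {t: i for i, t in enumerate(cfg.target_index)}
            off = len(cfg.drug_index)
            for drug in (drug_row, drug_col):
                if drug is None:
                    continue
                for mol in cfg.targets.get(drug, ()):  # count 0, 1 or 2
                    if mol in tpos:
                        vec[off + tpos[mol]] += 1
        return np.concatenate([cell_features, vec])

    width = cfg.block_width
    first = (cfg.drug_block(drug_row), conc_row)
    if drug_col is None:
        second = (np.zeros(width), 0.0)
    else:
        second = (cfg.drug_block(drug_col), conc_col)
    if order == "BA":
        first, second = second, first
    vec = np.concatenate([first[0], [first[1]], second[0], [second[1]]])
    return np.concatenate([cell_features, vec])


@dataclass
class Dataset:
    """Model-ready samples with per-sample provenance.

    ``provenance`` has one row per sample: the canonical entry key, the
    cell line, the treatment label (drug, or lexicographically sorted
    ``drugA+drugB``), a monotherapy flag and the drug-order flag
    (``AB``/``BA``).
    """

    X: np.ndarray
    y: np.ndarray
    provenance: pd.DataFrame

    def __len__(self) -> int:
        return len(self.y)

    def subset(self, mask) -> "Dataset":
        mask = np.asarray(mask)
        return Dataset(
            self.X[mask], self.y[mask], self.provenance.iloc[mask].reset_index(drop=True)
        )


def treatment_labels(df: pd.DataFrame) -> pd.Series:
    """Treatment id per entry: the drug name, or ``A+B`` sorted for pairs."""
    labels = []
    for row, col in zip(df["drug_row"], df["drug_col"]):
        if col is None or (isinstance(col, float) and np.isnan(col)):
            labels.append(str(row))
        else:
            labels.append("+".join(sorted((str(row), str(col)))))
    return pd.Series(labels, index=df.index)


def build_dataset(
    table: ScreenTable,
    cell_model: CellFeatureModel,
    cfg: DrugEncodingConfig,
    expression: pd.DataFrame,
    duplicate: bool = True,
) -> Dataset:
    """Encode a preprocessed screen table into a model-ready dataset.

    With ``duplicate=True`` under an order-sensitive setting, every
    combination entry contributes two samples (drug orders AB and BA) with
    the same target; monotherapies always contribute one sample.  For the
    order-free one-hot settings duplication is a no-op (warned).
    """
    if table.scale != "log1p":
        raise EncodingError("table must be preprocessed (log1p scale) before encoding")
    if duplicate and not cfg.order_sensitive:
        warnings.warn(
            f"setting {cfg.setting!r} is order-free; duplication has no effect",
            stacklevel=2,
        )
        duplicate = False

    df = table.df
    cells = sorted(df["cell_line"].unique())
    cell_feats = cell_model.transform(expression, cells)
    keys = entry_key_strings(df)
    labels = treatment_labels(df)

    cell_feat_map = {c: cell_feats.loc[c].to_numpy() for c in cells}
    keys_arr = keys.to_numpy()
    labels_arr = labels.to_numpy()

    rows_X: list[np.ndarray] = []
    rows_y: list[float] = []
    prov: list[tuple] = []
    cols = df[["cell_line", "drug_row", "drug_col", "conc_row", "conc_col", "inhibition"]]
    for i, (cell, drug_row, drug_col, conc_row, conc_col, inh) in enumerate(
        cols.itertuples(index=False, name=None)
    ):
        cf = cell_feat_map[cell]
        is_mono = drug_col is None or (isinstance(drug_col, float) and np.isnan(drug_col))
        if is_mono:
            drug_col = None
        orders = ("AB", "BA") if (duplicate and not is_mono) else ("AB",)
        for order in orders:
            rows_X.append(
                encode_entry(cf, cfg, drug_row, drug_col, conc_row, conc_col, order)
            )
            rows_y.append(inh)
            prov.append((keys_arr[i], cell, labels_arr[i], is_mono, order))
    provenance = pd.DataFrame(
        prov, columns=["entry_key", "cell_line", "treatment", "is_mono", "order"]
    )
    return Dataset(np.asarray(rows_X), np.asarray(rows_y, dtype=float), provenance)
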