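"""Combination-screen tables: data model, I/O and preprocessing.

A screen table holds one row per dose-response measurement:
``(cell_line, drug_row, drug_col, conc_row, conc_col, inhibition)``.
Concentrations are micromolar; ``drug_col`` is absent (``None``) for
monotherapies, in which case ``conc_col`` is 0.  Relative inhibition is a
percent-like quantity: positive values denote growth reduction relative to
the untreated control, negative values denote increased growth; quality
filtering bounds it to [-200, 200].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SCREEN_COLUMNS",
    "ScreenTable",
    "CMaxTable",
    "ScreenFormatError",
    "read_screen_table",
    "write_screen_table",
    "preprocess_screen",
    "replicate_noise_summary",
    "canonical_keys",
]

SCREEN_COLUMNS = (
    "cell_line",
    "drug_row",
    "drug_col",
    "conc_row",
    "conc_col",
    "inhibition",
)

#: tokens accepted as "no second drug" on read; written back as "NULL"
ABSENT_TOKENS = frozenset({"NULL", "", "NA"})


class ScreenFormatError(ValueError):
    """Raised for malformed screen files (missing columns, bad numerics)."""


@dataclass
class ScreenTable:
    """An ordered collection of screen entries plus the concentration scale.

    ``scale`` records whether log1p has been applied to the concentration
    columns, so that double normalization can be refused.
    """

    df: pd.DataFrame
    scale: str = "raw"  # "raw" (micromolar) or "log1p"

    def __post_init__(self) -> None:
        missing = [c for c in SCREEN_COLUMNS if c not in self.df.columns]
        if missing:
            raise ScreenFormatError(f"missing screen column(s): {missing}")
        if self.scale not in ("raw", "log1p"):
            raise ValueError(f"unknown concentration scale: {self.scale!r}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def is_mono(self) -> pd.Series:
        return self.df["drug_col"].isna()

    def copy(self) -> "ScreenTable":
        return ScreenTable(self.df.copy(), self.scale)


@dataclass
class CMaxTable:
    """Peak plasma concentration (CMax, in µM) per drug.

    CMax is the peak plasma concentration reached after administering the
    highest clinically recommended dose; it anchors the clinically
    achievable part of the concentration range.
    """

    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for drug, cmax in self.values.items():
            if not np.isfinite(cmax) or cmax <= 0:
                raise ValueError(f"CMax for {drug!r} must be finite and > 0, got {cmax}")

    def __contains__(self, drug: str) -> bool:
        return drug in self.values

    def __getitem__(self, drug: str) -> float:
        return self.values[drug]

    @classmethod
    def from_csv(cls, path) -> "CMaxTable":
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise ScreenFormatError("CMax table needs a drug column and a value column")
        return cls(dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float))))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"drug": list(self.values), "cmax": list(self.values.values())}
        ).to_csv(path, index=False)


def read_screen_table(path, sep: str = "\t") -> ScreenTable:
    """Read a raw screen table (DrugComb-style export) from TSV/CSV.

    ``drug_col`` values of ``NULL``, ``NA`` or empty string are treated as
    absent (monotherapy).  Returns the table unfiltered, in raw µM scale,
    preserving row order.  A missing column raises :class:`ScreenFormatError`;
    an unparseable numeric raises one naming the offending line.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in SCREEN_COLUMNS if c not in df.columns]
    if missing:
        raise ScreenFormatError(f"missing screen column(s): {missing}")
    df = df[list(SCREEN_COLUMNS)].copy()
    df["drug_col"] = df["drug_col"].map(
        lambda s: None if s.strip() in ABSENT_TOKENS else s
    )
    for col in ("conc_row", "conc_col", "inhibition"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & (df[col].astype(str).str.strip() != "")
        bad |= df[col].astype(str).str.strip() == ""
        if bad.any():
            # +2: header line plus 1-based numbering
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise ScreenFormatError(
                f"unparseable value {df[col].iloc[line - 2]!r} in column "
                f"{col!r} at line {line}"
            )
        df[col] = vals.astype(float)
    if df["inhibition"].isna().any():
        raise ScreenFormatError("NaN inhibition values are not allowed")
    df = df.reset_index(drop=True)
    return ScreenTable(df, scale="raw")


def write_screen_table(table: ScreenTable, path, sep: str = "\t") -> None:
    """Write a screen table; absent ``drug_col`` is emitted as ``NULL``."""
    out = table.df.copy()
    out["drug_col"] = out["drug_col"].map(lambda d: "NULL" if d is None or (isinstance(d, float) and np.isnan(d)) else d)
    out.to_csv(path, sep=sep, index=False)


def canonical_keys(df: pd.DataFrame) -> pd.DataFrame:
    """Canonical replicate key per entry: drugs ordered lexicographically.

    Concentrations follow their drugs during reordering, so ``(A, B, 1, 2)``
    and ``(B, A, 2, 1)`` map to the same key.  Monotherapies keep the empty
    string in the second drug slot.
    """
    d_row = df["drug_row"].astype(str).to_numpy()
    d_col = df["drug_col"].map(lambda d: "" if d is None else str(d)).to_numpy()
    c_row = df["conc_row"].to_numpy(dtype=float)
    c_col = df["conc_col"].to_numpy(dtype=float)
    swap = (d_col != "") & (d_col < d_row)
    drug_a = np.where(swap, d_col, d_row)
    drug_b = np.where(swap, d_row, d_col)
    conc_a = np.where(swap, c_col, c_row)
    conc_b = np.where(swap, c_row, c_col)
    return pd.DataFrame(
        {
            "cell_line": df["cell_line"].to_numpy(),
            "drug_a": drug_a,
            "drug_b": drug_b,
            "conc_a": conc_a,
            "conc_b": conc_b,
        },
        index=df.index,
    )


def entry_key_strings(df: pd.DataFrame) -> pd.Series:
    """Stable string form of the canonical key, usable as a provenance id."""
    keys = canonical_keys(df)
    return (
        keys["cell_line"].astype(str)
        + "|" + keys["drug_a"]
        + "|" + keys["drug_b"]
        + "|" + keys["conc_a"].map("{:.10g}".format)
        + "|" + keys["conc_b"].map("{:.10g}".format)
    )


def preprocess_screen(
    table: ScreenTable,
    drug_min_entries: int = 10_000,
    cells_with_expression: set[str] | None = None,
) -> ScreenTable:
    """Apply the full screen-cleaning pipeline, returning a new table.

    Steps, in order:

    1. drop entries with inhibition outside [-200, 200] (quality filter);
    2. drop entries where every tested concentration is 0;
    3. drop entries whose cell line has no expression profile;
    4. merge same-drug "pairs" into monotherapies by summing concentrations;
    5. rewrite two-drug entries where only one concentration is positive
       as monotherapies of the active drug;
    6. average inhibition over replicates sharing the canonical
       (cell, unordered drug pair, concentration pair) key;
    7. log1p-transform both concentration columns;
    8. keep only drugs appearing in at least ``drug_min_entries`` entries.

    The defaults mirror a large public screen corpus (entry threshold
    10,000); pass a smaller threshold for small synthetic screens.
    """
    if table.scale != "raw":
        raise ValueError("table is already log1p-scaled; refusing to normalize twice")
    df = table.df.copy()

    # (1) quality filter on inhibition
    df = df[(df["inhibition"] >= -200) & (df["inhibition"] <= 200)]
    # (2) all-zero concentrations carry no treatment
    df = df[~((df["conc_row"] == 0) & (df["conc_col"] == 0))]
    # (3) cell lines without expression cannot be featurized
    if cells_with_expression is not None:
        df = df[df["cell_line"].isin(cells_with_expression)]

    # (4) same drug in both slots: one treatment at the summed concentration
    same = df["drug_col"].notna() & (df["drug_col"] == df["drug_row"])
    df.loc[same, "conc_row"] = df.loc[same, "conc_row"] + df.loc[same, "conc_col"]
    df.loc[same, "conc_col"] = 0.0
    df.loc[same, "drug_col"] = None

    # (5) two drugs but one at zero concentration: actually a monotherapy
    col_only = df["drug_col"].notna() & (df["conc_row"] == 0) & (df["conc_col"] > 0)
    df.loc[col_only, "drug_row"] = df.loc[col_only, "drug_col"]
    df.loc[col_only, "conc_row"] = df.loc[col_only, "conc_col"]
    row_only = df["drug_col"].notna() & (df["conc_col"] == 0)
    df.loc[col_only | row_only, "conc_col"] = 0.0
    df.loc[col_only | row_only, "drug_col"] = None

    # (6) replicate averaging over the canonical key
    keys = canonical_keys(df)
    df = df.assign(
        _ca=keys["conc_a"], _cb=keys["conc_b"], _da=keys["drug_a"], _db=keys["drug_b"]
    )
    grouped = (
        df.groupby(["cell_line", "_da", "_db", "_ca", "_cb"], sort=False)["inhibition"]
        .mean()
        .reset_index()
    )
    out = pd.DataFrame(
        {
            "cell_line": grouped["cell_line"],
            "drug_row": grouped["_da"],
            "drug_col": grouped["_db"].map(lambda d: None if d == "" else d),
            "conc_row": grouped["_ca"],
            "conc_col": grouped["_cb"],
            "inhibition": grouped["inhibition"],
        }
    )

    # (7) log1p concentration normalization
    out["conc_row"] = np.log1p(out["conc_row"])
    out["conc_col"] = np.log1p(out["conc_col"])

    # (8) drop sparsely screened drugs (single pass, after all other filters)
    counts: dict[str, int] = {}
    for col in ("drug_row", "drug_col"):
        for drug, n in out[col].value_counts(dropna=True).items():
            counts[drug] = counts.get(drug, 0) + int(n)
    keep = {d for d, n in counts.items() if n >= drug_min_entries}
    mask = out["drug_row"].isin(keep) & (
        out["drug_col"].isna() | out["drug_col"].isin(keep)
    )
    out = out[mask].reset_index(drop=True)
    return ScreenTable(out, scale="log1p")


def replicate_noise_summary(table: ScreenTable) -> dict | None:
    """Mean and median replicate standard deviation, or None without replicates.

    For every canonical key measured at least twice, the sample standard
    deviation of the inhibitions is computed; the summary reports the mean
    and median of those per-key standard deviations together with the number
    of replicated keys.
    """
    keys = canonical_keys(table.df)
    df = table.df.assign(
        _ca=keys["conc_a"], _cb=keys["conc_b"], _da=keys["drug_a"], _db=keys["drug_b"]
    )
    sds = (
        df.groupby(["cell_line", "_da", "_db", "_ca", "_cb"], sort=False)["inhibition"]
        .agg(["std", "count"])
    )
    sds = sds[sds["count"] >= 2]["std"]
    if sds.empty:
        return None
    return {
        "mean_sd": float(sds.mean()),
        "median_sd": float(sds.median()),
        "n_replicated_keys": int(len(sds)),
    }
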