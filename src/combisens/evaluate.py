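"""Performance metrics and statistical comparisons for inhibition predictions.

Besides the usual overall MAE / Pearson correlation / R², this module
computes *per-treatment* correlations: because different drugs and
combinations have systematically different mean inhibitions, a correlation
over the pooled test set is inflated — even constant per-treatment
predictions correlate with the truth.  Per-drug / per-combination PCCs
remove that between-treatment component and measure whether a model can
rank cell lines within one treatment.

Approach comparisons use paired two-sided Wilcoxon signed-rank tests on
per-sample absolute errors, Bonferroni-adjusted over all pairwise tests,
with a signed effect size r = Z / sqrt(n).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "summarize_errors",
    "duplicate_agreement",
    "compare_approaches",
    "ComparisonResult",
    "DEFAULT_INTERVAL_EDGES",
]

#: half-open (lo, hi] inhibition intervals used for range stratification
DEFAULT_INTERVAL_EDGES = (-25.0, 0.0, 25.0, 50.0, 75.0, 100.0)


def _pcc(actual: np.ndarray, predicted: np.ndarray) -> float:
    """Pearson correlation; NaN (undefined) when either vector is constant."""
    if len(actual) < 2 or np.ptp(actual) == 0 or np.ptp(predicted) == 0:
        return float("nan")
    return float(stats.pearsonr(actual, predicted)[0])


def _metrics(actual: np.ndarray, predicted: np.ndarray) -> dict:
    err = predicted - actual
    ss_tot = float(np.sum((actual - actual.mean()) ** 2))
    r2 = float("nan") if ss_tot == 0 else 1.0 - float(np.sum(err**2)) / ss_tot
    return {
        "n": int(len(actual)),
        "mae": float(np.mean(np.abs(err))),
        "pcc": _pcc(actual, predicted),
        "r2": r2,
    }


def summarize_errors(
    actual,
    predicted,
    grouping: str = "none",
    provenance: pd.DataFrame | None = None,
    interval_edges=DEFAULT_INTERVAL_EDGES,
) -> pd.DataFrame:
    """Metric table (MAE, PCC, R²) overall or per group.

    ``grouping`` is one of ``none``, ``per_drug`` (monotherapy samples,
    grouped by drug), ``per_combination`` (combination samples, grouped by
    pair) or ``per_interval`` (all samples, stratified by the half-open
    actual-inhibition interval (lo, hi]).  Group rows are followed by a
    ``__macro__`` row averaging the per-group metrics; groups whose PCC is
    undefined (constant actuals) are excluded from the macro PCC and
    counted in ``n_undefined_pcc``.
    """
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.size == 0:
        raise ValueError("empty input")
    if actual.shape != predicted.shape:
        raise ValueError("actual and predicted must have equal length")

    if grouping == "none":
        return pd.DataFrame([{"group": "__all__", **_metrics(actual, predicted)}])

    if provenance is None:
        raise ValueError(f"grouping={grouping!r} requires provenance")
    if grouping in ("per_drug", "per_combination"):
        want_mono = grouping == "per_drug"
        mask = provenance["is_mono"].to_numpy() == want_mono
        keys = provenance["treatment"].to_numpy()[mask]
        a, p = actual[mask], predicted[mask]
    elif grouping == "per_interval":
        edges = np.asarray(interval_edges, dtype=float)
        idx = np.searchsorted(edges, actual, side="left") - 1
        valid = (idx >= 0) & (idx < len(edges) - 1)
        labels = np.array(
            [f"({edges[i]:g},{edges[i+1]:g}]" for i in range(len(edges) - 1)]
        )
        keys = labels[idx[valid]]
        a, p = actual[valid], predicted[valid]
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    rows = []
    for g in sorted(set(keys)):
        m = keys == g
        rows.append({"group": g, **_metrics(a[m], p[m])})
    table = pd.DataFrame(rows)
    defined = table["pcc"].notna()
    macro = {
        "group": "__macro__",
        "n": int(table["n"].sum()),
        "mae": float(table["mae"].mean()),
        "pcc": float(table.loc[defined, "pcc"].mean()) if defined.any() else float("nan"),
        "r2": float(table["r2"].mean()),
        "n_undefined_pcc": int((~defined).sum()),
    }
    return pd.concat([table, pd.DataFrame([macro])], ignore_index=True)


def duplicate_agreement(predictions: pd.DataFrame) -> dict:
    """Agreement between the AB and BA predictions of the same entries.

    ``predictions`` needs columns ``entry_key``, ``order`` ("AB"/"BA") and
    ``prediction``; every entry key must appear once per order.  Returns
    the Pearson correlation between the two prediction vectors and the
    mean absolute difference.
    """
    piv = predictions.pivot(index="entry_key", columns="order", values="prediction")
    if "AB" not in piv.columns or "BA" not in piv.columns or piv.isna().any().any():
        missing = piv.index[piv.isna().any(axis=1)].tolist() if not piv.empty else []
        raise ValueError(f"entries without both AB and BA predictions: {missing[:10]}")
    ab = piv["AB"].to_numpy()
    ba = piv["BA"].to_numpy()
    return {
        "pcc": _pcc(ab, ba),
        "mean_abs_difference": float(np.mean(np.abs(ab - ba))),
        "n_entries": int(len(piv)),
    }


@dataclass
class ComparisonResult:
    """One paired Wilcoxon comparison of two approaches' absolute errors."""

    approach_a: str
    approach_b: str
    p_raw: float
    p_adjusted: float
    r: float          # signed effect size; negative = a has smaller errors
    n_tests: int


def compare_approaches(error_sets: dict[str, np.ndarray]) -> list[ComparisonResult]:
    """All pairwise paired Wilcoxon signed-rank tests on absolute errors.

    Every vector must be aligned on the same test samples.  P-values are
    Bonferroni-adjusted by the number of pairs, capped at 1.  The effect
    size r is the standardized test statistic divided by sqrt(number of
    non-zero pairs), signed by the direction of the median difference
    (negative when the first approach has smaller errors).  Zero
    differences are dropped before ranking; a comparison of identical
    vectors reports p = NaN and r = 0.
    """
    names = list(error_sets)
    lengths = {len(np.asarray(v)) for v in error_sets.values()}
    if len(lengths) != 1:
        raise ValueError("error vectors must be key-aligned (equal lengths)")
    pairs = list(combinations(names, 2))
    n_tests = len(pairs)
    results = []
    for a, b in pairs:
        da = np.asarray(error_sets[a], dtype=float)
        db = np.asarray(error_sets[b], dtype=float)
        diff = da - db
        nz = diff != 0
        n_nz = int(nz.sum())
        if n_nz == 0:
            results.append(ComparisonResult(a, b, float("nan"), float("nan"), 0.0, n_tests))
            continue
        res = stats.wilcoxon(
            da[nz], db[nz], zero_method="wilcox", alternative="two-sided", method="approx"
        )
        z = float(abs(res.zstatistic))
        sign = -1.0 if np.median(diff[nz]) < 0 else 1.0
        if np.median(diff[nz]) == 0:
            sign = float(np.sign(np.mean(diff[nz]))) or 1.0
        r = sign * z / np.sqrt(n_nz)
        p_raw = float(res.pvalue)
        results.append(
            ComparisonResult(a, b, p_raw, min(1.0, p_raw * n_tests), float(r), n_tests)
        )
    return results
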