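"""Per-cell-line treatment rankings from (combination) CMax viabilities.

For personalized prioritization each cell line gets a list of treatments
ordered from most to least effective, i.e. from smallest to largest
(combination) CMax viability.  Predicted rankings are scored against
actual rankings by Spearman correlation, top-k overlap, the rank each
list's best treatment attains in the other, and the actual-viability gap
between the predicted-best and the actual-best treatment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["TreatmentRanking", "build_ranking", "score_rankings"]


@dataclass
class TreatmentRanking:
    """Treatments of one cell line, ascending by viability (best first)."""

    cell_line: str
    items: list[tuple[str, float]]
    scope: str = "mono_plus_combo"  # or "mono_only"
    n_excluded: int = 0             # records dropped for undefined viability

    @property
    def treatments(self) -> list[str]:
        return [t for t, _ in self.items]

    def viability(self, treatment: str) -> float:
        for t, v in self.items:
            if t == treatment:
                return v
        raise KeyError(treatment)

    def __len__(self) -> int:
        return len(self.items)


def build_ranking(
    records: dict[str, float | None], cell_line: str, scope: str = "mono_plus_combo"
) -> TreatmentRanking:
    """Rank treatments of one cell line by viability, ascending.

    ``records`` maps treatment identifier to a viability in [0, 1] (or
    None/NaN for undefined, which is excluded and counted).  Ties break
    lexicographically by treatment identifier, making the order
    deterministic.
    """
    kept = {
        t: float(v)
        for t, v in records.items()
        if v is not None and np.isfinite(v)
    }
    items = sorted(kept.items(), key=lambda tv: (tv[1], tv[0]))
    return TreatmentRanking(
        cell_line=cell_line,
        items=items,
        scope=scope,
        n_excluded=len(records) - len(kept),
    )


def score_rankings(
    actual: TreatmentRanking, predicted: TreatmentRanking, ks=(5, 10)
) -> dict:
    """Score a predicted ranking against the actual one.

    Returns Spearman correlation between the two viability orderings
    (average ranks for ties), the top-k overlap |top-k(actual) ∩
    top-k(predicted)| for each k, the 1-based rank of the actually best
    treatment in the predicted list (and vice versa; average rank under
    viability ties), and the viability gap: actual viability of the
    predicted-best treatment minus the actual minimum (always >= 0).
    """
    ta, tp = set(actual.treatments), set(predicted.treatments)
    if ta != tp:
        raise ValueError(
            f"treatment sets differ; only in actual: {sorted(ta - tp)[:5]}, "
            f"only in predicted: {sorted(tp - ta)[:5]}"
        )
    order = sorted(ta)
    va = np.array([actual.viability(t) for t in order])
    vp = np.array([predicted.viability(t) for t in order])
    scc = float(stats.spearmanr(va, vp)[0]) if len(order) > 1 else float("nan")

    ranks_pred = stats.rankdata(vp)  # 1-based, average for ties
    ranks_act = stats.rankdata(va)
    best_actual = actual.treatments[0]
    best_pred = predicted.treatments[0]
    i_best_actual = order.index(best_actual)
    i_best_pred = order.index(best_pred)

    out = {
        "scc": scc,
        "rank_of_actual_best_in_predicted": float(ranks_pred[i_best_actual]),
        "rank_of_predicted_best_in_actual": float(ranks_act[i_best_pred]),
        "viability_gap": float(va[i_best_pred] - va.min()),
        "n_treatments": len(order),
    }
    for k in ks:
        top_a = set(actual.treatments[:k])
        top_p = set(predicted.treatments[:k])
        out[f"overlap@{k}"] = len(top_a & top_p)
    return out
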