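"""Run aggregation and the Friedman rank analysis of competing optimizers.

A "case" is one (image, K) combination; each algorithm gets a rank per case
(1 = best, ties averaged), and the Friedman statistic

    χ² = 12·n / (A(A+1)) · Σ_j (R̄_j − (A+1)/2)²

over n cases and A algorithms tests whether the mean ranks R̄_j differ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

#: columns identifying one benchmark cell
CELL_KEYS = ["image", "channel", "objective", "K", "algorithm"]


def aggregate_runs(results: pd.DataFrame, metrics: list[str] | None = None) -> pd.DataFrame:
    """Mean and sample (n−1) standard deviation per benchmark cell.

    ``results`` must carry the ``CELL_KEYS`` columns plus a ``run`` column
    and one column per metric.  Raises ``ValueError`` on empty input or
    cells with fewer than two runs.
    """
    if results.empty:
        raise ValueError("no results to aggregate")
    metrics = metrics or [
        c for c in results.columns if c not in CELL_KEYS + ["run", "seed", "thresholds"]
    ]
    counts = results.groupby(CELL_KEYS, sort=True).size()
    if (counts < 2).any():
        bad = counts[counts < 2].index[0]
        raise ValueError(f"cell {bad} has fewer than 2 runs; cannot compute STD")
    agg = results.groupby(CELL_KEYS, sort=True)[metrics].agg(["mean", "std"])
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    return agg.reset_index()


def friedman_rank(scores: np.ndarray | dict[str, float], higher_is_better: bool = True):
    """Within-case ranks: 1 = best; ties get the average of tied positions."""
    if isinstance(scores, dict):
        names = list(scores)
        vals = np.asarray([scores[k] for k in names], dtype=float)
        ranks = sps.rankdata(-vals if higher_is_better else vals)
        return dict(zip(names, ranks))
    vals = np.asarray(scores, dtype=float)
    return sps.rankdata(-vals if higher_is_better else vals)


@dataclass(frozen=True)
class RankTable:
    """Friedman summary: per-case ranks, rank sums, mean and final ranks."""

    algorithms: list[str]
    case_ranks: pd.DataFrame     # one row per case, one column per algorithm
    rank_sum: pd.Series
    mean_rank: pd.Series
    final_rank: pd.Series        # ordinal; ties share the better ordinal
    chi2: float
    p_value: float

    @property
    def n_cases(self) -> int:
        return len(self.case_ranks)


def friedman_summary(
    case_scores: pd.DataFrame, higher_is_better: bool = True
) -> RankTable:
    """Friedman analysis of a cases × algorithms score table.

    Every row of ``case_scores`` is one case (e.g. one image × K); columns
    are algorithms.  NaNs are rejected — every case must rank the same
    algorithm set.
    """
    if case_scores.isna().any().any():
        raise ValueError("every case must score every algorithm")
    A = case_scores.shape[1]
    if A < 2:
        raise ValueError("need at least two algorithms")
    ranks = case_scores.apply(
        lambda row: pd.Series(
            friedman_rank(row.to_numpy(), higher_is_better), index=row.index
        ),
        axis=1,
    )
    rank_sum = ranks.sum(axis=0)
    mean_rank = rank_sum / len(ranks)
    # ordinal final ranks; tied mean ranks share the better (smaller) ordinal
    final = pd.Series(
        sps.rankdata(mean_rank.to_numpy(), method="min"), index=mean_rank.index
    )
    n = len(ranks)
    chi2 = float(12.0 * n / (A * (A + 1)) * ((mean_rank - (A + 1) / 2.0) ** 2).sum())
    p = float(sps.chi2.sf(chi2, df=A - 1))
    return RankTable(
        algorithms=list(case_scores.columns),
        case_ranks=ranks,
        rank_sum=rank_sum,
        mean_rank=mean_rank,
        final_rank=final,
        chi2=chi2,
        p_value=p,
    )
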