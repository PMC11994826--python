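"""Benchmark harness: repeated runs of pluggable optimizers + Friedman ranks.

An optimizer is any callable ``(hist, k, objective, cfg, seed) ->
(ThresholdVector, fitness)``.  The harness runs every registered optimizer
over every image × K × run, scores the class-mean reconstructions with
RMSE/PSNR/SSIM, and ranks the algorithms per case with the Friedman
analysis.  Only the RSA-Gbest method and a same-budget random-search
baseline ship built in; external optimizers plug in through the registry.
"""

from __future__ import annotations

from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .histograms import ChannelHistogram, image_histograms, split_channels
from .metrics import apply_thresholds, evaluate_segmentation
from .objectives import ObjectiveEvaluator, ThresholdVector
from .rsa import OptimizerConfig, decode_thresholds, optimize
from .stats import RankTable, aggregate_runs, friedman_summary

Optimizer = Callable[..., tuple[ThresholdVector, float]]


def rsa_optimizer(h, k, objective, cfg: OptimizerConfig, seed: int):
    tv, sc, _ = optimize(h, k, objective, cfg, seed=seed)
    return tv, sc


def random_search_optimizer(h, k, objective, cfg: OptimizerConfig, seed: int):
    """Uniform random search with the same evaluation budget as one RSA run."""
    rng = np.random.default_rng(seed)
    ev = ObjectiveEvaluator(h, objective)
    budget = cfg.population * cfg.iterations
    best_tv, best_sc = None, -np.inf
    for _ in range(budget):
        pos = rng.random(k) * 254.0 + 1.0
        tv = decode_thresholds(pos)
        sc = ev(tv.values)
        if sc > best_sc:
            best_tv, best_sc = tv, sc
    return best_tv, float(best_sc)


BUILTIN_OPTIMIZERS: dict[str, Optimizer] = {
    "rsa": rsa_optimizer,
    "random": random_search_optimizer,
}

RESULT_COLUMNS = [
    "image", "channel", "objective", "K", "algorithm", "run", "seed",
    "thresholds", "fitness", "rmse", "psnr", "ssim",
]


def run_benchmark(
    images: Mapping[str, np.ndarray],
    ks: Sequence[int],
    objectives: Sequence[str] = ("otsu",),
    optimizers: Mapping[str, Optimizer] | None = None,
    cfg: OptimizerConfig | None = None,
    runs: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Full factorial benchmark; returns the long-format results table.

    Run seeds are drawn once from ``seed`` and shared across algorithms so
    every algorithm sees the same sequence of independent restarts.
    """
    cfg = cfg or OptimizerConfig()
    runs = runs if runs is not None else cfg.runs
    optimizers = dict(optimizers or {"rsa": rsa_optimizer})
    root = np.random.default_rng(seed)
    run_seeds = [int(s) for s in root.integers(0, 2**31 - 1, size=runs)]
    records = []
    for name, img in images.items():
        channels = split_channels(img)
        hists = image_histograms(img)
        for hist, chan in zip(hists, channels):
            for objective in objectives:
                for k in ks:
                    for algo, fn in optimizers.items():
                        for run, s in enumerate(run_seeds):
                            tv, fitness = fn(hist, k, objective, cfg, s)
                            rep = evaluate_segmentation(chan, apply_thresholds(chan, tv))
                            records.append({
                                "image": name,
                                "channel": hist.channel,
                                "objective": objective,
                                "K": k,
                                "algorithm": algo,
                                "run": run,
                                "seed": s,
                                "thresholds": " ".join(map(str, tv.values)),
                                "fitness": fitness,
                                "rmse": rep.rmse,
                                "psnr": rep.psnr,
                                "ssim": rep.ssim,
                            })
    return pd.DataFrame.from_records(records, columns=RESULT_COLUMNS)


def rank_benchmark(
    results: pd.DataFrame, metric: str = "psnr", objective: str | None = None
) -> RankTable:
    """Friedman ranking over cases = image × channel × K (mean over runs)."""
    df = results
    if objective is not None:
        df = df[df["objective"] == objective]
    mean_scores = (
        df.groupby(["image", "channel", "K", "algorithm"])[metric]
        .mean()
        .unstack("algorithm")
    )
    return friedman_summary(mean_scores, higher_is_better=True)


def summarize_benchmark(results: pd.DataFrame) -> pd.DataFrame:
    """Mean/STD per cell, Tables-style."""
    return aggregate_runs(results, metrics=["fitness", "rmse", "psnr", "ssim"])
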