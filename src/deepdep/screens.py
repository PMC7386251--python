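"""Dependency labels from cell-line loss-of-function screens.

Screen metrics differ in direction: lower CERES (CRISPR) and zGARP (shRNA)
scores mean stronger essentiality, while higher BAGEL scores do.  Cutoffs are
inclusive on the dependency side (score <= cutoff for CERES/zGARP, >= for
BAGEL).  Balanced training sets are formed by sampling the same number of
independency cases uniformly from the other (strict) side of the cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

METRICS = {"CERES": "low", "zGARP": "low", "BAGEL": "high"}

LABEL_COLUMNS = ["gene", "cell_line", "label", "score", "metric"]


@dataclass
class ScreenScoreTable:
    """A gene x cell-line grid of dependency scores for one metric."""

    scores: pd.DataFrame
    metric: str

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}; expected one of {sorted(METRICS)}")

    def melt(self) -> pd.DataFrame:
        long = self.scores.stack().rename("score").reset_index()
        long.columns = ["gene", "cell_line", "score"]
        return long


def _dependent_mask(long: pd.DataFrame, metric: str, cutoff: float) -> pd.Series:
    if METRICS[metric] == "low":
        return long["score"] <= cutoff
    return long["score"] >= cutoff


def label_dependencies(table: ScreenScoreTable, cutoff: float) -> pd.DataFrame:
    """Positive (dependency) labels at the given cutoff; missing scores excluded."""
    long = table.melt()
    dep = long[_dependent_mask(long, table.metric, cutoff)].copy()
    dep["label"] = 1
    dep["metric"] = table.metric
    return dep[LABEL_COLUMNS].reset_index(drop=True)


def sample_independencies(
    table: ScreenScoreTable, cutoff: float, n: int, seed: int
) -> pd.DataFrame:
    """Draw ``n`` independency cases uniformly without replacement.

    Candidates are the (gene, cell line) pairs strictly on the non-dependent
    side of the cutoff (above it for CERES/zGARP, below for BAGEL).
    """
    long = table.melt()
    candidates = long[~_dependent_mask(long, table.metric, cutoff)].reset_index(drop=True)
    if n > len(candidates):
        raise ValueError(
            f"requested {n} independencies but only {len(candidates)} candidates available"
        )
    rng = np.random.default_rng(seed)
    picked = candidates.iloc[np.sort(rng.choice(len(candidates), size=n, replace=False))].copy()
    picked["label"] = 0
    picked["metric"] = table.metric
    return picked[LABEL_COLUMNS].reset_index(drop=True)


def balanced_labels(
    table: ScreenScoreTable, cutoff: float, seed: int, per_cell_line: bool = False
) -> pd.DataFrame:
    """Dependencies at the cutoff plus an equal number of sampled independencies.

    Balancing is global by default; with ``per_cell_line`` each cell line
    contributes as many independencies as it has dependencies.
    """
    pos = label_dependencies(table, cutoff)
    if not per_cell_line:
        neg = sample_independencies(table, cutoff, n=len(pos), seed=seed)
        return pd.concat([pos, neg], ignore_index=True)
    parts = [pos]
    for i, (cell, n_pos) in enumerate(pos.groupby("cell_line").size().items()):
        sub = ScreenScoreTable(scores=table.scores[[cell]], metric=table.metric)
        parts.append(sample_independencies(sub, cutoff, n=int(n_pos), seed=seed + i))
    return pd.concat(parts, ignore_index=True)


def merge_screens(tables: list[ScreenScoreTable], cutoffs: list[float]) -> pd.DataFrame:
    """Union of per-table positive labels.

    Duplicate (gene, cell line) pairs are deduplicated; a pair called a
    dependency by any source stays a dependency.
    """
    if len(tables) != len(cutoffs):
        raise ValueError("need one cutoff per table")
    parts = [label_dependencies(t, c) for t, c in zip(tables, cutoffs)]
    merged = pd.concat(parts, ignore_index=True)
    merged = merged.sort_values("label", ascending=False).drop_duplicates(
        subset=["gene", "cell_line"], keep="first"
    )
    return merged.sort_values(["gene", "cell_line"]).reset_index(drop=True)


def drop_cell_lines_without_expression(
    table: ScreenScoreTable, expression_samples: set[str]
) -> ScreenScoreTable:
    """Remove screened cell lines that have no expression profile (reported)."""
    keep = [c for c in table.scores.columns if c in expression_samples]
    dropped = set(table.scores.columns) - set(keep)
    if dropped:
        logger.info("dropped %d cell line(s) without expression: %s", len(dropped), sorted(dropped))
    return ScreenScoreTable(scores=table.scores[keep], metric=table.metric)
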