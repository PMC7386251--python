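"""Scoring clinical samples and calling tumor-specific dependencies.

Tumor and matched-normal transcriptomes are perturbed gene by gene and each
perturbed profile is scored by the trained classifier(s); a gene is called a
tumor-specific vulnerability for a donor when the tumor prediction score
exceeds 0.5 while the matched-normal score stays below 0.5 (strict on both
sides).  Differential dependency is the tumor score minus the normal score.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .network import RegulatoryNetwork
from .perturb import PerturbationConfig, ReferenceCorrelations, perturb_cohort
from .training import TrainedModel, predict_score

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = ["sample", "donor", "role"]  # role in {"tumor", "normal"}
SCORE_COLUMNS = ["sample", "gene", "score"]


def score_cohort(
    models: TrainedModel | Sequence[TrainedModel],
    net: RegulatoryNetwork,
    corr: Optional[ReferenceCorrelations],
    expr: pd.DataFrame,
    cfg: PerturbationConfig,
    targets: Optional[list[str]] = None,
) -> pd.DataFrame:
    """One dependency score per (sample, eligible target); deterministic order."""
    cohort = perturb_cohort(net, corr, expr, cfg, targets=targets)
    if not cohort.profiles:
        logger.warning("no eligible targets produced any perturbed profile")
        return pd.DataFrame(columns=SCORE_COLUMNS)
    profiles = cohort.to_frame()
    scores = predict_score(models, profiles)
    out = profiles.index.to_frame(index=False)
    out.columns = ["sample", "gene"]
    out["score"] = scores
    return out


def combine_screening_models(
    scores_a: pd.DataFrame, scores_b: pd.DataFrame
) -> pd.DataFrame:
    """Arithmetic mean of two screening models' scores (e.g. CRISPR and RNAi).

    Only (sample, gene) pairs scored by both models are kept; combination
    happens before any thresholding.
    """
    merged = scores_a.merge(scores_b, on=["sample", "gene"], suffixes=("_a", "_b"))
    merged["score"] = (merged["score_a"] + merged["score_b"]) / 2.0
    return merged[SCORE_COLUMNS]


def _paired(scores: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    """Inner-join tumor and normal scores per (donor, gene)."""
    meta = manifest[MANIFEST_COLUMNS]
    merged = scores.merge(meta, on="sample")
    tumor = merged[merged["role"] == "tumor"][["donor", "gene", "score"]]
    normal = merged[merged["role"] == "normal"][["donor", "gene", "score"]]
    donors_without_normal = set(tumor["donor"]) - set(normal["donor"])
    if donors_without_normal:
        logger.info(
            "skipped %d donor(s) without a matched normal: %s",
            len(donors_without_normal),
            sorted(donors_without_normal),
        )
    return tumor.merge(normal, on=["donor", "gene"], suffixes=("_tumor", "_normal"))


def call_tumor_specific(
    scores: pd.DataFrame, manifest: pd.DataFrame, threshold: float = 0.5
) -> pd.DataFrame:
    """Per-donor tumor-specific vulnerability calls.

    A gene is called when tumor score > threshold and normal score <
    threshold, both strict; a score equal to the threshold is excluded on
    both sides.
    """
    pairs = _paired(scores, manifest)
    called = pairs[
        (pairs["score_tumor"] > threshold) & (pairs["score_normal"] < threshold)
    ]
    return called[["donor", "gene"]].sort_values(["donor", "gene"]).reset_index(drop=True)


def differential_dependency(scores: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    """Tumor score minus matched-normal score per (donor, gene)."""
    pairs = _paired(scores, manifest)
    pairs["diff"] = pairs["score_tumor"] - pairs["score_normal"]
    return pairs[["donor", "gene", "diff"]].reset_index(drop=True)


def recurrence_summary(
    calls: pd.DataFrame, scores: pd.DataFrame, manifest: pd.DataFrame
) -> pd.Series:
    """Per-gene fraction of donors in which the gene was called, sorted descending.

    The denominator per gene counts donors with both a tumor and a normal
    score for that gene.
    """
    pairs = _paired(scores, manifest)
    n_donors = pairs.groupby("gene")["donor"].nunique()
    n_called = calls.groupby("gene")["donor"].nunique() if len(calls) else pd.Series(dtype=int)
    frac = (n_called.reindex(n_donors.index, fill_value=0) / n_donors).astype(float)
    frac.name = "fraction_of_donors"
    return frac.sort_values(ascending=False, kind="stable")


def dependent_group_expression(
    scores: pd.DataFrame,
    expr: pd.DataFrame,
    gene: str,
    threshold: float = 0.5,
    p_threshold: float = 0.005,
    top: int = 100,
) -> pd.DataFrame:
    """Genes overexpressed in samples dependent on ``gene``.

    Samples are split by whether their prediction score for ``gene`` exceeds
    ``threshold``; each expression row is tested with a two-sample t test in
    the dependent > non-dependent direction, filtered at ``p_threshold``, and
    the most significant ``top`` genes are returned (ranked by p value).
    Genes with degenerate variance in both groups are skipped.
    """
    gene_scores = scores[scores["gene"] == gene].set_index("sample")["score"]
    dep_samples = [s for s in expr.columns if gene_scores.get(s, np.nan) > threshold]
    other_samples = [s for s in expr.columns if s in gene_scores.index and s not in dep_samples]
    if len(dep_samples) < 2 or len(other_samples) < 2:
        raise ValueError("need >= 2 samples in each of the dependent/non-dependent groups")
    a = expr[dep_samples].to_numpy(dtype=float)
    b = expr[other_samples].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1)
    rows = pd.DataFrame({"gene": expr.index, "t": t, "p": p})
    rows = rows[np.isfinite(rows["t"])]  # degenerate-variance genes dropped
    rows = rows[(rows["t"] > 0) & (rows["p"] < p_threshold)]
    return rows.sort_values(["p", "gene"]).head(top).reset_index(drop=True)
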