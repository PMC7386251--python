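"""In silico CRISPR/RNAi: simulated gene suppression on a regulatory network.

Suppressing a target gene Y in a basal transcriptome reduces its expression
from y to y' (y' = 0 for CRISPR knockout; y' = 0.2*y for RNAi knockdown, the
average experimental shRNA efficacy).  The effect is propagated downstream:

* correlation rule (directed, e.g. Bayesian, networks): every descendant j of
  Y (any gene reachable via outgoing links) is adjusted as::

      x'_j = x_j - r_j * ((y - y') / y) * x_j

  where r_j is the Pearson correlation of X_j and Y across reference samples
  (the same panel used for network construction).

* conditional rule (oriented coexpression networks): only the direct (one-hop)
  regulatory targets of Y are adjusted, using the edge's regulation type and
  the winning conditional probability p::

      x'_j = x_j - p * ((y - y') / y) * x_j     (activation)
      x'_j = x_j + p * ((y - y') / y) * x_j     (inhibition)

All other genes keep their basal values exactly.  The correlation rule has an
equivalent matrix form P = -k (R . B) + diag(B) used for whole-cohort runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd

from . import network as nw
from .network import RegulatoryNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PerturbationConfig:
    """Mode and propagation rule for one in silico perturbation run."""

    mode: str = "crispr"  # "crispr" | "rnai"
    residual_fraction: Optional[float] = None  # default set by mode
    network_rule: str = "correlation"  # "correlation" | "conditional"

    def __post_init__(self) -> None:
        if self.mode not in ("crispr", "rnai"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.network_rule not in ("correlation", "conditional"):
            raise ValueError(f"unknown network rule {self.network_rule!r}")
        if self.residual_fraction is None:
            object.__setattr__(
                self, "residual_fraction", 0.0 if self.mode == "crispr" else 0.2
            )
        if not 0.0 <= self.residual_fraction < 1.0:
            raise ValueError("residual_fraction must lie in [0, 1)")

    @property
    def knockdown_factor(self) -> float:
        """k = (y - y') / y = 1 - residual_fraction."""
        return 1.0 - self.residual_fraction


@dataclass
class PerturbedProfile:
    """One expression vector after simulated suppression of one target gene."""

    target: str
    values: pd.Series  # same gene universe as the basal sample
    sample_id: str = ""
    config: Optional[PerturbationConfig] = None


@dataclass
class ReferenceCorrelations:
    """Pearson r between each eligible target and each of its descendants."""

    by_target: dict[str, pd.Series]  # target -> r indexed by descendant gene

    def get(self, target: str) -> pd.Series:
        return self.by_target[target]

    @property
    def targets(self) -> list[str]:
        return sorted(self.by_target)


def reference_correlations(
    net: RegulatoryNetwork,
    reference_expr: pd.DataFrame,
    targets: Optional[Iterable[str]] = None,
) -> ReferenceCorrelations:
    """Pearson correlations of each target with its descendants over the reference panel.

    Constant genes get r = 0 with a warning; genes absent from the expression
    panel are skipped and logged.  ``targets`` defaults to every network gene
    with expression and at least one descendant.
    """
    if reference_expr.shape[1] < 3:
        raise ValueError("reference panel must have >= 3 samples")
    genes = reference_expr.index
    gene_pos = {g: i for i, g in enumerate(genes)}
    arr = reference_expr.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    centered = arr - mean
    norms = np.sqrt((centered**2).sum(axis=1))
    constant = norms == 0
    if constant.any():
        logger.warning("%d constant gene(s); their correlations are set to 0", constant.sum())
    safe_norms = np.where(constant, 1.0, norms)
    z = centered / safe_norms[:, None]  # unit-norm rows; r = z_i . z_j

    if targets is None:
        targets = nw.eligible_targets(net, set(genes), min_downstream=1)
    by_target: dict[str, pd.Series] = {}
    n_skipped = 0
    for t in sorted(targets):
        if t not in gene_pos:
            n_skipped += 1
            continue
        desc = sorted(nw.descendants(net, t))
        desc_present = [d for d in desc if d in gene_pos]
        n_skipped += len(desc) - len(desc_present)
        if not desc_present:
            by_target[t] = pd.Series(dtype=float)
            continue
        ti = gene_pos[t]
        di = [gene_pos[d] for d in desc_present]
        r = z[di] @ z[ti]
        if constant[ti]:
            r = np.zeros_like(r)
        r[constant[di]] = 0.0
        by_target[t] = pd.Series(np.clip(r, -1.0, 1.0), index=desc_present)
    if n_skipped:
        logger.info("skipped %d gene pair(s) absent from expression", n_skipped)
    return ReferenceCorrelations(by_target=by_target)


def _check_nonnegative(values: pd.Series, target: str) -> None:
    bad = values.min()
    if bad < -1e-9:
        raise AssertionError(
            f"perturbation of {target!r} produced negative expression ({bad:.3g})"
        )


def perturb_correlation(
    net: RegulatoryNetwork,
    corr: ReferenceCorrelations,
    basal: pd.Series,
    target: str,
    cfg: PerturbationConfig,
    sample_id: str = "",
) -> PerturbedProfile:
    """Apply the correlation rule for one target on one basal sample."""
    y = float(basal.loc[target])
    if y <= 0:
        raise ValueError(f"target {target!r} has basal expression {y}; knockdown undefined")
    k = cfg.knockdown_factor
    values = basal.astype(float).copy()
    r = corr.get(target)
    common = r.index.intersection(values.index)
    values.loc[common] = values.loc[common] * (1.0 - r.loc[common] * k)
    values.loc[target] = cfg.residual_fraction * y
    _check_nonnegative(values, target)
    return PerturbedProfile(target=target, values=values, sample_id=sample_id, config=cfg)


def perturb_matrix(
    net: RegulatoryNetwork,
    corr: ReferenceCorrelations,
    basal: pd.Series,
    cfg: PerturbationConfig,
    targets: Optional[list[str]] = None,
    sample_id: str = "",
) -> pd.DataFrame:
    """Matrix form of the correlation rule for all targets at once.

    Row i of the returned targets x genes frame is ``perturb_correlation`` for
    target i: P = -k (R . B) + diag(B) broadcast, where R holds 1 on the
    diagonal and r(i, j) at descendant positions (0 elsewhere) and B is the
    diagonal basal expression matrix.  Under RNAi the scalar -k is the
    familiar -0.8 (residual fraction 0.2).
    """
    if targets is None:
        targets = [t for t in corr.targets if t in basal.index and basal.loc[t] > 0]
    genes = basal.index
    gene_pos = {g: i for i, g in enumerate(genes)}
    x = basal.to_numpy(dtype=float)
    k = cfg.knockdown_factor
    R = np.zeros((len(targets), len(genes)))
    for i, t in enumerate(targets):
        y = float(basal.loc[t])
        if y <= 0:
            raise ValueError(f"target {t!r} has basal expression {y}; knockdown undefined")
        r = corr.get(t)
        for d, rv in r.items():
            j = gene_pos.get(d)
            if j is not None:
                R[i, j] = rv
        R[i, gene_pos[t]] = 1.0
    P = -k * (R * x[None, :]) + x[None, :]
    out = pd.DataFrame(P, index=pd.Index(targets, name="target"), columns=genes)
    if out.to_numpy().min() < -1e-9:
        raise AssertionError("matrix perturbation produced negative expression")
    return out


def perturb_conditional(
    oriented_net: RegulatoryNetwork,
    basal: pd.Series,
    target: str,
    cfg: PerturbationConfig,
    sample_id: str = "",
) -> PerturbedProfile:
    """Apply the conditional-probability rule (strictly one hop) for one target.

    The oriented network's edges must carry a sign and a weight (the winning
    activator/inhibitor conditional probability from orientation).
    """
    if not oriented_net.directed:
        raise ValueError("conditional rule requires an oriented (directed) network")
    y = float(basal.loc[target])
    if y <= 0:
        raise ValueError(f"target {target!r} has basal expression {y}; knockdown undefined")
    succ = list(oriented_net.graph.successors(target))
    if not succ:
        raise ValueError(f"target {target!r} has no regulatory targets")
    k = cfg.knockdown_factor
    values = basal.astype(float).copy()
    for j in succ:
        if j not in values.index:
            continue
        data = oriented_net.graph.edges[target, j]
        sign, p = data.get("sign"), data.get("weight")
        if sign not in ("activation", "inhibition") or p is None:
            raise ValueError(f"edge {target}->{j} lacks orientation sign/probability")
        if sign == "activation":
            values.loc[j] = values.loc[j] - p * k * values.loc[j]
        else:
            values.loc[j] = values.loc[j] + p * k * values.loc[j]
    values.loc[target] = cfg.residual_fraction * y
    _check_nonnegative(values, target)
    return PerturbedProfile(target=target, values=values, sample_id=sample_id, config=cfg)


@dataclass
class CohortPerturbation:
    """Batch result: one perturbed profile per (sample, eligible target)."""

    profiles: list[PerturbedProfile] = field(default_factory=list)
    skipped: list[tuple[str, str, str]] = field(default_factory=list)  # sample, target, reason

    def to_frame(self) -> pd.DataFrame:
        """Stack profiles into a (sample, target) x genes frame."""
        if not self.profiles:
            return pd.DataFrame()
        idx = pd.MultiIndex.from_tuples(
            [(p.sample_id, p.target) for p in self.profiles], names=["sample", "target"]
        )
        return pd.DataFrame([p.values for p in self.profiles], index=idx)


def perturb_cohort(
    net: RegulatoryNetwork,
    corr: Optional[ReferenceCorrelations],
    expr: pd.DataFrame,
    cfg: PerturbationConfig,
    targets: Optional[list[str]] = None,
) -> CohortPerturbation:
    """Run in silico perturbation for every sample (column) and eligible target.

    Ordering is deterministic: samples in column order, targets sorted.
    Per-target failures (e.g. zero basal expression) are collected into the
    ``skipped`` report rather than aborting the batch.
    """
    if cfg.network_rule == "correlation":
        if corr is None:
            raise ValueError("correlation rule requires reference correlations")
        all_targets = corr.targets if targets is None else sorted(targets)
    else:
        if targets is None:
            all_targets = sorted(
                nw.eligible_targets(net, set(expr.index), min_downstream=1, count="targets")
            )
        else:
            all_targets = sorted(targets)

    result = CohortPerturbation()
    for sample in expr.columns:
        basal = expr[sample]
        for t in all_targets:
            if t not in basal.index:
                result.skipped.append((sample, t, "no expression"))
                continue
            try:
                if cfg.network_rule == "correlation":
                    prof = perturb_correlation(net, corr, basal, t, cfg, sample_id=sample)
                else:
                    prof = perturb_conditional(net, basal, t, cfg, sample_id=sample)
            except ValueError as exc:
                result.skipped.append((sample, t, str(exc)))
                continue
            result.profiles.append(prof)
    if result.skipped:
        logger.info("perturb_cohort skipped %d (sample, target) pair(s)", len(result.skipped))
    return result
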