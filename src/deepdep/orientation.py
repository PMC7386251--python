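"""Orientation of undirected coexpression links by conditional probability.

Coexpression networks (e.g. ARACNe output) report that two genes interact but
not which one regulates the other, nor whether the interaction activates or
inhibits.  Both are inferred here from a reference expression panel:

1. Each gene is discretized per reference sample into ``up`` (expression above
   mu + sigma), ``down`` (below mu - sigma) or ``mid``, where mu and sigma are
   the gene's mean and standard deviation across the reference panel.
2. For a candidate pair (X, Y) four conditional probabilities are estimated as
   sample frequencies, e.g.::

       P(X = activator) = [P(Y=up & X=up) + P(Y=down & X=down)]
                          / [P(X=up) + P(X=down)]

   and symmetrically for the inhibitor role and for Y.
3. X is considered a regulatory *target* of Y when
   P(X=activator) + P(X=inhibitor) < P(Y=activator) + P(Y=inhibitor); the
   regulation type of the retained link is activation when the winner's
   activator probability exceeds its inhibitor probability, inhibition when
   smaller.  Exact ties (direction or sign) leave the edge unoriented and it
   is dropped, for determinism.

Probabilities are pure frequency ratios over the reference panel; no
smoothing is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import RegulatoryNetwork, from_edges

logger = logging.getLogger(__name__)

UP, MID, DOWN = 1, 0, -1


@dataclass
class DiscretizedExpression:
    """Per-sample up/mid/down states with the defining per-gene mu and sigma."""

    states: pd.DataFrame  # genes x samples, values in {UP, MID, DOWN}
    mu: pd.Series
    sigma: pd.Series

    @property
    def genes(self) -> pd.Index:
        return self.states.index


@dataclass
class EdgeOrientationStats:
    """The four conditional probabilities for a candidate pair (X, Y)."""

    p_x_activator: float
    p_y_activator: float
    p_x_inhibitor: float
    p_y_inhibitor: float

    def __post_init__(self) -> None:
        for name in ("p_x_activator", "p_y_activator", "p_x_inhibitor", "p_y_inhibitor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0 + 1e-12:
                raise ValueError(f"{name}={v} outside [0, 1]")

    def swapped(self) -> "EdgeOrientationStats":
        """The same pair with the X/Y roles exchanged."""
        return EdgeOrientationStats(
            p_x_activator=self.p_y_activator,
            p_y_activator=self.p_x_activator,
            p_x_inhibitor=self.p_y_inhibitor,
            p_y_inhibitor=self.p_x_inhibitor,
        )


def discretize(reference_expr: pd.DataFrame, drop_missing: bool = False) -> DiscretizedExpression:
    """Discretize a genes x samples reference panel into up/mid/down states.

    Standard deviation uses the population convention (ddof=0).  A gene with
    constant expression (sigma = 0) is ``mid`` in every sample.
    """
    if reference_expr.shape[1] < 2:
        raise ValueError("discretize requires >= 2 reference samples")
    if reference_expr.isna().any().any():
        if not drop_missing:
            raise ValueError("missing values in reference expression (set drop_missing=True)")
        reference_expr = reference_expr.dropna(axis=0)
    mu = reference_expr.mean(axis=1)
    sigma = reference_expr.std(axis=1, ddof=0)
    arr = reference_expr.to_numpy(dtype=float)
    up = arr > (mu + sigma).to_numpy()[:, None]
    down = arr < (mu - sigma).to_numpy()[:, None]
    states = np.where(up, UP, np.where(down, DOWN, MID)).astype(np.int8)
    return DiscretizedExpression(
        states=pd.DataFrame(states, index=reference_expr.index, columns=reference_expr.columns),
        mu=mu,
        sigma=sigma,
    )


def edge_stats(disc: DiscretizedExpression, x: str, y: str) -> EdgeOrientationStats:
    """Estimate the four activator/inhibitor probabilities for genes x and y.

    Frequencies are taken over reference samples; a zero denominator (gene
    never leaves the mid state) yields probability 0 with a warning.
    """
    sx = disc.states.loc[x].to_numpy()
    sy = disc.states.loc[y].to_numpy()

    def _pair(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
        # roles: probabilities that gene a is an activator/inhibitor of gene b
        denom = int(np.sum(a != MID))
        if denom == 0:
            logger.warning("zero denominator in edge stats (gene never up or down)")
            return 0.0, 0.0
        agree = int(np.sum((b == UP) & (a == UP)) + np.sum((b == DOWN) & (a == DOWN)))
        oppose = int(np.sum((b == DOWN) & (a == UP)) + np.sum((b == UP) & (a == DOWN)))
        return agree / denom, oppose / denom

    p_x_act, p_x_inh = _pair(sx, sy)
    p_y_act, p_y_inh = _pair(sy, sx)
    return EdgeOrientationStats(
        p_x_activator=p_x_act,
        p_y_activator=p_y_act,
        p_x_inhibitor=p_x_inh,
        p_y_inhibitor=p_y_inh,
    )


@dataclass
class OrientedEdge:
    regulator: str  # "x" or "y" (role within the stats)
    sign: str  # "activation" or "inhibition"
    weight: float  # winning regulator's max(activator, inhibitor) probability


def orient_edge(stats: EdgeOrientationStats) -> OrientedEdge | None:
    """Apply the direction and sign rules; ``None`` when a tie leaves the edge unoriented."""
    sum_x = stats.p_x_activator + stats.p_x_inhibitor
    sum_y = stats.p_y_activator + stats.p_y_inhibitor
    if sum_x == sum_y:
        return None
    if sum_x < sum_y:
        regulator, p_act, p_inh = "y", stats.p_y_activator, stats.p_y_inhibitor
    else:
        regulator, p_act, p_inh = "x", stats.p_x_activator, stats.p_x_inhibitor
    if p_act == p_inh:
        return None
    sign = "activation" if p_act > p_inh else "inhibition"
    return OrientedEdge(regulator=regulator, sign=sign, weight=max(p_act, p_inh))


def orient_network(
    undirected: RegulatoryNetwork, reference_expr: pd.DataFrame
) -> RegulatoryNetwork:
    """Orient every edge of an undirected network against a reference panel.

    Edges whose genes are missing from the expression panel, or that tie in
    direction or sign, are dropped (counts logged).  Each retained edge
    carries the winning regulator's max(activator, inhibitor) probability as
    its weight.
    """
    if undirected.directed:
        raise ValueError("orient_network expects an undirected network")
    disc = discretize(reference_expr)
    have = set(disc.genes)
    directed_edges = []
    n_missing = n_tied = 0
    for u, v in sorted(undirected.graph.edges()):
        if u not in have or v not in have:
            n_missing += 1
            continue
        stats = edge_stats(disc, x=u, y=v)
        oriented = orient_edge(stats)
        if oriented is None:
            n_tied += 1
            continue
        if oriented.regulator == "y":
            directed_edges.append((v, u, oriented.sign, oriented.weight))
        else:
            directed_edges.append((u, v, oriented.sign, oriented.weight))
    if n_missing or n_tied:
        logger.info(
            "orientation dropped %d edge(s) with missing expression, %d tie(s)",
            n_missing,
            n_tied,
        )
    return from_edges(directed_edges, directed=True)
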