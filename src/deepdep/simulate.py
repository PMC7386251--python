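"""Synthetic inputs with planted, recoverable structure.

Everything the pipeline consumes can be generated here: regulatory networks
(random layered DAGs or symmetric regulator->descendant modules), reference
and cell-line expression panels from a linear structural model that respects
the network's edge signs, screen-score tables whose dependency labels follow
a planted viability rule, and somatic-variant cohorts with controllable
mutation-class composition.  All randomness flows from explicit seeds via
named substreams, so every artifact is byte-reproducible.

Expression model: genes are simulated in topological order; a root gene draws
an i.i.d. latent value per sample (Gaussian, or standardized lognormal for
heavy-tailed regulator marginals), a child gene is the signed sum of its
parents' latents plus Gaussian noise, standardized, and all latents are
mapped affinely onto a non-negative expression scale.  Activation edges give
positive parent-child correlation, inhibition edges negative.

Planted dependency rule: a fixed "viability signature" (a weighted gene set,
drawn stratified per regulator module so every knockout target can move it
equally) is evaluated on each cell line's basal profile; basal profiles are
normalised so the baseline signature is constant across cell lines (baseline
viability homeostasis), and a (target, cell line) pair is a dependency when
knocking the target out pushes the signature down by more than the cohort
median.  Screen scores are noisy monotone copies of that signature drop on
each metric's own scale, so cutoff labelling recovers the plant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

from .mutations import VariantRecord
from .network import RegulatoryNetwork, from_edges
from .screens import ScreenScoreTable

_SUBSTREAMS = {
    "dag": 11,
    "expression": 23,
    "signature": 37,
    "screens": 41,
    "variants": 53,
    "cells": 61,
}


def _substream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng((int(seed) * 1_000_003 + _SUBSTREAMS[name]) % (2**31))


# ---------------------------------------------------------------------------
# networks

def make_dag(
    n_genes: int,
    mean_out_degree: float = 2.0,
    activation_prob: float = 0.7,
    seed: int = 0,
    hub_descendants: int = 0,
) -> RegulatoryNetwork:
    """Random signed DAG over a fixed topological order.

    Each gene draws a Poisson out-degree and wires to genes later in the
    order.  ``hub_descendants`` > 0 additionally wires the first gene to that
    many direct targets (to exercise downstream-count filters).
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = _substream(seed, "dag")
    names = [f"G{i:04d}" for i in range(n_genes)]
    edges = []
    for i in range(n_genes - 1):
        later = n_genes - 1 - i
        d = min(int(rng.poisson(mean_out_degree)), later)
        targets = rng.choice(np.arange(i + 1, n_genes), size=d, replace=False)
        for j in sorted(targets):
            sign = "activation" if rng.random() < activation_prob else "inhibition"
            edges.append((names[i], names[int(j)], sign))
    if hub_descendants:
        if hub_descendants > n_genes - 1:
            raise ValueError("hub_descendants exceeds available genes")
        wired = {v for u, v, _ in edges if u == names[0]}
        for j in range(1, n_genes):
            if len(wired) >= hub_descendants:
                break
            if names[j] not in wired:
                edges.append((names[0], names[j], "activation"))
                wired.add(names[j])
    return from_edges(edges, directed=True, extra_nodes=names)


def make_module_dag(
    n_modules: int,
    module_size: int | tuple[int, int] | list[int],
    activation_prob: float = 1.0,
    seed: int = 0,
) -> RegulatoryNetwork:
    """Two-layer DAG: each regulator drives its own block of effector genes.

    ``module_size`` is one size shared by all modules (exchangeable knockout
    effects), an inclusive (low, high) range drawn per module, or an explicit
    list of candidate sizes allocated by cycling — e.g. a bimodal list
    separates regulators into equally many small- and large-footprint
    classes regardless of seed.
    """
    rng = _substream(seed, "dag")
    if isinstance(module_size, tuple):
        sizes = rng.integers(module_size[0], module_size[1] + 1, size=n_modules)
    elif isinstance(module_size, list):
        sizes = [module_size[m % len(module_size)] for m in range(n_modules)]
    else:
        sizes = [module_size] * n_modules
    edges = []
    for m in range(n_modules):
        reg = f"R{m:03d}"
        for i in range(int(sizes[m])):
            sign = "activation" if rng.random() < activation_prob else "inhibition"
            edges.append((reg, f"D{m:03d}_{i:02d}", sign))
    return from_edges(edges, directed=True)


def make_chain_pairs(n_pairs: int, activation_prob: float = 0.7, seed: int = 0,
                     parents_per_child: int = 1) -> RegulatoryNetwork:
    """Regulator->child edges for orientation benchmarks (children may share parents)."""
    rng = _substream(seed, "dag")
    n_regs = max(parents_per_child, int(np.ceil(n_pairs * parents_per_child / 2)))
    regs = [f"Y{i:03d}" for i in range(n_regs)]
    edges = []
    for c in range(n_pairs // parents_per_child):
        child = f"X{c:03d}"
        parents = rng.choice(n_regs, size=parents_per_child, replace=False)
        for p in parents:
            sign = "activation" if rng.random() < activation_prob else "inhibition"
            edges.append((regs[int(p)], child, sign))
    return from_edges(edges, directed=True)


# ---------------------------------------------------------------------------
# expression

def simulate_expression(
    net: RegulatoryNetwork,
    n_samples: int,
    noise_sd: float = 0.5,
    seed: int = 0,
    coef: float = 1.0,
    root_dist: str = "normal",
    offset: float = 10.0,
    scale: float = 2.0,
    gene_scales: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Genes x samples expression from a linear structural model on the DAG.

    ``root_dist='lognormal'`` gives root regulators heavy-tailed marginals
    (children, as signed parent sums plus Gaussian noise, end up closer to
    Gaussian) — the marginal-shape asymmetry that conditional-probability
    orientation exploits.  ``gene_scales`` overrides the shared ``scale`` per
    gene, emulating heterogeneous dynamic ranges (e.g. stably expressed
    regulators versus high-variance effector genes).
    """
    if not net.directed:
        raise ValueError("expression simulation requires a directed network")
    if root_dist not in ("normal", "lognormal"):
        raise ValueError(f"unknown root distribution {root_dist!r}")
    rng = _substream(seed, "expression")
    order = list(nx.topological_sort(net.graph))
    latent: dict[str, np.ndarray] = {}
    for gene in order:
        parents = list(net.graph.predecessors(gene))
        if not parents:
            if root_dist == "lognormal":
                z = rng.lognormal(0.0, 1.0, size=n_samples)
            else:
                z = rng.normal(0.0, 1.0, size=n_samples)
        else:
            z = rng.normal(0.0, noise_sd, size=n_samples)
            for p in parents:
                sgn = 1.0 if net.graph.edges[p, gene].get("sign") != "inhibition" else -1.0
                z = z + sgn * coef * latent[p]
        sd = z.std()
        latent[gene] = (z - z.mean()) / (sd if sd > 0 else 1.0)
    genes = sorted(net.graph.nodes)
    if gene_scales is None:
        arr = np.vstack([offset + scale * latent[g] for g in genes])
    else:
        arr = np.vstack([offset + float(gene_scales.get(g, scale)) * latent[g] for g in genes])
    np.clip(arr, 0.0, None, out=arr)
    return pd.DataFrame(arr, index=genes, columns=[f"S{i:04d}" for i in range(n_samples)])


# ---------------------------------------------------------------------------
# planted viability signature and screens

@dataclass
class ViabilitySignature:
    """Weighted gene set whose knockout-induced drop defines essentiality."""

    genes: list[str]
    weights: pd.Series
    knockdown_factor: float = 1.0  # CRISPR plant

    def basal_value(self, expr: pd.DataFrame) -> pd.Series:
        return expr.loc[self.genes].mul(self.weights, axis=0).sum(axis=0)


def draw_signature(
    net: RegulatoryNetwork, n_genes: int = 50, seed: int = 0
) -> ViabilitySignature:
    """Random viability signature over the regulated (non-root) genes.

    Knocking out a regulator moves the signature in proportion to how many
    signature genes sit downstream of it, so regulators with larger
    footprints plant stronger dependencies.
    """
    rng = _substream(seed, "signature")
    pool = sorted(g for g in net.graph.nodes if net.graph.in_degree(g) > 0)
    take = min(n_genes, len(pool))
    genes = sorted(rng.choice(pool, size=take, replace=False))
    return ViabilitySignature(genes=genes, weights=pd.Series(1.0, index=genes))


def draw_module_signature(
    net: RegulatoryNetwork,
    per_module: int = 2,
    seed: int = 0,
    fraction: Optional[float] = None,
) -> ViabilitySignature:
    """Stratified signature draw over each regulator's direct targets.

    With a fixed ``per_module`` count the expected knockout effect is equal
    across regulators (planted dependency rates carry no per-target
    information); with ``fraction`` set, each module contributes a share of
    its genes proportional to its size (at least one), so knockout effects
    scale with the regulator's downstream footprint.
    """
    rng = _substream(seed, "signature")
    regulators = sorted(g for g in net.graph.nodes if net.graph.out_degree(g) > 0)
    genes: list[str] = []
    for reg in regulators:
        succ = sorted(net.graph.successors(reg))
        if fraction is not None:
            take = min(len(succ), max(1, int(round(fraction * len(succ)))))
        else:
            take = min(per_module, len(succ))
        genes.extend(sorted(rng.choice(succ, size=take, replace=False)))
    weights = pd.Series(1.0, index=genes)
    return ViabilitySignature(genes=genes, weights=weights)


def normalize_baseline_signature(
    expr: pd.DataFrame, signature: ViabilitySignature
) -> pd.DataFrame:
    """Rescale each sample's signature genes so the basal signature is constant.

    Emulates baseline viability homeostasis: every unperturbed sample starts
    from the same signature level, and only perturbation moves it.
    """
    target_value = 10.0 * len(signature.genes)
    out = expr.copy()
    basal = signature.basal_value(expr)
    factors = target_value / basal
    out.loc[signature.genes] = out.loc[signature.genes].mul(factors, axis=1)
    return out


def _true_correlations(
    net: RegulatoryNetwork, seed: int, n_probe: int = 2000, **expr_kwargs
) -> dict[str, pd.Series]:
    """Target->descendant correlations from a large generator-internal panel."""
    probe = simulate_expression(net, n_probe, seed=seed + 7, **expr_kwargs)
    z = probe.sub(probe.mean(axis=1), axis=0)
    z = z.div(np.sqrt((z**2).sum(axis=1)).replace(0, 1.0), axis=0)
    out = {}
    for t in sorted(g for g in net.graph.nodes if net.graph.out_degree(g) > 0):
        desc = sorted(nx.descendants(net.graph, t))
        out[t] = pd.Series(z.loc[desc].to_numpy() @ z.loc[t].to_numpy(), index=desc)
    return out


@dataclass
class SimulatedScreens:
    """Planted screens: one table per metric plus the cutoffs that recover the plant."""

    tables: dict[str, ScreenScoreTable]
    cutoffs: dict[str, float]
    planted: pd.DataFrame  # gene, cell_line, label
    signature_drop: pd.DataFrame  # targets x cell lines


def simulate_screens(
    net: RegulatoryNetwork,
    cell_expr: pd.DataFrame,
    signature: ViabilitySignature,
    seed: int = 0,
    noise_sd: float = 0.1,
    dependency_quantile: float = 0.5,
    expr_kwargs: Optional[dict] = None,
) -> SimulatedScreens:
    """Emit CERES/zGARP/BAGEL score tables from the planted viability rule.

    The latent essentiality of (target, cell line) is the drop the target's
    knockout induces in the viability signature, computed with the
    generator's own correlation estimates (a large independent probe panel).
    CERES and zGARP are negative-shifted noisy standardizations of the drop,
    BAGEL positive-shifted; a cutoff of 0 on each recovers the plant up to
    the score noise.
    """
    rng = _substream(seed, "screens")
    rho = _true_correlations(net, seed, **(expr_kwargs or {}))
    k = signature.knockdown_factor
    targets = sorted(rho)
    drops = np.zeros((len(targets), cell_expr.shape[1]))
    for i, t in enumerate(targets):
        sig_desc = [g for g in signature.genes if g in rho[t].index]
        if not sig_desc:
            continue
        w = signature.weights.loc[sig_desc].to_numpy()
        r = rho[t].loc[sig_desc].to_numpy()
        drops[i] = (w * r * k) @ cell_expr.loc[sig_desc].to_numpy()
    drop_frame = pd.DataFrame(drops, index=targets, columns=cell_expr.columns)

    flat = drop_frame.to_numpy().ravel()
    threshold = float(np.quantile(flat, 1.0 - dependency_quantile))
    planted = (drop_frame > threshold).astype(int)
    z = (drop_frame - flat.mean()) / (flat.std() if flat.std() > 0 else 1.0)
    z_thr = (threshold - flat.mean()) / (flat.std() if flat.std() > 0 else 1.0)

    def _noisy(sign: float) -> pd.DataFrame:
        noise = rng.normal(0.0, noise_sd, size=z.shape) if noise_sd > 0 else 0.0
        return sign * (z - z_thr) + noise

    tables = {
        "CERES": ScreenScoreTable(scores=_noisy(-1.0), metric="CERES"),
        "zGARP": ScreenScoreTable(scores=_noisy(-1.0), metric="zGARP"),
        "BAGEL": ScreenScoreTable(scores=_noisy(+1.0), metric="BAGEL"),
    }
    cutoffs = {"CERES": 0.0, "zGARP": 0.0, "BAGEL": 0.0}
    planted_long = planted.stack().rename("label").reset_index()
    planted_long.columns = ["gene", "cell_line", "label"]
    return SimulatedScreens(
        tables=tables, cutoffs=cutoffs, planted=planted_long, signature_drop=drop_frame
    )


# ---------------------------------------------------------------------------
# variants

@dataclass
class VariantMix:
    """Planted composition of a synthetic somatic-variant cohort."""

    n_hetlof: int = 10
    n_homolof: int = 10
    n_gap: int = 5  # heterozygous calls inside the unclassified VAF gap
    recurrent_missense: list[tuple[str, int, str, int]] = field(default_factory=list)
    # (gene, position, substitution, n_carrier_samples)
    silent_only: dict[str, int] = field(default_factory=dict)  # gene -> n silent records
    n_background_missense: int = 0


def simulate_variants(
    samples: list[str],
    genes: list[str],
    mix: VariantMix,
    seed: int = 0,
) -> list[VariantRecord]:
    """Variant cohort with controllable hetLOF / homoLOF / gap / GOF / silent plants."""
    rng = _substream(seed, "variants")
    records: list[VariantRecord] = []

    def _sample() -> str:
        return samples[int(rng.integers(len(samples)))]

    def _gene() -> str:
        return genes[int(rng.integers(len(genes)))]

    for _ in range(mix.n_hetlof):
        cls = "nonsense" if rng.random() < 0.5 else "frameshift_indel"
        records.append(
            VariantRecord(_sample(), _gene(), cls, "heterozygous", float(rng.uniform(0.05, 0.39)))
        )
    for _ in range(mix.n_homolof):
        if rng.random() < 0.5:
            records.append(
                VariantRecord(_sample(), _gene(), "nonsense", "homozygous", float(rng.uniform(0.6, 1.0)))
            )
        else:
            records.append(
                VariantRecord(
                    _sample(), _gene(), "frameshift_indel", "heterozygous", float(rng.uniform(0.51, 0.9))
                )
            )
    for _ in range(mix.n_gap):
        records.append(
            VariantRecord(_sample(), _gene(), "nonsense", "heterozygous", float(rng.uniform(0.40, 0.50)))
        )
    for gene, pos, sub, n_carriers in mix.recurrent_missense:
        carriers = rng.choice(samples, size=n_carriers, replace=False)
        for s in carriers:
            records.append(
                VariantRecord(str(s), gene, "missense", "heterozygous",
                              float(rng.uniform(0.1, 0.6)), position=pos, substitution=sub)
            )
    for gene, n_silent in mix.silent_only.items():
        for _ in range(n_silent):
            records.append(
                VariantRecord(_sample(), gene, "silent", "heterozygous", float(rng.uniform(0.1, 0.6)))
            )
    for i in range(mix.n_background_missense):
        records.append(
            VariantRecord(
                _sample(), _gene(), "missense", "heterozygous", float(rng.uniform(0.1, 0.6)),
                position=1000 + i, substitution=f"p.A{1000 + i}V",
            )
        )
    return records
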