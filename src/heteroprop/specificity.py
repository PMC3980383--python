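"""Topology-bias correction and Z-score specificity ranking.

Converged probabilities partly reflect network centrality rather than
relevance to the query disease.  A reference run repeats the propagation
with every protein-interaction edge weight set to 1 (expression information
removed); each node's probability is then standardized against the
reference distribution of its network:

    Z_i(v) = (P_i(v) - avg(P_i^ref)) / std(P_i^ref)

with the population (divide-by-N) standard deviation.  Drugs with Z above
the threshold (default 2.33, one-tailed p = 0.01) are flagged significant.

Because avg and std of the reference set are scalars, ranking drugs by this
Z is identical to ranking by raw probability; an optional node-wise mode
(``z_mode='nodewise'``) standardizes P(v) - P^ref(v) instead, which corrects
centrality per node.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from heteroprop.model_io import (
    DiffusionConfig,
    HomoNetwork,
    IntegratedNetwork,
    ProbabilityState,
    ValidationError,
)
from heteroprop.edge_weights import attach_orphans
from heteroprop.propagation import propagate_integrated

logger = logging.getLogger(__name__)

DEFAULT_Z_THRESHOLD = 2.33


class DegenerateReferenceError(ValueError):
    """The reference probability distribution has zero variance."""


@dataclass
class ZScoreReport:
    """Per-node specificity scores for one network kind."""

    node_ids: list[str]
    probability: np.ndarray
    reference_mean: float
    reference_std: float
    z: np.ndarray
    significant: np.ndarray
    threshold: float = DEFAULT_Z_THRESHOLD


def uniform_reference_network(net: IntegratedNetwork) -> IntegratedNetwork:
    """Clone with every existing PIN edge weight replaced by 1.

    Sink smoothing for hetero-referenced genes is re-applied on the clone so
    drug targets and disease genes outside the PIN stay reachable.
    """
    gene = net.gene
    w = (gene.weights > 0).astype(float)
    if gene.smoothed:
        # smoothed rows carry uniform 1/(n-1) weights, not PIN edges; zero
        # them so attach_orphans re-applies the same smoothing on the clone
        n = gene.n_nodes
        idx = [i for i, g in enumerate(gene.node_ids) if g in gene.smoothed]
        w[idx, :] = 0.0
        w[:, idx] = 0.0
    flat = HomoNetwork(node_ids=list(gene.node_ids), weights=w, kind="gene")
    referenced = sorted(gene.smoothed)
    flat = attach_orphans(flat, referenced)
    # attach_orphans preserves node order; the hetero blocks stay aligned
    assert flat.node_ids == gene.node_ids
    return IntegratedNetwork(
        drug=net.drug,
        gene=flat,
        phenotype=net.phenotype,
        drug_gene=net.drug_gene,
        phenotype_gene=net.phenotype_gene,
        config=net.config,
    )


def reference_state(
    net: IntegratedNetwork,
    query_phenotypes: Sequence[str],
    config: DiffusionConfig | None = None,
) -> ProbabilityState:
    """Propagate on the uniformly-weighted clone to get P^ref per network."""
    return propagate_integrated(uniform_reference_network(net), query_phenotypes, config)


def z_scores(
    P: np.ndarray,
    P_ref: np.ndarray,
    threshold: float = DEFAULT_Z_THRESHOLD,
    z_mode: Literal["set", "nodewise"] = "set",
) -> tuple[np.ndarray, float, float, np.ndarray]:
    """Standardize probabilities against the reference distribution.

    Returns (z, reference mean, reference std, significance flags).  In
    ``set`` mode each P(v) is standardized by the scalar mean and population
    std of the full reference vector; ``nodewise`` standardizes the per-node
    excess P(v) - P^ref(v) by the same scalar std.
    """
    P = np.asarray(P, dtype=float)
    P_ref = np.asarray(P_ref, dtype=float)
    if P.shape != P_ref.shape or P.ndim != 1 or P.size < 2:
        raise ValidationError("P and P_ref must be equal-length vectors of size >= 2")
    mean = float(P_ref.mean())
    std = float(P_ref.std())  # population std: the reference set is the distribution
    if std == 0.0:
        raise DegenerateReferenceError("reference distribution is constant (std = 0)")
    if z_mode == "set":
        z = (P - mean) / std
    elif z_mode == "nodewise":
        z = (P - P_ref) / std
    else:
        raise ValidationError(f"unknown z_mode {z_mode!r}")
    return z, mean, std, z > threshold


def z_report(
    node_ids: Sequence[str],
    P: np.ndarray,
    P_ref: np.ndarray,
    threshold: float = DEFAULT_Z_THRESHOLD,
    z_mode: Literal["set", "nodewise"] = "set",
) -> ZScoreReport:
    """Build a :class:`ZScoreReport` for one network's nodes."""
    P = np.clip(np.asarray(P, dtype=float), 0.0, None)
    z, mean, std, sig = z_scores(P, P_ref, threshold=threshold, z_mode=z_mode)
    return ZScoreReport(
        node_ids=list(node_ids),
        probability=P,
        reference_mean=mean,
        reference_std=std,
        z=z,
        significant=sig,
        threshold=threshold,
    )


def rank_drugs(
    state: ProbabilityState,
    ref: ProbabilityState,
    drug_ids: Sequence[str],
    threshold: float = DEFAULT_Z_THRESHOLD,
    z_mode: Literal["set", "nodewise"] = "set",
) -> list[tuple[str, float, float, bool]]:
    """Rank drugs by Z descending; ties broken by id for determinism.

    Negative probabilities (possible under literal coefficient mode for
    non-standard initial states) are clamped to 0 before scoring, with a
    logged count.
    """
    P = np.asarray(state.vectors["drug"], dtype=float)
    n_neg = int((P < 0).sum())
    if n_neg:
        logger.info("clamped %d negative drug probabilities before Z-scoring", n_neg)
    P = np.clip(P, 0.0, None)
    P_ref = np.asarray(ref.vectors["drug"], dtype=float)
    z, _, _, sig = z_scores(P, P_ref, threshold=threshold, z_mode=z_mode)
    rows = [
        (drug_ids[i], float(P[i]), float(z[i]), bool(sig[i]))
        for i in range(len(drug_ids))
    ]
    rows.sort(key=lambda r: (-r[2], r[0]))
    return rows
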