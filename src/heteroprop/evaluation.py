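"""ROC/AUC benchmarking of drug rankings and the diffusion-parameter sweep.

Benchmark positives are the drugs with a known association to the query
disease; every other scored drug counts as a negative (no curated negative
set exists for drug repositioning).  AUC is the Mann-Whitney concordance
probability with ties counted 0.5, so it is invariant under any strictly
monotone rescaling of the scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from heteroprop.model_io import (
    BenchmarkSet,
    ConvergenceError,
    DiffusionConfig,
    IntegratedNetwork,
    ValidationError,
)
from heteroprop.propagation import propagate_integrated
from heteroprop.specificity import DegenerateReferenceError, rank_drugs, reference_state

logger = logging.getLogger(__name__)

#: The published sweep grid: every alpha in {0.1 .. 0.9} per network kind.
DEFAULT_ALPHA_GRID: list[tuple[float, float, float]] = [
    (ad, ag, ap)
    for ad in (0.1, 0.3, 0.5, 0.7, 0.9)
    for ag in (0.1, 0.3, 0.5, 0.7, 0.9)
    for ap in (0.1, 0.3, 0.5, 0.7, 0.9)
]


@dataclass
class RocResult:
    points: list[tuple[float, float]]  # (FPR, TPR), (0,0) .. (1,1)
    auc: float
    n_pos: int
    n_neg: int


def roc_auc(scores: Mapping[str, float], benchmark: BenchmarkSet) -> RocResult:
    """ROC curve and AUC of drug scores against benchmark positives.

    Drugs absent from the benchmark's positive set are the negatives.
    Requires at least one of each.
    """
    drug_ids = sorted(scores)  # deterministic, scores break the order anyway
    y_true = np.array([d in benchmark.positive_drug_ids for d in drug_ids], dtype=int)
    y_score = np.array([scores[d] for d in drug_ids], dtype=float)
    n_pos = int(y_true.sum())
    n_neg = len(y_true) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError(
            f"ROC needs >= 1 positive and >= 1 negative (got {n_pos}/{n_neg})"
        )
    fpr, tpr, _ = roc_curve(y_true, y_score)
    auc = float(roc_auc_score(y_true, y_score))
    return RocResult(
        points=list(zip(fpr.tolist(), tpr.tolist())),
        auc=auc,
        n_pos=n_pos,
        n_neg=n_neg,
    )


def rank_and_score(
    net: IntegratedNetwork,
    query_phenotypes: Sequence[str],
    config: DiffusionConfig | None = None,
    threshold: float = 2.33,
    z_mode: str = "set",
) -> list[tuple[str, float, float, bool]]:
    """Full pipeline for one configuration: propagate, reference, Z-rank."""
    state = propagate_integrated(net, query_phenotypes, config)
    ref = reference_state(net, query_phenotypes, config)
    return rank_drugs(state, ref, net.drug.node_ids, threshold=threshold, z_mode=z_mode)  # type: ignore[arg-type]


def parameter_sweep(
    net: IntegratedNetwork,
    query_phenotypes: Sequence[str],
    benchmark: BenchmarkSet,
    grid: Sequence[tuple[float, float, float]] | None = None,
) -> list[tuple[float, float, float, float]]:
    """AUC over a grid of (alpha_drug, alpha_gene, alpha_phenotype) triples.

    The default grid is the full 5 x 5 x 5 lattice over {0.1, 0.3, 0.5, 0.7,
    0.9} (125 combinations).  One complete rank-and-evaluate runs per cell;
    a cell whose propagation fails is recorded as NaN and the sweep
    continues.  Rows keep grid order.
    """
    if grid is None:
        grid = DEFAULT_ALPHA_GRID
    if not grid:
        raise ValidationError("sweep grid is empty")
    base = net.config
    rows: list[tuple[float, float, float, float]] = []
    for ad, ag, ap in grid:
        config = DiffusionConfig(
            alpha={"drug": ad, "gene": ag, "phenotype": ap},
            k=dict(base.k),
            coefficient_mode=base.coefficient_mode,
            tol=base.tol,
            max_iter=base.max_iter,
        )
        try:
            ranking = rank_and_score(net, query_phenotypes, config)
            scores = {drug: z for drug, _, z, _ in ranking}
            auc = roc_auc(scores, benchmark).auc
        except (ConvergenceError, DegenerateReferenceError) as exc:
            logger.warning("sweep cell (%.1f, %.1f, %.1f) failed: %s", ad, ag, ap, exc)
            auc = float("nan")
        rows.append((ad, ag, ap, auc))
    return rows
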