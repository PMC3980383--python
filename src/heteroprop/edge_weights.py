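"""Construction of the weighted homo- and hetero-networks.

Drug similarity is the Tanimoto coefficient on hashed bit fingerprints.
Phenotype similarity scores (raw text-mining scores in [0, 1]) pass through
a logistic transform that pushes the informative band [0.6, 1] towards 1 and
the non-informative band [0, 0.3] towards 0.  Protein-interaction edges are
weighted by case-sample co-expression times total differential expression:

    W_g(g_i, g_j) = |R^case(g_i, g_j)| * (|Ebar_i^case - Ebar_i^ctrl|
                                          + |Ebar_j^case - Ebar_j^ctrl|)

Hetero-networks are binary adjacency.  A drug target or disease gene with no
protein-interaction weight would absorb the walk as a sink; such genes are
connected to every other gene with weight 1/(n-1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from heteroprop.model_io import (
    ExpressionProfile,
    HeteroNetwork,
    HomoNetwork,
    ValidationError,
    node_order,
)

logger = logging.getLogger(__name__)

#: Default logistic calibration: transform(0) = 1e-4, midpoint at ~0.614.
DEFAULT_LOGISTIC_C = -15.0
DEFAULT_LOGISTIC_D = math.log(9999.0)


@dataclass(frozen=True)
class Fingerprint:
    """Hashed structural fingerprint of one drug, stored as set-bit indices."""

    drug_id: str
    bits: frozenset[int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "bits", frozenset(int(b) for b in self.bits))
        if any(b < 0 for b in self.bits):
            raise ValidationError(f"fingerprint for {self.drug_id!r} has negative bit index")


@dataclass(frozen=True)
class LogisticParams:
    """Parameters of transform(x) = 1 / (1 + exp(c*x + d)).

    ``c`` must be negative so the transform is strictly increasing.
    """

    c: float = DEFAULT_LOGISTIC_C
    d: float = DEFAULT_LOGISTIC_D

    def __post_init__(self) -> None:
        if self.c >= 0:
            raise ValidationError(f"logistic slope c must be negative, got {self.c}")


def tanimoto_similarity(a: Fingerprint, b: Fingerprint) -> float:
    """Intersection-over-union of set bits; symmetric, in [0, 1].

    Both fingerprints empty is undefined (0/0) and raises.
    """
    if not a.bits and not b.bits:
        raise ValidationError(
            f"Tanimoto undefined for two empty fingerprints ({a.drug_id!r}, {b.drug_id!r})"
        )
    inter = len(a.bits & b.bits)
    union = len(a.bits | b.bits)
    return inter / union


def build_drug_network(fps: list[Fingerprint]) -> HomoNetwork:
    """Pairwise Tanimoto similarity matrix over >= 2 drugs, zero diagonal."""
    if len(fps) < 2:
        raise ValidationError(f"need >= 2 drugs, got {len(fps)}")
    for fp in fps:
        if not fp.bits:
            raise ValidationError(f"drug {fp.drug_id!r} has an empty fingerprint")
    ids = node_order(fp.drug_id for fp in fps)
    if len(ids) != len(fps):
        raise ValidationError("duplicate drug ids among fingerprints")
    n = len(fps)
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = tanimoto_similarity(fps[i], fps[j])
            w[i, j] = w[j, i] = s
    return HomoNetwork(node_ids=ids, weights=w, kind="drug")


def logistic_transform(x: float | np.ndarray, params: LogisticParams = LogisticParams()) -> float | np.ndarray:
    """1 / (1 + exp(c*x + d)); strictly increasing on [0, 1] for c < 0."""
    arr = np.asarray(x, dtype=float)
    if ((arr < 0) | (arr > 1)).any():
        raise ValidationError("similarity scores must lie in [0, 1]")
    out = 1.0 / (1.0 + np.exp(params.c * arr + params.d))
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def build_phenotype_network(
    ids: list[str],
    raw: np.ndarray,
    params: LogisticParams = LogisticParams(),
) -> HomoNetwork:
    """Elementwise logistic transform of a raw symmetric similarity matrix.

    The diagonal is zeroed; near-zero transformed values are kept as small
    positives rather than truncated.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.shape != (len(ids), len(ids)):
        raise ValidationError("raw similarity matrix shape does not match ids")
    if not np.allclose(raw, raw.T, atol=1e-12, rtol=0):
        raise ValidationError("raw phenotype similarity matrix is asymmetric")
    w = np.asarray(logistic_transform(raw, params), dtype=float)
    np.fill_diagonal(w, 0.0)
    # transform of symmetric input can differ in the last ulp; resymmetrize
    w = (w + w.T) / 2.0
    return HomoNetwork(node_ids=list(ids), weights=w, kind="phenotype")


def coexpression_weight(
    r_case: float,
    ei_case: float,
    ei_ctrl: float,
    ej_case: float,
    ej_ctrl: float,
) -> float:
    """|r| times the summed absolute differential expression of both genes."""
    if not np.isfinite([r_case, ei_case, ei_ctrl, ej_case, ej_ctrl]).all():
        raise ValidationError("non-finite input to coexpression_weight")
    return abs(r_case) * (abs(ei_case - ei_ctrl) + abs(ej_case - ej_ctrl))


def build_gene_network(
    pin_edges: list[tuple[str, str]],
    expr: ExpressionProfile,
) -> HomoNetwork:
    """Expression-weight the protein-interaction network.

    Pearson correlation is computed from case samples only; the differential
    term uses within-class means over all samples of each class.  Genes in
    the PIN but absent from the expression profile are kept as isolated
    zero-weight nodes (smoothed later by :func:`attach_orphans` if a
    hetero-network references them).  Edges touching a gene with zero case
    variance get weight 0 with a warning.
    """
    gene_ids = node_order(g for edge in pin_edges for g in edge)
    index = {g: i for i, g in enumerate(gene_ids)}
    n = len(gene_ids)
    w = np.zeros((n, n))

    expr_index = {g: i for i, g in enumerate(expr.gene_ids)}
    missing = [g for g in gene_ids if g not in expr_index]
    if missing:
        logger.warning(
            "%d of %d PIN genes absent from expression data; kept as zero-weight nodes",
            len(missing),
            n,
        )

    case = expr.case_values()
    case_mean = case.mean(axis=1)
    ctrl_mean = expr.control_values().mean(axis=1)
    case_sd = case.std(axis=1)

    n_zero_var = 0
    for gi, gj in pin_edges:
        if gi == gj or gi not in expr_index or gj not in expr_index:
            continue
        ei, ej = expr_index[gi], expr_index[gj]
        if case_sd[ei] == 0.0 or case_sd[ej] == 0.0:
            n_zero_var += 1
            continue  # correlation undefined -> weight stays 0
        r = np.corrcoef(case[ei], case[ej])[0, 1]
        weight = coexpression_weight(r, case_mean[ei], ctrl_mean[ei], case_mean[ej], ctrl_mean[ej])
        i, j = index[gi], index[gj]
        w[i, j] = w[j, i] = max(w[i, j], weight)
    if n_zero_var:
        logger.warning("%d PIN edges touch a zero-case-variance gene; weights set to 0", n_zero_var)
    return HomoNetwork(node_ids=gene_ids, weights=w, kind="gene")


def build_hetero(
    pairs: list[tuple[str, str]],
    row_universe: list[str],
    col_universe: list[str],
    weighted: bool = False,
    weights: list[float] | None = None,
) -> HeteroNetwork:
    """Binary bipartite adjacency over the given universes.

    Pairs referencing unknown ids are dropped with a warning; if all pairs
    drop, that is an error.  ``weighted=True`` keeps supplied edge values
    instead of binarizing (for confidence-scored sources).
    """
    row_ids = list(row_universe)
    col_ids = list(col_universe)
    ri = {r: i for i, r in enumerate(row_ids)}
    ci = {c: i for i, c in enumerate(col_ids)}
    links = np.zeros((len(row_ids), len(col_ids)))
    kept = 0
    for idx, (r, c) in enumerate(pairs):
        if r not in ri or c not in ci:
            logger.warning("dropping association pair (%r, %r): unknown id", r, c)
            continue
        value = weights[idx] if (weighted and weights is not None) else 1.0
        links[ri[r], ci[c]] = value if weighted else 1.0
        kept += 1
    if pairs and kept == 0:
        raise ValidationError("all association pairs referenced unknown ids")
    return HeteroNetwork(row_ids=row_ids, col_ids=col_ids, links=links)


def attach_orphans(gene_net: HomoNetwork, referenced_genes: list[str]) -> HomoNetwork:
    """Smooth sink genes: hetero-referenced genes with zero row weight.

    Any gene referenced by a hetero-network whose row sum is 0 (no PIN edge,
    or only zero-weight edges) is connected to every other gene with weight
    1/(n-1), where n is the total gene count after adding genes that were
    missing from the PIN entirely.  Symmetry is preserved.
    """
    ids = node_order(list(gene_net.node_ids) + list(referenced_genes))
    n = len(ids)
    if n < 2:
        raise ValidationError(f"need >= 2 genes for sink smoothing, got {n}")
    n_old = gene_net.n_nodes
    w = np.zeros((n, n))
    w[:n_old, :n_old] = gene_net.weights
    if n > n_old:
        logger.warning("added %d hetero-referenced genes missing from the PIN", n - n_old)

    referenced = set(referenced_genes)
    row_sums = w.sum(axis=1)
    uniform = 1.0 / (n - 1)
    orphans = [i for i, g in enumerate(ids) if g in referenced and row_sums[i] == 0.0]
    for i in orphans:
        w[i, :] = np.maximum(w[i, :], uniform)
        w[:, i] = np.maximum(w[:, i], uniform)
        w[i, i] = 0.0
    if orphans:
        logger.info("smoothed %d sink genes with uniform weight 1/(n-1) = %.3g", len(orphans), uniform)
    smoothed = gene_net.smoothed | {ids[i] for i in orphans}
    return HomoNetwork(node_ids=ids, weights=w, kind="gene", smoothed=frozenset(smoothed))


def fingerprints_from_smiles(
    entries: list[tuple[str, str]],
    n_bits: int = 1024,
) -> list[Fingerprint]:
    """Hashed path-based fingerprints from SMILES via RDKit (optional extra).

    The core pipeline never requires a chemistry toolkit; precomputed
    bit-index files are the primary input path.
    """
    try:
        from rdkit import Chem  # type: ignore[import-not-found]
        from rdkit.Chem import rdFingerprintGenerator  # type: ignore[import-not-found]
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "RDKit is required for SMILES input; install the 'chem' extra or "
            "supply precomputed fingerprint bit indices"
        ) from exc
    gen = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=n_bits)
    fps = []
    for drug_id, smiles in entries:
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValidationError(f"unparsable SMILES for drug {drug_id!r}")
        bv = gen.GetFingerprint(mol)
        fps.append(Fingerprint(drug_id=drug_id, bits=frozenset(bv.GetOnBits())))
    return fps
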