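"""Assembly of an IntegratedNetwork from raw inputs or input files."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from heteroprop.model_io import (
    DiffusionConfig,
    ExpressionProfile,
    IntegratedNetwork,
    node_order,
    read_association_pairs,
    read_edge_list,
    read_expression_matrix,
    read_fingerprints,
    read_similarity_matrix,
)
from heteroprop.edge_weights import (
    Fingerprint,
    LogisticParams,
    attach_orphans,
    build_drug_network,
    build_gene_network,
    build_hetero,
    build_phenotype_network,
)


def assemble_network(
    fingerprints: list[Fingerprint],
    phenotype_ids: list[str],
    phenotype_raw: np.ndarray,
    pin_edges: list[tuple[str, str]],
    expression: ExpressionProfile,
    drug_target_pairs: list[tuple[str, str]],
    phenotype_gene_pairs: list[tuple[str, str]],
    config: DiffusionConfig | None = None,
    logistic: LogisticParams | None = None,
    weighted_hetero: bool = False,
) -> IntegratedNetwork:
    """Build all five networks and wire them into an IntegratedNetwork.

    Gene order is PIN first-appearance order; genes referenced only by a
    hetero-network are appended and sink-smoothed by ``attach_orphans``.
    """
    drug_net = build_drug_network(fingerprints)
    phen_net = build_phenotype_network(
        phenotype_ids, phenotype_raw, logistic or LogisticParams()
    )
    gene_net = build_gene_network(pin_edges, expression)
    referenced = node_order(
        [g for _, g in drug_target_pairs] + [g for _, g in phenotype_gene_pairs]
    )
    gene_net = attach_orphans(gene_net, referenced)
    drug_gene = build_hetero(
        drug_target_pairs, drug_net.node_ids, gene_net.node_ids, weighted=weighted_hetero
    )
    phenotype_gene = build_hetero(
        phenotype_gene_pairs, phen_net.node_ids, gene_net.node_ids, weighted=weighted_hetero
    )
    return IntegratedNetwork(
        drug=drug_net,
        gene=gene_net,
        phenotype=phen_net,
        drug_gene=drug_gene,
        phenotype_gene=phenotype_gene,
        config=config or DiffusionConfig(),
    )


def assemble_from_files(
    fingerprints_path: str | Path,
    phenotype_similarity_path: str | Path,
    pin_edges_path: str | Path,
    expression_path: str | Path,
    sample_labels_path: str | Path,
    drug_targets_path: str | Path,
    phenotype_genes_path: str | Path,
    config: DiffusionConfig | None = None,
    logistic: LogisticParams | None = None,
    weighted_hetero: bool = False,
) -> IntegratedNetwork:
    """Read the flat-file inputs and assemble the integrated network."""
    fps = [
        Fingerprint(drug_id=d, bits=bits)
        for d, bits in read_fingerprints(fingerprints_path)
    ]
    phen_ids, raw = read_similarity_matrix(phenotype_similarity_path)
    pin = [(u, v) for u, v, _ in read_edge_list(pin_edges_path)]
    expr = read_expression_matrix(expression_path, sample_labels_path)
    dt = read_association_pairs(drug_targets_path)
    gp = read_association_pairs(phenotype_genes_path)
    return assemble_network(
        fingerprints=fps,
        phenotype_ids=phen_ids,
        phenotype_raw=raw,
        pin_edges=pin,
        expression=expr,
        drug_target_pairs=dt,
        phenotype_gene_pairs=gp,
        config=config,
        logistic=logistic,
        weighted_hetero=weighted_hetero,
    )
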