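"""Domain types and flat-file I/O for the integrated drug-gene-phenotype network.

All inputs are delimited text: TSV edge lists, TSV association-pair lists,
a TSV expression matrix with a separate sample-label map, and square TSV
similarity matrices with an identifier header row and column.  Node order is
always first-appearance order and every downstream vector or matrix aligns
to it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NetworkKind = Literal["drug", "gene", "phenotype"]

SYMMETRY_TOL = 1e-12


class ValidationError(ValueError):
    """Input violates a documented precondition or invariant."""


class ParseError(ValueError):
    """A flat file could not be parsed; the message names the line."""


class ConvergenceError(RuntimeError):
    """Propagation failed to reach the tolerance within max_iter."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class ConfigurationError(ValueError):
    """A diffusion configuration is inconsistent with the requested mode."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class HomoNetwork:
    """Undirected weighted graph over nodes of one kind.

    ``weights`` is a square symmetric non-negative matrix with zero
    diagonal, aligned to ``node_ids``.
    """

    node_ids: list[str]
    weights: np.ndarray
    kind: NetworkKind
    #: genes whose rows were sink-smoothed to uniform 1/(n-1) weights;
    #: the topology-reference run re-applies the same smoothing
    smoothed: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.node_ids = list(self.node_ids)
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.node_ids)
        if len(set(self.node_ids)) != n:
            raise ValidationError(f"{self.kind} network has duplicate node ids")
        if self.weights.shape != (n, n):
            raise ValidationError(
                f"{self.kind} network weights shape {self.weights.shape} "
                f"does not match {n} node ids"
            )
        if n and (self.weights < 0).any():
            raise ValidationError(f"{self.kind} network has negative weights")
        if n and not np.allclose(self.weights, self.weights.T, atol=SYMMETRY_TOL, rtol=0):
            raise ValidationError(f"{self.kind} network weights are asymmetric")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def index_of(self, node_id: str) -> int:
        try:
            return self.node_ids.index(node_id)
        except ValueError:
            raise ValidationError(f"unknown {self.kind} node id {node_id!r}") from None


@dataclass
class HeteroNetwork:
    """Bipartite non-negative link matrix between two node kinds."""

    row_ids: list[str]
    col_ids: list[str]
    links: np.ndarray

    def __post_init__(self) -> None:
        self.row_ids = list(self.row_ids)
        self.col_ids = list(self.col_ids)
        self.links = np.asarray(self.links, dtype=float)
        if self.links.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValidationError(
                f"hetero-network links shape {self.links.shape} does not match "
                f"{len(self.row_ids)} x {len(self.col_ids)} ids"
            )
        if self.links.size and (self.links < 0).any():
            raise ValidationError("hetero-network has negative link weights")


@dataclass
class DiffusionConfig:
    """Per-network diffusion parameters.

    ``alpha`` maps each network kind to its diffusion parameter in [0, 1);
    ``k`` to the number of attached hetero-networks.  The restart weight of
    network *i* is ``a_i = 1 - k_i * alpha_i``.  With the published best
    setting (alpha_gene = 0.7, k_gene = 2) that weight is negative;
    ``coefficient_mode='literal'`` uses it as written while ``'strict'``
    rejects any configuration with a negative restart weight.
    """

    alpha: dict[NetworkKind, float] = field(
        default_factory=lambda: {"drug": 0.1, "gene": 0.7, "phenotype": 0.3}
    )
    k: dict[NetworkKind, int] = field(
        default_factory=lambda: {"drug": 1, "gene": 2, "phenotype": 1}
    )
    coefficient_mode: Literal["literal", "strict"] = "literal"
    tol: float = 1e-9
    max_iter: int = 10000

    def __post_init__(self) -> None:
        for kind, a in self.alpha.items():
            if not 0.0 <= a < 1.0:
                raise ValidationError(f"alpha[{kind}]={a} outside [0, 1)")
        for kind, kk in self.k.items():
            if kk < 0:
                raise ValidationError(f"k[{kind}]={kk} negative")
        if self.tol <= 0:
            raise ValidationError("tol must be positive")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be positive")
        if self.coefficient_mode not in ("literal", "strict"):
            raise ValidationError(f"unknown coefficient_mode {self.coefficient_mode!r}")

    def restart_weight(self, kind: NetworkKind) -> float:
        """a_i = 1 - k_i * alpha_i; in strict mode a negative value raises."""
        a = 1.0 - self.k[kind] * self.alpha[kind]
        if self.coefficient_mode == "strict" and a < 0:
            raise ConfigurationError(
                f"restart weight for {kind} network is {a:.3g} "
                f"(k={self.k[kind]}, alpha={self.alpha[kind]}): "
                "k*alpha > 1 is rejected in strict mode"
            )
        return a


@dataclass
class IntegratedNetwork:
    """Three homo-networks plus the two hetero-networks linking them.

    ``drug_gene`` rows are drugs, columns genes; ``phenotype_gene`` rows are
    phenotypes, columns genes.  After assembly every hetero id must exist in
    the corresponding homo-network.
    """

    drug: HomoNetwork
    gene: HomoNetwork
    phenotype: HomoNetwork
    drug_gene: HeteroNetwork
    phenotype_gene: HeteroNetwork
    config: DiffusionConfig = field(default_factory=DiffusionConfig)

    def __post_init__(self) -> None:
        pairs = [
            (self.drug_gene.row_ids, self.drug.node_ids, "drug_gene rows"),
            (self.drug_gene.col_ids, self.gene.node_ids, "drug_gene cols"),
            (self.phenotype_gene.row_ids, self.phenotype.node_ids, "phenotype_gene rows"),
            (self.phenotype_gene.col_ids, self.gene.node_ids, "phenotype_gene cols"),
        ]
        for ids, universe, what in pairs:
            missing = set(ids) - set(universe)
            if missing:
                raise ValidationError(
                    f"{what} reference ids absent from the homo-network: "
                    f"{sorted(missing)[:5]}"
                )

    def homo(self, kind: NetworkKind) -> HomoNetwork:
        return {"drug": self.drug, "gene": self.gene, "phenotype": self.phenotype}[kind]


@dataclass
class ProbabilityState:
    """Converged probability vectors, one per homo-network."""

    vectors: dict[NetworkKind, np.ndarray]
    converged: bool = True
    iterations: dict[NetworkKind, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vectors = {k: np.asarray(v, dtype=float) for k, v in self.vectors.items()}


@dataclass
class ExpressionProfile:
    """Genes x samples expression values with case/control labels."""

    gene_ids: list[str]
    values: np.ndarray
    sample_labels: list[Literal["case", "control"]]

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.values = np.asarray(self.values, dtype=float)
        self.sample_labels = list(self.sample_labels)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids in expression profile")
        if self.values.shape != (len(self.gene_ids), len(self.sample_labels)):
            raise ValidationError(
                f"expression values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_labels)} samples"
            )
        bad = set(self.sample_labels) - {"case", "control"}
        if bad:
            raise ValidationError(f"unknown sample labels: {sorted(bad)}")
        n_case = self.sample_labels.count("case")
        n_ctrl = self.sample_labels.count("control")
        if n_case < 2 or n_ctrl < 2:
            raise ValidationError(
                f"need >= 2 case and >= 2 control samples, got {n_case}/{n_ctrl}"
            )
        if n_case < 3 or n_ctrl < 3:
            logger.warning(
                "only %d case / %d control samples; correlations will be noisy",
                n_case,
                n_ctrl,
            )

    @property
    def case_mask(self) -> np.ndarray:
        return np.array([lbl == "case" for lbl in self.sample_labels])

    def case_values(self) -> np.ndarray:
        return self.values[:, self.case_mask]

    def control_values(self) -> np.ndarray:
        return self.values[:, ~self.case_mask]


@dataclass
class BenchmarkSet:
    """Known drug associations for one query disease."""

    disease_id: str
    positive_drug_ids: set[str]

    def __post_init__(self) -> None:
        self.positive_drug_ids = set(self.positive_drug_ids)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_edge_list(path: str | Path, directed: bool = False) -> list[tuple[str, str, float]]:
    """Parse a 2- or 3-column TSV edge list.

    Two-column rows get weight 1.0.  For undirected input, duplicate pairs
    (in either orientation) collapse to the maximum weight.  Self-loops are
    dropped with a warning.
    """
    path = Path(path)
    edges: dict[tuple[str, str], float] = {}
    order: list[tuple[str, str]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ParseError(f"{path}:{lineno}: expected >= 2 columns, got {len(cols)}")
            u, v = cols[0].strip(), cols[1].strip()
            if len(cols) >= 3:
                try:
                    w = float(cols[2])
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: non-numeric weight {cols[2]!r}"
                    ) from None
            else:
                w = 1.0
            if w < 0:
                raise ValidationError(f"{path}:{lineno}: negative weight {w}")
            if u == v:
                logger.warning("%s:%d: dropping self-loop on %r", path, lineno, u)
                continue
            key = (u, v) if directed or u <= v else (v, u)
            if key in edges:
                edges[key] = max(edges[key], w)
            else:
                edges[key] = w
                order.append(key)
    return [(u, v, edges[(u, v)]) for u, v in order]


def read_association_pairs(path: str | Path) -> list[tuple[str, str]]:
    """Parse a 2-column TSV pair list; duplicates dropped, order kept."""
    path = Path(path)
    seen: set[tuple[str, str]] = set()
    pairs: list[tuple[str, str]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(cols)}")
            pair = (cols[0].strip(), cols[1].strip())
            if pair not in seen:
                seen.add(pair)
                pairs.append(pair)
    if not pairs:
        raise ValidationError(f"{path}: empty association-pair file")
    return pairs


def read_expression_matrix(path: str | Path, labels_path: str | Path) -> ExpressionProfile:
    """Read a genes x samples TSV matrix plus a sample -> case/control map.

    Samples keep the header order.  Genes with any missing value are dropped
    with a logged count.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    labels_df = pd.read_csv(labels_path, sep="\t", header=None, names=["sample", "label"])
    label_map = dict(zip(labels_df["sample"].astype(str), labels_df["label"].astype(str)))
    missing = [s for s in df.columns if s not in label_map]
    if missing:
        raise ValidationError(f"samples missing from label file: {missing}")
    n_before = len(df)
    df = df.dropna()
    if len(df) < n_before:
        logger.warning("dropped %d genes with missing expression values", n_before - len(df))
    labels = [label_map[s] for s in df.columns]
    return ExpressionProfile(
        gene_ids=[str(g) for g in df.index],
        values=df.to_numpy(dtype=float),
        sample_labels=labels,  # type: ignore[arg-type]
    )


def read_similarity_matrix(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a square TSV similarity matrix with id header row and column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(i) for i in df.index]
    if [str(c) for c in df.columns] != ids:
        raise ValidationError(f"{path}: row and column ids differ")
    return ids, df.to_numpy(dtype=float)


def write_similarity_matrix(path: str | Path, ids: Sequence[str], matrix: np.ndarray) -> None:
    """Write a square matrix as TSV with id header row and column."""
    pd.DataFrame(np.asarray(matrix), index=list(ids), columns=list(ids)).to_csv(
        path, sep="\t", float_format="%.10g"
    )


def read_fingerprints(path: str | Path) -> list["tuple[str, frozenset[int]]"]:
    """Read TSV of drug_id -> comma-separated set-bit indices."""
    path = Path(path)
    out: list[tuple[str, frozenset[int]]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ParseError(f"{path}:{lineno}: expected drug_id<TAB>bits")
            try:
                bits = frozenset(int(b) for b in cols[1].split(",") if b.strip())
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer bit index") from None
            out.append((cols[0].strip(), bits))
    return out


def write_ranking(
    path: str | Path,
    rows: Iterable[tuple[str, float, float, bool]],
) -> None:
    """Write a drug ranking as TSV: drug_id, probability, z_score, significant.

    Byte-deterministic for a fixed input; rows are expected sorted by z
    descending.
    """
    with Path(path).open("w") as fh:
        fh.write("drug_id\tprobability\tz_score\tsignificant\n")
        for drug_id, prob, z, flag in rows:
            fh.write(f"{drug_id}\t{prob:.10g}\t{z:.10g}\t{str(bool(flag)).lower()}\n")


def read_ranking(path: str | Path) -> list[tuple[str, float, float, bool]]:
    """Read a ranking TSV written by :func:`write_ranking`."""
    df = pd.read_csv(path, sep="\t")
    return [
        (str(r.drug_id), float(r.probability), float(r.z_score), str(r.significant) == "true" or r.significant is True)
        for r in df.itertuples()
    ]


def read_benchmark(path: str | Path, disease_id: str | None = None) -> BenchmarkSet:
    """Read a benchmark TSV of (disease_id, drug_id) pairs.

    If ``disease_id`` is given only its pairs are kept; otherwise the file
    must contain a single disease.
    """
    pairs = read_association_pairs(path)
    diseases = {d for d, _ in pairs}
    if disease_id is None:
        if len(diseases) != 1:
            raise ValidationError(
                f"benchmark file lists {len(diseases)} diseases; pass disease_id"
            )
        disease_id = next(iter(diseases))
    positives = {drug for dis, drug in pairs if dis == disease_id}
    if not positives:
        raise ValidationError(f"no benchmark positives for disease {disease_id!r}")
    return BenchmarkSet(disease_id=disease_id, positive_drug_ids=positives)


def node_order(ids: Iterable[str]) -> list[str]:
    """Stable first-appearance order with duplicates removed."""
    seen: set[str] = set()
    out: list[str] = []
    for i in ids:
        if i not in seen:
            seen.add(i)
            out.append(i)
    return out
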