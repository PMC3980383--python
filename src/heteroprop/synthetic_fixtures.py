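"""Self-contained synthetic fixtures with planted drug-disease associations.

The generator emulates the statistical structure of the real inputs — hashed
bit fingerprints, a block-structured phenotype similarity matrix, a
scale-free-ish protein-interaction network with a planted disease module,
case/control expression with elevated differential expression and
correlation inside the module, and drug-target links that send the planted
positive drugs to module genes — so the full pipeline is testable without
any external database.

All randomness flows through one seeded generator, so a fixture is
reproducible (byte-identical files) from a single integer seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from heteroprop.model_io import (
    BenchmarkSet,
    DiffusionConfig,
    ExpressionProfile,
    HomoNetwork,
    HeteroNetwork,
    IntegratedNetwork,
    ValidationError,
    write_similarity_matrix,
)
from heteroprop.edge_weights import Fingerprint


@dataclass
class FixtureSpec:
    """Parameters of one synthetic study.

    ``signal_strength`` is the differential-expression shift of module genes
    in case samples, in units of the within-class noise SD;
    ``within_module_corr`` is the pairwise correlation induced among module
    genes in case samples by a shared latent factor.  ``null_targets``
    redirects the planted positives' targets to background genes (the null
    control in which no route links the query disease to its benchmark
    drugs).
    """

    n_drugs: int = 60
    n_genes: int = 200
    n_phenotypes: int = 20
    n_case: int = 15
    n_ctrl: int = 15
    module_size: int = 20
    n_positive_drugs: int = 10
    signal_strength: float = 2.0
    within_module_corr: float = 0.6
    fingerprint_bits: int = 1024
    seed: int = 0
    null_targets: bool = False

    def __post_init__(self) -> None:
        for name in ("n_drugs", "n_genes", "n_phenotypes", "n_case", "n_ctrl",
                     "module_size", "n_positive_drugs"):
            if getattr(self, name) < 2:
                raise ValidationError(f"{name} must be >= 2")
        if self.module_size > self.n_genes:
            raise ValidationError("module_size exceeds n_genes")
        if self.n_positive_drugs > self.n_drugs:
            raise ValidationError("n_positive_drugs exceeds n_drugs")
        if self.signal_strength < 0:
            raise ValidationError("signal_strength must be >= 0")
        if not 0.0 <= self.within_module_corr < 1.0:
            raise ValidationError("within_module_corr outside [0, 1)")
        if self.fingerprint_bits < 8:
            raise ValidationError("fingerprint_bits too small")


@dataclass
class Fixture:
    """Generated inputs for one synthetic study, ready to write or assemble."""

    spec: FixtureSpec
    query_phenotype: str
    benchmark: BenchmarkSet
    fingerprints: list[Fingerprint]
    phenotype_ids: list[str]
    phenotype_raw: np.ndarray
    pin_edges: list[tuple[str, str]]
    expression: ExpressionProfile
    drug_target_pairs: list[tuple[str, str]]
    phenotype_gene_pairs: list[tuple[str, str]]
    module_genes: list[str] = field(default_factory=list)

    def write(self, out_dir: str | Path) -> dict[str, str]:
        """Write every input as TSV plus a JSON manifest; returns the paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "fingerprints": "fingerprints.tsv",
            "phenotype_similarity": "phenotype_similarity.tsv",
            "pin_edges": "pin_edges.tsv",
            "expression": "expression.tsv",
            "sample_labels": "sample_labels.tsv",
            "drug_targets": "drug_targets.tsv",
            "phenotype_genes": "phenotype_genes.tsv",
            "benchmark": "benchmark.tsv",
        }
        with (out / paths["fingerprints"]).open("w") as fh:
            for fp in self.fingerprints:
                fh.write(f"{fp.drug_id}\t{','.join(str(b) for b in sorted(fp.bits))}\n")
        write_similarity_matrix(out / paths["phenotype_similarity"], self.phenotype_ids, self.phenotype_raw)
        with (out / paths["pin_edges"]).open("w") as fh:
            for u, v in self.pin_edges:
                fh.write(f"{u}\t{v}\n")
        expr = self.expression
        with (out / paths["expression"]).open("w") as fh:
            samples = [f"S{i}" for i in range(len(expr.sample_labels))]
            fh.write("gene\t" + "\t".join(samples) + "\n")
            for g, row in zip(expr.gene_ids, expr.values):
                fh.write(g + "\t" + "\t".join(f"{x:.6g}" for x in row) + "\n")
        with (out / paths["sample_labels"]).open("w") as fh:
            for i, lbl in enumerate(expr.sample_labels):
                fh.write(f"S{i}\t{lbl}\n")
        with (out / paths["drug_targets"]).open("w") as fh:
            for d, g in self.drug_target_pairs:
                fh.write(f"{d}\t{g}\n")
        with (out / paths["phenotype_genes"]).open("w") as fh:
            for p, g in self.phenotype_gene_pairs:
                fh.write(f"{p}\t{g}\n")
        with (out / paths["benchmark"]).open("w") as fh:
            for d in sorted(self.benchmark.positive_drug_ids):
                fh.write(f"{self.benchmark.disease_id}\t{d}\n")
        manifest = {
            "query_phenotype": self.query_phenotype,
            "spec": asdict(self.spec),
            "files": paths,
        }
        with (out / "manifest.json").open("w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return {k: str(out / v) for k, v in paths.items()}

    def assemble(self, config: DiffusionConfig | None = None) -> IntegratedNetwork:
        from heteroprop.assemble import assemble_network

        return assemble_network(
            fingerprints=self.fingerprints,
            phenotype_ids=self.phenotype_ids,
            phenotype_raw=self.phenotype_raw,
            pin_edges=self.pin_edges,
            expression=self.expression,
            drug_target_pairs=self.drug_target_pairs,
            phenotype_gene_pairs=self.phenotype_gene_pairs,
            config=config,
        )


def generate_fixture(spec: FixtureSpec, out_dir: str | Path | None = None) -> Fixture:
    """Generate one synthetic study; optionally write its input files.

    Construction: (a) random ~8%-density bit fingerprints, with the planted
    positive drugs sharing a common bit block; (b) control expression is
    i.i.d. standard normal, case samples add ``signal_strength`` to module
    genes plus a shared latent factor inducing ``within_module_corr``;
    (c) the PIN is a preferential-attachment background graph densified on
    the module genes; (d) phenotype similarity is block-structured, with the
    query's block in the informative band [0.6, 0.9] and everything else in
    [0.05, 0.3]; (e) the query phenotype (and its block) link to module
    genes, other phenotypes to background genes; (f) positives target module
    genes (background genes under ``null_targets``), negatives target
    background genes; (g) the benchmark is the planted positive set.
    """
    rng = np.random.default_rng(spec.seed)
    drugs = [f"D{i:03d}" for i in range(spec.n_drugs)]
    genes = [f"G{i:03d}" for i in range(spec.n_genes)]
    phenos = [f"P{i:02d}" for i in range(spec.n_phenotypes)]
    module = genes[: spec.module_size]
    background = genes[spec.module_size :]
    positives = drugs[: spec.n_positive_drugs]
    query = phenos[0]

    # (a) fingerprints: ~8% random bits; positives share a common block
    density = 0.08
    shared_block = rng.choice(spec.fingerprint_bits, size=max(8, spec.fingerprint_bits // 25), replace=False)
    fps = []
    for d in drugs:
        bits = set(np.nonzero(rng.random(spec.fingerprint_bits) < density)[0].tolist())
        if d in positives:
            bits |= set(shared_block.tolist())
        if not bits:  # astronomically unlikely; keep fingerprints non-empty
            bits = {int(rng.integers(spec.fingerprint_bits))}
        fps.append(Fingerprint(drug_id=d, bits=frozenset(int(b) for b in bits)))

    # (b) case/control expression
    n_samples = spec.n_case + spec.n_ctrl
    values = rng.standard_normal((spec.n_genes, n_samples))
    labels = ["case"] * spec.n_case + ["control"] * spec.n_ctrl
    rho = spec.within_module_corr
    latent = rng.standard_normal(spec.n_case)
    for gi in range(spec.module_size):
        noise = rng.standard_normal(spec.n_case)
        values[gi, : spec.n_case] = (
            spec.signal_strength + np.sqrt(rho) * latent + np.sqrt(1.0 - rho) * noise
        )
    expression = ExpressionProfile(gene_ids=genes, values=values, sample_labels=labels)  # type: ignore[arg-type]

    # (c) PIN: preferential-attachment background + dense module subgraph.
    # ~5% of genes stay outside the PIN (real interactomes are incomplete);
    # any of them picked as a drug target exercises the sink smoothing.
    n_pinless = min(max(2, spec.n_genes // 20), spec.n_genes - spec.module_size)
    n_pin = spec.n_genes - n_pinless
    g_bg = nx.barabasi_albert_graph(n_pin, m=2, seed=int(rng.integers(2**31)))
    pin = {tuple(sorted((genes[u], genes[v]))) for u, v in g_bg.edges()}
    for i in range(spec.module_size):
        for j in range(i + 1, spec.module_size):
            if rng.random() < 0.3:
                pin.add(tuple(sorted((module[i], module[j]))))
    pin_edges = sorted(pin)

    # (d) phenotype similarity: query block vs the rest
    block = phenos[: max(2, spec.n_phenotypes // 5)]  # query's disease family
    raw = np.zeros((spec.n_phenotypes, spec.n_phenotypes))
    for i in range(spec.n_phenotypes):
        for j in range(i + 1, spec.n_phenotypes):
            related = phenos[i] in block and phenos[j] in block
            raw[i, j] = rng.uniform(0.6, 0.9) if related else rng.uniform(0.05, 0.3)
            raw[j, i] = raw[i, j]

    # (e) gene-phenotype links
    gp_pairs: list[tuple[str, str]] = []
    n_links = min(8, spec.module_size)
    for p in phenos:
        if p in block:
            chosen = rng.choice(spec.module_size, size=n_links, replace=False)
            gp_pairs.extend((p, module[i]) for i in sorted(chosen))
        else:
            chosen = rng.choice(len(background), size=min(5, len(background)), replace=False)
            gp_pairs.extend((p, background[i]) for i in sorted(chosen))

    # (f) drug targets
    dt_pairs: list[tuple[str, str]] = []
    for d in drugs:
        n_targets = int(rng.integers(2, 5))
        if d in positives and not spec.null_targets:
            pool, names = spec.module_size, module
        else:
            pool, names = len(background), background
        chosen = rng.choice(pool, size=min(n_targets, pool), replace=False)
        dt_pairs.extend((d, names[i]) for i in sorted(chosen))

    fixture = Fixture(
        spec=spec,
        query_phenotype=query,
        benchmark=BenchmarkSet(disease_id=query, positive_drug_ids=set(positives)),
        fingerprints=fps,
        phenotype_ids=phenos,
        phenotype_raw=raw,
        pin_edges=pin_edges,
        expression=expression,
        drug_target_pairs=dt_pairs,
        phenotype_gene_pairs=gp_pairs,
        module_genes=list(module),
    )
    if out_dir is not None:
        fixture.write(out_dir)
    return fixture


def toy_network(variant: str = "chain", config: DiffusionConfig | None = None) -> IntegratedNetwork:
    """Hand-sized fixed-weight network for oracle tests.

    Variants: ``chain`` — the P1-G1-D1 path (P1 similar to P2 at 0.5, gene
    edge G1-G2 weight 1, drug edge D1-D2 weight 0.2, D1 targets G1, P1
    associates with G1); ``twin`` — both drugs target G1 with identical drug
    similarities, so their converged probabilities must coincide;
    ``uniform`` — all gene edge weights already 1, so the topology-reference
    run coincides with the main run.
    """
    if config is None:
        config = DiffusionConfig(
            alpha={"drug": 0.1, "gene": 0.2, "phenotype": 0.1},
            coefficient_mode="strict",
        )
    w_p = np.array([[0.0, 0.5], [0.5, 0.0]])
    w_g = np.array([[0.0, 1.0], [1.0, 0.0]])
    if variant == "chain":
        w_d = np.array([[0.0, 0.2], [0.2, 0.0]])
        dg = np.array([[1.0, 0.0], [0.0, 0.0]])  # D1 -> G1 only
    elif variant == "twin":
        w_d = np.array([[0.0, 0.2], [0.2, 0.0]])
        dg = np.array([[1.0, 0.0], [1.0, 0.0]])  # both drugs -> G1
    elif variant == "uniform":
        w_d = np.array([[0.0, 0.2], [0.2, 0.0]])
        dg = np.array([[1.0, 0.0], [0.0, 0.0]])
        w_g = np.array([[0.0, 1.0], [1.0, 0.0]])  # already all-ones weights
    else:
        raise ValidationError(f"unknown toy variant {variant!r}")
    pg = np.array([[1.0, 0.0], [0.0, 0.0]])  # P1 -> G1
    return IntegratedNetwork(
        drug=HomoNetwork(["D1", "D2"], w_d, "drug"),
        gene=HomoNetwork(["G1", "G2"], w_g, "gene"),
        phenotype=HomoNetwork(["P1", "P2"], w_p, "phenotype"),
        drug_gene=HeteroNetwork(["D1", "D2"], ["G1", "G2"], dg),
        phenotype_gene=HeteroNetwork(["P1", "P2"], ["G1", "G2"], pg),
        config=config,
    )
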