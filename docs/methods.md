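# Methods

## Model

The method treats drug–disease inference as a random walk with restart on
an integrated heterogeneous network. Three undirected weighted
homo-networks — drugs, genes/proteins, disease phenotypes — are joined by
two bipartite hetero-networks (drug–target, gene–phenotype). Probability
mass starts on the query phenotype, diffuses within each homo-network, and
crosses between networks through the bipartite links; drugs reachable from
the disease through phenotypically similar diseases, disease genes, and the
perturbed interactome end up with high visitation probability.

Assumptions worth stating explicitly:

- Similarity is relevance: chemically similar drugs are assumed to share
  targets and indications, phenotypically similar diseases to share genes.
  Both assumptions fail for specific cases (similar scaffolds with
  different targets), which is why the drug network gets the smallest
  diffusion parameter by default.
- The expression weighting assumes the case/control contrast captures the
  disease process: edges between co-expressed, differentially expressed
  genes carry the signal. Correlation is computed from case samples only;
  the differential term uses within-class means over all samples.
- Hetero links are treated as binary presence/absence. A
  `--weighted-hetero` switch preserves supplied confidence values for
  sources that provide them.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` (drug/gene/phenotype) | 0.1 / 0.7 / 0.3 | per-network diffusion: fraction of mass passed onward per step; `1−α` restarts at the (enriched) initial distribution. Defaults are the setting that maximized benchmark AUC in the sweep over the 5×5×5 grid {0.1,…,0.9}³. |
| `coefficient_mode` | `literal` | handling of the restart weight `a_i = 1 − k_i α_i` (see below) |
| `tol` | 1e-9 | L2 convergence threshold of the walk |
| `max_iter` | 10000 | iteration cap at both inner and outer level |
| logistic `c`, `d` | −15, ln 9999 | phenotype-score calibration: transform(0) = 1e-4, midpoint ≈ 0.614, so the informative band [0.6, 1] maps near 1 and the non-informative band [0, 0.3] near 0 |
| `z_threshold` | 2.33 | one-tailed p = 0.01 significance cut on the Z-score |
| `z_mode` | `set` | `set`: standardize `P(v)` by the scalar mean/std of the reference distribution; `nodewise`: standardize the per-node excess `P(v) − P^ref(v)` |

`k_i` is the number of hetero-networks attached to network *i* (drug 1,
gene 2, phenotype 1 in the standard layout); it is derived from the layout,
so two- or four-network layouts work unchanged.

## Update equations and their stationary point

After degree normalization `S = D_r^{-1/2} W D_c^{-1/2}`, network *i*
iterates

    p_i^t = (1 − α_i)(1 − k α_i) p_i^0 + α_i Σ_{j≠i} S_ij p_j^0 + α_i S_i p_i^{t−1}

with the neighbor vectors `p_j^0` held fixed during the inner loop; outer
sweeps are synchronous — every inner solve in a sweep reads the previous
sweep's converged neighbor vectors while the restart term stays anchored at
the query distribution. That makes the result independent of the order in
which networks are updated, and the limit the unique stationary point of
the coupled linear system `x = b + A x`, where `A` stacks `α_i S_i` on the
diagonal and `α_i S_ij` off-diagonal and `b_i = (1−α_i)(1−kα_i) p_i^0`.
(Replacing the restart anchor itself each sweep would make the map
homogeneous, whose only fixed point is zero and whose iterates lose the
query entirely; the anchored reading is the one under which the procedure
computes something query-specific.)

With several query phenotypes the initial mass is split uniformly so the
phenotype vector sums to one, preserving the probability reading of the
mixing constraint `a_i + Σ_j b_ij = 1`.

## Numerical behaviour: the stability boundary

The default gene parameter sits at the edge of stability. With `α_g = 0.7`
and `k = 2`, the restart weight is `a_g = 1 − 1.4 = −0.4`, and the spectral
radius of `A` lands at ≈ 0.99–1.02 depending on the realized network: the
aligned degree directions of the normalized blocks push the radius to ~1,
and only their imperfect alignment decides the side. Consequences and
choices:

- `coefficient_mode='strict'` rejects any configuration with a negative
  restart weight (so it rejects the default gene setting);
  `'literal'` (default) uses the formula as written.
- The converged state is *defined* as the stationary point of the coupled
  system. Small networks (≤ 2000 nodes, `solver='auto'`) compute it by one
  direct linear solve. When ρ(A) < 1 this is exactly the sweep limit (the
  sweep map is a regular splitting, so the two convergence conditions
  coincide), just much faster near ρ ≈ 1, where plain iteration needs ~10⁶
  sweeps to reach 1e-9. When ρ(A) ≥ 1 the iteration diverges; the
  stationary point still exists (unless an eigenvalue of `A` sits at 1,
  which raises a convergence error) and is returned with a logged warning.
  In that regime the solution can carry negative entries — they are clamped
  to zero at read-out with a logged count, and on some replicates the
  entire drug block clamps to zero, yielding an uninformative (AUC ≈ 0.5)
  ranking for that replicate. This is a property of the update equations at
  the default parameters, not of the solver; replicate medians absorb it.
- `solver='sweep'` keeps the literal iterate-until-converged semantics and
  raises on divergence; the test suite uses it to confirm both routes agree
  where iteration converges.
- Degenerate inputs: zero-sum rows/columns normalize to zero (no division
  error); a zero-variance gene makes the correlation undefined and the edge
  weight is set to 0 with a warning rather than dropping the gene; two
  empty fingerprints make the Tanimoto coefficient 0/0 and raise.
- Ties in the drug ranking break lexicographically by drug id, and the
  ranking TSV is byte-deterministic for fixed input.

## Z-score specificity

The reference run replaces every PIN edge weight by 1 (re-applying the
1/(n−1) sink smoothing on the clone so smoothed rows stay smoothed rather
than inflating to weight-1 rows) and repeats the propagation; a node's
probability is standardized against the reference distribution of its
network using the population (divide-by-N) standard deviation, since the
reference set is the whole distribution, not a sample. Two consequences are
documented rather than hidden: in `set` mode the mean and std are scalars,
so the drug ordering by Z equals the ordering by raw probability (a
regression test asserts this), and the number of drugs passing `Z > 2.33`
depends on how compressed the reference distribution is, so it varies
widely between replicates. The `nodewise` mode (`P(v) − P^ref(v)`, same
scalar std) corrects centrality per node and is exposed as an option
without being the default.

## Synthetic studies

The fixture generator emulates the statistical structure of the real
inputs so the whole pipeline is testable without external databases:

- fingerprints: 1024-bit hashed fingerprints with ~8% random density;
  planted positive drugs share a common 40-bit block, making them
  chemically similar to each other;
- expression: 15 case / 15 control samples (a typical small case/control
  microarray study); controls are i.i.d. standard normal; case samples add
  `signal_strength` (default 2.0 noise-SD units) to the 20 module genes
  plus one shared latent factor inducing pairwise correlation
  `within_module_corr` (default 0.6) — the simplest generative model of a
  co-expressed disease module;
- PIN: preferential-attachment background (m = 2) densified to ~30% edge
  probability inside the module; ~5% of genes stay outside the PIN so
  hetero-referenced targets exercise the sink smoothing;
- phenotype similarity: the query's block draws raw scores from
  [0.6, 0.9], all other pairs from [0.05, 0.3], mirroring the
  informative/non-informative score bands;
- links: the query block's phenotypes link to module genes; positives
  target module genes, background drugs (and positives under the null
  preset) target background genes; the benchmark is the planted positive
  set.

All draws flow through a single seeded generator, so a fixture is
byte-reproducible from one integer. What passing on these fixtures does
*not* show: real chemical-similarity distributions are far from uniform
random bits, real PINs have richer degree structure and noise in the
interactions themselves, and real case/control studies carry batch effects
and confounders the generator omits. Recovery of the planted signal
demonstrates the propagation and scoring machinery, not expected accuracy
on real databases.

## Problem sizes

The test suite and the acceptance script run the default study (60 drugs /
200 genes / 20 phenotypes) across 10–20 replicate seeds per condition and a
reduced study (20/50/8) for the 125-cell parameter sweep; these sizes give
stable medians in seconds while exercising every code path, and scale-up is
a matter of the input files supplied.

## Known limitations

- Only Tanimoto on bit fingerprints is implemented for drug similarity; no
  Dice/cosine variants, no atom-level descriptors.
- Identifier mapping (UniProt→Entrez and the like) is assumed done
  upstream; identifiers are opaque strings.
- The `set`-mode Z-score does not change the drug ordering relative to raw
  probabilities (see above); per-node correction is available but
  non-default.
- No GSEA/DAVID enrichment of the significant gene sets, and no database
  scrapers — the tool consumes pre-extracted flat files only.
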