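# Methods

`pathminer` identifies *active* miRNA–TF–gene regulatory pathways: directed
regulatory cascades that both respond transcriptionally to a two-group
contrast (e.g. control vs disease) and are enriched for nodes already known
to be disease-associated. This note documents the model, the tunable
parameters, the synthetic-data generator, and the numerical and design
choices behind the implementation.

## Pipeline model

The analysis composes five stages. Each is available as a library function
and as a CLI subcommand; `run_pipeline` chains them from a single YAML
config and writes every intermediate artifact, since the per-stage counts
(number of DE features, subnetwork size, path counts) are the analysis'
main audit trail.

### 1. Differential expression

Expression matrices are features × samples on a log-intensity scale, with
sample labels in {control, case}. Probe-level arrays are first collapsed to
one row per gene by averaging the probe rows mapped to it (`collapse_probes`;
unmapped probes are dropped and counted). The per-feature statistic is the
moderated d score

    d_i = (x̄_case,i − x̄_control,i) / (s_i + s0)

where `s_i` is the pooled standard error of the mean difference
(`sqrt(pooled_var · (1/n₁ + 1/n₂))`, pooled variance on n₁+n₂−2 df) and the
fudge factor `s0 ≥ 0` stabilises features with tiny spread. By default
`s0` is the median of the per-feature pooled standard errors, a standard
convention for this family of statistics; it is configurable, including 0
(in which case a feature with zero spread in both groups raises an error
rather than returning an undefined score).

Significance comes from group-label permutations. Permuted |d*| scores are
pooled across *all* features into one empirical null, and

    p_i = (1 + #{pooled permuted |d*| ≥ |d_i|}) / (1 + n_used · n_features).

When the number of distinct case/control assignments C(n, n_case) does not
exceed the requested permutation count, assignments are enumerated
exhaustively (so small designs get exact rank p-values); otherwise `n_perm`
assignments are sampled uniformly with replacement from a seeded generator.
q-values are Benjamini–Hochberg over the per-feature p-values. This is a
deliberately simplified variant of the classic microarray permutation
machinery: the delta-table/90th-percentile FDR sweep is not reproduced,
because downstream stages consume only a thresholded DE call.

Thresholds follow the two-rule convention of multi-omic designs: genes are
called DE at BH q < `gene_fdr` (default 0.01) **on every platform**
(`intersect_platforms`, mirroring multi-chip designs where a gene is only
trusted if all platforms agree); miRNAs — typically measured on a single
platform with few samples — are called at raw p ≤ `mirna_p` (default 0.05).
A generic sample-exclusion list (one id per line) supports removing
confounded subjects before testing.

### 2. Curated network construction

Regulatory edge lists (five-column TSV or SIF with a node-class sidecar)
declare each node's class in {miRNA, TF, gene}; classes are never inferred,
and an id declared with two classes is a hard error. Merging collapses
redundant edges between the same ordered pair into one edge whose
provenance is the union of the contributing resource labels, and deletes
self-directed edges while retaining their nodes. Edges are unweighted and
direction-only. IDs are opaque case-sensitive strings; no symbol
normalisation is attempted.

### 3. Active subnetwork

DE genes and miRNAs present in the network become seeds; the potential
active subnetwork is the seeds plus their immediate in- and out-neighbors
(upstream regulators *and* downstream targets — disease-relevant hubs can
hide just outside the DE set). By default the edge set is the induced
subgraph (neighbor–neighbor edges retained, giving a connected regulatory
web); `edge_policy: star` keeps only seed-incident edges.

### 4. Path enumeration and filtering

Candidate cascades are all simple directed paths from 0-indegree nodes
(upstream regulators nothing else regulates) to 0-outdegree nodes
(downstream targets that regulate nothing else). Because miRNA/TF feedback
makes the subnetwork cyclic, acyclicity is enforced per path: no node is
visited twice. Traversal is an iterative depth-first frontier expansion
with explicit path stacks; neighbor order is sorted, so output order is
deterministic (lexicographic at each branch). Correctness is defined by
the path *set*, which tests check against an independently coded recursive
search and, on DAGs, a dynamic-programming path count.

Path length counts **nodes**. Combinatorial growth is real, so two caps are
mandatory contracts: `max_len` (default 20 nodes) and `max_paths` (default
10⁶); hitting `max_paths` sets a truncation flag rather than raising.

A path qualifies as a *potential active pathway* when it has ≥ 3 nodes,
contains at least `min_de_nodes` (default 1) DE nodes, and no run of more
than one consecutive "inactive" node — non-DE **or lacking expression
measurements** — lies strictly between two DE nodes. Under the default
`terminal_rule: internal_only`, leading and trailing inactive runs are
unconstrained (the rule as stated governs gaps *between* DE nodes);
`all_runs` extends the constraint to the ends for users who want a stricter
reading.

### 5. Coverage scoring

Each potential active pathway is scored by its coverage rate

    CR = N_D / N_T,

the fraction of its N_T nodes that belong to the known disease-associated
list. Significance is the hypergeometric upper tail P(X ≥ N_D) for drawing
N_T nodes without replacement from a background of N nodes of which K are
known (evaluated in log space; stable to N ≈ 10⁵), followed by BH
adjustment across all candidate paths. Paths with q < `pathway_fdr`
(default 0.0005) form the active set, sorted by (q, p, −CR, path string)
for full determinism. The active set's union graph merges identical nodes
across paths and carries node classes over.

The default background is the *in-pathway* population: N = distinct nodes
across all potential active pathways, K = known nodes among them. Published
analyses of this kind rarely state their background population, and the
choice materially changes p-values, so both N and K can be overridden in
the config (`background: [N, K]`).

## Synthetic data generator

The generator (`simulate_study`) emulates the structure of a two-group,
multi-platform microarray study paired with a curated typed network. Its
defaults are the package's reference study conditions:

| parameter | default | meaning |
|---|---|---|
| n_tf / n_mirna / n_gene | 25 / 18 / 150 | node counts of the random network |
| density (per edge type) | 0.02–0.03 | Bernoulli probability per allowed class pair |
| n_control / n_case | 20 / 19 | samples per group (both datasets) |
| n_platforms | 6 | probe-level mRNA platforms, 1–3 probes per gene each |
| de_fraction | 0.1 | off-path nodes given a case-group shift |
| effect_size | 2.0 | shift of DE features, in noise-SD units |
| noise_sd | 1.0 | Gaussian noise SD on the log-intensity scale |
| baseline | 8.0 | mean log intensity |
| planted_path_len | 9 | nodes in the planted cascade |
| known_list_size | 12 | known-list size (planted nodes + contaminants) |
| planted_known_fraction | 1.0 | fraction of planted nodes put in the known list |
| unmeasured_fraction | 0.05 | network nodes with no expression rows |

Allowed edge types are TF→gene, TF→miRNA, miRNA→gene and miRNA→TF: genes
are pure targets, so self-loops cannot arise. The planted cascade
alternates miRNA and TF nodes and ends at a gene; background edges into its
head and out of its tail are removed, making the head a genuine 0-indegree
source and the tail a 0-outdegree sink, so the cascade must appear among
enumerated source→sink paths if its nodes survive DE detection and
filtering. All planted nodes receive the case-group shift and (by default)
known-list membership — the planted cascade models a fully curated disease
pathway, like the CR = 1 cascades such analyses report — while the known
list is topped up with random off-path contaminants so the hypergeometric
background is non-degenerate.

Default sizing was chosen so that a recovered planted cascade is clearly
significant under the in-pathway background: with ~150-node networks the
potential-pathway population is typically N ≈ 40–80 with K ≤ 12 known, and
a fully-known 9-node path has tail probability C(K,9)/C(N,9) ≈ 10⁻⁷–10⁻⁹,
surviving BH at 0.0005 across the few hundred to few thousand competing
paths these densities produce. Sample sizes (20/19) follow a typical
adipose-tissue cohort; the generator applies one sample-size pair to both
the mRNA and miRNA datasets even though real paired designs often profile
different cohorts per molecule type.

What the generator does **not** emulate: probe-affinity effects,
saturation, array batch effects, scale-free topology, correlated
expression along regulatory edges, and non-Gaussian noise. Passing the
recovery tests therefore demonstrates the pipeline's logic and calibration
under its stated noise model, not robustness to real microarray artifacts.

Generation is a pure function of the spec (including its seed): the same
spec reproduces identical bytes on disk. Flattened edge lists write
isolated nodes as self-directed rows, which the merge step turns back into
bare nodes, making write → read round-trips exact.

## Numerical and design choices

- **Exhaustive vs sampled permutations.** Exhaustive enumeration below the
  `n_perm` threshold makes small-design p-values exact and removes Monte
  Carlo noise from tests; sampling is with replacement, which keeps the
  estimator unbiased and the implementation simple.
- **Pooled permutation null.** Pooling |d*| across features multiplies the
  effective null sample size by `n_features`, giving usable p-value
  resolution (min p ≈ 1/(n_perm·n_features)) at modest permutation counts.
  The cost is mild conservatism when many features are truly shifted.
- **Degenerate inputs.** Zero spread with s0 = 0 raises; empty seed sets
  yield an empty subnetwork with a warning; zero candidate paths yield
  empty score tables; `fdr = 0` yields an empty active set (strict
  inequality); a known list disjoint from the background warns and returns
  p = 1 everywhere.
- **Tie-breaking.** Score ordering falls back to the path's node sequence,
  so outputs are byte-identical across reruns with the same config.
- **Seeds.** Every stochastic step (permutation tests per platform,
  generator) derives a child seed from the config/spec seed via
  `numpy.random.SeedSequence`, so a single integer reproduces a whole run.

## Test problem sizes

The suites run the generator at reduced scale where full defaults add
nothing: unit tests use ~30–40-node networks and 4–6 samples per group;
the calibration suites use the sizes their claims are about (null: 500
features, 10+10 samples, 200 permutations, 50 replicates; power: 200
features, 3-SD shifts, 20 replicates; end-to-end recovery: the default
study conditions above, 20 seeded replicates).

## Known limitations

- The spacing filter reads "no more than one inactive node between DE
  nodes" as a constraint on *maximal runs*; with fewer than two DE nodes in
  a path the between-DE constraint is vacuous, so `min_de_nodes` exists for
  users who want to require two.
- The hypergeometric model treats path nodes as a uniform draw from the
  background, ignoring path length correlations and shared sub-cascades;
  no degree-preserving or rewiring null is provided.
- No expression normalisation, background correction or batch correction:
  inputs are assumed preprocessed.
- Identifier harmonisation (gene symbols, miRNA naming versions) is out of
  scope; ids are matched as exact strings across all inputs.
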