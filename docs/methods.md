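# Methods

This note records the modeling choices, conventions and defaults of
`rhizonet`, and what the synthetic-data experiments do and do not
demonstrate.

## Interaction descriptors

Abundances enter the descriptors on the `log10(x + 1)` scale, so zero
counts stay at zero and a zero-abundance OTU simply drops out of every
pair involving it. For a pair with transformed abundances
`x_u > x_v > 0` the four descriptors are

- mutualism `Z_mu = x_u x_v / (x_u − x_v)`,
- antagonism `Z_an = 1 / (x_u x_v (x_u − x_v))`,
- aggression `Z_ag = x_u / x_v`,
- altruism `Z_al = 1 − x_v / x_u`.

Useful identities, enforced by tests: `Z_al = 1 − 1/Z_ag`,
`Z_mu · Z_an = 1/(x_u − x_v)²`, `Z_ag > 1`, `Z_al ∈ (0, 1)`. `Z_ag`
and `Z_al` depend only on the abundance ratio. Tied pairs
(`x_u = x_v`) make the difference-denominators vanish; they are
excluded rather than epsilon-perturbed, since with continuous
abundances exact ties have probability ~0. Antagonism values are used
as printed — a large `Z_an` (small product and small gap) is read as
strong antagonism; no sign flip is applied.

Each host × type matrix is min–max normalized over its own defined
entries (per-host scope, the default; a `scope="global"` switch pools
the min/max across hosts for cross-host comparability, and the choice
is recorded in the run manifest). A degenerate range (all entries
equal) maps to 0. Sparsification retains entries **strictly** above
the threshold; shipped thresholds are 0.95 for mutualism, antagonism
and aggression and 0.99 for altruism. Because the normalized maximum
is exactly 1, every non-degenerate matrix keeps at least one edge.

A consequence worth knowing: `Z_mu` and `Z_an` diverge as
`x_u → x_v`, so the matrix maximum is usually an extreme outlier and
min–max normalization pushes the bulk of entries far below the
threshold. Per-host networks are therefore very sparse (often a
handful of edges among thousands of candidate pairs), and several
emergent indices take few distinct values across hosts. This is
intrinsic to the descriptor/threshold design, not an implementation
artifact.

## Networks and emergent indices

Mutualism and antagonism networks are undirected; aggression and
altruism are directed from the more to the less abundant member. All
OTUs of the panel remain as nodes, so isolated nodes dilute
network-level means. All centralities are computed on the unweighted
topology (an edge either survived thresholding or did not); retained
weights are export-only.

Conventions for possibly disconnected graphs:

- **closeness** uses the Wasserman–Faust correction
  `(r / Σ d) · (r / (N − 1))` over the `r` nodes reachable from the
  node (outward distances in directed graphs); isolated or sink nodes
  get 0;
- **betweenness** is the raw shortest-path count (no pair
  normalization), unordered pairs for undirected graphs;
- **eccentricity** is the maximum distance to reachable nodes, 0 when
  none;
- **eigencentrality** is the leading eigenvector of the symmetrized
  binary adjacency, non-negative, scaled to maximum 1 (all zeros for
  an edgeless graph);
- **PageRank** uses damping 0.85 (tolerance 1e-12; uniform `1/N` for
  edgeless graphs).

All four path-based quantities and PageRank are verified against
independent brute-force oracles (Floyd–Warshall distances, explicit
path counting, dense power iteration) on every graph with at most six
nodes and on random directed graphs.

The six network-level indices are the edge density (`Con`, which
respects directedness) and the mean over all nodes of each of the five
node centralities. Mean-over-nodes is an explicit convention of this
package. One known degeneracy follows from it: PageRank sums to 1 over
nodes, so the mean-PageRank index is the constant `1/N` whenever the
panel size is fixed — it is kept for interface completeness but
carries no between-host signal (its association scans are reported but
deflated by construction). Density is likewise topology-only.

## Hub taxa

Hubs of a network are nodes whose degree **and** closeness both
strictly exceed their cutoffs. Cutoffs are either absolute values or,
by default, the 0.90 quantile of each metric among non-isolated nodes
(a quantile of 0 disables that cutoff, so every non-isolated node can
qualify; as the quantile approaches 1 the hub set empties — strict
exceedance of the maximum is impossible). Absolute, data-derived
cutoffs as used on specific datasets are supported via the override;
quantile mode is the portable default and both are logged.

Hub calling runs on the consensus network of each interaction type,
built from the across-host mean of log-transformed abundances through
the same normalize/threshold path, giving one hub set per type. Hubs
and non-hubs carry the field's role vocabulary per type:
leaders/followers, antagonists/agonists, hawks/doves,
beneficiaries/altruists. The hub-vs-non-hub abundance comparison is a
Wilcoxon rank-sum test of mean log10 abundance (one-sided "hubs more
abundant" per the role semantics, with the two-sided p also reported).
Hub calling itself is purely cutoff-based; no significance is attached
to hub membership.

## Association mapping

SNPs are filtered to minor allele frequency strictly above 5%
(computed on non-missing calls); SNPs with more than 10% missing calls
are dropped, and remaining missing calls are mean-imputed per SNP
(genotypes are 0/1 on inbred homozygous hosts; heterozygous VCF calls
are treated as missing). Phenotypes are `log10(index + 1e-6)`; the
offset keeps exact-zero indices finite and is recorded in the
manifest.

The per-SNP model is simple linear regression of the transformed
phenotype on the 0/1 genotype, with optional covariate columns (e.g.
subpopulation memberships, the Q-model) projected out of both sides —
algebraically identical to including them in the fit. The
implementation is closed-form and vectorized over SNPs; tests pin it
to statsmodels OLS at 1e-10 relative accuracy. Mixed-model (kinship)
correction is out of scope; on structured synthetic data the Q-model
covariates demonstrably reduce the genomic-control lambda.

Significance uses the fixed line `−log10(P) ≥ 5` (inclusive); no
further multiple-testing correction is applied, though the hit table
carries everything needed to add one. `lambda_GC` is the median
observed 1-df chi-square over its theoretical median (0.4549).

Heritability: per-SNP h² is the R² of the single-SNP fit; the total
SNP-h² of a phenotype is the R² of the joint OLS fit on all its
significant SNPs. When the number of hits reaches `n − 1` the joint
fit switches to ridge regression with a fixed small penalty
(`1e-3 · n` on the Gram diagonal) and the table flags it. This joint-R²
convention is a deliberate, recorded choice; other estimators of
SNP-based heritability exist and will not agree numerically.

## QTL networks

For each phenotype with at least two significant SNPs, the phenotype
is re-expressed per SNP as genotype-group means (hosts split at call
0.5, so each column takes at most two values; the column mean always
equals the phenotype mean). A Bayesian network over these columns is
learned by greedy hill climbing — add/delete/reverse moves, acyclicity
enforced per move, a parent cap (default 3), random restarts (default
10, seeded) — maximizing the Gaussian BIC
`Σ_nodes [loglik(child | parents) − ½ log(n) · k]` with MLE variance
(floored at 1e-12) and `k` counting coefficients, intercept and
variance. The score is decomposable and cached per
(child, parent-set). Constant columns are excluded with a warning.

On 4-node problems the climber attains the exhaustive-enumeration
optimum (543 DAGs) in ≥ 95% of random datasets, and recovers the
X→Y→Z chain skeleton from simulated chains at n = 500. Edge
directions are statistical dependency orientations chosen by the
score; because genotype-mean columns are deterministic functions of
genotype, they must not be read as biological causality. Hub QTLs are
nodes whose total degree strictly exceeds the 0.90 quantile among
non-isolated nodes (absolute override available).

## Synthetic data

The generator emulates the targeted study design: 179 inbred hosts, a
panel of the 100 most abundant bacterial and 100 most abundant fungal
OTUs (integer ids, bacteria first), and thousands of biallelic SNPs
whose ancestral allele frequencies are uniform on (0.01, 0.5) — i.e.
spanning both sides of the 5% MAF filter. Defaults:

| parameter | default | meaning |
|---|---|---|
| `n_hosts` | 179 | cohort size |
| `n_bacteria`, `n_fungi` | 100, 100 | OTU panel per kingdom |
| `n_snps` | 2000 | biallelic markers |
| `maf_range` | (0.01, 0.5) | ancestral allele frequency range |
| `n_causal` | 0 | planted SNPs (0 = null data) |
| `n_affected_otus` | 5 | OTUs shifted per causal SNP |
| `effect_size` | 1.0 | per-allele shift of log10 abundance |
| `abundance_log_mean_range` | (1.0, 4.0) | OTU baseline log10 abundance |
| `abundance_log_sd` | 0.5 | per-host log10 abundance noise |
| `n_subpops`, `divergence` | 1, 0.15 | Balding–Nichols structure |

Baselines are sorted descending within each kingdom so OTU rank tracks
id, mirroring a "most abundant first" panel. Effects act additively on
log10 abundance; abundances return on the raw scale and are strictly
positive. With `n_subpops > 1`, subpopulation allele frequencies are
Beta perturbations of the ancestral frequency with divergence constant
F, and hosts are assigned round-robin. A single seeded generator per
operation makes every output bit-reproducible.

Two planting modes exist because the abundance → network → index map
is strongly nonlinear: abundance mode (above) exercises the whole
pipeline, while index mode (`plant_index_effect`) adds the effect
directly to a computed emergent index and isolates the association
machinery for calibration and power experiments.

What the generator does **not** emulate: sequence-level noise,
compositionality/rarefaction artifacts of real amplicon tables,
linkage disequilibrium beyond subpopulation structure, and ecological
dynamics (the descriptors are static functions of abundance). Passing
recovery tests on this generator shows the pipeline's statistical
machinery behaves as designed, not that real root microbiomes satisfy
the generative assumptions.

## Calibration and power experiments

The null-calibration experiment uses 100 replicates of 200 hosts ×
2000 SNPs with no planted effects; the phenotype is the aggression
network's edge density computed through the full descriptor pipeline
on a 20+20-OTU panel. That index was selected because it varies
continuously across hosts on panels of this size; several other
indices are too discrete there for a tail-calibration experiment (and
mean PageRank is constant by construction, see above). The pooled
fraction of p-values below 0.01 must sit inside the 99% binomial band
and the pooled lambda_GC within [0.9, 1.1]. The power experiment
plants an index-mode effect explaining 15% of phenotype variance at
n = 179 and requires the causal SNP to rank first in ≥ 90% of
replicates. Problem sizes in `scripts/acceptance.py` (30 calibration
replicates, 20 power replicates, 50 + 25 BN datasets) are reduced
relative to the test suite to keep a single script run near one
minute; the test suite runs the full versions.

## Numerical details and degenerate inputs

- Min–max normalization clips to [0, 1] against rounding.
- A constant phenotype yields `beta = 0, p = 1` for every SNP;
  perfect fits floor the p-value at 1e-300 to stay within (0, 1].
- Monomorphic SNPs (zero variance after imputation) are skipped and
  listed; hosts with fewer than two nonzero OTUs get all-zero indices
  and are flagged.
- Ranking ties in top-k OTU selection break lexicographically by OTU
  id; hill-climbing ties break deterministically by move order, making
  learned DAGs seed-reproducible.
- Wilcoxon tests use the normal approximation with tie and continuity
  corrections (groups here are far above exact-test sizes).

## Known limitations

- Descriptor divergence near ties plus min–max normalization makes
  per-host networks extremely sparse; emergent indices on small panels
  are coarse. Interpret between-host index variation accordingly.
- The mean-PageRank index is constant on a fixed panel (see above).
- No kinship mixed model; structure correction is covariates-only.
- Heritability is a joint-R² convention, not a variance-component
  estimate.
- BN learning on genotype-mean columns inherits their two-point
  support; with many hits and few hosts, scores between sparse DAGs
  can be nearly tied, and only the seed-deterministic optimum is
  reported.
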