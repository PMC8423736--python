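# rhizonet

Genetic mapping of host effects on microbial interaction networks.

Host-associated microbiomes are shaped not only by the abundance of
individual taxa but by how taxa interact. `rhizonet` implements a
behavioral-ecology approach to this problem for host cohorts (e.g.
plant accessions) profiled for both their root/rhizosphere microbiome
(an OTU abundance table spanning bacteria and fungi) and their genome
(biallelic SNPs on inbred, homozygous lines). It is aimed at
microbiome and quantitative-genetics researchers who want to treat
*network structure* — rather than single-taxon abundance — as a
heritable quantitative phenotype.

## The model

For each host, every ordered pair of OTUs with log-transformed
abundances `x_u > x_v > 0` (working scale `log10(x + 1)`) receives four
interaction descriptors:

| type       | formula                         | reading                               |
|------------|---------------------------------|---------------------------------------|
| mutualism  | `Z_mu = x_u x_v / (x_u − x_v)`  | cooperation strength                  |
| antagonism | `Z_an = 1 / (x_u x_v (x_u − x_v))` | competition strength               |
| aggression | `Z_ag = x_u / x_v`              | exploitation of the weaker partner    |
| altruism   | `Z_al = 1 − x_v / x_u`          | sacrifice toward the weaker partner   |

Each host×type matrix is min–max normalized to [0, 1] and sparsified by
strict thresholding (0.95 for mutualism/antagonism/aggression, 0.99 for
altruism), giving four networks per host: mutualism and antagonism
undirected, aggression and altruism directed (abundant → rare). Six
emergent indices summarize each network — edge density (`Con`) and the
node means of closeness `C(u)`, betweenness `B(u)`, eccentricity
`E(u)`, eigencentrality `G(u)` and PageRank `P(u)` — yielding 24
phenotypes per host.

Each phenotype `y` (log10-transformed) is then mapped onto every SNP
with minor allele frequency > 5% by single-marker regression

    y_i = mu + x_i * beta + e_i,    x_i in {0, 1},

with a t-test on `beta` and a significance line of `−log10(P) ≥ 5`.
Hub taxa are called per network from degree and closeness cutoffs, and
a directed acyclic "QTL network" over each phenotype's significant
SNPs is learned by hill climbing on the Gaussian BIC after a
genotype-mean transform of the phenotype; its high-degree nodes are hub
QTLs.

## Worked example

```python
import warnings; warnings.simplefilter("ignore")
from rhizonet.simulate import SimulationConfig, simulate_all
from rhizonet import networks as nw, gwas as gw

cfg = SimulationConfig(n_hosts=100, n_bacteria=20, n_fungi=20,
                       n_snps=1000, n_causal=2, effect_size=1.0, seed=7)
geno, taxonomy, abundance, truth = simulate_all(cfg)
print("causal SNPs:", truth.causal_snp_ids)

indices = nw.index_table(abundance, taxonomy)
print(indices[["aggression_Con", "aggression_Eccentricity"]].head(3).round(4))

design = gw.prepare_genotypes(gw.maf_filter(geno))
y = gw.log_transform_phenotype(indices["aggression_Con"].to_numpy())
res = gw.associate(y, design)
print(res.nsmallest(3, "p_value")[["beta", "p_value", "maf"]].round(4))
lam, _ = gw.qq_inflation(res["p_value"])
print(f"lambda_GC = {lam:.3f}")
```

prints

```
causal SNPs: ['S00102', 'S00279']
         aggression_Con  aggression_Eccentricity
host_id
H0001            0.0006                    0.025
H0002            0.0019                    0.050
H0003            0.0006                    0.025
          beta  p_value   maf
snp_id
S00729 -0.1465   0.0002  0.48
S00005  0.1525   0.0007  0.25
S00634  0.1306   0.0010  0.41
lambda_GC = 1.118
```

The index table holds the 24 network phenotypes per host (here the
aggression network's edge density and mean eccentricity for the first
three hosts). The association scan returns the effect size, p-value and
minor allele frequency per SNP — at this sample size and effect the
planted SNPs do not reach the genome-wide line (`−log10 P ≥ 5`), and
the genomic-control inflation factor `lambda_GC` near 1 indicates a
well-calibrated scan. With the planted effect routed directly into an
index (index mode, `plant_index_effect`) and 15% of phenotype variance
explained, the causal SNP ranks first in ≥ 90% of replicates (see
`tests/test_acceptance.py`).

The same analysis is available as a CLI:

```bash
rhizonet simulate --out fixture --seed 1
rhizonet run --config run.yaml        # io -> networks -> hubs -> gwas -> bn
```

where `run.yaml` points at the OTU table, taxonomy and genotypes
(VCF or TSV) and overrides any defaults. Every run writes a
`manifest.json` recording all parameters and conventions; reruns with
the same seed are byte-identical.

## Layout

- `rhizonet.simulate` — synthetic genotypes/taxonomy/abundances with
  planted effects and recorded ground truth
- `rhizonet.io` — TSV/VCF/GraphML readers and writers, host alignment
- `rhizonet.descriptors` — the four interaction descriptors,
  normalization, thresholding
- `rhizonet.networks` — graph construction, centralities, emergent
  indices, interkingdom statistics
- `rhizonet.hubs` — hub taxon calling and hub-vs-other comparisons
- `rhizonet.gwas` — MAF filtering, per-SNP OLS, significance, QQ/lambda,
  SNP heritability
- `rhizonet.qtl_network` — genotype-mean transform, BIC-scored DAG
  learning, hub QTLs
- `rhizonet.pipeline` / `rhizonet.cli` — orchestration and the
  `rhizonet` command

See `docs/methods.md` for modeling assumptions, parameter defaults and
known limitations.
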