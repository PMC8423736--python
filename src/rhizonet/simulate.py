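"""Synthetic genotype / taxonomy / abundance fixtures with recorded
ground truth.

The generator emulates the study design the pipeline targets: ~179
inbred homozygous hosts, a panel of the 100 most abundant bacterial and
100 most abundant fungal OTUs (ids 1..n_bacteria are bacteria,
n_bacteria+1.. are fungi), and thousands of biallelic SNPs whose allele
frequencies span both sides of the 5% MAF filter. Host effects are
planted on the log10 abundance scale: the log10 abundance of OTU j in
host i is

    baseline_j + sum over causal SNPs s affecting j of effect * x_is
    + Normal(0, abundance_log_sd),

returned on the raw scale (10**value, strictly positive). Baselines are
drawn uniformly from ``abundance_log_mean_range`` and sorted descending
within each kingdom so that OTU rank roughly tracks id, mirroring a
"most abundant first" panel. Optional population structure follows a
Balding-Nichols-style model: subpopulation allele frequencies are Beta
perturbations of the ancestral frequency with divergence constant F.

A second planting mode adds an effect directly to a computed emergent
index ("index mode"), which isolates association-mapping behavior from
the nonlinear abundance -> network -> index map; see
:func:`plant_index_effect`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from rhizonet.errors import ConfigError, DimensionError
from rhizonet.io import AbundanceMatrix, GenotypeMatrix

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_genotypes",
    "simulate_taxonomy",
    "simulate_abundances",
    "simulate_all",
    "plant_index_effect",
    "effect_for_variance_explained",
    "write_fixture",
]

# small fixed taxonomy vocabulary: (class, phylum) per kingdom
BACTERIAL_CLASSES = (
    ("Betaproteobacteria", "Proteobacteria"),
    ("Alphaproteobacteria", "Proteobacteria"),
    ("Gammaproteobacteria", "Proteobacteria"),
    ("Actinobacteria", "Actinobacteria"),
    ("Flavobacteriia", "Bacteroidetes"),
    ("Sphingobacteriia", "Bacteroidetes"),
)
FUNGAL_CLASSES = (
    ("Leotiomycetes", "Ascomycota"),
    ("Dothideomycetes", "Ascomycota"),
    ("Sordariomycetes", "Ascomycota"),
    ("Agaricomycetes", "Basidiomycota"),
    ("Mortierellomycetes", "Mortierellomycota"),
)


@dataclass
class SimulationConfig:
    """Study-condition parameters of the generator.

    Defaults emulate the target design: 179 hosts, 100 + 100 OTUs,
    2000 SNPs with ancestral allele frequencies spanning the 5% MAF
    filter, no planted effects, no population structure.
    """

    n_hosts: int = 179
    n_bacteria: int = 100
    n_fungi: int = 100
    n_snps: int = 2000
    maf_range: tuple[float, float] = (0.01, 0.5)
    n_causal: int = 0
    n_affected_otus: int = 5
    effect_size: float = 1.0
    abundance_log_mean_range: tuple[float, float] = (1.0, 4.0)
    abundance_log_sd: float = 0.5
    n_subpops: int = 1
    divergence: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if self.n_hosts < 2:
            raise ConfigError("n_hosts must be at least 2")
        if self.n_snps < 1:
            raise ConfigError("n_snps must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must lie within (0, 0.5]")
        if self.n_causal > self.n_snps:
            raise ConfigError("n_causal cannot exceed n_snps")
        if self.n_causal < 0:
            raise ConfigError("n_causal must be non-negative")
        if self.abundance_log_sd <= 0:
            raise ConfigError("abundance_log_sd must be positive")
        if self.n_subpops < 1:
            raise ConfigError("n_subpops must be positive")
        if not 0 < self.divergence < 1:
            raise ConfigError("divergence must be in (0, 1)")


@dataclass
class GroundTruth:
    """Planted SNP -> OTU effect map for recovery tests."""

    effects: pd.DataFrame  # columns: snp_id, otu_id, effect_size
    subpops: pd.Series | None = None  # host -> subpopulation label

    @property
    def causal_snp_ids(self) -> list:
        return sorted(set(self.effects["snp_id"]), key=str)

    def affected_otus(self, snp_id) -> list:
        sel = self.effects[self.effects["snp_id"] == snp_id]
        return list(sel["otu_id"])


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent, reproducible stream per operation
    return np.random.default_rng([int(config.seed), stream])


def _host_ids(n: int) -> list[str]:
    return [f"H{i:04d}" for i in range(1, n + 1)]


def _snp_ids(n: int) -> list[str]:
    return [f"S{i:05d}" for i in range(1, n + 1)]


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Hosts x SNPs 0/1 calls for inbred homozygous hosts.

    Ancestral allele frequencies are uniform on ``maf_range``; with
    ``n_subpops > 1`` each subpopulation's frequency is a
    Balding-Nichols Beta(p(1-F)/F, (1-p)(1-F)/F) draw around the
    ancestral value and hosts are assigned to subpopulations
    round-robin.
    """
    config.validate()
    rng = _rng(config, 1)
    p = rng.uniform(config.maf_range[0], config.maf_range[1], size=config.n_snps)
    if config.n_subpops > 1:
        F = config.divergence
        shape = (1.0 - F) / F
        sub_p = rng.beta(
            shape * p[None, :], shape * (1.0 - p[None, :]),
            size=(config.n_subpops, config.n_snps),
        )
        assignment = np.arange(config.n_hosts) % config.n_subpops
        p_host = sub_p[assignment]
    else:
        p_host = np.broadcast_to(p, (config.n_hosts, config.n_snps))
    calls = (rng.random((config.n_hosts, config.n_snps)) < p_host).astype(float)
    return GenotypeMatrix(
        calls=pd.DataFrame(
            calls,
            index=_host_ids(config.n_hosts),
            columns=_snp_ids(config.n_snps),
        )
    )


def simulate_taxonomy(config: SimulationConfig) -> pd.DataFrame:
    """OTU ids 1..n_bacteria are bacteria, the rest fungi; class and
    phylum labels are drawn from a small fixed vocabulary."""
    rng = _rng(config, 2)
    rows = []
    for i in range(1, config.n_bacteria + 1):
        cls, phy = BACTERIAL_CLASSES[rng.integers(len(BACTERIAL_CLASSES))]
        rows.append((i, "bacteria", phy, cls))
    for i in range(config.n_bacteria + 1, config.n_bacteria + config.n_fungi + 1):
        cls, phy = FUNGAL_CLASSES[rng.integers(len(FUNGAL_CLASSES))]
        rows.append((i, "fungi", phy, cls))
    return pd.DataFrame(
        rows, columns=["otu_id", "kingdom", "phylum", "class"]
    ).set_index("otu_id")


def simulate_abundances(
    genotypes: GenotypeMatrix,
    taxonomy: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[AbundanceMatrix, GroundTruth]:
    """Raw-scale abundances with planted per-allele log10 shifts."""
    config.validate()
    if genotypes.calls.shape[0] != config.n_hosts:
        raise DimensionError("genotype host count disagrees with config")
    rng = _rng(config, 3)
    otu_ids = list(taxonomy.index)
    m = len(otu_ids)
    kingdoms = taxonomy["kingdom"].to_numpy()
    baseline = rng.uniform(
        config.abundance_log_mean_range[0],
        config.abundance_log_mean_range[1],
        size=m,
    )
    # sort descending within each kingdom so abundance rank tracks id
    for kingdom in ("bacteria", "fungi"):
        sel = kingdoms == kingdom
        baseline[sel] = np.sort(baseline[sel])[::-1]

    calls = genotypes.calls.to_numpy(dtype=float)
    imputed = np.where(np.isnan(calls), np.nanmean(calls, axis=0), calls)
    shift = np.zeros((config.n_hosts, m))
    records = []
    if config.n_causal > 0:
        causal_idx = rng.choice(calls.shape[1], size=config.n_causal, replace=False)
        snp_ids = list(genotypes.snp_ids)
        for s in sorted(causal_idx):
            n_aff = min(config.n_affected_otus, m)
            affected = rng.choice(m, size=n_aff, replace=False)
            for j in sorted(affected):
                shift[:, j] += config.effect_size * imputed[:, s]
                records.append((snp_ids[s], otu_ids[j], config.effect_size))
    noise = rng.normal(0.0, config.abundance_log_sd, size=(config.n_hosts, m))
    log10_abund = baseline[None, :] + shift + noise
    abundance = AbundanceMatrix(
        values=pd.DataFrame(
            np.power(10.0, log10_abund),
            index=genotypes.host_ids,
            columns=otu_ids,
        )
    )
    truth = GroundTruth(
        effects=pd.DataFrame(records, columns=["snp_id", "otu_id", "effect_size"]),
        subpops=(
            pd.Series(
                np.arange(config.n_hosts) % config.n_subpops,
                index=genotypes.host_ids,
                name="subpop",
            )
            if config.n_subpops > 1
            else None
        ),
    )
    return abundance, truth


def simulate_all(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame, AbundanceMatrix, GroundTruth]:
    """Convenience wrapper running all three generators."""
    geno = simulate_genotypes(config)
    taxonomy = simulate_taxonomy(config)
    abundance, truth = simulate_abundances(geno, taxonomy, config)
    return geno, taxonomy, abundance, truth


def effect_for_variance_explained(
    index_values, genotype_col, variance_explained: float
) -> float:
    """Per-allele effect size that makes a planted SNP explain the
    requested fraction of the resulting phenotype's variance."""
    if not 0 < variance_explained < 1:
        raise ConfigError("variance_explained must be in (0, 1)")
    var_y = float(np.var(np.asarray(index_values, dtype=float)))
    var_x = float(np.var(np.asarray(genotype_col, dtype=float)))
    if var_x == 0:
        raise ConfigError("monomorphic SNP cannot explain variance")
    return float(
        np.sqrt(variance_explained / (1.0 - variance_explained) * var_y / var_x)
    )


def plant_index_effect(index_values, genotype_col, effect_size: float) -> np.ndarray:
    """Index-mode planting: add ``effect_size * x`` directly to a
    computed emergent index."""
    y = np.asarray(index_values, dtype=float)
    x = np.asarray(genotype_col, dtype=float)
    if y.shape != x.shape:
        raise DimensionError("index and genotype vectors differ in length")
    return y + effect_size * x


def write_fixture(config: SimulationConfig, out_dir) -> dict[str, str]:
    """Write OTU table, taxonomy, genotypes (TSV and VCF), and ground
    truth to a directory; returns the path map."""
    import os

    from rhizonet import io as rio

    os.makedirs(out_dir, exist_ok=True)
    geno, taxonomy, abundance, truth = simulate_all(config)
    paths = {
        "otu_table": os.path.join(out_dir, "otu_table.tsv"),
        "taxonomy": os.path.join(out_dir, "taxonomy.tsv"),
        "genotypes_tsv": os.path.join(out_dir, "genotypes.tsv"),
        "genotypes_vcf": os.path.join(out_dir, "genotypes.vcf"),
        "ground_truth": os.path.join(out_dir, "ground_truth.tsv"),
    }
    rio.write_otu_table(abundance, paths["otu_table"])
    rio.write_taxonomy(taxonomy, paths["taxonomy"])
    rio.write_genotypes_tsv(geno, paths["genotypes_tsv"])
    rio.write_genotypes_vcf(geno, paths["genotypes_vcf"])
    truth.effects.to_csv(paths["ground_truth"], sep="\t", index=False)
    return paths
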