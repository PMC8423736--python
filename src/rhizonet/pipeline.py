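"""One-command orchestration of the full analysis.

Stage order: io -> descriptors/networks (index table) -> consensus
networks + hubs -> gwas -> qtl networks. Every run writes a JSON
manifest recording parameters, seed, convention switches, stage counts
and the package version, so a run is reproducible from its manifest
alone. Reruns with identical inputs and seed produce byte-identical
result tables.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from rhizonet import descriptors as desc
from rhizonet import gwas as gw
from rhizonet import hubs as hb
from rhizonet import io as rio
from rhizonet import networks as nw
from rhizonet import qtl_network as qn
from rhizonet.errors import ConfigError

log = logging.getLogger("rhizonet.pipeline")

__all__ = ["RunConfig", "validate_config", "run_pipeline"]


@dataclass
class RunConfig:
    """Declarative run configuration; defaults are the shipped analysis
    settings (100 OTUs per kingdom, thresholds 0.95/0.95/0.95/0.99,
    MAF > 5%, -log10 p >= 5)."""

    otu_table: str
    taxonomy: str
    genotypes: str
    out_dir: str
    covariates: str | None = None
    top_k: int = 100
    taus: dict = field(default_factory=lambda: dict(desc.DEFAULT_TAU))
    scope: str = "per_host"
    hub_mode: str = "quantile"
    hub_degree_quantile: float = 0.90
    hub_closeness_quantile: float = 0.90
    hub_degree_cutoff: float | None = None
    hub_closeness_cutoff: float | None = None
    maf: float = 0.05
    logp: float = 5.0
    bn_max_parents: int = 3
    bn_restarts: int = 10
    seed: int = 7
    phenotype_offset: float = gw.PHENOTYPE_OFFSET

    @classmethod
    def from_file(cls, path: str, **overrides) -> "RunConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of violations (empty when the config is valid)."""
    violations: list[str] = []
    for name in ("otu_table", "taxonomy", "genotypes"):
        path = getattr(config, name)
        if not path or not os.path.exists(path):
            violations.append(f"{name} file not found: {path!r}")
    if config.covariates is not None and not os.path.exists(config.covariates):
        violations.append(f"covariates file not found: {config.covariates!r}")
    for t, tau in config.taus.items():
        if t not in desc.INTERACTION_TYPES:
            violations.append(f"unknown interaction type in taus: {t!r}")
        elif not 0 < tau < 1:
            violations.append(f"tau[{t}] must be in (0, 1), got {tau}")
    if not 0 < config.maf < 0.5:
        violations.append(f"maf must be in (0, 0.5), got {config.maf}")
    if config.logp <= 0:
        violations.append(f"logp must be positive, got {config.logp}")
    if config.scope not in ("per_host", "global"):
        violations.append(f"scope must be per_host or global, got {config.scope!r}")
    if config.hub_mode not in ("quantile", "absolute"):
        violations.append(f"hub_mode must be quantile or absolute, got {config.hub_mode!r}")
    if config.top_k < 1:
        violations.append("top_k must be positive")
    return violations


def _write_tsv(df: pd.DataFrame, path: str, **kw) -> None:
    df.to_csv(path, sep="\t", **kw)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written to
    ``manifest.json`` in the output directory)."""
    violations = validate_config(config)
    if violations:
        raise ConfigError("; ".join(violations))
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict = {
        "package": "rhizonet",
        "version": _package_version(),
        "parameters": {
            k: (dict(v) if isinstance(v, dict) else v)
            for k, v in asdict(config).items()
        },
        "conventions": {
            "abundance_transform": "log10(x + 1)",
            "normalization_scope": config.scope,
            "threshold_rule": "strictly greater than tau",
            "phenotype_transform": f"log10(index + {config.phenotype_offset})",
            "maf_rule": "minor allele frequency strictly above threshold",
            "significance_rule": "-log10(p) >= logp (inclusive)",
            "hub_rule": "degree AND closeness strictly above cutoffs",
            "bn_score": "gaussian_bic",
        },
        "stages": {},
    }
    stage = "io"
    try:
        taxonomy = rio.read_taxonomy(config.taxonomy)
        abundance = rio.read_otu_table(
            config.otu_table, taxonomy=taxonomy, top_k=config.top_k
        )
        genotypes = rio.read_genotypes(config.genotypes, abundance=abundance)
        abundance, genotypes = rio.align_hosts(abundance, genotypes)
        covariates = None
        if config.covariates:
            cov = pd.read_csv(config.covariates, sep="\t", index_col=0)
            covariates = cov.loc[abundance.host_ids]
        manifest["stages"]["io"] = {
            "n_hosts": len(abundance.host_ids),
            "n_otus": abundance.m,
            "n_snps": len(genotypes.snp_ids),
            "dropped_hosts": len(genotypes.dropped_hosts),
        }
        log.info("io: %s", manifest["stages"]["io"])

        stage = "descriptors/networks"
        indices = nw.index_table(
            abundance, taxonomy, taus=config.taus, scope=config.scope
        )
        _write_tsv(indices, os.path.join(config.out_dir, "index_table.tsv"))
        manifest["stages"]["indices"] = {
            "n_phenotypes": indices.shape[1],
            "degenerate_hosts": len(indices.attrs["degenerate_hosts"]),
        }

        stage = "hubs"
        reports: dict[str, hb.HubReport] = {}
        kingdom_tests = []
        for t in desc.INTERACTION_TYPES:
            G = nw.consensus_network(abundance, taxonomy, t, tau=config.taus[t])
            rio.write_network(
                G, os.path.join(config.out_dir, f"consensus_{t}.graphml")
            )
            cent = nw.node_centralities(G)
            _write_tsv(cent, os.path.join(config.out_dir, f"centrality_{t}.tsv"))
            inter, within = nw.interkingdom_edges(G, taxonomy)
            _write_tsv(
                inter,
                os.path.join(config.out_dir, f"interkingdom_{t}.tsv"),
                index=False,
            )
            try:
                w_stat, w_p, med_b, med_f = nw.kingdom_degree_test(G, taxonomy)
                kingdom_tests.append((t, w_stat, w_p, med_b, med_f))
            except Exception:
                kingdom_tests.append((t, np.nan, np.nan, np.nan, np.nan))
            if config.hub_mode == "absolute":
                report = hb.detect_hubs(
                    cent,
                    network_type=t,
                    taxonomy=taxonomy,
                    degree_cutoff=config.hub_degree_cutoff,
                    closeness_cutoff=config.hub_closeness_cutoff,
                )
            else:
                report = hb.detect_hubs(
                    cent,
                    network_type=t,
                    taxonomy=taxonomy,
                    degree_quantile=config.hub_degree_quantile,
                    closeness_quantile=config.hub_closeness_quantile,
                )
            reports[t] = report
            _write_tsv(report.hubs, os.path.join(config.out_dir, f"hubs_{t}.tsv"))
        membership, phylum_overlap = hb.shared_hubs(reports, taxonomy)
        _write_tsv(membership, os.path.join(config.out_dir, "shared_hubs.tsv"))
        _write_tsv(
            phylum_overlap, os.path.join(config.out_dir, "shared_hub_phyla.tsv")
        )
        _write_tsv(
            pd.DataFrame(
                kingdom_tests,
                columns=["type", "statistic", "p_value", "median_bacteria", "median_fungi"],
            ),
            os.path.join(config.out_dir, "kingdom_degree_tests.tsv"),
            index=False,
        )
        manifest["stages"]["hubs"] = {
            t: {
                "n_hubs": len(r.hub_otus),
                "degree_cutoff": float(r.degree_cutoff),
                "closeness_cutoff": float(r.closeness_cutoff),
                "labels": [r.hub_label, r.nonhub_label],
            }
            for t, r in reports.items()
        }

        stage = "gwas"
        filtered = gw.maf_filter(genotypes, min_maf=config.maf)
        design = gw.prepare_genotypes(filtered)
        results = []
        hits_frames = []
        herit_rows = []
        lambda_rows = []
        for pheno in indices.columns:
            y = gw.log_transform_phenotype(
                indices[pheno].to_numpy(float), offset=config.phenotype_offset
            )
            res = gw.associate(y, design, covariates=covariates)
            res = res.assign(phenotype=pheno)
            results.append(res)
            hits = gw.significant_hits(res, threshold_logp=config.logp)
            if len(hits):
                hits_frames.append(hits.assign(phenotype=pheno))
            lam, _ = gw.qq_inflation(res["p_value"])
            lambda_rows.append((pheno, lam))
            herit = gw.snp_heritability(y, hits, design)
            herit_rows.append(
                (pheno, len(hits), herit.total, herit.ridge_fallback)
            )
        all_res = pd.concat(results).reset_index()
        _write_tsv(
            all_res[["phenotype", "snp_id", "beta", "se", "p_value", "maf", "n_used"]],
            os.path.join(config.out_dir, "gwas_results.tsv"),
            index=False,
        )
        all_hits = (
            pd.concat(hits_frames).reset_index()
            if hits_frames
            else pd.DataFrame(
                columns=["snp_id", "beta", "se", "p_value", "neg_log10_p", "phenotype"]
            )
        )
        _write_tsv(
            all_hits, os.path.join(config.out_dir, "gwas_hits.tsv"), index=False
        )
        _write_tsv(
            pd.DataFrame(lambda_rows, columns=["phenotype", "lambda_gc"]),
            os.path.join(config.out_dir, "lambda_gc.tsv"),
            index=False,
        )
        _write_tsv(
            pd.DataFrame(
                herit_rows,
                columns=["phenotype", "n_hits", "total_snp_h2", "ridge_fallback"],
            ),
            os.path.join(config.out_dir, "heritability.tsv"),
            index=False,
        )
        per_type = {
            t: int(
                all_hits["phenotype"].str.startswith(t + "_").sum()
                if len(all_hits)
                else 0
            )
            for t in desc.INTERACTION_TYPES
        }
        manifest["stages"]["gwas"] = {
            "n_snps_after_maf": design.shape[1],
            "n_significant": int(len(all_hits)),
            "per_type": per_type,
        }

        stage = "qtl_network"
        bn_summaries = {}
        for i, pheno in enumerate(indices.columns):
            pheno_hits = (
                all_hits[all_hits["phenotype"] == pheno]["snp_id"].tolist()
                if len(all_hits)
                else []
            )
            if len(pheno_hits) < 2:
                continue
            y = gw.log_transform_phenotype(
                indices[pheno].to_numpy(float), offset=config.phenotype_offset
            )
            gm = qn.genotype_mean_transform(y, design[pheno_hits])
            net = qn.learn_bn(
                gm,
                max_parents=config.bn_max_parents,
                restarts=config.bn_restarts,
                seed=config.seed + i,
            )
            net.hub_ids = qn.hub_qtls(net)
            rio.write_network(
                net.graph,
                os.path.join(config.out_dir, f"qtl_network_{pheno}.graphml"),
            )
            edges = pd.DataFrame(
                list(net.graph.edges()), columns=["source", "target"]
            )
            _write_tsv(
                edges,
                os.path.join(config.out_dir, f"qtl_network_{pheno}.tsv"),
                index=False,
            )
            bn_summaries[pheno] = {
                "n_nodes": net.graph.number_of_nodes(),
                "n_edges": net.graph.number_of_edges(),
                "n_hub_qtls": len(net.hub_ids),
                "score": net.score,
            }
        manifest["stages"]["qtl_network"] = bn_summaries
    except Exception as exc:  # preserve partial artifacts, name the stage
        manifest["failed_stage"] = stage
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        with open(
            os.path.join(config.out_dir, "manifest.json"), "w", encoding="utf-8"
        ) as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        raise

    manifest["phenotypes"] = list(indices.columns)
    with open(
        os.path.join(config.out_dir, "manifest.json"), "w", encoding="utf-8"
    ) as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest


def _package_version() -> str:
    from rhizonet import __version__

    return __version__
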