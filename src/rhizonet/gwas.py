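"""Single-marker association mapping of emergent network indices.

Each emergent index y (log-transformed as log10(y + 1e-6), since
indices can be exactly zero) is regressed on every SNP one at a time,

    y_i = mu + x_i * beta + e_i,

where x_i is 0 for the high-frequency allele and 1 for the
low-frequency allele of an inbred homozygous host. The per-SNP fit is
ordinary least squares with a two-sided t-test on beta; optional
covariate columns (e.g. subpopulation membership proportions) are
projected out of both y and x first, which is equivalent to including
them in the model. SNPs are pre-filtered to minor allele frequency
strictly above 5% by default; the significance line is
-log10(P) >= 5, inclusive.

The implementation is vectorized over SNPs (closed-form simple
regression after residualization); it matches statsmodels OLS to
floating-point accuracy and is fast enough for tens of phenotypes times
tens of thousands of SNPs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from rhizonet.errors import ConfigError
from rhizonet.io import GenotypeMatrix

__all__ = [
    "PHENOTYPE_OFFSET",
    "minor_allele_frequency",
    "maf_filter",
    "prepare_genotypes",
    "log_transform_phenotype",
    "associate",
    "significant_hits",
    "qq_inflation",
    "snp_heritability",
    "HeritabilityTable",
]

#: offset added before log10 so zero-valued indices stay finite
PHENOTYPE_OFFSET = 1e-6

_P_FLOOR = 1e-300  # keep p-values inside (0, 1] even for perfect fits


def minor_allele_frequency(calls: pd.DataFrame) -> pd.Series:
    """Per-SNP MAF on non-missing calls (NaN for all-missing SNPs)."""
    freq = calls.mean(axis=0, skipna=True)
    return pd.concat([freq, 1.0 - freq], axis=1).min(axis=1)


def maf_filter(geno: GenotypeMatrix, min_maf: float = 0.05) -> GenotypeMatrix:
    """Keep SNPs with minor allele frequency strictly above ``min_maf``
    (all-missing SNPs are dropped with a warning)."""
    if not 0 <= min_maf < 0.5:
        raise ConfigError(f"min_maf must be in [0, 0.5), got {min_maf}")
    maf = minor_allele_frequency(geno.calls)
    all_missing = maf.isna()
    if all_missing.any():
        warnings.warn(
            f"dropping {int(all_missing.sum())} all-missing SNPs", stacklevel=2
        )
    keep = maf.notna() & (maf > min_maf)
    return GenotypeMatrix(
        calls=geno.calls.loc[:, keep], dropped_hosts=list(geno.dropped_hosts)
    )


def prepare_genotypes(
    geno: GenotypeMatrix, max_missing: float = 0.10
) -> pd.DataFrame:
    """Numeric design matrix: SNPs with > ``max_missing`` missing
    fraction dropped, remaining missing calls mean-imputed per SNP."""
    calls = geno.calls
    miss_frac = calls.isna().mean(axis=0)
    dropped = miss_frac[miss_frac > max_missing]
    if len(dropped):
        warnings.warn(
            f"dropping {len(dropped)} SNPs with >{max_missing:.0%} missing calls",
            stacklevel=2,
        )
    kept = calls.loc[:, miss_frac <= max_missing].astype(float)
    return kept.fillna(kept.mean(axis=0))


def log_transform_phenotype(y, offset: float = PHENOTYPE_OFFSET) -> np.ndarray:
    """log10(y + offset); indices are non-negative and may be 0."""
    y = np.asarray(y, dtype=float)
    if np.nanmin(y) < 0:
        raise ConfigError("phenotypes must be non-negative before log transform")
    return np.log10(y + offset)


def _residualize(Z: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Residual of each column of M after OLS on Z (Z includes the
    intercept)."""
    coef, *_ = np.linalg.lstsq(Z, M, rcond=None)
    return M - Z @ coef


def associate(
    y,
    genotypes,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-SNP OLS of a phenotype on 0/1 genotype (+ covariates).

    ``genotypes`` is a GenotypeMatrix or an imputed hosts x SNPs
    DataFrame. Returns a DataFrame indexed by SNP id with columns
    beta, se, t, p_value, maf, n_used, r2; monomorphic SNPs (zero
    variance after imputation) are skipped and listed in
    ``df.attrs["skipped_snps"]``.
    """
    if isinstance(genotypes, GenotypeMatrix):
        X_df = prepare_genotypes(genotypes)
    else:
        X_df = pd.DataFrame(genotypes)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n != X_df.shape[0]:
        raise ConfigError("phenotype and genotype host counts differ")
    if n < 3:
        raise ConfigError("need at least 3 hosts for association")
    X = X_df.to_numpy(dtype=float)
    maf = np.minimum(X_df.mean(axis=0), 1 - X_df.mean(axis=0)).to_numpy(float)

    Z = np.ones((n, 1))
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        Z = np.hstack([Z, C])
    k = Z.shape[1]  # intercept + covariates
    dof = n - k - 1
    if dof <= 0:
        raise ConfigError("not enough hosts for the requested covariates")

    yr = _residualize(Z, y[:, None])[:, 0]
    Xr = _residualize(Z, X)
    sxx = (Xr**2).sum(axis=0)
    polymorphic = sxx > 1e-12
    syy = 0.0 if np.all(y == y[0]) else float(yr @ yr)

    beta = np.zeros(X.shape[1])
    se = np.zeros(X.shape[1])
    tstat = np.zeros(X.shape[1])
    pval = np.ones(X.shape[1])
    r2 = np.zeros(X.shape[1])
    if syy > 0:
        with np.errstate(divide="ignore", invalid="ignore"):
            sxy = Xr.T @ yr
            b = np.where(polymorphic, sxy / np.where(polymorphic, sxx, 1.0), 0.0)
            sse = np.maximum(syy - b * sxy, 0.0)
            sigma2 = sse / dof
            s = np.sqrt(np.where(polymorphic, sigma2 / np.where(polymorphic, sxx, 1.0), 0.0))
            t = np.where(s > 0, b / np.where(s > 0, s, 1.0), np.inf * np.sign(b))
            t = np.where(b == 0, 0.0, t)
            p = 2.0 * stats.t.sf(np.abs(t), dof)
        beta = np.where(polymorphic, b, 0.0)
        se = np.where(polymorphic, s, 0.0)
        tstat = np.where(polymorphic, t, 0.0)
        pval = np.where(polymorphic, np.clip(p, _P_FLOOR, 1.0), 1.0)
        r2 = np.where(polymorphic, np.clip(beta * sxy / syy, 0.0, 1.0), 0.0)

    res = pd.DataFrame(
        {
            "beta": beta,
            "se": se,
            "t": tstat,
            "p_value": pval,
            "maf": maf,
            "n_used": n,
            "r2": r2,
        },
        index=pd.Index(X_df.columns, name="snp_id"),
    )
    res.attrs["skipped_snps"] = list(X_df.columns[~polymorphic])
    res.attrs["dof"] = int(dof)
    return res


def significant_hits(res: pd.DataFrame, threshold_logp: float = 5.0) -> pd.DataFrame:
    """SNPs with -log10(p) >= ``threshold_logp`` (inclusive), sorted by
    p ascending."""
    if threshold_logp <= 0:
        raise ConfigError("threshold_logp must be positive")
    logp = -np.log10(res["p_value"].to_numpy(float))
    hits = res.loc[logp >= threshold_logp].sort_values("p_value", kind="stable")
    hits = hits.copy()
    hits["neg_log10_p"] = -np.log10(hits["p_value"])
    return hits


def qq_inflation(p_values) -> tuple[float, pd.DataFrame]:
    """Genomic-control lambda and QQ-plot coordinates.

    lambda_GC = median observed 1-df chi-square (from p) divided by the
    theoretical median 0.4549; the returned frame has sorted expected
    and observed -log10 p for plotting.
    """
    p = np.sort(np.asarray(p_values, dtype=float))
    if p.size == 0:
        raise ConfigError("no p-values supplied")
    chi2_obs = stats.chi2.isf(p, df=1)
    lam = float(np.median(chi2_obs) / stats.chi2.ppf(0.5, df=1))
    n = p.size
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    observed = -np.log10(p)
    coords = pd.DataFrame({"expected": expected, "observed": observed})
    return lam, coords


@dataclass
class HeritabilityTable:
    """Per-SNP and joint variance explained for one phenotype."""

    per_snp: pd.DataFrame  # index snp_id, column h2
    total: float
    ridge_fallback: bool = False


def snp_heritability(
    y,
    hits: pd.DataFrame,
    genotypes,
    ridge_penalty: float = 1e-3,
) -> HeritabilityTable:
    """Variance explained by significant SNPs.

    Per-SNP h2 is the R-squared of the single-SNP fit; the total SNP-h2
    is the R-squared of the joint OLS fit on all significant SNPs. When
    the number of hits reaches n - 1 the joint fit switches to ridge
    regression with a fixed small penalty and is flagged.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if isinstance(genotypes, GenotypeMatrix):
        X_df = prepare_genotypes(genotypes)
    else:
        X_df = pd.DataFrame(genotypes)
    hit_ids = [s for s in hits.index if s in X_df.columns]
    if not hit_ids:
        return HeritabilityTable(
            per_snp=pd.DataFrame(columns=["h2"]), total=0.0
        )
    X = X_df[hit_ids].to_numpy(dtype=float)
    yc = y - y.mean()
    syy = float(yc @ yc)
    if syy == 0:
        return HeritabilityTable(
            per_snp=pd.DataFrame({"h2": np.zeros(len(hit_ids))}, index=hit_ids),
            total=0.0,
        )
    Xc = X - X.mean(axis=0)
    sxx = (Xc**2).sum(axis=0)
    sxy = Xc.T @ yc
    with np.errstate(divide="ignore", invalid="ignore"):
        per = np.where(sxx > 0, (sxy**2) / np.where(sxx > 0, sxx, 1.0) / syy, 0.0)
    per = np.clip(per, 0.0, 1.0)

    ridge = len(hit_ids) >= n - 1
    if ridge:
        A = Xc.T @ Xc + ridge_penalty * n * np.eye(Xc.shape[1])
        coef = np.linalg.solve(A, sxy)
    else:
        coef, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    resid = yc - Xc @ coef
    total = float(np.clip(1.0 - (resid @ resid) / syy, 0.0, 1.0))
    return HeritabilityTable(
        per_snp=pd.DataFrame({"h2": per}, index=pd.Index(hit_ids, name="snp_id")),
        total=total,
        ridge_fallback=ridge,
    )
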