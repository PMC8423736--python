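"""Readers, writers, and the core in-memory containers.

All tabular artifacts are tab-delimited UTF-8 text with a mandatory
header row. The three standard inputs are

* an OTU abundance table (rows = OTUs, columns = hosts; a transposed
  table is auto-detected when a taxonomy is available),
* an OTU taxonomy table (columns: ``otu_id``, ``kingdom``, ``phylum``,
  ``class``; kingdom is ``bacteria`` or ``fungi``),
* a host genotype matrix, either a VCF of homozygous diploid calls
  (``0/0`` -> 0, ``1/1`` -> 1, heterozygous or missing -> NaN) or a TSV
  of 0/1 calls (rows = SNPs, columns = hosts).

Containers are thin dataclasses around pandas DataFrames; hosts are
always rows and OTUs/SNPs columns once inside the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from rhizonet.errors import AlignmentError, FormatError

__all__ = [
    "AbundanceMatrix",
    "GenotypeMatrix",
    "read_otu_table",
    "read_taxonomy",
    "read_genotypes",
    "align_hosts",
    "write_otu_table",
    "write_taxonomy",
    "write_genotypes_tsv",
    "write_genotypes_vcf",
    "write_network",
    "read_network",
]

KINGDOMS = ("bacteria", "fungi")


@dataclass
class AbundanceMatrix:
    """Hosts x OTUs non-negative abundance matrix.

    ``values`` is a DataFrame with host ids as the index and OTU ids as
    columns. ``m`` is the number of OTUs.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if arr.size and np.nanmin(arr) < 0:
            raise FormatError("abundance matrix contains negative values")
        if self.values.columns.has_duplicates or self.values.index.has_duplicates:
            raise FormatError("abundance matrix ids must be unique")

    @property
    def host_ids(self) -> list:
        return list(self.values.index)

    @property
    def otu_ids(self) -> list:
        return list(self.values.columns)

    @property
    def m(self) -> int:
        return self.values.shape[1]


@dataclass
class GenotypeMatrix:
    """Hosts x SNPs calls in {0, 1, NaN} for homozygous inbred hosts."""

    calls: pd.DataFrame
    dropped_hosts: list = field(default_factory=list)

    def __post_init__(self) -> None:
        arr = self.calls.to_numpy(dtype=float)
        valid = np.isnan(arr) | (arr == 0.0) | (arr == 1.0)
        if not valid.all():
            raise FormatError("genotype calls must be 0, 1 or missing")

    @property
    def host_ids(self) -> list:
        return list(self.calls.index)

    @property
    def snp_ids(self) -> list:
        return list(self.calls.columns)


def _maybe_int(value):
    """Coerce numeric-looking ids to int (TSV headers always parse as
    text, while numeric index columns parse as integers)."""
    try:
        return int(value)
    except (TypeError, ValueError):
        return value


def _looks_like_otus(ids, taxonomy: pd.DataFrame) -> float:
    """Fraction of ids found in the taxonomy index."""
    tax_ids = set(taxonomy.index)
    ids = [_maybe_int(i) for i in ids]
    if not ids:
        return 0.0
    return sum(1 for i in ids if i in tax_ids) / len(ids)


def read_otu_table(
    path,
    taxonomy: pd.DataFrame | None = None,
    top_k: int | None = None,
) -> AbundanceMatrix:
    """Read an OTU abundance TSV, optionally keeping the ``top_k`` most
    abundant OTUs per kingdom.

    Rows are expected to be OTUs and columns hosts; the transposed
    orientation is auto-detected by matching ids against the taxonomy.
    Ranking is by total abundance across hosts, bacteria first then
    fungi, each in descending order; ties break by OTU id (as text).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy(dtype=float) < 0).any():
        raise FormatError(f"negative abundances in {path}")
    if taxonomy is not None:
        frac_rows = _looks_like_otus(df.index, taxonomy)
        frac_cols = _looks_like_otus(df.columns, taxonomy)
        if frac_cols > frac_rows:
            values = df  # hosts already on rows
        else:
            values = df.T
    else:
        values = df.T
    values.columns = [_maybe_int(c) for c in values.columns]
    mat = AbundanceMatrix(values=values)
    if top_k is not None:
        if taxonomy is None:
            raise FormatError("per-kingdom top_k filtering requires a taxonomy")
        mat = select_top_otus(mat, taxonomy, top_k)
    return mat


def select_top_otus(
    mat: AbundanceMatrix, taxonomy: pd.DataFrame, top_k: int
) -> AbundanceMatrix:
    """Restrict to the ``top_k`` most abundant OTUs of each kingdom."""
    totals = mat.values.sum(axis=0)
    keep: list = []
    for kingdom in KINGDOMS:
        in_kingdom = [
            o
            for o in mat.otu_ids
            if o in taxonomy.index and taxonomy.loc[o, "kingdom"] == kingdom
        ]
        if len(in_kingdom) < top_k:
            warnings.warn(
                f"only {len(in_kingdom)} {kingdom} OTUs available "
                f"(top_k={top_k}); keeping all",
                stacklevel=2,
            )
        ranked = sorted(in_kingdom, key=lambda o: (-totals[o], str(o)))
        keep.extend(ranked[:top_k])
    return AbundanceMatrix(values=mat.values[keep])


def read_taxonomy(path) -> pd.DataFrame:
    """Read a taxonomy TSV into a DataFrame indexed by OTU id."""
    df = pd.read_csv(path, sep="\t")
    required = {"otu_id", "kingdom", "phylum", "class"}
    if not required.issubset(df.columns):
        raise FormatError(f"taxonomy must have columns {sorted(required)}")
    bad = set(df["kingdom"]) - set(KINGDOMS)
    if bad:
        raise FormatError(f"unknown kingdoms in taxonomy: {sorted(bad)}")
    return df.set_index("otu_id")


def _read_genotypes_vcf(path) -> pd.DataFrame:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    hosts = list(vcf.samples)
    snp_ids: list[str] = []
    rows: list[np.ndarray] = []
    # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
    code = np.array([0.0, np.nan, np.nan, 1.0])
    for var in vcf:
        sid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        snp_ids.append(sid)
        rows.append(code[np.asarray(var.gt_types)])
    calls = pd.DataFrame(
        np.array(rows).T if rows else np.empty((len(hosts), 0)),
        index=hosts,
        columns=snp_ids,
    )
    return calls


def read_genotypes(path, abundance: AbundanceMatrix | None = None) -> GenotypeMatrix:
    """Read genotypes from VCF or TSV; optionally align hosts to an
    abundance matrix (intersection, abundance host order)."""
    path = str(path)
    if path.endswith(".vcf") or path.endswith(".vcf.gz"):
        calls = _read_genotypes_vcf(path)
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
        calls = df.T  # rows = SNPs on disk
    geno = GenotypeMatrix(calls=calls)
    if abundance is not None:
        _, geno = align_hosts(abundance, geno)
    return geno


def align_hosts(
    abundance: AbundanceMatrix, genotypes: GenotypeMatrix
) -> tuple[AbundanceMatrix, GenotypeMatrix]:
    """Intersect hosts of the two tables, preserving abundance order.

    Raises :class:`AlignmentError` when no hosts overlap; dropped
    genotype hosts are recorded on the returned matrix.
    """
    geno_hosts = set(genotypes.host_ids)
    shared = [h for h in abundance.host_ids if h in geno_hosts]
    if not shared:
        raise AlignmentError("no overlapping hosts between abundance and genotypes")
    shared_set = set(shared)
    dropped = [
        h
        for h in list(abundance.host_ids) + list(genotypes.host_ids)
        if h not in shared_set
    ]
    if dropped:
        warnings.warn(f"dropped {len(dropped)} unmatched hosts", stacklevel=2)
    return (
        AbundanceMatrix(values=abundance.values.loc[shared]),
        GenotypeMatrix(calls=genotypes.calls.loc[shared], dropped_hosts=dropped),
    )


def write_otu_table(mat: AbundanceMatrix, path) -> None:
    """Write rows = OTUs, columns = hosts (common amplicon convention)."""
    mat.values.T.to_csv(path, sep="\t", index_label="otu_id")


def write_taxonomy(taxonomy: pd.DataFrame, path) -> None:
    taxonomy.reset_index().to_csv(path, sep="\t", index=False)


def write_genotypes_tsv(geno: GenotypeMatrix, path) -> None:
    """Write rows = SNPs, columns = hosts; missing as empty field."""
    out = geno.calls.T
    out.to_csv(path, sep="\t", index_label="snp_id", float_format="%.0f")


def write_genotypes_vcf(geno: GenotypeMatrix, path, n_chromosomes: int = 5) -> None:
    """Write a minimal VCF 4.2 with synthetic coordinates.

    SNPs are distributed round-robin over ``n_chromosomes`` chromosomes
    with increasing positions; calls are homozygous (0/0 or 1/1),
    missing as ``./.``.
    """
    hosts = [str(h) for h in geno.host_ids]
    arr = geno.calls.to_numpy(dtype=float)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in range(1, n_chromosomes + 1):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(hosts)
            + "\n"
        )
        for j, sid in enumerate(geno.snp_ids):
            chrom = j % n_chromosomes + 1
            pos = 1000 * (j // n_chromosomes + 1)
            gts = []
            for v in arr[:, j]:
                if np.isnan(v):
                    gts.append("./.")
                elif v == 0:
                    gts.append("0/0")
                else:
                    gts.append("1/1")
            fh.write(
                f"{chrom}\t{pos}\t{sid}\tA\tT\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def write_network(net: nx.Graph, path, format: str = "graphml") -> None:
    """Export a network as GraphML or an edge-list TSV.

    GraphML keeps node attributes (kingdom, taxon class, hub flag) and
    the edge ``weight``; the edge list has columns source, target,
    weight, directed.
    """
    if format == "graphml":
        nx.write_graphml(net, path)
    elif format == "edgelist-tsv":
        directed = int(net.is_directed())
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("source\ttarget\tweight\tdirected\n")
            for u, v, data in net.edges(data=True):
                w = data.get("weight", 1.0)
                fh.write(f"{u}\t{v}\t{w!r}\t{directed}\n")
    else:
        raise ValueError(f"unknown network format: {format!r}")


def read_network(path) -> nx.Graph:
    """Read back a GraphML file written by :func:`write_network`."""
    return nx.read_graphml(path)
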