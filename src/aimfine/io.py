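"""Readers, writers and run configuration.

Coordinate conventions: VCF positions are 1-based; BED intervals are
0-based half-open; all in-memory positions are 0-based and converted at
the I/O boundary. All tabular formats are tab-delimited UTF-8 with
'#'-prefixed comment lines.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .aim import COUNT_COLUMNS
from .core import ConfigurationError, CorrelationMatrix, InputError, SummaryStatVector

__all__ = [
    "GenotypeData",
    "RunConfig",
    "read_phased_vcf",
    "write_phased_vcf",
    "read_genotype_tsv",
    "write_genotype_tsv",
    "read_allelic_counts",
    "write_allelic_counts",
    "read_zscores",
    "write_zscores",
    "read_correlation",
    "write_correlation",
    "read_bed",
    "read_tss_table",
    "write_causal_sets",
]


@dataclass
class GenotypeData:
    """Dosages, het indicators and phasing flags for n samples x m variants."""

    dosage: np.ndarray  # (n, m) float, NaN = missing
    het: np.ndarray  # (n, m) float 0/1, NaN = missing
    phased: np.ndarray  # (n, m) bool
    samples: list[str]
    variant_ids: list[str]
    positions: np.ndarray  # 0-based
    chrom: list[str]

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def m(self) -> int:
        return self.dosage.shape[1]


def read_phased_vcf(path: str) -> GenotypeData:
    """Parse GT fields of a VCF into dosage / heterozygosity matrices.

    Het is 1 for 0|1, 1|0 (or unphased 0/1); missing GTs give NaN in both
    matrices. Positions are converted to 0-based.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    dosages, hets, phased_rows, ids, positions, chroms = [], [], [], [], [], []
    for var in vcf:
        gts = var.genotypes  # [allele1, allele2, phased] per sample
        dos = np.full(len(samples), np.nan)
        het = np.full(len(samples), np.nan)
        ph = np.zeros(len(samples), dtype=bool)
        for i, gt in enumerate(gts):
            a, b = gt[0], gt[1]
            ph[i] = bool(gt[2])
            if a < 0 or b < 0:
                continue
            dos[i] = a + b
            het[i] = float(a != b)
        dosages.append(dos)
        hets.append(het)
        phased_rows.append(ph)
        ids.append(var.ID if var.ID else f"{var.CHROM}:{var.POS}")
        positions.append(var.POS - 1)
        chroms.append(var.CHROM)
    if not dosages:
        raise InputError(f"no variants found in {path}")
    return GenotypeData(
        dosage=np.array(dosages).T,
        het=np.array(hets).T,
        phased=np.array(phased_rows).T,
        samples=samples,
        variant_ids=ids,
        positions=np.array(positions, dtype=np.int64),
        chrom=chroms,
    )


def write_phased_vcf(
    haplotypes: np.ndarray,
    path: str,
    variant_ids: list[str] | None = None,
    positions: np.ndarray | None = None,
    sample_ids: list[str] | None = None,
    chrom: str = "1",
) -> None:
    """Write a (2n, m) 0/1 haplotype matrix as a minimal phased VCF."""
    haps = np.asarray(haplotypes)
    n, m = haps.shape[0] // 2, haps.shape[1]
    variant_ids = variant_ids or [f"v{i}" for i in range(m)]
    positions = positions if positions is not None else np.arange(m)
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids) + "\n")
        for j in range(m):
            gts = "\t".join(f"{haps[2 * i, j]}|{haps[2 * i + 1, j]}" for i in range(n))
            fh.write(f"{chrom}\t{int(positions[j]) + 1}\t{variant_ids[j]}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


def read_genotype_tsv(path: str) -> tuple[np.ndarray, list[str], list[str]]:
    """Variants-x-samples dosage TSV (first column = variant id) -> (n, m) matrix."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return df.to_numpy(dtype=float).T, list(df.columns), list(df.index)


def write_genotype_tsv(
    dosage: np.ndarray,
    path: str,
    sample_ids: list[str] | None = None,
    variant_ids: list[str] | None = None,
) -> None:
    """Write an (n, m) dosage matrix as a variants-x-samples TSV."""
    n, m = np.asarray(dosage).shape
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    variant_ids = variant_ids or [f"v{i}" for i in range(m)]
    pd.DataFrame(np.asarray(dosage).T, index=variant_ids, columns=sample_ids).to_csv(
        path, sep="\t", index_label="variant"
    )


def read_allelic_counts(path: str) -> pd.DataFrame:
    """GTEx-ASE-style count table: sample, gene, snp, hap1_count, hap2_count."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError:
        warnings.warn(f"empty allelic count table at {path}")
        return pd.DataFrame(columns=COUNT_COLUMNS)
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"allelic count table missing columns {missing}")
    for col in ("hap1_count", "hap2_count"):
        if not pd.api.types.is_integer_dtype(df[col]):
            raise InputError(f"column {col} must contain integers")
        if (df[col] < 0).any():
            raise InputError(f"negative read counts in {col}")
    dup = df.duplicated(subset=["sample", "gene", "snp"])
    if dup.any():
        raise InputError(f"duplicate (sample, gene, snp) rows: {df[dup].head().to_dict('records')}")
    if df.empty:
        warnings.warn(f"allelic count table at {path} has a header but no rows")
    return df[COUNT_COLUMNS]


def write_allelic_counts(df: pd.DataFrame, path: str) -> None:
    df[COUNT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_zscores(path: str) -> SummaryStatVector:
    """Z-score TSV with columns variant, z, kind (single kind per file)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("variant", "z", "kind"):
        if col not in df.columns:
            raise InputError(f"z-score table missing column {col!r}")
    kinds = df["kind"].unique()
    if len(kinds) != 1:
        raise InputError(f"z-score file must contain one kind, found {kinds.tolist()}")
    return SummaryStatVector(
        z=df["z"].to_numpy(float), kind=str(kinds[0]), variant_ids=df["variant"].astype(str).tolist()
    )


def write_zscores(stat: SummaryStatVector, path: str) -> None:
    pd.DataFrame({"variant": stat.variant_ids, "z": stat.z, "kind": stat.kind}).to_csv(
        path, sep="\t", index=False
    )


def read_correlation(path: str, kind: str = "genotype_ld") -> CorrelationMatrix:
    """Dense whitespace-delimited correlation matrix with a variant-id header row."""
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    return CorrelationMatrix(values=df.to_numpy(float), kind=kind, variant_ids=list(df.columns))


def write_correlation(corr: CorrelationMatrix, path: str) -> None:
    pd.DataFrame(corr.values, columns=corr.variant_ids).to_csv(path, sep="\t", index=False)


def read_bed(path: str) -> pd.DataFrame:
    """BED intervals (0-based half-open); only the first three columns are used."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    if df.shape[1] < 3:
        raise InputError("BED file needs at least chrom, start, end columns")
    out = df.iloc[:, :3].copy()
    out.columns = ["chrom", "start", "end"]
    return out


def read_tss_table(path: str) -> pd.DataFrame:
    """TSS TSV with columns gene, chrom, position, strand (position 1-based in
    the file, converted to 0-based)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("gene", "chrom", "position"):
        if col not in df.columns:
            raise InputError(f"TSS table missing column {col!r}")
    df = df.copy()
    df["position"] = df["position"].astype(int) - 1
    if "strand" not in df.columns:
        df["strand"] = "+"
    return df


def write_causal_sets(records: list[dict], path: str) -> None:
    """Long-format causal-set TSV: gene, statistic_kind, variant, pip, in_set, attained_mass."""
    pd.DataFrame(
        records, columns=["gene", "statistic_kind", "variant", "pip", "in_set", "attained_mass"]
    ).to_csv(path, sep="\t", index=False)


@dataclass
class RunConfig:
    """Resolved parameters of a pipeline run; written verbatim next to outputs."""

    genotypes: str = ""
    counts: str = ""
    expression: str = ""
    zscores: str = ""
    annotations: str = ""
    out_dir: str = "aimfine_out"
    min_reads: int = 20
    ar_lo: float = 0.35
    ar_hi: float = 0.65
    binarization: str = "empirical"
    top_k: int = 50
    sigma: float = 5.2
    pi_causal: float = 0.01
    k_max: int = 3
    rho: float = 0.95
    ridge: float = 1e-3
    eqtl_z_threshold: float = 0.0
    # individuals entering the heterozygosity correlation: those with an AIM
    # call for the gene (the set informing the AIM statistic) or everyone
    het_corr_individuals: str = "aim_called"
    seed: int = 0
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.binarization not in ("empirical", "binomial"):
            raise ConfigurationError(f"unknown binarization {self.binarization!r}")
        if not 0 < self.rho < 1:
            raise ConfigurationError("rho must be in (0, 1)")
        if self.sigma <= 0 or not 0 < self.pi_causal < 1 or self.k_max < 1:
            raise ConfigurationError("invalid prior parameters")
        if self.min_reads < 0 or self.top_k < 1 or self.ridge < 0:
            raise ConfigurationError("invalid filter parameters")
        if not 0 <= self.ar_lo <= self.ar_hi <= 1:
            raise ConfigurationError("need 0 <= ar_lo <= ar_hi <= 1")
        if self.het_corr_individuals not in ("aim_called", "all"):
            raise ConfigurationError(
                f"het_corr_individuals must be 'aim_called' or 'all', got {self.het_corr_individuals!r}"
            )

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "extras"}
        extras = dict(data.pop("extras", {}) or {})
        kwargs = {k: v for k, v in data.items() if k in known}
        extras.update({k: v for k, v in data.items() if k not in known})
        return cls(**kwargs, extras=extras)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
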