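"""End-to-end per-gene fine-mapping pipeline.

For each gene with allelic count data: call AIM status per individual,
skip genes with no AIM individuals (the AIM statistic is undefined there),
compute or load eQTL z-scores, restrict to the top-k variants by |z|,
build the genotype-LD / heterozygosity / meta correlation matrices,
compute the AIM z-scores and both meta statistics, fine-map the eQTL-only
and meta statistics, and report causal sets and the per-gene reduction
rate. Gene-level failures are logged and skipped; they never abort a run.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .aim import call_aim
from .core import (
    AimfineError,
    CausalPrior,
    InputError,
    NoAIMIndividualsError,
    SummaryStatVector,
)
from .evaluate import reduction_rate
from .finemap import finemap, finemap_meta, pip as compute_pip
from .io import (
    GenotypeData,
    RunConfig,
    read_allelic_counts,
    read_genotype_tsv,
    read_phased_vcf,
    read_zscores,
    write_causal_sets,
)
from .meta import meta_correlation, meta_statistics
from .stats import (
    aim_zscores,
    eqtl_zscores,
    genotype_correlation,
    heterozygosity_correlation,
    regularize,
    select_top_variants,
)

__all__ = ["run_pipeline", "load_genotypes"]


def load_genotypes(path: str) -> GenotypeData:
    """Load genotypes from a phased VCF (by extension) or a variants-x-samples TSV."""
    if path.endswith((".vcf", ".vcf.gz")):
        return read_phased_vcf(path)
    dosage, samples, variant_ids = read_genotype_tsv(path)
    het = (dosage == 1).astype(float)
    het[np.isnan(dosage)] = np.nan
    return GenotypeData(
        dosage=dosage,
        het=het,
        phased=np.zeros_like(dosage, dtype=bool),
        samples=samples,
        variant_ids=variant_ids,
        positions=np.arange(dosage.shape[1], dtype=np.int64),
        chrom=["1"] * dosage.shape[1],
    )


def _gene_zscores(
    gene: str,
    config: RunConfig,
    geno: GenotypeData,
    expression: pd.DataFrame | None,
) -> SummaryStatVector:
    if expression is not None:
        if gene not in expression.index:
            raise InputError(f"gene {gene} absent from expression table")
        y = expression.loc[gene, geno.samples].to_numpy(float)
        return eqtl_zscores(y, geno.dosage, variant_ids=geno.variant_ids)
    if not config.zscores:
        raise InputError("neither expression nor precomputed z-scores provided")
    stat = read_zscores(config.zscores)
    if stat.kind != "eqtl":
        raise InputError(f"precomputed statistics must be of kind 'eqtl', got {stat.kind!r}")
    return stat


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Run the full pipeline; returns the per-gene summary frame and writes
    causal_sets.tsv, summary.tsv, aim_status.tsv, run_log.tsv and the
    resolved config.yaml into ``config.out_dir``."""
    os.makedirs(config.out_dir, exist_ok=True)
    geno = load_genotypes(config.genotypes)
    counts = read_allelic_counts(config.counts)
    expression = None
    if config.expression:
        expression = pd.read_csv(config.expression, sep="\t", comment="#", index_col=0)

    prior = CausalPrior(sigma=config.sigma, pi_causal=config.pi_causal, k_max=config.k_max)
    genes = sorted(counts["gene"].unique())
    aim_frames, set_records, summary_rows, log_rows = [], [], [], []

    for gene in genes:
        try:
            summary_row, sets, aim_status = _run_gene(gene, config, geno, counts, expression, prior)
        except NoAIMIndividualsError:
            log_rows.append({"gene": gene, "status": "skipped", "reason": "no AIM individuals"})
            continue
        except AimfineError as err:
            log_rows.append({"gene": gene, "status": "skipped", "reason": str(err)})
            continue
        aim_frames.append(aim_status)
        set_records.extend(sets)
        summary_rows.append(summary_row)
        log_rows.append(
            {
                "gene": gene,
                "status": "ok",
                "reason": "",
                "n_aim": summary_row["n_aim"],
                "n_balanced": summary_row["n_balanced"],
                "n_eqtl_set": summary_row["n_eqtl_set"],
                "n_meta_set": summary_row["n_meta_set"],
                "reduction_rate": summary_row["reduction_rate"],
            }
        )

    summary = pd.DataFrame(
        summary_rows,
        columns=[
            "gene",
            "n_aim",
            "n_balanced",
            "n_variants",
            "n_eqtl_set",
            "n_meta_set",
            "chosen_kind",
            "reduction_rate",
        ],
    )
    summary.to_csv(os.path.join(config.out_dir, "summary.tsv"), sep="\t", index=False)
    write_causal_sets(set_records, os.path.join(config.out_dir, "causal_sets.tsv"))
    aim_all = (
        pd.concat(aim_frames, ignore_index=True)
        if aim_frames
        else pd.DataFrame(columns=["gene", "sample", "snp", "ar", "status", "method"])
    )
    aim_all.to_csv(os.path.join(config.out_dir, "aim_status.tsv"), sep="\t", index=False)
    pd.DataFrame(log_rows).to_csv(os.path.join(config.out_dir, "run_log.tsv"), sep="\t", index=False)
    config.to_yaml(os.path.join(config.out_dir, "config.yaml"))
    return summary


def _run_gene(gene, config, geno, counts, expression, prior):
    gene_counts = counts[counts["gene"] == gene]
    aim_status = call_aim(
        gene_counts,
        method=config.binarization,
        min_reads=config.min_reads,
        ar_lo=config.ar_lo,
        ar_hi=config.ar_hi,
    )
    status_by_sample = dict(zip(aim_status["sample"], aim_status["status"]))
    status = np.array([status_by_sample.get(s, np.nan) for s in geno.samples])
    n_aim = int(np.nansum(status == 1))
    n_bal = int(np.nansum(status == 0))
    if n_aim == 0:
        raise NoAIMIndividualsError(f"gene {gene}: no individuals with AIM")

    stat_e_full = _gene_zscores(gene, config, geno, expression)
    if config.eqtl_z_threshold > 0 and np.max(np.abs(stat_e_full.z)) < config.eqtl_z_threshold:
        raise InputError(f"gene {gene}: no eQTL reaches |z| >= {config.eqtl_z_threshold}")

    id_to_col = {v: i for i, v in enumerate(geno.variant_ids)}
    try:
        cols_full = np.array([id_to_col[v] for v in stat_e_full.variant_ids])
    except KeyError as err:
        raise InputError(f"gene {gene}: z-score variant {err} absent from genotypes") from err

    top = select_top_variants(stat_e_full, config.top_k)
    keep = np.sort(top)  # genomic order within the locus
    cols = cols_full[keep]
    z_e = stat_e_full.z[keep]
    ids = [stat_e_full.variant_ids[i] for i in keep]

    dosage = geno.dosage[:, cols]
    complete = ~np.isnan(dosage).any(axis=1)
    called = ~np.isnan(status)
    het_called = geno.het[np.ix_(called & complete, cols)]
    status_called = status[called & complete]

    stat_a, undefined = aim_zscores(het_called, status_called, variant_ids=ids)
    if undefined:
        defined = np.array([i for i in range(len(ids)) if i not in set(undefined)])
        if defined.size < 1:
            raise InputError(f"gene {gene}: AIM statistic undefined for every variant")
        cols = cols[defined]
        z_e = z_e[defined]
        ids = [ids[i] for i in defined]
        dosage = geno.dosage[:, cols]
        complete = ~np.isnan(dosage).any(axis=1)
        het_called = geno.het[np.ix_(called & complete, cols)]
        status_called = status[called & complete]
        stat_a, still_undefined = aim_zscores(het_called, status_called, variant_ids=ids)
        if still_undefined:
            raise InputError(f"gene {gene}: AIM statistics unstable after dropping variants")

    stat_e = SummaryStatVector(z=z_e, kind="eqtl", variant_ids=ids)
    sigma_e = genotype_correlation(geno.dosage[np.ix_(complete, cols)], variant_ids=ids)
    if config.het_corr_individuals == "all":
        sigma_a = heterozygosity_correlation(geno.het[np.ix_(complete, cols)], variant_ids=ids)
    else:
        sigma_a = heterozygosity_correlation(het_called, variant_ids=ids)
    sigma_m = meta_correlation(sigma_e, sigma_a)
    sm1, sm2 = meta_statistics(stat_a, stat_e)

    sigma_e_r = regularize(sigma_e, config.ridge)
    sigma_m_r = regularize(sigma_m, config.ridge)
    eqtl_set, eqtl_table = finemap(stat_e, sigma_e_r, prior, config.rho)
    meta_set = finemap_meta(sm1, sm2, sigma_m_r, prior, config.rho)

    records = []
    pips = compute_pip(eqtl_table)
    members = set(eqtl_set.variants)
    for i, vid in enumerate(ids):
        records.append(
            {
                "gene": gene,
                "statistic_kind": "eqtl",
                "variant": vid,
                "pip": round(float(pips[i]), 6),
                "in_set": int(i in members),
                "attained_mass": round(eqtl_set.mass, 6),
            }
        )
    meta_members = set(meta_set.variants)
    for i, vid in enumerate(ids):
        records.append(
            {
                "gene": gene,
                "statistic_kind": meta_set.kind,
                "variant": vid,
                "pip": "",
                "in_set": int(i in meta_members),
                "attained_mass": round(meta_set.mass, 6),
            }
        )
    summary_row = {
        "gene": gene,
        "n_aim": n_aim,
        "n_balanced": n_bal,
        "n_variants": len(ids),
        "n_eqtl_set": eqtl_set.size,
        "n_meta_set": meta_set.size,
        "chosen_kind": meta_set.kind,
        "reduction_rate": round(reduction_rate(eqtl_set.size, meta_set.size), 6),
    }
    return summary_row, records, aim_status
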