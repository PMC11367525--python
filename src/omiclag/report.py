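"""End-to-end orchestration and the accounting summary table."""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .cluster_enrich import cluster_logfc, pca_top_variable
from .concordance import (
    fraction_of_total,
    lag_matrix,
    matched_vs_mismatched,
    per_gene_correlations,
    rma_per_timepoint,
    top_k_share,
)
from .data_model_io import (
    PairedOmicsDataset,
    collapse_to_protein_coding,
    filter_expressed,
    select_quantified_proteins,
    write_dataset,
)
from .factor_integration import fit_multiview_factors, select_factor_genes
from .protein_de import ImputationParams, impute_minprob, moderated_f_test
from .ratios import ratio_analysis
from .synthetic_data import SimulationConfig, generate_paired_dataset
from .transcript_de import log_transform, nb_lrt

logger = logging.getLogger("omiclag")


def percent(count: int, denominator: int) -> float:
    """100 * count / denominator, rounded half-up to one decimal."""
    if denominator == 0:
        raise ZeroDivisionError("denominator is 0")
    if count == 0:
        return 0.0
    ratio = Decimal(100 * count) / Decimal(denominator)
    return float(ratio.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class SummaryCounts:
    """Raw accounting inputs for the summary table."""

    protein_coding: int
    expressed_transcripts: int
    quantified_proteins: int  # directly quantified + imputed
    both_quantified: int
    de_transcripts: int
    de_proteins: int
    de_both: int


@dataclass
class SummaryTable:
    """Counts plus the derived percentages (one decimal, half-up)."""

    counts: SummaryCounts
    pct_expressed_transcripts: float
    pct_quantified_proteins: float
    pct_both_quantified: float
    pct_de_transcripts: float
    pct_de_proteins: float
    pct_de_both: float

    def to_frame(self) -> pd.DataFrame:
        c = self.counts
        return pd.DataFrame(
            {
                "transcripts": [c.protein_coding, c.expressed_transcripts,
                                self.pct_expressed_transcripts, c.de_transcripts,
                                self.pct_de_transcripts],
                "proteins": [c.protein_coding, c.quantified_proteins,
                             self.pct_quantified_proteins, c.de_proteins,
                             self.pct_de_proteins],
                "transcripts_and_proteins": [c.protein_coding, c.both_quantified,
                                             self.pct_both_quantified, c.de_both,
                                             self.pct_de_both],
            },
            index=[
                "all_protein_coding_genes",
                "expressed_or_quantified",
                "pct_expressed_or_quantified",
                "differentially_expressed",
                "pct_differentially_expressed",
            ],
        )


def summarize(counts: SummaryCounts) -> SummaryTable:
    """Derive the six percentages from the accounting counts.

    Denominators: all protein-coding genes for the expression rows; the
    expressed/quantified totals of the corresponding column for the DE
    rows.
    """
    inv = (
        counts.de_both <= min(counts.de_transcripts, counts.de_proteins),
        counts.expressed_transcripts <= counts.protein_coding,
        counts.quantified_proteins <= counts.protein_coding,
    )
    if not all(inv):
        raise ValueError(f"inconsistent summary counts: {counts}")
    return SummaryTable(
        counts=counts,
        pct_expressed_transcripts=percent(counts.expressed_transcripts, counts.protein_coding),
        pct_quantified_proteins=percent(counts.quantified_proteins, counts.protein_coding),
        pct_both_quantified=percent(counts.both_quantified, counts.protein_coding),
        pct_de_transcripts=percent(counts.de_transcripts, counts.expressed_transcripts),
        pct_de_proteins=percent(counts.de_proteins, counts.quantified_proteins),
        pct_de_both=percent(counts.de_both, counts.both_quantified),
    )


def summarize_dataset(dataset: PairedOmicsDataset, de_rna, de_prot, both_quantified: int) -> SummaryTable:
    """Build the summary from an analyzed dataset."""
    annot = dataset.genes.table
    n_coding = int(annot["is_protein_coding"].astype(bool).sum())
    direct, imputable, _ = select_quantified_proteins(dataset.intensities, dataset.samples)
    de_rna_genes = set(de_rna.de_genes)
    de_prot_genes = set(de_prot.de_genes)
    counts = SummaryCounts(
        protein_coding=n_coding,
        expressed_transcripts=len(de_rna.table),
        quantified_proteins=len(direct) + len(imputable),
        both_quantified=both_quantified,
        de_transcripts=len(de_rna_genes),
        de_proteins=len(de_prot_genes),
        de_both=len(de_rna_genes & de_prot_genes),
    )
    return summarize(counts)


def run_pipeline(
    config: SimulationConfig,
    out_dir: str,
    k_clusters: int = 4,
    k_factors: int = 3,
    n_perm: int = 200,
    n_mc: int = 20_000,
) -> dict:
    """Run the whole analysis on a freshly generated synthetic dataset.

    Stages: simulate -> preprocess -> DE (both modalities) -> cluster ->
    concordance/lag -> ratios -> factors -> summary. Writes TSV outputs and
    a JSON manifest under ``out_dir`` and returns the manifest dict.
    """
    os.makedirs(out_dir, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    def stage(name):
        t0 = time.time()
        logger.info("stage %s ...", name)
        return t0

    t0 = stage("simulate")
    dataset = generate_paired_dataset(config)
    write_dataset(dataset, os.path.join(out_dir, "dataset"))
    manifest["stages"]["simulate"] = round(time.time() - t0, 2)

    t0 = stage("preprocess")
    counts = collapse_to_protein_coding(dataset.counts, dataset.genes)
    counts = filter_expressed(counts)
    direct, imputable, _ = select_quantified_proteins(dataset.intensities, dataset.samples)
    params = ImputationParams(seed=config.seed)
    n_imputed = dataset.intensities.missing_mask.sum(axis=1)
    intensities = impute_minprob(dataset.intensities, direct, imputable, params)
    manifest["stages"]["preprocess"] = round(time.time() - t0, 2)

    t0 = stage("differential expression")
    de_rna = nb_lrt(counts, dataset.samples)
    de_rna.to_tsv(os.path.join(out_dir, "de_rna.tsv"))
    de_prot = moderated_f_test(
        intensities, dataset.samples, n_imputed=n_imputed.loc[intensities.gene_ids]
    )
    de_prot.to_tsv(os.path.join(out_dir, "de_protein.tsv"))
    manifest["stages"]["de"] = round(time.time() - t0, 2)

    t0 = stage("clustering / PCA")
    if de_rna.table["is_DE"].sum() >= k_clusters:
        clusters = cluster_logfc(de_rna, k=k_clusters)
        clusters.assignments.to_csv(os.path.join(out_dir, "clusters_rna.tsv"), sep="\t")
    logged = log_transform(counts)
    scores, ve = pca_top_variable(logged, n_top=min(500, len(counts.gene_ids)))
    scores.iloc[:, :2].assign(variance_explained_pc1=ve[0] if ve.size else np.nan).to_csv(
        os.path.join(out_dir, "pca_rna.tsv"), sep="\t"
    )
    manifest["stages"]["cluster"] = round(time.time() - t0, 2)

    t0 = stage("concordance")
    common = [g for g in counts.gene_ids if g in set(intensities.gene_ids)]
    rna_frac = fraction_of_total(counts.subset_genes(common))
    prot_frac = fraction_of_total(intensities.subset_genes(common), delog=True)
    conc = lag_matrix(rna_frac, prot_frac, dataset.samples)
    conc.lag_matrix.to_csv(os.path.join(out_dir, "lag_matrix.tsv"), sep="\t")
    per_gene = per_gene_correlations(rna_frac, prot_frac, dataset.samples)
    per_gene.to_csv(os.path.join(out_dir, "per_gene_r.tsv"), sep="\t")
    rma = rma_per_timepoint(rna_frac, prot_frac, dataset.samples)
    rma.to_csv(os.path.join(out_dir, "rma.tsv"), sep="\t", index=False)
    matched, mism, perm_p = matched_vs_mismatched(
        rna_frac, prot_frac, dataset.samples, n_perm=n_perm, seed=config.seed
    )
    manifest["concordance"] = {
        "estimated_lag_h": conc.estimated_lag_h,
        "matched_median_r": matched,
        "mismatched_mean_median_r": mism,
        "permutation_p": perm_p,
        "top2_share_rna": top_k_share(rna_frac, 2),
        "top2_share_protein": top_k_share(prot_frac, 2),
    }
    manifest["stages"]["concordance"] = round(time.time() - t0, 2)

    t0 = stage("ratios")
    ratio_res = ratio_analysis(
        rna_frac, prot_frac, dataset.samples, de_rna, n_mc=n_mc, seed=config.seed
    )
    ratio_res.dunnett.to_csv(os.path.join(out_dir, "ratios_dunnett.tsv"), sep="\t", index=False)
    manifest["stages"]["ratios"] = round(time.time() - t0, 2)

    t0 = stage("factors")
    logged_common = logged.subset_genes(common)
    model = fit_multiview_factors(
        logged_common, intensities.subset_genes(common), dataset.samples, k=k_factors
    )
    model.variance_explained.to_csv(os.path.join(out_dir, "variance_explained.tsv"), sep="\t")
    model.factors.to_csv(os.path.join(out_dir, "factors.tsv"), sep="\t")
    select_factor_genes(model, 1).to_csv(os.path.join(out_dir, "factor1_genes.tsv"), sep="\t")
    manifest["stages"]["factors"] = round(time.time() - t0, 2)

    t0 = stage("summary")
    summary = summarize_dataset(dataset, de_rna, de_prot, both_quantified=len(common))
    summary.to_frame().to_csv(os.path.join(out_dir, "summary.tsv"), sep="\t")
    manifest["summary"] = {
        "de_transcripts": summary.counts.de_transcripts,
        "de_proteins": summary.counts.de_proteins,
        "de_both": summary.counts.de_both,
        "pct_de_transcripts": summary.pct_de_transcripts,
        "pct_de_proteins": summary.pct_de_proteins,
    }
    manifest["stages"]["summary"] = round(time.time() - t0, 2)

    with open(os.path.join(out_dir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
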