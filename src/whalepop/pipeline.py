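"""End-to-end orchestration: filter -> structure -> diversity -> ROH -> load,
with cross-statistic correlations and a cohort-level summary table.

The report mirrors the shape of a per-cohort diversity/inbreeding/load table:
mean heterozygosity, pi, Watterson's theta, Tajima's D, F_H, F_ROH above
1 Mbp, LoF counts and mutational load, plus Pearson correlations between
statistic pairs (e.g. heterozygosity against F_ROH).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import diversity_stats, population_structure, roh_analysis
from .genotype_io import (
    GenotypeMatrix,
    SiteFilterConfig,
    apply_site_filters,
    read_vcf,
    remove_related,
)
from .stats_tests import anova_oneway, pearson_correlation  # re-exported

logger = logging.getLogger("whalepop")

__all__ = [
    "PipelineConfig",
    "CohortReport",
    "run_pipeline",
    "pearson_correlation",
    "anova_oneway",
]


@dataclass
class PipelineConfig:
    """Everything `run_pipeline` needs beyond the data itself."""

    site_filters: SiteFilterConfig = field(default_factory=SiteFilterConfig)
    expected_mean_depth: Optional[float] = None
    pihat_cutoff: float = 0.2
    contig_lengths: Optional[dict] = None
    l_callable: Optional[float] = None  # callable length for per-site pi/theta
    roh_window: int = roh_analysis.DEFAULT_WINDOW
    roh_het_threshold: float = roh_analysis.DEFAULT_HET_THRESHOLD
    roh_min_windows: int = roh_analysis.DEFAULT_MIN_WINDOWS
    min_contig_length: int = roh_analysis.MIN_CONTIG_LENGTH
    annotation: Optional[object] = None  # CodingAnnotation for the load stage
    stages: tuple = ("filter", "relatedness", "structure", "diversity", "roh", "load")


@dataclass
class CohortReport:
    cohort_table: pd.DataFrame
    individual_table: pd.DataFrame
    correlations: pd.DataFrame
    filter_report: Optional[object] = None
    pcoa: Optional[object] = None
    roh_profiles: dict = field(default_factory=dict)
    load_table: Optional[pd.DataFrame] = None


def _correlation_rows(ind: pd.DataFrame, pairs: list) -> pd.DataFrame:
    rows = []
    for x, y in pairs:
        if x not in ind.columns or y not in ind.columns:
            continue
        xs, ys = ind[x].to_numpy(float), ind[y].to_numpy(float)
        ok = np.isfinite(xs) & np.isfinite(ys)
        try:
            r, p = pearson_correlation(xs[ok], ys[ok])
        except ValueError:
            r, p = np.nan, np.nan
        rows.append({"x": x, "y": y, "pearson_r": r, "p": p, "n": int(ok.sum())})
    return pd.DataFrame(rows, columns=["x", "y", "pearson_r", "p", "n"])


def run_pipeline(
    data,
    config: Optional[PipelineConfig] = None,
    cohorts: Optional[dict] = None,
    seed: int = 0,
) -> CohortReport:
    """Run the analysis stages in fixed order on a VCF path or a
    :class:`GenotypeMatrix`.

    Deterministic given the seed; each stage logs its parameters.  Stages can
    be disabled through ``config.stages``; downstream statistics that depend
    on a skipped stage are reported as NaN.
    """
    config = config or PipelineConfig()
    logger.info("pipeline start seed=%s stages=%s", seed, config.stages)
    if isinstance(data, (str,)):
        gm = read_vcf(data, keep_monomorphic=True)
    elif isinstance(data, GenotypeMatrix):
        gm = data
    else:
        raise TypeError("data must be a VCF path or a GenotypeMatrix")
    if cohorts is not None:
        gm.cohort_labels = [cohorts.get(s, "all") for s in gm.sample_ids]
    if "load" in config.stages and config.annotation is None:
        raise ValueError("load stage enabled but no annotation configured")

    filter_report = None
    if "filter" in config.stages:
        logger.info("stage=filter cfg=%s", config.site_filters)
        try:
            gm, filter_report = apply_site_filters(
                gm, config.site_filters, config.expected_mean_depth
            )
        except ValueError as exc:
            raise ValueError(f"stage 'filter' failed: {exc}") from exc

    if "relatedness" in config.stages and gm.n_individuals >= 2:
        logger.info("stage=relatedness cutoff=%s", config.pihat_cutoff)
        seg = gm.take_sites(gm.is_segregating())
        if seg.n_sites:
            kept = remove_related(seg, config.pihat_cutoff).sample_ids
            gm = gm.take_individuals([gm.sample_ids.index(s) for s in kept])

    pcoa_result = None
    if "structure" in config.stages and gm.n_individuals >= 3:
        logger.info("stage=structure")
        snp = gm.take_sites(gm.is_segregating())
        d = population_structure.allele_sharing_distance(snp)
        pcoa_result = population_structure.pcoa(d, n_axes=min(2, gm.n_individuals - 1))

    l_callable = config.l_callable or float(gm.n_sites)
    ind = diversity_stats.cohort_diversity_table(gm, l_callable)

    roh_profiles: dict = {}
    if "roh" in config.stages:
        lengths = config.contig_lengths
        if lengths is None:
            lengths = {
                str(c): int(gm.positions[gm.chrom_ids == c].max())
                for c in pd.unique(gm.chrom_ids)
            }
        logger.info("stage=roh window=%s threshold=%s", config.roh_window, config.roh_het_threshold)
        froh_top = []
        for sid in gm.sample_ids:
            tracks = roh_analysis.window_heterozygosity(
                gm, sid, lengths,
                window_size=config.roh_window,
                min_contig_length=config.min_contig_length,
            )
            segs = [
                s
                for tr in tracks
                for s in roh_analysis.detect_roh(
                    tr, config.roh_het_threshold, config.roh_min_windows
                )
            ]
            analyzed = sum(
                v for v in lengths.values() if v >= config.min_contig_length
            )
            if analyzed > 0:
                prof = roh_analysis.froh_profile(segs, analyzed)
                roh_profiles[sid] = prof
                froh_top.append(prof.froh_at_cutoff[-1])
            else:
                froh_top.append(np.nan)
        ind["froh_1mb"] = froh_top
    else:
        ind["froh_1mb"] = np.nan

    load_table = None
    if "load" in config.stages:
        from .mutational_load import classify_variants, load_summary

        logger.info("stage=load")
        snp = gm.take_sites(gm.is_segregating())
        effects = classify_variants(snp, config.annotation)
        load_table = load_summary(effects, snp)
        ind = ind.merge(
            load_table[["sample", "n_lof", "n_lof_het", "n_lof_hom", "load"]],
            on="sample",
            how="left",
        )

    agg_cols = [
        c
        for c in (
            "het_frac", "pi_per_site", "theta_w_per_site", "tajimas_d",
            "f_h", "froh_1mb", "n_lof", "n_lof_het", "n_lof_hom", "load",
        )
        if c in ind.columns
    ]
    cohort_table = ind.groupby("cohort")[agg_cols].mean().reset_index()
    correlations = _correlation_rows(
        ind,
        [("het_frac", "froh_1mb"), ("het_frac", "f_h"), ("het_frac", "load"),
         ("froh_1mb", "load")],
    )
    return CohortReport(
        cohort_table=cohort_table,
        individual_table=ind,
        correlations=correlations,
        filter_report=filter_report,
        pcoa=pcoa_result,
        roh_profiles=roh_profiles,
        load_table=load_table,
    )
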