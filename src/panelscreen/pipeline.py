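"""End-to-end orchestration of the filtering and profiling stages.

Stage order: coverage exclusion -> allele-fraction filter -> quality
gates -> SNP/non-SNP partition -> annotation consolidation + retention
-> binarization -> group contrasts. Every stage appends entering/leaving
counts to a stage log, and filters only ever remove calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from . import annotate, profiles, qc
from .annotate import RetentionConfig
from .cohort import CohortBundle
from .panels import PanelDefinition

__all__ = ["FilterThresholds", "PipelineResult", "run_pipeline"]

VARIANT_KEY = ["sample_id", "chrom", "pos", "ref", "alt"]


@dataclass(frozen=True)
class FilterThresholds:
    min_region_depth: float = 5.0
    min_vaf: float = 0.10
    min_alt_bases: int = 2
    min_qual: float = 20.0
    min_mapq: float = 20.0
    min_depth: int = 5
    retention: RetentionConfig = field(default_factory=RetentionConfig)


@dataclass
class PipelineResult:
    stage_log: pd.DataFrame
    removal_ledger: pd.DataFrame
    retained_calls: pd.DataFrame
    retained_variants: dict  # (stratum, class_subset) -> DataFrame
    matrices: dict  # (stratum, class_subset) -> BinarizedMatrix
    frequencies: dict  # (stratum, class_subset) -> DataFrame
    comparison: pd.DataFrame
    missing: set


def _coverage_filter(calls: pd.DataFrame, depth: pd.DataFrame,
                     excluded: set) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop calls falling inside an excluded (sample, region) pair."""
    if calls.empty or not excluded:
        return calls.copy(), calls.iloc[0:0].assign(failed_gate=pd.Series(dtype=str))
    regions = depth[["chrom", "start", "end"]].drop_duplicates()
    keep = pd.Series(True, index=calls.index)
    for row in regions.itertuples(index=False):
        in_region = ((calls["chrom"] == row.chrom)
                     & (calls["pos"] >= row.start) & (calls["pos"] <= row.end))
        if not in_region.any():
            continue
        bad_samples = {s for (s, c, st, en) in excluded
                       if (c, st, en) == (row.chrom, row.start, row.end)}
        if bad_samples:
            keep &= ~(in_region & calls["sample_id"].isin(bad_samples))
    retained = calls[keep].copy()
    removed = calls[~keep].copy()
    removed["failed_gate"] = "COVERAGE"
    return retained, removed


def run_pipeline(bundle: CohortBundle, panel: PanelDefinition,
                 thresholds: FilterThresholds = FilterThresholds(),
                 groups: Optional[pd.Series] = None) -> PipelineResult:
    """Run filtering, annotation retention, binarization and contrasts."""
    if groups is None:
        groups = bundle.samples.set_index("sample_id")["group"]
    stage_rows = []
    ledgers = []

    excluded = qc.low_coverage_mask(bundle.depth, thresholds.min_region_depth)
    missing = qc.missing_genes(bundle.depth, thresholds.min_region_depth)

    calls = bundle.calls
    after_cov, led_cov = _coverage_filter(calls, bundle.depth, excluded)
    stage_rows.append({"stage": "coverage", "entering": len(calls),
                       "leaving": len(after_cov), "removed": len(led_cov)})
    ledgers.append(led_cov)

    after_vaf, led_vaf = qc.vaf_filter(after_cov, thresholds.min_vaf)
    stage_rows.append({"stage": "vaf", "entering": len(after_cov),
                       "leaving": len(after_vaf), "removed": len(led_vaf)})
    ledgers.append(led_vaf)

    after_q, led_q = qc.quality_filter(
        after_vaf, min_alt_bases=thresholds.min_alt_bases,
        min_qual=thresholds.min_qual, min_mapq=thresholds.min_mapq,
        min_depth=thresholds.min_depth)
    stage_rows.append({"stage": "quality", "entering": len(after_vaf),
                       "leaving": len(after_q), "removed": len(led_q)})
    ledgers.append(led_q)

    snps, non_snps = qc.partition_by_class(after_q)
    stage_rows.append({"stage": "partition", "entering": len(after_q),
                       "leaving": len(snps) + len(non_snps), "removed": 0})

    # annotation retention, independently per class subset and stratum
    keyed_anno = bundle.annotations.set_index(VARIANT_KEY, drop=False)
    retained_variants: dict = {}
    samples = list(bundle.samples["sample_id"])
    matrices: dict = {}
    frequencies: dict = {}
    class_frames = {"snp": snps, "non_snp": non_snps}
    for stratum in annotate.STRATA:
        per_class = {}
        for cls, frame in class_frames.items():
            if frame.empty:
                per_class[cls] = annotate.retain_table([], stratum,
                                                       thresholds.retention)
                continue
            keys = list(frame[VARIANT_KEY].itertuples(index=False, name=None))
            rows = keyed_anno.loc[keyed_anno.index.isin(keys)]
            avs = annotate.consolidate_table(rows.reset_index(drop=True))
            per_class[cls] = annotate.retain_table(avs, stratum,
                                                   thresholds.retention)
        nonempty = [t for t in (per_class["snp"], per_class["non_snp"])
                    if len(t)]
        combined = (pd.concat(nonempty, ignore_index=True) if nonempty
                    else per_class["snp"].copy())
        per_class["combined"] = combined
        for cls, table in per_class.items():
            retained_variants[(stratum, cls)] = table
            matrix = profiles.binarize(
                table[~table["incidental"]] if len(table) else table,
                panel.genes, samples, stratum, cls, missing=missing,
                panel=panel.name)
            matrices[(stratum, cls)] = matrix
            frequencies[(stratum, cls)] = profiles.cumulative_frequency(
                matrix, groups)

    n_retained = len(retained_variants[("HIGH_OR_MODERATE", "combined")])
    stage_rows.append({"stage": "annotation_retention",
                       "entering": len(after_q), "leaving": n_retained,
                       "removed": len(after_q) - n_retained})

    comparison = profiles.comparison_report(
        matrices.values(), groups,
        droplist=thresholds.retention.report_droplist)

    ledger = (pd.concat(ledgers, ignore_index=True) if ledgers
              else pd.DataFrame())
    return PipelineResult(
        stage_log=pd.DataFrame(stage_rows), removal_ledger=ledger,
        retained_calls=after_q, retained_variants=retained_variants,
        matrices=matrices, frequencies=frequencies, comparison=comparison,
        missing=missing)
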