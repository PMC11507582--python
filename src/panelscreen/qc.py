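"""Pre-annotation variant filters.

Implements the coverage-depth region exclusion, the allele-fraction
filter, the four explicit quality gates and the SNP/non-SNP partition.
Variant calls travel as pandas DataFrames with the columns listed in
:data:`CALL_COLUMNS`; every filter returns the retained frame plus a
removal ledger attributing each dropped call to the gate(s) it failed.

Boundary conventions: "minimum X of N" gates retain values >= N; the
allele-fraction rule removes calls strictly below the threshold; region
exclusion removes mean depths strictly below the threshold.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "CALL_COLUMNS",
    "VARIANT_CLASSES",
    "classify_alleles",
    "low_coverage_mask",
    "missing_genes",
    "variant_allele_fraction",
    "vaf_filter",
    "quality_filter",
    "partition_by_class",
]

CALL_COLUMNS = (
    "sample_id", "chrom", "pos", "ref", "alt", "variant_class",
    "qual", "mapq", "depth", "ref_depth", "alt_depth",
)

VARIANT_CLASSES = frozenset({"snp", "indel", "mnp", "bnd", "other"})

_BASES = frozenset("ACGTacgt")


def classify_alleles(ref: str, alt: str) -> str:
    """Assign a variant class from REF/ALT allele strings.

    Single-base substitutions are ``snp``; equal-length multi-base
    substitutions are ``mnp``; length-changing allele pairs are
    ``indel``; symbolic or breakend ALT notation is ``bnd``; anything
    else falls through to ``other``.
    """
    if len(ref) == 1 and len(alt) == 1 and ref in _BASES and alt in _BASES:
        return "snp"
    if alt.startswith("<") or "[" in alt or "]" in alt:
        return "bnd"
    if all(c in _BASES for c in ref) and all(c in _BASES for c in alt):
        if len(ref) == len(alt):
            return "mnp"
        return "indel"
    return "other"


def low_coverage_mask(summaries: pd.DataFrame,
                      min_mean_depth: float = 5.0) -> set[tuple]:
    """Per-sample region exclusions from mean-depth summaries.

    A (sample, region) pair is excluded iff its mean coverage depth is
    strictly below ``min_mean_depth``. Returns a set of
    ``(sample_id, chrom, start, end)`` keys.
    """
    if min_mean_depth < 0:
        raise ValueError("min_mean_depth must be non-negative")
    if summaries.empty:
        return set()
    bad = summaries[summaries["mean_depth"] < min_mean_depth]
    return set(zip(bad["sample_id"], bad["chrom"], bad["start"], bad["end"]))


def missing_genes(summaries: pd.DataFrame,
                  min_mean_depth: float = 5.0) -> set[tuple[str, str]]:
    """(sample, gene) pairs whose every enriched region is excluded.

    Such genes are MISSING for the sample downstream (dropped pairwise
    from contingency tables), not scored as unaltered.
    """
    if summaries.empty:
        return set()
    ok = summaries.assign(_pass=summaries["mean_depth"] >= min_mean_depth)
    by_gene = ok.groupby(["sample_id", "gene"])["_pass"].any()
    return set(by_gene[~by_gene].index)


def variant_allele_fraction(calls: pd.DataFrame) -> pd.Series:
    """alt_depth / (ref_depth + alt_depth), NaN where no allele evidence."""
    total = calls["ref_depth"] + calls["alt_depth"]
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = calls["alt_depth"] / total
    return vaf.where(total > 0, np.nan)


def _split(calls: pd.DataFrame, keep: pd.Series, gate: pd.Series):
    retained = calls[keep].copy()
    ledger = calls[~keep].copy()
    ledger["failed_gate"] = gate[~keep]
    return retained, ledger


def vaf_filter(calls: pd.DataFrame, min_fraction: float = 0.10
               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove calls with allele fraction strictly below ``min_fraction``.

    Calls with zero total allele depth cannot be assessed and are
    removed with the distinct reason ``NO_ALLELE_EVIDENCE``.
    """
    if min_fraction < 0:
        raise ValueError("min_fraction must be non-negative")
    if calls.empty:
        return calls.copy(), calls.assign(failed_gate=pd.Series(dtype=str))
    vaf = variant_allele_fraction(calls)
    no_evidence = vaf.isna()
    keep = (vaf >= min_fraction) & ~no_evidence
    gate = pd.Series(np.where(no_evidence, "NO_ALLELE_EVIDENCE", "VAF"),
                     index=calls.index)
    return _split(calls, keep, gate)


def quality_filter(calls: pd.DataFrame, min_alt_bases: int = 2,
                   min_qual: float = 20.0, min_mapq: float = 20.0,
                   min_depth: int = 5) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the four explicit quality gates, all inclusive minima.

    Removal ledger tags each dropped call with every failing gate,
    comma-joined (``ALT_BASES``, ``QUAL``, ``MAPQ``, ``DEPTH``).
    """
    for name, v in (("min_alt_bases", min_alt_bases), ("min_qual", min_qual),
                    ("min_mapq", min_mapq), ("min_depth", min_depth)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    if calls.empty:
        return calls.copy(), calls.assign(failed_gate=pd.Series(dtype=str))
    fails = pd.DataFrame({
        "ALT_BASES": calls["alt_depth"] < min_alt_bases,
        "QUAL": calls["qual"] < min_qual,
        "MAPQ": calls["mapq"] < min_mapq,
        "DEPTH": calls["depth"] < min_depth,
    })
    keep = ~fails.any(axis=1)
    gate = fails.apply(lambda row: ",".join(fails.columns[row.values]), axis=1)
    return _split(calls, keep, gate)


def partition_by_class(calls: pd.DataFrame
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split calls into the SNP subset and the non-SNP subset.

    Non-SNPs are indels, mnps, breakpoints and anything else; the two
    frames partition the input exactly.
    """
    unknown = set(calls["variant_class"]) - VARIANT_CLASSES
    if unknown:
        raise ValueError(f"unknown variant class label(s): {sorted(unknown)}")
    is_snp = calls["variant_class"] == "snp"
    return calls[is_snp].copy(), calls[~is_snp].copy()
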