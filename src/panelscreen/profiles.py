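"""Binary alteration matrices and group contrasts.

Builds the samples x genes 0/1 matrix from retained variants, computes
per-group cumulative alteration frequencies, per-sample variant-count
rank tests, and pairwise per-gene 2x2 contrasts (Fisher's exact test or
the chi-squared test chosen by the expected-cell-count rule).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BinarizedMatrix",
    "GroupContrast",
    "binarize",
    "cumulative_frequency",
    "count_distribution_tests",
    "contrast_2x2",
    "pairwise_gene_contrast",
    "comparison_report",
]


@dataclass
class BinarizedMatrix:
    """Samples x genes alteration matrix; NaN marks MISSING entries.

    MISSING appears only where coverage masking removed every enriched
    region of a gene for a sample.
    """

    data: pd.DataFrame  # float: 0.0, 1.0 or NaN
    stratum: str
    class_subset: str  # snp | non_snp | combined
    panel: str

    def __post_init__(self) -> None:
        vals = self.data.to_numpy(dtype=float)
        ok = np.isnan(vals) | (vals == 0.0) | (vals == 1.0)
        if not ok.all():
            raise ValueError("matrix entries must be 0, 1 or MISSING")

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def genes(self) -> list[str]:
        return list(self.data.columns)


def binarize(retained: pd.DataFrame, panel_genes: Sequence[str],
             samples: Sequence[str], stratum: str, class_subset: str,
             missing: Optional[Iterable[tuple[str, str]]] = None,
             panel: str = "panel") -> BinarizedMatrix:
    """1 iff the sample carries >= 1 retained variant in the gene.

    ``retained`` must already be stratum/class filtered and carry
    ``sample_id`` and ``gene`` columns. Variants in genes outside the
    panel raise a warning and land in an incidental bucket attached to
    the result as the attribute ``incidental``.
    """
    data = pd.DataFrame(0.0, index=list(samples), columns=list(panel_genes))
    incidental: list[tuple[str, str]] = []
    panel_set = set(panel_genes)
    if not retained.empty:
        for sample_id, gene in zip(retained["sample_id"], retained["gene"]):
            if gene not in panel_set:
                incidental.append((sample_id, gene))
                continue
            if sample_id in data.index:
                data.at[sample_id, gene] = 1.0
    if incidental:
        warnings.warn(
            f"{len(incidental)} retained variant(s) in off-panel genes "
            "assigned to the incidental bucket", stacklevel=2)
    for sample_id, gene in (missing or ()):
        if sample_id in data.index and gene in data.columns:
            data.at[sample_id, gene] = np.nan
    matrix = BinarizedMatrix(data=data, stratum=stratum,
                             class_subset=class_subset, panel=panel)
    matrix.incidental = incidental
    return matrix


def cumulative_frequency(matrix: BinarizedMatrix,
                         groups: Mapping[str, str] | pd.Series) -> pd.DataFrame:
    """Altered fraction per gene per group over non-MISSING samples.

    Genes with zero non-MISSING samples in a group get NaN.
    """
    labels = pd.Series(dict(groups)).reindex(matrix.data.index)
    if labels.isna().any():
        missing = list(labels[labels.isna()].index)
        raise ValueError(f"unlabelled sample(s): {missing[:5]}")
    return matrix.data.groupby(labels).mean().T


def count_distribution_tests(counts: pd.Series,
                             groups: Mapping[str, str] | pd.Series
                             ) -> dict:
    """Kruskal-Wallis omnibus plus all pairwise Wilcoxon rank-sum tests.

    Pairwise tests use scipy's Mann-Whitney U with continuity correction
    in the asymptotic branch (exact p when samples are tiny and tie
    free). Fully degenerate inputs (every value identical) report p=1.
    """
    labels = pd.Series(dict(groups)).reindex(counts.index)
    group_names = sorted(labels.dropna().unique())
    if len(group_names) < 2:
        raise ValueError("need at least two groups")
    per_group = {g: counts[labels == g].to_numpy(dtype=float) for g in group_names}
    for g, arr in per_group.items():
        if len(arr) < 2:
            raise ValueError(f"group {g!r} has fewer than two samples")

    all_vals = np.concatenate(list(per_group.values()))
    if np.all(all_vals == all_vals[0]):
        omnibus_p = 1.0
    else:
        omnibus_p = float(stats.kruskal(*per_group.values()).pvalue)

    pairwise = pd.DataFrame(np.nan, index=group_names, columns=group_names)
    for i, ga in enumerate(group_names):
        for gb in group_names[i + 1:]:
            a, b = per_group[ga], per_group[gb]
            both = np.concatenate([a, b])
            if np.all(both == both[0]):
                p = 1.0
            else:
                p = float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                             use_continuity=True,
                                             method="auto").pvalue)
            pairwise.at[ga, gb] = p
            pairwise.at[gb, ga] = p
    return {"omnibus_p": omnibus_p, "pairwise_p": pairwise}


@dataclass(frozen=True)
class GroupContrast:
    gene: str
    group_a: str
    group_b: str
    p_value: float
    direction: Optional[str]  # group with the higher altered fraction
    test_used: str  # chi_squared | fisher_exact
    table: tuple  # ((altered_a, unaltered_a), (altered_b, unaltered_b))


def contrast_2x2(altered_a: int, unaltered_a: int, altered_b: int,
                 unaltered_b: int, force_fisher: bool = False
                 ) -> tuple[float, str]:
    """p-value and test name for one 2x2 altered/unaltered table.

    Fisher's exact test whenever any expected cell count is below 5
    (or when forced); otherwise the chi-squared test without continuity
    correction.
    """
    table = np.array([[altered_a, unaltered_a], [altered_b, unaltered_b]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("empty 2x2 margin")
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    if force_fisher or (expected < 5).any():
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        return p, "fisher_exact"
    p = float(stats.chi2_contingency(table, correction=False)[1])
    return p, "chi_squared"


def pairwise_gene_contrast(matrix: BinarizedMatrix, gene: str, group_a: str,
                           group_b: str,
                           groups: Mapping[str, str] | pd.Series,
                           force_fisher: bool = False
                           ) -> Optional[GroupContrast]:
    """Altered-fraction contrast for one gene between two groups.

    MISSING entries are excluded pairwise. Returns None when a margin
    of the resulting table is empty (contrast undefined).
    """
    labels = pd.Series(dict(groups)).reindex(matrix.data.index)
    col = matrix.data[gene]
    cells = {}
    for g in (group_a, group_b):
        vals = col[labels == g].dropna()
        if len(vals) == 0:
            return None
        cells[g] = (int(vals.sum()), int(len(vals) - vals.sum()))
    (aa, ua), (ab, ub) = cells[group_a], cells[group_b]
    try:
        p, test = contrast_2x2(aa, ua, ab, ub, force_fisher=force_fisher)
    except ValueError:
        return None
    frac_a, frac_b = aa / (aa + ua), ab / (ab + ub)
    if frac_a > frac_b:
        direction = group_a
    elif frac_b > frac_a:
        direction = group_b
    else:
        direction = None
    return GroupContrast(gene=gene, group_a=group_a, group_b=group_b,
                         p_value=p, direction=direction, test_used=test,
                         table=((aa, ua), (ab, ub)))


def comparison_report(matrices: Iterable[BinarizedMatrix],
                      groups: Mapping[str, str] | pd.Series,
                      alpha: float = 0.05,
                      droplist: Iterable[str] = ("CRNDE",),
                      force_fisher: bool = False,
                      bh_correct: bool = False) -> pd.DataFrame:
    """Long-form report of significant pairwise per-gene contrasts.

    One row per (panel, stratum, class_subset, gene, pair) with p below
    ``alpha`` (uncorrected by default, mirroring the source analysis;
    ``bh_correct`` switches on Benjamini-Hochberg within each matrix).
    """
    labels = pd.Series(dict(groups))
    drop = set(droplist)
    rows = []
    for matrix in matrices:
        present = sorted(labels.reindex(matrix.data.index).dropna().unique())
        candidates = []
        for gene in sorted(matrix.genes):
            if gene in drop:
                continue
            for i, ga in enumerate(present):
                for gb in present[i + 1:]:
                    c = pairwise_gene_contrast(matrix, gene, ga, gb, labels,
                                               force_fisher=force_fisher)
                    if c is not None:
                        candidates.append(c)
        pvals = np.array([c.p_value for c in candidates])
        if bh_correct and len(pvals):
            from statsmodels.stats.multitest import multipletests
            pvals = multipletests(pvals, method="fdr_bh")[1]
        for c, p in zip(candidates, pvals):
            if p < alpha:
                rows.append({
                    "panel": matrix.panel, "stratum": matrix.stratum,
                    "class_subset": matrix.class_subset, "gene": c.gene,
                    "group_a": c.group_a, "group_b": c.group_b,
                    "p_value": float(p), "direction": c.direction,
                    "test_used": c.test_used,
                })
    columns = ["panel", "stratum", "class_subset", "gene", "group_a",
               "group_b", "p_value", "direction", "test_used"]
    return pd.DataFrame.from_records(rows, columns=columns)
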