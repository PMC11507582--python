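"""Annotation-table retention logic.

Consolidates per-transcript annotation rows into one record per variant,
stratifies by predicted impact, and applies the retention rules: known
adverse clinical significance, predicted protein damage, novelty, fully
empty prediction fields, or rarity below a population-frequency cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "IMPACT_ORDER",
    "STRATA",
    "AnnotatedVariant",
    "RetentionConfig",
    "consolidate_transcript_rows",
    "consolidate_table",
    "impact_in_stratum",
    "retain_annotated",
    "retain_table",
]

# Severity ranking, most severe first.
IMPACT_ORDER = ("HIGH", "MODERATE", "LOW", "MODIFIER")
_IMPACT_RANK = {imp: i for i, imp in enumerate(IMPACT_ORDER)}

STRATA = ("HIGH_OR_MODERATE", "HIGH", "MODERATE")

# Category rankings used for worst-case consolidation across transcripts
# (lower rank = more deleterious). Unlisted labels rank least severe.
_SIFT_RANK = {
    "deleterious": 0,
    "deleterious_low_confidence": 1,
    "tolerated_low_confidence": 2,
    "tolerated": 3,
}
_POLYPHEN_RANK = {
    "probably_damaging": 0,
    "possibly_damaging": 1,
    "benign": 2,
    "unknown": 3,
}


@dataclass(frozen=True)
class AnnotatedVariant:
    """Consolidated functional annotation for one called variant."""

    key: tuple  # (sample_id, chrom, pos, ref, alt)
    gene: str
    impact: str
    existing_ids: tuple[str, ...] = ()
    clin_sig: frozenset[str] = frozenset()
    sift: Optional[str] = None
    polyphen: Optional[str] = None
    max_af: Optional[float] = None
    consequence: tuple[str, ...] = ()
    protein_change: Optional[str] = None

    def __post_init__(self) -> None:
        if self.impact not in _IMPACT_RANK:
            raise ValueError(f"impact must be one of {IMPACT_ORDER}, got {self.impact!r}")
        if self.max_af is not None and not (0.0 <= self.max_af <= 1.0):
            raise ValueError(f"max_af out of [0,1]: {self.max_af}")


@dataclass(frozen=True)
class RetentionConfig:
    """Rule sets for the retention decision; all config-exposed."""

    adverse_clinsig: frozenset[str] = frozenset({"pathogenic", "likely_pathogenic"})
    deleterious_sift: frozenset[str] = frozenset({"deleterious", "deleterious_low_confidence"})
    damaging_polyphen: frozenset[str] = frozenset({"probably_damaging", "possibly_damaging"})
    rare_af: float = 0.01
    # Genes never shown in final reports (still processed internally).
    report_droplist: frozenset[str] = frozenset({"CRNDE"})
    # Incidentally enriched genes flagged (not removed) in outputs.
    incidental_genes: frozenset[str] = frozenset({"KCNMB3", "FBXW7-AS1"})


def _split_multi(value) -> tuple[str, ...]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return ()
    text = str(value).strip()
    if not text or text in {"-", "."}:
        return ()
    return tuple(p for p in text.replace("&", ",").split(",") if p and p not in {"-", "."})


def _strip_score(label) -> Optional[str]:
    """'deleterious(0.01)' -> 'deleterious'; empty markers -> None."""
    parts = _split_multi(label)
    if not parts:
        return None
    return parts[0].split("(")[0]


def consolidate_transcript_rows(rows: pd.DataFrame) -> AnnotatedVariant:
    """Collapse the per-transcript rows of one variant, worst case wins.

    Impact is the most severe across rows and the gene is taken from a
    row carrying that impact; identifier and clinical-significance
    fields are unioned; SIFT/PolyPhen take the most deleterious
    category; MAX_AF takes the smallest value present.
    """
    if rows.empty:
        raise ValueError("no annotation rows supplied")
    keys = set(zip(rows["sample_id"], rows["chrom"], rows["pos"],
                   rows["ref"], rows["alt"]))
    if len(keys) != 1:
        raise ValueError(f"rows span {len(keys)} distinct variant keys")
    (key,) = keys

    ranks = rows["impact"].map(_IMPACT_RANK)
    if ranks.isna().any():
        bad = rows.loc[ranks.isna(), "impact"].unique()
        raise ValueError(f"unknown impact label(s): {list(bad)}")
    top = rows.loc[ranks.idxmin()]

    existing: list[str] = []
    clin: set[str] = set()
    consequences: list[str] = []
    for _, row in rows.iterrows():
        for ident in _split_multi(row.get("existing_ids")):
            if ident not in existing:
                existing.append(ident)
        clin.update(_split_multi(row.get("clin_sig")))
        for c in _split_multi(row.get("consequence")):
            if c not in consequences:
                consequences.append(c)

    sifts = [s for s in (_strip_score(v) for v in rows.get("sift", ())) if s]
    polys = [s for s in (_strip_score(v) for v in rows.get("polyphen", ())) if s]
    afs = pd.to_numeric(rows.get("max_af", pd.Series(dtype=float)), errors="coerce").dropna()
    prot = next((p for p in (_strip_score(v) for v in rows.get("protein_change", ())) if p), None)

    return AnnotatedVariant(
        key=key,
        gene=str(top["gene"]),
        impact=str(top["impact"]),
        existing_ids=tuple(existing),
        clin_sig=frozenset(clin),
        sift=min(sifts, key=lambda s: _SIFT_RANK.get(s, 99)) if sifts else None,
        polyphen=min(polys, key=lambda s: _POLYPHEN_RANK.get(s, 99)) if polys else None,
        max_af=float(afs.min()) if len(afs) else None,
        consequence=tuple(consequences),
        protein_change=prot,
    )


def consolidate_table(table: pd.DataFrame) -> list[AnnotatedVariant]:
    """Consolidate a whole annotation table, one record per variant key."""
    out = []
    for _, rows in table.groupby(["sample_id", "chrom", "pos", "ref", "alt"],
                                 sort=False):
        out.append(consolidate_transcript_rows(rows))
    return out


def impact_in_stratum(av: AnnotatedVariant, stratum: str) -> bool:
    """Whether the variant's impact belongs to the given stratum.

    LOW and MODIFIER impacts never pass any stratum.
    """
    if stratum not in STRATA:
        raise ValueError(f"unknown stratum {stratum!r}")
    if stratum == "HIGH_OR_MODERATE":
        return av.impact in ("HIGH", "MODERATE")
    return av.impact == stratum


def retain_annotated(av: AnnotatedVariant,
                     config: RetentionConfig = RetentionConfig()
                     ) -> tuple[bool, Optional[str]]:
    """Retention decision with the first-firing rule as reason code.

    R1 adverse clinical significance; R2 predicted protein damage
    (SIFT or PolyPhen); R3 novel variant (no known identifier);
    R4 CLIN_SIG, SIFT and PolyPhen all empty; R5 maximum population
    allele frequency below the rarity cutoff. Logical OR — rule order
    only determines attribution.
    """
    if av.clin_sig & config.adverse_clinsig:
        return True, "R1"
    if (av.sift in config.deleterious_sift
            or av.polyphen in config.damaging_polyphen):
        return True, "R2"
    if not av.existing_ids:
        return True, "R3"
    if not av.clin_sig and av.sift is None and av.polyphen is None:
        return True, "R4"
    if av.max_af is not None and av.max_af < config.rare_af:
        return True, "R5"
    return False, None


def retain_table(variants: Iterable[AnnotatedVariant], stratum: str,
                 config: RetentionConfig = RetentionConfig()) -> pd.DataFrame:
    """Apply stratum then retention rules; tabulate the survivors.

    Output columns include the consolidated fields, the firing reason
    code and an ``incidental`` flag for off-panel enriched genes.
    """
    records = []
    for av in variants:
        if not impact_in_stratum(av, stratum):
            continue
        keep, reason = retain_annotated(av, config)
        if not keep:
            continue
        sample_id, chrom, pos, ref, alt = av.key
        records.append({
            "sample_id": sample_id, "chrom": chrom, "pos": pos,
            "ref": ref, "alt": alt, "gene": av.gene, "impact": av.impact,
            "stratum": stratum, "reason": reason,
            "incidental": av.gene in config.incidental_genes,
        })
    columns = ["sample_id", "chrom", "pos", "ref", "alt", "gene", "impact",
               "stratum", "reason", "incidental"]
    df = pd.DataFrame.from_records(records, columns=columns)
    return df.astype({"incidental": bool})
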