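"""Enrichment panel definitions.

Two panels ship with the package: a 44-gene hereditary ovarian cancer
panel and a 37-gene hot-spot panel of frequently mutated oncogenes and
suppressors. Gene lists are fixed; genomic regions attached to each gene
are synthetic placeholders (the pipeline only requires that every gene
own at least one enriched region with stable coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "Region",
    "PanelDefinition",
    "HEREDITARY_PANEL_GENES",
    "HOTSPOT_PANEL_GENES",
    "hereditary_panel",
    "hotspot_panel",
    "default_panels",
    "panel_union_size",
]

HEREDITARY_PANEL_GENES: tuple[str, ...] = (
    "ATM", "ATR", "ATRX", "BAP1", "BARD1", "BCL2L1", "BLM", "BRCA1",
    "BRCA2", "BRIP1", "CCNE1", "CEBPA", "CHEK1", "CHEK2", "CRNDE",
    "EMSY", "FANCA", "FANCB", "FANCC", "FANCD2", "FANCE", "FANCF",
    "FANCG", "FANCI", "FANCL", "FANCM", "IRX5", "MDM2", "MRE11",
    "MUTYH", "NBN", "PALB2", "PARP1", "PIK3CA", "PRKDC", "PTEN",
    "RAD50", "RAD51B", "RAD51C", "RAD51D", "RAD54L", "RPA1", "SEM1",
    "TP53",
)

HOTSPOT_PANEL_GENES: tuple[str, ...] = (
    "AKT1", "ALK", "APC", "ATM", "BRAF", "BRCA1", "CDKN2A", "CTNNB1",
    "EGFR", "ERBB2", "ESR1", "FBXW7", "FGFR1", "FGFR2", "FGFR3",
    "GNA11", "GNAQ", "GNAS", "HRAS", "IDH1", "IDH2", "JAK2", "KIT",
    "KRAS", "NF1", "NRAS", "NTRK3", "PDGFRA", "PIK3CA", "POLE",
    "PTCH1", "PTEN", "RET", "STK11", "TP53", "TSC1", "TSC2",
)


@dataclass(frozen=True)
class Region:
    """One enriched interval, 1-based inclusive coordinates."""

    chrom: str
    start: int
    end: int
    gene: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid region coordinates {self.start}-{self.end}")


@dataclass(frozen=True)
class PanelDefinition:
    """A named gene panel with its enriched regions."""

    name: str
    genes: tuple[str, ...]
    regions: tuple[Region, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"duplicate gene symbols in panel {self.name!r}")
        panel_genes = set(self.genes)
        for r in self.regions:
            if r.gene not in panel_genes:
                raise ValueError(
                    f"region {r.chrom}:{r.start}-{r.end} maps to {r.gene!r}, "
                    f"not a gene of panel {self.name!r}"
                )

    @property
    def size(self) -> int:
        return len(self.genes)

    def regions_for(self, gene: str) -> tuple[Region, ...]:
        return tuple(r for r in self.regions if r.gene == gene)


def _synthetic_regions(genes: Sequence[str], regions_per_gene: int,
                       region_length: int) -> tuple[Region, ...]:
    # Deterministic placeholder coordinates: each gene parked on its own
    # megabase of a recycled chromosome set.
    regions = []
    for i, gene in enumerate(genes):
        chrom = f"chr{(i % 22) + 1}"
        base = 1_000_000 * (i + 1)
        for j in range(regions_per_gene):
            start = base + j * (region_length + 500) + 1
            regions.append(Region(chrom, start, start + region_length - 1, gene))
    return tuple(regions)


def hereditary_panel() -> PanelDefinition:
    """The 44-gene hereditary ovarian cancer enrichment panel."""
    return PanelDefinition(
        name="hereditary-44",
        genes=HEREDITARY_PANEL_GENES,
        regions=_synthetic_regions(HEREDITARY_PANEL_GENES, 3, 1500),
    )


def hotspot_panel() -> PanelDefinition:
    """The 37-gene hot-spot enrichment panel."""
    return PanelDefinition(
        name="hotspot-37",
        genes=HOTSPOT_PANEL_GENES,
        regions=_synthetic_regions(HOTSPOT_PANEL_GENES, 1, 900),
    )


def default_panels() -> dict[str, PanelDefinition]:
    p1, p2 = hereditary_panel(), hotspot_panel()
    return {p1.name: p1, p2.name: p2}


def panel_union_size(panels: Iterable[PanelDefinition]) -> int:
    """Number of distinct gene symbols across the given panels."""
    union: set[str] = set()
    for panel in panels:
        union.update(panel.genes)
    return len(union)
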