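"""Seeded synthetic cohort generator.

Produces a complete testing bundle — clinical table, per-sample variant
calls, a transcript-level annotation table, and per-region depth
summaries — with planted per-gene per-group alteration frequencies,
proportional-hazards survival effects, logistic response effects,
sub-threshold decoy calls (each violating exactly one filter gate) and
low-coverage regions. Identical config + seed gives byte-identical
serialized output.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .panels import PanelDefinition, hereditary_panel
from .qc import CALL_COLUMNS
from .vcfio import read_sample_vcf, write_sample_vcf

__all__ = [
    "GROUPS", "ENDPOINTS", "OUTCOMES", "DECOY_GATES",
    "CohortConfig", "CohortBundle",
    "generate_cohort", "write_bundle", "read_bundle",
]

GROUPS = ("BOT", "BOT.V600E", "lgOvCa", "hgOvCa")
BOTS_GROUPS = ("BOT", "BOT.V600E")
CARCINOMA_GROUPS = ("lgOvCa", "hgOvCa")
ENDPOINTS = ("OS", "DFS", "RFS")
OUTCOMES = ("CR", "PS", "microinvasion_or_implants")
DECOY_GATES = ("VAF", "ALT_BASES", "QUAL", "MAPQ", "DEPTH", "IMPACT")

DEFAULT_GROUP_SIZES = {"BOT": 53, "BOT.V600E": 23, "lgOvCa": 10, "hgOvCa": 139}

# Mean exponential survival scale in months per group (baseline hazard
# = 1/scale); more aggressive groups fail faster.
_BASE_SCALE = {"BOT": 150.0, "BOT.V600E": 150.0, "lgOvCa": 90.0, "hgOvCa": 45.0}

CLINICAL_COLUMNS = (
    "sample_id", "group", "histotype", "age", "primary_tumor", "chemo",
    "tp53_accumulation", "figo_stage", "residual_tumor",
    "os_time", "os_event", "dfs_time", "dfs_event", "rfs_time", "rfs_event",
    "cr", "ps", "microinvasion", "implants",
)

ANNOTATION_COLUMNS = (
    "sample_id", "chrom", "pos", "ref", "alt", "gene", "consequence",
    "impact", "existing_ids", "clin_sig", "sift", "polyphen", "max_af",
    "protein_change",
)

DEPTH_COLUMNS = ("sample_id", "chrom", "start", "end", "gene", "mean_depth")

TRUTH_COLUMNS = ("sample_id", "chrom", "pos", "ref", "alt", "gene", "kind",
                 "stratum", "decoy_gate")


class ConfigurationError(ValueError):
    """Raised when a cohort configuration violates its invariants."""


@dataclass
class CohortConfig:
    """All knobs of the synthetic cohort."""

    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    panel: PanelDefinition = field(default_factory=hereditary_panel)
    # (gene, group, stratum) -> alteration probability. Stratum is the
    # impact stratum the planted variants fall into.
    gene_freqs: Mapping[tuple[str, str, str], float] = field(default_factory=dict)
    noise_vaf_rate: float = 1.0  # expected sub-threshold decoys / sample
    other_decoy_rate: float = 0.3  # expected decoys / sample / other gate
    lowcov_region_rate: float = 0.02
    survival_effects: Sequence[tuple[str, str, float]] = ()
    response_effects: Sequence[tuple[str, str, float]] = ()
    censoring_rate: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise ConfigurationError(f"unknown group {g!r}")
            if n < 0:
                raise ConfigurationError(f"negative size for group {g!r}")
        panel_genes = set(self.panel.genes)
        for (gene, group, stratum), p in self.gene_freqs.items():
            if gene not in panel_genes:
                raise ConfigurationError(f"gene_freqs gene {gene!r} not in panel")
            if group not in GROUPS:
                raise ConfigurationError(f"gene_freqs group {group!r} unknown")
            if stratum not in ("HIGH", "MODERATE", "HIGH_OR_MODERATE"):
                raise ConfigurationError(f"gene_freqs stratum {stratum!r} unknown")
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"probability out of [0,1] for {gene!r}")
        for gene, endpoint, _ in self.survival_effects:
            if gene not in panel_genes:
                raise ConfigurationError(f"survival effect gene {gene!r} not in panel")
            if endpoint not in ENDPOINTS:
                raise ConfigurationError(f"unknown endpoint {endpoint!r}")
        for gene, outcome, _ in self.response_effects:
            if gene not in panel_genes:
                raise ConfigurationError(f"response effect gene {gene!r} not in panel")
            if outcome not in OUTCOMES:
                raise ConfigurationError(f"unknown outcome {outcome!r}")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ConfigurationError("censoring_rate must be in [0,1)")
        for name in ("noise_vaf_rate", "other_decoy_rate", "lowcov_region_rate"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if not 0.0 <= self.lowcov_region_rate <= 1.0:
            raise ConfigurationError("lowcov_region_rate must be in [0,1]")


@dataclass
class CohortBundle:
    """In-memory cohort: clinical + calls + annotations + depth + truth."""

    samples: pd.DataFrame
    calls: pd.DataFrame
    annotations: pd.DataFrame
    depth: pd.DataFrame
    truth: pd.DataFrame
    panel: Optional[PanelDefinition] = None

    def equals(self, other: "CohortBundle") -> bool:
        for name in ("samples", "calls", "annotations", "depth", "truth"):
            a = getattr(self, name).reset_index(drop=True)
            b = getattr(other, name).reset_index(drop=True)
            if not a.equals(b):
                return False
        return True


_BASE_CHOICES = "ACGT"


def _random_snp_alleles(rng: np.random.Generator) -> tuple[str, str]:
    ref = _BASE_CHOICES[rng.integers(4)]
    alt = _BASE_CHOICES[rng.integers(4)]
    while alt == ref:
        alt = _BASE_CHOICES[rng.integers(4)]
    return ref, alt


def _random_alleles(rng: np.random.Generator, variant_class: str
                    ) -> tuple[str, str]:
    if variant_class == "snp":
        return _random_snp_alleles(rng)
    if variant_class == "indel":
        anchor = _BASE_CHOICES[rng.integers(4)]
        tail = "".join(_BASE_CHOICES[rng.integers(4)]
                       for _ in range(int(rng.integers(1, 5))))
        if rng.random() < 0.5:
            return anchor + tail, anchor  # deletion
        return anchor, anchor + tail  # insertion
    if variant_class == "mnp":
        n = int(rng.integers(2, 4))
        ref = "".join(_BASE_CHOICES[rng.integers(4)] for _ in range(n))
        alt = "".join(_BASE_CHOICES[rng.integers(4)] for _ in range(n))
        while alt == ref:
            alt = "".join(_BASE_CHOICES[rng.integers(4)] for _ in range(n))
        return ref, alt
    # symbolic non-SNP allele
    return _BASE_CHOICES[rng.integers(4)], "<DEL>"


def _pick_class(rng: np.random.Generator) -> str:
    u = rng.random()
    if u < 0.70:
        return "snp"
    if u < 0.88:
        return "indel"
    if u < 0.96:
        return "mnp"
    return "bnd"


def _make_clinical_row(rng: np.random.Generator, sample_id: str, group: str
                       ) -> dict:
    is_bots = group in BOTS_GROUPS
    age_mean = 45.0 if group == "BOT.V600E" else 57.0
    age = float(np.clip(rng.normal(age_mean, 12.0), 18.0, 95.0))
    row = {
        "sample_id": sample_id,
        "group": group,
        "histotype": "serous" if rng.random() < 0.8 else "other",
        "age": round(age, 1),
        "primary_tumor": int(rng.random() < 0.85),
        "figo_stage": int(rng.integers(1, 3)) if is_bots else int(rng.integers(2, 5)),
        "residual_tumor": ("none" if is_bots else
                           ["none", "lt2cm", "ge2cm"][
                               int(rng.choice(3, p=[0.5, 0.3, 0.2]))]),
    }
    if is_bots:
        row["chemo"] = ("none" if rng.random() < 60 / 76
                        else ("PC" if rng.random() < 0.5 else "TP"))
        row["tp53_accumulation"] = pd.NA
        row["cr"] = pd.NA
        row["ps"] = pd.NA
    else:
        row["chemo"] = "PC" if rng.random() < 35 / 147 else "TP"
        row["tp53_accumulation"] = int(rng.random() < 0.5)
        row["microinvasion"] = pd.NA
        row["implants"] = pd.NA
    return row


def _survival_draw(rng: np.random.Generator, scale: float, lp: float,
                   censoring_rate: float) -> tuple[float, int]:
    t = rng.exponential(scale / math.exp(lp))
    if censoring_rate > 0:
        c = rng.exponential(scale * (1 - censoring_rate) / censoring_rate)
    else:
        c = math.inf
    time = min(t, c)
    return round(float(min(time, 600.0)), 2), int(t <= c)


def _logit(p: float) -> float:
    return math.log(p / (1 - p))


def generate_cohort(config: CohortConfig) -> CohortBundle:
    """Generate a full synthetic cohort bundle from a validated config.

    Every planted alteration yields at least one call passing the VAF
    and quality gates with an impact inside its stratum; every decoy
    violates exactly the gate recorded for it in the truth table.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    panel = config.panel

    # ---- sample roster ------------------------------------------------
    sample_ids: list[str] = []
    sample_groups: list[str] = []
    idx = 1
    for group in GROUPS:
        for _ in range(int(config.group_sizes.get(group, 0))):
            sample_ids.append(f"S{idx:04d}")
            sample_groups.append(group)
            idx += 1
    group_of = dict(zip(sample_ids, sample_groups))

    # ---- planted alterations -----------------------------------------
    call_rows: list[dict] = []
    anno_rows: list[dict] = []
    truth_rows: list[dict] = []
    # (sample, gene) -> True if carries a planted HIGH/MODERATE variant
    indicator: dict[tuple[str, str], bool] = {}
    # genes that must keep covered regions per sample
    force_covered: set[tuple[str, str]] = set()

    pos_counter = 0
    for (gene, group, stratum) in sorted(config.gene_freqs):
        p = config.gene_freqs[(gene, group, stratum)]
        regions = panel.regions_for(gene)
        if not regions:
            raise ConfigurationError(f"panel has no regions for gene {gene!r}")
        for sid in sample_ids:
            if group_of[sid] != group:
                continue
            if rng.random() >= p:
                continue
            indicator[(sid, gene)] = True
            region = regions[int(rng.integers(len(regions)))]
            force_covered.add((sid, gene))
            pos_counter += 1
            pos = int(region.start + (pos_counter % max(region.end - region.start, 1)))
            if stratum == "HIGH_OR_MODERATE":
                impact = "HIGH" if rng.random() < 0.5 else "MODERATE"
            else:
                impact = stratum
            vclass = _pick_class(rng)
            ref, alt = _random_alleles(rng, vclass)
            depth = int(rng.integers(30, 200))
            vaf = float(rng.uniform(0.15, 0.9))
            alt_depth = max(2, int(round(vaf * depth)))
            ref_depth = depth - alt_depth
            call_rows.append({
                "sample_id": sid, "chrom": region.chrom, "pos": pos,
                "ref": ref, "alt": alt, "variant_class": vclass,
                "qual": round(float(rng.uniform(30, 100)), 1),
                "mapq": round(float(rng.uniform(40, 60)), 1),
                "depth": depth, "ref_depth": ref_depth, "alt_depth": alt_depth,
            })
            novel = rng.random() < 0.7
            anno_rows.append({
                "sample_id": sid, "chrom": region.chrom, "pos": pos,
                "ref": ref, "alt": alt, "gene": gene,
                "consequence": ("stop_gained" if impact == "HIGH"
                                else "missense_variant"),
                "impact": impact,
                "existing_ids": "" if novel else f"rs{int(rng.integers(10**6, 10**8))}",
                "clin_sig": "" if novel else "pathogenic",
                "sift": "", "polyphen": "",
                "max_af": "" if novel else f"{rng.uniform(0.0001, 0.005):.6f}",
                "protein_change": "",
            })
            truth_rows.append({
                "sample_id": sid, "chrom": region.chrom, "pos": pos,
                "ref": ref, "alt": alt, "gene": gene, "kind": "planted",
                "stratum": stratum, "decoy_gate": "",
            })

    # ---- decoys -------------------------------------------------------
    all_regions = panel.regions
    for sid in sample_ids:
        counts = {"VAF": rng.poisson(config.noise_vaf_rate)}
        for gate in DECOY_GATES[1:]:
            counts[gate] = rng.poisson(config.other_decoy_rate)
        for gate in DECOY_GATES:
            for _ in range(int(counts[gate])):
                region = all_regions[int(rng.integers(len(all_regions)))]
                # keep the decoy's region covered so only its own gate
                # can remove it
                force_covered.add((sid, region.gene))
                pos_counter += 1
                pos = int(region.start
                          + (pos_counter % max(region.end - region.start, 1)))
                vclass = _pick_class(rng)
                ref, alt = _random_alleles(rng, vclass)
                qual = round(float(rng.uniform(30, 100)), 1)
                mapq = round(float(rng.uniform(40, 60)), 1)
                impact = "HIGH"
                if gate == "VAF":
                    alt_depth = int(rng.integers(2, 4))
                    ref_depth = int(alt_depth * rng.uniform(11.0, 40.0))
                    depth = ref_depth + alt_depth
                elif gate == "ALT_BASES":
                    # ref depth >= 4 keeps total depth clear of the DEPTH gate
                    alt_depth, ref_depth = 1, int(rng.integers(4, 9))
                    depth = ref_depth + alt_depth
                elif gate == "QUAL":
                    alt_depth = int(rng.integers(5, 30))
                    ref_depth = int(rng.integers(5, 30))
                    depth = ref_depth + alt_depth
                    qual = round(float(rng.uniform(0, 19.5)), 1)
                elif gate == "MAPQ":
                    alt_depth = int(rng.integers(5, 30))
                    ref_depth = int(rng.integers(5, 30))
                    depth = ref_depth + alt_depth
                    mapq = round(float(rng.uniform(0, 19.5)), 1)
                elif gate == "DEPTH":
                    alt_depth, ref_depth = 2, int(rng.integers(0, 3))
                    depth = ref_depth + alt_depth  # 2..4 < 5
                else:  # IMPACT
                    alt_depth = int(rng.integers(5, 30))
                    ref_depth = int(rng.integers(5, 30))
                    depth = ref_depth + alt_depth
                    impact = "LOW" if rng.random() < 0.5 else "MODIFIER"
                call_rows.append({
                    "sample_id": sid, "chrom": region.chrom, "pos": pos,
                    "ref": ref, "alt": alt, "variant_class": vclass,
                    "qual": qual, "mapq": mapq, "depth": depth,
                    "ref_depth": ref_depth, "alt_depth": alt_depth,
                })
                anno_rows.append({
                    "sample_id": sid, "chrom": region.chrom, "pos": pos,
                    "ref": ref, "alt": alt, "gene": region.gene,
                    "consequence": ("synonymous_variant" if gate == "IMPACT"
                                    else "missense_variant"),
                    "impact": impact, "existing_ids": "", "clin_sig": "",
                    "sift": "", "polyphen": "", "max_af": "",
                    "protein_change": "",
                })
                truth_rows.append({
                    "sample_id": sid, "chrom": region.chrom, "pos": pos,
                    "ref": ref, "alt": alt, "gene": region.gene,
                    "kind": "decoy", "stratum": "", "decoy_gate": gate,
                })

    # ---- depth summaries ---------------------------------------------
    depth_rows: list[dict] = []
    for sid in sample_ids:
        for region in all_regions:
            lowcov = (rng.random() < config.lowcov_region_rate
                      and (sid, region.gene) not in force_covered)
            mean_depth = (float(rng.uniform(0.0, 4.99)) if lowcov
                          else float(rng.uniform(30.0, 100.0)))
            depth_rows.append({
                "sample_id": sid, "chrom": region.chrom, "start": region.start,
                "end": region.end, "gene": region.gene,
                "mean_depth": round(mean_depth, 2),
            })

    # ---- clinical table ----------------------------------------------
    surv_by_ep: dict[str, list] = {ep: [] for ep in ENDPOINTS}
    for gene, ep, loghr in config.survival_effects:
        surv_by_ep[ep].append((gene, loghr))
    resp_by_out: dict[str, list] = {out: [] for out in OUTCOMES}
    for gene, out, logor in config.response_effects:
        resp_by_out[out].append((gene, logor))

    def lp_for(sid: str, effects: list) -> float:
        return sum(eff for gene, eff in effects if indicator.get((sid, gene)))

    clin_rows = []
    for sid in sample_ids:
        group = group_of[sid]
        row = _make_clinical_row(rng, sid, group)
        scale = _BASE_SCALE[group]
        row["os_time"], row["os_event"] = _survival_draw(
            rng, scale, lp_for(sid, surv_by_ep["OS"]), config.censoring_rate)
        if group in BOTS_GROUPS:
            row["rfs_time"], row["rfs_event"] = _survival_draw(
                rng, scale * 0.8, lp_for(sid, surv_by_ep["RFS"]),
                config.censoring_rate)
            row["dfs_time"], row["dfs_event"] = pd.NA, pd.NA
            mi_p = 1 / (1 + math.exp(-(_logit(0.25)
                        + lp_for(sid, resp_by_out["microinvasion_or_implants"]))))
            row["microinvasion"] = int(rng.random() < mi_p)
            row["implants"] = int(rng.random() < mi_p)
        else:
            row["rfs_time"], row["rfs_event"] = pd.NA, pd.NA
            cr_p = 1 / (1 + math.exp(-(_logit(0.55)
                        + lp_for(sid, resp_by_out["CR"]))))
            ps_p = 1 / (1 + math.exp(-(_logit(0.6)
                        + lp_for(sid, resp_by_out["PS"]))))
            row["cr"] = int(rng.random() < cr_p)
            row["ps"] = int(rng.random() < ps_p)
            if row["cr"]:
                row["dfs_time"], row["dfs_event"] = _survival_draw(
                    rng, scale * 0.7, lp_for(sid, surv_by_ep["DFS"]),
                    config.censoring_rate)
            else:
                row["dfs_time"], row["dfs_event"] = pd.NA, pd.NA
        clin_rows.append(row)

    samples = pd.DataFrame.from_records(clin_rows, columns=CLINICAL_COLUMNS)
    samples = _coerce_clinical(samples)
    calls = (pd.DataFrame.from_records(call_rows, columns=list(CALL_COLUMNS))
             .sort_values(["sample_id", "chrom", "pos", "ref", "alt"],
                          kind="mergesort").reset_index(drop=True))
    annotations = (pd.DataFrame.from_records(anno_rows,
                                             columns=ANNOTATION_COLUMNS)
                   .sort_values(["sample_id", "chrom", "pos", "ref", "alt"],
                                kind="mergesort").reset_index(drop=True))
    depth = pd.DataFrame.from_records(depth_rows, columns=DEPTH_COLUMNS)
    truth = (pd.DataFrame.from_records(truth_rows, columns=TRUTH_COLUMNS)
             .sort_values(["sample_id", "chrom", "pos", "ref", "alt"],
                          kind="mergesort").reset_index(drop=True))
    return CohortBundle(samples=samples, calls=calls, annotations=annotations,
                        depth=depth, truth=truth, panel=panel)


_FLAG_COLS = ("primary_tumor", "tp53_accumulation", "os_event", "dfs_event",
              "rfs_event", "cr", "ps", "microinvasion", "implants")
_FLOAT_COLS = ("age", "os_time", "dfs_time", "rfs_time")


def _coerce_clinical(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in _FLAG_COLS:
        df[col] = df[col].astype("Int64")
    for col in _FLOAT_COLS:
        df[col] = df[col].astype("Float64")
    df["figo_stage"] = df["figo_stage"].astype("Int64")
    return df


# ---- serialization ----------------------------------------------------

_ANNOTATION_FILE_HEADER = {
    "sample_id": "SAMPLE", "chrom": "CHROM", "pos": "POS", "ref": "REF",
    "alt": "ALT", "gene": "SYMBOL", "consequence": "Consequence",
    "impact": "IMPACT", "existing_ids": "Existing_variation",
    "clin_sig": "CLIN_SIG", "sift": "SIFT", "polyphen": "PolyPhen",
    "max_af": "MAX_AF", "protein_change": "HGVSp",
}
_DEPTH_FILE_HEADER = {
    "sample_id": "SAMPLE", "chrom": "CHROM", "start": "START", "end": "END",
    "gene": "GENE", "mean_depth": "MEAN_DEPTH",
}


def write_bundle(bundle: CohortBundle, directory: str) -> dict[str, str]:
    """Serialize a bundle: clinical CSV, annotation/depth/truth TSVs, one
    VCF per sample, and the panel region table. Returns written paths."""
    os.makedirs(directory, exist_ok=True)
    vcf_dir = os.path.join(directory, "vcf")
    os.makedirs(vcf_dir, exist_ok=True)
    paths = {}

    clin_path = os.path.join(directory, "clinical.csv")
    bundle.samples.to_csv(clin_path, index=False)
    paths["clinical"] = clin_path

    anno_path = os.path.join(directory, "annotations.tsv")
    bundle.annotations.rename(columns=_ANNOTATION_FILE_HEADER).to_csv(
        anno_path, sep="\t", index=False)
    paths["annotations"] = anno_path

    depth_path = os.path.join(directory, "depth.tsv")
    bundle.depth.rename(columns=_DEPTH_FILE_HEADER).to_csv(
        depth_path, sep="\t", index=False, float_format="%.2f")
    paths["depth"] = depth_path

    truth_path = os.path.join(directory, "truth.tsv")
    bundle.truth.to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path

    if bundle.panel is not None:
        panel_path = os.path.join(directory, "panel.tsv")
        pd.DataFrame([{"GENE": r.gene, "CHROM": r.chrom, "START": r.start,
                       "END": r.end} for r in bundle.panel.regions]).to_csv(
            panel_path, sep="\t", index=False)
        with open(os.path.join(directory, "panel_genes.txt"), "w") as fh:
            fh.write("\n".join(bundle.panel.genes) + "\n")
        paths["panel"] = panel_path

    for sid in bundle.samples["sample_id"]:
        vcf_path = os.path.join(vcf_dir, f"{sid}.vcf")
        write_sample_vcf(bundle.calls, sid, vcf_path)
    paths["vcf_dir"] = vcf_dir
    return paths


def read_bundle(directory: str, panel: Optional[PanelDefinition] = None
                ) -> CohortBundle:
    """Read a serialized bundle back into memory (inverse of write)."""
    samples = pd.read_csv(os.path.join(directory, "clinical.csv"),
                          dtype={"sample_id": str})
    samples = _coerce_clinical(samples)
    rev_anno = {v: k for k, v in _ANNOTATION_FILE_HEADER.items()}
    annotations = pd.read_csv(
        os.path.join(directory, "annotations.tsv"), sep="\t",
        keep_default_na=False, dtype=str).rename(columns=rev_anno)
    annotations["pos"] = annotations["pos"].astype(int)
    rev_depth = {v: k for k, v in _DEPTH_FILE_HEADER.items()}
    depth = pd.read_csv(os.path.join(directory, "depth.tsv"),
                        sep="\t").rename(columns=rev_depth)
    truth_path = os.path.join(directory, "truth.tsv")
    if os.path.exists(truth_path):
        truth = pd.read_csv(truth_path, sep="\t", keep_default_na=False,
                            dtype=str)
        if len(truth):
            truth["pos"] = truth["pos"].astype(int)
    else:
        truth = pd.DataFrame(columns=TRUTH_COLUMNS)

    vcf_dir = os.path.join(directory, "vcf")
    frames = []
    for name in sorted(os.listdir(vcf_dir)):
        if name.endswith(".vcf"):
            frame = read_sample_vcf(os.path.join(vcf_dir, name),
                                    sample_id=name[:-4])
            if len(frame):
                frames.append(frame)
    calls = (pd.concat(frames, ignore_index=True) if frames
             else pd.DataFrame(columns=list(CALL_COLUMNS)))
    if len(calls):
        for col in ("pos", "depth", "ref_depth", "alt_depth"):
            calls[col] = calls[col].astype("int64")
        for col in ("qual", "mapq"):
            calls[col] = calls[col].astype("float64")
        calls = calls.sort_values(["sample_id", "chrom", "pos", "ref", "alt"],
                                  kind="mergesort").reset_index(drop=True)
    return CohortBundle(samples=samples, calls=calls, annotations=annotations,
                        depth=depth, truth=truth, panel=panel)
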