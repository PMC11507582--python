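"""Uni/multivariable biomarker screening.

For each gene and patient subgroup, fits matched pairs of univariable
and multivariable models — Cox proportional hazards for time-to-event
endpoints, logistic regression for binary response endpoints — then
cross-validates discrimination with bootstrap AUCs, derives
time-dependent ROC curves with Youden cutoffs, stratifies Kaplan-Meier
curves, and applies the model-matching decision (significance, effect
direction concordance, AUC floor).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "AnalysisSpec", "ModelResult", "MatchDecision", "RocCurve",
    "ModelSkipped", "build_subgroup", "design_frame", "fit_cox",
    "fit_logistic", "bootstrap_auc", "binary_roc", "time_dependent_roc",
    "youden_cutoff", "km_stratify", "match_models", "run_screen",
    "screen_report",
]

SURVIVAL_ENDPOINTS = {"OS": ("os_time", "os_event"),
                      "DFS": ("dfs_time", "dfs_event"),
                      "RFS": ("rfs_time", "rfs_event")}
BINARY_ENDPOINTS = ("CR", "PS", "microinvasion_or_implants")

BOTS_COVARIATES = ("chemo_given", "primary_tumor", "histotype_serous", "age")
HGOVCA_COVARIATES = ("histotype_serous", "figo_stage", "rt_lt2cm", "rt_ge2cm")


class ModelSkipped(RuntimeError):
    """A screened combination that cannot be fitted (logged, not fatal)."""


@dataclass(frozen=True)
class AnalysisSpec:
    """One gene x endpoint x subgroup screening combination."""

    tumor_class: str  # BOTS | hgOvCa
    endpoint: str  # RFS | OS | DFS | CR | PS | microinvasion_or_implants
    gene: str
    chemo: str = "any"  # PC | TP | any (hgOvCa subgrouping)
    tp53_accumulation: str = "any"  # yes | no | any (hgOvCa subgrouping)
    bots_subset: str = "all"  # all | BOT | BOT.V600E

    def __post_init__(self) -> None:
        if self.tumor_class not in ("BOTS", "hgOvCa"):
            raise ValueError(
                f"regression analysis is restricted to BOTS and hgOvCa, "
                f"got {self.tumor_class!r}")
        if self.endpoint not in set(SURVIVAL_ENDPOINTS) | set(BINARY_ENDPOINTS):
            raise ValueError(f"unknown endpoint {self.endpoint!r}")
        if self.endpoint in ("RFS", "microinvasion_or_implants") \
                and self.tumor_class != "BOTS":
            raise ValueError(f"{self.endpoint} is a BOTS-only endpoint")
        if self.endpoint in ("DFS", "CR", "PS") and self.tumor_class != "hgOvCa":
            raise ValueError(f"{self.endpoint} is an hgOvCa-only endpoint")
        if self.chemo not in ("PC", "TP", "any"):
            raise ValueError(f"bad chemo filter {self.chemo!r}")
        if self.tp53_accumulation not in ("yes", "no", "any"):
            raise ValueError(f"bad tp53 filter {self.tp53_accumulation!r}")
        if self.bots_subset not in ("all", "BOT", "BOT.V600E"):
            raise ValueError(f"bad BOTS subset {self.bots_subset!r}")

    @property
    def is_survival(self) -> bool:
        return self.endpoint in SURVIVAL_ENDPOINTS

    @property
    def covariates(self) -> tuple[str, ...]:
        return BOTS_COVARIATES if self.tumor_class == "BOTS" else HGOVCA_COVARIATES

    def subgroup_label(self) -> str:
        parts = [self.tumor_class]
        if self.tumor_class == "BOTS" and self.bots_subset != "all":
            parts.append(self.bots_subset)
        if self.chemo != "any":
            parts.append(self.chemo)
        if self.tp53_accumulation != "any":
            parts.append(f"TP53acc={self.tp53_accumulation}")
        return "/".join(parts)


@dataclass
class ModelResult:
    spec: AnalysisSpec
    mode: str  # univariable | multivariable
    estimate: float  # HR or OR for the gene indicator
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    n_events: Optional[int] = None
    ph_ok: Optional[bool] = None  # Cox only
    auc_original: Optional[float] = None
    auc_boot: Optional[float] = None
    unstable: bool = False
    covariate_table: Optional[pd.DataFrame] = None
    risk_scores: Optional[pd.Series] = None
    params: Optional[pd.Series] = None  # linear-predictor coefficients
    eval_time: Optional[float] = None

    def score(self, frame: pd.DataFrame) -> pd.Series:
        """Linear risk score of new samples under the fitted model."""
        cols = list(self.params.index)
        return pd.Series(np.dot(frame[cols], self.params), index=frame.index)


@dataclass(frozen=True)
class MatchDecision:
    gene: str
    spec: AnalysisSpec
    matched: bool
    reasons: tuple[str, ...]


@dataclass(frozen=True)
class RocCurve:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


# ---------------------------------------------------------------------
# subgroup construction and design matrices
# ---------------------------------------------------------------------

def build_subgroup(samples: pd.DataFrame, spec: AnalysisSpec) -> pd.DataFrame:
    """Rows of the clinical table satisfying all of the spec's filters.

    DFS additionally restricts to complete-remission patients.
    """
    df = samples
    if spec.tumor_class == "BOTS":
        if spec.bots_subset == "all":
            df = df[df["group"].isin(["BOT", "BOT.V600E"])]
        else:
            df = df[df["group"] == spec.bots_subset]
    else:
        df = df[df["group"] == "hgOvCa"]
        if spec.chemo != "any":
            df = df[df["chemo"] == spec.chemo]
        if spec.tp53_accumulation != "any":
            want = 1 if spec.tp53_accumulation == "yes" else 0
            df = df[df["tp53_accumulation"] == want]
    if spec.endpoint == "DFS":
        df = df[df["cr"] == 1]
    return df.copy()


def design_frame(subgroup: pd.DataFrame, spec: AnalysisSpec,
                 gene_indicator: pd.Series) -> pd.DataFrame:
    """Assemble the modelling frame: gene indicator, covariates, outcome.

    Samples whose gene status is MISSING are dropped. The returned frame
    has ``gene`` plus the class-specific covariate encoding, and either
    ``duration``/``event`` (survival) or ``outcome`` (binary).
    """
    df = subgroup.set_index("sample_id")
    gene = gene_indicator.reindex(df.index)
    df = df[gene.notna()]
    gene = gene.loc[df.index]
    out = pd.DataFrame(index=df.index)
    out["gene"] = gene.astype(float)
    out["histotype_serous"] = (df["histotype"] == "serous").astype(float)
    out["age"] = df["age"].astype(float)
    if spec.tumor_class == "BOTS":
        out["chemo_given"] = (df["chemo"] != "none").astype(float)
        out["primary_tumor"] = df["primary_tumor"].astype(float)
    else:
        out["figo_stage"] = df["figo_stage"].astype(float)
        out["rt_lt2cm"] = (df["residual_tumor"] == "lt2cm").astype(float)
        out["rt_ge2cm"] = (df["residual_tumor"] == "ge2cm").astype(float)
    if spec.is_survival:
        tcol, ecol = SURVIVAL_ENDPOINTS[spec.endpoint]
        out["duration"] = df[tcol].astype(float)
        out["event"] = df[ecol].astype(float)
        out = out.dropna(subset=["duration", "event"])
    elif spec.endpoint == "microinvasion_or_implants":
        out["outcome"] = ((df["microinvasion"] == 1)
                          | (df["implants"] == 1)).astype(float)
    else:
        col = "cr" if spec.endpoint == "CR" else "ps"
        out["outcome"] = df[col].astype(float)
        out = out.dropna(subset=["outcome"])
    keep = ["gene"] + [c for c in spec.covariates if c in out.columns]
    keep += (["duration", "event"] if spec.is_survival else ["outcome"])
    return out[keep]


def _model_columns(frame: pd.DataFrame, spec: AnalysisSpec, mode: str
                   ) -> list[str]:
    cols = ["gene"]
    if mode == "multivariable":
        for c in spec.covariates:
            # constant covariates in a filtered subgroup are dropped
            if c in frame.columns and frame[c].nunique() > 1:
                cols.append(c)
    return cols


# ---------------------------------------------------------------------
# model fits
# ---------------------------------------------------------------------

def fit_cox(spec: AnalysisSpec, frame: pd.DataFrame, mode: str,
            check_ph: bool = True) -> ModelResult:
    """Cox proportional-hazards fit; gene enters as a 0/1 indicator.

    Raises :class:`ModelSkipped` on zero events or a constant gene
    indicator. The PH diagnostic (scaled-residual test at alpha=0.05
    across all variables) sets ``ph_ok`` but never excludes the model.
    """
    from lifelines import CoxPHFitter

    if not spec.is_survival:
        raise ValueError("fit_cox requires a survival endpoint")
    n_events = int(frame["event"].sum())
    if n_events == 0:
        raise ModelSkipped(f"zero events for {spec.gene} in {spec.subgroup_label()}")
    if frame["gene"].nunique() < 2:
        raise ModelSkipped(f"constant gene indicator for {spec.gene}")
    cols = _model_columns(frame, spec, mode)
    data = frame[cols + ["duration", "event"]]
    cph = CoxPHFitter()
    with warnings.catch_warnings(), np.errstate(over="ignore"):
        warnings.simplefilter("ignore")
        cph.fit(data, duration_col="duration", event_col="event")
        summ = cph.summary
    est = float(np.exp(np.clip(summ.loc["gene", "coef"], -700, 700)))
    unstable = bool(abs(summ.loc["gene", "coef"]) > 15
                    or not np.isfinite(summ.loc["gene", "se(coef)"]))
    ph_ok = None
    if check_ph:
        try:
            from lifelines.statistics import proportional_hazard_test
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ph = proportional_hazard_test(cph, data)
            ph_ok = bool((ph.summary["p"] > 0.05).all())
        except Exception:
            ph_ok = False
    cov = summ.loc[[c for c in cols if c != "gene"],
                   ["exp(coef)", "exp(coef) lower 95%",
                    "exp(coef) upper 95%", "p"]] if mode == "multivariable" else None
    lo = float(np.clip(summ.loc["gene", "coef lower 95%"], -700, 700))
    hi = float(np.clip(summ.loc["gene", "coef upper 95%"], -700, 700))
    return ModelResult(
        spec=spec, mode=mode, estimate=est,
        ci_low=float(np.exp(lo)), ci_high=float(np.exp(hi)),
        p_value=float(summ.loc["gene", "p"]),
        n=len(data), n_events=n_events, ph_ok=ph_ok, unstable=unstable,
        covariate_table=cov, params=cph.params_[cols],
        risk_scores=pd.Series(np.dot(data[cols], cph.params_[cols]),
                              index=data.index),
    )


def fit_logistic(spec: AnalysisSpec, frame: pd.DataFrame, mode: str
                 ) -> ModelResult:
    """Logistic regression of a binary endpoint on the gene indicator.

    Complete separation is flagged (``unstable=True``) and such models
    are excluded from matching downstream.
    """
    import statsmodels.api as sm

    if spec.is_survival:
        raise ValueError("fit_logistic requires a binary endpoint")
    y = frame["outcome"]
    if y.nunique() < 2:
        raise ModelSkipped("degenerate outcome: single class present")
    if frame["gene"].nunique() < 2:
        raise ModelSkipped(f"constant gene indicator for {spec.gene}")
    cols = _model_columns(frame, spec, mode)
    X = sm.add_constant(frame[cols], has_constant="add")
    unstable = False
    z = 1.959963984540054
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            params, bse, pvalues = res.params, res.bse, res.pvalues
            if not res.mle_retvals.get("converged", True):
                unstable = True
        except Exception:
            # separation or singular Hessian: ridge-stabilized point
            # estimate only; inference withheld and the fit flagged
            ridge = sm.GLM(y, X, family=sm.families.Binomial())
            params = ridge.fit_regularized(alpha=1e-3, L1_wt=0.0).params
            bse = pd.Series(np.inf, index=params.index)
            pvalues = pd.Series(1.0, index=params.index)
            unstable = True
    coef = float(params["gene"])
    se = float(bse["gene"])
    if not np.isfinite(se) or abs(coef) > 15 or se > 50:
        unstable = True
    cov = None
    if mode == "multivariable":
        rows = [c for c in cols if c != "gene"]
        cov = pd.DataFrame({
            "exp(coef)": np.exp(params[rows]),
            "exp(coef) lower 95%": np.exp(params[rows] - z * bse[rows]),
            "exp(coef) upper 95%": np.exp(params[rows] + z * bse[rows]),
            "p": pvalues[rows],
        })
    with np.errstate(over="ignore"):
        ci_low = float(np.exp(coef - z * se)) if np.isfinite(se) else 0.0
        ci_high = float(np.exp(coef + z * se)) if np.isfinite(se) else math.inf
    return ModelResult(
        spec=spec, mode=mode, estimate=float(np.exp(coef)),
        ci_low=ci_low, ci_high=ci_high, p_value=float(pvalues["gene"]),
        n=len(frame), ph_ok=None, unstable=unstable, covariate_table=cov,
        params=params[cols],
        risk_scores=pd.Series(np.dot(frame[cols], params[cols]),
                              index=frame.index),
    )


def _fit(spec: AnalysisSpec, frame: pd.DataFrame, mode: str,
         check_ph: bool = True) -> ModelResult:
    if spec.is_survival:
        return fit_cox(spec, frame, mode, check_ph=check_ph)
    return fit_logistic(spec, frame, mode)


# ---------------------------------------------------------------------
# ROC machinery
# ---------------------------------------------------------------------

def binary_roc(labels: np.ndarray, scores: np.ndarray) -> RocCurve:
    """Empirical ROC over all observed score thresholds (rule: score >= t
    predicts positive), with trapezoidal AUC."""
    labels = np.asarray(labels, dtype=float)
    scores = np.asarray(scores, dtype=float)
    pos = labels.sum()
    neg = len(labels) - pos
    if pos == 0 or neg == 0:
        raise ValueError("ROC undefined: need both cases and controls")
    thresholds = np.unique(scores)[::-1]
    sens = np.array([(labels[scores >= t] == 1).sum() / pos for t in thresholds])
    spec_ = np.array([(labels[scores < t] == 0).sum() / neg for t in thresholds])
    # anchor endpoints (0,0) and (1,1)
    fpr = np.concatenate([[0.0], 1 - spec_, [1.0]])
    tpr = np.concatenate([[0.0], sens, [1.0]])
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thresholds, sensitivity=sens,
                    specificity=spec_, auc=auc)


def time_dependent_roc(scores: pd.Series | np.ndarray,
                       durations: pd.Series | np.ndarray,
                       events: pd.Series | np.ndarray,
                       eval_time: float) -> RocCurve:
    """Cumulative-case / dynamic-control ROC at ``eval_time``.

    Cases are subjects with an observed event by ``eval_time``; controls
    are subjects still at risk beyond it. Subjects censored before
    ``eval_time`` are excluded.
    """
    scores = np.asarray(scores, dtype=float)
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=float)
    case = (durations <= eval_time) & (events == 1)
    control = durations > eval_time
    use = case | control
    if case.sum() == 0 or control.sum() == 0:
        raise ValueError(f"no cases or no controls at t={eval_time}")
    return binary_roc(case[use].astype(float), scores[use])


def youden_cutoff(roc: RocCurve) -> tuple[float, float, float]:
    """Cutoff maximizing sensitivity + specificity - 1 (lowest on ties)."""
    j = roc.sensitivity + roc.specificity - 1.0
    best = np.flatnonzero(j >= j.max() - 1e-12)
    i = best[np.argmin(roc.thresholds[best])]
    return (float(roc.thresholds[i]), float(roc.sensitivity[i]),
            float(roc.specificity[i]))


def _model_auc(result: ModelResult, frame: pd.DataFrame,
               eval_time: Optional[float] = None) -> float:
    spec = result.spec
    scores = result.risk_scores
    sub = frame.loc[scores.index]
    if spec.is_survival:
        if eval_time is None:
            ev = sub.loc[sub["event"] == 1, "duration"]
            if ev.empty:
                raise ValueError("no events; AUC undefined")
            eval_time = float(ev.median())
        roc = time_dependent_roc(scores, sub["duration"], sub["event"], eval_time)
        return roc.auc
    return binary_roc(sub["outcome"].to_numpy(), scores.to_numpy()).auc


def default_eval_time(frame: pd.DataFrame) -> float:
    """Median observed event time — the default ROC evaluation point."""
    ev = frame.loc[frame["event"] == 1, "duration"]
    if ev.empty:
        raise ValueError("no events observed")
    return float(ev.median())


def bootstrap_auc(spec: AnalysisSpec, frame: pd.DataFrame, mode: str,
                  B: int = 1000, seed: int = 0,
                  eval_time: Optional[float] = None) -> float:
    """Bootstrap cross-validated AUC: mean over ``B`` replicates of the
    model refitted on a with-replacement resample and evaluated on the
    out-of-bag samples. Deterministic per seed; replicates whose refit
    or AUC is undefined are skipped."""
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(frame)
    aucs = []
    for _ in range(B):
        idx = rng.integers(0, n, n)
        oob_mask = np.ones(n, dtype=bool)
        oob_mask[np.unique(idx)] = False
        if not oob_mask.any():
            continue
        boot = frame.iloc[idx].copy()
        boot.index = [f"b{i}" for i in range(n)]
        oob = frame.iloc[oob_mask]
        try:
            res = _fit(spec, boot, mode, check_ph=False)
            scores = res.score(oob)
            if spec.is_survival:
                t = eval_time if eval_time is not None else default_eval_time(frame)
                auc = time_dependent_roc(scores, oob["duration"],
                                         oob["event"], t).auc
            else:
                auc = binary_roc(oob["outcome"].to_numpy(),
                                 scores.to_numpy()).auc
            aucs.append(auc)
        except (ModelSkipped, ValueError, np.linalg.LinAlgError):
            continue
    if not aucs:
        raise ValueError("all bootstrap replicates failed")
    return float(np.mean(aucs))


# ---------------------------------------------------------------------
# KM stratification
# ---------------------------------------------------------------------

def km_stratify(durations, events, scores, cutoff: float) -> dict:
    """Kaplan-Meier curves for high vs low risk plus the log-rank test."""
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=float)
    scores = np.asarray(scores, dtype=float)
    high = scores >= cutoff
    if high.all() or (~high).all():
        raise ValueError("risk cutoff does not split the cohort")
    curves = {}
    for name, mask in (("high", high), ("low", ~high)):
        km = KaplanMeierFitter(label=name)
        km.fit(durations[mask], events[mask])
        curves[name] = km
    lr = logrank_test(durations[high], durations[~high],
                      events[high], events[~high])
    return {"curves": curves, "logrank_stat": float(lr.test_statistic),
            "logrank_p": float(lr.p_value)}


# ---------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------

def match_models(uni: ModelResult, multi: ModelResult, alpha: float = 0.05,
                 auc_floor: float = 0.65) -> MatchDecision:
    """Matched iff both models are significant, effect directions agree
    (same side of 1) and every available AUC strictly exceeds the floor.

    Unstable fits never match.
    """
    if uni.spec.gene != multi.spec.gene or uni.spec != multi.spec:
        raise ValueError("univariable and multivariable specs differ")
    reasons = []
    if uni.unstable or multi.unstable:
        reasons.append("unstable")
    if not (uni.p_value < alpha and multi.p_value < alpha):
        reasons.append("significance")
    same_side = ((uni.estimate > 1 and multi.estimate > 1)
                 or (uni.estimate < 1 and multi.estimate < 1))
    if not same_side:
        reasons.append("direction")
    aucs = [a for a in (uni.auc_original, uni.auc_boot,
                        multi.auc_original, multi.auc_boot) if a is not None]
    if not aucs or not all(a > auc_floor for a in aucs):
        reasons.append("auc_floor")
    return MatchDecision(gene=uni.spec.gene, spec=uni.spec,
                         matched=not reasons, reasons=tuple(reasons))


# ---------------------------------------------------------------------
# full screen
# ---------------------------------------------------------------------

def run_screen(samples: pd.DataFrame, gene_matrix: pd.DataFrame,
               specs: Iterable[AnalysisSpec], alpha: float = 0.05,
               auc_floor: float = 0.65, B: int = 1000, seed: int = 0,
               min_subgroup: int = 10) -> dict:
    """Execute the screen over all specs; returns results + decisions.

    ``gene_matrix`` is the binarized samples x genes frame (NaN =
    MISSING). Combinations that cannot be fitted are recorded in the
    notice log and skipped.
    """
    results: list[tuple[ModelResult, ModelResult]] = []
    decisions: list[MatchDecision] = []
    frames: list[pd.DataFrame] = []
    notices: list[str] = []
    for k, spec in enumerate(specs):
        sub = build_subgroup(samples, spec)
        if len(sub) < min_subgroup:
            notices.append(f"{spec.gene}/{spec.endpoint}/{spec.subgroup_label()}: "
                           f"subgroup too small (n={len(sub)})")
            continue
        if spec.gene not in gene_matrix.columns:
            notices.append(f"{spec.gene}: not in gene matrix")
            continue
        frame = design_frame(sub, spec, gene_matrix[spec.gene])
        try:
            eval_time = default_eval_time(frame) if spec.is_survival else None
            uni = _fit(spec, frame, "univariable")
            multi = _fit(spec, frame, "multivariable")
            uni.eval_time = multi.eval_time = eval_time
            uni.auc_original = _model_auc(uni, frame, eval_time)
            multi.auc_original = _model_auc(multi, frame, eval_time)
            uni.auc_boot = bootstrap_auc(spec, frame, "univariable", B=B,
                                         seed=seed + 2 * k, eval_time=eval_time)
            multi.auc_boot = bootstrap_auc(spec, frame, "multivariable", B=B,
                                           seed=seed + 2 * k + 1,
                                           eval_time=eval_time)
        except (ModelSkipped, ValueError) as exc:
            notices.append(f"{spec.gene}/{spec.endpoint}/"
                           f"{spec.subgroup_label()}: {exc}")
            continue
        results.append((uni, multi))
        frames.append(frame)
        decisions.append(match_models(uni, multi, alpha=alpha,
                                      auc_floor=auc_floor))
    return {"results": results, "decisions": decisions, "frames": frames,
            "notices": notices}


def roc_km_artifacts(screen: dict) -> dict[str, pd.DataFrame]:
    """ROC and Kaplan-Meier coordinate tables for each matched model.

    ROC curves come from the multivariable risk scores; the Youden
    cutoff splits the cohort for the KM curves (survival endpoints).
    """
    artifacts: dict[str, pd.DataFrame] = {}
    for (uni, multi), frame, dec in zip(screen["results"], screen["frames"],
                                        screen["decisions"]):
        if not dec.matched:
            continue
        spec = multi.spec
        tag = f"{spec.gene}_{spec.endpoint}_{spec.subgroup_label().replace('/', '-')}"
        scores = multi.risk_scores
        sub = frame.loc[scores.index]
        try:
            if spec.is_survival:
                roc = time_dependent_roc(scores, sub["duration"],
                                         sub["event"], multi.eval_time)
            else:
                roc = binary_roc(sub["outcome"].to_numpy(),
                                 scores.to_numpy())
            cutoff, sens, spec_ = youden_cutoff(roc)
            artifacts[f"roc_{tag}"] = pd.DataFrame({
                "threshold": roc.thresholds,
                "sensitivity": roc.sensitivity,
                "specificity": roc.specificity,
                "youden_cutoff": cutoff, "auc": roc.auc,
            })
            if spec.is_survival:
                km = km_stratify(sub["duration"], sub["event"],
                                 scores.to_numpy(), cutoff)
                pieces = []
                for name, fitter in km["curves"].items():
                    sf = fitter.survival_function_
                    pieces.append(pd.DataFrame({
                        "stratum": name, "time": sf.index,
                        "survival": sf.iloc[:, 0].to_numpy(),
                        "logrank_p": km["logrank_p"],
                    }))
                artifacts[f"km_{tag}"] = pd.concat(pieces, ignore_index=True)
        except ValueError:
            continue
    return artifacts


def screen_report(screen: dict) -> pd.DataFrame:
    """Long-form report of matched models only.

    Gene rows for both modes plus multivariable covariate contrast rows
    (e.g. residual-tumor categories).
    """
    rows = []
    for (uni, multi), dec in zip(screen["results"], screen["decisions"]):
        if not dec.matched:
            continue
        spec = uni.spec
        base = {"endpoint": spec.endpoint, "subgroup": spec.subgroup_label(),
                "gene": spec.gene}
        for res in (uni, multi):
            rows.append({**base, "mode": res.mode, "term": "gene",
                         "estimate": res.estimate, "ci_low": res.ci_low,
                         "ci_high": res.ci_high, "p_value": res.p_value,
                         "auc_original": res.auc_original,
                         "auc_boot": res.auc_boot, "n": res.n})
        if multi.covariate_table is not None:
            for term, r in multi.covariate_table.iterrows():
                rows.append({**base, "mode": "multivariable", "term": term,
                             "estimate": float(r["exp(coef)"]),
                             "ci_low": float(r["exp(coef) lower 95%"]),
                             "ci_high": float(r["exp(coef) upper 95%"]),
                             "p_value": float(r["p"]),
                             "auc_original": None, "auc_boot": None,
                             "n": multi.n})
    columns = ["endpoint", "subgroup", "gene", "mode", "term", "estimate",
               "ci_low", "ci_high", "p_value", "auc_original", "auc_boot", "n"]
    return pd.DataFrame.from_records(rows, columns=columns)
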