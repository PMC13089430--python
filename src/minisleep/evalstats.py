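"""Agreement and fragmentation statistics for mini-epoch scorings.

Implements the evaluation methodology of a pairwise scorer comparison at the
PSG level: one confusion matrix per recording (segments combined, artifact
mini-epochs excluded), per-stage precision/recall/F1 with careful handling of
absent stages, prevalence-weighted overall F1, percentile-bootstrap means and
95% CIs, Wilcoxon signed-rank paired tests with r = Z/sqrt(n), stage
fractions, transition indices, and a linear mixed-effects group comparison
(family random intercept, age/sex adjusted, square-root transformed outcome,
Cohen's d = group coefficient / residual SD).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import ART, STAGE_INDEX, STAGES, MiniEpochHypnogram

logger = logging.getLogger(__name__)

N_STAGES = len(STAGES)


@dataclass
class ConfusionMatrix:
    """5x5 stage-by-stage counts; rows = reference, columns = comparison."""

    counts: np.ndarray
    n_excluded_artifacts: int = 0
    recording_id: str | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (N_STAGES, N_STAGES):
            raise ValueError("confusion matrix must be 5x5")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class F1Report:
    """Per-stage agreement plus prevalence-weighted overall F1.

    A stage's scores are defined iff the stage occurs in the reference or
    the comparison scoring of this recording; otherwise the entries are None
    (missing agreement, not disagreement).
    """

    precision: dict
    recall: dict
    f1: dict
    support: dict
    tp: dict
    fp: dict
    fn: dict
    overall_weighted_f1: float | None
    recording_id: str | None = None
    cm: ConfusionMatrix | None = None


@dataclass
class TransitionStats:
    any_transitions_per_min: float
    sleep_wake_transitions_per_min: float
    recording_id: str | None = None


@dataclass
class ComparisonResult:
    statistic: float
    p_value: float
    effect_size: float  # r = Z/sqrt(n) for Wilcoxon; Cohen's d for the LMM
    effect_kind: str
    n: int
    coefficient: float | None = None
    model: str | None = None


# ---------------------------------------------------------------------------
# hypnogram manipulation
# ---------------------------------------------------------------------------

def expand_epochs(hyp: MiniEpochHypnogram, target_period: float = 5.0
                  ) -> MiniEpochHypnogram:
    """Split each epoch into equal mini-epochs carrying the epoch's label.

    A 30-s epoch becomes six 5-s mini-epochs; char_flag is True throughout
    by convention (epoch scorings carry no characteristic flags).
    """
    ratio = hyp.period / target_period
    r = int(round(ratio))
    if abs(ratio - r) > 1e-9 or r < 1:
        raise ValueError(
            f"epoch period {hyp.period}s not divisible by {target_period}s")
    return MiniEpochHypnogram(
        labels=np.repeat(hyp.labels, r),
        char_flag=np.ones(len(hyp) * r, bool),
        period=target_period,
        t0=hyp.t0,
    )


def collapse_to_epochs(hyp: MiniEpochHypnogram, epoch_period: float = 30.0
                       ) -> MiniEpochHypnogram:
    """Majority-collapse mini-epochs into epochs (the conventional view).

    Ties break to the earlier label in the order W, N1, N2, N3, REM, ART.
    """
    ratio = epoch_period / hyp.period
    r = int(round(ratio))
    if abs(ratio - r) > 1e-9 or r < 1 or len(hyp) % r:
        raise ValueError("hypnogram length/period incompatible with epoch period")
    order = list(STAGES) + [ART]
    labels = []
    for i in range(len(hyp) // r):
        block = hyp.labels[i * r:(i + 1) * r]
        best = max(order, key=lambda s: ((block == s).sum(), -order.index(s)))
        labels.append(best)
    return MiniEpochHypnogram(
        labels=np.array(labels), char_flag=np.ones(len(labels), bool),
        period=epoch_period, t0=hyp.t0)


# ---------------------------------------------------------------------------
# confusion / F1
# ---------------------------------------------------------------------------

def confusion_from_indices(ref: np.ndarray, cmp: np.ndarray,
                           recording_id: str | None = None) -> ConfusionMatrix:
    """Tally already-integer stage indices (no ART entries)."""
    counts = np.zeros((N_STAGES, N_STAGES), dtype=int)
    np.add.at(counts, (ref, cmp), 1)
    return ConfusionMatrix(counts, 0, recording_id)


def build_confusion(
    reference: MiniEpochHypnogram | list[MiniEpochHypnogram],
    comparison: MiniEpochHypnogram | list[MiniEpochHypnogram],
    recording_id: str | None = None,
) -> ConfusionMatrix:
    """One confusion matrix per recording, segments combined.

    Mini-epochs where either scorer labelled ART are excluded and counted in
    ``n_excluded_artifacts``.
    """
    refs = reference if isinstance(reference, list) else [reference]
    cmps = comparison if isinstance(comparison, list) else [comparison]
    if len(refs) != len(cmps):
        raise ValueError("segment lists differ in length")
    counts = np.zeros((N_STAGES, N_STAGES), dtype=int)
    excluded = 0
    for ref, cmp in zip(refs, cmps):
        if len(ref) != len(cmp) or abs(ref.period - cmp.period) > 1e-9:
            raise ValueError(
                f"aligned sequences required: {len(ref)}x{ref.period}s vs "
                f"{len(cmp)}x{cmp.period}s")
        keep = (ref.labels != ART) & (cmp.labels != ART)
        excluded += int((~keep).sum())
        r = np.array([STAGE_INDEX[s] for s in ref.labels[keep]])
        c = np.array([STAGE_INDEX[s] for s in cmp.labels[keep]])
        if len(r):
            np.add.at(counts, (r, c), 1)
    return ConfusionMatrix(counts, excluded, recording_id)


def f1_report(cm: ConfusionMatrix, weights: str = "reference") -> F1Report:
    """Per-stage precision/recall/F1 and prevalence-weighted overall F1.

    A stage is *present* when either scorer used it at least once (row or
    column total > 0); absent stages get None rather than zero.  The overall
    F1 weights each present stage by its prevalence — reference-scorer
    support by default, pooled support of both scorers with
    ``weights="pooled"``.
    """
    if weights not in ("reference", "pooled"):
        raise ValueError("weights must be 'reference' or 'pooled'")
    c = cm.counts
    row = c.sum(axis=1)
    col = c.sum(axis=0)
    present = (row + col) > 0
    precision, recall, f1, support = {}, {}, {}, {}
    tp_d, fp_d, fn_d = {}, {}, {}
    for i, s in enumerate(STAGES):
        support[s] = int(row[i])
        if not present[i]:
            precision[s] = recall[s] = f1[s] = None
            tp_d[s] = fp_d[s] = fn_d[s] = 0
            continue
        tp = int(c[i, i])
        fp = int(col[i] - tp)
        fn = int(row[i] - tp)
        tp_d[s], fp_d[s], fn_d[s] = tp, fp, fn
        precision[s] = tp / (tp + fp) if tp + fp else 0.0
        recall[s] = tp / (tp + fn) if tp + fn else 0.0
        denom = precision[s] + recall[s]
        f1[s] = 2 * precision[s] * recall[s] / denom if denom else 0.0
    w = row + col if weights == "pooled" else row
    w = np.where(present, w, 0).astype(float)
    overall = None
    if w.sum() > 0:
        vals = np.array([f1[s] if f1[s] is not None else 0.0 for s in STAGES])
        overall = float((vals * w).sum() / w.sum())
    return F1Report(precision=precision, recall=recall, f1=f1, support=support,
                    tp=tp_d, fp=fp_d, fn=fn_d, overall_weighted_f1=overall,
                    recording_id=cm.recording_id, cm=cm)


def bootstrap_mean_ci(values: np.ndarray, n_boot: int = 1000,
                      rng_seed: int = 0, level: float = 0.95
                      ) -> tuple[float, float, float]:
    """Percentile bootstrap of the mean: (mean, lo, hi), seeded."""
    values = np.asarray(values, float)
    rng = np.random.default_rng(rng_seed)
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    means = values[idx].mean(axis=1)
    alpha = (1 - level) / 2
    lo, hi = np.quantile(means, [alpha, 1 - alpha])
    return float(values.mean()), float(lo), float(hi)


def aggregate_f1(reports: list[F1Report], n_boot: int = 1000,
                 rng_seed: int = 0) -> dict:
    """Across-recording stage means with bootstrap 95% CIs.

    A stage's mean only averages recordings where that stage's F1 is defined
    (present for either scorer); the contributing n is reported per stage.
    """
    if not reports:
        raise ValueError("need at least one report")
    out: dict = {"per_stage": {}, "overall": None}
    for s in STAGES:
        vals = np.array([r.f1[s] for r in reports if r.f1[s] is not None])
        if vals.size == 0:
            out["per_stage"][s] = {"mean": None, "ci": (None, None), "n": 0}
        else:
            mean, lo, hi = bootstrap_mean_ci(vals, n_boot, rng_seed)
            out["per_stage"][s] = {"mean": mean, "ci": (lo, hi), "n": int(vals.size)}
    ov = np.array([r.overall_weighted_f1 for r in reports
                   if r.overall_weighted_f1 is not None])
    if ov.size:
        mean, lo, hi = bootstrap_mean_ci(ov, n_boot, rng_seed)
        out["overall"] = {"mean": mean, "ci": (lo, hi), "n": int(ov.size)}
    return out


def normalize_confusion(cm: ConfusionMatrix, mode: str) -> np.ndarray:
    """Row- (recall-weighted) or column- (precision-weighted) normalized
    fractions; zero-sum lines become NaN, not 0."""
    c = cm.counts.astype(float)
    if mode == "row":
        denom = c.sum(axis=1, keepdims=True)
    elif mode == "column":
        denom = c.sum(axis=0, keepdims=True)
    else:
        raise ValueError("mode must be 'row' or 'column'")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = c / denom
    out[np.broadcast_to(denom == 0, out.shape)] = np.nan
    return out


# ---------------------------------------------------------------------------
# fragmentation
# ---------------------------------------------------------------------------

def transition_stats(segments: MiniEpochHypnogram | list[MiniEpochHypnogram],
                     recording_id: str | None = None) -> TransitionStats:
    """Transition indices per recording, combining its segments.

    Transitions are adjacent label changes within a segment (never across
    segment boundaries).  ART labels are removed and their flanking labels
    treated as non-adjacent; the duration denominator keeps the full segment
    minutes.  Sleep-wake transitions are pairs where exactly one side is W.
    """
    segs = segments if isinstance(segments, list) else [segments]
    any_n = sw_n = 0
    minutes = 0.0
    for seg in segs:
        minutes += seg.duration / 60.0
        lab = seg.labels
        ok = lab != ART
        adjacent = ok[:-1] & ok[1:]
        a, b = lab[:-1][adjacent], lab[1:][adjacent]
        any_n += int((a != b).sum())
        sw_n += int(((a == "W") ^ (b == "W")).sum())
    if minutes == 0:
        raise ValueError("zero total duration")
    return TransitionStats(any_n / minutes, sw_n / minutes, recording_id)


def stage_fractions(hyp: MiniEpochHypnogram | list[MiniEpochHypnogram]) -> dict:
    """Share of each stage among non-artifact mini-epochs (sums to 1)."""
    segs = hyp if isinstance(hyp, list) else [hyp]
    lab = np.concatenate([s.labels for s in segs])
    lab = lab[lab != ART]
    if lab.size == 0:
        raise ValueError("all mini-epochs are artifacts; fractions undefined")
    return {s: float((lab == s).mean()) for s in STAGES}


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def paired_compare(values_a, values_b) -> ComparisonResult:
    """Two-sided Wilcoxon signed-rank with effect size r = Z/sqrt(n).

    No multiple-testing correction is applied.  When every pair is tied the
    result is the null convention (p = 1, r = 0).
    """
    from scipy import stats

    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    n = len(a)
    if n < 5:
        raise ValueError("need at least 5 pairs")
    if np.allclose(a, b):
        return ComparisonResult(statistic=0.0, p_value=1.0, effect_size=0.0,
                                effect_kind="r", n=n)
    res = stats.wilcoxon(a, b, method="approx", correction=False)
    r = float(res.zstatistic) / np.sqrt(n)
    return ComparisonResult(statistic=float(res.statistic),
                            p_value=float(res.pvalue),
                            effect_size=r, effect_kind="r", n=n)


def group_compare_lmm(outcome, metas) -> ComparisonResult:
    """NT1-vs-sibling comparison of a per-recording outcome.

    Fits sqrt(outcome) ~ group + age + sex with a family random intercept;
    Cohen's d is the group coefficient divided by the residual SD on the
    transformed scale.  Without family replication (every family a
    singleton) or on a singular fit, an independent-errors linear model is
    used instead, with a logged warning.
    """
    import statsmodels.formula.api as smf

    y = np.asarray(outcome, float)
    if (y < 0).any():
        raise ValueError("outcome must be non-negative for the sqrt transform")
    df = pd.DataFrame({
        "y": np.sqrt(y),
        "is_nt1": [1.0 if m.group == "NT1" else 0.0 for m in metas],
        "age": [m.age for m in metas],
        "is_male": [1.0 if m.sex == "M" else 0.0 for m in metas],
        "family": [m.family_id for m in metas],
    })
    has_replication = df["family"].value_counts().max() > 1
    model_used = "lmm"
    result = None
    if has_replication:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                md = smf.mixedlm("y ~ is_nt1 + age + is_male", df,
                                 groups=df["family"])
                result = md.fit(reml=True)
            if not np.isfinite(result.params["is_nt1"]):
                result = None
        except Exception:
            result = None
    if result is not None:
        coef = float(result.params["is_nt1"])
        resid_sd = float(np.sqrt(result.scale))
        p = float(result.pvalues["is_nt1"])
    else:
        if has_replication:
            logger.warning("mixed model singular; falling back to OLS")
        model_used = "ols"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ols = smf.ols("y ~ is_nt1 + age + is_male", df).fit()
        coef = float(ols.params["is_nt1"])
        resid_sd = float(np.sqrt(ols.mse_resid))
        p = float(ols.pvalues["is_nt1"])
    d = coef / resid_sd if resid_sd > 0 else 0.0
    return ComparisonResult(statistic=coef / resid_sd if resid_sd else 0.0,
                            p_value=p, effect_size=float(d), effect_kind="d",
                            n=len(df), coefficient=coef, model=model_used)


def stratify_by_characteristics(
    reference: MiniEpochHypnogram | list[MiniEpochHypnogram],
    comparison: MiniEpochHypnogram | list[MiniEpochHypnogram],
    recording_id: str | None = None,
) -> dict:
    """F1 reports split by the reference scorer's characteristic flag.

    Only N1/N2/REM are meaningful in the "without" stratum, since W and N3
    cannot be scored without characteristics.  Returns a dict with "with"
    and "without" F1Reports (None for an empty stratum); the two strata's
    confusion matrices sum elementwise to the pooled matrix.
    """
    refs = reference if isinstance(reference, list) else [reference]
    cmps = comparison if isinstance(comparison, list) else [comparison]
    out = {}
    for name, want in (("with", True), ("without", False)):
        sub_r, sub_c = [], []
        for ref, cmp in zip(refs, cmps):
            m = ref.char_flag == want
            sub_r.append(MiniEpochHypnogram(ref.labels[m], ref.char_flag[m],
                                            ref.period))
            sub_c.append(MiniEpochHypnogram(
                cmp.labels[m], np.ones(int(m.sum()), bool), cmp.period))
        total = sum(len(h) for h in sub_r)
        if total == 0:
            out[name] = None
            continue
        cm = build_confusion(sub_r, sub_c, recording_id)
        out[name] = f1_report(cm)
    return out
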