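"""Diagnostic-accuracy statistics for a paired optical-diagnosis study.

One row per diminutive (1-5 mm) polyp joins the CADx output, the
endoscopist's prediction, and the histopathology reference. The analyses
implemented here mirror a paired diagnostic-accuracy design:

* exclusion of lesions whose histology is outside the three target classes
  (carcinoma, traditional serrated adenoma, normal, inflammatory, missing);
* the binary neoplastic (adenoma + SSL) vs non-neoplastic (hyperplastic)
  confusion table, in which an SSL called adenoma (or vice versa) counts as
  correct, and the derived accuracy / sensitivity / specificity / PPV / NPV
  with 95 % CIs;
* per-subtype (3-class) accuracy and one-vs-rest metrics;
* subgroup views (segment, confidence tier);
* McNemar's test with continuity correction (exact binomial option) for
  paired accuracy comparisons, Fisher's exact test and a patient-clustered
  bootstrap for predictive-value comparisons;
* surveillance-interval agreement under a configurable rule table;
* the paired-McNemar sample-size formula and its conversion to a patient
  count, plus a simulation check of the achieved power.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

TARGET_CLASSES = ("adenoma", "ssl", "hyperplastic")
NEOPLASTIC = frozenset({"adenoma", "ssl", "carcinoma"})
EXCLUDED_HISTOLOGY = ("carcinoma", "tsa", "normal", "inflammatory", "missing")
KNOWN_HISTOLOGY = TARGET_CLASSES + EXCLUDED_HISTOLOGY

_CI_METHODS = {"clopper-pearson": "beta", "wald": "normal", "wilson": "wilson"}


@dataclass(frozen=True)
class PolypRecord:
    """Study-level row for one diminutive polyp."""

    polyp_id: str
    patient_id: str
    size_mm: int
    segment: str                      # rectosigmoid | proximal
    morphology: str = ""              # Paris class label, free text
    endoscopist_dx: str | None = None # adenoma|ssl|hyperplastic|carcinoma|other
    endoscopist_confidence: str | None = None   # high | low
    cadx_dx: str | None = None        # class label, or None on CADx failure
    cadx_tier: str | None = None      # high | low
    histology: str = "adenoma"

    def __post_init__(self) -> None:
        if not 1 <= self.size_mm <= 5:
            raise ValueError("diminutive polyps are 1-5 mm")
        if self.histology not in KNOWN_HISTOLOGY:
            raise ValueError(f"unknown histology code {self.histology!r}")

    def prediction(self, rater: str) -> str | None:
        if rater == "cadx":
            return self.cadx_dx
        if rater == "endoscopist":
            return self.endoscopist_dx
        raise ValueError(f"unknown rater {rater!r}")

    def confidence(self, rater: str) -> str | None:
        return self.cadx_tier if rater == "cadx" else self.endoscopist_confidence


def filter_lesions(records: Iterable[PolypRecord]) -> tuple[list[PolypRecord], Counter]:
    """Keep lesions with adenoma/SSL/hyperplastic histology; tally exclusions
    by reason."""
    kept, tally = [], Counter()
    for r in records:
        if r.histology in TARGET_CLASSES:
            kept.append(r)
        else:
            tally[r.histology] += 1
    return kept, tally


# ---------------------------------------------------------------------------
# confusion tables and metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionTable:
    """Binary 2x2 tally; positive = neoplastic (or the one-vs-rest target)."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def is_neoplastic(label: str) -> bool:
    return label in NEOPLASTIC


def binary_confusion(records: Sequence[PolypRecord], rater: str) -> ConfusionTable:
    """Neoplastic-vs-non-neoplastic table.

    Adenoma and SSL jointly form the positive class, so an SSL predicted as
    adenoma (or vice versa) is a true positive. Records without a prediction
    (CADx failures) are excluded here and accounted for by the success rate.
    """
    tp = fn = fp = tn = 0
    for r in records:
        pred = r.prediction(rater)
        if pred is None:
            continue
        truth_pos = is_neoplastic(r.histology)
        pred_pos = is_neoplastic(pred)
        tp += truth_pos and pred_pos
        fn += truth_pos and not pred_pos
        fp += pred_pos and not truth_pos
        tn += not truth_pos and not pred_pos
    return ConfusionTable(tp=tp, fn=fn, fp=fp, tn=tn)


@dataclass(frozen=True)
class Estimate:
    value: float
    ci: tuple[float, float]

    def __post_init__(self) -> None:
        if not (self.ci[0] - 1e-12 <= self.value <= self.ci[1] + 1e-12):
            raise ValueError("CI must contain the point estimate")


@dataclass(frozen=True)
class MetricSet:
    accuracy: Estimate | None
    sensitivity: Estimate | None
    specificity: Estimate | None
    ppv: Estimate | None
    npv: Estimate | None

    def as_dict(self) -> dict:
        out = {}
        for name in ("accuracy", "sensitivity", "specificity", "ppv", "npv"):
            e = getattr(self, name)
            out[name] = None if e is None else {"value": e.value, "ci": list(e.ci)}
        return out


def proportion_estimate(k: int, n: int, ci_method: str = "clopper-pearson",
                        alpha: float = 0.05) -> Estimate | None:
    """Point estimate and CI for a binomial proportion; None when undefined
    (zero denominator) — undefined metrics are flagged absent, never 0."""
    if n == 0:
        return None
    lo, hi = proportion_confint(k, n, alpha=alpha, method=_CI_METHODS[ci_method])
    return Estimate(value=k / n, ci=(float(lo), float(hi)))


def metrics(table: ConfusionTable, ci_method: str = "clopper-pearson",
            alpha: float = 0.05) -> MetricSet:
    """Accuracy, sensitivity, specificity, PPV and NPV with 95 % CIs.

    The default interval is exact Clopper-Pearson; Wald and Wilson are
    available (the Wald interval reproduces published predictive-value
    intervals in this design, see the methods note).
    """
    t = table
    est = lambda k, n: proportion_estimate(k, n, ci_method, alpha)
    return MetricSet(
        accuracy=est(t.tp + t.tn, t.n),
        sensitivity=est(t.tp, t.tp + t.fn),
        specificity=est(t.tn, t.tn + t.fp),
        ppv=est(t.tp, t.tp + t.fp),
        npv=est(t.tn, t.tn + t.fn),
    )


def subtype_confusion(records: Sequence[PolypRecord], rater: str) -> np.ndarray:
    """3x3 tally, rows = histology, cols = prediction; predictions outside the
    three target classes are mapped onto the binary-compatible class
    (carcinoma -> adenoma, other -> hyperplastic)."""
    remap = {"carcinoma": "adenoma", "other": "hyperplastic"}
    m = np.zeros((3, 3), dtype=int)
    for r in records:
        pred = r.prediction(rater)
        if pred is None:
            continue
        pred = remap.get(pred, pred)
        m[TARGET_CLASSES.index(r.histology), TARGET_CLASSES.index(pred)] += 1
    return m


def subtype_accuracy(records: Sequence[PolypRecord], rater: str,
                     ci_method: str = "clopper-pearson") -> Estimate | None:
    """Three-class accuracy: fraction of lesions whose predicted subtype
    equals the histology subtype."""
    m = subtype_confusion(records, rater)
    return proportion_estimate(int(np.trace(m)), int(m.sum()), ci_method)


def one_vs_rest(records: Sequence[PolypRecord], rater: str, target: str,
                ci_method: str = "clopper-pearson") -> MetricSet:
    """Collapse the other two classes and compute binary metrics for one
    subtype (e.g. SSL vs non-SSL)."""
    if target not in TARGET_CLASSES:
        raise ValueError(f"target must be one of {TARGET_CLASSES}")
    m = subtype_confusion(records, rater)
    i = TARGET_CLASSES.index(target)
    tp = int(m[i, i])
    fn = int(m[i].sum() - tp)
    fp = int(m[:, i].sum() - tp)
    tn = int(m.sum() - tp - fn - fp)
    return metrics(ConfusionTable(tp=tp, fn=fn, fp=fp, tn=tn), ci_method)


def subgroup(records: Sequence[PolypRecord],
             predicate: Callable[[PolypRecord], bool]) -> list[PolypRecord]:
    """Filtered view over records; composable."""
    return [r for r in records if predicate(r)]


def high_confidence(rater: str) -> Callable[[PolypRecord], bool]:
    return lambda r: r.confidence(rater) == "high"


def in_segment(segment: str) -> Callable[[PolypRecord], bool]:
    return lambda r: r.segment == segment


# ---------------------------------------------------------------------------
# paired tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TestResult:
    statistic: float | None
    p_value: float
    method: str


def mcnemar(b: int, c: int, method: str = "cc") -> TestResult:
    """McNemar's test on the discordant counts (b, c).

    ``method="cc"`` (default): continuity-corrected chi-square,
    chi2 = (max(|b-c|-1, 0))^2 / (b+c), two-sided p from chi2 with 1 df.
    ``method="exact"``: two-sided exact binomial on b out of b+c at 1/2
    (recommended for b+c < 25). ``method="auto"`` picks exact below 25.
    With no discordant pairs, p = 1.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be nonnegative")
    t = b + c
    if t == 0:
        return TestResult(statistic=0.0, p_value=1.0, method=method)
    if method == "auto":
        method = "exact" if t < 25 else "cc"
    if method == "exact":
        p = stats.binomtest(b, t, 0.5).pvalue
        return TestResult(statistic=None, p_value=float(p), method="exact")
    if method == "cc":
        stat = max(abs(b - c) - 1, 0) ** 2 / t
        return TestResult(statistic=float(stat),
                          p_value=float(stats.chi2.sf(stat, 1)), method="cc")
    raise ValueError(f"unknown method {method!r}")


def paired_correctness(records: Sequence[PolypRecord],
                       correct: Callable[[PolypRecord, str], bool | None]) -> tuple[int, int]:
    """Discordant counts (b, c) = (A correct & B wrong, A wrong & B correct)
    for raters (cadx, endoscopist); records where either correctness is
    undefined are skipped."""
    b = c = 0
    for r in records:
        ca, cb = correct(r, "cadx"), correct(r, "endoscopist")
        if ca is None or cb is None:
            continue
        b += ca and not cb
        c += cb and not ca
    return b, c


def binary_correct(record: PolypRecord, rater: str) -> bool | None:
    pred = record.prediction(rater)
    if pred is None:
        return None
    return is_neoplastic(pred) == is_neoplastic(record.histology)


def mcnemar_from_records(records: Sequence[PolypRecord], method: str = "cc") -> TestResult:
    """Paired comparison of binary diagnostic accuracy, CADx vs endoscopist."""
    b, c = paired_correctness(records, binary_correct)
    return mcnemar(b, c, method=method)


def fisher_exact(table: Sequence[Sequence[int]]) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 table."""
    _, p = stats.fisher_exact(np.asarray(table), alternative="two-sided")
    return TestResult(statistic=None, p_value=float(p), method="fisher")


@dataclass(frozen=True)
class PredictiveValueComparison:
    ppv_diff: float | None
    ppv_p: float | None
    npv_diff: float | None
    npv_p: float | None
    n_bootstrap: int
    method: str = "clustered-bootstrap"


def _pv(records: Sequence[PolypRecord], rater: str) -> tuple[float | None, float | None]:
    t = binary_confusion(records, rater)
    ppv = t.tp / (t.tp + t.fp) if t.tp + t.fp else None
    npv = t.tn / (t.tn + t.fn) if t.tn + t.fn else None
    return ppv, npv


def compare_predictive_values(records: Sequence[PolypRecord], n_bootstrap: int = 2000,
                              seed: int = 0) -> PredictiveValueComparison:
    """Paired PPV/NPV comparison (CADx minus endoscopist) by patient-clustered
    bootstrap: patients are resampled with replacement, the difference is
    recomputed, and the two-sided p-value is the doubled tail of the bootstrap
    distribution around zero. Deterministic under seed.
    """
    rng = np.random.default_rng(seed)
    by_patient: dict[str, list[PolypRecord]] = {}
    for r in records:
        by_patient.setdefault(r.patient_id, []).append(r)
    patients = sorted(by_patient)
    ppv_d, npv_d = _diffs(records)
    draws_ppv, draws_npv = [], []
    for _ in range(n_bootstrap):
        sample: list[PolypRecord] = []
        for pid in rng.choice(patients, size=len(patients), replace=True):
            sample.extend(by_patient[pid])
        dp, dn = _diffs(sample)
        draws_ppv.append(dp)
        draws_npv.append(dn)

    def pval(draws, observed):
        if observed is None:
            return None
        d = np.array([x for x in draws if x is not None])
        if len(d) == 0:
            return None
        lo = np.mean(d <= 0)
        hi = np.mean(d >= 0)
        return float(min(1.0, 2 * min(lo, hi)))

    return PredictiveValueComparison(
        ppv_diff=ppv_d, ppv_p=pval(draws_ppv, ppv_d),
        npv_diff=npv_d, npv_p=pval(draws_npv, npv_d),
        n_bootstrap=n_bootstrap)


def _diffs(records: Sequence[PolypRecord]) -> tuple[float | None, float | None]:
    pa, na = _pv(records, "cadx")
    pb, nb = _pv(records, "endoscopist")
    dp = pa - pb if pa is not None and pb is not None else None
    dn = na - nb if na is not None and nb is not None else None
    return dp, dn


# ---------------------------------------------------------------------------
# surveillance-interval agreement
# ---------------------------------------------------------------------------

RuleTable = Sequence[tuple[Callable[[Mapping[str, int]], bool], str]]

#: a simple, configurable default keyed on the number of neoplastic findings
#: per patient (the published rules are guideline-specific and supplied via
#: config in real use)
DEFAULT_SURVEILLANCE_RULES: RuleTable = (
    (lambda f: f["n_neoplastic"] == 0, "routine"),
    (lambda f: f["n_neoplastic"] <= 2, "5y"),
    (lambda f: f["n_neoplastic"] <= 4, "3y"),
    (lambda f: True, "1y"),
)


def _interval(findings: Mapping[str, int], rules: RuleTable) -> str:
    for pred, label in rules:
        if pred(findings):
            return label
    raise ValueError(f"no surveillance rule covers findings {dict(findings)}")


def _findings(records: Sequence[PolypRecord], labeler: Callable[[PolypRecord], str | None]) -> Mapping[str, int]:
    labels = [labeler(r) for r in records]
    labels = [x for x in labels if x is not None]
    return {
        "n_neoplastic": sum(is_neoplastic(x) for x in labels),
        "n_adenoma": sum(x == "adenoma" for x in labels),
        "n_ssl": sum(x == "ssl" for x in labels),
        "n_hyperplastic": sum(x == "hyperplastic" for x in labels),
    }


def surveillance_agreement(records: Sequence[PolypRecord], rater: str = "cadx",
                           rules: RuleTable = DEFAULT_SURVEILLANCE_RULES,
                           high_confidence_only: bool = True,
                           ci_method: str = "clopper-pearson") -> Estimate | None:
    """Fraction of patients whose follow-up interval from optical diagnosis
    equals the interval from histology, with CI."""
    by_patient: dict[str, list[PolypRecord]] = {}
    for r in records:
        by_patient.setdefault(r.patient_id, []).append(r)

    def optical(r: PolypRecord) -> str | None:
        if high_confidence_only and r.confidence(rater) != "high":
            return None
        return r.prediction(rater)

    agree = 0
    for recs in by_patient.values():
        i_opt = _interval(_findings(recs, optical), rules)
        i_hist = _interval(_findings(recs, lambda r: r.histology), rules)
        agree += i_opt == i_hist
    return proportion_estimate(agree, len(by_patient), ci_method)


# ---------------------------------------------------------------------------
# competence criteria
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompetenceCriterion:
    """One declarative threshold, e.g. 'NPV in the rectosigmoid >= 0.90'."""

    name: str
    metric: str        # accuracy | sensitivity | specificity | ppv | npv | agreement
    threshold: float
    comparison: str = "ge"


def competence_check(criteria: Sequence[CompetenceCriterion],
                     computed: Mapping[str, float | None]) -> dict[str, bool]:
    """Evaluate each criterion against pre-computed metric values (keyed by
    criterion metric name); a criterion referencing an absent metric errors."""
    out = {}
    for c in criteria:
        if c.metric not in computed or computed[c.metric] is None:
            raise KeyError(f"criterion {c.name!r} references absent metric {c.metric!r}")
        v = computed[c.metric]
        out[c.name] = v >= c.threshold if c.comparison == "ge" else v <= c.threshold
    return out


# ---------------------------------------------------------------------------
# sample size and power
# ---------------------------------------------------------------------------

def mcnemar_sample_size(alpha: float, power: float, discordance: float,
                        difference: float) -> int:
    """Pairs required for a two-sided paired McNemar comparison.

    With overall discordance psi (probability the two raters disagree on a
    lesion) and detectable accuracy difference delta:

        n = ceil( (z_{1-alpha/2} sqrt(psi) + z_{1-beta} sqrt(psi - delta^2))^2
                  / delta^2 )
    """
    psi, delta = discordance, difference
    if not 0 < delta <= psi < 1:
        raise ValueError("need 0 < difference <= discordance < 1")
    za = stats.norm.ppf(1 - alpha / 2)
    zb = stats.norm.ppf(power)
    n = (za * math.sqrt(psi) + zb * math.sqrt(psi - delta**2)) ** 2 / delta**2
    return math.ceil(n)


def patients_from_polyps(n_polyps: int, mean_polyps_per_colonoscopy: float,
                         dropout: float) -> int:
    """Patients needed to observe ``n_polyps`` given the per-colonoscopy polyp
    yield, inflated by the dropout rate: round((n/mean) * (1 + dropout)).

    The (1 + dropout) inflation (rather than division by 1 - dropout) is the
    documented convention of this package.
    """
    if mean_polyps_per_colonoscopy <= 0:
        raise ValueError("mean polyp yield must be positive")
    if not 0 <= dropout < 1:
        raise ValueError("dropout must be in [0, 1)")
    x = (n_polyps / mean_polyps_per_colonoscopy) * (1 + dropout)
    return int(math.floor(x + 0.5))


def mcnemar_power_simulation(n_pairs: int, discordance: float, difference: float,
                             alpha: float = 0.05, n_replicates: int = 10_000,
                             seed: int = 0, method: str = "asymptotic") -> float:
    """Empirical power of the paired comparison at the design alternative.

    Each replicate draws the discordant split (p10, p01) =
    ((psi + delta)/2, (psi - delta)/2) for n pairs and applies the two-sided
    McNemar test. ``method="asymptotic"`` uses the uncorrected chi-square
    (the test underlying the sample-size formula); ``method="cc"`` applies the
    continuity correction. Vectorized and deterministic under seed.
    """
    psi, delta = discordance, difference
    if not 0 < delta <= psi < 1:
        raise ValueError("need 0 < difference <= discordance < 1")
    rng = np.random.default_rng(seed)
    p10, p01 = (psi + delta) / 2, (psi - delta) / 2
    draws = rng.multinomial(n_pairs, [p10, p01, 1 - psi], size=n_replicates)
    b, c = draws[:, 0].astype(float), draws[:, 1].astype(float)
    t = b + c
    with np.errstate(divide="ignore", invalid="ignore"):
        if method == "cc":
            stat = np.where(t > 0, np.maximum(np.abs(b - c) - 1, 0) ** 2 / t, 0.0)
        elif method == "asymptotic":
            stat = np.where(t > 0, (b - c) ** 2 / t, 0.0)
        else:
            raise ValueError(f"unknown method {method!r}")
    crit = stats.chi2.ppf(1 - alpha, 1)
    return float(np.mean(stat > crit))
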