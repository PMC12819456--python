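"""Agreement and association statistics between two binary assessments.

Compares a test rater (e.g. bedside visual reading) against a reference
(e.g. computational post hoc analysis): sensitivity, specificity,
concordance, Cohen's kappa with its large-sample significance test, and the
odds ratio with a Woolf (log-normal) confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .errors import ParameterError, ValidationError


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts, test rater vs. reference: tp = both positive, fp = test
    positive only, fn = reference positive only, tn = both negative."""

    tp: int
    fp: int
    fn: int
    tn: int

    def validate(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValidationError("confusion counts must be non-negative")
        if self.n == 0:
            raise ValidationError("confusion matrix is empty")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class Proportion:
    value: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class AgreementStats:
    sensitivity: Proportion
    specificity: Proportion
    concordance: Proportion
    kappa: float
    kappa_ci: tuple[float, float]
    kappa_p: float
    po: float
    pe: float
    kappa_defined: bool


@dataclass(frozen=True)
class OddsRatioResult:
    or_value: float
    ci_low: float
    ci_high: float
    continuity_corrected: bool
    defined: bool


def build_confusion(test_labels, reference_labels) -> ConfusionMatrix:
    """Cross-tabulate two binary label vectors (test, reference)."""
    t = np.asarray(test_labels).astype(bool)
    r = np.asarray(reference_labels).astype(bool)
    if t.shape != r.shape:
        raise ValidationError(
            f"label vectors differ in length: {t.shape} vs {r.shape}")
    return ConfusionMatrix(tp=int(np.sum(t & r)), fp=int(np.sum(t & ~r)),
                           fn=int(np.sum(~t & r)), tn=int(np.sum(~t & ~r)))


def _wilson(k: int, n: int) -> Proportion:
    if n == 0:
        return Proportion(np.nan, np.nan, np.nan)
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return Proportion(k / n, float(lo), float(hi))


def proportion(k: int, n: int) -> Proportion:
    """A simple proportion with its 95% Wilson interval (e.g. the fraction of
    false negatives occurring in a patient stratum)."""
    if not 0 <= k <= n:
        raise ParameterError("need 0 <= k <= n")
    return _wilson(k, n)


def agreement_stats(cm: ConfusionMatrix) -> AgreementStats:
    """Sensitivity / specificity / concordance with Wilson CIs, and Cohen's
    kappa with a normal-approximation CI and large-sample H0 p-value.

    kappa = (po - pe) / (1 - pe) with po the observed agreement and pe the
    chance agreement from the row/column margins. Degenerate margins
    (pe = 1) yield a flagged, undefined kappa rather than an exception.
    """
    cm.validate()
    n = cm.n
    sens = _wilson(cm.tp, cm.tp + cm.fn)
    spec = _wilson(cm.tn, cm.tn + cm.fp)
    conc = _wilson(cm.tp + cm.tn, n)

    po = (cm.tp + cm.tn) / n
    p_test_pos = (cm.tp + cm.fp) / n
    p_ref_pos = (cm.tp + cm.fn) / n
    pe = p_test_pos * p_ref_pos + (1 - p_test_pos) * (1 - p_ref_pos)
    if pe >= 1.0:
        return AgreementStats(sens, spec, conc, np.nan, (np.nan, np.nan),
                              np.nan, po, pe, kappa_defined=False)
    kappa = (po - pe) / (1 - pe)

    # large-sample SE under H0: kappa = 0 (Fleiss/Cohen)
    margins = [(p_test_pos, p_ref_pos), (1 - p_test_pos, 1 - p_ref_pos)]
    s = sum(pi * qi * (pi + qi) for pi, qi in margins)
    se0 = np.sqrt(max(pe + pe**2 - s, 0.0)) / ((1 - pe) * np.sqrt(n))
    if se0 > 0:
        z = kappa / se0
        kappa_p = 2 * stats.norm.sf(abs(z))
    else:
        kappa_p = np.nan
    se = np.sqrt(po * (1 - po) / n) / (1 - pe)
    ci = (kappa - 1.96 * se, min(kappa + 1.96 * se, 1.0))
    return AgreementStats(sens, spec, conc, float(kappa), ci, float(kappa_p),
                          po, pe, kappa_defined=True)


def odds_ratio(cm: ConfusionMatrix) -> OddsRatioResult:
    """Cross-product odds ratio with Woolf 95% CI.

    The 2x2 table is read as exposure x outcome with a = tp, b = fp, c = fn,
    d = tn. Any zero cell triggers the Haldane-Anscombe +0.5 correction to
    all cells; two zero cells on a cross-diagonal make the OR undefined
    (flagged, not raised).
    """
    cm.validate()
    a, b, c, d = float(cm.tp), float(cm.fp), float(cm.fn), float(cm.tn)
    if (a == 0 and d == 0) or (b == 0 and c == 0):
        return OddsRatioResult(np.nan, np.nan, np.nan, False, defined=False)
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_value = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = np.exp(np.log(or_value) - 1.96 * se)
    hi = np.exp(np.log(or_value) + 1.96 * se)
    return OddsRatioResult(float(or_value), float(lo), float(hi),
                           continuity_corrected=corrected, defined=True)


def simulate_agreement_study(n: int, prevalence: float, rater_sens: float,
                             rater_spec: float, seed: int
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Seeded reference labels ~ Bernoulli(prevalence) and test labels drawn
    conditionally with the stated sensitivity / specificity."""
    for name, v in [("prevalence", prevalence), ("rater_sens", rater_sens),
                    ("rater_spec", rater_spec)]:
        if not 0 <= v <= 1:
            raise ParameterError(f"{name} must be in [0, 1]")
    if n <= 0:
        raise ParameterError("n must be positive")
    rng = np.random.default_rng(seed)
    ref = rng.random(n) < prevalence
    test = np.where(ref, rng.random(n) < rater_sens,
                    rng.random(n) >= rater_spec)
    return test.astype(bool), ref.astype(bool)


def expected_kappa(prevalence: float, rater_sens: float, rater_spec: float) -> float:
    """Closed-form population kappa for a rater with the given operating point
    against a Bernoulli(prevalence) reference."""
    pi = prevalence
    po = pi * rater_sens + (1 - pi) * rater_spec
    tau = pi * rater_sens + (1 - pi) * (1 - rater_spec)  # test-positive rate
    pe = pi * tau + (1 - pi) * (1 - tau)
    return (po - pe) / (1 - pe)
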