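"""Screening-performance statistics against a truth table.

A sample is *positive* when its true copy pair differs from the wild-type
(2, 2) — i.e. it carries an abnormal α-globin gene copy number — and a call
is *predicted positive* when the called pair differs from (2, 2). Sensitivity
and specificity come with exact (Clopper–Pearson) binomial 95% confidence
intervals: for k = n successes the lower bound is (α/2)^(1/n).

Ambiguity policy: flagged calls (``ambiguous`` / ``improbable_reference``)
are by default counted as *discordant* with the truth, the conservative
choice for a screening claim; alternatively they can be taken at face value
(``as-called``) or dropped from the denominators (``excluded``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .calling import CopyNumberCall
from .errors import ValidationInputError

__all__ = [
    "ConfusionCounts",
    "ValidationReport",
    "confusion",
    "exact_binomial_ci",
    "run_validation",
]

AmbiguousPolicy = Literal["as-discordant", "as-called", "excluded"]

WILD_TYPE_PAIR = (2, 2)


@dataclass(frozen=True)
class ConfusionCounts:
    true_positives: int
    false_negatives: int
    true_negatives: int
    false_positives: int

    @property
    def n_total(self) -> int:
        return (
            self.true_positives
            + self.false_negatives
            + self.true_negatives
            + self.false_positives
        )

    @property
    def n_positive_truth(self) -> int:
        return self.true_positives + self.false_negatives

    @property
    def n_negative_truth(self) -> int:
        return self.true_negatives + self.false_positives


@dataclass(frozen=True)
class ValidationReport:
    counts: ConfusionCounts
    sensitivity: float | None
    specificity: float | None
    sensitivity_ci95: tuple[float, float] | None
    specificity_ci95: tuple[float, float] | None
    confidence: float = 0.95

    def to_text(self) -> str:
        c = self.counts
        def fmt(p, ci):
            if p is None:
                return "n/a (no samples in this class)"
            lo, hi = ci
            return f"{100 * p:.1f}% (95% CI {100 * lo:.1f}-{100 * hi:.1f}%)"

        return "\n".join(
            [
                f"samples:      {c.n_total} "
                f"({c.n_positive_truth} abnormal, {c.n_negative_truth} normal by truth)",
                f"TP={c.true_positives}  FN={c.false_negatives}  "
                f"TN={c.true_negatives}  FP={c.false_positives}",
                f"sensitivity:  {fmt(self.sensitivity, self.sensitivity_ci95)}",
                f"specificity:  {fmt(self.specificity, self.specificity_ci95)}",
            ]
        )

    def to_frame(self) -> pd.DataFrame:
        c = self.counts
        row = {
            "n_total": c.n_total,
            "n_positive_truth": c.n_positive_truth,
            "n_negative_truth": c.n_negative_truth,
            "true_positives": c.true_positives,
            "false_negatives": c.false_negatives,
            "true_negatives": c.true_negatives,
            "false_positives": c.false_positives,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "sensitivity_ci95_low": self.sensitivity_ci95 and self.sensitivity_ci95[0],
            "sensitivity_ci95_high": self.sensitivity_ci95 and self.sensitivity_ci95[1],
            "specificity_ci95_low": self.specificity_ci95 and self.specificity_ci95[0],
            "specificity_ci95_high": self.specificity_ci95 and self.specificity_ci95[1],
        }
        return pd.DataFrame([row])


def _truth_pairs(truth) -> dict[str, tuple[int, int]]:
    if isinstance(truth, pd.DataFrame):
        need = {"sample_id", "hba1_copies", "hba2_copies"}
        if not need.issubset(truth.columns):
            raise ValidationInputError(
                f"truth table needs columns {sorted(need)}, got {list(truth.columns)}"
            )
        return {
            str(r.sample_id): (int(r.hba1_copies), int(r.hba2_copies))
            for r in truth.itertuples()
        }
    return {str(k): (int(v[0]), int(v[1])) for k, v in dict(truth).items()}


def confusion(
    calls: Iterable[CopyNumberCall],
    truth: pd.DataFrame | Mapping[str, tuple[int, int]],
    ambiguous: AmbiguousPolicy = "as-discordant",
) -> ConfusionCounts:
    """Confusion counts of abnormal-vs-normal screening calls against truth."""
    calls = list(calls)
    if not calls:
        raise ValidationInputError("no calls to validate")
    pairs = _truth_pairs(truth)
    tp = fn = tn = fp = 0
    for call in calls:
        if call.sample_id not in pairs:
            raise ValidationInputError(
                f"sample {call.sample_id!r} has no truth entry"
            )
        truth_positive = pairs[call.sample_id] != WILD_TYPE_PAIR
        if call.is_flagged:
            if ambiguous == "excluded":
                continue
            if ambiguous == "as-discordant":
                # A flagged call is treated as a miscall whatever it says.
                if truth_positive:
                    fn += 1
                else:
                    fp += 1
                continue
            # "as-called" falls through to face value.
        called_positive = call.copy_pair != WILD_TYPE_PAIR
        if truth_positive and called_positive:
            tp += 1
        elif truth_positive:
            fn += 1
        elif called_positive:
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(tp, fn, tn, fp)


def exact_binomial_ci(
    successes: int, trials: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Exact (Clopper–Pearson) binomial confidence interval as proportions."""
    if trials < 1 or not 0 <= successes <= trials:
        raise ValueError(f"invalid counts: {successes}/{trials}")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    lo, hi = proportion_confint(successes, trials, alpha=1 - confidence, method="beta")
    # statsmodels returns NaN at the closed ends; the exact bounds there are 0/1.
    lo = 0.0 if successes == 0 or lo != lo else float(lo)
    hi = 1.0 if successes == trials or hi != hi else float(hi)
    return lo, hi


def run_validation(
    calls: Iterable[CopyNumberCall],
    truth: pd.DataFrame | Mapping[str, tuple[int, int]],
    ambiguous: AmbiguousPolicy = "as-discordant",
    confidence: float = 0.95,
) -> ValidationReport:
    """Confusion counts plus sensitivity/specificity with exact CIs.

    With zero truth-positive (or truth-negative) samples, the corresponding
    rate is reported as ``None`` (not applicable), never as 0.
    """
    c = confusion(calls, truth, ambiguous)
    if c.n_positive_truth:
        sens = c.true_positives / c.n_positive_truth
        sens_ci = exact_binomial_ci(c.true_positives, c.n_positive_truth, confidence)
    else:
        sens, sens_ci = None, None
    if c.n_negative_truth:
        spec = c.true_negatives / c.n_negative_truth
        spec_ci = exact_binomial_ci(c.true_negatives, c.n_negative_truth, confidence)
    else:
        spec, spec_ci = None, None
    return ValidationReport(c, sens, spec, sens_ci, spec_ci, confidence)
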