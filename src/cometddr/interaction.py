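"""Interaction Factor: additive-scale epistasis test between repair pathways.

For a wild-type strain, two single pathway mutants and their double mutant,
the Interaction Factor compares the double mutant's induced damage with the
sum of the single mutants' effects on the additive scale:

    IF = (induced_wt + induced_double) - (induced_mut1 + induced_mut2)

where each term is a treated-minus-control study-level mean tail moment.
Under additivity (independent pathways) IF = 0.  Its standard error is
propagated from the eight underlying condition SEs assuming independence,

    SE(IF) = sqrt( sum over the 8 cells of SE^2 ),

and a normal-quantile confidence interval classifies the verdict:
``synergistic`` when the CI lies above 0, ``antagonistic`` below 0,
``additive`` when 0 is inside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .records import ConditionSummary
from .stats import TestResult

__all__ = [
    "InteractionResult",
    "interaction_factor",
    "if_standard_error",
    "if_confidence_interval",
    "classify_interaction",
    "interaction_from_summaries",
    "per_experiment_interaction",
]


@dataclass(frozen=True)
class InteractionResult:
    if_value: float
    se_if: float
    ci_low: float
    ci_high: float
    level: float
    verdict: str
    dose: float | None = None

    def __post_init__(self) -> None:
        if self.se_if < 0:
            raise ValueError("se_if must be >= 0")
        if not self.ci_low <= self.if_value <= self.ci_high:
            raise ValueError("confidence interval must bracket the point estimate")


def interaction_factor(
    induced_wt: float,
    induced_double: float,
    induced_mut1: float,
    induced_mut2: float,
) -> float:
    """(wt + double) - (mut1 + mut2) on the induced-TM scale."""
    return (induced_wt + induced_double) - (induced_mut1 + induced_mut2)


def if_standard_error(*ses: float) -> float:
    """Propagated SE of the IF: root of the sum of the squared condition SEs.

    Takes the eight standard errors (negative control and treated, for each
    of the four strains, in any order); independence of the condition means
    is assumed.
    """
    if len(ses) != 8:
        raise ValueError(f"expected the 8 condition SEs, got {len(ses)}")
    if any(s < 0 for s in ses):
        raise ValueError("standard errors must be non-negative")
    return math.sqrt(sum(s * s for s in ses))


def if_confidence_interval(
    if_value: float, se_if: float, level: float = 0.95
) -> tuple[float, float]:
    """Normal-quantile CI: ``if_value +/- z_{1-(1-level)/2} * se_if``."""
    if se_if < 0:
        raise ValueError("se_if must be >= 0")
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must be in (0, 1), got {level!r}")
    z = sps.norm.ppf(1 - (1 - level) / 2)
    return if_value - z * se_if, if_value + z * se_if

def classify_interaction(ci_low: float, ci_high: float) -> str:
    """``additive`` if 0 is inside the closed CI, else the sign of the effect."""
    if ci_low > ci_high:
        raise ValueError("ci_low must not exceed ci_high")
    if ci_low > 0:
        return "synergistic"
    if ci_high < 0:
        return "antagonistic"
    return "additive"


def _cell(
    summaries: Sequence[ConditionSummary], strain: str, dose: float, extract: str
) -> ConditionSummary:
    for s in summaries:
        if (
            s.strain == strain
            and np.isclose(s.dose, dose)
            and s.extract == extract
            and s.level == "study"
        ):
            return s
    raise KeyError(f"no study summary for strain={strain!r} dose={dose} extract={extract!r}")


def interaction_from_summaries(
    summaries: Sequence[ConditionSummary],
    dose: float,
    wt: str = "OK",
    mut1: str = "mus201",
    mut2: str = "mus308",
    double: str = "mus201;mus308",
    control_dose: float = 0.0,
    extract: str = "none",
    level: float = 0.95,
) -> InteractionResult:
    """Full IF pipeline from study-level summaries at one dose.

    Looks up the treated and control cells of the four strains, forms the
    induced TMs, the IF, its propagated SE and the normal-quantile CI, and
    classifies the verdict.
    """
    cells = {}
    for strain in (wt, double, mut1, mut2):
        cells[strain] = (
            _cell(summaries, strain, control_dose, extract),
            _cell(summaries, strain, dose, extract),
        )
    induced = {s: t.mean_tm - c.mean_tm for s, (c, t) in cells.items()}
    value = interaction_factor(induced[wt], induced[double], induced[mut1], induced[mut2])
    ses = [se for c, t in cells.values() for se in (c.se_tm, t.se_tm)]
    se = if_standard_error(*ses)
    lo, hi = if_confidence_interval(value, se, level)
    return InteractionResult(
        if_value=value,
        se_if=se,
        ci_low=lo,
        ci_high=hi,
        level=level,
        verdict=classify_interaction(lo, hi),
        dose=dose,
    )


def per_experiment_interaction(
    exp_means: "Mapping[str, Mapping[str, Sequence[float]]] | object",
    dose: float,
    wt: str = "OK",
    mut1: str = "mus201",
    mut2: str = "mus308",
    double: str = "mus201;mus308",
    control_dose: float = 0.0,
) -> tuple[np.ndarray, TestResult]:
    """Sensitivity analysis: per-experiment IFs and a one-sample t-test vs 0.

    This is an extension beyond the study-level IF: it computes one IF per
    experiment (pairing conditions by experiment) and tests their mean
    against zero.  ``exp_means`` is the frame from
    :func:`cometddr.stats.experiment_means`.
    """
    df = exp_means
    ifs = []
    exps = sorted(df["experiment_id"].unique())
    for e in exps:
        sub = df[df["experiment_id"] == e]

        def cell(strain: str, d: float) -> float:
            m = sub[(sub["strain"] == strain) & np.isclose(sub["dose"], d)]
            if len(m) != 1:
                raise ValueError(
                    f"experiment {e!r}: expected one mean for {strain!r} at {d}"
                )
            return float(m["mean_tm"].iloc[0])

        induced = {
            s: cell(s, dose) - cell(s, control_dose) for s in (wt, double, mut1, mut2)
        }
        ifs.append(
            interaction_factor(induced[wt], induced[double], induced[mut1], induced[mut2])
        )
    arr = np.asarray(ifs)
    if arr.size < 2 or np.ptp(arr) == 0:
        test = TestResult(0.0, 1.0, "one-sample-t", arr.size, 1, degenerate=True)
    else:
        res = sps.ttest_1samp(arr, 0.0)
        test = TestResult(
            float(res.statistic), float(res.pvalue), "one-sample-t", int(arr.size), 1
        )
    return arr, test
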