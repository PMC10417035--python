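"""Simulation-based calibration of the Interaction Factor verdict.

Runs many replicate synthetic studies through the full pipeline (generator
-> experiment means -> study summary -> IF with propagated SE) to measure
how often the verdict is ``additive`` when the ground truth is exactly
additive, and ``synergistic`` when a known synergy offset is injected into
the double mutant.  Because the propagated SE assumes independent condition
means while treated and control share an experiment effect, the additive
coverage is expected to be conservative (above the nominal level).
"""

from __future__ import annotations

import dataclasses
from collections import Counter

import numpy as np

from .interaction import interaction_from_summaries
from .simulate import GeneratorParams
from .simulate import generate_invivo_study
from .stats import experiment_means, study_summary

__all__ = ["additive_params", "simulate_if_verdicts", "if_calibration"]


def additive_params(
    base: GeneratorParams = GeneratorParams(),
    dose: float = 0.5,
    synergy_offset: float = 0.0,
    double: str = "mus201;mus308",
    wt: str = "OK",
    mut1: str = "mus201",
    mut2: str = "mus308",
) -> GeneratorParams:
    """Generator parameters with an exactly additive double mutant.

    The double mutant's induced slope is set so that at every dose its
    induced damage equals ``mut1 + mut2 - wt`` (IF = 0), plus an optional
    ``synergy_offset`` added at the evaluation ``dose``.  Only the control
    and the evaluation dose are simulated (the IF uses no other cells).
    """
    slopes = dict(base.dose_slopes)
    additive_slope = slopes[mut1] + slopes[mut2] - slopes[wt]
    slopes[double] = additive_slope + synergy_offset / dose
    return dataclasses.replace(
        base, dose_slopes=slopes, plateau_induced={}, doses=(0.0, dose)
    )


def simulate_if_verdicts(
    n_reps: int,
    seed: int,
    params: GeneratorParams,
    dose: float = 0.5,
) -> tuple[list[str], np.ndarray]:
    """Verdicts and propagated SEs of the IF over replicate studies."""
    rng = np.random.default_rng(seed)
    verdicts: list[str] = []
    ses = np.empty(n_reps)
    for i in range(n_reps):
        study_seed = int(rng.integers(0, 2**31 - 1))
        df = generate_invivo_study(params, seed=study_seed)
        summaries = study_summary(experiment_means(df))
        res = interaction_from_summaries(summaries, dose)
        verdicts.append(res.verdict)
        ses[i] = res.se_if
    return verdicts, ses


def if_calibration(
    n_reps: int = 500,
    seed: int = 0,
    dose: float = 0.5,
    base: GeneratorParams = GeneratorParams(),
) -> dict[str, float]:
    """Two-phase calibration: additive coverage, then synergy power.

    Phase 1 simulates ``n_reps`` studies under exact additivity and reports
    the fraction with verdict ``additive``.  Phase 2 injects a synergy
    offset of 4 x (median propagated SE from phase 1) into the double mutant
    and reports the fraction with verdict ``synergistic``.
    """
    verdicts, ses = simulate_if_verdicts(n_reps, seed, additive_params(base, dose), dose)
    additive_rate = Counter(verdicts)["additive"] / n_reps
    offset = 4.0 * float(np.median(ses))
    verdicts2, _ = simulate_if_verdicts(
        n_reps, seed + 1, additive_params(base, dose, synergy_offset=offset), dose
    )
    synergy_rate = Counter(verdicts2)["synergistic"] / n_reps
    return {
        "additive_rate": additive_rate,
        "synergy_rate": synergy_rate,
        "synergy_offset": offset,
    }
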