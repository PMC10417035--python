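"""Ex vivo comet pipeline: protein adjustment and relative incision activity.

In the ex vivo assay, nucleoids from in-vivo treated or untreated wild-type
larvae are incubated with cell-free protein extracts (or plain reaction
buffer).  Extra strand breaks over the buffer lane measure the extract's
incision activity.  Each repair-mutant extract (MR) is expressed relative to
the efficient-repair extract (ER), separately for spontaneous and induced
damage:

    activity_spontaneous(%) = 100 * (MRBC - BC) / (ERBC - BC)
    activity_induced(%)     = 100 * (MRTC - TC) / (ERTC - TC)

with BC/TC the buffer-incubated untreated/treated means and *BC/*TC the
extract-incubated counterparts.  Extract lanes are first adjusted for
protein content by multiplicative normalization to a common reference
concentration (buffer lanes contain no extract and are left unadjusted).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .records import ConditionSummary
from .stats import TestResult, experiment_means, paired_t_across_experiments

__all__ = [
    "RelativeActivityResult",
    "ExVivoStudyResult",
    "adjust_for_protein",
    "relative_activity_spontaneous",
    "relative_activity_induced",
    "exvivo_study",
]

_DENOM_RTOL = 1e-9

#: Disagreement (percentage points) between the per-experiment-averaged and
#: the plug-in (study-mean) activity estimates above which the result is
#: flagged as a nonlinearity diagnostic.
ESTIMATE_DISAGREEMENT_POINTS = 5.0


@dataclass(frozen=True)
class RelativeActivityResult:
    """Relative incision activity of one extract, % of the ER extract.

    ``activity_pct`` is the mean of per-experiment estimates and ``se_pct``
    their SE over ``n_experiments``; ``plug_in_pct`` applies the ratio
    formula to the study-level means instead.  Values are never clipped:
    they may exceed 100 or go negative.
    """

    extract: str
    kind: str  # "spontaneous" | "induced"
    activity_pct: float
    se_pct: float
    n_experiments: int
    plug_in_pct: float = float("nan")
    estimates_disagree: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("spontaneous", "induced"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if not math.isnan(self.se_pct) and self.se_pct < 0:
            raise ValueError("se_pct must be >= 0")


@dataclass
class ExVivoStudyResult:
    """Adjusted condition means, relative activities and significance tests."""

    condition_summaries: list[ConditionSummary]
    activities: list[RelativeActivityResult]
    treatment_tests: dict[str, TestResult] = field(default_factory=dict)
    vs_buffer_tests: dict[tuple[str, str], TestResult] = field(default_factory=dict)
    vs_er_tests: dict[tuple[str, str], TestResult] = field(default_factory=dict)

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {
                "extract": s.extract,
                "treatment": "treated" if s.dose > 0 else "untreated",
                "mean_tm": s.mean_tm,
                "se_tm": s.se_tm,
                "n": s.n,
            }
            for s in self.condition_summaries
        ]
        return pd.DataFrame(rows)

    def activity_frame(self) -> pd.DataFrame:
        rows = [
            {
                "extract": a.extract,
                "kind": a.kind,
                "activity_pct": a.activity_pct,
                "se_pct": a.se_pct,
                "n_experiments": a.n_experiments,
                "plug_in_pct": a.plug_in_pct,
                "estimates_disagree": a.estimates_disagree,
            }
            for a in self.activities
        ]
        return pd.DataFrame(rows)


def adjust_for_protein(
    mean_tm: float, protein_conc: float, reference_conc: float
) -> float:
    """Normalize a TM mean to equal protein input.

    ``adjusted = mean_tm * reference_conc / protein_conc`` — an extract with
    more protein than the reference gets its signal scaled down
    proportionally.
    """
    if protein_conc <= 0:
        raise ValueError(f"protein_conc must be > 0, got {protein_conc!r}")
    if reference_conc <= 0:
        raise ValueError(f"reference_conc must be > 0, got {reference_conc!r}")
    return mean_tm * reference_conc / protein_conc


def _relative_activity(mr: float, er: float, baseline: float, what: str) -> float:
    denom = er - baseline
    scale = max(abs(er), abs(baseline), 1.0)
    if abs(denom) < _DENOM_RTOL * scale:
        raise ZeroDivisionError(
            f"undefined {what} activity: efficient-repair extract produced no "
            f"incision signal over baseline (ER={er!r}, baseline={baseline!r})"
        )
    return 100.0 * (mr - baseline) / denom


def relative_activity_spontaneous(mrbc: float, erbc: float, bc: float) -> float:
    """Mutant extract's activity on spontaneous damage, % of the ER extract."""
    return _relative_activity(mrbc, erbc, bc, "spontaneous")


def relative_activity_induced(mrtc: float, ertc: float, tc: float) -> float:
    """Mutant extract's activity on induced damage, % of the ER extract."""
    return _relative_activity(mrtc, ertc, tc, "induced")


def _check_design(
    exp: pd.DataFrame, buffer_label: str, er_label: str, doses: Sequence[float]
) -> None:
    extracts = sorted(exp["extract"].unique())
    if buffer_label not in extracts:
        raise ValueError(f"missing buffer lane {buffer_label!r}")
    if er_label not in extracts:
        raise ValueError(f"missing efficient-repair extract {er_label!r}")
    if len(extracts) < 3:
        raise ValueError("need at least one mutant-repair extract besides buffer and ER")
    experiments = sorted(exp["experiment_id"].unique())
    if len(experiments) < 2:
        raise ValueError("need at least 2 experiments")
    missing = []
    for ext in extracts:
        for d in doses:
            for e in experiments:
                m = exp[
                    (exp["extract"] == ext)
                    & np.isclose(exp["dose"], d)
                    & (exp["experiment_id"] == e)
                ]
                if m.empty:
                    missing.append((ext, d, e))
    if missing:
        raise ValueError(f"missing design cells (extract, dose, experiment): {missing}")


def exvivo_study(
    records: pd.DataFrame,
    protein_conc: Mapping[str, float],
    er_label: str = "OK",
    buffer_label: str = "buffer",
    control_dose: float = 0.0,
    treated_dose: float = 1.0,
    reference_conc: float | None = None,
    exclude_hedgehogs: bool = False,
) -> ExVivoStudyResult:
    """Run the full ex vivo analysis on a per-nucleoid records table.

    Steps: pool nucleoids into per-experiment means per (extract x
    treatment); protein-adjust extract lanes (buffer unadjusted) to
    ``reference_conc`` (default: mean of the extract concentrations);
    summarize at study level; compute per-experiment relative activities for
    every mutant extract, averaged across experiments with their SE; run
    treated-vs-untreated, extract-vs-buffer and extract-vs-ER paired t-tests
    on the experiment means.
    """
    exp = experiment_means(
        records, group_keys=["extract", "dose"], exclude_hedgehogs=exclude_hedgehogs
    )
    doses = (control_dose, treated_dose)
    _check_design(exp, buffer_label, er_label, doses)
    extracts = sorted(exp["extract"].unique())
    mutant_extracts = [e for e in extracts if e not in (buffer_label, er_label)]
    experiments = sorted(exp["experiment_id"].unique())

    if reference_conc is None:
        reference_conc = float(np.mean([protein_conc[e] for e in extracts if e != buffer_label]))
    adj = exp.copy()
    factors = adj["extract"].map(
        lambda e: 1.0 if e == buffer_label else reference_conc / protein_conc[e]
    )
    adj["mean_tm"] = adj["mean_tm"] * factors

    def cell_series(ext: str, d: float) -> np.ndarray:
        sub = adj[(adj["extract"] == ext) & np.isclose(adj["dose"], d)]
        sub = sub.set_index("experiment_id").loc[experiments]
        return sub["mean_tm"].to_numpy(dtype=float)

    # Study-level adjusted summaries.
    summaries: list[ConditionSummary] = []
    cells: dict[tuple[str, float], np.ndarray] = {}
    for ext in extracts:
        for d in doses:
            vals = cell_series(ext, d)
            cells[(ext, d)] = vals
            summaries.append(
                ConditionSummary(
                    strain="",
                    dose=d,
                    extract=ext,
                    level="study",
                    mean_tm=float(vals.mean()),
                    se_tm=float(np.std(vals, ddof=1) / np.sqrt(vals.size)),
                    n=int(vals.size),
                )
            )

    def study_mean(ext: str, d: float) -> float:
        return float(cells[(ext, d)].mean())

    # Warn when the ER-over-buffer increment is unstable relative to its SE.
    for d, what in ((control_dose, "spontaneous"), (treated_dose, "induced")):
        diff = cells[(er_label, d)] - cells[(buffer_label, d)]
        se_diff = float(np.std(diff, ddof=1) / np.sqrt(diff.size))
        if abs(diff.mean()) < 0.5 * se_diff:
            warnings.warn(
                f"unstable {what} activity denominator: |ER - buffer| < 0.5 SE",
                stacklevel=2,
            )

    activities: list[RelativeActivityResult] = []
    for kind, d, formula in (
        ("spontaneous", control_dose, relative_activity_spontaneous),
        ("induced", treated_dose, relative_activity_induced),
    ):
        for ext in [er_label] + mutant_extracts:
            per_exp = np.array(
                [
                    formula(
                        cells[(ext, d)][i],
                        cells[(er_label, d)][i],
                        cells[(buffer_label, d)][i],
                    )
                    for i in range(len(experiments))
                ]
            )
            plug_in = formula(
                study_mean(ext, d), study_mean(er_label, d), study_mean(buffer_label, d)
            )
            mean_act = float(per_exp.mean())
            se_act = float(np.std(per_exp, ddof=1) / np.sqrt(per_exp.size))
            activities.append(
                RelativeActivityResult(
                    extract=ext,
                    kind=kind,
                    activity_pct=mean_act,
                    se_pct=se_act,
                    n_experiments=int(per_exp.size),
                    plug_in_pct=plug_in,
                    estimates_disagree=abs(mean_act - plug_in)
                    > ESTIMATE_DISAGREEMENT_POINTS,
                )
            )

    treatment_tests = {
        ext: paired_t_across_experiments(
            cells[(ext, treated_dose)], cells[(ext, control_dose)], experiments
        )
        for ext in extracts
    }
    vs_buffer_tests = {
        (ext, kind): paired_t_across_experiments(
            cells[(ext, d)], cells[(buffer_label, d)], experiments
        )
        for ext in extracts
        if ext != buffer_label
        for kind, d in (("spontaneous", control_dose), ("induced", treated_dose))
    }
    vs_er_tests = {
        (ext, kind): paired_t_across_experiments(
            cells[(ext, d)], cells[(er_label, d)], experiments
        )
        for ext in mutant_extracts
        for kind, d in (("spontaneous", control_dose), ("induced", treated_dose))
    }
    return ExVivoStudyResult(
        condition_summaries=summaries,
        activities=activities,
        treatment_tests=treatment_tests,
        vs_buffer_tests=vs_buffer_tests,
        vs_er_tests=vs_er_tests,
    )
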