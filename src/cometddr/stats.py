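"""Two-tier treatment-vs-control statistics for comet tail moments.

Nucleoid-level tail-moment distributions are right-skewed, so within one
experiment treated and control gels are compared with the non-parametric
Mann-Whitney U-test.  Experiment means, in contrast, are close to normal, so
cross-experiment comparisons use paired Student t-tests, pairing by
experiment.  The unit of replication for study-level summaries is the
independent experiment: nucleoids from the gels of one condition are pooled
into one experiment mean, and the study mean and SE are taken over those
experiment means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .records import ConditionSummary

__all__ = [
    "TestResult",
    "significance_code",
    "mann_whitney_u",
    "experiment_means",
    "study_summary",
    "paired_t_across_experiments",
]

#: Largest n1*n2 for which the exact (enumerative) Mann-Whitney null
#: distribution is used when the pooled sample is tie-free.
EXACT_MW_LIMIT = 400

CONDITION_KEYS = ["strain", "dose", "extract"]


def significance_code(p_value: float) -> str:
    """Conventional star code: ``***`` p<0.001, ``**`` p<0.01, ``*`` p<0.05."""
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    test_name: str
    n1: int
    n2: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value out of [0, 1]: {self.p_value!r}")

    @property
    def significance_code(self) -> str:
        return significance_code(self.p_value)


def mann_whitney_u(
    treated_tms: Sequence[float],
    control_tms: Sequence[float],
    alternative: str = "two-sided",
) -> TestResult:
    """Mann-Whitney U-test of treated vs control tail moments.

    The reported statistic is U for the treated sample.  The exact null
    distribution is used when ``n1 * n2 <= EXACT_MW_LIMIT`` and the pooled
    sample has no ties; otherwise the normal approximation with midrank tie
    correction and continuity correction is used.  Two identical constant
    samples give p = 1 rather than an error.
    """
    x = np.asarray(treated_tms, dtype=float)
    y = np.asarray(control_tms, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:  # all values identical: no information
        return TestResult(
            statistic=x.size * y.size / 2.0,
            p_value=1.0,
            test_name="mann-whitney-u",
            n1=int(x.size),
            n2=int(y.size),
            degenerate=True,
        )
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size * y.size <= EXACT_MW_LIMIT and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        test_name=f"mann-whitney-u ({method})",
        n1=int(x.size),
        n2=int(y.size),
    )


def experiment_means(
    records: pd.DataFrame,
    group_keys: Sequence[str] = CONDITION_KEYS,
    exclude_hedgehogs: bool = False,
) -> pd.DataFrame:
    """One mean TM per condition x experiment, pooling that experiment's gels.

    Returns a frame with ``group_keys``, ``experiment_id``, ``mean_tm``,
    ``n_nucleoids`` and ``hedgehog_fraction`` columns.  Conditions with zero
    records after filtering are dropped with a warning.
    """
    df = records
    if exclude_hedgehogs:
        kept = df[~df["hedgehog_flag"].astype(bool)]
        dropped = (
            df.groupby(list(group_keys), sort=False, observed=True)
            .size()
            .index.difference(
                kept.groupby(list(group_keys), sort=False, observed=True).size().index
            )
        )
        if len(dropped):
            warnings.warn(
                f"conditions with only hedgehog comets dropped: {list(dropped)}",
                stacklevel=2,
            )
        df = kept
    keys = list(group_keys) + ["experiment_id"]
    out = (
        df.groupby(keys, sort=False, observed=True)
        .agg(
            mean_tm=("tail_moment", "mean"),
            n_nucleoids=("tail_moment", "size"),
            hedgehog_fraction=("hedgehog_flag", "mean"),
        )
        .reset_index()
    )
    return out


def study_summary(
    exp_means: pd.DataFrame,
    group_keys: Sequence[str] = CONDITION_KEYS,
) -> list[ConditionSummary]:
    """Study-level summaries: mean of experiment means, SE over experiments.

    ``SE = sd(experiment means) / sqrt(n_experiments)`` with the n-1 sample
    standard deviation.  A condition represented by a single experiment gets
    ``se_tm = nan`` and a warning (SE undefined).
    """
    out: list[ConditionSummary] = []
    for key, grp in exp_means.groupby(list(group_keys), sort=False, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        cond = dict(zip(group_keys, key))
        vals = grp["mean_tm"].to_numpy(dtype=float)
        n = vals.size
        if n < 2:
            warnings.warn(
                f"single experiment for condition {cond}; SE undefined", stacklevel=2
            )
            se = float("nan")
        else:
            se = float(np.std(vals, ddof=1) / np.sqrt(n))
        out.append(
            ConditionSummary(
                strain=cond.get("strain", ""),
                dose=float(cond.get("dose", np.nan)),
                extract=cond.get("extract", "none"),
                level="study",
                mean_tm=float(vals.mean()),
                se_tm=se,
                n=int(n),
            )
        )
    return out


def paired_t_across_experiments(
    means_a: Sequence[float],
    means_b: Sequence[float],
    experiment_ids: Sequence[str] | None = None,
) -> TestResult:
    """Two-sided paired Student t-test on experiment means.

    The vectors must be paired by experiment (same order; pass
    ``experiment_ids`` to have mismatches reported by label).  Degenerate
    cases never raise: all differences zero gives p = 1; constant non-zero
    differences (zero variance) give p = 0 with ``degenerate=True``.
    """
    a = np.asarray(means_a, dtype=float)
    b = np.asarray(means_b, dtype=float)
    if a.size != b.size:
        if experiment_ids is not None:
            raise ValueError(
                f"mismatched pairing; experiments {list(experiment_ids)} do not align"
            )
        raise ValueError(f"paired vectors differ in length: {a.size} vs {b.size}")
    if a.size < 2:
        raise ValueError("paired t-test needs at least 2 experiments")
    d = a - b
    if np.ptp(d) == 0:  # zero variance of differences
        if d[0] == 0:
            return TestResult(0.0, 1.0, "paired-t", a.size, b.size, degenerate=True)
        return TestResult(
            float(np.inf if d[0] > 0 else -np.inf),
            0.0,
            "paired-t",
            int(a.size),
            int(b.size),
            degenerate=True,
        )
    res = sps.ttest_rel(a, b)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        test_name="paired-t",
        n1=int(a.size),
        n2=int(b.size),
    )
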