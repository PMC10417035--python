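"""Induced-damage dose-response regression and cross-strain line comparison.

Because spontaneous strand-break levels differ among strains (different
genetic backgrounds), only the treatment-induced damage is compared:
``induced TM = treated study mean - control study mean``.  Each strain's
induced TM is regressed linearly on dose; strains are then compared with a
classical common-slope ANCOVA: an F-test of slope homogeneity on the full
dose x strain interaction model, followed (when slopes are homogeneous) by
pairwise elevation (intercept) contrasts under the pooled common slope.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .records import ConditionSummary

__all__ = [
    "RegressionFit",
    "SlopeElevationComparison",
    "induced_tm",
    "induced_se",
    "fit_dose_response",
    "compare_strain_lines",
]


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of induced tail moment on dose for one strain."""

    strain: str
    slope: float
    intercept: float
    r_squared: float
    slope_se: float
    n_points: int
    slope_p: float

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("a regression fit needs at least 2 points")
        if not (math.isnan(self.r_squared) or 0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError(f"r_squared out of [0, 1]: {self.r_squared!r}")


@dataclass(frozen=True)
class SlopeElevationComparison:
    """Slope-homogeneity F-test and pairwise elevation p-values.

    ``pairwise_elevation_p`` is a symmetric strain x strain DataFrame with
    unit diagonal; entries are p-values for equal elevations under the pooled
    common slope.  When slopes are heterogeneous the elevation comparison is
    still reported but should be read with caution (flagged by
    ``slope_homogeneity_p``).
    """

    slope_homogeneity_p: float
    pairwise_elevation_p: pd.DataFrame
    common_slope: float


def induced_tm(
    treated_mean: float | ConditionSummary,
    control_mean: float | ConditionSummary,
) -> float:
    """MMS-induced tail moment: treated minus control study mean.

    May be negative; reported as-is.  When :class:`ConditionSummary` objects
    are passed, their strains must match.
    """
    if isinstance(treated_mean, ConditionSummary) and isinstance(
        control_mean, ConditionSummary
    ):
        if treated_mean.strain != control_mean.strain:
            raise ValueError(
                f"strain mismatch: {treated_mean.strain!r} vs {control_mean.strain!r}"
            )
        return treated_mean.mean_tm - control_mean.mean_tm
    return float(treated_mean) - float(control_mean)


def induced_se(se_treated: float, se_control: float) -> float:
    """SE of an induced TM assuming independent treated and control means."""
    if se_treated < 0 or se_control < 0:
        raise ValueError("standard errors must be non-negative")
    return math.hypot(se_treated, se_control)


def fit_dose_response(
    doses: Sequence[float],
    induced_tms: Sequence[float],
    strain: str = "",
    include_zero_dose: bool = False,
) -> RegressionFit:
    """Ordinary least-squares fit of induced TM on dose.

    By default only the non-zero concentrations enter the fit (induced damage
    at dose 0 is identically 0 by construction and is not a measured point);
    pass ``include_zero_dose=True`` to add a (0, 0) anchor.
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(induced_tms, dtype=float)
    if x.shape != y.shape:
        raise ValueError("doses and induced_tms must have equal length")
    if include_zero_dose and not np.any(x == 0):
        x = np.concatenate([[0.0], x])
        y = np.concatenate([[0.0], y])
    if x.size < 2:
        raise ValueError("need at least 2 (dose, induced TM) points")
    if np.ptp(x) == 0:
        raise ValueError("zero dose variance: all doses identical")
    res = sps.linregress(x, y)
    r2 = float(res.rvalue**2)
    return RegressionFit(
        strain=strain,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=min(r2, 1.0),
        slope_se=float(res.stderr) if x.size > 2 else float("nan"),
        n_points=int(x.size),
        slope_p=float(res.pvalue) if x.size > 2 else float("nan"),
    )


def compare_strain_lines(
    strain_data: Mapping[str, tuple[Sequence[float], Sequence[float]]],
) -> SlopeElevationComparison:
    """ANCOVA-style comparison of per-strain dose-response lines.

    Parameters
    ----------
    strain_data
        Mapping strain -> (doses, induced TMs).  Strains with fewer than 3
        points are excluded with a warning (no residual df for the test).

    Procedure: (1) F-test of the dose x strain interaction (slope
    homogeneity) comparing the separate-slopes model against the common-slope
    model; (2) refit with a single pooled slope and test each pair of strain
    elevations with a t-test on the intercept contrast.
    """
    kept: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for strain, (d, y) in strain_data.items():
        d = np.asarray(d, dtype=float)
        y = np.asarray(y, dtype=float)
        if d.size < 3:
            warnings.warn(f"strain {strain!r} excluded: fewer than 3 points", stacklevel=2)
            continue
        kept[strain] = (d, y)
    if len(kept) < 2:
        raise ValueError("need at least 2 strains with >= 3 points each")

    strains = list(kept)
    frames = [
        pd.DataFrame({"dose": d, "y": y, "strain": s}) for s, (d, y) in kept.items()
    ]
    df = pd.concat(frames, ignore_index=True)

    # Design matrices: separate intercepts always; slopes either per strain
    # (full) or pooled (reduced).
    intercepts = pd.get_dummies(df["strain"], dtype=float)[strains]
    full_X = pd.concat(
        [intercepts, intercepts.mul(df["dose"], axis=0).add_suffix(":dose")], axis=1
    )
    reduced_X = pd.concat([intercepts, df[["dose"]]], axis=1)

    full = sm.OLS(df["y"], full_X).fit()
    reduced = sm.OLS(df["y"], reduced_X).fit()

    df_num = full.df_model - reduced.df_model
    df_den = full.df_resid
    if df_den <= 0 or full.ssr <= 0:
        # Saturated or perfect fit: no residual variation to test against.
        slope_p = 1.0 if reduced.ssr <= max(full.ssr, 1e-12) else 0.0
    else:
        f_stat = ((reduced.ssr - full.ssr) / df_num) / (full.ssr / df_den)
        slope_p = float(sps.f.sf(max(f_stat, 0.0), df_num, df_den))

    # Pairwise elevation contrasts under the pooled slope.
    k = len(strains)
    pmat = np.ones((k, k))
    params = reduced.params
    cov = reduced.cov_params()
    for i in range(k):
        for j in range(i + 1, k):
            contrast = np.zeros(len(params))
            contrast[list(params.index).index(strains[i])] = 1.0
            contrast[list(params.index).index(strains[j])] = -1.0
            est = float(contrast @ params.to_numpy())
            var = float(contrast @ cov.to_numpy() @ contrast)
            if var <= 0:
                p = 1.0 if est == 0 else 0.0
            else:
                t = est / math.sqrt(var)
                p = float(2 * sps.t.sf(abs(t), reduced.df_resid))
            pmat[i, j] = pmat[j, i] = p
    return SlopeElevationComparison(
        slope_homogeneity_p=min(slope_p, 1.0),
        pairwise_elevation_p=pd.DataFrame(pmat, index=strains, columns=strains),
        common_slope=float(params["dose"]),
    )
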