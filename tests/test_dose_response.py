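"""Induced damage, dose-response fits and the ANCOVA line comparison."""

import numpy as np
import pytest

from cometddr import (
    ConditionSummary,
    compare_strain_lines,
    fit_dose_response,
    induced_se,
    induced_tm,
)
from cometddr.datasets import DOSES_MM, STRAINS, invivo_study_summaries

NONZERO = [d for d in DOSES_MM if d > 0]

# Published per-strain regression table the fits must reproduce
# (slope, intercept, r_squared).
PUBLISHED_FITS = {
    "OK": (3.61, 1.27, 0.996),
    "mus201": (4.68, 3.84, 0.953),
    "mus308": (6.02, 7.37, 0.926),
    "mus201;mus308": (0.16, 11.95, 0.017),
}


def induced_by_strain():
    summaries = invivo_study_summaries()
    out = {}
    for strain in STRAINS:
        cells = {s.dose: s for s in summaries if s.strain == strain}
        out[strain] = [induced_tm(cells[d], cells[0.0]) for d in NONZERO]
    return out


def test_induced_tm_examples():
    assert induced_tm(7.89, 6.20) == pytest.approx(1.69)
    assert induced_tm(14.21, 2.61) == pytest.approx(11.60)
    assert induced_tm(4.2, 4.2) == 0.0


def test_induced_tm_strain_mismatch():
    a = ConditionSummary("OK", 0.1, "none", "study", 7.89, 1.12, 3)
    b = ConditionSummary("mus201", 0.0, "none", "study", 4.70, 0.57, 3)
    with pytest.raises(ValueError, match="mismatch"):
        induced_tm(a, b)


def test_induced_se_quadrature():
    assert induced_se(3.0, 4.0) == pytest.approx(5.0)
    with pytest.raises(ValueError):
        induced_se(-0.1, 1.0)


@pytest.mark.parametrize("strain", STRAINS)
def test_fit_reproduces_published_regressions(strain):
    slope, intercept, r2 = PUBLISHED_FITS[strain]
    fit = fit_dose_response(NONZERO, induced_by_strain()[strain], strain=strain)
    assert fit.slope == pytest.approx(slope, abs=0.01)
    assert fit.intercept == pytest.approx(intercept, abs=0.02)
    assert fit.r_squared == pytest.approx(r2, abs=0.001)


def test_fit_perfect_line():
    fit = fit_dose_response([0.1, 0.5, 1.0], [1.2, 2.0, 3.0])
    assert fit.r_squared == pytest.approx(1.0)
    assert fit.slope == pytest.approx(2.0)


def test_fit_scale_equivariance():
    doses = np.array([0.1, 0.5, 1.0])
    y = np.array([1.69, 2.96, 4.93])
    f1 = fit_dose_response(doses, y)
    f2 = fit_dose_response(10 * doses, y)
    assert f2.slope == pytest.approx(f1.slope / 10)
    assert f2.r_squared == pytest.approx(f1.r_squared)
    assert f2.intercept == pytest.approx(f1.intercept)


def test_fit_input_validation():
    with pytest.raises(ValueError):
        fit_dose_response([0.5], [1.0])
    with pytest.raises(ValueError, match="dose variance"):
        fit_dose_response([0.5, 0.5], [1.0, 2.0])


def test_fit_zero_dose_flag_adds_origin():
    fit = fit_dose_response([0.5, 1.0], [2.0, 4.0], include_zero_dose=True)
    assert fit.n_points == 3


def test_compare_identical_strains_no_difference():
    d = [0.1, 0.5, 1.0]
    y = [1.7, 3.0, 4.9]
    cmp = compare_strain_lines({"a": (d, y), "b": (d, y)})
    assert cmp.slope_homogeneity_p == pytest.approx(1.0)
    assert cmp.pairwise_elevation_p.loc["a", "b"] == pytest.approx(1.0)
    assert np.allclose(np.diag(cmp.pairwise_elevation_p), 1.0)


def test_compare_parallel_offset_lines():
    rng = np.random.default_rng(2)
    d = np.linspace(0.1, 1.0, 8)
    ya = 3.0 * d + rng.normal(0, 0.05, d.size)
    yb = 3.0 * d + 5.0 + rng.normal(0, 0.05, d.size)
    cmp = compare_strain_lines({"a": (d, ya), "b": (d, yb)})
    assert cmp.slope_homogeneity_p > 0.05
    assert cmp.pairwise_elevation_p.loc["a", "b"] < 0.01


def test_compare_detects_slope_heterogeneity():
    rng = np.random.default_rng(3)
    d = np.linspace(0.1, 1.0, 20)
    ya = 1.0 * d + rng.normal(0, 0.1, d.size)
    yb = 10.0 * d + rng.normal(0, 0.1, d.size)
    cmp = compare_strain_lines({"a": (d, ya), "b": (d, yb)})
    assert cmp.slope_homogeneity_p < 0.001


def test_compare_elevation_matrix_symmetry_on_study_fits():
    data = {s: (NONZERO, induced_by_strain()[s]) for s in STRAINS}
    cmp = compare_strain_lines(data)
    m = cmp.pairwise_elevation_p
    assert np.allclose(m, m.T)
    assert ((m.to_numpy() >= 0) & (m.to_numpy() <= 1)).all()
    assert cmp.slope_homogeneity_p > 0.05  # published finding: homogeneous slopes


def test_compare_excludes_short_strains():
    d = [0.1, 0.5, 1.0]
    with pytest.warns(UserWarning, match="excluded"):
        cmp = compare_strain_lines(
            {"a": (d, [1, 2, 3]), "b": (d, [2, 3, 4]), "c": ([0.1], [1.0])}
        )
    assert "c" not in cmp.pairwise_elevation_p.index


def test_compare_null_calibration():
    """Identical true lines: the slope-homogeneity F-test rejects at ~alpha."""
    rng = np.random.default_rng(17)
    d = np.array([0.1, 0.3, 0.5, 0.7, 0.9, 1.0])
    reps, rejections = 400, 0
    for _ in range(reps):
        ya = 2.0 + 3.0 * d + rng.normal(0, 0.5, d.size)
        yb = 2.0 + 3.0 * d + rng.normal(0, 0.5, d.size)
        cmp = compare_strain_lines({"a": (d, ya), "b": (d, yb)})
        rejections += cmp.slope_homogeneity_p < 0.05
    assert 0.02 <= rejections / reps <= 0.09
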