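"""Mann-Whitney, experiment aggregation and paired-t behaviour."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cometddr import (
    experiment_means,
    mann_whitney_u,
    paired_t_across_experiments,
    study_summary,
)
from cometddr.stats import significance_code


def mw_two_sided_bruteforce(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all rank assignments.

    Tie-free samples only: every split of the pooled order statistics into a
    group of size n1 is equally likely under the null; p is the null
    probability of a U at least as far from n1*n2/2 as the observed one.
    """
    x, y = list(x), list(y)
    n1, n2 = len(x), len(y)
    pooled = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(ranks[v] for v in x) - n1 * (n1 + 1) / 2
    mid = n1 * n2 / 2
    hits = total = 0
    for combo in itertools.combinations(range(n1 + n2), n1):
        u = sum(c + 1 for c in combo) - n1 * (n1 + 1) / 2
        hits += abs(u - mid) >= abs(u_obs - mid)
        total += 1
    return hits / total


def test_mw_identical_samples_is_uninformative():
    res = mann_whitney_u([3.0, 3.0, 3.0], [3.0, 3.0])
    assert res.statistic == pytest.approx(3.0)  # n1*n2/2
    assert res.p_value == 1.0
    assert res.degenerate


def test_mw_complete_separation_exact_p():
    res = mann_whitney_u([3, 4, 5], [0, 1, 2])
    assert res.statistic == 9.0
    assert res.p_value == pytest.approx(0.1)  # 2/20 by enumeration
    assert res.p_value == pytest.approx(mw_two_sided_bruteforce([3, 4, 5], [0, 1, 2]))


def test_mw_full_ties_p_one():
    res = mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4])
    assert res.p_value == pytest.approx(1.0)


def test_mw_exact_matches_bruteforce_enumeration():
    """Exact p equals the brute-force null enumeration for small samples."""
    rng = np.random.default_rng(5)
    for _ in range(40):
        n1, n2 = rng.integers(2, 6, size=2)
        pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1))  # tie-free
        x, y = pooled[:n1], pooled[n1:]
        res = mann_whitney_u(x, y)
        assert res.p_value == pytest.approx(mw_two_sided_bruteforce(x, y), abs=1e-12)


def test_mw_u_statistics_sum_to_n1n2():
    rng = np.random.default_rng(7)
    for _ in range(200):
        n1, n2 = rng.integers(2, 15, size=2)
        x = rng.gamma(2.0, 3.0, size=n1)
        y = rng.gamma(2.0, 3.0, size=n2)
        u1 = mann_whitney_u(x, y).statistic
        u2 = mann_whitney_u(y, x).statistic
        assert u1 + u2 == pytest.approx(n1 * n2)


def test_mw_p_invariant_under_monotone_transform():
    rng = np.random.default_rng(9)
    x = rng.gamma(2.0, 3.0, size=12)
    y = rng.gamma(2.0, 5.0, size=10)
    p0 = mann_whitney_u(x, y).p_value
    assert mann_whitney_u(np.log(x), np.log(y)).p_value == pytest.approx(p0)
    assert mann_whitney_u(x**2, y**2).p_value == pytest.approx(p0)


def test_mw_rejects_empty():
    with pytest.raises(ValueError):
        mann_whitney_u([], [1.0])


def test_mw_null_rejection_rate_calibrated():
    """Under identical gamma populations the 5% test rejects ~5% of the time."""
    rng = np.random.default_rng(123)
    rejections = 0
    reps = 1000
    for _ in range(reps):
        x = rng.gamma(2.0, 3.1, size=50)
        y = rng.gamma(2.0, 3.1, size=50)
        rejections += mann_whitney_u(x, y).p_value < 0.05
    assert 0.03 <= rejections / reps <= 0.07


def _records(rows):
    df = pd.DataFrame(
        rows,
        columns=["strain", "dose", "extract", "experiment_id", "gel_id", "tail_moment"],
    )
    df["hedgehog_flag"] = False
    df["percent_tail_dna"] = np.nan
    df["tail_length"] = np.nan
    return df


def test_experiment_means_pools_gels():
    rows = [("OK", 0.0, "none", "e1", g, tm) for g in ("g1", "g2") for tm in [4.0] * 50]
    exp = experiment_means(_records(rows))
    assert len(exp) == 1
    assert exp["mean_tm"].iloc[0] == pytest.approx(4.0)
    assert exp["n_nucleoids"].iloc[0] == 100


def test_experiment_means_known_mixture():
    rows = [("OK", 0.0, "none", "e1", "g1", tm) for tm in [2.0] * 25 + [6.0] * 25]
    exp = experiment_means(_records(rows))
    assert exp["mean_tm"].iloc[0] == pytest.approx(4.0)


def test_experiment_means_gamma_sample_near_truth():
    rng = np.random.default_rng(21)
    tms = rng.gamma(2.0, 6.2 / 2.0, size=100)
    rows = [("OK", 0.0, "none", "e1", "g1", tm) for tm in tms]
    exp = experiment_means(_records(rows))
    se = 6.2 / np.sqrt(2.0) / np.sqrt(100)  # gamma sd / sqrt(n)
    assert abs(exp["mean_tm"].iloc[0] - 6.2) < 3 * se


def test_experiment_means_hedgehog_exclusion_switch():
    df = _records(
        [("OK", 0.0, "none", "e1", "g1", 2.0), ("OK", 0.0, "none", "e1", "g1", 10.0)]
    )
    df.loc[1, "hedgehog_flag"] = True
    assert experiment_means(df)["mean_tm"].iloc[0] == pytest.approx(6.0)
    assert (
        experiment_means(df, exclude_hedgehogs=True)["mean_tm"].iloc[0]
        == pytest.approx(2.0)
    )


def test_study_summary_closed_form():
    exp = pd.DataFrame(
        {
            "strain": "OK", "dose": 0.0, "extract": "none",
            "experiment_id": ["e1", "e2", "e3"], "mean_tm": [5.0, 6.0, 7.0],
            "n_nucleoids": 100, "hedgehog_fraction": 0.0,
        }
    )
    (s,) = study_summary(exp)
    assert s.mean_tm == pytest.approx(6.0)
    assert s.se_tm == pytest.approx(1.0 / np.sqrt(3))  # sd 1 over 3 experiments
    assert s.n == 3 and s.level == "study"


def test_study_summary_equal_experiments_zero_se():
    exp = pd.DataFrame(
        {
            "strain": "OK", "dose": 0.0, "extract": "none",
            "experiment_id": ["e1", "e2"], "mean_tm": [4.0, 4.0],
            "n_nucleoids": 10, "hedgehog_fraction": 0.0,
        }
    )
    assert study_summary(exp)[0].se_tm == 0.0


def test_study_summary_order_invariant(full_invivo):
    exp = experiment_means(full_invivo)
    shuffled = exp.sample(frac=1.0, random_state=3).reset_index(drop=True)
    a = {(s.strain, s.dose): (s.mean_tm, s.se_tm) for s in study_summary(exp)}
    b = {(s.strain, s.dose): (s.mean_tm, s.se_tm) for s in study_summary(shuffled)}
    assert a.keys() == b.keys()
    for k in a:
        assert a[k] == pytest.approx(b[k])


def test_study_summary_single_experiment_flagged():
    exp = pd.DataFrame(
        {
            "strain": "OK", "dose": 0.0, "extract": "none",
            "experiment_id": ["e1"], "mean_tm": [4.0],
            "n_nucleoids": 10, "hedgehog_fraction": 0.0,
        }
    )
    with pytest.warns(UserWarning, match="SE undefined"):
        (s,) = study_summary(exp)
    assert np.isnan(s.se_tm)


def test_paired_t_identical_vectors():
    res = paired_t_across_experiments([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.p_value == 1.0 and res.degenerate


def test_paired_t_constant_nonzero_difference():
    res = paired_t_across_experiments([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
    assert res.p_value == 0.0 and res.degenerate


def test_paired_t_hand_oracle_zero_t():
    # differences (-1, 1, 0): mean 0 so t = 0 and p = 1
    res = paired_t_across_experiments([1.0, 2.0, 3.0], [2.0, 1.0, 3.0])
    assert res.statistic == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)


def test_paired_t_hand_oracle_textbook_formula():
    # differences (1, 1, 3): mean 5/3, sd(d) = sqrt(4/3),
    # t = (5/3) / (sqrt(4/3)/sqrt(3)) = 2.5; two-sided p with 2 df = 0.12961
    res = paired_t_across_experiments([1.0, 2.0, 4.0], [0.0, 1.0, 1.0])
    assert res.statistic == pytest.approx(2.5)
    assert res.p_value == pytest.approx(0.129612, abs=1e-5)


def test_paired_t_mismatched_pairing():
    with pytest.raises(ValueError, match="e1"):
        paired_t_across_experiments([1.0, 2.0], [1.0], experiment_ids=["e1", "e2"])


@pytest.mark.parametrize(
    "p, code", [(0.2, "ns"), (0.04, "*"), (0.009, "**"), (0.0009, "***")]
)
def test_significance_codes(p, code):
    assert significance_code(p) == code
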