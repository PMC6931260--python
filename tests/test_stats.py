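"""Variety statistics: Tukey ranking, calendars, OLS, cross-date matching."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import studentized_range

from orchardpheno.stats import (build_calendar, compact_letter_display,
                                fit_yield_volume, match_trees_across_dates,
                                rank_varieties)


def _records(means, sds, ns, rng, column="max_height_m"):
    rows = []
    for i, (m, s, n) in enumerate(zip(means, sds, ns)):
        for v in rng.normal(m, s, n):
            rows.append({"variety": f"V{i}", column: v})
    return pd.DataFrame(rows)


def tukey_oracle(samples, alpha=0.05):
    """Independent Tukey-Kramer decisions from the studentized-range law."""
    k = len(samples)
    n_total = sum(len(s) for s in samples)
    df = n_total - k
    mse = sum(((s - s.mean()) ** 2).sum() for s in samples) / df
    qcrit = studentized_range.ppf(1 - alpha, k, df)
    decisions = {}
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(mse / 2 * (1 / len(samples[i]) + 1 / len(samples[j])))
            q = abs(samples[i].mean() - samples[j].mean()) / se
            decisions[(i, j)] = q > qcrit
    return decisions


def test_identical_varieties_share_one_letter():
    rng = np.random.default_rng(0)
    values = rng.normal(3.0, 0.2, 8)
    table = pd.DataFrame({
        "variety": ["A"] * 8 + ["B"] * 8,
        "max_height_m": np.concatenate([values, values]),
    })
    ranking = rank_varieties(table, "height")
    assert set(ranking.table["letters"]) == {"a"}


def test_strongly_separated_means_get_distinct_letters():
    rng = np.random.default_rng(1)
    table = _records([10.0, 5.0, 1.0], [0.01] * 3, [8] * 3, rng)
    ranking = rank_varieties(table, "height")
    out = ranking.table
    assert out["mean"].is_monotonic_decreasing
    assert list(out["letters"]) == ["a", "b", "c"]


def test_tukey_decisions_match_studentized_range_oracle():
    rng = np.random.default_rng(2)
    for trial in range(10):
        k = int(rng.integers(3, 6))
        ns = rng.integers(4, 11, k)
        means = rng.uniform(0, 3, k)
        samples = [rng.normal(means[i], 1.0, ns[i]) for i in range(k)]
        rows = []
        for i, s in enumerate(samples):
            rows += [{"variety": f"V{i}", "max_height_m": v} for v in s]
        ranking = rank_varieties(pd.DataFrame(rows), "height")
        oracle = tukey_oracle(samples)
        got = {}
        for r in ranking.pairwise.itertuples(index=False):
            i = int(r.group1[1:]); j = int(r.group2[1:])
            got[tuple(sorted((i, j)))] = bool(r.reject)
        assert got == oracle


def test_letters_invariant_to_relabeling():
    rng = np.random.default_rng(3)
    table = _records([4.0, 3.0, 2.0], [0.3] * 3, [8] * 3, rng)
    r1 = rank_varieties(table, "height")
    relabeled = table.copy()
    relabeled["variety"] = relabeled["variety"].map(
        {"V0": "zz", "V1": "aa", "V2": "mm"})
    shuffled = relabeled.sample(frac=1.0, random_state=0)
    r2 = rank_varieties(shuffled, "height")
    np.testing.assert_allclose(r1.table["mean"], r2.table["mean"])
    assert list(r1.table["letters"]) == list(r2.table["letters"])


def test_small_variety_excluded_with_warning():
    rng = np.random.default_rng(4)
    table = _records([4.0, 3.0], [0.2] * 2, [8, 8], rng)
    table = pd.concat([table, pd.DataFrame([{"variety": "tiny",
                                             "max_height_m": 2.0}])])
    with pytest.warns(UserWarning, match="tiny"):
        ranking = rank_varieties(table, "height")
    assert "tiny" not in set(ranking.table["variety"])


def test_cld_pairs_share_letter_iff_not_significant():
    sig = {("A", "C"), ("A", "D"), ("B", "D")}
    letters = compact_letter_display(["A", "B", "C", "D"], sig)
    for a, b in [("A", "B"), ("B", "C"), ("C", "D")]:
        assert set(letters[a]) & set(letters[b])
    for a, b in sig:
        assert not (set(letters[a]) & set(letters[b]))


def test_calendar_peak_and_stage_dates():
    rows = []
    densities = {1: 0.0, 2: 8.0, 3: 2.0, 4: 0.0}
    for date, dens in densities.items():
        for tree in range(4):
            rows.append({"date": date, "tree_id": tree, "variety": "A",
                         "flower_density_per_m3": dens})
    cal = build_calendar(pd.DataFrame(rows))
    stage = cal.stages.iloc[0]
    assert stage["peak_date"] == 2
    assert stage["peak_density"] == pytest.approx(8.0)
    assert stage["start"] == 2  # first date over 5% of peak (0.4)
    assert stage["full_start"] == 2 and stage["full_end"] == 2
    assert stage["end"] == 3  # density 2.0 still above 5% of peak


def test_calendar_flags_no_bloom():
    rows = [{"date": d, "tree_id": t, "variety": "A",
             "flower_density_per_m3": 0.0}
            for d in (1, 2) for t in range(3)]
    cal = build_calendar(pd.DataFrame(rows))
    assert bool(cal.stages.iloc[0]["no_bloom"])


def _closed_form_ols(x, y):
    n = x.size
    X = np.column_stack([np.ones(n), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    ss_res = resid @ resid
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1 - ss_res / ss_tot
    sigma2 = ss_res / (n - 2)
    se_slope = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
    from scipy.stats import t as tdist
    p = 2 * tdist.sf(abs(beta[1] / se_slope), n - 2)
    return beta[1], beta[0], r2, p


def _fit(x, y):
    volumes = pd.DataFrame({"variety": "A", "block": range(len(x)),
                            "crown_volume_m3": x})
    yields = pd.DataFrame({"variety": "A", "block": range(len(x)),
                           "yield_kg": y})
    return fit_yield_volume(volumes, yields).iloc[0]


def test_ols_matches_closed_form_to_1e10():
    rng = np.random.default_rng(5)
    for _ in range(5):
        x = rng.uniform(5, 30, 6)
        y = 0.8 * x + rng.normal(0, 3.0, 6)
        row = _fit(x, y)
        slope, intercept, r2, p = _closed_form_ols(x, y)
        assert row["slope"] == pytest.approx(slope, abs=1e-10)
        assert row["intercept"] == pytest.approx(intercept, abs=1e-10)
        assert row["r_squared"] == pytest.approx(r2, abs=1e-10)
        assert row["p_value"] == pytest.approx(p, abs=1e-10)
        assert row["significant_05"] == (p < 0.05)
        assert row["significant_10"] == (p < 0.10)


def test_collinear_data_gives_r2_one_and_constant_y_zero():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    row = _fit(x, 2.0 * x + 1.0)
    assert row["r_squared"] == pytest.approx(1.0, abs=1e-12)
    row0 = _fit(x, np.full(4, 7.0))
    assert row0["r_squared"] == 0.0 and row0["slope"] == 0.0


def test_zero_volume_variance_flagged_undefined():
    row = _fit(np.full(4, 10.0), np.array([1.0, 2.0, 3.0, 4.0]))
    assert bool(row["undefined"])


def test_matching_identity_and_missing_tree():
    d1 = pd.DataFrame({"tree_id": [1, 2, 3], "x": [0.0, 6.0, 12.0],
                       "y": [0.0, 0.0, 0.0]})
    same = d1.copy()
    maps = match_trees_across_dates([d1, same])
    assert maps[1] == {1: 1, 2: 2, 3: 3}
    missing = d1[d1.tree_id != 2].copy()
    maps2 = match_trees_across_dates([d1, missing])
    assert maps2[1] == {1: 1, 3: 3}


def test_matching_with_jitter_recovers_all_trees():
    rng = np.random.default_rng(6)
    xs = np.repeat(np.arange(6) * 6.0, 4)
    ys = np.tile(np.arange(4) * 7.0, 6)
    d1 = pd.DataFrame({"tree_id": np.arange(24), "x": xs, "y": ys})
    d2 = pd.DataFrame({
        "tree_id": rng.permutation(24) + 100,  # different local ids
        "x": xs + rng.normal(0, 0.2, 24),
        "y": ys + rng.normal(0, 0.2, 24)})
    maps = match_trees_across_dates([d1, d2])
    # every local crown on date 2 maps back to the co-located global id
    for row in d2.itertuples(index=False):
        gid = maps[1][int(row.tree_id)]
        truth = d1.iloc[[int(np.argmin(np.hypot(d1.x - row.x, d1.y - row.y)))]]
        assert gid == int(truth["tree_id"].iloc[0])
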