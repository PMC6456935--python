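"""Rank tests against enumeration oracles, Storey q-values against BH, and
the multi-criterion selection pipeline on hand-built tables."""

import dataclasses
import math
from itertools import combinations

import numpy as np
import pytest
from statsmodels.stats.multitest import fdrcorrection

from apexdiff.differential import (
    DiffConfig,
    differential_analysis,
    q3_quantile,
    storey_qvalues,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)
from apexdiff.table import OtuTable, SampleMetadata

# ---------------------------------------------------------------------------
# Independent enumeration oracles (symmetric two-sided tail probability)
# ---------------------------------------------------------------------------


def ranksum_oracle(x, y):
    """Exact two-sided rank-sum p by enumerating all rank splits."""
    pooled = sorted(x) + sorted(y)
    assert len(set(pooled)) == len(pooled), "oracle requires no ties"
    ranks = {v: i + 1 for i, v in enumerate(sorted(pooled))}
    nx = len(x)
    rx = sum(ranks[v] for v in x)
    u_obs = rx - nx * (nx + 1) / 2
    mu = nx * len(y) / 2
    all_ranks = list(range(1, len(pooled) + 1))
    total = extreme = 0
    for subset in combinations(all_ranks, nx):
        u = sum(subset) - nx * (nx + 1) / 2
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
            extreme += 1
    return extreme / total


def signed_rank_oracle(diffs):
    """Exact two-sided signed-rank p by enumerating all 2^n sign patterns."""
    d = [v for v in diffs if v != 0]
    mags = sorted(abs(v) for v in d)
    assert len(set(mags)) == len(mags), "oracle requires no tied magnitudes"
    ranks = {m: i + 1 for i, m in enumerate(mags)}
    n = len(d)
    w_obs = sum(ranks[abs(v)] for v in d if v > 0)
    mu = n * (n + 1) / 4
    total = extreme = 0
    for bits in range(2**n):
        w = sum(i + 1 for i in range(n) if bits >> i & 1)
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            extreme += 1
    return extreme / total


# ---------------------------------------------------------------------------
# Rank-sum
# ---------------------------------------------------------------------------


def test_ranksum_separated_groups_exact():
    stat, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
    assert p == pytest.approx(0.1)  # 2 of C(6,3)=20 splits as extreme


def test_ranksum_identical_multisets():
    _, p = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
    assert p == pytest.approx(1.0)


def test_ranksum_empty_input():
    with pytest.raises(ValueError):
        wilcoxon_rank_sum([], [1.0])


@pytest.mark.parametrize("nx,ny", [(2, 2), (3, 3), (2, 4), (4, 4), (5, 5)])
def test_ranksum_matches_enumeration_oracle(nx, ny):
    n = nx + ny
    values = list(range(1, n + 1))
    for xs in combinations(range(n), nx):
        x = [values[i] for i in xs]
        y = [values[i] for i in range(n) if i not in xs]
        _, p = wilcoxon_rank_sum(x, y)
        assert p == pytest.approx(ranksum_oracle(x, y), abs=1e-9)


def test_ranksum_approximation_close_to_exact():
    from scipy import stats

    values = list(range(1, 11))
    worst = 0.0
    for xs in combinations(range(10), 5):
        x = [values[i] for i in xs]
        y = [values[i] for i in range(10) if i not in xs]
        _, p_exact = wilcoxon_rank_sum(x, y)
        p_approx = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        ).pvalue
        worst = max(worst, abs(p_exact - p_approx))
    assert worst < 0.02


# ---------------------------------------------------------------------------
# Signed-rank
# ---------------------------------------------------------------------------


def test_signed_rank_all_positive():
    _, p = wilcoxon_signed_rank([1, 2, 3, 4, 5])
    assert p == pytest.approx(2 / 32)


def test_signed_rank_antisymmetric():
    _, p = wilcoxon_signed_rank([-2, -1, 1, 2])
    assert p == pytest.approx(1.0)


def test_signed_rank_negation_invariance():
    d = [3.0, -1.0, 4.0, 2.5, -0.5]
    assert wilcoxon_signed_rank(d)[1] == pytest.approx(
        wilcoxon_signed_rank([-v for v in d])[1]
    )


def test_signed_rank_all_zero_warns():
    with pytest.warns(UserWarning):
        _, p = wilcoxon_signed_rank([0.0, 0.0])
    assert p == 1.0


@pytest.mark.parametrize("n", [3, 5, 8])
def test_signed_rank_matches_enumeration_oracle(n):
    base = [float(i + 1) for i in range(n)]
    for bits in range(2**n):
        d = [v if bits >> i & 1 else -v for i, v in enumerate(base)]
        _, p = wilcoxon_signed_rank(d)
        assert p == pytest.approx(signed_rank_oracle(d), abs=1e-9)


# ---------------------------------------------------------------------------
# Storey q-values and the Q3 quantile
# ---------------------------------------------------------------------------


def test_pi0_hand_example():
    est, _ = storey_qvalues([0.6, 0.7, 0.8, 0.9], lam=0.5)
    assert est.pi0 == pytest.approx(1.0)


def test_qvalues_equal_bh_when_pi0_forced_to_one():
    rng = np.random.default_rng(5)
    p = np.concatenate([rng.uniform(size=60), rng.uniform(0, 0.01, size=15)])
    _, q = storey_qvalues(p, pi0=1.0)
    _, bh = fdrcorrection(p, method="indep")
    assert np.allclose(q, bh, atol=1e-12)


def test_qvalues_monotone_in_p_and_bounded():
    rng = np.random.default_rng(3)
    p = rng.uniform(size=100)
    est, q = storey_qvalues(p)
    assert 0 < est.pi0 <= 1
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-12)
    assert np.all((q >= 0) & (q <= 1))


def test_all_equal_p_gives_equal_q():
    _, q = storey_qvalues([0.2, 0.2, 0.2])
    assert len(set(np.round(q, 12))) == 1


def test_invalid_p_rejected():
    with pytest.raises(ValueError):
        storey_qvalues([0.5, 1.2])


@pytest.mark.parametrize(
    "values,expected",
    [([0, 0, 0, 100], 25.0), ([0, 0, 0], 0.0), ([7, 7, 7, 7, 7], 7.0)],
)
def test_q3_quantile(values, expected):
    assert q3_quantile(values) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# The full selection procedure
# ---------------------------------------------------------------------------


def _toy_cohort(n_per_group=6, seed=0):
    """12 samples (two groups), equal depths, one strongly enriched feature,
    one depleted, one null, plus a feature absent everywhere."""
    rng = np.random.default_rng(seed)
    na = nb = n_per_group
    depth = 1000
    base = np.array([200, 200, 300])
    counts = np.zeros((4, na + nb), dtype=int)
    for j in range(na + nb):
        in_a = j < na
        p = base.astype(float).copy()
        p[0] *= 8 if in_a else 1      # up in A
        p[1] *= 1 if in_a else 8      # up in B
        p = np.append(p, 0.0)
        p = p / p.sum()
        counts[:, j] = rng.multinomial(depth, p)
    samples = [f"A{j}" for j in range(na)] + [f"B{j}" for j in range(nb)]
    table = OtuTable(["up_a", "up_b", "null", "absent"], [()] * 4, samples, counts)
    meta = [SampleMetadata(s, "NRCT" if s.startswith("A") else "HT", s) for s in samples]
    return table, meta


def test_pipeline_flags_planted_and_excludes_absent():
    table, meta = _toy_cohort()
    records = differential_analysis(table, meta, "NRCT", "HT", DiffConfig(), seed=1)
    by_id = {r.feature_id: r for r in records}
    assert "absent" not in by_id  # all-zero: removed by the prevalence filter
    assert by_id["up_a"].significant and by_id["up_a"].direction == "up_in_a"
    assert by_id["up_b"].significant and by_id["up_b"].direction == "up_in_b"
    assert not by_id["null"].significant


def test_relabeling_flips_direction_only():
    table, meta = _toy_cohort()
    ab = differential_analysis(table, meta, "NRCT", "HT", DiffConfig(), seed=1)
    ba = differential_analysis(table, meta, "HT", "NRCT", DiffConfig(), seed=1)
    fa = {r.feature_id: r for r in ab}
    fb = {r.feature_id: r for r in ba}
    assert set(fa) == set(fb)
    for fid in fa:
        assert fa[fid].p_value == pytest.approx(fb[fid].p_value)
        assert fa[fid].q_value == pytest.approx(fb[fid].q_value)
        assert fa[fid].fold_change == pytest.approx(fb[fid].fold_change)
        assert fa[fid].significant == fb[fid].significant
        if fa[fid].mean_a != fa[fid].mean_b:
            assert fa[fid].direction != fb[fid].direction


def test_q3_floor_blocks_low_abundance_candidates():
    table, meta = _toy_cohort()
    strict = dataclasses.replace(DiffConfig(), q3_min_otu=1e6)
    records = differential_analysis(table, meta, "NRCT", "HT", strict, seed=1)
    assert not any(r.significant for r in records)
    assert not any(r.passes_q3 for r in records)


def test_unknown_group_rejected(default_cohort):
    table, meta, _ = default_cohort
    with pytest.raises(ValueError):
        differential_analysis(table, meta, "NOPE", "HT", DiffConfig(), seed=0)


def test_paired_mode_uses_subject_matching():
    """Paired analysis on subject-matched samples: a consistent within-pair
    shift is detected even though group-level values overlap."""
    rng = np.random.default_rng(2)
    n_subj = 8
    depth = 500
    counts = np.zeros((2, 2 * n_subj), dtype=int)
    samples, meta = [], []
    for i in range(n_subj):
        subject_level = rng.uniform(0.1, 0.6)
        pa = np.array([subject_level * 1.6, 1 - subject_level * 1.6])
        pb = np.array([subject_level, 1 - subject_level])
        counts[:, i] = rng.multinomial(depth, pa / pa.sum())
        counts[:, n_subj + i] = rng.multinomial(depth, pb / pb.sum())
        samples.append(f"T{i}")
        meta.append(SampleMetadata(f"T{i}", "HT", f"subj{i}"))
    for i in range(n_subj):
        samples.append(f"O{i}")
        meta.append(SampleMetadata(f"O{i}", "HO", f"subj{i}"))
    table = OtuTable(["marker", "rest"], [(), ()], samples, counts)
    cfg = dataclasses.replace(DiffConfig(), paired=True)
    records = differential_analysis(table, meta, "HT", "HO", cfg, seed=0)
    marker = next(r for r in records if r.feature_id == "marker")
    unpaired = differential_analysis(table, meta, "HT", "HO", DiffConfig(), seed=0)
    marker_unpaired = next(r for r in unpaired if r.feature_id == "marker")
    assert marker.p_value < marker_unpaired.p_value
    assert marker.p_value < 0.05
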