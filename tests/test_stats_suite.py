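"""Exact tests against enumeration oracles; permutation tests; intervals."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from operon_assembly import (
    ContingencyTable2x2,
    GeneLocus,
    Operon,
    PairOrder,
    binomial_test_two_sided,
    correlation_difference_shuffle,
    fisher_exact_two_sided,
    gene_order_randomization_null,
    predictor_concordance,
    spearman_rho,
    wilcoxon_rank_sum,
    wilson_interval,
)
from operon_assembly.operon_map import GenePairRecord


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by direct hypergeometric enumeration.

    With margins fixed, sums P(table) over all tables whose probability is
    at most the observed table's probability.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(1.0, total)


def binomial_oracle_half(k, n):
    """Two-sided binomial p at p0 = 1/2 by enumerating all 2^n sequences."""
    p_obs = math.comb(n, k)
    count = sum(
        math.comb(n, j) for j in range(n + 1) if math.comb(n, j) <= p_obs
    )
    return count / 2**n


# ---------------------------------------------------------------------------
# exact tests
# ---------------------------------------------------------------------------


def test_fisher_balanced_table_p_one():
    assert fisher_exact_two_sided(ContingencyTable2x2(10, 10, 10, 10)).p_value == pytest.approx(1.0)


def test_fisher_zero_margin_warns_p_one():
    with pytest.warns(UserWarning, match="zero margin"):
        res = fisher_exact_two_sided(ContingencyTable2x2(5, 0, 3, 0))
    assert res.p_value == 1.0


def test_fisher_matches_enumeration_for_all_small_tables():
    for n in range(1, 13):
        for a in range(n + 1):
            for b in range(n + 1 - a):
                for c in range(n + 1 - a - b):
                    d = n - a - b - c
                    if min(a + b, c + d, a + c, b + d) == 0:
                        continue
                    got = fisher_exact_two_sided(ContingencyTable2x2(a, b, c, d)).p_value
                    assert got == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-9), (a, b, c, d)


def test_binomial_symmetry_center():
    assert binomial_test_two_sided(36, 72, 0.5).p_value == pytest.approx(1.0)


def test_binomial_matches_sequence_enumeration():
    for n in range(1, 11):
        for k in range(n + 1):
            got = binomial_test_two_sided(k, n, 0.5).p_value
            assert got == pytest.approx(binomial_oracle_half(k, n), rel=1e-12), (k, n)


def test_binomial_general_p0_le_likelihood_convention():
    # oracle: sum P(X = j) over j with P(j) <= P(k)
    n, p0 = 10, 0.3
    for k in range(n + 1):
        probs = [math.comb(n, j) * p0**j * (1 - p0) ** (n - j) for j in range(n + 1)]
        expected = sum(p for p in probs if p <= probs[k] * (1 + 1e-12))
        got = binomial_test_two_sided(k, n, p0).p_value
        assert got == pytest.approx(min(1.0, expected), rel=1e-9)


# ---------------------------------------------------------------------------
# rank tests and correlation
# ---------------------------------------------------------------------------


def test_wilcoxon_identical_samples_p_one():
    x = [3.0, 3.0, 3.0]
    assert wilcoxon_rank_sum(x, x).p_value == 1.0


def test_wilcoxon_same_multiset_p_near_one():
    x = [1.0, 2.0, 5.0, 9.0]
    assert wilcoxon_rank_sum(x, list(x)).p_value == pytest.approx(1.0, abs=0.05)


def test_wilcoxon_extreme_separation_exact_enumeration():
    # all 3 ranks of x below y: 2 of C(6,3)=20 orderings as extreme, two-sided
    res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
    assert res.p_value == pytest.approx(2 / 20)
    assert res.extras["approximation"] == "exact"


def test_wilcoxon_p_decreases_with_shift():
    rng = np.random.default_rng(0)
    x = rng.lognormal(3.0, 1.0, 200)
    ps = [
        wilcoxon_rank_sum(x, x * math.exp(shift)).p_value for shift in (0.2, 0.6, 1.2)
    ]
    assert ps[0] > ps[1] > ps[2]


def test_spearman_monotone_and_reversed():
    x = [1.0, 2.0, 5.0, 9.0, 20.0]
    assert spearman_rho(x, [v**2 for v in x]) == pytest.approx(1.0)
    assert spearman_rho(x, [-v for v in x]) == pytest.approx(-1.0)


def test_spearman_matches_rank_definition():
    rng = np.random.default_rng(4)
    x, y = rng.normal(size=10), rng.normal(size=10)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    brute = np.corrcoef(rx, ry)[0, 1]
    assert spearman_rho(x, y) == pytest.approx(brute)
    assert spearman_rho(x, y) == pytest.approx(sps.spearmanr(x, y).statistic)


def test_spearman_zero_rank_variance_raises():
    with pytest.raises(ValueError):
        spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# ---------------------------------------------------------------------------
# group-shuffle correlation test
# ---------------------------------------------------------------------------


def _correlated_pairs(rng, n, rho):
    cov = [[1.0, rho], [rho, 1.0]]
    z = rng.multivariate_normal([0, 0], cov, size=n)
    return np.exp(z)


def test_shuffle_identical_groups_large_p():
    rng = np.random.default_rng(5)
    pool = _correlated_pairs(rng, 120, 0.5)
    res = correlation_difference_shuffle(pool[:60], pool[60:], n_shuffles=500, seed=1)
    assert res.p_value > 0.05


def test_shuffle_detects_designed_correlation_difference():
    rng = np.random.default_rng(6)
    g1 = _correlated_pairs(rng, 100, 0.9)
    g2 = _correlated_pairs(rng, 100, 0.0)
    res = correlation_difference_shuffle(g1, g2, n_shuffles=2000, seed=2)
    assert res.p_value < 0.01


def test_shuffle_deterministic_and_p_in_unit_interval():
    rng = np.random.default_rng(7)
    g1 = _correlated_pairs(rng, 30, 0.7)
    g2 = _correlated_pairs(rng, 30, 0.2)
    r1 = correlation_difference_shuffle(g1, g2, n_shuffles=300, seed=42)
    r2 = correlation_difference_shuffle(g1, g2, n_shuffles=300, seed=42)
    assert r1.p_value == r2.p_value
    assert 0.0 < r1.p_value <= 1.0


# ---------------------------------------------------------------------------
# Wilson interval
# ---------------------------------------------------------------------------


def test_wilson_boundaries():
    assert wilson_interval(0, 20, 0.68)[0] == 0.0
    assert wilson_interval(20, 20, 0.68)[1] == 1.0


def test_wilson_matches_closed_form():
    k, n, mass = 57, 72, 0.95
    z = sps.norm.ppf(0.5 + mass / 2)
    p = k / n
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    low, high = wilson_interval(k, n, mass)
    assert low == pytest.approx(center - half, rel=1e-9)
    assert high == pytest.approx(center + half, rel=1e-9)
    assert low < p < high


def test_wilson_68_uses_exact_quantile():
    # z for central 68% mass is ~0.9945, not 1
    low, high = wilson_interval(50, 100, 0.68)
    z = sps.norm.ppf(0.84)
    assert z == pytest.approx(0.9945, abs=1e-4)
    denom = 1 + z**2 / 100
    assert (high - low) == pytest.approx(2 * z * math.sqrt(0.25 / 100 + z**2 / 40000) / denom, rel=1e-9)


def test_wilson_width_decreases_with_n():
    widths = []
    for n in (10, 40, 160, 640):
        k = n // 4
        low, high = wilson_interval(k, n, 0.68)
        widths.append(high - low)
    assert widths == sorted(widths, reverse=True)


# ---------------------------------------------------------------------------
# gene-order randomization null
# ---------------------------------------------------------------------------


def _operon(operon_id, gene_ids):
    genes = [
        GeneLocus(gene_id=g, start=100 + 1000 * i, end=1000 + 1000 * i, strand="+", position=i + 1)
        for i, g in enumerate(gene_ids)
    ]
    return Operon(operon_id=operon_id, genes=genes)


def _interacting_record(operon_id, gx, gy, distance):
    return GenePairRecord(
        gene_x=gx,
        gene_y=gy,
        same_operon=True,
        operon_id=operon_id,
        distance=distance,
        adjacent=distance == 1,
        interface_area=500.0,
        physically_interacting=True,
    )


def test_randomization_null_adjacent_pairs_significant():
    operons, records = [], []
    for i in range(12):
        genes = [f"o{i}g{j}" for j in range(10)]
        operons.append(_operon(f"op{i:02d}", genes))
        records.append(_interacting_record(f"op{i:02d}", genes[0], genes[1], 1))
    res = gene_order_randomization_null(operons, records, n_shuffles=1000, seed=3)
    assert res.statistic == 1.0
    assert res.p_value < 0.05


def test_randomization_null_length_two_operon_p_one():
    op = _operon("op1", ["g1", "g2"])
    rec = _interacting_record("op1", "g1", "g2", 1)
    res = gene_order_randomization_null([op], [rec], n_shuffles=200, seed=0)
    assert res.p_value == 1.0


def test_randomization_null_calibrated_under_random_placement():
    """p is roughly uniform when interacting pairs are placed at random."""
    rng = np.random.default_rng(9)
    ps = []
    for rep in range(100):
        operons, records = [], []
        for i in range(4):
            genes = [f"r{rep}o{i}g{j}" for j in range(8)]
            operons.append(_operon(f"op{i}", genes))
            a, b = sorted(rng.choice(8, size=2, replace=False))
            records.append(
                _interacting_record(f"op{i}", genes[a], genes[b], int(b - a))
            )
        ps.append(
            gene_order_randomization_null(operons, records, n_shuffles=200, seed=rep).p_value
        )
    # coarse uniformity: mean near 1/2 and both tails populated
    assert 0.35 < float(np.mean(ps)) < 0.65
    assert min(ps) < 0.25 and max(ps) > 0.75


def test_randomization_null_requires_interacting_pairs():
    with pytest.raises(ValueError):
        gene_order_randomization_null([_operon("op1", ["g1", "g2"])], [], 100, 0)


# ---------------------------------------------------------------------------
# predictor concordance
# ---------------------------------------------------------------------------


def _ordered_record(i, order, ab_x, ab_y):
    return GenePairRecord(
        gene_x=f"gx{i}",
        gene_y=f"gy{i}",
        same_operon=True,
        operon_id="op1",
        distance=1,
        adjacent=True,
        pair_order=order,
        abundance_x=ab_x,
        abundance_y=ab_y,
    )


def test_concordance_all_gene_order_matches():
    rng = np.random.default_rng(12)
    records = [
        _ordered_record(i, PairOrder.FIRST_PRECEDES, float(rng.lognormal(3, 1)), float(rng.lognormal(3, 1)))
        for i in range(50)
    ]
    summary = predictor_concordance(records)
    assert summary.gene_order_fraction == 1.0
    assert 0.0 <= summary.abundance_fraction <= 1.0


def test_concordance_recovers_designed_fractions():
    rng = np.random.default_rng(13)
    n = 200
    records = []
    for i in range(n):
        gene_match = rng.random() < 0.8
        order = PairOrder.FIRST_PRECEDES if gene_match else PairOrder.SECOND_PRECEDES
        # abundance predictor right with probability 0.5: random abundances
        records.append(
            _ordered_record(i, order, float(rng.lognormal(3, 1)), float(rng.lognormal(3, 1)))
        )
    summary = predictor_concordance(records)
    lo, hi = wilson_interval(int(0.8 * n), n, 0.95)
    assert lo <= summary.gene_order_fraction <= hi
    lo, hi = wilson_interval(n // 2, n, 0.95)
    assert lo - 0.02 <= summary.abundance_fraction <= hi + 0.02
    assert summary.n == n
    assert summary.comparison.p_value < 0.01  # gene order clearly better


def test_concordance_empty_raises():
    with pytest.raises(ValueError):
        predictor_concordance([])
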