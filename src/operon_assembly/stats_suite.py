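"""Statistics for the operon/assembly concordance analysis.

Exact tests (Fisher, binomial), the Wilcoxon rank-sum test, Spearman's rho
and the Wilson score interval follow their standard definitions (scipy and
statsmodels supply the numerics).  The two seeded permutation procedures —
the group-shuffle test for a difference of Spearman correlations and the
within-operon gene-order randomization null — are implemented here.

Conventions pinned because they vary between texts:

* Fisher two-sided p: sum of the probabilities of all tables with the same
  margins whose hypergeometric probability is at most the observed table's.
* Binomial two-sided p: sum of P(X = k') over all k' whose likelihood is at
  most the observed one (for p0 = 0.5 this equals 2·min(P(X≤k), P(X≥k)),
  capped at 1).
* Permutation p-values use the add-one estimator (count + 1) / (n + 1), so
  p = 0 is never reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .operon_map import GenePairRecord, Operon
from .assembly import PairOrder

__all__ = [
    "ContingencyTable2x2",
    "TestResult",
    "ConcordanceSummary",
    "fisher_exact_two_sided",
    "binomial_test_two_sided",
    "wilcoxon_rank_sum",
    "spearman_rho",
    "correlation_difference_shuffle",
    "wilson_interval",
    "gene_order_randomization_null",
    "predictor_concordance",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows are groups, columns outcome yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("table must have positive total")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: int
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")


def fisher_exact_two_sided(table: ContingencyTable2x2) -> TestResult:
    """Fisher's exact test, two-sided, on a 2x2 table.

    Returns the sample odds ratio as statistic.  A zero margin carries no
    information about association: p = 1 with a warning.
    """
    arr = table.as_array()
    if 0 in arr.sum(axis=0) or 0 in arr.sum(axis=1):
        warnings.warn("zero margin in contingency table; p = 1", stacklevel=2)
        return TestResult(np.nan, 1.0, "fisher_exact", table.total)
    odds, p = sps.fisher_exact(arr, alternative="two-sided")
    return TestResult(float(odds), float(min(p, 1.0)), "fisher_exact", table.total)


def binomial_test_two_sided(k: int, n: int, p0: float = 0.5) -> TestResult:
    """Exact two-sided binomial test of k successes in n trials against p0."""
    if not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n")
    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must be in (0, 1)")
    res = sps.binomtest(k, n, p0, alternative="two-sided")
    return TestResult(k / n if n else np.nan, float(res.pvalue), "binomial", n)


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney) test, two-sided, midrank ties.

    Exact enumeration for samples of at most 25 without ties; otherwise the
    normal approximation with continuity and tie correction.  Identical
    pooled values give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    n = len(pooled)
    if np.all(pooled == pooled[0]):
        return TestResult(float(len(x) * len(y) / 2.0), 1.0, "wilcoxon_rank_sum", n)
    has_ties = len(np.unique(pooled)) < n
    method = "exact" if (max(len(x), len(y)) <= 25 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return TestResult(
        float(res.statistic), float(min(res.pvalue, 1.0)), "wilcoxon_rank_sum", n,
        extras={"approximation": method},
    )


def spearman_rho(x, y) -> float:
    """Spearman's rho: Pearson correlation of midrank-transformed values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples of size >= 3")
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("zero variance in ranks; rho undefined")
    return float(np.corrcoef(rx, ry)[0, 1])


def correlation_difference_shuffle(
    group1_pairs,
    group2_pairs,
    n_shuffles: int = 100_000,
    seed: int = 0,
) -> TestResult:
    """Group-shuffle significance for a difference of Spearman correlations.

    The observed statistic is rho(group1) − rho(group2) over (x, y)
    abundance tuples.  The null is built by randomly reassigning the pooled
    pairs to two groups of the original sizes; the two-sided p-value is
    (#{|null| >= |observed|} + 1) / (n_shuffles + 1).
    """
    g1 = np.asarray(group1_pairs, dtype=float)
    g2 = np.asarray(group2_pairs, dtype=float)
    if g1.ndim != 2 or g2.ndim != 2 or g1.shape[1] != 2 or g2.shape[1] != 2:
        raise ValueError("groups must be sequences of (x, y) tuples")
    if len(g1) < 3 or len(g2) < 3:
        raise ValueError("each group needs at least 3 pairs")
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")

    observed = spearman_rho(g1[:, 0], g1[:, 1]) - spearman_rho(g2[:, 0], g2[:, 1])
    pool = np.vstack([g1, g2])
    n1 = len(g1)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_shuffles):
        perm = rng.permutation(len(pool))
        a, b = pool[perm[:n1]], pool[perm[n1:]]
        null = spearman_rho(a[:, 0], a[:, 1]) - spearman_rho(b[:, 0], b[:, 1])
        if abs(null) >= abs(observed):
            count += 1
    p = (count + 1) / (n_shuffles + 1)
    return TestResult(
        float(observed), float(p), "correlation_difference_shuffle", len(pool),
        extras={"n_shuffles": n_shuffles, "seed": seed},
    )


def wilson_interval(k: int, n: int, mass: float = 0.68) -> tuple[float, float]:
    """Wilson score interval covering central probability ``mass``.

    The 68% interval uses the exact central-mass normal quantile
    (z ≈ 0.9945), not z = 1.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n")
    if not (0.0 < mass < 1.0):
        raise ValueError("mass must be in (0, 1)")
    from statsmodels.stats.proportion import proportion_confint

    low, high = proportion_confint(k, n, alpha=1.0 - mass, method="wilson")
    # the score interval hits the boundary exactly at k = 0 and k = n
    low = 0.0 if k == 0 else float(max(0.0, low))
    high = 1.0 if k == n else float(min(1.0, high))
    return low, high


def gene_order_randomization_null(
    operons: list[Operon],
    records: list[GenePairRecord],
    n_shuffles: int = 1000,
    seed: int = 0,
) -> TestResult:
    """Within-operon gene-order randomization null for pair closeness.

    Observed statistic: mean positional distance between physically
    interacting co-operonic pairs.  Null: permute gene order uniformly and
    independently within each operon and recompute the mean (pairs sharing
    an operon share its permutation).  One-sided p (small distances = genes
    close), add-one corrected.
    """
    eligible = [
        r
        for r in records
        if r.same_operon and r.physically_interacting and r.distance is not None
    ]
    if not eligible:
        raise ValueError("no physically interacting co-operonic pairs")
    by_id = {op.operon_id: op for op in operons}
    # pair -> (operon length, index of each gene in the operon's gene list)
    plan: list[tuple[int, int, int]] = []
    for r in eligible:
        op = by_id[r.operon_id]
        gid = op.gene_ids
        plan.append((len(op), gid.index(r.gene_x), gid.index(r.gene_y)))
    observed = float(np.mean([r.distance for r in eligible]))

    # group pairs by operon so one permutation per operon per shuffle
    operon_lengths: dict[str, int] = {}
    pair_operon: list[str] = [r.operon_id for r in eligible]
    for r in eligible:
        operon_lengths[r.operon_id] = len(by_id[r.operon_id])

    rng = np.random.default_rng(seed)
    count = 0
    n_pairs = len(eligible)
    for _ in range(n_shuffles):
        perms = {
            oid: rng.permutation(length) for oid, length in operon_lengths.items()
        }
        total = 0.0
        for (length, ix, iy), oid in zip(plan, pair_operon):
            perm = perms[oid]
            total += abs(int(perm[ix]) - int(perm[iy]))
        if total / n_pairs <= observed:
            count += 1
    p = (count + 1) / (n_shuffles + 1)
    return TestResult(
        observed, float(p), "gene_order_randomization_null", n_pairs,
        extras={"n_shuffles": n_shuffles, "seed": seed},
    )


@dataclass(frozen=True)
class ConcordanceSummary:
    """How well gene order vs abundance order predict assembly order."""

    gene_order_fraction: float
    abundance_fraction: float
    n: int
    n_discordant: int
    comparison: TestResult


def predictor_concordance(records: list[GenePairRecord]) -> ConcordanceSummary:
    """Compare gene order and abundance order as predictors of assembly order.

    Eligible records have a resolved assembly order (one entity assembles
    first) and both abundances.  Gene order predicts the upstream subunit
    assembles first; abundance order predicts the more abundant subunit
    assembles first (ties never match).  The two predictors are compared
    with an exact two-sided binomial test on the records where exactly one
    of them is correct (a McNemar-style discordant-pair test).
    """
    eligible = [
        r
        for r in records
        if r.pair_order in (PairOrder.FIRST_PRECEDES, PairOrder.SECOND_PRECEDES)
        and r.abundance_x is not None
        and r.abundance_y is not None
    ]
    if not eligible:
        raise ValueError("no eligible records (resolved order + abundances)")
    gene_hits = 0
    abund_hits = 0
    gene_only = 0
    either_only = 0
    for r in eligible:
        gene_ok = r.pair_order == PairOrder.FIRST_PRECEDES
        if r.abundance_x > r.abundance_y:
            abund_ok = r.pair_order == PairOrder.FIRST_PRECEDES
        elif r.abundance_x < r.abundance_y:
            abund_ok = r.pair_order == PairOrder.SECOND_PRECEDES
        else:
            abund_ok = False
        gene_hits += gene_ok
        abund_hits += abund_ok
        if gene_ok != abund_ok:
            either_only += 1
            gene_only += gene_ok
    if either_only > 0:
        comparison = binomial_test_two_sided(gene_only, either_only, 0.5)
    else:
        comparison = TestResult(np.nan, 1.0, "binomial", 0)
    return ConcordanceSummary(
        gene_order_fraction=gene_hits / len(eligible),
        abundance_fraction=abund_hits / len(eligible),
        n=len(eligible),
        n_discordant=either_only,
        comparison=comparison,
    )
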