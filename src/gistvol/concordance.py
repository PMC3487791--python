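"""Paired-classification concordance and measurement-agreement statistics.

The central piece is an exact test of symmetry for square contingency
tables of paired categorical calls (e.g. a 3x3 table of 1D-vs-3D change
directions).  Conditional on each off-diagonal pair total
``n_ij + n_ji`` (i < j), the split is Binomial(n, 1/2) under the null of
symmetry; the two-sided p-value is the total null probability of all
off-diagonal configurations whose null probability does not exceed the
observed one (probability ordering, as in exact multinomial tests).
Computed in exact rational arithmetic, so tied configurations are handled
without floating-point tolerance.

Also here: Bland-Altman limits of agreement and Spearman rank correlation
(exact permutation p for small n).
"""

from __future__ import annotations

import itertools
import math
from collections import defaultdict
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SquareTable",
    "SymmetryTestResult",
    "AgreementResult",
    "cross_tabulate",
    "exact_symmetry_test",
    "bowker_statistic",
    "bland_altman",
    "spearman",
]

#: Above this many off-diagonal configurations the exact enumeration is
#: abandoned in favor of the asymptotic Bowker test.
_MAX_EXACT_CONFIGURATIONS = 2_000_000


@dataclass(frozen=True)
class SquareTable:
    """k x k paired cross-classification.

    ``counts[i][j]`` is the number of subjects classified ``labels[i]`` by
    method A (rows) and ``labels[j]`` by method B (columns).
    """

    labels: tuple[str, ...]
    counts: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        k = len(self.labels)
        if k < 2:
            raise ValueError("need at least 2 categories")
        if len(self.counts) != k or any(len(r) != k for r in self.counts):
            raise ValueError("counts must be square and match labels")
        if any(c < 0 for row in self.counts for c in row):
            raise ValueError("counts must be non-negative")
        if self.total < 1:
            raise ValueError("table must contain at least one observation")

    @classmethod
    def from_array(cls, counts, labels: Sequence[str]) -> "SquareTable":
        arr = np.asarray(counts, dtype=int)
        return cls(tuple(labels), tuple(tuple(int(c) for c in row) for row in arr))

    @property
    def k(self) -> int:
        return len(self.labels)

    @property
    def total(self) -> int:
        return sum(sum(row) for row in self.counts)

    @property
    def array(self) -> np.ndarray:
        return np.array(self.counts, dtype=int)

    def row_totals(self) -> tuple[int, ...]:
        return tuple(sum(row) for row in self.counts)

    def col_totals(self) -> tuple[int, ...]:
        return tuple(sum(col) for col in zip(*self.counts))

    def discordant_pairs(self) -> list[tuple[int, int]]:
        """Off-diagonal pairs (n_ij, n_ji) for i < j."""
        return [
            (self.counts[i][j], self.counts[j][i])
            for i in range(self.k)
            for j in range(i + 1, self.k)
        ]

    def transpose(self) -> "SquareTable":
        return SquareTable(self.labels, tuple(zip(*self.counts)))

    def to_dict(self) -> dict:
        return {"labels": list(self.labels),
                "counts": [list(r) for r in self.counts],
                "row_totals": list(self.row_totals()),
                "col_totals": list(self.col_totals()),
                "n": self.total}


@dataclass(frozen=True)
class SymmetryTestResult:
    p_value: float
    n_discordant: int
    method: str  # "exact" or "asymptotic_bowker"
    statistic: float | None = None  # Bowker chi-square when asymptotic
    df: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 + 1e-12):
            raise ValueError("p-value out of range")


@dataclass(frozen=True)
class AgreementResult:
    """Bland-Altman agreement summary; differences are (first - second)."""

    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    spearman_r: float
    spearman_p: float
    relative_variability_pct: float
    n: int
    sign_convention: str = "a-b"


def cross_tabulate(
    calls_a: Mapping[str, str],
    calls_b: Mapping[str, str],
    labels: Sequence[str],
) -> SquareTable:
    """Cross-classify two per-subject call series into a square table."""
    only_a = sorted(set(calls_a) - set(calls_b))
    only_b = sorted(set(calls_b) - set(calls_a))
    if only_a or only_b:
        raise ValueError(
            f"subject sets differ: only in A {only_a}, only in B {only_b}"
        )
    index = {lab: i for i, lab in enumerate(labels)}
    counts = [[0] * len(labels) for _ in labels]
    for subject, a in calls_a.items():
        b = calls_b[subject]
        if a not in index or b not in index:
            raise ValueError(f"label outside universe for subject {subject!r}")
        counts[index[a]][index[b]] += 1
    return SquareTable(tuple(labels), tuple(tuple(r) for r in counts))


def _binomial_pmf(n: int) -> list[Fraction]:
    denom = 2**n
    return [Fraction(math.comb(n, x), denom) for x in range(n + 1)]


def _exact_symmetry_p(pairs: Sequence[tuple[int, int]]) -> Fraction:
    """Probability-ordering exact p over independent Binomial(n, 1/2) pairs."""
    pmfs: list[list[Fraction]] = []
    observed = Fraction(1)
    for a, b in pairs:
        n = a + b
        if n == 0:
            continue  # contributes probability 1
        pmf = _binomial_pmf(n)
        pmfs.append(pmf)
        observed *= pmf[a]
    if not pmfs:
        return Fraction(1)
    # Distribution of the configuration probability itself: the product of
    # independent pmf values, accumulated as {product value: total mass}.
    dist: dict[Fraction, Fraction] = {Fraction(1): Fraction(1)}
    for pmf in pmfs:
        nxt: dict[Fraction, Fraction] = defaultdict(Fraction)
        # Distinct pmf values with multiplicity (pmf is symmetric).
        values: dict[Fraction, int] = defaultdict(int)
        for q in pmf:
            values[q] += 1
        for prob, mass in dist.items():
            for q, mult in values.items():
                nxt[prob * q] += mass * q * mult
        dist = dict(nxt)
    return sum(
        (mass for prob, mass in dist.items() if prob <= observed), Fraction(0)
    )


def bowker_statistic(table: SquareTable) -> tuple[float, int]:
    """Bowker's chi-square for table symmetry and its degrees of freedom.

    ``sum (n_ij - n_ji)^2 / (n_ij + n_ji)`` over pairs with positive total.
    """
    chi2 = 0.0
    df = 0
    for a, b in table.discordant_pairs():
        if a + b > 0:
            chi2 += (a - b) ** 2 / (a + b)
            df += 1
    return chi2, df


def exact_symmetry_test(table: SquareTable, method: str = "auto") -> SymmetryTestResult:
    """Test the symmetry of a paired square table.

    ``method`` is ``"exact"`` (probability-ordering enumeration),
    ``"asymptotic_bowker"``, or ``"auto"`` (exact unless the off-diagonal
    configuration space is unreasonably large).  A table with all
    off-diagonal zeros yields p = 1.
    """
    pairs = table.discordant_pairs()
    n_discordant = sum(a + b for a, b in pairs)
    n_configs = math.prod(a + b + 1 for a, b in pairs)

    if method == "auto":
        method = (
            "exact" if n_configs <= _MAX_EXACT_CONFIGURATIONS else "asymptotic_bowker"
        )
    if method == "exact":
        p = _exact_symmetry_p(pairs)
        return SymmetryTestResult(
            p_value=float(p), n_discordant=n_discordant, method="exact"
        )
    if method == "asymptotic_bowker":
        chi2, df = bowker_statistic(table)
        p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
        return SymmetryTestResult(
            p_value=p,
            n_discordant=n_discordant,
            method="asymptotic_bowker",
            statistic=chi2,
            df=df,
        )
    raise ValueError(f"unknown method {method!r}")


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Ties receive average ranks.  For n > 10 the p-value uses the usual
    t-approximation; for n <= 10 it is an exact permutation p-value over
    all n! pairings.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for a constant vector")

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    r_obs = float(np.corrcoef(rx, ry)[0, 1])

    if n > 10:
        res = stats.spearmanr(x, y)
        return r_obs, float(res.pvalue)

    # Exact permutation distribution of the rank correlation.  Correlation
    # is monotone in sum(rx * ry_perm), so enumerate that statistic.
    perms = np.fromiter(
        itertools.chain.from_iterable(itertools.permutations(range(n))),
        dtype=np.int8,
        count=math.factorial(n) * n,
    ).reshape(math.factorial(n), n)
    sums = ry[perms] @ rx  # permute y-ranks against fixed x-ranks
    mx, my = rx.mean(), ry.mean()
    sx = rx.std(ddof=0)
    sy = ry.std(ddof=0)
    r_all = (sums / n - mx * my) / (sx * sy)
    p = float(np.mean(np.abs(r_all) >= abs(r_obs) - 1e-12))
    return r_obs, p


def bland_altman(a: Sequence[float], b: Sequence[float]) -> AgreementResult:
    """Bland-Altman agreement between two paired measurement series.

    bias = mean(a - b); limits of agreement = bias +/- 1.96 * SD(a - b);
    relative variability = mean(|a - b| / midpoint) * 100 (symmetric
    percent difference).  Spearman correlation of the pairs is reported
    alongside.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D of equal length")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    diffs = a - b
    mids = (a + b) / 2.0
    if np.any(mids <= 0):
        raise ValueError("relative variability needs positive measurements")
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    rel = float(np.mean(np.abs(diffs) / mids) * 100.0)
    try:
        r, p = spearman(a, b)
    except ValueError:
        r, p = float("nan"), float("nan")
    return AgreementResult(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        sd_diff=sd,
        spearman_r=r,
        spearman_p=p,
        relative_variability_pct=rel,
        n=int(a.size),
    )
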