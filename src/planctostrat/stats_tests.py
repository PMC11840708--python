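"""Inferential statistics: paired Wilcoxon signed-rank tests and PERMANOVA.

Both procedures are implemented directly. The Wilcoxon test drops zero
differences, mid-ranks ties, and switches from the exact sign-enumeration
null (all 2^n sign assignments) to a tie-corrected, continuity-corrected
normal approximation above n_effective = 15; at exactly 15 both p-values are
reported. PERMANOVA computes the pseudo-F from squared distances and obtains
its p-value from seeded free permutations of the group labels; the observed
statistic is always included in numerator and denominator, so p is never 0.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm, rankdata

from .io_formats import DistanceMatrix


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float
    n_effective: int
    p_value: float
    alternative: str
    method: str
    p_exact: float | None = None
    p_normal: float | None = None

    def __post_init__(self) -> None:
        max_w = self.n_effective * (self.n_effective + 1) / 2
        if not 0 <= self.statistic <= max_w:
            raise ValueError("W outside [0, n(n+1)/2]")
        if not 0 < self.p_value <= 1:
            raise ValueError("p-value outside (0, 1]")


def _exact_p(ranks: np.ndarray, w_obs: float, alternative: str) -> float:
    """Exact null by enumerating all 2^n sign assignments of |d| ranks."""
    n = len(ranks)
    # W+ for every sign assignment, vectorized over the 2^n bit patterns.
    patterns = np.arange(2 ** n, dtype=np.uint32)
    bits = (patterns[:, None] >> np.arange(n)) & 1
    w_plus = bits @ ranks
    total = ranks.sum()
    eps = 1e-9
    if alternative == "greater":
        # evidence for x > y is a small negative-rank sum W-
        w_minus = total - w_plus
        return float((w_minus <= w_obs + eps).mean())
    w_min = np.minimum(w_plus, total - w_plus)
    return float((w_min <= w_obs + eps).mean())


def _normal_p(
    ranks: np.ndarray, d: np.ndarray, w_obs: float, alternative: str
) -> float:
    """Tie-corrected normal approximation with continuity correction."""
    n = len(ranks)
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    sd = math.sqrt(var)
    # w_obs is the small-tail statistic in both alternatives
    z = (w_obs - mean + 0.5) / sd
    p = float(norm.cdf(z))
    if alternative == "two_sided":
        p = min(1.0, 2.0 * p)
    return max(p, np.finfo(float).tiny)


def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two_sided",
    exact_cutoff: int = 15,
) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test of x vs y.

    alternative "two_sided" tests a symmetric-about-zero difference;
    "greater" tests x > y (small negative-rank sum W- is the evidence).
    """
    if alternative not in ("two_sided", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("x and y must have equal length")
    if len(xa) < 5:
        raise ValueError("need at least 5 pairs")
    d = xa - ya
    d = d[d != 0]
    if len(d) == 0:
        raise ValueError("all differences are zero")
    n = len(d)
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = w_minus if alternative == "greater" else min(w_plus, w_minus)

    p_exact = _exact_p(ranks, w, alternative) if n <= exact_cutoff else None
    p_normal = _normal_p(ranks, d, w, alternative) if n >= exact_cutoff else None
    if p_exact is not None:
        p_value, method = p_exact, "exact"
    else:
        p_value, method = p_normal, "normal"
    return WilcoxonResult(
        statistic=w, n_effective=n, p_value=p_value,
        alternative=alternative, method=method,
        p_exact=p_exact, p_normal=p_normal,
    )


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    n_permutations: int
    p_value: float
    group_sizes: dict

    def __post_init__(self) -> None:
        if self.pseudo_F < 0:
            raise ValueError("pseudo-F must be >= 0")
        if not 0 < self.p_value <= 1:
            raise ValueError("p-value outside (0, 1]")


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """One-way PERMANOVA pseudo-F from squared distances and group codes."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    df_between = n_groups - 1
    df_within = n - n_groups
    if ss_within <= 0:
        return math.inf if ss_between > 0 else 0.0
    return (ss_between / df_between) / (ss_within / df_within)


def _distinct_assignments(codes: np.ndarray) -> np.ndarray:
    """All distinct label arrangements of a multiset of group codes."""
    n = len(codes)
    counts: dict[int, int] = {}
    for c in codes:
        counts[int(c)] = counts.get(int(c), 0) + 1
    out: list[np.ndarray] = []

    def rec(prefix: list[int], remaining: dict[int, int]) -> None:
        if len(prefix) == n:
            out.append(np.array(prefix, dtype=np.int64))
            return
        for c in sorted(remaining):
            if remaining[c] > 0:
                remaining[c] -= 1
                prefix.append(c)
                rec(prefix, remaining)
                prefix.pop()
                remaining[c] += 1

    rec([], counts)
    return np.stack(out)


def permanova(
    dm: DistanceMatrix,
    groups: Mapping[str, str],
    n_permutations: int | str = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix with free label permutations.

    ``n_permutations="exhaustive"`` enumerates every distinct label
    arrangement instead of sampling (p = share of arrangements, the observed
    one included, with F >= F_observed).
    """
    labels = []
    for sid in dm.ids:
        if sid not in groups:
            raise ValueError(f"sample {sid!r} missing from group map")
        labels.append(groups[sid])
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    codes = np.array([uniq.index(l) for l in labels], dtype=np.int64)
    sizes = {u: int((codes == i).sum()) for i, u in enumerate(uniq)}
    for u, c in sizes.items():
        if c < 2:
            raise ValueError(f"group {u!r} has size {c} (< 2)")

    d2 = dm.d.astype(float) ** 2
    f_obs = _pseudo_f(d2, codes, len(uniq))

    if n_permutations == "exhaustive":
        assignments = _distinct_assignments(codes)
        f_perm = np.array([
            _pseudo_f(d2, a, len(uniq)) for a in assignments
        ])
        p = float((f_perm >= f_obs - 1e-12).sum() / len(assignments))
        n_perm = len(assignments)
    else:
        n_perm = int(n_permutations)
        if n_perm < 99:
            raise ValueError("need at least 99 permutations")
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(codes)
            if _pseudo_f(d2, perm, len(uniq)) >= f_obs - 1e-12:
                exceed += 1
        p = (1 + exceed) / (1 + n_perm)

    return PermanovaResult(
        pseudo_F=float(f_obs), n_permutations=n_perm,
        p_value=float(p), group_sizes=sizes,
    )
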