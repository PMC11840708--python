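"""Alpha diversity, Bray-Curtis beta diversity, single-linkage clustering
and analytic rarefaction, implemented from scratch.

Shannon entropy is reported in bits (log base 2, switchable), matching the
default of the Python ecology stack. Rarefaction uses the exact
hypergeometric expectation computed in log space, so curves are
deterministic; a seeded Monte Carlo mode exists for parity checks.
Bray-Curtis is bounded in [0, 1] and symmetric but not a metric (the
triangle inequality can fail), so no triangle property is assumed anywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io_formats import AsvTable, DistanceMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlphaResult:
    sample_id: str
    observed_asvs: int
    shannon: float

    def __post_init__(self) -> None:
        if self.observed_asvs < 0:
            raise ValueError("observed_asvs must be >= 0")
        if self.shannon < 0:
            raise ValueError("shannon must be >= 0")


def shannon(counts: Sequence[int] | np.ndarray, base: float = 2.0) -> float:
    """Shannon diversity H = -sum p_i log_base p_i over positive counts."""
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("negative count")
    total = c.sum()
    if total <= 0:
        raise ValueError("all-zero count vector")
    p = c[c > 0] / total
    return float(-(p * (np.log(p) / np.log(base))).sum())


def observed(counts: Sequence[int] | np.ndarray) -> int:
    """Number of taxa with strictly positive counts (observed features)."""
    c = np.asarray(counts)
    return int((c > 0).sum())


def alpha_table(table: AsvTable, base: float = 2.0) -> pd.DataFrame:
    """Per-sample observed ASVs and Shannon index (samples with zero reads
    get observed 0 and Shannon NaN)."""
    rows = []
    for i, sid in enumerate(table.sample_ids):
        c = table.counts[i]
        rows.append({
            "sample_id": sid,
            "layer": table.layer_of[sid],
            "observed_asvs": observed(c),
            "shannon": shannon(c, base=base) if c.sum() > 0 else float("nan"),
        })
    return pd.DataFrame(rows, columns=["sample_id", "layer", "observed_asvs", "shannon"])


# ---------------------------------------------------------------------------
# Beta diversity
# ---------------------------------------------------------------------------

def bray_curtis(u: Sequence[int] | np.ndarray, v: Sequence[int] | np.ndarray) -> float:
    """Bray-Curtis dissimilarity BC = sum|u-v| / sum(u+v), in [0, 1]."""
    a = np.asarray(u, dtype=float)
    b = np.asarray(v, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    if a.sum() <= 0 or b.sum() <= 0:
        raise ValueError("zero-total count vector")
    return float(np.abs(a - b).sum() / (a + b).sum())


def bray_curtis_matrix(table: AsvTable, drop_empty: bool = True) -> DistanceMatrix:
    """Pairwise Bray-Curtis over samples; zero-read samples are dropped with
    a warning (they have no defined dissimilarity)."""
    totals = table.counts.sum(axis=1)
    keep = [i for i in range(table.n_samples) if totals[i] > 0]
    dropped = [table.sample_ids[i] for i in range(table.n_samples) if totals[i] == 0]
    if dropped:
        if not drop_empty:
            raise ValueError(f"samples with zero reads: {dropped}")
        logger.warning("dropping %d zero-read sample(s) from beta diversity: %s",
                       len(dropped), dropped)
    ids = [table.sample_ids[i] for i in keep]
    n = len(ids)
    d = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            d[a, b] = d[b, a] = bray_curtis(
                table.counts[keep[a]], table.counts[keep[b]]
            )
    return DistanceMatrix(ids=ids, d=d)


# ---------------------------------------------------------------------------
# Single-linkage clustering
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    """Binary merge tree: leaves 0..n-1 (labels), internal nodes n, n+1, ...

    merges[k] = (node_a, node_b, height, new_node); heights are non-decreasing
    (single-linkage monotonicity).
    """

    labels: list[str]
    merges: list[tuple[int, int, float, int]]

    def __post_init__(self) -> None:
        n = len(self.labels)
        if len(self.merges) != n - 1:
            raise ValueError(f"{n} leaves require {n - 1} merges")
        heights = [m[2] for m in self.merges]
        if any(b < a - 1e-12 for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def heights(self) -> list[float]:
        return [m[2] for m in self.merges]


def single_linkage(dm: DistanceMatrix) -> Dendrogram:
    """Agglomerate by minimum inter-cluster distance (nearest point).

    Ties are broken by the lexicographically smallest pair of cluster
    representative ids (each cluster represented by its smallest member id),
    making the topology platform-independent.
    """
    n = len(dm)
    if n < 2:
        raise ValueError("need at least 2 samples to cluster")

    # active cluster: node index -> (set of leaf indices, representative id)
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    rep = {i: dm.ids[i] for i in range(n)}
    merges: list[tuple[int, int, float, int]] = []
    next_node = n

    while len(clusters) > 1:
        best = None  # (distance, rep_lo, rep_hi, node_a, node_b)
        items = list(clusters.items())
        for ai in range(len(items)):
            for bi in range(ai + 1, len(items)):
                na, members_a = items[ai]
                nb, members_b = items[bi]
                dist = min(dm.d[x, y] for x in members_a for y in members_b)
                lo, hi = sorted((rep[na], rep[nb]))
                key = (dist, lo, hi)
                if best is None or key < best[0]:
                    # orient the pair so node_a carries the smaller rep id
                    if rep[na] <= rep[nb]:
                        best = (key, na, nb)
                    else:
                        best = (key, nb, na)
        (dist, _, _), na, nb = best
        merges.append((na, nb, float(dist), next_node))
        clusters[next_node] = clusters.pop(na) + clusters.pop(nb)
        rep[next_node] = min(rep[na], rep[nb])
        next_node += 1

    return Dendrogram(labels=list(dm.ids), merges=merges)


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------

def _log_comb(n: np.ndarray | float, k: float) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefaction_curve(
    counts: Sequence[int] | np.ndarray, depths: Sequence[int]
) -> list[tuple[int, float]]:
    """Expected richness at each subsampling depth (exact hypergeometric).

    E[S_d] = sum_i [1 - C(N - n_i, d) / C(N, d)], evaluated in log space.
    """
    c = np.asarray(counts, dtype=np.int64)
    if np.any(c < 0):
        raise ValueError("negative count")
    c = c[c > 0]
    N = int(c.sum())
    depths = list(depths)
    if any(b <= a for a, b in zip(depths, depths[1:])):
        raise ValueError("depths must be strictly increasing")
    out: list[tuple[int, float]] = []
    for d in depths:
        if d < 0:
            raise ValueError("negative depth")
        if d > N:
            raise ValueError(f"depth {d} exceeds total count {N}")
        if d == 0:
            out.append((0, 0.0))
            continue
        absent = np.zeros(len(c))
        ok = (N - c) >= d
        absent[ok] = np.exp(_log_comb((N - c[ok]).astype(float), float(d))
                            - _log_comb(float(N), float(d)))
        out.append((int(d), float((1.0 - absent).sum())))
    return out


def rarefaction_resampled(
    counts: Sequence[int] | np.ndarray,
    depths: Sequence[int],
    n_iter: int = 100,
    seed: int | None = None,
) -> list[tuple[int, float]]:
    """Monte Carlo rarefaction (subsampling without replacement); exists as a
    seeded parity check for the analytic curve."""
    rng = np.random.default_rng(seed)
    c = np.asarray(counts, dtype=np.int64)
    c = c[c > 0]
    N = int(c.sum())
    pool = np.repeat(np.arange(len(c)), c)
    out = []
    for d in depths:
        if d > N:
            raise ValueError(f"depth {d} exceeds total count {N}")
        rich = [len(np.unique(rng.choice(pool, size=d, replace=False)))
                for _ in range(n_iter)]
        out.append((int(d), float(np.mean(rich))))
    return out


def rarefaction_table(table: AsvTable, n_depths: int = 10) -> pd.DataFrame:
    """Analytic rarefaction curves for every sample, at n_depths evenly spaced
    depths up to each sample's total."""
    rows = []
    for i, sid in enumerate(table.sample_ids):
        total = int(table.counts[i].sum())
        if total == 0:
            continue
        depths = sorted(set(np.linspace(1, total, n_depths, dtype=int)))
        for d, s in rarefaction_curve(table.counts[i], depths):
            rows.append({"sample_id": sid, "depth": d, "expected_richness": s})
    return pd.DataFrame(rows, columns=["sample_id", "depth", "expected_richness"])
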