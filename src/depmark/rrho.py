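"""Rank-rank hypergeometric overlap (RRHO) between two signed gene rankings.

Each differential-expression list is ranked by the signed score
``s = -log10(p) * sign(FC)`` (most significantly up-regulated first, most
significantly down-regulated last).  For every pair of rank thresholds
``(i, j)`` on a fixed step grid, the overlap ``k`` of the two top-``i`` /
top-``j`` segments is scored with an exact hypergeometric tail test; cells
where ``k`` exceeds its expectation ``i*j/N`` are labelled over-enriched
(upper tail), the rest under-enriched (lower tail).  Because the grid spans
the whole lists, concordance shows up along the diagonal and blood-brain
anti-correlation in the off-diagonal corners.

Per-cell p-values are strongly dependent across the map, so the summary
statistic is the map maximum, optionally calibrated against a permutation
null of independently shuffled lists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .errors import DataError

#: cap on -log10(p) to avoid infinities at extreme overlaps
NEG_LOG10_CAP = 320.0

_LOG10 = np.log(10.0)


@dataclass
class RankedList:
    """Genes ordered by descending signed significance score."""

    genes: np.ndarray   # ordered ids
    scores: np.ndarray  # aligned signed scores, descending

    def __post_init__(self) -> None:
        if len(self.genes) != len(set(self.genes)):
            raise DataError("ranked list contains duplicate gene ids")
        if np.any(np.diff(self.scores) > 1e-12):
            raise DataError("ranked list scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def n_positive(self) -> int:
        """Number of genes with strictly positive score (up-regulated head)."""
        return int(np.count_nonzero(self.scores > 0))

    def ranks(self) -> pd.Series:
        """1-based rank per gene."""
        return pd.Series(np.arange(1, len(self) + 1), index=self.genes)


def signed_rank(contrast: pd.DataFrame) -> RankedList:
    """Rank a contrast table by -log10(p) * sign(FC), descending.

    Ties are broken deterministically by gene id (ascending).  A p-value of
    exactly 0 is rejected; contrasts floor p upstream.
    """
    p = contrast["p"].to_numpy(dtype=float)
    if (p <= 0).any():
        raise DataError("p = 0 encountered; p-values must be floored upstream")
    if (p > 1).any():
        raise DataError("p > 1 encountered")
    score = -np.log10(p) * contrast["sign"].to_numpy()
    order = np.lexsort((contrast.index.to_numpy(), -score))
    return RankedList(genes=contrast.index.to_numpy()[order], scores=score[order])


# ---------------------------------------------------------------------------
# hypergeometric tail
# ---------------------------------------------------------------------------

def _log_pmf(N: int, K, n, x):
    """log PMF of Hypergeom(N, K, n) at x, via log-gamma."""
    K = np.asarray(K, dtype=float)
    n = np.asarray(n, dtype=float)
    x = np.asarray(x, dtype=float)
    return (
        gammaln(K + 1) - gammaln(x + 1) - gammaln(K - x + 1)
        + gammaln(N - K + 1) - gammaln(n - x + 1) - gammaln(N - K - n + x + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )


def log_hypergeom_tail(N: int, K: int, n: int, k: int, lower: bool = False) -> float:
    """Natural log of P(X >= k) (or P(X <= k) with ``lower``) for
    X ~ Hypergeom(N, K, n), by exact tail summation in log space."""
    if not (0 <= k <= min(K, n) <= N) or n > N or K > N or min(K, n, k) < 0:
        raise DataError(f"inconsistent hypergeometric arguments N={N} K={K} n={n} k={k}")
    x_min = max(0, n + K - N)
    x_max = min(K, n)
    if (not lower and k <= x_min) or (lower and k >= x_max):
        return 0.0  # the tail covers the whole support: probability exactly 1
    xs = np.arange(x_min, k + 1) if lower else np.arange(k, x_max + 1)
    if len(xs) == 0:
        return -np.inf
    return float(min(logsumexp(_log_pmf(N, K, n, xs)), 0.0))


def hypergeom_tail(N: int, K: int, n: int, k: int, lower: bool = False) -> float:
    """Exact hypergeometric tail probability P(X >= k) (upper, default) or
    P(X <= k); numerically stable for universes up to ~1e5."""
    return float(min(1.0, np.exp(log_hypergeom_tail(N, K, n, k, lower=lower))))


def _neg_log10_tail_grid(N: int, K: np.ndarray, n: np.ndarray, k: np.ndarray,
                         lower: np.ndarray) -> np.ndarray:
    """-log10 tail probability per grid cell.  K, n, k, lower are same-shape."""
    out = np.empty(k.shape, dtype=float)
    it = np.nditer(k, flags=["multi_index"])
    lg = gammaln(np.arange(2 * N + 2) + 1.0)  # lookup table for integer gammaln

    def log_pmf_int(Ki, ni, xs):
        return (
            lg[Ki] - lg[xs] - lg[Ki - xs]
            + lg[N - Ki] - lg[ni - xs] - lg[N - Ki - ni + xs]
            - (lg[N] - lg[ni] - lg[N - ni])
        )

    for _ in it:
        idx = it.multi_index
        Ki, ni, ki, lo = int(K[idx]), int(n[idx]), int(k[idx]), bool(lower[idx])
        x_min = max(0, ni + Ki - N)
        x_max = min(Ki, ni)
        if (not lo and ki <= x_min) or (lo and ki >= x_max):
            out[idx] = 0.0  # certain event: tail covers the whole support
            continue
        xs = np.arange(x_min, ki + 1) if lo else np.arange(ki, x_max + 1)
        val = logsumexp(log_pmf_int(Ki, ni, xs)) if len(xs) else -np.inf
        out[idx] = min(-val / _LOG10, NEG_LOG10_CAP)
    return np.clip(out, 0.0, NEG_LOG10_CAP)


# ---------------------------------------------------------------------------
# the map
# ---------------------------------------------------------------------------

@dataclass
class RRHOMap:
    """Grid of hypergeometric -log10(p) values over rank-threshold pairs."""

    neg_log_p: np.ndarray      # (len(thresholds_a), len(thresholds_b))
    sign: np.ndarray           # +1 over-enriched, -1 under-enriched
    counts: np.ndarray         # overlap k per cell
    thresholds_a: np.ndarray
    thresholds_b: np.ndarray
    step: int
    n_genes: int
    n_positive_a: int
    n_positive_b: int
    mode: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.neg_log_p, index=self.thresholds_a,
                            columns=self.thresholds_b)


def default_step(n_genes: int) -> int:
    """Grid step giving roughly 100 x 100 maps."""
    return max(1, n_genes // 100)


def rrho_map(
    list_a: RankedList,
    list_b: RankedList,
    step: int | None = None,
    mode: str = "two_ends",
) -> RRHOMap:
    """Build the RRHO grid for two rankings over an identical gene universe.

    ``mode="two_ends"`` (default) scores over-enriched cells with the upper
    tail and under-enriched cells with the lower tail; ``mode="over_only"``
    scores every cell with the upper tail only (a variant restricted to
    over-enrichment).
    """
    if mode not in ("two_ends", "over_only"):
        raise DataError(f"unknown mode {mode!r}")
    if set(list_a.genes) != set(list_b.genes):
        raise DataError("ranked lists cover different gene universes")
    n = len(list_a)
    if step is None:
        step = default_step(n)
    if step < 1:
        raise DataError("step must be >= 1")
    thresholds = np.arange(step, n + 1, step)

    rank_b = pd.Series(np.arange(1, n + 1), index=list_b.genes)
    pos_b = rank_b.loc[list_a.genes].to_numpy()  # rank in B, ordered by A
    pos_a = np.arange(1, n + 1)
    edges = np.concatenate([[0.5], thresholds + 0.5])
    hist, _, _ = np.histogram2d(pos_a, pos_b, bins=[edges, edges])
    counts = hist.cumsum(axis=0).cumsum(axis=1)

    i_grid = thresholds[:, None].astype(float)
    j_grid = thresholds[None, :].astype(float)
    expected = i_grid * j_grid / n
    over = counts >= expected
    sign = np.where(over, 1, -1)
    lower = ~over if mode == "two_ends" else np.zeros_like(over)
    values = _neg_log10_tail_grid(
        n,
        np.broadcast_to(i_grid, counts.shape),
        np.broadcast_to(j_grid, counts.shape),
        counts,
        np.broadcast_to(lower, counts.shape),
    )
    return RRHOMap(
        neg_log_p=values,
        sign=sign,
        counts=counts.astype(int),
        thresholds_a=thresholds,
        thresholds_b=thresholds,
        step=step,
        n_genes=n,
        n_positive_a=list_a.n_positive,
        n_positive_b=list_b.n_positive,
        mode=mode,
    )


@dataclass
class RRHOSummary:
    max_neg_log_p: float
    argmax: tuple[int, int]     # rank thresholds (i, j)
    quadrant: str               # e.g. "up-up"
    null_percentile: float | None = None


def rrho_summary(rrho: RRHOMap, null_maxima: np.ndarray | None = None) -> RRHOSummary:
    """Map maximum, its rank-threshold location (ties -> smallest (i, j)
    lexicographically) and the dominant quadrant; if a permutation null of map
    maxima is supplied, also the observed maximum's percentile within it."""
    if rrho.neg_log_p.size == 0:
        raise DataError("empty map")
    flat = np.argwhere(rrho.neg_log_p == rrho.neg_log_p.max())
    ai, bj = min((tuple(x) for x in flat))
    i = int(rrho.thresholds_a[ai])
    j = int(rrho.thresholds_b[bj])
    quadrant = (
        ("up" if i <= rrho.n_positive_a else "down")
        + "-" + ("up" if j <= rrho.n_positive_b else "down")
    )
    pct = None
    if null_maxima is not None and len(null_maxima):
        pct = float(np.mean(np.asarray(null_maxima) <= rrho.neg_log_p.max()) * 100.0)
    return RRHOSummary(
        max_neg_log_p=float(rrho.neg_log_p.max()),
        argmax=(i, j),
        quadrant=quadrant,
        null_percentile=pct,
    )


def null_max_distribution(
    n_genes: int, step: int | None = None, n_reps: int = 100,
    seed: int | None = 0, mode: str = "two_ends",
) -> np.ndarray:
    """Map maxima for independently permuted rankings (the permutation null)."""
    rng = np.random.default_rng(seed)
    genes = np.array([f"n{i}" for i in range(n_genes)])
    scores = np.linspace(3.0, -3.0, n_genes)
    maxima = np.empty(n_reps)
    for r in range(n_reps):
        la = RankedList(genes=genes[rng.permutation(n_genes)], scores=scores)
        lb = RankedList(genes=genes[rng.permutation(n_genes)], scores=scores)
        maxima[r] = rrho_map(la, lb, step=step, mode=mode).neg_log_p.max()
    return maxima


# ---------------------------------------------------------------------------
# overlap gene extraction
# ---------------------------------------------------------------------------

def _best_segment_overlap(
    order_a: np.ndarray, order_b: np.ndarray, n: int, step: int,
    lim_a: int, lim_b: int,
) -> tuple[list[str], float, tuple[int, int]]:
    """Most over-enriched top-segment pair within (lim_a, lim_b); returns the
    intersection genes, the -log10 p, and the (i, j) thresholds."""
    thr_a = np.arange(step, lim_a + 1, step)
    thr_b = np.arange(step, lim_b + 1, step)
    if len(thr_a) == 0 or len(thr_b) == 0:
        return [], 0.0, (0, 0)
    rank_b = pd.Series(np.arange(1, n + 1), index=order_b)
    pos_b = rank_b.loc[order_a].to_numpy()
    pos_a = np.arange(1, n + 1)
    edges_a = np.concatenate([[0.5], thr_a + 0.5, [n + 0.5]])
    edges_b = np.concatenate([[0.5], thr_b + 0.5, [n + 0.5]])
    hist, _, _ = np.histogram2d(pos_a, pos_b, bins=[edges_a, edges_b])
    counts = hist.cumsum(axis=0).cumsum(axis=1)[: len(thr_a), : len(thr_b)]
    i_grid = np.broadcast_to(thr_a[:, None].astype(float), counts.shape)
    j_grid = np.broadcast_to(thr_b[None, :].astype(float), counts.shape)
    values = _neg_log10_tail_grid(
        n, i_grid, j_grid, counts, np.zeros_like(counts, dtype=bool)
    )
    flat = np.argwhere(values == values.max())
    ai, bj = min((tuple(x) for x in flat))
    i, j = int(thr_a[ai]), int(thr_b[bj])
    top_a = set(order_a[:i])
    genes = [g for g in order_b[:j] if g in top_a]
    return genes, float(values[ai, bj]), (i, j)


def overlap_genes(
    rrho: RRHOMap, list_a: RankedList, list_b: RankedList, mode: str,
) -> list[str]:
    """Extract the co-dysregulated genes behind the relevant map quadrant.

    ``concordant_up``   - up-regulated heads of both lists;
    ``concordant_down`` - down-regulated tails of both lists;
    ``discordant``      - head of one list against the tail of the other, both
                          orientations combined.
    The segment pair is the over-enrichment argmax within the quadrant, and
    the returned genes are the intersection of the two segments.
    """
    n = rrho.n_genes
    step = rrho.step
    a_desc, b_desc = list_a.genes, list_b.genes
    a_asc, b_asc = list_a.genes[::-1], list_b.genes[::-1]
    n_neg_a = n - list_a.n_positive - int(np.count_nonzero(list_a.scores == 0))
    n_neg_b = n - list_b.n_positive - int(np.count_nonzero(list_b.scores == 0))

    if mode == "concordant_up":
        genes, _, _ = _best_segment_overlap(
            a_desc, b_desc, n, step, list_a.n_positive, list_b.n_positive)
    elif mode == "concordant_down":
        genes, _, _ = _best_segment_overlap(a_asc, b_asc, n, step, n_neg_a, n_neg_b)
    elif mode == "discordant":
        up_down, _, _ = _best_segment_overlap(
            a_desc, b_asc, n, step, list_a.n_positive, n_neg_b)
        down_up, _, _ = _best_segment_overlap(
            a_asc, b_desc, n, step, n_neg_a, list_b.n_positive)
        seen = set()
        genes = [g for g in up_down + down_up if not (g in seen or seen.add(g))]
    else:
        raise DataError(f"unknown overlap mode {mode!r}")
    if not genes:
        warnings.warn(f"empty overlap quadrant for mode {mode!r}", stacklevel=2)
    return genes
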