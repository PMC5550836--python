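"""Behavioral phenotyping: responder classification and group statistics.

Stressed, fluoxetine-treated mice (S-FLX) are split into responders (S-FLX-R,
sum of the two coat-state scores <= 2) and nonresponders (S-FLX-NR, sum > 2).
Weight gain is compared by pooled-variance Student t-tests after a
Shapiro-Wilk normality check; coat and nest scores use an exact Mann-Whitney
test (small samples, ordinal scores).
"""

from __future__ import annotations

import itertools
import warnings
from math import comb, sqrt

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix
from .errors import DataError

RESPONDER_CUTOFF = 2.0


def derive_scores(behavior: pd.DataFrame) -> pd.DataFrame:
    """Add ``coat_sum`` (coat1 + coat2) and ``nest_diff`` (24h - 5h) columns."""
    out = behavior.copy()
    if "coat_sum" not in out.columns:
        out["coat_sum"] = out["coat1"] + out["coat2"]
    if "nest_diff" not in out.columns and {"nest5h", "nest24h"} <= set(out.columns):
        out["nest_diff"] = out["nest24h"] - out["nest5h"]
    return out


def classify_response(records: pd.DataFrame, cutoff: float = RESPONDER_CUTOFF) -> pd.DataFrame:
    """Split S-FLX mice into responders/nonresponders by coat-score sum.

    Only S-FLX records are relabeled: coat_sum <= cutoff -> ``S-FLX-R``,
    coat_sum > cutoff -> ``S-FLX-NR``.  Idempotent: already-split labels pass
    through unchanged.
    """
    records = derive_scores(records)
    is_sflx = records["group"] == "S-FLX"
    missing = records.loc[is_sflx & records["coat_sum"].isna()]
    if len(missing):
        raise DataError(f"S-FLX mice without coat_sum: {missing['mouse'].tolist()}")
    out = records.copy()
    out.loc[is_sflx, "group"] = np.where(
        records.loc[is_sflx, "coat_sum"] <= cutoff, "S-FLX-R", "S-FLX-NR"
    )
    return out


def exclude_outlier_samples(matrix: ExpressionMatrix, sample_ids: list[str]) -> ExpressionMatrix:
    """Drop listed samples (e.g. a transcriptional-outlier mouse) from a matrix.

    Every remaining group must keep at least two samples so downstream
    contrasts stay defined.
    """
    if not sample_ids:
        return matrix
    unknown = [s for s in sample_ids if s not in matrix.samples.index]
    if unknown:
        raise DataError(f"unknown sample ids: {unknown}")
    keep = [s for s in matrix.samples.index if s not in set(sample_ids)]
    remaining = matrix.samples.loc[keep, "group"].value_counts()
    starved = remaining[remaining < 2]
    if len(starved):
        raise DataError(
            f"removal would leave groups with < 2 samples: {starved.to_dict()}"
        )
    warnings.warn(f"excluded samples: {sorted(sample_ids)}", stacklevel=2)
    return matrix.subset_samples(keep)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for sample x: #(x_i > y_j) + half the tied pairs."""
    gt = (x[:, None] > y[None, :]).sum()
    ties = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(ties)


def mann_whitney_exact(x, y) -> tuple[float, float]:
    """Mann-Whitney U (for ``x``) with a two-sided p-value.

    The p-value is exact by enumeration of all C(n_x+n_y, n_x) group
    assignments of the pooled values when n_x + n_y <= 16 (ties handled by
    enumerating the observed multiset), otherwise a normal approximation with
    tie correction is used.  Two-sided p = 2 * min(P(U <= u), P(U >= u)),
    capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DataError("Mann-Whitney requires both samples non-empty")
    nx, ny = x.size, y.size
    u = _u_statistic(x, y)
    if nx + ny <= 16:
        # U for a subset equals its midrank sum minus nx(nx+1)/2, so the whole
        # null distribution is one vectorized gather over all C(n, nx) subsets
        pooled = np.concatenate([x, y])
        n = nx + ny
        midranks = stats.rankdata(pooled)
        combs = np.fromiter(
            itertools.chain.from_iterable(itertools.combinations(range(n), nx)),
            dtype=np.intp,
        ).reshape(-1, nx)
        us = midranks[combs].sum(axis=1) - nx * (nx + 1) / 2.0
        total = comb(n, nx)
        eps = 1e-9
        p_le = np.count_nonzero(us <= u + eps) / total
        p_ge = np.count_nonzero(us >= u - eps) / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return u, p
    # normal approximation with tie correction
    pooled = np.concatenate([x, y])
    n = nx + ny
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / (n * (n - 1))
    sigma2 = nx * ny / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return u, 1.0
    z = (u - nx * ny / 2.0) / sqrt(sigma2)
    return u, min(1.0, 2.0 * stats.norm.sf(abs(z)))


def student_t(x, y) -> tuple[float, float]:
    """Pooled-variance two-sample Student t with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise DataError("t-test requires >= 2 observations per group")
    df = nx + ny - 2
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / df
    se = sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    diff = x.mean() - y.mean()
    if se == 0.0:
        return (0.0, 1.0) if diff == 0.0 else (np.inf * np.sign(diff), 0.0)
    t = diff / se
    return float(t), float(2.0 * stats.t.sf(abs(t), df))


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


#: measure -> (column, test) used by behavior_summary
_MEASURES = {
    "weight_gain": ("weight_gain", "t"),
    "coat_sum": ("coat_sum", "mann-whitney"),
    "nest_diff": ("nest_diff", "mann-whitney"),
}


def behavior_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Pairwise group statistics for weight gain, coat and nest scores.

    Shapiro-Wilk p-values are reported as a normality gate for each group but
    never switch the test (tests are pre-assigned per measure); groups with
    fewer than three observations skip the gate with a warning.
    """
    records = derive_scores(records)
    groups = sorted(records["group"].unique())
    rows = []
    for measure, (column, test) in _MEASURES.items():
        if column not in records.columns:
            continue
        for g1, g2 in itertools.combinations(groups, 2):
            x = records.loc[records["group"] == g1, column].dropna().to_numpy()
            y = records.loc[records["group"] == g2, column].dropna().to_numpy()
            shapiro = []
            for g, vals in ((g1, x), (g2, y)):
                if len(vals) < 3:
                    warnings.warn(
                        f"group {g} has < 3 observations; Shapiro-Wilk gate skipped",
                        stacklevel=2,
                    )
                    shapiro.append(np.nan)
                elif np.ptp(vals) == 0:
                    shapiro.append(np.nan)  # degenerate: identical values
                else:
                    shapiro.append(stats.shapiro(vals).pvalue)
            if test == "t":
                stat, p = student_t(x, y)
            else:
                stat, p = mann_whitney_exact(x, y)
            rows.append({
                "measure": measure, "group1": g1, "group2": g2,
                "n1": len(x), "n2": len(y),
                "shapiro_p1": shapiro[0], "shapiro_p2": shapiro[1],
                "test": test, "stat": stat, "p": p,
                "stars": significance_stars(p),
            })
    return pd.DataFrame(rows)
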