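"""Per-gene contrasts, SAM permutation-FDR selection, and candidate filters.

Contrasts use pooled-variance (Student) two-sample t-tests per gene with
linear-scale fold changes, FC = 2**(mean_a - mean_b).  The Significance
Analysis of Microarrays (SAM) implementation follows the classical two-class
unpaired d-statistic d_i = r_i / (s_i + s0), with the exchangeability factor
s0 chosen to minimise the coefficient of variation of the d spread across
5th-percentile windows of s, and FDR estimated as the median permutation
false-call count over the observed call count.

Two selection rules mirror the discovery strategy:

* :func:`reversal_filter` keeps genes dysregulated by stress (p < 0.05),
  restored in treatment responders (p < 0.05 with opposite direction), and
  untouched by the drug alone;
* :func:`stress_filter` keeps genes strongly stress-specific
  (p < 0.01 and fold change beyond 1.2 in either direction).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CONTRAST_COLUMNS, MIN_P, ExpressionMatrix
from .errors import DataError


def _pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise pooled-variance t and two-sided p for two sample blocks."""
    na, nb = a.shape[1], b.shape[1]
    df = na + nb - 2
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    sp2 = ((a.var(axis=1, ddof=1) * (na - 1)) + (b.var(axis=1, ddof=1) * (nb - 1))) / df
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    diff = mean_a - mean_b
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    t = np.where((se == 0) & (diff == 0), 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isnan(p), MIN_P, p)  # se == 0, diff != 0 -> infinite t
    return t, np.clip(p, MIN_P, 1.0)


def contrast(matrix: ExpressionMatrix, group_a: str, group_b: str) -> pd.DataFrame:
    """Per-gene contrast table for ``group_a`` vs ``group_b``.

    Returns a DataFrame indexed by gene with columns mean_a, mean_b, t, p,
    fc (linear scale) and sign (+1 if group_a mean >= group_b mean).
    p-values are floored at the smallest positive float so -log10(p) stays
    finite downstream.
    """
    samples_a = matrix.group_samples(group_a)
    samples_b = matrix.group_samples(group_b)
    for name, s in ((group_a, samples_a), (group_b, samples_b)):
        if len(s) < 2:
            raise DataError(f"group {name!r} has {len(s)} samples; need >= 2")
    a = matrix.values[samples_a].to_numpy(dtype=float)
    b = matrix.values[samples_b].to_numpy(dtype=float)
    t, p = _pooled_t(a, b)
    diff = a.mean(axis=1) - b.mean(axis=1)
    table = pd.DataFrame(
        {
            "mean_a": a.mean(axis=1),
            "mean_b": b.mean(axis=1),
            "t": t,
            "p": p,
            "fc": 2.0 ** diff,
            "sign": np.where(diff >= 0, 1, -1).astype(int),
        },
        index=matrix.values.index.copy(),
    )
    table.attrs["contrast"] = f"{group_a} vs {group_b}"
    table.attrs["multiplicity_control"] = "none"
    return table[list(CONTRAST_COLUMNS)]


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

@dataclass
class SamResult:
    """Outcome of a two-class SAM run."""

    d: pd.Series                      # observed d statistic per gene
    s0: float                         # fudge factor
    delta_table: pd.DataFrame         # delta, n_called, n_false_median, fdr
    selected: list[str]               # largest gene set with FDR <= target
    delta: float                      # delta achieving that set
    fdr: float                        # FDR estimate at that delta
    target_fdr: float
    n_perm: int
    seed: int | None
    cuts: tuple[float, float] = field(default=(np.inf, -np.inf))  # (cutup, cutlow)


def _d_statistic(values: np.ndarray, mask_b: np.ndarray, s0: float) -> np.ndarray:
    a = values[:, ~mask_b]
    b = values[:, mask_b]
    na, nb = a.shape[1], b.shape[1]
    r = b.mean(axis=1) - a.mean(axis=1)
    sp2 = ((a.var(axis=1, ddof=1) * (na - 1)) + (b.var(axis=1, ddof=1) * (nb - 1))) / (na + nb - 2)
    s = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    return r / (s + s0)


def _pooled_se(values: np.ndarray, mask_b: np.ndarray) -> np.ndarray:
    a = values[:, ~mask_b]
    b = values[:, mask_b]
    na, nb = a.shape[1], b.shape[1]
    sp2 = ((a.var(axis=1, ddof=1) * (na - 1)) + (b.var(axis=1, ddof=1) * (nb - 1))) / (na + nb - 2)
    return np.sqrt(sp2 * (1.0 / na + 1.0 / nb))


def choose_s0(r: np.ndarray, s: np.ndarray) -> float:
    """Tusher-style fudge factor: the s-quantile minimising the coefficient of
    variation of the d spread across 5th-percentile windows of s."""
    qs = np.quantile(s, np.arange(0.0, 1.01, 0.05))
    edges = np.quantile(s, np.arange(0.0, 1.01, 0.05))
    window = np.clip(np.searchsorted(edges[1:-1], s, side="right"), 0, 19)
    best_s0, best_cv = float(np.median(s)), np.inf
    for s0 in np.unique(qs):
        d = r / (s + s0)
        mads = np.array([
            stats.median_abs_deviation(d[window == w], scale="normal")
            for w in range(20) if np.count_nonzero(window == w) >= 2
        ])
        mads = mads[np.isfinite(mads) & (mads > 0)]
        if len(mads) < 2:
            continue
        cv = mads.std(ddof=1) / mads.mean()
        if cv < best_cv:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def _label_permutations(mask_b: np.ndarray, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Distinct two-class label assignments: exhaustive when few, sampled otherwise."""
    n = mask_b.size
    nb = int(mask_b.sum())
    n_distinct = comb(n, nb)
    if n_distinct <= n_perm:
        perms = np.zeros((n_distinct, n), dtype=bool)
        for i, idx in enumerate(itertools.combinations(range(n), nb)):
            perms[i, list(idx)] = True
        return perms
    perms = np.zeros((n_perm, n), dtype=bool)
    for i in range(n_perm):
        perms[i, rng.choice(n, size=nb, replace=False)] = True
    return perms


def sam_select(
    matrix: ExpressionMatrix | pd.DataFrame,
    labels: pd.Series | dict | None = None,
    target_fdr: float = 0.01,
    n_perm: int = 200,
    seed: int | None = 0,
    s0: float | None = None,
    n_delta: int = 40,
) -> SamResult:
    """Two-class unpaired SAM with permutation FDR.

    ``labels`` maps sample id to one of two class labels; for an
    :class:`ExpressionMatrix` it defaults to the sample sheet's group column.
    Genes are called at a threshold delta on the sorted observed d versus the
    permutation-mean order statistics; the reported set is the largest one
    whose estimated FDR (median permutation false calls / observed calls) is
    at or below ``target_fdr``.
    """
    if isinstance(matrix, ExpressionMatrix):
        frame = matrix.values
        if labels is None:
            labels = matrix.samples["group"]
    else:
        frame = matrix
        if labels is None:
            raise DataError("labels required when passing a bare DataFrame")
    labels = pd.Series(labels).loc[frame.columns]
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise DataError(f"SAM needs exactly two classes, got {classes}")
    if n_perm < 50:
        raise DataError("n_perm must be >= 50 for a usable FDR estimate")
    values = frame.to_numpy(dtype=float)
    mask_b = (labels == classes[1]).to_numpy()

    a = values[:, ~mask_b]
    b = values[:, mask_b]
    r = b.mean(axis=1) - a.mean(axis=1)
    s = _pooled_se(values, mask_b)
    if s0 is None:
        s0 = choose_s0(r, s)

    d_obs = r / (s + s0)
    order = np.argsort(d_obs)
    d_sorted = d_obs[order]

    rng = np.random.default_rng(seed)
    perms = _label_permutations(mask_b, n_perm, rng)
    d_perm_sorted = np.empty((len(perms), len(d_obs)))
    for i, pm in enumerate(perms):
        d_perm_sorted[i] = np.sort(_d_statistic(values, pm, s0))
    d_bar = d_perm_sorted.mean(axis=0)

    gaps = d_sorted - d_bar
    max_gap = float(np.abs(gaps).max()) if len(gaps) else 0.0
    deltas = np.linspace(0.0, max_gap, n_delta + 1)[1:]

    n_genes = len(d_obs)
    centre = n_genes // 2
    rows = []
    chosen = None
    for delta in deltas:
        # cutup: smallest sorted d above the centre whose gap exceeds delta
        up_idx = np.flatnonzero(gaps[centre:] >= delta)
        cutup = d_sorted[centre + up_idx[0]] if len(up_idx) else np.inf
        low_idx = np.flatnonzero(-gaps[:centre + 1] >= delta)
        cutlow = d_sorted[low_idx[-1]] if len(low_idx) else -np.inf
        called = (d_obs >= cutup) | (d_obs <= cutlow)
        n_called = int(called.sum())
        false_counts = ((d_perm_sorted >= cutup) | (d_perm_sorted <= cutlow)).sum(axis=1)
        n_false = float(np.median(false_counts))
        fdr = min(1.0, n_false / n_called) if n_called else 0.0
        rows.append({"delta": delta, "n_called": n_called,
                     "n_false_median": n_false, "fdr": fdr,
                     "cutup": cutup, "cutlow": cutlow})
        if fdr <= target_fdr and n_called and chosen is None:
            chosen = rows[-1]
    delta_table = pd.DataFrame(rows)
    if chosen is None:
        chosen = {"delta": float(deltas[-1]) if len(deltas) else 0.0,
                  "n_called": 0, "fdr": 0.0, "cutup": np.inf, "cutlow": -np.inf}
    called = (d_obs >= chosen["cutup"]) | (d_obs <= chosen["cutlow"])
    selected = frame.index[called].tolist()
    return SamResult(
        d=pd.Series(d_obs, index=frame.index),
        s0=float(s0),
        delta_table=delta_table,
        selected=selected,
        delta=float(chosen["delta"]),
        fdr=float(chosen["fdr"]),
        target_fdr=target_fdr,
        n_perm=len(perms),
        seed=seed,
        cuts=(float(chosen["cutup"]), float(chosen["cutlow"])),
    )


# ---------------------------------------------------------------------------
# threshold filters
# ---------------------------------------------------------------------------

def _check_universe(*tables: pd.DataFrame) -> None:
    base = set(tables[0].index)
    for t in tables[1:]:
        other = set(t.index)
        if other != base:
            diff = sorted(base ^ other)
            raise DataError(f"contrast tables differ on genes (symmetric difference): {diff[:10]}")


def reversal_filter(
    stress: pd.DataFrame,
    recovery: pd.DataFrame,
    flx_only: pd.DataFrame,
    p_thresh: float = 0.05,
) -> pd.DataFrame:
    """Stress-dysregulated, responder-reversed, drug-neutral gene selection.

    A gene is kept iff stress.p < p_thresh AND recovery.p < p_thresh AND the
    recovery direction is opposite to the stress direction AND the
    drug-without-stress contrast is not significant.  Returns a table over the
    whole universe with a ``kept`` flag, the stress direction, and the reason
    for exclusion.  No multiplicity control is applied (flagged in attrs).
    """
    _check_universe(stress, recovery, flx_only)
    genes = stress.index
    rec = recovery.loc[genes]
    flx = flx_only.loc[genes]
    sig_stress = stress["p"] < p_thresh
    sig_rec = rec["p"] < p_thresh
    reversed_dir = rec["sign"].to_numpy() == -stress["sign"].to_numpy()
    sig_flx = flx["p"] < p_thresh
    kept = sig_stress & sig_rec & reversed_dir & ~sig_flx
    reason = np.select(
        [~sig_stress, ~sig_rec, ~reversed_dir, sig_flx],
        ["stress_ns", "recovery_ns", "not_reversed", "flx_only_effect"],
        default="",
    )
    out = pd.DataFrame(
        {
            "kept": kept,
            "stress_sign": stress["sign"],
            "stress_p": stress["p"],
            "recovery_p": rec["p"],
            "flx_only_p": flx["p"],
            "reason": reason,
        },
        index=genes,
    )
    out.attrs["p_thresh"] = p_thresh
    out.attrs["multiplicity_control"] = "none"
    return out


def stress_filter(
    stress: pd.DataFrame, p_thresh: float = 0.01, fc_thresh: float = 1.2
) -> pd.DataFrame:
    """Stress-specific selection: p < p_thresh and fold change beyond fc_thresh.

    Fold-change symmetry: max(FC, 1/FC) > fc_thresh, so down-regulated genes
    qualify on the same footing as up-regulated ones.
    """
    fc = stress["fc"].to_numpy()
    sym_fc = np.maximum(fc, 1.0 / fc)
    kept = (stress["p"] < p_thresh) & (sym_fc > fc_thresh)
    out = pd.DataFrame(
        {"kept": kept, "stress_sign": stress["sign"], "stress_p": stress["p"],
         "sym_fc": sym_fc},
        index=stress.index,
    )
    out.attrs["p_thresh"] = p_thresh
    out.attrs["fc_thresh"] = fc_thresh
    return out


def kept_genes(filter_table: pd.DataFrame) -> list[str]:
    """Gene ids flagged ``kept`` in a filter output."""
    return filter_table.index[filter_table["kept"]].tolist()
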