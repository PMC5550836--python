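"""Trait / state / prediction biomarker statistics for the human cohort.

* Trait: a two-way mixed ANOVA (between factor = group, within factor =
  visit) on each gene's relative quantities; a gene is a trait candidate when
  the group effect is significant while neither the visit effect nor the
  group x visit interaction is.  Partial eta squared is reported per effect
  against its own error term; no sphericity correction is applied by default
  (a Greenhouse-Geisser flag exists and is recorded in the output metadata).
* State: ordinary least squares of the HDRS change on the concurrent
  expression change (baseline to week 8).
* Prediction: OLS of the week-8 HDRS change on the early (baseline to week 2)
  expression change.

Calls are three-level: significant (p < 0.05), trend (p < 0.1), ns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import MIN_P
from .errors import DataError

ALPHA = 0.05
TREND = 0.1


@dataclass
class TraitResult:
    """Mixed-design ANOVA decomposition for one gene."""

    table: pd.DataFrame          # index effect, columns ss, df, ms, F, p, partial_eta2
    n_subjects: int
    n_groups: int
    n_visits: int
    dropped_subjects: list[str]
    sphericity_correction: str = "none"

    def effect(self, name: str) -> pd.Series:
        return self.table.loc[name]


@dataclass
class StateResult:
    """OLS slope of an HDRS change on an expression change."""

    b: float
    ci_low: float
    ci_high: float
    se: float
    p: float
    n: int
    window_expr: tuple | None = None
    window_hdrs: tuple | None = None


def rm_anova(
    values: pd.DataFrame,
    groups: pd.Series,
    correction: bool = False,
) -> TraitResult:
    """Two-way mixed ANOVA: rows = subjects, columns = visits.

    Subjects with any missing visit are dropped (complete-case) and reported.
    Sums of squares use the weighted (group-size) decomposition, which is
    exactly additive: SS_total = SS_group + SS_subjects(group) + SS_visit +
    SS_interaction + SS_error.  F for the group effect uses subjects-within-
    group as its error; visit and interaction use visit x subjects-within-
    group.  Degenerate inputs (all values identical) report F = 0, p = 1.

    ``correction=True`` applies a Greenhouse-Geisser adjustment to the
    within-subject degrees of freedom.
    """
    complete = values.dropna(axis=0)
    dropped = [str(s) for s in values.index.difference(complete.index)]
    groups = pd.Series(groups).loc[complete.index]
    y = complete.to_numpy(dtype=float)
    n_subj, n_vis = y.shape
    labels = sorted(groups.unique())
    n_groups = len(labels)
    if n_groups < 2 or n_vis < 2:
        raise DataError("mixed ANOVA needs >= 2 groups and >= 2 visits")
    sizes = groups.value_counts()
    if (sizes < 2).any():
        raise DataError(f"every group needs >= 2 complete subjects, got {sizes.to_dict()}")

    grand = y.mean()
    subj_mean = y.mean(axis=1)
    visit_mean = y.mean(axis=0)
    group_of = groups.to_numpy()
    g_masks = {g: group_of == g for g in labels}
    group_mean = {g: y[m].mean() for g, m in g_masks.items()}
    cell_mean = {g: y[m].mean(axis=0) for g, m in g_masks.items()}
    n_g = {g: int(m.sum()) for g, m in g_masks.items()}

    ss_between = n_vis * ((subj_mean - grand) ** 2).sum()
    ss_group = n_vis * sum(n_g[g] * (group_mean[g] - grand) ** 2 for g in labels)
    ss_subj = ss_between - ss_group

    ss_within = ((y - subj_mean[:, None]) ** 2).sum()
    # weighted visit effect: group-size-weighted mean of within-group visit shifts
    visit_hat = sum(n_g[g] * (cell_mean[g] - group_mean[g]) for g in labels) / n_subj
    ss_visit = n_subj * (visit_hat ** 2).sum()
    ss_inter = sum(
        n_g[g] * ((cell_mean[g] - group_mean[g] - visit_hat) ** 2).sum() for g in labels
    )
    ss_error = ss_within - ss_visit - ss_inter

    df_group = n_groups - 1
    df_subj = n_subj - n_groups
    df_visit = n_vis - 1
    df_inter = df_group * df_visit
    df_error = df_subj * df_visit

    eps = 1.0
    if correction and n_vis > 2:
        # Greenhouse-Geisser epsilon from the pooled within-group covariance
        resid = np.vstack([y[m] - cell_mean[g] for g, m in g_masks.items()])
        cov = np.cov(resid, rowvar=False)
        k = cov.shape[0]
        mean_var = np.trace(cov) / k
        mean_all = cov.mean()
        row_means = cov.mean(axis=1)
        num = (k * (mean_var - mean_all)) ** 2
        den = (k - 1) * ((cov ** 2).sum() - 2 * k * (row_means ** 2).sum()
                         + k ** 2 * mean_all ** 2)
        eps = float(num / den) if den > 0 else 1.0
        eps = min(1.0, max(eps, 1.0 / (k - 1)))

    def frow(ss_eff, df_eff, ss_err, df_err, within: bool):
        adj = eps if within else 1.0
        ms_eff = ss_eff / df_eff if df_eff else 0.0
        ms_err = ss_err / df_err if df_err else 0.0
        if ms_err <= 0:
            f = 0.0 if ss_eff <= 1e-12 else np.inf
            p = 1.0 if ss_eff <= 1e-12 else MIN_P
        else:
            f = ms_eff / ms_err
            p = float(stats.f.sf(f, df_eff * adj, df_err * adj))
        eta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        return {"ss": ss_eff, "df": df_eff, "ms": ms_eff, "F": f,
                "p": max(p, MIN_P), "partial_eta2": eta}

    table = pd.DataFrame(
        {
            "group": frow(ss_group, df_group, ss_subj, df_subj, False),
            "subjects_within_group": {"ss": ss_subj, "df": df_subj,
                                      "ms": ss_subj / df_subj if df_subj else 0.0,
                                      "F": np.nan, "p": np.nan, "partial_eta2": np.nan},
            "visit": frow(ss_visit, df_visit, ss_error, df_error, True),
            "group_x_visit": frow(ss_inter, df_inter, ss_error, df_error, True),
            "error_within": {"ss": ss_error, "df": df_error,
                             "ms": ss_error / df_error if df_error else 0.0,
                             "F": np.nan, "p": np.nan, "partial_eta2": np.nan},
        }
    ).T
    return TraitResult(
        table=table,
        n_subjects=n_subj,
        n_groups=n_groups,
        n_visits=n_vis,
        dropped_subjects=dropped,
        sphericity_correction="greenhouse-geisser" if correction and n_vis > 2 else "none",
    )


def delta_regression(delta_expr, delta_hdrs, conf: float = 0.95) -> StateResult:
    """OLS of the clinical-score change on the expression change.

    Returns the slope b with its two-sided t-based p and the ``conf``
    confidence interval b +/- t_{1-(1-conf)/2, n-2} * SE.  Requires at least
    three complete pairs and non-zero predictor variance.
    """
    x = np.asarray(delta_expr, dtype=float)
    y = np.asarray(delta_hdrs, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise DataError(f"regression needs >= 3 paired observations, got {n}")
    sxx = ((x - x.mean()) ** 2).sum()
    if sxx == 0:
        raise DataError("zero predictor variance")
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    b = sxy / sxx
    resid = y - (y.mean() + b * (x - x.mean()))
    s2 = (resid ** 2).sum() / (n - 2)
    se = float(np.sqrt(s2 / sxx))
    if se == 0.0:
        p = MIN_P if b != 0 else 1.0
        return StateResult(b=float(b), ci_low=float(b), ci_high=float(b),
                           se=0.0, p=p, n=n)
    t = b / se
    p = max(float(2.0 * stats.t.sf(abs(t), n - 2)), MIN_P)
    tcrit = float(stats.t.ppf(1.0 - (1.0 - conf) / 2.0, n - 2))
    return StateResult(b=float(b), ci_low=float(b - tcrit * se),
                       ci_high=float(b + tcrit * se), se=se, p=p, n=n)


def call_level(p: float, alpha: float = ALPHA, trend: float = TREND) -> str:
    if p < alpha:
        return "significant"
    if p < trend:
        return "trend"
    return "ns"


def classify_trait(result: TraitResult, alpha: float = ALPHA, trend: float = TREND) -> str:
    """Trait call: group effect present while visit and interaction are not."""
    group_p = result.effect("group")["p"]
    visit_p = result.effect("visit")["p"]
    inter_p = result.effect("group_x_visit")["p"]
    if visit_p < alpha or inter_p < alpha:
        return "ns"
    if group_p < alpha:
        return "trait"
    if group_p < trend:
        return "trait_trend"
    return "ns"


def biomarker_verdicts(
    rq: pd.DataFrame,
    clinical: pd.DataFrame,
    state_window: tuple[int, int] = (0, 8),
    prediction_window: tuple[int, int] = (0, 2),
    expr_scale: str = "rq",
    alpha: float = ALPHA,
    trend: float = TREND,
) -> pd.DataFrame:
    """Per-gene verdict table from an RQ table and the clinical table.

    ``rq`` is long-format (subject, group, visit, gene, rq); ``clinical`` has
    (subject, group, visit, hdrs).  State regressions pair the expression
    change over ``state_window`` with the HDRS change over the same window;
    prediction regressions pair the early expression change over
    ``prediction_window`` with the HDRS change over ``state_window``, both in
    patients only.  ``expr_scale='log2'`` uses log2-RQ differences instead of
    RQ differences (recorded in attrs).
    """
    if expr_scale not in ("rq", "log2"):
        raise DataError(f"unknown expr_scale {expr_scale!r}")
    rq = rq.copy()
    rq["value"] = np.log2(rq["rq"]) if expr_scale == "log2" else rq["rq"]
    hdrs = clinical.set_index(["subject", "visit"])["hdrs"]
    group_by_subject = clinical.drop_duplicates("subject").set_index("subject")["group"]
    patients = group_by_subject.index[group_by_subject == "patient"]

    rows = []
    for gene, sub in rq.groupby("gene", sort=True):
        wide = sub.pivot_table(index="subject", columns="visit", values="value")
        trait = rm_anova(wide, group_by_subject.loc[wide.index])

        def window_delta(subjects, w):
            a = wide[w[0]].reindex(subjects)
            b = wide[w[1]].reindex(subjects)
            return (b - a).to_numpy(dtype=float)

        def hdrs_delta(subjects, w):
            a = hdrs.reindex([(s, w[0]) for s in subjects]).to_numpy(dtype=float)
            b = hdrs.reindex([(s, w[1]) for s in subjects]).to_numpy(dtype=float)
            return b - a

        pts = [s for s in patients if s in wide.index]

        def safe_regression(dx, dy):
            # a gene whose expression does not move (zero predictor variance)
            # has no defined slope; report NaN instead of aborting the table
            try:
                return delta_regression(dx, dy)
            except DataError:
                return StateResult(b=np.nan, ci_low=np.nan, ci_high=np.nan,
                                   se=np.nan, p=np.nan, n=len(dx))

        state = safe_regression(window_delta(pts, state_window),
                                hdrs_delta(pts, state_window))
        pred = safe_regression(window_delta(pts, prediction_window),
                               hdrs_delta(pts, state_window))
        rows.append({
            "gene": gene,
            "trait_F": trait.effect("group")["F"],
            "trait_p": trait.effect("group")["p"],
            "trait_eta2": trait.effect("group")["partial_eta2"],
            "visit_p": trait.effect("visit")["p"],
            "interaction_p": trait.effect("group_x_visit")["p"],
            "trait_call": classify_trait(trait, alpha, trend),
            "state_b": state.b, "state_ci_low": state.ci_low,
            "state_ci_high": state.ci_high, "state_p": state.p,
            "state_call": call_level(state.p, alpha, trend),
            "pred_b": pred.b, "pred_ci_low": pred.ci_low,
            "pred_ci_high": pred.ci_high, "pred_p": pred.p,
            "pred_call": call_level(pred.p, alpha, trend),
        })
    out = pd.DataFrame(rows).set_index("gene")
    out.attrs["expr_scale"] = expr_scale
    out.attrs["sphericity_correction"] = "none"
    out.attrs["state_window"] = state_window
    out.attrs["prediction_window"] = prediction_window
    return out
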