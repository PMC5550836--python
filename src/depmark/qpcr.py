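"""RT-qPCR quantification: replicate aggregation, QC, and 2^-ddCt.

Relative quantities follow the classical 2^-ddCt model:
dCt = Ct_target - Ct_reference per sample, ddCt = dCt minus the mean dCt over
a calibrator group, RQ = 2^-ddCt.  The calibrator geometric-mean RQ is 1 by
construction, and adding a constant to every Ct of a sample (a plate offset)
leaves RQ unchanged.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import DataError

SAMPLE_KEYS = ("subject", "visit")


def _sample_keys(table: pd.DataFrame) -> list[str]:
    return [k for k in SAMPLE_KEYS if k in table.columns] or ["subject"]


def aggregate_ct(records: pd.DataFrame, max_spread: float = 0.5) -> pd.DataFrame:
    """Mean Ct per subject x visit x gene with QC flags.

    Replicates with spread above ``max_spread`` cycles are flagged (never
    dropped); a missing replicate yields the single value with its own flag.
    Carries through any ``group`` column.
    """
    required = {"subject", "gene", "ct"}
    if not required <= set(records.columns):
        raise DataError(f"Ct table needs columns {sorted(required)}")
    if ((records["ct"] <= 0) | (records["ct"] > 50)).any():
        raise DataError("Ct values must lie in (0, 50]")
    keys = _sample_keys(records) + ["gene"]
    if "group" in records.columns:
        keys = ["group"] + keys
    grouped = records.groupby(keys, sort=True)["ct"]
    out = grouped.agg(
        ct="mean",
        n_replicates="count",
        spread=lambda v: float(v.max() - v.min()),
    ).reset_index()
    out["flag_spread"] = out["spread"] > max_spread
    out["flag_single_replicate"] = out["n_replicates"] < 2
    return out


def low_expression_filter(
    mean_ct: pd.DataFrame, ct_max: float = 35.0, min_fraction_detected: float = 0.8
) -> tuple[list[str], pd.DataFrame]:
    """Drop genes detected (Ct <= ct_max) in too few samples.

    A gene is retained when the detected fraction is at or above
    ``min_fraction_detected`` (boundary inclusive).  Returns the retained gene
    list and a per-gene report.
    """
    report = (
        mean_ct.assign(detected=mean_ct["ct"] <= ct_max)
        .groupby("gene")["detected"]
        .agg(fraction_detected="mean", n_samples="count")
        .reset_index()
    )
    report["retained"] = report["fraction_detected"] >= min_fraction_detected
    retained = report.loc[report["retained"], "gene"].tolist()
    return retained, report.set_index("gene")


def reference_stability(
    matrices,
    candidates: list[str],
    group_col: str = "group",
) -> pd.DataFrame:
    """Rank candidate reference genes by cross-group expression stability.

    ``matrices`` is an :class:`~depmark.datatypes.ExpressionMatrix` or a dict
    of them (one per tissue); the stability score per gene is the standard
    deviation of its group (x tissue) means plus its overall standard
    deviation, ranked ascending.  Genes in the middle two quartiles of overall
    mean intensity are flagged as moderately expressed (preferred reference
    band).
    """
    from .datatypes import ExpressionMatrix  # local import to avoid cycle

    if isinstance(matrices, ExpressionMatrix):
        matrices = {matrices.tissue: matrices}
    all_means = pd.concat(
        [m.values.mean(axis=1) for m in matrices.values()], axis=0
    ).groupby(level=0).mean()
    q25, q75 = all_means.quantile([0.25, 0.75])

    rows = []
    for gene in candidates:
        group_means = []
        values = []
        present = False
        for m in matrices.values():
            if gene not in m.values.index:
                continue
            present = True
            groups = m.samples[group_col]
            for g in groups.unique():
                cols = groups.index[groups == g]
                group_means.append(float(m.values.loc[gene, cols].mean()))
            values.append(m.values.loc[gene].to_numpy(dtype=float))
        if not present:
            warnings.warn(f"candidate {gene!r} absent from all matrices; skipped",
                          stacklevel=2)
            continue
        values = np.concatenate(values)
        group_sd = float(np.std(group_means, ddof=1)) if len(group_means) > 1 else 0.0
        overall_sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
        mean_level = float(values.mean())
        rows.append({
            "gene": gene,
            "group_mean_sd": group_sd,
            "overall_sd": overall_sd,
            "stability_score": group_sd + overall_sd,
            "mean_level": mean_level,
            "moderate_expression": bool(q25 <= mean_level <= q75),
        })
    if not rows:
        raise DataError("no candidate reference gene present in the matrices")
    table = pd.DataFrame(rows).set_index("gene").sort_values("stability_score")
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def delta_delta_ct(
    mean_ct: pd.DataFrame,
    reference_gene: str,
    calibrator: str | pd.Series,
    group_col: str = "group",
) -> pd.DataFrame:
    """Relative quantities RQ = 2^-ddCt against a reference gene and calibrator.

    ``calibrator`` is either a group label (all samples of that group, across
    visits, form the calibrator) or a boolean Series indexed like the sample
    keys.  Samples lacking a reference-gene Ct are dropped and reported via a
    warning.
    """
    keys = _sample_keys(mean_ct)
    ref = mean_ct.loc[mean_ct["gene"] == reference_gene]
    if ref.empty:
        raise DataError(f"reference gene {reference_gene!r} absent from the Ct table")
    ref_ct = ref.set_index(keys)["ct"]
    targets = mean_ct.loc[mean_ct["gene"] != reference_gene].copy()
    sample_index = pd.MultiIndex.from_frame(targets[keys]) if len(keys) > 1 \
        else pd.Index(targets[keys[0]])
    matched = ref_ct.reindex(sample_index)
    missing = sample_index[matched.isna().to_numpy()].unique()
    if len(missing):
        warnings.warn(
            f"samples without reference Ct dropped: {list(missing)[:10]}", stacklevel=2
        )
    targets["dct"] = targets["ct"].to_numpy() - matched.to_numpy()
    targets = targets.loc[targets["dct"].notna()].copy()

    if isinstance(calibrator, str):
        if group_col not in targets.columns:
            raise DataError(f"no {group_col!r} column to resolve calibrator group")
        cal_mask = targets[group_col] == calibrator
    else:
        idx = pd.MultiIndex.from_frame(targets[keys]) if len(keys) > 1 \
            else pd.Index(targets[keys[0]])
        cal_mask = pd.Series(calibrator).reindex(idx).fillna(False).to_numpy(bool)
    if not np.any(cal_mask):
        raise DataError("calibrator group is empty")

    cal_mean = targets.loc[cal_mask].groupby("gene")["dct"].mean()
    absent = set(targets["gene"]) - set(cal_mean.index)
    if absent:
        raise DataError(f"genes without calibrator samples: {sorted(absent)}")
    targets["ddct"] = targets["dct"] - targets["gene"].map(cal_mean).to_numpy()
    targets["rq"] = 2.0 ** (-targets["ddct"])
    targets["reference_gene"] = reference_gene
    targets["calibrator"] = str(calibrator)
    return targets


def assign_reference_strata(
    mean_ct: pd.DataFrame,
    references: tuple[str, str] = ("CRYL1", "SV2A"),
    boundary: float = 30.0,
) -> dict[str, str]:
    """Map each target gene to a reference gene by expression stratum:
    mean Ct at or below ``boundary`` (highly/moderately expressed) uses the
    first reference, weaker expression the second."""
    levels = mean_ct.loc[~mean_ct["gene"].isin(references)].groupby("gene")["ct"].mean()
    return {g: (references[0] if ct <= boundary else references[1])
            for g, ct in levels.items()}
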