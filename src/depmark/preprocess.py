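"""Matrix preprocessing: quantile normalization, probe collapsing, clustering.

Blood and brain matrices are normalized independently (their intensity scales
differ by 2-3x), matching the usual practice for single-channel arrays.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .datatypes import ExpressionMatrix
from .errors import DataError


def quantile_normalize(matrix: ExpressionMatrix | pd.DataFrame) -> ExpressionMatrix | pd.DataFrame:
    """Force every sample onto the common distribution of row-wise sorted means.

    After normalization every column contains the same multiset of values (the
    mean of the sorted columns); tied values within a column receive the mean
    of the quantile values their rank range spans.  The operation is
    idempotent, and a matrix whose columns already share one distribution is a
    fixed point.
    """
    frame = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    arr = frame.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        bad = np.argwhere(~np.isfinite(arr))[:10]
        cells = [(frame.index[i], frame.columns[j]) for i, j in bad]
        raise DataError(f"non-finite values at cells (first 10): {cells}")
    n, m = arr.shape
    if m < 2:
        raise DataError("quantile normalization needs >= 2 samples")
    target = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(m):
        col = arr[:, j]
        order = np.argsort(col, kind="mergesort")
        ranked = np.empty(n)
        ranked[order] = target
        # ties: average the target values across the rank span they occupy
        means = pd.Series(ranked).groupby(col).transform("mean").to_numpy()
        out[:, j] = means
    result = pd.DataFrame(out, index=frame.index, columns=frame.columns)
    if isinstance(matrix, ExpressionMatrix):
        return ExpressionMatrix(values=result, samples=matrix.samples.copy())
    return result


def collapse_probes(
    matrix: ExpressionMatrix,
    probe_to_gene: pd.Series | dict,
    reference: pd.DataFrame,
) -> tuple[ExpressionMatrix, pd.Series]:
    """Keep, per gene, the probe most significant in a reference contrast.

    Ties on p are broken by larger \\|log2 FC\\|, then lexicographically smaller
    probe id.  Genes with no probe in the matrix are omitted with a warning.
    Returns the gene-level matrix and the chosen probe per gene.
    """
    mapping = pd.Series(probe_to_gene)
    probes = matrix.values.index
    in_matrix = mapping.index.intersection(probes)
    lost = set(mapping.unique()) - set(mapping.loc[in_matrix].unique())
    if lost:
        warnings.warn(f"genes with no probe in matrix omitted: {sorted(lost)}", stacklevel=2)
    missing_ref = in_matrix.difference(reference.index)
    if len(missing_ref):
        raise DataError(f"reference contrast lacks probes: {missing_ref.tolist()[:10]}")
    table = pd.DataFrame({
        "probe": in_matrix,
        "gene": mapping.loc[in_matrix].to_numpy(),
        "p": reference.loc[in_matrix, "p"].to_numpy(),
        "abs_lfc": np.abs(np.log2(reference.loc[in_matrix, "fc"].to_numpy())),
    })
    table = table.sort_values(
        ["gene", "p", "abs_lfc", "probe"], ascending=[True, True, False, True]
    )
    best = table.groupby("gene", sort=True).first()
    chosen = best["probe"]
    values = matrix.values.loc[chosen.to_numpy()].copy()
    values.index = pd.Index(chosen.index, name="gene")
    return ExpressionMatrix(values=values, samples=matrix.samples.copy()), chosen


def pearson_distance_matrix(values: pd.DataFrame) -> np.ndarray:
    """1 - Pearson correlation between sample columns."""
    arr = values.to_numpy(dtype=float)
    sds = arr.std(axis=0)
    if (sds == 0).any():
        flat = values.columns[sds == 0].tolist()
        raise DataError(f"zero-variance samples under Pearson distance: {flat}")
    corr = np.corrcoef(arr, rowvar=False)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    return np.clip(dist, 0.0, None)


def cluster_samples(
    matrix: ExpressionMatrix | pd.DataFrame,
    distance: str = "pearson",
    linkage: str = "average",
) -> tuple[list[str], np.ndarray]:
    """Agglomerative clustering of samples; returns leaf order and merge tree.

    The merge tree is a scipy linkage matrix; leaf order is the dendrogram
    order, deterministic for fixed input.
    """
    frame = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    if frame.shape[1] < 3:
        raise DataError("clustering needs >= 3 samples")
    if distance == "pearson":
        dist = pearson_distance_matrix(frame)
    elif distance == "euclidean":
        arr = frame.to_numpy(dtype=float)
        diff = arr[:, :, None] - arr[:, None, :]
        dist = np.sqrt((diff ** 2).sum(axis=0))
    else:
        raise DataError(f"unknown distance {distance!r}")
    condensed = squareform(dist, checks=False)
    tree = hierarchy.linkage(condensed, method=linkage)
    order = hierarchy.leaves_list(tree)
    return [frame.columns[i] for i in order], tree


def low_intensity_floor(
    matrix: ExpressionMatrix, floor_log2: float
) -> tuple[ExpressionMatrix, list[str]]:
    """Optional filter dropping probes whose mean log2 intensity is below a floor."""
    means = matrix.values.mean(axis=1)
    keep = means.index[means >= floor_log2]
    dropped = means.index.difference(keep).tolist()
    filtered = ExpressionMatrix(values=matrix.values.loc[keep].copy(),
                                samples=matrix.samples.copy())
    return filtered, dropped
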