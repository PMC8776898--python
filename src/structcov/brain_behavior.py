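"""Sex- and group-stratified Pearson correlations of volume vs behavior.

Correlations are exploratory: two-tailed p-values are reported uncorrected
(a BH column is offered for convenience but significance calls deliberately
remain uncorrected). Missing behavior values are handled pairwise-complete.
Heatmap ordering uses agglomerative clustering with Euclidean distance and
average (UPGMA) linkage on rows and columns independently; correlations are
clustered as-is, without row scaling.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import pdist

from ._exceptions import DegenerateDataError, ValidationError
from .regional_stats import fdr_adjust
from .volumes_io import CELLS, VolumeTable

MIN_PAIRS = 3


def pearson_r(x, y) -> tuple[float, float]:
    """Sample Pearson r with its two-tailed p (t on n−2 df).

    Requires n ≥ 3 paired finite values and nonzero variance in both
    variables; degenerate input raises :class:`DegenerateDataError`.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("pearson_r expects two equal-length 1-D vectors")
    if len(x) < MIN_PAIRS:
        raise ValidationError(f"pearson_r requires n >= {MIN_PAIRS}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("pearson_r requires finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("zero variance in one of the variables")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def brain_behavior_matrix(
    vt: VolumeTable,
    behavior: pd.DataFrame,
    region_subset: list[str] | None = None,
    strata: dict[str, pd.Series] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Correlate regional volumes with behavioral measures per stratum.

    Parameters
    ----------
    vt : VolumeTable
    behavior : DataFrame
        Wide table indexed by subject_id, one numeric column per measure;
        NaN allowed (pairwise-complete deletion).
    region_subset : list of region ids, optional
        Defaults to all regions; callers typically pass the FDR-passing
        regions of a reference contrast.
    strata : mapping stratum label → boolean subject mask, optional
        Defaults to the four sex×treatment cells.

    Returns a tidy frame (region_id, measure, stratum, n, r, p,
    significant, p_bh, computable). Strata with fewer than 3 complete
    pairs, or with zero variance, give ``computable=False`` rows.
    """
    if region_subset is None:
        region_subset = vt.regions
    missing = sorted(set(region_subset) - set(vt.regions))
    if missing:
        raise ValidationError(f"regions not in volume table: {missing}")
    extra = sorted(set(behavior.index) - set(vt.subjects))
    if extra:
        raise ValidationError(f"behavior subjects absent from design: {extra}")
    if strata is None:
        strata = {
            cell: vt.subject_mask(sex=cell.split("_")[1], group=cell.split("_")[0])
            for cell in CELLS
        }
    beh = behavior.reindex(vt.volumes.index)
    rows = []
    for label, mask in strata.items():
        subjects = vt.volumes.index[np.asarray(mask, bool)]
        for measure in behavior.columns:
            b = beh.loc[subjects, measure]
            complete = b.notna()
            for region in region_subset:
                v = vt.volumes.loc[subjects, region]
                x = v[complete].to_numpy()
                y = b[complete].to_numpy()
                row = {
                    "region_id": region,
                    "measure": measure,
                    "stratum": label,
                    "n": int(complete.sum()),
                    "r": np.nan,
                    "p": np.nan,
                    "significant": False,
                    "computable": False,
                }
                if len(x) >= MIN_PAIRS and np.ptp(x) > 0 and np.ptp(y) > 0:
                    r, p = pearson_r(x, y)
                    row.update(r=r, p=p, significant=bool(p < alpha), computable=True)
                rows.append(row)
    out = pd.DataFrame(rows)
    # optional BH column for users; significance stays uncorrected by design
    ok = out["computable"]
    out["p_bh"] = np.nan
    if ok.any():
        out.loc[ok, "p_bh"] = fdr_adjust(out.loc[ok, "p"].to_numpy(), method="bh").q
    out.attrs["correction"] = "uncorrected"
    return out


def pivot_r_matrix(results: pd.DataFrame) -> pd.DataFrame:
    """Pivot tidy results to a region × (stratum, measure) r matrix."""
    wide = results.pivot_table(
        index="region_id", columns=["stratum", "measure"], values="r", sort=False
    )
    return wide


def _upgma_order(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """UPGMA leaf order and linkage for row vectors.

    Leaf order is made deterministic by visiting, at every internal node,
    the child subtree containing the smallest original index first; fully
    tied inputs therefore keep their input order.
    """
    n = len(points)
    d = pdist(points, metric="euclidean")
    link = sch.linkage(d, method="average")
    min_leaf = list(range(n)) + [0] * (n - 1)
    for i, (a, b, _, _) in enumerate(link):
        min_leaf[n + i] = min(min_leaf[int(a)], min_leaf[int(b)])
    order: list[int] = []
    stack = [2 * n - 2]
    while stack:
        node = stack.pop()
        if node < n:
            order.append(node)
            continue
        a, b = int(link[node - n][0]), int(link[node - n][1])
        first, second = (a, b) if min_leaf[a] <= min_leaf[b] else (b, a)
        stack.append(second)  # LIFO: push the later subtree first
        stack.append(first)
    return np.array(order), link


def heatmap_order(matrix: pd.DataFrame) -> tuple[list, list]:
    """Row and column orders from independent UPGMA/Euclidean clustering.

    Not-computable (NaN) cells are imputed as 0 for ordering only, with a
    warning. Fewer than 2 rows or columns gives the identity order.
    """
    mat = matrix.to_numpy(dtype=float)
    if np.isnan(mat).any():
        warnings.warn("NaN cells imputed as 0 for heatmap ordering only", stacklevel=2)
        mat = np.nan_to_num(mat, nan=0.0)
    if mat.shape[0] >= 2:
        row_idx, _ = _upgma_order(mat)
    else:
        row_idx = np.arange(mat.shape[0])
    if mat.shape[1] >= 2:
        col_idx, _ = _upgma_order(mat.T)
    else:
        col_idx = np.arange(mat.shape[1])
    return list(matrix.index[row_idx]), list(matrix.columns[col_idx])


def ordered_r_matrix(results: pd.DataFrame) -> pd.DataFrame:
    """The pivoted r matrix reordered for heatmap rendering."""
    wide = pivot_r_matrix(results)
    row_order, col_order = heatmap_order(wide)
    return wide.loc[row_order, col_order]
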