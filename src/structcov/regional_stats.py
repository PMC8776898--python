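"""Group comparisons of total, absolute and relative regional volumes.

Per-region tests are Welch two-sample t tests by default (pooled-variance t
available). Multiplicity is handled by Benjamini–Hochberg step-up q-values
or the adaptive two-stage step-up procedure; effect sizes are Cohen's d
with pooled SD, signed treated − control (male − female for sex contrasts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import DegenerateDataError, ValidationError
from .volumes_io import GROUPS, SEXES, AtlasHierarchy, VolumeTable, cell_label

CONTRASTS = ("full", "male", "female")


# ---------------------------------------------------------------------------
# Effect size
# ---------------------------------------------------------------------------

def cohens_d(x, y) -> float:
    """Cohen's d = (mean(x) − mean(y)) / pooled SD.

    Pooled SD uses the (n₁−1, n₂−1)-weighted variances. Degenerate input
    (pooled SD = 0) raises :class:`DegenerateDataError`.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("cohens_d requires n >= 2 in each sample")
    n1, n2 = len(x), len(y)
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        if x.mean() == y.mean():
            return 0.0
        raise DegenerateDataError("pooled SD is zero with unequal means")
    return float((x.mean() - y.mean()) / np.sqrt(sp2))


def _cohens_d_columns(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized Cohen's d over columns of two 2-D arrays."""
    n1, n2 = x.shape[0], y.shape[0]
    sp2 = ((n1 - 1) * x.var(axis=0, ddof=1) + (n2 - 1) * y.var(axis=0, ddof=1)) / (
        n1 + n2 - 2
    )
    diff = x.mean(axis=0) - y.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = diff / np.sqrt(sp2)
    d[(sp2 == 0) & (diff == 0)] = 0.0
    return d


# ---------------------------------------------------------------------------
# FDR adjustment
# ---------------------------------------------------------------------------

@dataclass
class FdrResult:
    q: np.ndarray
    reject: np.ndarray
    method: str
    level: float
    m0_estimate: int | None = None  # two-stage only


def _bh_q(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _bh_reject(p: np.ndarray, level: float) -> np.ndarray:
    m = len(p)
    order = np.argsort(p, kind="stable")
    thresh = level * np.arange(1, m + 1) / m
    below = p[order] <= thresh
    reject = np.zeros(m, bool)
    if below.any():
        k = int(np.max(np.nonzero(below)[0])) + 1
        reject[order[:k]] = True
    return reject


def fdr_adjust(p, method: str = "bh", level: float = 0.05) -> FdrResult:
    """Adjust p-values for multiplicity.

    method="bh"
        Benjamini–Hochberg step-up q-values; reject where q < level is
        equivalent to the step-up rule at ``level``.
    method="two_stage_bky" (alias "bky")
        Adaptive two-stage step-up: stage 1 runs BH at q′ = level/(1+level)
        to estimate m₀ = m − r₁ true nulls; stage 2 is a step-up with
        thresholds i·q′/m₀. Adaptive q-values satisfy (q ≤ level) ⇔ reject.
    """
    p = np.asarray(p, float)
    if p.ndim != 1 or len(p) == 0:
        raise ValidationError("p must be a nonempty 1-D vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = len(p)
    if method == "bh":
        q = _bh_q(p)
        return FdrResult(q=q, reject=_bh_reject(p, level), method="bh", level=level)
    if method in ("two_stage_bky", "bky"):
        qprime = level / (1.0 + level)
        r1 = int(_bh_reject(p, qprime).sum())
        m0 = m - r1
        if m0 == 0:
            return FdrResult(q=np.zeros(m), reject=np.ones(m, bool),
                             method="two_stage_bky", level=level, m0_estimate=0)
        # step-up with thresholds i*qprime/m0; adaptive q solves p*m0*(1+level)/i <= level
        order = np.argsort(p, kind="stable")
        thresh = np.arange(1, m + 1) * qprime / m0
        below = p[order] <= thresh
        reject = np.zeros(m, bool)
        if below.any():
            k = int(np.max(np.nonzero(below)[0])) + 1
            reject[order[:k]] = True
        raw = p[order] * m0 * (1.0 + level) / np.arange(1, m + 1)
        q_sorted = np.minimum.accumulate(raw[::-1])[::-1]
        q = np.empty(m)
        q[order] = np.minimum(q_sorted, 1.0)
        return FdrResult(q=q, reject=reject, method="two_stage_bky", level=level,
                         m0_estimate=m0)
    raise ValidationError(f"unknown FDR method {method!r}")


# ---------------------------------------------------------------------------
# Total brain volume
# ---------------------------------------------------------------------------

@dataclass
class TbvComparison:
    f_statistic: float
    p_value: float
    cell_means: pd.Series
    pairwise: pd.DataFrame  # Tukey-HSD adjusted pairwise comparisons


def compare_tbv(vt: VolumeTable) -> TbvComparison:
    """One-way ANOVA of TBV across the sex×group cells + Tukey HSD.

    Cells with no subjects are dropped; at least two populated cells are
    required, and every populated cell needs at least two subjects.
    """
    cells = {}
    for g in GROUPS:
        for s in SEXES:
            mask = vt.subject_mask(sex=s, group=g)
            vals = vt.tbv[mask].to_numpy()
            if len(vals) == 0:
                continue
            if len(vals) < 2:
                raise ValidationError(
                    f"cell {cell_label(g, s)} has {len(vals)} subject(s); need >= 2"
                )
            cells[cell_label(g, s)] = vals
    if len(cells) < 2:
        raise ValidationError("need at least two populated sex-by-group cells")
    labels = list(cells)
    values = [cells[c] for c in labels]
    if all(np.ptp(v) == 0 for v in values) and len({v[0] for v in values}) == 1:
        f_stat, p = 0.0, 1.0
    else:
        f_stat, p = stats.f_oneway(*values)
    means = pd.Series({c: float(v.mean()) for c, v in cells.items()})

    res = stats.tukey_hsd(*values)
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            rows.append({
                "cell_a": labels[i],
                "cell_b": labels[j],
                "mean_diff": float(values[i].mean() - values[j].mean()),
                "p_adj": float(res.pvalue[i, j]),
            })
    return TbvComparison(
        f_statistic=float(f_stat),
        p_value=float(p),
        cell_means=means,
        pairwise=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# Region-wise comparisons
# ---------------------------------------------------------------------------

def _contrast_masks(vt: VolumeTable, contrast: str) -> tuple[pd.Series, pd.Series]:
    if contrast not in CONTRASTS:
        raise ValidationError(f"unknown contrast {contrast!r}; allowed: {CONTRASTS}")
    sex = {"full": None, "male": "M", "female": "F"}[contrast]
    a = vt.subject_mask(sex=sex, group="treated")
    b = vt.subject_mask(sex=sex, group="control")
    if a.sum() == 0 or b.sum() == 0:
        raise ValidationError(f"contrast {contrast!r} has an empty side")
    return a, b


def regionwise_compare(
    vt: VolumeTable,
    contrast: str = "full",
    measure: str = "absolute",
    fdr_method: str = "bh",
    level: float = 0.05,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-region treated-vs-control comparison with FDR and Cohen's d.

    Returns a tidy frame with one row per region: mean_diff (treated −
    control), t, p, q, cohens_d, significant_at_q05. ``measure="relative"``
    divides each region by subject TBV first.
    """
    if measure not in ("absolute", "relative"):
        raise ValidationError(f"unknown measure {measure!r}")
    data = vt.volumes if measure == "absolute" else vt.relative_volumes()
    mask_a, mask_b = _contrast_masks(vt, contrast)
    x = data[mask_a].to_numpy()
    y = data[mask_b].to_numpy()

    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(x, y, equal_var=equal_var, axis=0)
    t = np.asarray(t, float)
    p = np.asarray(p, float)
    diff = x.mean(axis=0) - y.mean(axis=0)
    # zero-variance, zero-difference columns: define t=0, p=1 with a warning
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        zero_diff = degenerate & (diff == 0)
        t[zero_diff] = 0.0
        p[zero_diff] = 1.0
        still_bad = degenerate & (diff != 0)
        if still_bad.any():
            names = [data.columns[i] for i in np.nonzero(still_bad)[0]]
            raise DegenerateDataError(
                f"zero within-group variance with nonzero difference in {names[:5]}"
            )
        warnings.warn("regions with zero variance and zero difference set to p=1, d=0",
                      stacklevel=2)
    d = _cohens_d_columns(x, y)
    fdr = fdr_adjust(p, method=fdr_method, level=level)
    out = pd.DataFrame({
        "region_id": data.columns,
        "contrast": contrast,
        "measure": measure,
        "mean_diff": diff,
        "t": t,
        "p": p,
        "q": fdr.q,
        "cohens_d": d,
        "significant_at_q05": fdr.reject,
    })
    out.attrs["n_significant"] = int(fdr.reject.sum())
    out.attrs["d_sign_convention"] = "treated_minus_control"
    out.attrs["fdr_method"] = fdr.method
    return out


def area_effect_summary(
    results: pd.DataFrame,
    hierarchy: AtlasHierarchy,
    region_subset: list[str] | None = None,
) -> pd.DataFrame:
    """Unweighted mean Cohen's d per anatomical area over a region subset.

    Default subset: regions passing FDR in ``results`` (significant_at_q05).
    Areas left empty after subsetting are omitted with a warning.
    """
    if region_subset is None:
        region_subset = list(results.loc[results["significant_at_q05"], "region_id"])
    sub = results[results["region_id"].isin(region_subset)].copy()
    missing_d = sub["cohens_d"].isna()
    if missing_d.any():
        raise ValidationError("regions in subset lack a Cohen's d value")
    hierarchy.check_covers(list(sub["region_id"]))
    sub["area"] = [hierarchy.area_of(r) for r in sub["region_id"]]
    all_areas = sorted(set(hierarchy.table["area"]))
    grouped = sub.groupby("area")["cohens_d"].agg(["mean", "count"]).reset_index()
    grouped = grouped.rename(columns={"mean": "mean_cohens_d", "count": "n_regions"})
    empty = sorted(set(all_areas) - set(grouped["area"]))
    if empty and len(sub):
        warnings.warn(f"areas with no regions in subset omitted: {empty}", stacklevel=2)
    return grouped.sort_values("area").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Sexual dimorphism
# ---------------------------------------------------------------------------

DIMORPHISM_PATTERNS = ("dimorphic_preserved", "dimorphism_lost", "not_dimorphic", "other")


def _interaction_p(values: np.ndarray, sex: np.ndarray, group: np.ndarray) -> float:
    """Sex×group interaction p from a two-way fixed-effects OLS model."""
    import statsmodels.api as sm

    s = (sex == "M").astype(float)
    g = (group == "treated").astype(float)
    X = sm.add_constant(np.column_stack([s, g, s * g]))
    fit = sm.OLS(values, X).fit()
    return float(fit.pvalues[-1])


def dimorphism_test(
    vt: VolumeTable, regions: list[str], alpha: float = 0.05
) -> pd.DataFrame:
    """Test loss of male–female volume differences in a-priori regions.

    Within each treatment group a Welch M-vs-F test and Cohen's d
    (male − female) are computed; a sex×group interaction p is reported
    alongside. Pattern calls at ``alpha``:

    - ``dimorphism_lost``: control p < α and treated p ≥ α
    - ``dimorphic_preserved``: both p < α
    - ``not_dimorphic``: both p ≥ α
    - ``other``: treated-only dimorphism
    """
    missing = sorted(set(regions) - set(vt.regions))
    if missing:
        raise ValidationError(f"regions missing from volume table: {missing}")
    sex = vt.design["sex"].to_numpy()
    group = vt.design["group"].to_numpy()
    for g in GROUPS:
        for s in SEXES:
            if ((sex == s) & (group == g)).sum() < 2:
                raise ValidationError(f"cell {cell_label(g, s)} has < 2 subjects")
    rows = []
    for region in regions:
        vals = vt.volumes[region].to_numpy()
        entry: dict = {"region_id": region}
        for g in GROUPS:
            m = vals[(group == g) & (sex == "M")]
            f = vals[(group == g) & (sex == "F")]
            _, p = stats.ttest_ind(m, f, equal_var=False)
            entry[f"{g}_d"] = cohens_d(m, f)
            entry[f"{g}_p"] = float(p)
        entry["interaction_p"] = _interaction_p(vals, sex, group)
        ctrl_sig = entry["control_p"] < alpha
        trt_sig = entry["treated_p"] < alpha
        if ctrl_sig and not trt_sig:
            entry["pattern"] = "dimorphism_lost"
        elif ctrl_sig and trt_sig:
            entry["pattern"] = "dimorphic_preserved"
        elif not ctrl_sig and not trt_sig:
            entry["pattern"] = "not_dimorphic"
        else:
            entry["pattern"] = "other"
        rows.append(entry)
    out = pd.DataFrame(rows)
    out.attrs["d_sign_convention"] = "male_minus_female"
    return out
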