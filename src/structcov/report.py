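"""Human-readable summary assembly from a results directory."""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def _load(path: Path) -> pd.DataFrame | None:
    return pd.read_csv(path) if path.exists() else None


def render_report(results_dir: str | Path) -> str:
    """Summarize the CSV artifacts of a run as markdown.

    Missing analyses produce explicit gap lines rather than errors, so a
    partial results directory still renders.
    """
    results_dir = Path(results_dir)
    lines = ["# Analysis summary", ""]
    any_section = False

    tbv = _load(results_dir / "tbv_comparison.csv")
    if tbv is not None:
        any_section = True
        lines.append("## Total brain volume")
        lines.append(f"- one-way ANOVA across 4 cells: F = {tbv['f_statistic'][0]:.3f}, "
                     f"p = {tbv['p_value'][0]:.4g}")
        lines.append("")

    for contrast in ("full", "male", "female"):
        for measure in ("absolute", "relative"):
            df = _load(results_dir / f"regional_{contrast}_{measure}.csv")
            if df is None:
                continue
            any_section = True
            sig = df[df["significant_at_q05"]]
            lines.append(f"## Regional comparison — {contrast} contrast, {measure} volume")
            lines.append(f"- {len(sig)}/{len(df)} regions flagged at FDR 5%")
            if len(sig):
                top = sig.reindex(sig["q"].sort_values().index).head(10)
                for _, row in top.iterrows():
                    lines.append(
                        f"  - {row['region_id']}: d = {row['cohens_d']:.2f}, "
                        f"q = {row['q']:.3g}"
                    )
            lines.append("")

    areas = _load(results_dir / "area_effects.csv")
    if areas is not None:
        any_section = True
        lines.append("## Area-level mean effect sizes")
        for _, row in areas.iterrows():
            lines.append(f"- {row['area']}: mean d = {row['mean_cohens_d']:.2f} "
                         f"({int(row['n_regions'])} regions)")
        lines.append("")

    dim = _load(results_dir / "dimorphism.csv")
    if dim is not None:
        any_section = True
        lines.append("## Sexual dimorphism")
        for _, row in dim.iterrows():
            lines.append(
                f"- {row['region_id']}: control p = {row['control_p']:.3g}, "
                f"treated p = {row['treated_p']:.3g} -> {row['pattern']}"
            )
        lines.append("")

    blocks = _load(results_dir / "covariance_blocks.csv")
    if blocks is not None:
        any_section = True
        flagged = blocks[blocks["omnibus_passed"]]
        lines.append("## Structural covariance blocks")
        lines.append(f"- {len(flagged)}/{len(blocks)} cluster-pair blocks flagged "
                     "(q < 0.05 and eta-squared > 0.14)")
        for _, row in flagged.iterrows():
            lines.append(
                f"  - {row['cluster_a']} x {row['cluster_b']}: "
                f"eta2 = {row['eta_squared']:.2f}, class = {row['effect_class']}"
            )
        lines.append("")

    bb = _load(results_dir / "brain_behavior.csv")
    if bb is not None:
        any_section = True
        ok = bb[bb["computable"]].copy()
        lines.append("## Brain-behavior correlations (uncorrected)")
        lines.append(f"- {int(ok['significant'].sum())} significant of {len(ok)} computed")
        top = ok.reindex(ok["r"].abs().sort_values(ascending=False).index).head(10)
        for _, row in top.iterrows():
            lines.append(
                f"  - {row['region_id']} ~ {row['measure']} [{row['stratum']}]: "
                f"r = {row['r']:.3f}, p = {row['p']:.3g}, n = {int(row['n'])}"
            )
        lines.append("")

    if not any_section:
        lines.append("No analyses were run: the results directory holds no known CSVs.")
    return "\n".join(lines) + "\n"
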