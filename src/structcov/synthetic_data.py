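"""Synthetic cohort generation with known ground truth.

Cohorts are drawn per sex×treatment cell from a multivariate normal whose
correlation matrix has a six-cluster block structure (within-cluster r_w,
between-cluster r_b) optionally perturbed by cell-specific block deltas
("desynchronization"), and whose mean vector carries enlargement and
sexual-dimorphism shifts expressed in within-region SD units. Target
correlation matrices are repaired to positive definite by eigenvalue
clipping followed by diagonal renormalization; realized (post-repair)
block means are recorded in the emitted ground truth.

Randomness comes from :class:`numpy.random.Generator` seeded PCG64, so a
given seed reproduces the cohort bit-exactly across platforms.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from ._exceptions import ValidationError
from .volumes_io import (
    CELLS,
    CLUSTERS,
    AtlasHierarchy,
    LabelImage,
    VolumeTable,
    default_hierarchy,
)

DEFAULT_N_PER_CELL = {"control_M": 12, "control_F": 11, "treated_M": 11, "treated_F": 11}

BEHAVIOR_MEASURES = (
    "nag_bouts",
    "following",
    "push_crawl",
    "groom_bouts",
    "groom_time",
    "mfsi_groom_bouts",
    "mfsi_groom_time",
)
MALE_ONLY_MEASURES = frozenset({"mfsi_groom_bouts", "mfsi_groom_time"})


@dataclass
class EnlargementSpec:
    """Mean shift of ``d`` within-region SDs in the listed cells."""

    regions: list[str]
    d: float
    cells: list[str]


@dataclass
class DimorphismSpec:
    """Male − female mean gap of ``delta`` SDs within the listed groups."""

    regions: list[str]
    delta: float
    groups: list[str]  # e.g. ["control"] for control-only dimorphism


@dataclass
class DesyncSpec:
    """Additive correlation delta on one cluster-pair block, per cell."""

    cluster_a: str
    cluster_b: str
    delta_r: dict[str, float]  # cell label -> delta


@dataclass
class BehaviorCoupling:
    """behavior = offset + β·z(volume of region, within cell) + noise."""

    measure: str
    region: str
    beta: dict[str, float]  # cell label -> beta (unlisted cells: 0)
    noise_sd: float = 1.0
    offset: float = 10.0


@dataclass
class SimulationConfig:
    n_per_cell: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_N_PER_CELL))
    hierarchy: AtlasHierarchy | None = None  # default: packaged 159-region hierarchy
    mean_low: float = 0.05  # smallest regional mean volume, mm³
    mean_high: float = 30.0  # largest regional mean volume, mm³
    cv: float = 0.06  # within-cell SD as a fraction of the regional mean
    r_within: float = 0.6
    r_between: float = 0.3
    r_unassigned: float = 0.1  # correlation of unassigned regions to everything
    enlargements: list[EnlargementSpec] = field(default_factory=list)
    dimorphisms: list[DimorphismSpec] = field(default_factory=list)
    desyncs: list[DesyncSpec] = field(default_factory=list)
    couplings: list[BehaviorCoupling] = field(default_factory=list)
    behavior_measures: tuple[str, ...] = BEHAVIOR_MEASURES
    log_scale: bool = False
    max_repair_distortion: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hierarchy is None:
            self.hierarchy = default_hierarchy()

    def validate(self) -> None:
        for cell, n in self.n_per_cell.items():
            if cell not in CELLS:
                raise ValidationError(f"unknown cell label {cell!r}")
            if n < 3:
                raise ValidationError(f"cell {cell} needs n >= 3 (got {n})")
        for r in (self.r_within, self.r_between, self.r_unassigned):
            if not -1 < r < 1:
                raise ValidationError("correlation parameters must lie in (-1, 1)")
        regions = set(self.hierarchy.regions)
        for spec in self.enlargements + self.dimorphisms:
            missing = sorted(set(spec.regions) - regions)
            if missing:
                raise ValidationError(f"effect regions not in hierarchy: {missing}")
            for cell_or_group in getattr(spec, "cells", getattr(spec, "groups", [])):
                if cell_or_group not in CELLS + ("control", "treated"):
                    raise ValidationError(f"unknown cell/group {cell_or_group!r}")
        for ds in self.desyncs:
            for c in (ds.cluster_a, ds.cluster_b):
                if c not in CLUSTERS:
                    raise ValidationError(f"unknown cluster {c!r} in desync spec")
            for cell in ds.delta_r:
                if cell not in CELLS:
                    raise ValidationError(f"unknown cell {cell!r} in desync spec")
        for cp in self.couplings:
            if cp.region not in regions:
                raise ValidationError(f"coupling region {cp.region!r} not in hierarchy")
            if cp.measure not in self.behavior_measures:
                raise ValidationError(f"coupling measure {cp.measure!r} not listed")
        if self.cv <= 0 or self.mean_low <= 0 or self.mean_high <= self.mean_low:
            raise ValidationError("invalid mean/cv parameters")


@dataclass
class SyntheticTruth:
    """Ground truth emitted with every simulated cohort."""

    seed: int
    enlargements: list[dict]
    dimorphisms: list[dict]
    desync_blocks: list[dict]  # requested and realized (post-repair) block deltas
    couplings: list[dict]
    cell_sizes: dict[str, int]

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# Correlation-matrix construction
# ---------------------------------------------------------------------------

def repair_correlation(target: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Nearest convenient PD correlation: clip eigenvalues, renormalize diagonal."""
    sym = (target + target.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    if vals.min() >= floor:
        out = sym.copy()
    else:
        vals = np.clip(vals, floor, None)
        out = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return (out + out.T) / 2.0


def _base_target(config: SimulationConfig, regions: list[str]) -> np.ndarray:
    h = config.hierarchy
    clusters = np.array([h.cluster_of(r) or "" for r in regions], dtype=object)
    p = len(regions)
    target = np.full((p, p), config.r_between)
    unassigned = clusters == ""
    target[unassigned, :] = config.r_unassigned
    target[:, unassigned] = config.r_unassigned
    for c in CLUSTERS:
        idx = np.nonzero(clusters == c)[0]
        target[np.ix_(idx, idx)] = config.r_within
    np.fill_diagonal(target, 1.0)
    return target


def _cell_target(config: SimulationConfig, regions: list[str], cell: str) -> np.ndarray:
    """Target correlation matrix for one cell.

    Between-cluster deltas shift the flat block value directly. An
    intra-cluster delta models increased idiosyncratic variance of that
    cluster's regions, so it additionally attenuates every correlation
    involving the cluster by sqrt(λ'/λ) where λ is the within-cluster r —
    the factor-consistent interpretation that keeps the target close to
    positive definite at large block sizes.
    """
    target = _base_target(config, regions)
    h = config.hierarchy
    idx_of_cluster = {
        c: [i for i, r in enumerate(regions) if h.cluster_of(r) == c] for c in CLUSTERS
    }
    lam = {c: config.r_within for c in CLUSTERS}
    for ds in config.desyncs:
        delta = ds.delta_r.get(cell, 0.0)
        if delta == 0.0:
            continue
        if ds.cluster_a == ds.cluster_b:
            lam[ds.cluster_a] += delta
            if lam[ds.cluster_a] <= 0:
                raise ValidationError(
                    f"intra-cluster delta drives {ds.cluster_a} correlation <= 0"
                )
        else:
            ia = idx_of_cluster[ds.cluster_a]
            ib = idx_of_cluster[ds.cluster_b]
            target[np.ix_(ia, ib)] += delta
            target[np.ix_(ib, ia)] = target[np.ix_(ia, ib)].T
    # idiosyncratic-variance scaling for desynchronized clusters
    scale = np.ones(len(regions))
    for c in CLUSTERS:
        if lam[c] != config.r_within:
            scale[idx_of_cluster[c]] = np.sqrt(lam[c] / config.r_within)
    target = target * np.outer(scale, scale)
    np.fill_diagonal(target, 1.0)
    if np.abs(target - np.diag(np.diag(target))).max() >= 1.0:
        raise ValidationError("requested deltas push |r| to 1 or beyond")
    return target


def _block_mean(mat: np.ndarray, ia, ib, intra: bool) -> float:
    block = mat[np.ix_(ia, ib)]
    if intra:
        iu = np.triu_indices(len(ia), k=1)
        return float(block[iu].mean())
    return float(block.mean())


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def simulate_cohort(
    config: SimulationConfig, seed: int | None = None
) -> tuple[VolumeTable, pd.DataFrame, SyntheticTruth]:
    """Draw one cohort: volume table, behavior table, ground truth.

    Fully reproducible from ``seed`` (defaults to ``config.seed``).
    """
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    h = config.hierarchy
    regions = list(h.regions)
    p = len(regions)

    # deterministic regional scale: geometric ramp of means, sd = cv * mean
    means = np.geomspace(config.mean_low, config.mean_high, p)
    sds = config.cv * means

    # per-cell target correlation, PD repair, cholesky
    chol: dict[str, np.ndarray] = {}
    realized: dict[str, np.ndarray] = {}
    for cell in CELLS:
        target = _cell_target(config, regions, cell)
        repaired = repair_correlation(target)
        off = ~np.eye(p, dtype=bool)
        distortion = float(np.abs(repaired - target)[off].max())
        if distortion > config.max_repair_distortion:
            raise ValidationError(
                f"PD repair distorts cell {cell} correlations by {distortion:.3f} "
                f"(max allowed {config.max_repair_distortion}); request smaller deltas"
            )
        chol[cell] = np.linalg.cholesky(repaired)
        realized[cell] = repaired

    # per-cell mean shifts in SD units
    region_index = {r: i for i, r in enumerate(regions)}
    shifts = {cell: np.zeros(p) for cell in CELLS}
    for spec in config.enlargements:
        for cell in spec.cells:
            for r in spec.regions:
                shifts[cell][region_index[r]] += spec.d
    for spec in config.dimorphisms:
        for grp in spec.groups:
            for r in spec.regions:
                shifts[f"{grp}_M"][region_index[r]] += spec.delta

    frames = []
    design_rows = []
    for cell in CELLS:
        n = config.n_per_cell.get(cell, 0)
        if n == 0:
            continue
        group, sex = cell.rsplit("_", 1)
        z = rng.standard_normal((n, p)) @ chol[cell].T + shifts[cell]
        if config.log_scale:
            x = means * np.exp(config.cv * z)
        else:
            x = means + sds * z
            if (x <= 0).any():
                warnings.warn("non-positive simulated volumes truncated", stacklevel=2)
                x = np.maximum(x, 1e-9)
        ids = [f"{cell}_{i + 1:02d}" for i in range(n)]
        frames.append(pd.DataFrame(x, index=ids, columns=regions))
        design_rows += [{"subject_id": i, "sex": sex, "group": group} for i in ids]

    volumes = pd.concat(frames)
    design = pd.DataFrame(design_rows).set_index("subject_id")
    vt = VolumeTable(volumes=volumes, design=design)

    behavior = _simulate_behavior(config, vt, rng)
    truth = _build_truth(config, seed, regions, realized)
    return vt, behavior, truth


def _simulate_behavior(
    config: SimulationConfig, vt: VolumeTable, rng: np.random.Generator
) -> pd.DataFrame:
    couplings_by_measure: dict[str, list[BehaviorCoupling]] = {}
    for cp in config.couplings:
        couplings_by_measure.setdefault(cp.measure, []).append(cp)
    out = pd.DataFrame(index=vt.volumes.index, dtype=float)
    for measure in config.behavior_measures:
        vals = pd.Series(np.nan, index=vt.volumes.index)
        for cell in CELLS:
            group, sex = cell.rsplit("_", 1)
            mask = vt.subject_mask(sex=sex, group=group)
            if mask.sum() == 0:
                continue
            if measure in MALE_ONLY_MEASURES and sex == "F":
                continue
            n = int(mask.sum())
            signal = np.zeros(n)
            offset, noise_sd = 10.0, 1.0
            for cp in couplings_by_measure.get(measure, []):
                offset, noise_sd = cp.offset, cp.noise_sd
                beta = cp.beta.get(cell, 0.0)
                if beta != 0.0:
                    v = vt.volumes.loc[mask, cp.region].to_numpy()
                    zv = (v - v.mean()) / v.std(ddof=0)
                    signal = signal + beta * zv
            vals[mask] = offset + signal + rng.normal(0.0, noise_sd, n)
        out[measure] = vals
    return out


def _build_truth(config, seed, regions, realized) -> SyntheticTruth:
    h = config.hierarchy
    idx_of_cluster = {
        c: [i for i, r in enumerate(regions) if h.cluster_of(r) == c] for c in CLUSTERS
    }
    base = _base_target(config, regions)
    desync_blocks = []
    for ds in config.desyncs:
        ia, ib = idx_of_cluster[ds.cluster_a], idx_of_cluster[ds.cluster_b]
        intra = ds.cluster_a == ds.cluster_b
        base_mean = _block_mean(base, ia, ib, intra)
        entry = {
            "cluster_a": ds.cluster_a,
            "cluster_b": ds.cluster_b,
            "requested_delta_r": dict(ds.delta_r),
            "realized_mean_r": {
                cell: _block_mean(realized[cell], ia, ib, intra) for cell in CELLS
            },
            "base_mean_r": base_mean,
        }
        entry["realized_delta_r"] = {
            cell: entry["realized_mean_r"][cell] - base_mean for cell in CELLS
        }
        desync_blocks.append(entry)
    return SyntheticTruth(
        seed=seed,
        enlargements=[asdict(e) for e in config.enlargements],
        dimorphisms=[asdict(d) for d in config.dimorphisms],
        desync_blocks=desync_blocks,
        couplings=[asdict(c) for c in config.couplings],
        cell_sizes=dict(config.n_per_cell),
    )


# ---------------------------------------------------------------------------
# Label images
# ---------------------------------------------------------------------------

def simulate_label_image(
    voxel_counts: dict[int, int],
    voxel_size: tuple[float, float, float] = (0.04, 0.04, 0.04),
    label_map: dict[int, str] | None = None,
    shape: tuple[int, int, int] | None = None,
) -> LabelImage:
    """Deterministically place exact voxel counts per label in a 3-D array."""
    for label, count in voxel_counts.items():
        if label == 0:
            raise ValidationError("label 0 is reserved for background")
        if count < 0:
            raise ValidationError("voxel counts must be non-negative")
    total = sum(voxel_counts.values())
    if shape is None:
        side = max(1, int(np.ceil((total + 1) ** (1 / 3))))
        shape = (side, side, side)
    capacity = int(np.prod(shape))
    if total > capacity:
        raise ValidationError(f"{total} voxels requested but shape holds {capacity}")
    flat = np.zeros(capacity, dtype=np.int32)
    pos = 0
    for label in sorted(voxel_counts):
        c = voxel_counts[label]
        flat[pos:pos + c] = label
        pos += c
    if label_map is None:
        label_map = {label: f"region_{label}" for label in voxel_counts}
    return LabelImage(labels=flat.reshape(shape), voxel_size=voxel_size,
                      label_map=label_map)


# ---------------------------------------------------------------------------
# Preset
# ---------------------------------------------------------------------------

#: Regions given a d = 1.2 enlargement in treated females by the preset;
#: spans white matter, cortical, basal-nuclei, hippocampal and cerebellar
#: structures (20 regions).
PRESET_ENLARGED_REGIONS = [
    "anterior_commissure",
    "corpus_callosum",
    "fimbria",
    "internal_capsule",
    "stria_terminalis",
    "medial_orbital_cortex",
    "cingulate_cortex",
    "insular_cortex",
    "caudomedial_entorhinal_cortex",
    "nucleus_accumbens",
    "caudoputamen",
    "globus_pallidus",
    "basal_forebrain",
    "lateral_septum",
    "amygdala",
    "bed_nucleus_stria_terminalis",
    "cerebellar_cortex",
    "vermis",
    "paraflocculus",
    "stratum_granulosum",
]

PRESET_DIMORPHIC_REGIONS = ["amygdala", "bed_nucleus_stria_terminalis", "hypothalamus"]


def paper_scenario(seed: int = 0) -> SimulationConfig:
    """Preset emulating the study's qualitative structure.

    Female-treated regional enlargement (d = 1.2, 20 regions spanning four
    anatomical areas), male-biased dimorphism (δ = 1.0 in both groups) in
    amygdala/BNST/hypothalamus that the female-treated enlargement closes
    ("masculinization": the sex gap survives only in controls),
    hindbrain-block desynchronization (Δr = −0.4) in both treated cells,
    male-treated-only cortical and intra-hippocampal desynchronization,
    and a sex-opposed coupling of BNST volume to nose-to-anogenital
    sniffing (R² = 0.5 per cell), plus a male-treated grooming coupling to
    the dorsolateral orbital cortex.
    """
    both_treated = {"treated_M": -0.4, "treated_F": -0.4}
    male_treated = {"treated_M": -0.4}
    config = SimulationConfig(
        enlargements=[
            EnlargementSpec(regions=list(PRESET_ENLARGED_REGIONS), d=1.2,
                            cells=["treated_F"]),
            # closes the hypothalamus sex gap in treated females without
            # making the region FDR-detectable at n = 11
            EnlargementSpec(regions=["hypothalamus"], d=1.0, cells=["treated_F"]),
        ],
        dimorphisms=[
            DimorphismSpec(regions=list(PRESET_DIMORPHIC_REGIONS), delta=1.0,
                           groups=["control", "treated"]),
        ],
        desyncs=[
            DesyncSpec("posterior_cortical", "brainstem_cerebellum", dict(both_treated)),
            DesyncSpec("anterior_cortical", "brainstem_cerebellum", dict(both_treated)),
            DesyncSpec("midbrain", "brainstem_cerebellum", dict(both_treated)),
            DesyncSpec("hippocampal", "hippocampal", dict(male_treated)),
            DesyncSpec("posterior_cortical", "posterior_cortical", dict(male_treated)),
            DesyncSpec("posterior_cortical", "anterior_cortical", dict(male_treated)),
        ],
        couplings=[
            BehaviorCoupling(
                measure="nag_bouts",
                region="bed_nucleus_stria_terminalis",
                beta={"treated_F": 1.0, "treated_M": -1.0},
                noise_sd=1.0,
            ),
            BehaviorCoupling(
                measure="following",
                region="stratum_granulosum",
                beta={"treated_F": 1.0},
                noise_sd=1.0,
            ),
            BehaviorCoupling(
                measure="mfsi_groom_bouts",
                region="dorsolateral_orbital_cortex",
                beta={"treated_M": 1.0},
                noise_sd=1.0,
            ),
        ],
        seed=seed,
    )
    config.validate()
    return config


def write_cohort(
    out_dir,
    vt: VolumeTable,
    behavior: pd.DataFrame,
    truth: SyntheticTruth,
    hierarchy: AtlasHierarchy,
) -> dict[str, str]:
    """Write a simulated cohort as the CSV/TSV files the readers accept."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "volumes": out / "volumes.csv",
        "design": out / "design.csv",
        "behavior": out / "behavior.csv",
        "hierarchy": out / "hierarchy.tsv",
        "truth": out / "truth.json",
    }
    vt.write(paths["volumes"], paths["design"])
    behavior.to_csv(paths["behavior"], index_label="subject_id")
    hierarchy.write(paths["hierarchy"])
    truth.to_json(paths["truth"])
    return {k: str(v) for k, v in paths.items()}
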