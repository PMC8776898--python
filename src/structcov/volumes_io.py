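"""Input/output and validation for volume, design, hierarchy and behavior tables.

Tabular inputs are CSV or TSV (UTF-8, header row, decimal point); the
delimiter is inferred from the file suffix (``.tsv`` → tab, otherwise
comma). Label images are NIfTI-1; regional volumes are obtained by pure
voxel counting — no resampling or reorientation is performed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from ._exceptions import ValidationError

SEXES = ("M", "F")
GROUPS = ("treated", "control")

#: Canonical covariance-cluster names, in display order.
CLUSTERS = (
    "posterior_cortical",
    "hippocampal",
    "anterior_cortical",
    "subcortical",
    "midbrain",
    "brainstem_cerebellum",
)

#: Canonical sex-by-group cell labels, in display order.
CELLS = ("control_M", "control_F", "treated_M", "treated_F")


def cell_label(group: str, sex: str) -> str:
    return f"{group}_{sex}"


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file not found: {path}")
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


# ---------------------------------------------------------------------------
# Design / volume tables
# ---------------------------------------------------------------------------

def read_design(path: str | Path) -> pd.DataFrame:
    """Read a subject design table (columns: subject_id, sex, group)."""
    df = _read_table(path)
    required = {"subject_id", "sex", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"design table missing columns: {sorted(missing)}")
    df = df[["subject_id", "sex", "group"]].copy()
    df["subject_id"] = df["subject_id"].astype(str)
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate subject_id in design: {sorted(set(dup))}")
    for col, levels in (("sex", SEXES), ("group", GROUPS)):
        bad = df.loc[~df[col].isin(levels)]
        if len(bad):
            row = bad.iloc[0]
            raise ValidationError(
                f"unknown {col} value {row[col]!r} for subject {row['subject_id']!r}"
                f" (allowed: {levels})"
            )
    return df.set_index("subject_id")


@dataclass
class VolumeTable:
    """Subjects × regions absolute volumes (mm³) joined to design metadata.

    Attributes
    ----------
    volumes : pandas.DataFrame
        Strictly positive absolute volumes, one row per subject, one
        column per region; row index equals ``design``'s index.
    design : pandas.DataFrame
        ``sex`` and ``group`` per subject.
    tbv : pandas.Series
        Total brain volume per subject. Computed as the row sum of all
        regions unless supplied explicitly.
    tbv_explicit : bool
        Whether ``tbv`` came from an explicit input column.
    """

    volumes: pd.DataFrame
    design: pd.DataFrame
    tbv: pd.Series = field(default=None)  # type: ignore[assignment]
    tbv_explicit: bool = False

    def __post_init__(self) -> None:
        if self.tbv is None:
            self.tbv = self.volumes.sum(axis=1)
            self.tbv_explicit = False
        self.validate()

    def validate(self) -> None:
        if list(self.volumes.index) != list(self.design.index):
            vol_only = set(self.volumes.index) - set(self.design.index)
            des_only = set(self.design.index) - set(self.volumes.index)
            if vol_only or des_only:
                raise ValidationError(
                    "subject mismatch between volumes and design: "
                    f"only in volumes {sorted(vol_only)}, only in design {sorted(des_only)}"
                )
            # same subjects, different order: align volumes to design order
            self.volumes = self.volumes.loc[self.design.index]
            self.tbv = self.tbv.loc[self.design.index]
        if self.volumes.index.duplicated().any():
            raise ValidationError("duplicate subject_id in volume table")
        vals = self.volumes.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValidationError("non-numeric volume entries present")
        bad = ~np.isfinite(vals) | (vals <= 0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"volume must be finite and > 0; offending (subject, region) = "
                f"({self.volumes.index[i]!r}, {self.volumes.columns[j]!r})"
            )
        if (self.tbv + 1e-9 < self.volumes.max(axis=1)).any():
            sid = self.tbv.index[(self.tbv + 1e-9 < self.volumes.max(axis=1)).argmax()]
            raise ValidationError(f"tbv smaller than largest regional volume for {sid!r}")

    # -- convenience accessors ------------------------------------------------

    @property
    def regions(self) -> list[str]:
        return list(self.volumes.columns)

    @property
    def subjects(self) -> list[str]:
        return list(self.volumes.index)

    def subject_mask(self, sex: str | None = None, group: str | None = None) -> pd.Series:
        mask = pd.Series(True, index=self.design.index)
        if sex is not None:
            mask &= self.design["sex"] == sex
        if group is not None:
            mask &= self.design["group"] == group
        return mask

    def cell_counts(self) -> pd.Series:
        """Subject counts per sex×group cell, indexed by canonical cell label."""
        counts = {
            cell_label(g, s): int(((self.design["sex"] == s) & (self.design["group"] == g)).sum())
            for g in GROUPS
            for s in SEXES
        }
        return pd.Series(counts)

    def relative_volumes(self) -> pd.DataFrame:
        """Regional volumes as a fraction of each subject's TBV."""
        return self.volumes.div(self.tbv, axis=0)

    def write(self, volumes_path: str | Path, design_path: str | Path) -> None:
        sep_v = "\t" if str(volumes_path).endswith(".tsv") else ","
        sep_d = "\t" if str(design_path).endswith(".tsv") else ","
        out = self.volumes.copy()
        if self.tbv_explicit:
            out.insert(0, "tbv", self.tbv)
        # %.17g keeps doubles round-trippable through text
        out.to_csv(volumes_path, sep=sep_v, index_label="subject_id",
                   float_format="%.17g")
        self.design.to_csv(design_path, sep=sep_d, index_label="subject_id")


def read_volume_table(volumes_path: str | Path, design_path: str | Path) -> VolumeTable:
    """Read and cross-validate a volume table and its design table.

    The volumes file has ``subject_id`` in the first column and one column
    per region. An optional ``tbv`` column supplies explicit total brain
    volume; otherwise TBV is the row sum over regions. Region ordering in
    the file is preserved.
    """
    vdf = _read_table(volumes_path)
    if vdf.columns[0] != "subject_id":
        vdf = vdf.rename(columns={vdf.columns[0]: "subject_id"})
    vdf["subject_id"] = vdf["subject_id"].astype(str)
    if vdf["subject_id"].duplicated().any():
        dups = sorted(set(vdf["subject_id"][vdf["subject_id"].duplicated()]))
        raise ValidationError(f"duplicate subject_id in volumes: {dups}")
    vdf = vdf.set_index("subject_id")

    tbv = None
    explicit = False
    if "tbv" in vdf.columns:
        tbv = vdf.pop("tbv").astype(float)
        explicit = True
    for col in vdf.columns:
        if not np.issubdtype(vdf[col].dtype, np.number):
            bad = vdf[col][pd.to_numeric(vdf[col], errors="coerce").isna()]
            raise ValidationError(
                f"non-numeric volume for region {col!r}, subject {bad.index[0]!r}"
            )
    design = read_design(design_path)
    if set(vdf.index) != set(design.index):
        vol_only = sorted(set(vdf.index) - set(design.index))
        des_only = sorted(set(design.index) - set(vdf.index))
        raise ValidationError(
            f"subject mismatch: only in volumes {vol_only}, only in design {des_only}"
        )
    vdf = vdf.loc[design.index].astype(float)
    if tbv is not None:
        tbv = tbv.loc[design.index]
    return VolumeTable(volumes=vdf, design=design, tbv=tbv, tbv_explicit=explicit)


def total_brain_volume(vt: VolumeTable) -> pd.Series:
    """Per-subject TBV: explicit column if supplied, else sum over regions."""
    return vt.tbv.copy()


# ---------------------------------------------------------------------------
# Atlas hierarchy
# ---------------------------------------------------------------------------

@dataclass
class AtlasHierarchy:
    """Region → (anatomical area, covariance cluster or None) mapping."""

    table: pd.DataFrame  # index: region_id; columns: area, cluster (object, None allowed)

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            dups = sorted(set(self.table.index[self.table.index.duplicated()]))
            raise ValidationError(f"duplicate region_id in hierarchy: {dups}")
        bad = self.table["cluster"].dropna()
        unknown = sorted(set(bad) - set(CLUSTERS))
        if unknown:
            raise ValidationError(
                f"unknown cluster name(s) {unknown}; allowed: {list(CLUSTERS)}"
            )

    @property
    def regions(self) -> list[str]:
        return list(self.table.index)

    def area_of(self, region: str) -> str:
        return self.table.loc[region, "area"]

    def cluster_of(self, region: str) -> str | None:
        c = self.table.loc[region, "cluster"]
        return None if pd.isna(c) else c

    def regions_in_cluster(self, cluster: str) -> list[str]:
        if cluster not in CLUSTERS:
            raise ValidationError(f"unknown cluster name {cluster!r}")
        return list(self.table.index[self.table["cluster"] == cluster])

    @property
    def clustered_regions(self) -> list[str]:
        return list(self.table.index[self.table["cluster"].notna()])

    def cluster_census(self) -> dict[str, int]:
        """Region counts per cluster plus an ``unassigned`` tally."""
        census = {c: int((self.table["cluster"] == c).sum()) for c in CLUSTERS}
        census["unassigned"] = int(self.table["cluster"].isna().sum())
        return census

    def check_covers(self, regions: list[str]) -> None:
        missing = sorted(set(regions) - set(self.table.index))
        if missing:
            raise ValidationError(f"regions absent from hierarchy: {missing[:10]}")

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="region_id")


def read_hierarchy(path: str | Path) -> AtlasHierarchy:
    """Read a region hierarchy TSV (columns region_id, area, cluster)."""
    df = _read_table(path)
    required = {"region_id", "area", "cluster"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"hierarchy missing columns: {sorted(missing)}")
    df["region_id"] = df["region_id"].astype(str)
    df = df.set_index("region_id")[["area", "cluster"]]
    df["cluster"] = df["cluster"].replace("", np.nan)
    return AtlasHierarchy(table=df)


def default_hierarchy() -> AtlasHierarchy:
    """The packaged 159-region demonstration hierarchy."""
    path = Path(__file__).parent / "data" / "demo_hierarchy.tsv"
    return read_hierarchy(path)


# ---------------------------------------------------------------------------
# Behavior table
# ---------------------------------------------------------------------------

def read_behavior_table(path: str | Path, design: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read a wide behavior table (subject_id + one numeric column per measure).

    Missing values are allowed and propagate as NaN (pairwise-complete
    handling downstream). If ``design`` is given, behavior subjects must be
    a subset of the design's.
    """
    df = _read_table(path)
    if df.columns[0] != "subject_id":
        df = df.rename(columns={df.columns[0]: "subject_id"})
    df["subject_id"] = df["subject_id"].astype(str)
    if df["subject_id"].duplicated().any():
        raise ValidationError("duplicate subject_id in behavior table")
    df = df.set_index("subject_id")
    for col in df.columns:
        df[col] = pd.to_numeric(df[col], errors="raise")
        vals = df[col].dropna()
        if not np.isfinite(vals).all():
            raise ValidationError(f"non-finite behavior value in measure {col!r}")
    if design is not None:
        extra = sorted(set(df.index) - set(design.index))
        if extra:
            raise ValidationError(f"behavior subjects absent from design: {extra}")
    return df


# ---------------------------------------------------------------------------
# Label images
# ---------------------------------------------------------------------------

@dataclass
class LabelImage:
    """Integer 3-D label volume with voxel size (mm) and label→region map."""

    labels: np.ndarray
    voxel_size: tuple[float, float, float]
    label_map: Mapping[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError("label image must have an integer dtype")
        if self.labels.ndim != 3:
            raise ValidationError("label image must be 3-D")
        if any(v <= 0 for v in self.voxel_size):
            raise ValidationError("voxel dimensions must be strictly positive")
        if 0 in self.label_map:
            raise ValidationError("label 0 is reserved for background")

    @property
    def voxel_volume(self) -> float:
        dx, dy, dz = self.voxel_size
        return dx * dy * dz

    def to_nifti(self, path: str | Path) -> None:
        import nibabel as nib

        affine = np.diag([*self.voxel_size, 1.0])
        img = nib.Nifti1Image(self.labels.astype(np.int32), affine)
        img.header.set_zooms(self.voxel_size)
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path: str | Path, label_map: Mapping[int, str]) -> "LabelImage":
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if not np.issubdtype(data.dtype, np.integer):
            rounded = np.rint(data)
            if not np.allclose(data, rounded):
                raise ValidationError("NIfTI label image contains non-integer values")
            data = rounded.astype(np.int32)
        # NIfTI-1 stores zooms as float32; round to 1e-6 mm so that
        # human-specified decimal voxel sizes (e.g. 0.040) survive exactly
        zooms = tuple(round(float(z), 6) for z in img.header.get_zooms()[:3])
        return cls(labels=data, voxel_size=zooms, label_map=dict(label_map))


def read_label_map(path: str | Path) -> dict[int, str]:
    """Read a label→region map from JSON ({"1": "region"}) or TSV (label, region_id)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        raw = json.loads(path.read_text())
        return {int(k): str(v) for k, v in raw.items()}
    df = _read_table(path)
    if df.shape[1] < 2:
        raise ValidationError("label map needs two columns: label, region_id")
    return {int(l): str(r) for l, r in zip(df.iloc[:, 0], df.iloc[:, 1])}


def extract_region_volumes(image: LabelImage) -> pd.Series:
    """Per-region volume (mm³) by voxel counting: count × dx·dy·dz.

    Regions in the label map that do not occur in the image get volume 0
    with a warning; a nonzero label absent from the map is an error.
    """
    labels, counts = np.unique(image.labels, return_counts=True)
    present = dict(zip(labels.tolist(), counts.tolist()))
    present.pop(0, None)
    unknown = sorted(set(present) - set(image.label_map))
    if unknown:
        raise ValidationError(f"nonzero label(s) missing from label_map: {unknown}")
    out = {}
    for label, region in image.label_map.items():
        n = present.get(label, 0)
        if n == 0:
            warnings.warn(f"region {region!r} (label {label}) absent from image; volume 0",
                          stacklevel=2)
        out[region] = n * image.voxel_volume
    return pd.Series(out, name="volume_mm3")
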