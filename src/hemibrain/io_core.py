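"""Domain types and file I/O for the hemispheric connectivity pipeline.

All tabular artifacts are plain delimited text (CSV), partitions are JSON,
and optional parcel extraction reads NIfTI through nibabel.  Matrices are
indexed by the *included* regions of a :class:`RegionTable` in canonical
order: left-hemisphere regions sorted by ``pair_index`` followed by the
right-hemisphere regions in the same pair order, so that row ``i`` and row
``i + n_pairs`` are always a homotopic pair.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "PairingError",
    "GeometryError",
    "ConfigurationError",
    "RegionTable",
    "SubjectRecord",
    "ConnectivityMatrix",
    "AgreementMatrix",
    "Partition",
    "AssociationResult",
    "CommunityFlow",
    "read_region_table",
    "write_region_table",
    "read_timeseries",
    "read_covariates",
    "extract_parcel_timeseries",
    "read_matrix",
    "write_matrix",
    "read_partition",
    "write_partition",
    "write_metrics_table",
    "write_association_results",
    "write_community_flow",
    "FLOAT_FORMAT",
]

#: Fixed float formatting for every CSV the pipeline writes (12 significant
#: digits) so that identical runs produce byte-identical outputs.
FLOAT_FORMAT = "%.12g"

HEMISPHERES = ("L", "R")


class FormatError(ValueError):
    """Malformed input file or table."""


class PairingError(FormatError):
    """Homotopic pairing invariant violated."""


class GeometryError(ValueError):
    """Voxel-grid mismatch between image and atlas."""


class ConfigurationError(ValueError):
    """Invalid configuration value or degenerate configuration outcome."""


# ---------------------------------------------------------------------------
# Region table
# ---------------------------------------------------------------------------


@dataclass
class RegionTable:
    """Mirror-paired parcellation table.

    Parameters
    ----------
    table:
        DataFrame with columns ``region_id`` (unique non-negative int),
        ``hemisphere`` (``"L"``/``"R"``), ``pair_index`` (shared by exactly
        one region per hemisphere), ``name`` and ``included`` (bool).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy()
        required = ["region_id", "hemisphere", "pair_index", "name"]
        for col in required:
            if col not in df.columns:
                raise FormatError(f"region table missing column {col!r}")
        if "included" not in df.columns:
            df["included"] = True
        df["region_id"] = df["region_id"].astype(int)
        df["pair_index"] = df["pair_index"].astype(int)
        df["hemisphere"] = df["hemisphere"].astype(str)
        df["included"] = df["included"].astype(bool)
        self.table = df.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        df = self.table
        if (df["region_id"] < 0).any():
            raise FormatError("region_id must be non-negative")
        if df["region_id"].duplicated().any():
            dupes = df.loc[df["region_id"].duplicated(), "region_id"].tolist()
            raise FormatError(f"duplicate region_id values: {dupes}")
        bad = set(df["hemisphere"]) - set(HEMISPHERES)
        if bad:
            raise FormatError(f"hemisphere must be L or R, got {sorted(bad)}")
        counts = df.groupby("pair_index")["hemisphere"].agg(list)
        for pair, hemis in counts.items():
            if sorted(hemis) != ["L", "R"]:
                raise PairingError(
                    f"pair_index {pair} must occur once per hemisphere, got {hemis}"
                )
        n_l = int((df["hemisphere"] == "L").sum())
        n_r = int((df["hemisphere"] == "R").sum())
        if n_l != n_r:  # implied by pairing, kept as an explicit guard
            raise PairingError(f"hemisphere counts differ: {n_l} L vs {n_r} R")
        # a pair is included or excluded as a whole
        inc = df.groupby("pair_index")["included"].nunique()
        if (inc > 1).any():
            raise PairingError("pair with mixed included flags")

    # -- derived views ----------------------------------------------------

    @property
    def n_regions(self) -> int:
        return len(self.table)

    @property
    def n_pairs(self) -> int:
        return self.n_regions // 2

    @property
    def region_ids(self) -> np.ndarray:
        return self.table["region_id"].to_numpy()

    def included_pairs(self) -> np.ndarray:
        df = self.table
        return np.sort(df.loc[df["included"], "pair_index"].unique())

    @property
    def n_included_pairs(self) -> int:
        return len(self.included_pairs())

    def canonical_rows(self) -> pd.DataFrame:
        """Included rows ordered L-block then R-block, each by pair_index."""
        df = self.table.loc[self.table["included"]].copy()
        df["_h"] = (df["hemisphere"] == "R").astype(int)
        df = df.sort_values(["_h", "pair_index"]).drop(columns="_h")
        return df.reset_index(drop=True)

    def canonical_columns(self) -> np.ndarray:
        """Positional indices into the table rows giving canonical order."""
        df = self.table.reset_index()
        df = df.loc[df["included"]]
        order = np.argsort(
            (df["hemisphere"] == "R").to_numpy() * (self.n_pairs + df["pair_index"].max() + 1)
            + df["pair_index"].to_numpy(),
            kind="stable",
        )
        return df["index"].to_numpy()[order]

    def with_excluded_pairs(self, pair_indices: Iterable[int]) -> "RegionTable":
        """Return a copy with the given homotopic pairs marked excluded."""
        drop = set(int(p) for p in pair_indices)
        df = self.table.copy()
        df.loc[df["pair_index"].isin(drop), "included"] = False
        return RegionTable(df)

    def hemisphere_slices(self) -> tuple[slice, slice]:
        """(L, R) slices into a canonically ordered included-region matrix."""
        n = self.n_included_pairs
        return slice(0, n), slice(n, 2 * n)


def read_region_table(path: str | Path) -> RegionTable:
    df = pd.read_csv(path)
    return RegionTable(df)


def write_region_table(regions: RegionTable, path: str | Path) -> None:
    regions.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Subjects
# ---------------------------------------------------------------------------


@dataclass
class SubjectRecord:
    """One participant: parcellated time series plus covariates."""

    subject_id: str
    age: float
    sex: int
    mean_fd: float
    timeseries: np.ndarray  # T x n_regions, columns in RegionTable row order

    def __post_init__(self) -> None:
        self.timeseries = np.asarray(self.timeseries, dtype=float)
        if self.timeseries.ndim != 2:
            raise FormatError("timeseries must be a 2-D array")
        if self.timeseries.shape[0] < 3:
            raise FormatError(
                f"subject {self.subject_id}: need T >= 3 timepoints, "
                f"got {self.timeseries.shape[0]}"
            )
        if self.sex not in (0, 1):
            raise FormatError(f"sex must be coded 0/1, got {self.sex!r}")
        if not np.isnan(self.mean_fd) and self.mean_fd < 0:
            raise FormatError("mean_fd must be non-negative")

    @property
    def n_timepoints(self) -> int:
        return int(self.timeseries.shape[0])


def read_timeseries(
    path: str | Path,
    regions: RegionTable,
    orientation: str = "time-by-regions",
) -> np.ndarray:
    """Read a delimited time-series table and realign columns to the table.

    The file's header row (or first column for ``regions-by-time``) carries
    region ids; columns are permuted into the region-table row order.
    """
    if orientation not in ("time-by-regions", "regions-by-time"):
        raise ConfigurationError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path)
    if orientation == "regions-by-time":
        first = df.columns[0]
        df = df.set_index(first).T
        df.columns = [str(c) for c in df.columns]
        df = df.reset_index(drop=True)
    try:
        file_ids = np.array([int(str(c)) for c in df.columns])
    except ValueError as exc:
        raise FormatError(f"non-integer region id in header of {path}") from exc
    wanted = regions.region_ids
    missing = set(wanted) - set(file_ids)
    if missing:
        raise FormatError(f"{path}: missing region ids {sorted(missing)}")
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any() and df.isna().any().any():
        raise FormatError(f"{path}: non-numeric or missing cells")
    pos = {rid: i for i, rid in enumerate(file_ids)}
    order = np.array([pos[rid] for rid in wanted])
    return values[:, order]


def read_covariates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("subject_id", "age", "sex", "mean_fd"):
        if col not in df.columns:
            raise FormatError(f"covariates file missing column {col!r}")
    df["subject_id"] = df["subject_id"].astype(str)
    return df


def extract_parcel_timeseries(
    bold_img,
    atlas_img,
    regions: RegionTable,
    label_map: Mapping[int, int] | None = None,
) -> np.ndarray:
    """Average a 4-D BOLD image over atlas parcels.

    ``label_map`` maps atlas label -> region_id; by default atlas labels are
    assumed to equal ``region_id + 1`` (0 is background).  Returns a
    T x n_regions matrix in region-table row order.  Empty parcels yield a
    NaN column and a warning, to be caught by SNR screening downstream.
    """
    import warnings

    import nibabel as nib

    if isinstance(bold_img, (str, Path)):
        bold_img = nib.load(str(bold_img))
    if isinstance(atlas_img, (str, Path)):
        atlas_img = nib.load(str(atlas_img))
    bold = np.asanyarray(bold_img.dataobj, dtype=float)
    atlas = np.asanyarray(atlas_img.dataobj)
    atlas = np.rint(atlas).astype(int)
    if bold.ndim != 4:
        raise GeometryError("BOLD image must be 4-D")
    if atlas.shape != bold.shape[:3]:
        raise GeometryError(
            f"atlas grid {atlas.shape} != BOLD grid {bold.shape[:3]}"
        )
    if not np.allclose(bold_img.affine, atlas_img.affine, atol=1e-4):
        raise GeometryError("BOLD and atlas affines differ")
    if label_map is None:
        label_map = {int(rid) + 1: int(rid) for rid in regions.region_ids}
    known = set(label_map)
    present = set(np.unique(atlas)) - {0}
    unknown = present - known
    if unknown:
        raise GeometryError(f"atlas labels not in region table: {sorted(unknown)}")
    t = bold.shape[3]
    out = np.full((t, regions.n_regions), np.nan)
    flat = bold.reshape(-1, t)
    atlas_flat = atlas.ravel()
    for row, rid in enumerate(regions.region_ids):
        labels = [lab for lab, r in label_map.items() if r == rid]
        mask = np.isin(atlas_flat, labels)
        if not mask.any():
            warnings.warn(f"empty parcel for region_id {rid}; column set to NaN")
            continue
        out[:, row] = flat[mask].mean(axis=0)
    return out


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------


@dataclass
class ConnectivityMatrix:
    """Symmetric Fisher-z connectivity matrix over included regions."""

    z: np.ndarray
    provenance: str = "group"
    threshold_applied: str = "none"  # none | absolute:<theta> | proportional:<d>

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 2 or self.z.shape[0] != self.z.shape[1]:
            raise FormatError("connectivity matrix must be square")
        if not np.allclose(self.z, self.z.T, atol=1e-10):
            raise FormatError("connectivity matrix must be symmetric")
        if not np.allclose(np.diag(self.z), 0.0):
            raise FormatError("connectivity matrix diagonal must be zero")

    @property
    def n(self) -> int:
        return int(self.z.shape[0])


@dataclass
class AgreementMatrix:
    """Co-assignment frequencies across clustering runs (one hemisphere)."""

    d: np.ndarray
    n_runs: int

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.ndim != 2 or self.d.shape[0] != self.d.shape[1]:
            raise FormatError("agreement matrix must be square")
        if not np.allclose(self.d, self.d.T, atol=1e-10):
            raise FormatError("agreement matrix must be symmetric")
        if (self.d < -1e-12).any() or (self.d > 1 + 1e-12).any():
            raise FormatError("agreement entries must lie in [0, 1]")
        if not np.allclose(np.diag(self.d), 1.0):
            raise FormatError("agreement diagonal must be 1")


def write_matrix(
    m: np.ndarray, region_ids: Sequence[int], path: str | Path
) -> None:
    df = pd.DataFrame(m, columns=[str(r) for r in region_ids])
    df.insert(0, "region_id", list(region_ids))
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_matrix(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    ids = df["region_id"].to_numpy(dtype=int)
    m = df.drop(columns="region_id").to_numpy(dtype=float)
    return m, ids


# ---------------------------------------------------------------------------
# Partitions
# ---------------------------------------------------------------------------


@dataclass
class Partition:
    """Node -> community assignment.

    ``labels`` is positional over whatever node set the producing operation
    documents (one hemisphere's pairs, or both hemispheres in canonical
    order).  When ``symmetric`` is set, homotopic partners share labels.
    """

    labels: np.ndarray
    symmetric: bool = False
    network_names: dict[int, str] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise FormatError("partition labels must be a vector")
        if self.symmetric:
            n = len(self.labels)
            if n % 2:
                raise PairingError("symmetric partition needs an even node count")
            half = n // 2
            if not np.array_equal(self.labels[:half], self.labels[half:]):
                raise PairingError("symmetric partition has mismatched hemispheres")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def name_of(self, label: int) -> str:
        if self.network_names and label in self.network_names:
            return self.network_names[label]
        return str(label)


def write_partition(
    p: Partition, region_ids: Sequence[int], path: str | Path
) -> None:
    if len(region_ids) != p.n_nodes:
        raise FormatError("region_ids length does not match partition")
    obj = {
        "symmetric": bool(p.symmetric),
        "labels": {str(int(r)): int(c) for r, c in zip(region_ids, p.labels)},
        "network_names": {str(k): v for k, v in (p.network_names or {}).items()},
    }
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))


def read_partition(path: str | Path) -> tuple[Partition, np.ndarray]:
    obj = json.loads(Path(path).read_text())
    items = sorted(obj["labels"].items(), key=lambda kv: int(kv[0]))
    ids = np.array([int(k) for k, _ in items])
    labels = np.array([int(v) for _, v in items])
    names = {int(k): v for k, v in obj.get("network_names", {}).items()} or None
    # region ids are stored sorted; the caller realigns to canonical order
    return Partition(labels, symmetric=False, network_names=names), ids


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------


@dataclass
class AssociationResult:
    metric: str
    network: str
    hemisphere: str
    n: int
    r: float
    p: float
    p_adjusted: float
    correction: str
    significant: bool
    covariates: tuple[str, ...] = ("sex", "mean_fd")

    def __post_init__(self) -> None:
        if not (-1 - 1e-9 <= self.r <= 1 + 1e-9):
            raise FormatError(f"|r| > 1: {self.r}")
        if self.p_adjusted + 1e-12 < self.p:
            raise FormatError("adjusted p below raw p")


ASSOCIATION_COLUMNS = [
    "metric",
    "network",
    "hemisphere",
    "n",
    "r",
    "p",
    "p_adjusted",
    "correction",
    "significant",
    "covariates",
]


def write_association_results(
    results: Sequence[AssociationResult], path: str | Path
) -> None:
    rows = [
        {
            "metric": a.metric,
            "network": a.network,
            "hemisphere": a.hemisphere,
            "n": a.n,
            "r": a.r,
            "p": a.p,
            "p_adjusted": a.p_adjusted,
            "correction": a.correction,
            "significant": a.significant,
            "covariates": "+".join(a.covariates),
        }
        for a in results
    ]
    df = pd.DataFrame(rows, columns=ASSOCIATION_COLUMNS)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


METRICS_COLUMNS = [
    "network",
    "hemisphere",
    "sum_z_within",
    "sum_z_homotopic",
    "segregation",
    "inter_integration",
    "intra_integration",
    "whole_contra_integration",
]


def write_metrics_table(table: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in table.columns if c not in METRICS_COLUMNS]
    table = table[cols + [c for c in METRICS_COLUMNS if c in table.columns]]
    table.to_csv(path, index=False, float_format=FLOAT_FORMAT)


@dataclass
class CommunityFlow:
    """Contingency tables of community reassignment across ordered groups."""

    group_labels: tuple[str, ...]
    tables: dict  # (hemisphere, pair_idx) -> DataFrame (rows: group g, cols: g+1)
    n_communities: dict  # (hemisphere, group_label) -> int

    def __post_init__(self) -> None:
        totals = {}
        for (hemi, i), tab in self.tables.items():
            total = int(tab.to_numpy().sum())
            totals.setdefault(hemi, set()).add(total)
        for hemi, ts in totals.items():
            if len(ts) > 1:
                raise FormatError(f"hemisphere {hemi}: flow totals differ: {ts}")


def write_community_flow(flow: CommunityFlow, out_dir: str | Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for (hemi, i), tab in sorted(flow.tables.items()):
        a, b = flow.group_labels[i], flow.group_labels[i + 1]
        path = out_dir / f"flow_{hemi}_{a}_to_{b}.csv"
        tab.to_csv(path, float_format=FLOAT_FORMAT)
        written.append(path)
    counts = pd.DataFrame(
        [
            {"hemisphere": h, "group": g, "n_communities": n}
            for (h, g), n in sorted(flow.n_communities.items())
        ]
    )
    cpath = out_dir / "community_counts.csv"
    counts.to_csv(cpath, index=False)
    written.append(cpath)
    return written
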