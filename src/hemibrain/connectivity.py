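"""Subject/region screening and connectivity-matrix construction.

Framewise displacement follows the Power convention: per-frame sum of
absolute backward differences of the six rigid-body parameters, with the
three rotations (radians) converted to millimetres of arc on a 50 mm
sphere.  Connectivity is Pearson correlation over time followed by the
Fisher z-transform; thresholding keeps entries strictly above theta
(absolute scheme) or the strongest positive edges at a target density
(proportional scheme).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import (
    ConfigurationError,
    ConnectivityMatrix,
    FormatError,
    RegionTable,
    SubjectRecord,
)

__all__ = [
    "SnrReport",
    "mean_framewise_displacement",
    "screen_subjects",
    "screen_regions_by_snr",
    "connectivity_matrix",
    "fisher_z",
    "threshold_absolute",
    "threshold_proportional",
]

ROTATION_RADIUS_MM = 50.0
#: correlations clipped to +-(1 - CLIP_EPS) before atanh
CLIP_EPS = 1e-12


def mean_framewise_displacement(motion: np.ndarray) -> float:
    """Mean FD (mm) from a T x 6 rigid-body parameter series.

    Columns are three translations (mm) then three rotations (rad).  The
    first frame contributes zero displacement.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise FormatError(
            f"motion parameters must be T x 6, got shape {motion.shape}"
        )
    if motion.shape[0] < 2:
        raise FormatError("need at least 2 frames to compute FD")
    diffs = np.abs(np.diff(motion, axis=0))
    diffs[:, 3:] *= ROTATION_RADIUS_MM
    fd = diffs.sum(axis=1)
    return float(fd.sum() / motion.shape[0])  # first frame contributes 0


def screen_subjects(
    cohort: list[SubjectRecord], fd_max: float = 0.2
) -> tuple[list[SubjectRecord], pd.DataFrame]:
    """Drop subjects whose mean FD exceeds ``fd_max``; log the exclusions."""
    retained, excluded = [], []
    for s in cohort:
        if s.mean_fd > fd_max:
            excluded.append({"subject_id": s.subject_id, "mean_fd": s.mean_fd})
        else:
            retained.append(s)
    if not retained:
        raise ConfigurationError(
            f"fd_max={fd_max} excludes every subject ({len(cohort)} total)"
        )
    log = pd.DataFrame(excluded, columns=["subject_id", "mean_fd"])
    return retained, log


@dataclass
class SnrReport:
    """Subject-averaged region SNR and the pairs it excluded."""

    region_snr: pd.Series  # indexed by region_id
    mu: float
    sigma: float
    excluded_pairs: list[int]

    def to_frame(self) -> pd.DataFrame:
        df = self.region_snr.rename("snr").reset_index()
        df["mu"] = self.mu
        df["sigma"] = self.sigma
        return df


def screen_regions_by_snr(
    cohort: list[SubjectRecord],
    regions: RegionTable,
    k_sd: float = 2.0,
) -> tuple[SnrReport, RegionTable]:
    """Exclude homotopic pairs with outlying signal-to-noise ratio.

    Region SNR is mean(timeseries)/sd(timeseries) per subject, averaged
    over subjects.  Regions whose SNR falls outside mu +/- k_sd * sigma of
    the across-region distribution are flagged, and a flagged region always
    excludes its whole homotopic pair.  Zero-variance regions have
    undefined SNR and are force-excluded with a warning.
    """
    if k_sd < 0:
        raise ConfigurationError("k_sd must be non-negative")
    if not cohort:
        raise ConfigurationError("empty cohort")
    if regions.n_regions < 2:
        raise ConfigurationError("need at least 2 regions")
    snr_sum = np.zeros(regions.n_regions)
    undefined = np.zeros(regions.n_regions, dtype=bool)
    for s in cohort:
        ts = s.timeseries
        if ts.shape[1] != regions.n_regions:
            raise FormatError(
                f"subject {s.subject_id}: {ts.shape[1]} columns for "
                f"{regions.n_regions} regions"
            )
        sd = ts.std(axis=0, ddof=0)
        zero = sd == 0
        undefined |= zero
        with np.errstate(divide="ignore", invalid="ignore"):
            snr = np.where(zero, np.nan, ts.mean(axis=0) / sd)
        snr_sum += np.where(zero, 0.0, snr)
    snr_mean = snr_sum / len(cohort)
    snr_mean[undefined] = np.nan
    valid = ~undefined
    mu = float(np.mean(snr_mean[valid])) if valid.any() else np.nan
    sigma = float(np.std(snr_mean[valid], ddof=0)) if valid.any() else np.nan
    flagged = undefined.copy()
    if valid.any():
        dev = np.abs(snr_mean - mu)
        flagged |= valid & (dev > k_sd * sigma)
    if undefined.any():
        bad = regions.region_ids[undefined].tolist()
        warnings.warn(f"zero-variance regions force-excluded: {bad}")
    pair_idx = regions.table["pair_index"].to_numpy()
    excluded_pairs = sorted(set(pair_idx[flagged].tolist()))
    updated = regions.with_excluded_pairs(excluded_pairs)
    if updated.n_included_pairs == 0:
        raise ConfigurationError("SNR screening excluded every region pair")
    report = SnrReport(
        region_snr=pd.Series(snr_mean, index=regions.region_ids),
        mu=mu,
        sigma=sigma,
        excluded_pairs=excluded_pairs,
    )
    return report, updated


def fisher_z(r: np.ndarray) -> np.ndarray:
    """atanh with clipping so perfect correlations stay finite."""
    r = np.clip(np.asarray(r, dtype=float), -(1 - CLIP_EPS), 1 - CLIP_EPS)
    return np.arctanh(r)


def connectivity_matrix(
    subject: SubjectRecord, regions: RegionTable
) -> ConnectivityMatrix:
    """Fisher-z correlation matrix over included regions, canonical order."""
    cols = regions.canonical_columns()
    ts = subject.timeseries[:, cols]
    if ts.shape[0] < 3:
        raise FormatError("need T >= 3 for correlation")
    sd = ts.std(axis=0, ddof=0)
    if (sd == 0).any():
        ids = regions.canonical_rows()["region_id"].to_numpy()[sd == 0]
        raise FormatError(
            f"subject {subject.subject_id}: constant time series in regions "
            f"{ids.tolist()} (should have been screened)"
        )
    r = np.corrcoef(ts, rowvar=False)
    z = fisher_z(r)
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(z=z, provenance=subject.subject_id)


def threshold_absolute(
    m: ConnectivityMatrix, theta: float = 0.2
) -> ConnectivityMatrix:
    """Zero every entry not strictly greater than ``theta``."""
    if theta < 0:
        raise ConfigurationError("absolute threshold must be non-negative")
    z = np.where(m.z > theta, m.z, 0.0)
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(
        z=z, provenance=m.provenance, threshold_applied=f"absolute:{theta:g}"
    )


def threshold_proportional(
    m: ConnectivityMatrix, density: float
) -> ConnectivityMatrix:
    """Keep the top ceil(density * E) strongest positive edges.

    E counts all upper-triangle entries.  Ties at the cutoff weight are all
    retained, so the rule is deterministic and order-independent.
    """
    if not (0 < density <= 1):
        raise ConfigurationError(f"density must lie in (0, 1], got {density}")
    n = m.n
    iu = np.triu_indices(n, k=1)
    w = m.z[iu]
    n_edges = len(w)
    k = int(np.ceil(density * n_edges))
    pos = w[w > 0]
    if pos.size == 0:
        raise ConfigurationError("no positive entries to threshold")
    if k >= pos.size:
        cutoff = np.min(pos)
    else:
        cutoff = np.sort(pos)[::-1][k - 1]
    z = np.where(m.z >= cutoff, m.z, 0.0)
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(
        z=z, provenance=m.provenance, threshold_applied=f"proportional:{density:g}"
    )
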