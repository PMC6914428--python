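"""Synthetic cohorts with planted hemispheric network structure.

Each subject's parcellated time series is drawn from a zero-mean
multivariate normal whose correlation matrix has a mirror-paired block
layout: networks of homotopic region pairs, a configurable baseline
within- and between-network coupling inside each hemisphere, mirror-pair
homotopic correlations that drift linearly with age, and optional linear
age drifts of within-network and cross-network coupling.  (The homotopic
value sits on the mirror-pair entries rather than the whole contralateral
block: strong block-level cross-hemisphere coupling exceeding the
within-hemisphere between-network baseline cannot be positive definite.)  Only second-order
structure matters to the downstream analysis, so no haemodynamic model is
attempted; an optional AR(1) coefficient adds temporal autocorrelation
while preserving the stationary covariance.

Cross-network age slopes can be *balanced*: a designated network's
coupling to every other network rises while the couplings among the other
networks decline just enough to keep each non-designated network's total
within-hemisphere connectivity flat in expectation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io_core import ConfigurationError, RegionTable, SubjectRecord

__all__ = [
    "SimulationConfig",
    "network_layout",
    "region_table",
    "build_covariance",
    "simulate_subject",
    "simulate_cohort",
]

_DEF_NETWORKS = {f"N{i + 1}": 5 for i in range(6)}

#: maximum tolerated positive-definiteness repair (max abs off-diagonal change)
MAX_PD_SHRINKAGE = 0.05


@dataclass
class SimulationConfig:
    n_subjects: int = 100
    age_range: tuple[float, float] = (19.0, 80.0)
    n_pairs_per_network: dict[str, int] = field(
        default_factory=lambda: dict(_DEF_NETWORKS)
    )
    t_points: int = 230
    within_network_r: float = 0.5
    within_network_age_slope: dict[str, float] = field(default_factory=dict)
    between_network_r: float = 0.1
    cross_network_age_slope: dict[str, float] = field(default_factory=dict)
    balanced_cross_slopes: bool = True
    homotopic_r0: float = 0.5
    homotopic_age_slope: dict[str, float] = field(default_factory=dict)
    cross_hemisphere_r: float = 0.03
    cross_hemisphere_same_network_r: float | None = None
    noise_sd: float = 0.0
    ar_coef: float = 0.0
    fd_lognormal: tuple[float, float] = (-2.6, 0.35)
    fd_age_slope: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.age_range
        if not lo < hi:
            raise ConfigurationError("age_range must be increasing")
        if self.t_points < 3:
            raise ConfigurationError("t_points must be >= 3")
        if not self.n_pairs_per_network:
            raise ConfigurationError("need at least one network")
        if any(n < 1 for n in self.n_pairs_per_network.values()):
            raise ConfigurationError("every network needs >= 1 pair")
        if not (0 <= self.ar_coef < 1):
            raise ConfigurationError("ar_coef must lie in [0, 1)")
        for bad in set(self.homotopic_age_slope) - set(self.n_pairs_per_network):
            raise ConfigurationError(f"unknown network in homotopic slopes: {bad}")
        for bad in set(self.cross_network_age_slope) - set(self.n_pairs_per_network):
            raise ConfigurationError(f"unknown network in cross slopes: {bad}")
        for bad in set(self.within_network_age_slope) - set(self.n_pairs_per_network):
            raise ConfigurationError(f"unknown network in within slopes: {bad}")
        # fail early if the implied correlation matrix degenerates anywhere
        for age in self.age_range:
            build_covariance(self, age)

    @property
    def network_names(self) -> list[str]:
        return list(self.n_pairs_per_network)

    @property
    def n_pairs(self) -> int:
        return sum(self.n_pairs_per_network.values())


def network_layout(cfg: SimulationConfig) -> np.ndarray:
    """Network index (into ``cfg.network_names``) for every homotopic pair."""
    return np.concatenate(
        [
            np.full(n, i, dtype=int)
            for i, n in enumerate(cfg.n_pairs_per_network.values())
        ]
    )


def region_table(cfg: SimulationConfig) -> RegionTable:
    """Mirror-paired region table in canonical order (L block then R)."""
    p = cfg.n_pairs
    layout = network_layout(cfg)
    names = cfg.network_names
    rows = []
    for hemi, offset in (("L", 0), ("R", p)):
        for pair in range(p):
            rows.append(
                {
                    "region_id": offset + pair,
                    "hemisphere": hemi,
                    "pair_index": pair,
                    "name": f"{names[layout[pair]]}_{hemi}{pair}",
                    "included": True,
                }
            )
    return RegionTable(pd.DataFrame(rows))


def _between_slope_matrix(cfg: SimulationConfig) -> np.ndarray:
    """Per-network-pair age slope of the between-network correlation."""
    names = cfg.network_names
    k = len(names)
    s = np.zeros((k, k))
    sizes = np.array(list(cfg.n_pairs_per_network.values()), dtype=float)
    for name, slope in cfg.cross_network_age_slope.items():
        c = names.index(name)
        for d in range(k):
            if d != c:
                s[c, d] += slope
                s[d, c] += slope
        if cfg.balanced_cross_slopes and k > 2:
            # decrement the other networks' mutual coupling so each keeps a
            # flat expected total; exact when network sizes are equal
            if len(set(sizes)) > 1:
                warnings.warn(
                    "balanced cross slopes are only exact for equal-size networks"
                )
            dec = slope * sizes[c] / (sizes[[i for i in range(k) if i != c]].mean() * (k - 2))
            for d in range(k):
                for e in range(d + 1, k):
                    if c not in (d, e):
                        s[d, e] -= dec
                        s[e, d] -= dec
    return s


def build_covariance(cfg: SimulationConfig, age: float) -> np.ndarray:
    """Target correlation matrix (2P x 2P, canonical order) at a given age."""
    p = cfg.n_pairs
    layout = network_layout(cfg)
    names = cfg.network_names
    da = age - cfg.age_range[0]
    within = np.array(
        [
            cfg.within_network_r + cfg.within_network_age_slope.get(nm, 0.0) * da
            for nm in names
        ]
    )
    homo = np.array(
        [
            cfg.homotopic_r0 + cfg.homotopic_age_slope.get(nm, 0.0) * da
            for nm in names
        ]
    )
    between = cfg.between_network_r + _between_slope_matrix(cfg) * da
    same_net = layout[:, None] == layout[None, :]
    # within-hemisphere block
    b = between[np.ix_(layout, layout)]
    b[same_net] = within[layout[np.where(same_net)[0]]]
    np.fill_diagonal(b, 1.0)
    # cross-hemisphere block (pair-aligned): homotopic value on the mirror
    # diagonal, same-network baseline elsewhere in the contralateral block
    xh_net = (
        cfg.cross_hemisphere_same_network_r
        if cfg.cross_hemisphere_same_network_r is not None
        else cfg.cross_hemisphere_r
    )
    x = np.full((p, p), cfg.cross_hemisphere_r)
    x[same_net] = xh_net
    np.fill_diagonal(x, homo[layout])
    r = np.block([[b, x], [x.T, b]])
    bad = np.abs(r[~np.eye(2 * p, dtype=bool)]) >= 1.0
    if bad.any():
        raise ConfigurationError(
            f"correlation magnitude >= 1 at age {age:g}; rescale the slopes"
        )
    return _nearest_pd(r)


def _nearest_pd(r: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    vals, vecs = np.linalg.eigh(r)
    if vals.min() >= floor:
        return r
    clipped = np.clip(vals, floor, None)
    fixed = (vecs * clipped) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    shrink = float(np.max(np.abs(fixed - r)))
    if shrink > MAX_PD_SHRINKAGE:
        raise ConfigurationError(
            f"positive-definiteness repair needed shrinkage {shrink:.3f} "
            f"(> {MAX_PD_SHRINKAGE}); choose gentler slopes"
        )
    warnings.warn(f"covariance repaired to positive definite (shrinkage {shrink:.4f})")
    return fixed


def simulate_subject(
    cfg: SimulationConfig,
    age: float,
    rng: np.random.Generator | int | None = None,
    subject_id: str = "sim-subject",
) -> SubjectRecord:
    """Draw one subject's time series and covariates at a given age."""
    rng = np.random.default_rng(rng)
    r = build_covariance(cfg, age)
    chol = np.linalg.cholesky(r)
    n = r.shape[0]
    innov = rng.standard_normal((cfg.t_points, n))
    if cfg.ar_coef > 0:
        phi = cfg.ar_coef
        scale = np.sqrt(1.0 - phi**2)
        out = np.empty_like(innov)
        out[0] = innov[0]
        for t in range(1, cfg.t_points):
            out[t] = phi * out[t - 1] + scale * innov[t]
        innov = out
    ts = innov @ chol.T
    if cfg.noise_sd > 0:
        ts = ts + cfg.noise_sd * rng.standard_normal(ts.shape)
    mu, sigma = cfg.fd_lognormal
    fd = float(rng.lognormal(mu, sigma) + cfg.fd_age_slope * (age - cfg.age_range[0]))
    return SubjectRecord(
        subject_id=subject_id,
        age=float(age),
        sex=int(rng.integers(0, 2)),
        mean_fd=max(fd, 0.0),
        timeseries=ts,
    )


def simulate_cohort(
    cfg: SimulationConfig,
) -> tuple[list[SubjectRecord], dict, RegionTable]:
    """Simulate the full cohort plus a ground-truth record.

    Ages are drawn uniformly over ``cfg.age_range``.  The truth record
    carries the planted partition (per region, canonical order), network
    names and every planted slope, for recovery tests.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.age_range
    ages = rng.uniform(lo, hi, cfg.n_subjects)
    cohort = []
    width = len(str(cfg.n_subjects))
    for i, age in enumerate(ages):
        cohort.append(
            simulate_subject(cfg, age, rng, subject_id=f"sub-{i:0{width}d}")
        )
    layout = network_layout(cfg)
    truth = {
        "network_names": cfg.network_names,
        "partition": np.concatenate([layout, layout]).tolist(),
        "homotopic_age_slope": dict(cfg.homotopic_age_slope),
        "cross_network_age_slope": dict(cfg.cross_network_age_slope),
        "within_network_age_slope": dict(cfg.within_network_age_slope),
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(cfg).items()
        },
    }
    regions = region_table(cfg)
    return cohort, truth, regions
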