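"""Weighted Louvain modularity maximisation, consensus clustering and the
cross-hemisphere symmetric group partition.

The Louvain routine is a self-contained two-phase implementation on dense
non-negative weight matrices: greedy local moves in randomised node order,
then aggregation of communities into super-nodes, repeated until the
modularity

    Q = (1/2m) * sum_ij [ w_ij - gamma * k_i * k_j / 2m ] * delta(c_i, c_j)

stops improving.  The reported Q is always re-evaluated directly from this
formula on the returned partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import (
    AgreementMatrix,
    CommunityFlow,
    ConfigurationError,
    FormatError,
    Partition,
)

__all__ = [
    "LouvainConfig",
    "ConsensusError",
    "modularity",
    "louvain",
    "agreement",
    "consensus_partition",
    "group_symmetric_partition",
    "count_communities",
    "match_labels",
    "community_flow",
]


@dataclass
class LouvainConfig:
    gamma: float = 1.0
    n_runs_subject: int = 150
    n_runs_consensus: int = 100
    tau: float = 0.5
    seed: int = 0
    max_consensus_iter: int = 50

    def __post_init__(self) -> None:
        if self.n_runs_subject < 1 or self.n_runs_consensus < 1:
            raise ConfigurationError("run counts must be >= 1")
        if not (0 <= self.tau < 1):
            raise ConfigurationError("tau must lie in [0, 1)")


class ConsensusError(RuntimeError):
    """Consensus clustering failed to stabilise."""

    def __init__(self, message: str, dispersion: float):
        super().__init__(message)
        self.dispersion = dispersion


def _check_weights(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise FormatError("weight matrix must be square")
    if not np.allclose(w, w.T, atol=1e-10):
        raise FormatError("weight matrix must be symmetric")
    if (w < 0).any():
        raise ValueError("negative weights: threshold the matrix first")
    if not np.allclose(np.diag(w), 0.0):
        raise FormatError("weight matrix diagonal must be zero")
    return w


def modularity(w: np.ndarray, labels: np.ndarray, gamma: float = 1.0) -> float:
    """Direct evaluation of weighted modularity for a labelling."""
    w = np.asarray(w, dtype=float)
    labels = np.asarray(labels)
    k = w.sum(axis=1)
    two_m = k.sum()
    if two_m <= 0:
        raise ValueError("total weight must be positive")
    q = 0.0
    for c in np.unique(labels):
        idx = labels == c
        q += w[np.ix_(idx, idx)].sum() - gamma * k[idx].sum() ** 2 / two_m
    return q / two_m


def _local_move(w: np.ndarray, gamma: float, rng: np.random.Generator) -> np.ndarray:
    """One Louvain level: greedy node moves until no gain.  ``w`` may carry
    self-loops (aggregated graphs); they are invariant under moves."""
    n = w.shape[0]
    k = w.sum(axis=1)
    two_m = k.sum()
    comm = np.arange(n)
    ctot = k.copy()
    moved = True
    while moved:
        moved = False
        for i in rng.permutation(n):
            ci = comm[i]
            row = w[i].copy()
            row[i] = 0.0  # self-loop moves with the node; drop from links
            links = np.bincount(comm, weights=row, minlength=n)
            ctot[ci] -= k[i]
            gains = links - gamma * k[i] * ctot / two_m
            best = int(np.argmax(gains))
            if gains[best] > gains[ci] + 1e-12:
                comm[i] = best
                ctot[best] += k[i]
                moved = True
            else:
                ctot[ci] += k[i]
    return comm


def _louvain_labels(
    w: np.ndarray, gamma: float, rng: np.random.Generator
) -> np.ndarray:
    n = w.shape[0]
    labels = np.arange(n)
    graph = w.copy()
    while True:
        comm = _local_move(graph, gamma, rng)
        uniq, compact = np.unique(comm, return_inverse=True)
        if len(uniq) == graph.shape[0]:
            break
        # aggregate: S[i, c] = 1 if node i in community c
        s = np.zeros((graph.shape[0], len(uniq)))
        s[np.arange(graph.shape[0]), compact] = 1.0
        graph = s.T @ graph @ s
        labels = compact[labels]
    _, labels = np.unique(labels, return_inverse=True)
    return labels


def louvain(
    w: np.ndarray,
    gamma: float = 1.0,
    rng: np.random.Generator | int | None = None,
) -> tuple[Partition, float]:
    """Run Louvain once; returns the partition and its directly evaluated Q."""
    w = _check_weights(w)
    if w.sum() <= 0:
        raise ValueError("total weight must be positive")
    rng = np.random.default_rng(rng)
    labels = _louvain_labels(w, gamma, rng)
    q = modularity(w, labels, gamma)
    return Partition(labels=labels), q


def agreement(partitions: list[Partition | np.ndarray]) -> AgreementMatrix:
    """Co-assignment frequency matrix across runs."""
    if not partitions:
        raise ValueError("agreement of an empty partition list")
    mats = []
    n = None
    for p in partitions:
        labels = p.labels if isinstance(p, Partition) else np.asarray(p)
        if n is None:
            n = len(labels)
        elif len(labels) != n:
            raise FormatError("partitions cover different node sets")
        mats.append(labels[:, None] == labels[None, :])
    d = np.mean(mats, axis=0)
    np.fill_diagonal(d, 1.0)
    return AgreementMatrix(d=d, n_runs=len(partitions))


def _canonical(labels: np.ndarray) -> tuple:
    """Relabel by first occurrence so label permutations compare equal."""
    _, inv = np.unique(labels, return_inverse=True)
    order = {}
    out = np.empty_like(inv)
    for i, v in enumerate(inv):
        if v not in order:
            order[v] = len(order)
        out[i] = order[v]
    return tuple(out.tolist())


def consensus_partition(
    d: AgreementMatrix,
    cfg: LouvainConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> Partition:
    """Iteratively re-cluster the agreement matrix until all runs agree.

    At each iteration the agreement matrix is thresholded at ``cfg.tau``
    (entries <= tau dropped), Louvain is run ``cfg.n_runs_consensus`` times,
    and a new agreement matrix is built from the runs; the loop ends when
    every run returns the identical partition.
    """
    cfg = cfg or LouvainConfig()
    rng = np.random.default_rng(rng if rng is not None else cfg.seed)
    current = d
    dispersion = np.nan
    for _ in range(cfg.max_consensus_iter):
        w = np.where(current.d > cfg.tau, current.d, 0.0)
        np.fill_diagonal(w, 0.0)
        if w.sum() == 0:
            # no pair ever co-assigned above tau: stable all-singletons state
            return Partition(labels=np.arange(current.d.shape[0]))
        runs = [
            _louvain_labels(w, cfg.gamma, rng)
            for _ in range(cfg.n_runs_consensus)
        ]
        canon = {_canonical(r) for r in runs}
        if len(canon) == 1:
            return Partition(labels=np.array(canon.pop()))
        current = agreement(runs)
        off = current.d[~np.eye(current.d.shape[0], dtype=bool)]
        dispersion = float(np.mean((off > 0) & (off < 1)))
    raise ConsensusError(
        f"consensus did not converge in {cfg.max_consensus_iter} iterations "
        f"(agreement dispersion {dispersion:.3f})",
        dispersion,
    )


def subject_agreement(
    w_hemi: np.ndarray,
    cfg: LouvainConfig,
    rng: np.random.Generator,
) -> AgreementMatrix:
    """Agreement matrix from ``cfg.n_runs_subject`` Louvain runs."""
    runs = [
        _louvain_labels(w_hemi, cfg.gamma, rng)
        for _ in range(cfg.n_runs_subject)
    ]
    return agreement(runs)


def group_symmetric_partition(
    matrices: list[np.ndarray],
    cfg: LouvainConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> Partition:
    """Mirror-symmetric group partition from per-subject thresholded matrices.

    Each matrix covers both hemispheres in canonical order (L block then R
    block, homotopic pairs aligned).  Per subject and hemisphere, repeated
    Louvain runs build an agreement matrix; subject agreements are averaged
    per hemisphere across the cohort, the two hemispheric group matrices
    are summed and halved (pair-aligned), and consensus clustering of the
    fused matrix yields one labelling per homotopic pair, copied to both
    hemispheres.
    """
    if not matrices:
        raise ValueError("empty cohort")
    cfg = cfg or LouvainConfig()
    rng = np.random.default_rng(rng if rng is not None else cfg.seed)
    n = matrices[0].shape[0]
    if n % 2:
        raise FormatError("canonical matrix must have an even node count")
    half = n // 2
    sums = {"L": np.zeros((half, half)), "R": np.zeros((half, half))}
    for w in matrices:
        if w.shape != (n, n):
            raise FormatError("matrices differ in size")
        _check_weights(w)
        for hemi, block in (("L", w[:half, :half]), ("R", w[half:, half:])):
            sums[hemi] += subject_agreement(block, cfg, rng).d
    d_l = sums["L"] / len(matrices)
    d_r = sums["R"] / len(matrices)
    fused = (d_l + d_r) / 2.0
    np.fill_diagonal(fused, 1.0)
    pair_part = consensus_partition(
        AgreementMatrix(d=fused, n_runs=2 * len(matrices) * cfg.n_runs_subject),
        cfg,
        rng,
    )
    labels = np.concatenate([pair_part.labels, pair_part.labels])
    return Partition(labels=labels, symmetric=True)


def count_communities(p: Partition) -> int:
    return int(len(np.unique(p.labels)))


def match_labels(ref: np.ndarray, other: np.ndarray) -> dict[int, int]:
    """Greedy maximum-Jaccard matching of ``other``'s labels onto ``ref``'s.

    Ties broken toward lower labels; unmatched communities in ``other``
    receive fresh labels above both label ranges.
    """
    ref = np.asarray(ref)
    other = np.asarray(other)
    if ref.shape != other.shape:
        raise FormatError("partitions cover different node sets")
    ref_labels = np.unique(ref)
    oth_labels = np.unique(other)
    scores = []
    for a in ref_labels:
        ia = ref == a
        for b in oth_labels:
            ib = other == b
            jac = np.logical_and(ia, ib).sum() / np.logical_or(ia, ib).sum()
            scores.append((jac, int(a), int(b)))
    # sort: highest Jaccard first, then lower ref label, then lower other label
    scores.sort(key=lambda t: (-t[0], t[1], t[2]))
    mapping: dict[int, int] = {}
    used_ref: set[int] = set()
    for jac, a, b in scores:
        if jac <= 0 or b in mapping or a in used_ref:
            continue
        mapping[b] = a
        used_ref.add(a)
    fresh = int(max(ref_labels.max(), oth_labels.max())) + 1
    for b in oth_labels:
        if int(b) not in mapping:
            mapping[int(b)] = fresh
            fresh += 1
    return mapping


def community_flow(
    partitions_by_group: list[Partition],
    group_labels: list[str],
    network_names: dict[int, str] | None = None,
) -> CommunityFlow:
    """Contingency tables of node movement between consecutive age groups.

    Each partition must be symmetric over the same canonical node set; the
    per-hemisphere half-labelling is compared between consecutive groups
    after greedy Jaccard label matching (labels are chained: group g+1 is
    matched to the already-matched labels of group g).
    """
    if len(partitions_by_group) != len(group_labels):
        raise FormatError("one partition per group label required")
    if len(partitions_by_group) < 2:
        raise ConfigurationError("need at least two groups for a flow")
    n = partitions_by_group[0].n_nodes
    for p in partitions_by_group:
        if p.n_nodes != n:
            raise FormatError("partitions cover different node sets")
    half = n // 2
    tables: dict = {}
    counts: dict = {}
    for hemi, sl in (("L", slice(0, half)), ("R", slice(half, n))):
        chain = [np.asarray(partitions_by_group[0].labels[sl])]
        for p in partitions_by_group[1:]:
            cur = np.asarray(p.labels[sl])
            mapping = match_labels(chain[-1], cur)
            chain.append(np.array([mapping[int(c)] for c in cur]))
        for g, labels in zip(group_labels, chain):
            counts[(hemi, g)] = int(len(np.unique(labels)))
        for i in range(len(chain) - 1):
            a, b = chain[i], chain[i + 1]
            tab = pd.crosstab(
                pd.Series(a, name=f"from_{group_labels[i]}"),
                pd.Series(b, name=f"to_{group_labels[i + 1]}"),
            )
            if network_names:
                tab.index = [network_names.get(int(c), str(c)) for c in tab.index]
                tab.columns = [network_names.get(int(c), str(c)) for c in tab.columns]
                tab.index.name = f"from_{group_labels[i]}"
                tab.columns.name = f"to_{group_labels[i + 1]}"
            tables[(hemi, i)] = tab
    return CommunityFlow(
        group_labels=tuple(group_labels), tables=tables, n_communities=counts
    )
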