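"""Hemispheric network statistics.

Three statistics per (network, hemisphere):

* segregation   = (sum_z_within - sum_z_homotopic) / sum_z_within, with
  sum_z_within the summed z of a network's nodes to all same-hemisphere
  nodes (within-network unordered pairs counted once by default) and
  sum_z_homotopic the summed z of the network's nodes to the same
  network's nodes in the opposite hemisphere;
* inter-hemispheric integration = sum_z_homotopic itself;
* intra-hemispheric integration = mean weighted participation coefficient
  of the network's nodes on the thresholded within-hemisphere subgraph.

Sums use the unthresholded signed z matrix by default; participation
coefficients use the thresholded non-negative matrix.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io_core import ConnectivityMatrix, FormatError, Partition

__all__ = [
    "within_hemisphere_sum",
    "homotopic_sum",
    "whole_contralateral_sum",
    "hemispheric_segregation",
    "participation_coefficients",
    "intra_hemispheric_integration",
    "metrics_table",
]


def _masks(labels: np.ndarray, network: int, hemi: str):
    n = len(labels)
    if n % 2:
        raise FormatError("canonical node set must have an even size")
    half = n // 2
    hemi_mask = np.zeros(n, dtype=bool)
    if hemi == "L":
        hemi_mask[:half] = True
    elif hemi == "R":
        hemi_mask[half:] = True
    else:
        raise FormatError(f"hemisphere must be L or R, got {hemi!r}")
    net_mask = (np.asarray(labels) == network) & hemi_mask
    if not net_mask.any():
        raise ValueError(f"network {network} empty in hemisphere {hemi}")
    return net_mask, hemi_mask


def within_hemisphere_sum(
    z: np.ndarray,
    labels: np.ndarray,
    network: int,
    hemi: str,
    double_count_within: bool = False,
) -> float:
    """Summed z from a network's nodes to all nodes of its own hemisphere.

    Network-to-outside pairs are counted once; pairs inside the network are
    counted once by default (``double_count_within`` switches convention —
    the segregation ratio is invariant to a global doubling).
    """
    z = np.asarray(z, dtype=float)
    net, hemi_mask = _masks(labels, network, hemi)
    total = z[np.ix_(net, hemi_mask)].sum()  # inner pairs twice, outer once
    if not double_count_within:
        total -= z[np.ix_(net, net)].sum() / 2.0
    return float(total)


def homotopic_sum(
    z: np.ndarray, labels: np.ndarray, network: int, hemi: str
) -> float:
    """Summed z between a network and the same network contralaterally."""
    z = np.asarray(z, dtype=float)
    net, hemi_mask = _masks(labels, network, hemi)
    opp = ~hemi_mask
    contra = (np.asarray(labels) == network) & opp
    return float(z[np.ix_(net, contra)].sum())


def whole_contralateral_sum(
    z: np.ndarray, labels: np.ndarray, network: int, hemi: str
) -> float:
    """Summed z between a network and every contralateral node."""
    z = np.asarray(z, dtype=float)
    net, hemi_mask = _masks(labels, network, hemi)
    return float(z[np.ix_(net, ~hemi_mask)].sum())


def hemispheric_segregation(sum_z_within: float, sum_z_homotopic: float) -> float:
    """(sum_z_within - sum_z_homotopic) / sum_z_within; NaN if undefined."""
    if sum_z_within == 0:
        warnings.warn("sum_z_within is zero: segregation undefined, reporting NaN")
        return float("nan")
    return (sum_z_within - sum_z_homotopic) / sum_z_within


def participation_coefficients(
    w: np.ndarray, labels: np.ndarray, hemi: str
) -> np.ndarray:
    """Weighted participation coefficient per node of one hemisphere.

    Computed on the hemisphere-restricted subgraph of the (non-negative,
    thresholded) matrix: P_i = 1 - sum_s (kappa_is / k_i)^2.  Nodes with
    zero strength get P = 0.
    """
    w = np.asarray(w, dtype=float)
    labels = np.asarray(labels)
    n = len(labels)
    half = n // 2
    sl = slice(0, half) if hemi == "L" else slice(half, n)
    if hemi not in ("L", "R"):
        raise FormatError(f"hemisphere must be L or R, got {hemi!r}")
    sub = w[sl, sl]
    if (sub < 0).any():
        raise ValueError("participation requires a non-negative (thresholded) matrix")
    sub_labels = labels[sl]
    k = sub.sum(axis=1)
    communities = np.unique(sub_labels)
    kappa = np.stack([sub[:, sub_labels == c].sum(axis=1) for c in communities], axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = kappa / k[:, None]
    p = 1.0 - np.sum(frac**2, axis=1)
    p[k == 0] = 0.0
    return p


def intra_hemispheric_integration(
    pc: np.ndarray, labels_hemi: np.ndarray, network: int
) -> float:
    """Mean participation coefficient over a network's nodes in one hemisphere."""
    mask = np.asarray(labels_hemi) == network
    if not mask.any():
        raise ValueError(f"network {network} empty in this hemisphere")
    return float(np.mean(np.asarray(pc)[mask]))


def metrics_table(
    z_full: ConnectivityMatrix | np.ndarray,
    z_thresholded: ConnectivityMatrix | np.ndarray,
    partition: Partition,
    double_count_within: bool = False,
) -> pd.DataFrame:
    """One row of all five statistics per (network, hemisphere)."""
    z = z_full.z if isinstance(z_full, ConnectivityMatrix) else np.asarray(z_full)
    zt = (
        z_thresholded.z
        if isinstance(z_thresholded, ConnectivityMatrix)
        else np.asarray(z_thresholded)
    )
    labels = partition.labels
    if z.shape[0] != len(labels) or zt.shape[0] != len(labels):
        raise FormatError("matrix and partition sizes disagree")
    half = len(labels) // 2
    rows = []
    for hemi, sl in (("L", slice(0, half)), ("R", slice(half, len(labels)))):
        pc = participation_coefficients(zt, labels, hemi)
        for network in np.unique(labels):
            if not (labels[sl] == network).any():
                continue
            szll = within_hemisphere_sum(
                z, labels, network, hemi, double_count_within
            )
            szlr = homotopic_sum(z, labels, network, hemi)
            rows.append(
                {
                    "network": partition.name_of(int(network)),
                    "hemisphere": hemi,
                    "sum_z_within": szll,
                    "sum_z_homotopic": szlr,
                    "segregation": hemispheric_segregation(szll, szlr),
                    "inter_integration": szlr,
                    "intra_integration": intra_hemispheric_integration(
                        pc, labels[sl], network
                    ),
                    "whole_contra_integration": whole_contralateral_sum(
                        z, labels, network, hemi
                    ),
                }
            )
    return pd.DataFrame(rows)
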