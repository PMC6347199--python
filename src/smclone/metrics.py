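"""Permutation-matched error metrics for subclonal reconstructions.

A deconvolution of read counts into genotypes and proportions is only
identified up to relabeling of the subclones, so before comparing an
estimate against ground truth the estimated columns are matched to the true
columns by the permutation minimizing the mean absolute genotype deviation.
Because the total mismatch is a sum of independent column-pair costs, the
optimal permutation is a minimum-cost assignment and is found exactly with
the Hungarian algorithm rather than by enumerating all C! permutations.

Three errors are reported, all mean absolute deviations:

* ``e_Z``  -- genotypes, averaged over T * C entries;
* ``e_W``  -- proportions, summed over all C + 1 rows (noise row included)
  but divided by C * S;
* ``e_pts`` -- fitted success probabilities (expected VAFs), averaged over
  T * S entries; invariant to the column permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .observation import success_probability_matrix

__all__ = [
    "EvaluationReport",
    "match_columns",
    "genotype_error",
    "proportion_error",
    "pts_error",
    "evaluate_estimate",
]


@dataclass
class EvaluationReport:
    """Bundle of the three reconstruction errors and the matching used."""

    e_Z: float
    e_W: float
    e_pts: float
    permutation: list[int] = field(default_factory=list)
    columns_padded: bool = False

    def to_dict(self) -> dict:
        return {
            "e_Z": self.e_Z,
            "e_W": self.e_W,
            "e_pts": self.e_pts,
            "permutation": list(map(int, self.permutation)),
            "columns_padded": self.columns_padded,
        }


def _pad_columns(M: np.ndarray, width: int) -> np.ndarray:
    """Right-pad a T x c matrix with zero columns up to the given width."""
    d = width - M.shape[1]
    return np.pad(M, ((0, 0), (0, d))) if d > 0 else M


def _pad_rows(M: np.ndarray, height: int) -> np.ndarray:
    d = height - M.shape[0]
    return np.pad(M, ((0, d), (0, 0))) if d > 0 else M


def match_columns(Z_hat: np.ndarray, Z_true: np.ndarray) -> np.ndarray:
    """Permutation of estimated columns minimizing the genotype error.

    Returns ``perm`` such that column ``perm[j]`` of ``Z_hat`` is matched to
    column ``j`` of ``Z_true``; i.e. ``Z_hat[:, perm]`` is the relabeled
    estimate.  If the column counts differ, the narrower matrix is padded
    with zero columns first (callers can detect this from the shapes).
    """
    Z_hat = np.asarray(Z_hat, dtype=float)
    Z_true = np.asarray(Z_true, dtype=float)
    if Z_hat.size == 0 and Z_true.size == 0:
        raise ValueError("cannot match empty genotype matrices")
    if Z_hat.shape[0] != Z_true.shape[0]:
        raise ValueError("matrices must have the same number of loci")
    width = max(Z_hat.shape[1], Z_true.shape[1])
    Z_hat = _pad_columns(Z_hat, width)
    Z_true = _pad_columns(Z_true, width)
    # cost[i, j] = mean |Z_hat[:, i] - Z_true[:, j]|
    cost = np.mean(np.abs(Z_hat[:, :, None] - Z_true[:, None, :]), axis=0)
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(width, dtype=int)
    perm[cols] = rows
    return perm


def genotype_error(
    Z_hat: np.ndarray, Z_true: np.ndarray, permutation: np.ndarray
) -> float:
    """Mean absolute genotype deviation after relabeling: e_Z."""
    Z_hat = np.asarray(Z_hat, dtype=float)
    Z_true = np.asarray(Z_true, dtype=float)
    width = len(permutation)
    Z_hat = _pad_columns(Z_hat, width)
    Z_true = _pad_columns(Z_true, width)
    return float(np.mean(np.abs(Z_hat[:, permutation] - Z_true)))


def proportion_error(
    W_hat: np.ndarray, W_true: np.ndarray, permutation: np.ndarray
) -> float:
    """Proportion error e_W: sum over all C+1 rows, divided by C * S.

    Row 0 (the noise weight) is compared directly; subclone rows of the
    estimate are reordered by the genotype-matching permutation.  The
    divisor is C * S even though C + 1 rows enter the sum, matching the
    printed definition of the metric.
    """
    W_hat = np.asarray(W_hat, dtype=float)
    W_true = np.asarray(W_true, dtype=float)
    n_rows = len(permutation) + 1
    W_hat = _pad_rows(W_hat, n_rows)
    W_true = _pad_rows(W_true, n_rows)
    if W_hat.shape[1] != W_true.shape[1]:
        raise ValueError("proportion matrices must have the same sample count")
    C = n_rows - 1
    S = W_true.shape[1]
    reordered = np.vstack([W_hat[0:1], W_hat[1:][permutation]])
    return float(np.sum(np.abs(reordered - W_true)) / (C * S))


def pts_error(
    Z_hat: np.ndarray,
    W_hat: np.ndarray,
    p_hat: float,
    P_true: np.ndarray,
    permutation: np.ndarray | None = None,
) -> float:
    """Mean absolute deviation of fitted success probabilities: e_pts.

    The fitted matrix is rebuilt from the estimates as
    p_hat * w_0s + sum_c z_tc w_cs; applying the same column permutation to
    Z_hat and W_hat leaves it unchanged, so ``permutation`` is accepted only
    for interface symmetry.
    """
    del permutation  # p_hat_ts is invariant to a consistent relabeling
    P_hat = success_probability_matrix(Z_hat, W_hat, p_hat)
    P_true = np.asarray(P_true, dtype=float)
    if P_hat.shape != P_true.shape:
        raise ValueError("fitted and true probability matrices differ in shape")
    return float(np.mean(np.abs(P_hat - P_true)))


def evaluate_estimate(
    Z_hat: np.ndarray,
    W_hat: np.ndarray,
    p_hat: float,
    Z_true: np.ndarray,
    W_true: np.ndarray,
    P_true: np.ndarray,
    binary_mode: bool = False,
) -> EvaluationReport:
    """Full evaluation of an estimate against ground truth.

    In ``binary_mode`` (truth generated over {0, 0.5} only) any homozygous
    call in the estimated genotypes is mapped to 0.5 before the errors are
    computed, so methods differing only in that distinction are compared on
    the presence/absence of the mutation.
    """
    Z_hat = np.asarray(Z_hat, dtype=float)
    if binary_mode:
        Z_hat = np.where(Z_hat == 1.0, 0.5, Z_hat)
    padded = Z_hat.shape[1] != np.asarray(Z_true).shape[1]
    perm = match_columns(Z_hat, Z_true)
    return EvaluationReport(
        e_Z=genotype_error(Z_hat, Z_true, perm),
        e_W=proportion_error(W_hat, W_true, perm),
        e_pts=pts_error(Z_hat, W_hat, p_hat, P_true),
        permutation=list(map(int, perm)),
        columns_padded=bool(padded),
    )
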