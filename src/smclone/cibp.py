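"""Categorical Indian buffet process (cIBP) prior over ternary genotype matrices.

The prior builds a loci-by-subclones matrix row by row.  Each entry takes one
of three genotype levels: 0 (homozygous wild-type), 0.5 (heterozygous mutant)
or 1 (homozygous mutant).  Row 1 opens a Poisson(alpha) number of columns;
every later row t first revisits each existing column -- reusing it with
probability m_c / t, where m_c counts the previous non-zero entries in that
column, and splitting the reuse mass between 0.5 and 1 according to the
category pseudo-counts -- and then opens Poisson(alpha / t) fresh columns.
Columns are never deleted once created, so after T rows the expected number
of columns is alpha * H_T (the T-th harmonic number).

This three-category process is the state-transition kernel of the subclone
model: rows are mutation loci processed sequentially, columns are subclones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GENOTYPE_LEVELS",
    "CIBPParams",
    "category_probs",
    "sample_first_row",
    "sample_next_row",
    "sample_genotype_matrix",
    "column_category_counts",
]

#: The three allelic genotype levels, in increasing order.
GENOTYPE_LEVELS = (0.0, 0.5, 1.0)


@dataclass(frozen=True)
class CIBPParams:
    """Hyperparameters of the three-category Indian buffet process.

    Parameters
    ----------
    alpha
        Expected number of new subclone columns opened by the first locus;
        later loci open new columns at rate ``alpha / t``.  Must be positive.
    beta
        Category pseudo-count controlling the split between heterozygous
        (0.5) and homozygous (1) reuse of an existing column.  Must be
        positive.  The total pseudo-count ``beta_star`` is ``2 * beta`` (one
        ``beta`` per non-zero category), so a fresh column is heterozygous or
        homozygous with probability 1/2 each.
    """

    alpha: float = 1.0
    beta: float = 0.5

    def __post_init__(self) -> None:
        if not (self.alpha > 0):
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if not (self.beta > 0):
            raise ValueError(f"beta must be > 0, got {self.beta}")

    @property
    def beta_star(self) -> float:
        """Total pseudo-count over the two non-zero categories (always 2*beta)."""
        return 2.0 * self.beta


def category_probs(
    m_c1: int | np.ndarray,
    m_c2: int | np.ndarray,
    t: int,
    params: CIBPParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray] | tuple[float, float, float]:
    """Genotype-category probabilities for an existing column at row ``t``.

    ``m_c1`` and ``m_c2`` count the previous heterozygous (0.5) and
    homozygous (1) entries in the column.  With ``m_c = m_c1 + m_c2`` the
    column is skipped (entry 0) with probability ``1 - m_c / t``; otherwise
    the reuse mass ``m_c / t`` splits as ``(beta + m_c1) / (beta* + m_c)``
    for 0.5 and ``(beta + m_c2) / (beta* + m_c)`` for 1.  The triple always
    sums to one exactly because ``(beta + m_c1) + (beta + m_c2) =
    beta* + m_c``.

    Accepts scalars or aligned integer arrays; returns the same shape.
    """
    m1 = np.asarray(m_c1)
    m2 = np.asarray(m_c2)
    if t <= 0:
        raise ValueError(f"row index t must be positive, got {t}")
    if np.any(m1 < 0) or np.any(m2 < 0):
        raise ValueError("category counts must be nonnegative")
    m = m1 + m2
    if np.any(m < 1):
        raise ValueError("column must be non-zero: m_c1 + m_c2 >= 1")
    reuse = m / t
    denom = params.beta_star + m
    p0 = 1.0 - reuse
    p05 = reuse * (params.beta + m1) / denom
    p1 = reuse * (params.beta + m2) / denom
    if np.isscalar(m_c1) and np.isscalar(m_c2):
        return float(p0), float(p05), float(p1)
    return p0, p05, p1


def _sample_new_columns(k: int, rng: np.random.Generator) -> np.ndarray:
    """Entries for k freshly opened columns: 0.5 or 1, probability 1/2 each."""
    return np.where(rng.random(k) < 0.5, 0.5, 1.0)


def sample_first_row(params: CIBPParams, rng: np.random.Generator) -> np.ndarray:
    """Sample the first row: Poisson(alpha) new columns, each 0.5 or 1."""
    k = int(rng.poisson(params.alpha))
    return _sample_new_columns(k, rng)


def column_category_counts(Z_prev: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column counts of heterozygous (0.5) and homozygous (1) entries."""
    Z_prev = np.asarray(Z_prev, dtype=float)
    m1 = np.count_nonzero(Z_prev == 0.5, axis=0)
    m2 = np.count_nonzero(Z_prev == 1.0, axis=0)
    return m1, m2


def sample_next_row(
    Z_prev: np.ndarray,
    t: int,
    params: CIBPParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample row ``t`` given the previous ``t - 1`` rows.

    ``Z_prev`` is the (t-1) x C matrix of rows sampled so far; it is never
    modified.  The returned row has length C plus the Poisson(alpha / t)
    number of freshly opened columns.
    """
    Z_prev = np.asarray(Z_prev, dtype=float)
    if Z_prev.ndim != 2:
        raise ValueError("Z_prev must be a 2-D matrix of previous rows")
    if t != Z_prev.shape[0] + 1:
        raise ValueError(
            f"row index t={t} inconsistent with {Z_prev.shape[0]} previous rows"
        )
    m1, m2 = column_category_counts(Z_prev)
    return _sample_row_from_counts(m1, m2, t, params, rng)


def _sample_row_from_counts(
    m1: np.ndarray,
    m2: np.ndarray,
    t: int,
    params: CIBPParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Row-t draw given cached per-column category counts (hot path)."""
    n_cols = m1.shape[0]
    if n_cols:
        p0, p05, _ = category_probs(m1, m2, t, params)
        u = rng.random(n_cols)
        existing = np.where(u < p0, 0.0, np.where(u < p0 + p05, 0.5, 1.0))
    else:
        existing = np.empty(0)
    k = int(rng.poisson(params.alpha / t))
    if k == 0:
        return existing
    return np.concatenate([existing, _sample_new_columns(k, rng)])


def sample_genotype_matrix(
    T: int, params: CIBPParams, rng: np.random.Generator
) -> np.ndarray:
    """Sample a full T-row genotype matrix from the prior.

    Earlier rows are zero-padded as later rows open new columns, so the
    result is a T x C ternary matrix with C the total number of columns
    opened over the T rows.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    Z = sample_first_row(params, rng).reshape(1, -1)
    for t in range(2, T + 1):
        row = sample_next_row(Z, t, params, rng)
        d = row.shape[0] - Z.shape[1]
        if d:
            Z = np.pad(Z, ((0, 0), (0, d)))
        Z = np.vstack([Z, row])
    return Z
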