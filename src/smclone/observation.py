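"""Binomial observation model for variant read counts.

At locus t in sample s the variant count is y_ts ~ Binomial(v_ts, p_ts) with
success probability

    p_ts = w_0s * p + sum_c z_tc * w_cs,

i.e. the expected variant allele frequency is the genotype of each subclone
weighted by its cellular proportion, plus a background term in which p is the
sequencing/processing error rate and w_0s absorbs signal not explained by the
subclones.  Stacking loci, P = [p Z] . W -- a matrix factorization of the
expected VAF matrix.

All likelihood arithmetic is done in log space; binomial coefficients come
from log-gamma.  Success probabilities are clipped to [PROB_FLOOR,
1 - PROB_FLOOR] before the pmf is evaluated so that a structurally impossible
read (p_ts = 0 with y_ts > 0) yields a very small, finite log-likelihood
instead of -inf, which would break importance weighting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

__all__ = [
    "PROB_FLOOR",
    "ReadCountData",
    "success_probability",
    "success_probability_matrix",
    "log_binom_coeff",
    "loglik_row",
]

#: Clip bound keeping binomial success probabilities inside the open (0, 1).
PROB_FLOOR = 1e-12


@dataclass
class ReadCountData:
    """Paired T x S integer matrices of variant (Y) and total (V) read counts.

    Rows are mutation loci, columns are tumor samples.  Row order defines the
    order in which loci are processed by the sequential sampler.
    """

    Y: np.ndarray
    V: np.ndarray
    locus_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=np.int64)
        self.V = np.asarray(self.V, dtype=np.int64)
        if self.Y.ndim != 2 or self.V.ndim != 2:
            raise ValueError("Y and V must be 2-D matrices")
        if self.Y.shape != self.V.shape:
            raise ValueError(
                f"Y and V shapes differ: {self.Y.shape} vs {self.V.shape}"
            )
        if not self.locus_ids:
            self.locus_ids = [f"locus_{t + 1:04d}" for t in range(self.Y.shape[0])]
        if not self.sample_ids:
            self.sample_ids = [f"sample_{s + 1:02d}" for s in range(self.Y.shape[1])]
        if len(self.locus_ids) != self.Y.shape[0]:
            raise ValueError("locus_ids length does not match row count")
        if len(self.sample_ids) != self.Y.shape[1]:
            raise ValueError("sample_ids length does not match column count")
        if np.any(self.Y < 0) or np.any(self.V < 0):
            raise ValueError("read counts must be nonnegative")
        bad = np.argwhere(self.Y > self.V)
        if bad.size:
            t, s = bad[0]
            raise ValueError(
                f"variant count exceeds total count at locus "
                f"{self.locus_ids[t]!r}, sample {self.sample_ids[s]!r}"
            )

    @property
    def n_loci(self) -> int:
        return self.Y.shape[0]

    @property
    def n_samples(self) -> int:
        return self.Y.shape[1]


def success_probability(
    z_row: np.ndarray, w_col: np.ndarray, p: float
) -> float | np.ndarray:
    """Expected VAF p_ts = w_0 * p + sum_c z_c * w_c for one locus.

    ``z_row`` holds the C ternary genotypes of the locus; ``w_col`` is the
    (C+1)-vector of proportions for one sample (noise weight first) or a
    (C+1) x S matrix, in which case an S-vector is returned.  The result is
    guaranteed to lie in [0, 1] because genotypes are at most 1 and each
    proportion column sums to one.
    """
    z_row = np.asarray(z_row, dtype=float)
    w_col = np.asarray(w_col, dtype=float)
    if w_col.shape[0] != z_row.shape[0] + 1:
        raise ValueError(
            f"proportion vector has {w_col.shape[0]} rows; expected "
            f"{z_row.shape[0] + 1} (noise row + one per subclone)"
        )
    out = w_col[0] * p + z_row @ w_col[1:]
    if out.ndim == 0:
        return float(out)
    return out


def success_probability_matrix(Z: np.ndarray, W: np.ndarray, p: float) -> np.ndarray:
    """Full T x S expected-VAF matrix P = [p Z] . W."""
    Z = np.asarray(Z, dtype=float)
    W = np.asarray(W, dtype=float)
    if W.shape[0] != Z.shape[1] + 1:
        raise ValueError("W must have one more row than Z has columns")
    return p * W[0][None, :] + Z @ W[1:]


def log_binom_coeff(y: np.ndarray, v: np.ndarray) -> np.ndarray:
    """log C(v, y) via log-gamma; depends only on the observed counts."""
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    return gammaln(v + 1.0) - gammaln(y + 1.0) - gammaln(v - y + 1.0)


def loglik_row(
    y_row: np.ndarray,
    v_row: np.ndarray,
    z_row: np.ndarray,
    W: np.ndarray,
    p: float,
    log_coeff: np.ndarray | None = None,
) -> float:
    """Log-likelihood of one locus: sum_s log Binomial(y_s | v_s, p_s).

    ``log_coeff`` optionally supplies the precomputed log binomial
    coefficients for this locus (they do not depend on the model state, so
    callers evaluating many parameter hypotheses against the same row should
    compute them once with :func:`log_binom_coeff`).
    """
    y = np.asarray(y_row, dtype=float)
    v = np.asarray(v_row, dtype=float)
    if y.shape != v.shape:
        raise ValueError("y and v rows must have equal length")
    if np.any(y < 0) or np.any(y > v):
        raise ValueError("require 0 <= y <= v elementwise")
    pts = np.asarray(success_probability(z_row, W, p), dtype=float)
    pts = np.clip(pts, PROB_FLOOR, 1.0 - PROB_FLOOR)
    if log_coeff is None:
        log_coeff = log_binom_coeff(y, v)
    return float(np.sum(log_coeff + y * np.log(pts) + (v - y) * np.log1p(-pts)))
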