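"""Particle filter for joint inference of subclone number, genotypes and
proportions.

The genotype matrix is built one locus (row) at a time: the hidden state at
step t is the t-th ternary row, drawn from the categorical Indian buffet
process given the rows already in place, while the proportion parameters and
the error rate evolve by small random-walk steps (artificial dynamics that
let static parameters be tracked by the filter).  Proportions are
parameterized by positive, unnormalized weights theta whose columnwise
normalization w_cs = theta_cs / sum_c' theta_c's keeps every proportion
column on the simplex even as subclone columns appear.

Two importance distributions are provided:

``proposal="prior"``
    The plain bootstrap filter: states are proposed from the prior
    transition kernel and the weight update is the binomial likelihood of
    the new row.  Faithful to the simplest reading of the algorithm, but
    with read depths around 100 the likelihood is so peaked that prior
    proposals collapse the ensemble (effective sample size near 1) and the
    static proportions never converge.

``proposal="guided"`` (default)
    A marginalized (locally optimal) proposal evaluated in K tempered
    substeps per row.  For the existing columns the ternary row is
    enumerated exactly; theta is integrated over a mixture of the
    random-walk kernel and occasional fresh prior refits, with exact
    importance-ratio correction; the column-opening decision is a branch
    whose new-column theta integral factorizes over samples and is computed
    by per-sample Monte Carlo, so opening pays its honest Occam factor.
    The incremental weight is the resulting predictive estimate.  This is
    the package's own design for the importance distribution; the model
    being targeted (cIBP prior, random-walk dynamics, binomial likelihood)
    is identical in both modes.

After the last locus the particles hold genotype matrices with varying
column counts.  The posterior over the number of subclones C is the
weighted frequency of those counts; all other estimates condition on its
mode: the MAP-count particles are relabeled onto a common column order
(minimum-L1 assignment against the highest-weight particle, the same
matcher used by the evaluation metrics), genotypes are summarized by the
weighted elementwise mode and proportions by the weighted mean.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import gammaln, log_ndtr, logsumexp

from . import cibp
from .cibp import CIBPParams
from .observation import (
    PROB_FLOOR,
    ReadCountData,
    log_binom_coeff,
    success_probability_matrix,
)
from .metrics import match_columns

__all__ = [
    "Particle",
    "SMCConfig",
    "PosteriorSummary",
    "DegenerateWeightsError",
    "init_particles",
    "propagate",
    "weight_update",
    "normalize_log_weights",
    "resample",
    "run",
    "summarize",
]

logger = logging.getLogger(__name__)


def _lse(a: np.ndarray, axis: int | None = None, keepdims: bool = False):
    """Lean log-sum-exp (scipy's carries heavy array-API overhead per call)."""
    amax = np.max(a, axis=axis, keepdims=True)
    amax = np.where(np.isfinite(amax), amax, 0.0)
    out = np.log(np.sum(np.exp(a - amax), axis=axis, keepdims=True)) + amax
    if keepdims:
        return out
    out = np.squeeze(out, axis=axis) if axis is not None else out.reshape(())
    return out if axis is not None else float(out)

_LOG_HALF = math.log(0.5)


class DegenerateWeightsError(RuntimeError):
    """All particle weights underflowed to zero (likelihood collapse)."""


@dataclass
class Particle:
    """One weighted hypothesis of the particle filter.

    ``Z`` holds the genotype rows processed so far (t x C); ``theta`` the
    positive unnormalized proportions ((C+1) x S, noise row first); ``p``
    the background error rate.  ``m1``/``m2`` cache the per-column counts of
    0.5 and 1 entries so the prior kernel does not rescan ``Z`` each step.
    """

    Z: np.ndarray
    theta: np.ndarray
    p: float
    log_weight: float
    m1: np.ndarray = field(default=None)  # type: ignore[assignment]
    m2: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.m1 is None or self.m2 is None:
            self.m1, self.m2 = cibp.column_category_counts(self.Z)

    @property
    def n_columns(self) -> int:
        return self.Z.shape[1]

    @property
    def W(self) -> np.ndarray:
        """Implied proportion matrix: columnwise normalization of theta."""
        return self.theta / self.theta.sum(axis=0, keepdims=True)

    def copy(self) -> "Particle":
        return Particle(
            Z=self.Z.copy(),
            theta=self.theta.copy(),
            p=self.p,
            log_weight=self.log_weight,
            m1=self.m1.copy(),
            m2=self.m2.copy(),
        )


@dataclass(frozen=True)
class SMCConfig:
    """Particle-filter settings and prior hyperparameters.

    Random-walk standard deviations ``sigma_theta`` / ``sigma_p`` control how
    fast the static parameters can drift; the gamma shapes ``a0`` (noise row)
    and ``a1`` (subclone rows) set the prior scale of the unnormalized
    proportions; ``a00``/``b00`` are the beta shapes of the error-rate prior
    (defaults give mean 1/31, small as a sequencing error rate should be).

    Guided-proposal knobs: ``n_substeps`` tempered refinement passes per row,
    ``n_draws`` Monte-Carlo draws for the marginalized theta integrals,
    ``refresh_prob`` probability that a theta entry is re-proposed from its
    prior instead of the walk kernel, ``sigma0`` initial exploration scale
    (decaying as 1/sqrt(row)), ``max_columns`` enumeration guard on the
    number of subclone columns.
    """

    n_particles: int = 1000
    sigma_theta: float = 0.01
    sigma_p: float = 0.003
    a0: float = 0.1
    a1: float = 1.0
    a00: float = 1.0
    b00: float = 30.0
    cibp: CIBPParams = field(default_factory=CIBPParams)
    seed: int = 0
    resampling: str = "multinomial"
    proposal: str = "guided"
    n_substeps: int = 5
    n_draws: int = 12
    refresh_prob: float = 0.25
    sigma0: float = 0.5
    max_columns: int = 9
    enum_top: int = 32

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("need at least 2 particles")
        for name in ("a0", "a1", "a00", "b00"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sigma_theta < 0 or self.sigma_p < 0:
            raise ValueError("random-walk standard deviations must be >= 0")
        if self.resampling not in ("multinomial", "systematic"):
            raise ValueError(f"unknown resampling scheme {self.resampling!r}")
        if self.proposal not in ("guided", "prior"):
            raise ValueError(f"unknown proposal {self.proposal!r}")
        if self.n_substeps < 1 or self.n_draws < 2:
            raise ValueError("n_substeps >= 1 and n_draws >= 2 required")
        if not (0 <= self.refresh_prob < 1):
            raise ValueError("refresh_prob must lie in [0, 1)")


@dataclass
class PosteriorSummary:
    """Posterior estimates conditioned on the MAP number of subclones."""

    c_pmf: dict[int, float]
    c_map: int
    Z_hat: np.ndarray
    W_hat: np.ndarray
    p_hat: float
    P_hat: np.ndarray
    ess_trace: list[float] = field(default_factory=list)


def init_particles(
    config: SMCConfig, n_samples: int, rng: np.random.Generator
) -> list[Particle]:
    """Draw the initial ensemble from the priors.

    Each particle starts with no genotype rows, a single theta row of
    Gamma(a0, 1) noise weights, p ~ Beta(a00, b00) and uniform weight 1/N.
    """
    particles = []
    log_w = -math.log(config.n_particles)
    for _ in range(config.n_particles):
        theta0 = rng.gamma(config.a0, 1.0, size=(1, n_samples))
        theta0 = np.maximum(theta0, PROB_FLOOR)  # gamma can underflow to 0.0
        p = float(rng.beta(config.a00, config.b00))
        particles.append(
            Particle(Z=np.empty((0, 0)), theta=theta0, p=p, log_weight=log_w)
        )
    return particles


def _walk_positive(
    x: np.ndarray, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian random-walk step truncated to stay strictly positive.

    Proposals <= 0 are redrawn entrywise (rejection sampling, equivalent to
    a truncated-normal step), preserving the Gaussian form of the dynamics
    while keeping the unnormalized proportions valid.
    """
    if sigma == 0:
        return x.copy()
    out = x + rng.normal(0.0, sigma, size=x.shape)
    bad = out <= 0
    while bad.any():
        out[bad] = x[bad] + rng.normal(0.0, sigma, size=int(bad.sum()))
        bad = out <= 0
    return out


def _walk_reflected(x: float, sigma: float, rng: np.random.Generator) -> float:
    """Gaussian random-walk step reflected at the boundaries of (0, 1)."""
    if sigma == 0:
        return x
    y = x + float(rng.normal(0.0, sigma))
    # fold back into [0, 1]; sigma << 1 so one or two reflections suffice
    while y < 0.0 or y > 1.0:
        if y < 0.0:
            y = -y
        if y > 1.0:
            y = 2.0 - y
    return min(max(y, PROB_FLOOR), 1.0 - PROB_FLOOR)


def propagate(
    particle: Particle, t: int, config: SMCConfig, rng: np.random.Generator
) -> Particle:
    """Advance one particle to locus ``t`` with the prior transition kernel.

    The new row is drawn from the buffet-process kernel given the particle's
    current rows.  If d new columns appear, the earlier rows are padded with
    d zero columns and d fresh theta rows are drawn from Gamma(a1, 1).
    Every pre-existing theta entry and p then take one random-walk step.
    Returns a new particle; the input is not modified.
    """
    if t != particle.Z.shape[0] + 1:
        raise ValueError(
            f"propagate called with t={t} but particle has "
            f"{particle.Z.shape[0]} rows"
        )
    if t == 1:
        row = cibp.sample_first_row(config.cibp, rng)
    else:
        row = cibp._sample_row_from_counts(
            particle.m1, particle.m2, t, config.cibp, rng
        )
    d = row.shape[0] - particle.n_columns
    Z = particle.Z
    if d:
        Z = np.pad(Z, ((0, 0), (0, d)))
    Z = np.vstack([Z, row[None, :]])

    m1 = np.concatenate([particle.m1, np.zeros(d, dtype=np.int64)])
    m2 = np.concatenate([particle.m2, np.zeros(d, dtype=np.int64)])
    m1 = m1 + (row == 0.5)
    m2 = m2 + (row == 1.0)

    theta = _walk_positive(particle.theta, config.sigma_theta, rng)
    if d:
        new_rows = rng.gamma(config.a1, 1.0, size=(d, theta.shape[1]))
        new_rows = np.maximum(new_rows, PROB_FLOOR)
        theta = np.vstack([theta, new_rows])
    p = _walk_reflected(particle.p, config.sigma_p, rng)
    return Particle(Z=Z, theta=theta, p=p, log_weight=particle.log_weight,
                    m1=m1, m2=m2)


def weight_update(
    log_weight_prev: float,
    y_row: np.ndarray,
    v_row: np.ndarray,
    particle: Particle,
    log_coeff: np.ndarray | None = None,
) -> float:
    """Bootstrap-filter weight update: previous log-weight + log-likelihood.

    When particles are proposed from the prior transition kernel, the
    importance correction reduces to the binomial likelihood of the new row.
    """
    z_row = particle.Z[-1] if particle.Z.shape[0] else np.empty(0)
    if z_row.shape[0] + 1 != particle.theta.shape[0]:
        raise ValueError("particle genotype row and theta rows are inconsistent")
    y = np.asarray(y_row, dtype=float)
    v = np.asarray(v_row, dtype=float)
    W = particle.W
    pts = particle.p * W[0] + z_row @ W[1:]
    pts = np.clip(pts, PROB_FLOOR, 1.0 - PROB_FLOOR)
    if log_coeff is None:
        log_coeff = log_binom_coeff(y, v)
    ll = float(np.sum(log_coeff + y * np.log(pts) + (v - y) * np.log1p(-pts)))
    return log_weight_prev + ll


def normalize_log_weights(log_weights: np.ndarray) -> tuple[np.ndarray, float]:
    """Normalize log-weights; returns (weights summing to 1, ESS)."""
    log_weights = np.asarray(log_weights, dtype=float)
    total = logsumexp(log_weights)
    if not np.isfinite(total):
        raise DegenerateWeightsError(
            "all particle weights underflowed; the likelihood collapsed"
        )
    w = np.exp(log_weights - total)
    ess = 1.0 / float(np.sum(w**2))
    return w, ess


def resample(
    particles: list[Particle],
    weights: np.ndarray,
    rng: np.random.Generator,
    scheme: str = "multinomial",
) -> list[Particle]:
    """Draw N particles proportionally to the weights; reset weights to 1/N.

    The returned particles are independent copies, so mutating one never
    affects another.  ``systematic`` uses a single uniform offset with
    stratified positions and lower Monte-Carlo variance; ``multinomial`` is
    the plain i.i.d. draw.
    """
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("weights must be nonnegative")
    total = weights.sum()
    if total <= 0:
        raise DegenerateWeightsError("cannot resample from all-zero weights")
    weights = weights / total
    n = len(particles)
    if scheme == "multinomial":
        idx = rng.choice(n, size=n, p=weights)
    elif scheme == "systematic":
        positions = (rng.random() + np.arange(n)) / n
        idx = np.searchsorted(np.cumsum(weights), positions)
        idx = np.clip(idx, 0, n - 1)
    else:
        raise ValueError(f"unknown resampling scheme {scheme!r}")
    log_w = -math.log(n)
    out = []
    for i in idx:
        child = particles[i].copy()
        child.log_weight = log_w
        out.append(child)
    return out


# ---------------------------------------------------------------------------
# guided proposal internals
# ---------------------------------------------------------------------------

@lru_cache(maxsize=32)
def _ternary_combos(n_cols: int) -> np.ndarray:
    """All genotype rows over n_cols columns, as a (3^n, n) array."""
    return np.array(
        list(itertools.product(cibp.GENOTYPE_LEVELS, repeat=n_cols))
    )


def _poisson_logpmf(d: int, lam: float) -> float:
    return d * math.log(lam) - lam - float(gammaln(d + 1))


def _mixture_theta_draws_batch(
    theta: np.ndarray,
    sigma: float,
    config: SMCConfig,
    rng: np.random.Generator,
    n_draws: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Theta proposals from (1-rho)*TruncNormal(theta, sigma) + rho*prior.

    ``theta`` is a (B, C+1, S) stack for B particles sharing a column count.
    The fresh-prior component lets a column re-scale in one move when the
    data demand it (without it, a mis-scaled column can only be patched by
    opening a spurious sibling).  Returns draws of shape (B, M, C+1, S) and
    the per-sample log importance ratio  log p_dyn - log q  summed over
    theta rows (shape (B, M, S)), needed to weight the draws against the
    model's own random-walk dynamics.
    """
    rho = config.refresh_prob
    B, n_rows, S = theta.shape
    M = n_draws
    shp = (B, M, n_rows, S)
    base = theta[:, None, :, :]
    a_shape = np.concatenate([[config.a0], np.full(n_rows - 1, config.a1)])
    a_full = np.broadcast_to(a_shape[None, None, :, None], shp)
    fresh = rng.random(shp) < rho
    draws = base + rng.normal(0.0, sigma, shp)
    if fresh.any():
        draws[fresh] = np.maximum(rng.gamma(a_full[fresh], 1.0), PROB_FLOOR)
    bad = draws <= 0
    while bad.any():
        draws[bad] = (np.broadcast_to(base, shp)[bad]
                      + rng.normal(0.0, sigma, int(bad.sum())))
        bad = draws <= 0
    z = (draws - base) / sigma
    log_dyn = (
        -0.5 * z * z
        - math.log(sigma)
        - 0.5 * math.log(2 * math.pi)
        - log_ndtr(base / sigma)
    )
    if rho == 0:
        return draws, np.zeros((B, M, S))
    gl = gammaln(a_shape)[None, None, :, None]  # constant per theta row
    log_gamma = (a_full - 1) * np.log(draws) - draws - gl
    log_q = np.logaddexp(math.log1p(-rho) + log_dyn, math.log(rho) + log_gamma)
    return draws, (log_dyn - log_q).sum(axis=2)


def _group_combo_tables(
    group: list[Particle], t: int, config: SMCConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Enumerated rows over existing columns and per-particle cIBP log-priors.

    All particles in the group share the column count C; the combo matrix
    (3^C, C) is common while the log-priors differ through each particle's
    usage counts.  Returns (combos, log-priors of shape (B, 3^C)).
    """
    n_cols = group[0].n_columns
    B = len(group)
    if n_cols == 0:
        return np.zeros((1, 0)), np.zeros((B, 1))
    m1 = np.stack([q.m1 for q in group])
    m2 = np.stack([q.m2 for q in group])
    p0, p05, p1 = cibp.category_probs(m1, m2, t, config.cibp)
    logcat = np.log(np.clip(np.stack([p0, p05, p1], axis=-1), 1e-300, None))
    # logcat: (B, C, 3); lp[b, k] = sum_c logcat[b, c, idx[k, c]]
    cb = _ternary_combos(n_cols)
    idx = (cb * 2 + 0.5).astype(int)                     # (K0, C)
    lp = logcat[:, np.arange(n_cols)[None, :], idx].sum(axis=2)
    return cb, lp


def _row_categorical(log_probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One categorical draw per row of a (B, K) log-probability table."""
    prob = np.exp(log_probs - _lse(log_probs, axis=1, keepdims=True))
    u = rng.random(len(prob))
    return (np.cumsum(prob, axis=1) < u[:, None]).sum(axis=1).clip(
        max=prob.shape[1] - 1
    )


def _per_sample_pick(l_ms: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Per-sample draw index selection: l_ms has shape (B, M, S)."""
    pm = np.exp(l_ms - _lse(l_ms, axis=1, keepdims=True))
    u = rng.random((l_ms.shape[0], l_ms.shape[2]))
    return (np.cumsum(pm, axis=1) < u[:, None, :]).sum(axis=1).clip(
        max=l_ms.shape[1] - 1
    )


def _guided_substep(
    y: np.ndarray,
    v: np.ndarray,
    group: list[Particle],
    t: int,
    sigma_t: float,
    config: SMCConfig,
    rng: np.random.Generator,
    allow_open: bool,
) -> np.ndarray:
    """One marginalized move for a group of particles with equal column
    count.  Mutates each particle's theta (and, when ``allow_open``, appends
    the sampled genotype row); returns the per-particle log predictive.

    The move integrates theta over the mixture kernel and, on the opening
    substep, weighs a single-birth branch whose new-column theta integral
    factorizes over samples; per-sample resampling of the draw index then
    commits a concrete theta.  The returned predictive is the particle's
    importance-weight increment.
    """
    B = len(group)
    S = y.shape[0]
    M = config.n_draws
    top = config.enum_top
    cb, lp = _group_combo_tables(group, t, config)
    theta = np.stack([q.theta for q in group])           # (B, C+1, S)
    p_arr = np.array([q.p for q in group])

    draws, lratio = _mixture_theta_draws_batch(theta, sigma_t, config, rng, M)
    den = draws.sum(axis=2)                              # (B, M, S)

    # point-theta screen to bound the enumeration
    if len(cb) > top:
        numer_pt = (p_arr[:, None, None] * theta[:, None, 0, :]
                    + np.einsum("kc,bcs->bks", cb, theta[:, 1:, :]))
        pts_pt = np.clip(numer_pt / theta.sum(axis=1)[:, None, :],
                         PROB_FLOOR, 1 - PROB_FLOOR)
        ll_pt = (y * np.log(pts_pt)
                 + (v - y) * np.log1p(-pts_pt)).sum(axis=2) + lp
        keep = np.argpartition(ll_pt, -top, axis=1)[:, -top:]  # (B, top)
        cbk = cb[keep]                                    # (B, K, C)
        lpk = np.take_along_axis(lp, keep, axis=1)        # (B, K)
    else:
        cbk = np.broadcast_to(cb[None], (B,) + cb.shape)
        lpk = lp

    numer = (p_arr[:, None, None, None] * draws[:, None, :, 0, :]
             + np.einsum("bkc,bmcs->bkms", cbk, draws[:, :, 1:, :]))
    pts = np.clip(numer / den[:, None], PROB_FLOOR, 1 - PROB_FLOOR)
    l_sm0 = (y * np.log(pts) + (v - y) * np.log1p(-pts)
             + lratio[:, None])                           # (B, K, M, S)
    L0 = _lse(l_sm0, axis=2) - math.log(M)                # (B, K, S)
    joint0 = lpk + L0.sum(axis=2)                         # (B, K)
    logpred0 = _lse(joint0, axis=1)                       # (B,)

    def commit_existing(idx: np.ndarray) -> None:
        """Sample (combo, per-sample theta) for the given particle indices."""
        if len(idx) == 0:
            return
        k = _row_categorical(joint0[idx], rng)
        l_ms = l_sm0[idx, k]                              # (b, M, S)
        midx = _per_sample_pick(l_ms, rng)                # (b, S)
        chosen = np.take_along_axis(
            draws[idx], midx[:, None, None, :], axis=1
        )[:, 0]                                           # (b, C+1, S)
        for j, (b, kk) in enumerate(zip(idx, k)):
            q = group[b]
            q.theta = chosen[j]
            if allow_open:
                _append_row(q, cbk[b, kk], 0)

    lam = config.cibp.alpha / t
    can_open = allow_open and group[0].n_columns < config.max_columns
    if not can_open:
        commit_existing(np.arange(B))
        return logpred0

    # single-birth branch: per-sample Monte Carlo for the new-column integral
    theta_new = np.maximum(rng.gamma(config.a1, 1.0, (B, M, S)), PROB_FLOOR)
    levels = np.array([0.5, 1.0])
    add = levels[None, :, None, None] * theta_new[:, None]     # (B, 2, M, S)
    dd = den + theta_new                                        # (B, M, S)
    num1 = numer[:, :, None] + add[:, None]                     # (B, K, 2, M, S)
    pts1 = np.clip(num1 / dd[:, None, None], PROB_FLOOR, 1 - PROB_FLOOR)
    l_sm1 = (y * np.log(pts1) + (v - y) * np.log1p(-pts1)
             + lratio[:, None, None])                           # (B, K, 2, M, S)
    L1 = _lse(l_sm1, axis=3) - math.log(M)                      # (B, K, 2, S)
    joint1 = lpk[:, :, None] + _LOG_HALF + L1.sum(axis=3)       # (B, K, 2)

    logw0 = _poisson_logpmf(0, lam) + logpred0
    logw1 = _poisson_logpmf(1, lam) + _lse(
        joint1.reshape(B, -1), axis=1
    )
    logpred = np.logaddexp(logw0, logw1)
    opens = rng.random(B) >= np.exp(logw0 - logpred)
    commit_existing(np.flatnonzero(~opens))
    idx = np.flatnonzero(opens)
    if len(idx):
        flat = joint1[idx].reshape(len(idx), -1)
        pick = _row_categorical(flat, rng)
        ki, li = np.divmod(pick, 2)
        l_ms = l_sm1[idx, ki, li]                               # (b, M, S)
        midx = _per_sample_pick(l_ms, rng)
        chosen = np.take_along_axis(
            draws[idx], midx[:, None, None, :], axis=1
        )[:, 0]
        new_rows = np.take_along_axis(theta_new[idx], midx[:, None, :],
                                      axis=1)[:, 0]             # (b, S)
        for j, b in enumerate(idx):
            q = group[b]
            q.theta = np.vstack([chosen[j], new_rows[j][None, :]])
            _append_row(q, np.concatenate([cbk[b, ki[j]], [levels[li[j]]]]), 1)
    return logpred


@lru_cache(maxsize=8)
def _birth_patterns(d: int) -> np.ndarray:
    """All level assignments over d freshly opened columns."""
    return np.array(list(itertools.product([0.5, 1.0], repeat=d)))


def _first_row_move(
    y: np.ndarray,
    v: np.ndarray,
    group: list[Particle],
    config: SMCConfig,
    rng: np.random.Generator,
    sigma_t: float,
    d_max: int = 5,
) -> np.ndarray:
    """Opening move for the first locus: d = 0..d_max columns at once.

    The first row carries no committed columns, so restricting it to a
    single birth would force distinct subclones active at locus 1 into one
    merged column that the sequential construction can never split again.
    All d-column branches are weighed with the per-sample Monte-Carlo
    integral over the new columns' theta (an extra draw budget keeps the
    higher-dimensional integrals tame); the noise-row theta is integrated
    over its mixture kernel as in the generic move.  Mutates the particles
    and appends their first genotype row; returns per-particle predictives.
    """
    B = len(group)
    S = y.shape[0]
    M = config.n_draws * 4
    lam = config.cibp.alpha
    theta = np.stack([q.theta for q in group])                # (B, 1, S)
    p_arr = np.array([q.p for q in group])
    draws, lratio = _mixture_theta_draws_batch(theta, sigma_t, config, rng, M)
    theta0 = draws[:, :, 0, :]                                # (B, M, S)
    numer0 = p_arr[:, None, None] * theta0
    pts0 = np.clip(numer0 / theta0, PROB_FLOOR, 1 - PROB_FLOOR)
    l0 = (y * np.log(pts0) + (v - y) * np.log1p(-pts0) + lratio)  # (B, M, S)
    branch_logw = [
        _poisson_logpmf(0, lam) + (_lse(l0, axis=1) - math.log(M)).sum(axis=1)
    ]
    branch_data = [None]
    d_cap = min(d_max, config.max_columns)
    for d in range(1, d_cap + 1):
        thn = np.maximum(rng.gamma(config.a1, 1.0, (B, M, d, S)), PROB_FLOOR)
        pats = _birth_patterns(d)                             # (P, d)
        add = np.einsum("pd,bmds->bpms", pats, thn)           # (B, P, M, S)
        den = theta0 + thn.sum(axis=2)                        # (B, M, S)
        pts = np.clip((numer0[:, None] + add) / den[:, None],
                      PROB_FLOOR, 1 - PROB_FLOOR)
        l_sm = (y * np.log(pts) + (v - y) * np.log1p(-pts)
                + lratio[:, None])                            # (B, P, M, S)
        L = _lse(l_sm, axis=2) - math.log(M)                  # (B, P, S)
        joint = d * _LOG_HALF + L.sum(axis=2)                 # (B, P)
        branch_logw.append(_poisson_logpmf(d, lam) + _lse(joint, axis=1))
        branch_data.append((joint, thn, pats, l_sm))
    branch_logw = np.stack(branch_logw, axis=1)               # (B, D+1)
    logpred = _lse(branch_logw, axis=1)
    d_pick = _row_categorical(branch_logw, rng)
    for b in range(B):
        q = group[b]
        d = int(d_pick[b])
        if d == 0:
            midx = _per_sample_pick(l0[b][None], rng)[0]       # (S,)
            q.theta = theta0[b, midx, np.arange(S)][None, :]
            _append_row(q, np.empty(0), 0)
            continue
        joint, thn, pats, l_sm = branch_data[d]
        pi = _row_categorical(joint[b][None], rng)[0]
        midx = _per_sample_pick(l_sm[b, pi][None], rng)[0]     # (S,)
        new_rows = thn[b, midx, :, np.arange(S)].T             # (d, S)
        q.theta = np.vstack([theta0[b, midx, np.arange(S)][None, :], new_rows])
        _append_row(q, pats[pi], d)
    return logpred


def _append_row(particle: Particle, row: np.ndarray, d: int) -> None:
    particle.Z = np.vstack([np.pad(particle.Z, ((0, 0), (0, d))), row[None, :]])
    particle.m1 = np.concatenate(
        [particle.m1, np.zeros(d, dtype=np.int64)]
    ) + (row == 0.5)
    particle.m2 = np.concatenate(
        [particle.m2, np.zeros(d, dtype=np.int64)]
    ) + (row == 1.0)


def _run_guided(
    data: ReadCountData, config: SMCConfig, rng: np.random.Generator
) -> tuple[list[Particle], list[float]]:
    particles = init_particles(config, data.n_samples, rng)
    K = config.n_substeps
    inv_k = 1.0 / K
    ess_trace: list[float] = []
    for t in range(1, data.n_loci + 1):
        y = data.Y[t - 1].astype(float)
        v = data.V[t - 1].astype(float)
        lc = float(log_binom_coeff(y, v).sum())
        sigma_t = max(config.sigma0 / math.sqrt(t), config.sigma_theta)
        for particle in particles:
            # Eq-(5) dynamics for the error rate: one step per locus
            particle.p = _walk_reflected(particle.p, config.sigma_p, rng)
        for j in range(K):
            last = j == K - 1
            # batch the move over groups with a common column count
            by_cols: dict[int, list[int]] = {}
            for i, q in enumerate(particles):
                by_cols.setdefault(q.n_columns, []).append(i)
            for indices in by_cols.values():
                group = [particles[i] for i in indices]
                if last and t == 1:
                    logpred = _first_row_move(
                        y, v, group, config, rng, sigma_t
                    )
                else:
                    logpred = _guided_substep(
                        y, v, group, t, sigma_t, config, rng, allow_open=last
                    )
                for i, lpred in zip(indices, logpred):
                    particles[i].log_weight += (lc + lpred) * inv_k
            weights, ess = normalize_log_weights(
                np.array([q.log_weight for q in particles])
            )
            particles = resample(particles, weights, rng, config.resampling)
        ess_trace.append(ess)
        logger.info(
            "step %d/%d: ESS %.1f of %d particles", t, data.n_loci, ess,
            config.n_particles,
        )
    return particles, ess_trace


def _run_prior(
    data: ReadCountData, config: SMCConfig, rng: np.random.Generator
) -> tuple[list[Particle], list[float]]:
    particles = init_particles(config, data.n_samples, rng)
    ess_trace: list[float] = []
    for t in range(1, data.n_loci + 1):
        y_row = data.Y[t - 1]
        v_row = data.V[t - 1]
        log_coeff = log_binom_coeff(y_row, v_row)
        for i, particle in enumerate(particles):
            moved = propagate(particle, t, config, rng)
            moved.log_weight = weight_update(
                particle.log_weight, y_row, v_row, moved, log_coeff
            )
            particles[i] = moved
        weights, ess = normalize_log_weights(
            np.array([q.log_weight for q in particles])
        )
        ess_trace.append(ess)
        logger.info(
            "step %d/%d: ESS %.1f of %d particles", t, data.n_loci, ess,
            config.n_particles,
        )
        particles = resample(particles, weights, rng, config.resampling)
    return particles, ess_trace


def run(
    data: ReadCountData, config: SMCConfig
) -> tuple[list[Particle], PosteriorSummary]:
    """Run the full filter over all loci and summarize the posterior.

    Loci are processed in the row order of ``data``.  A single seeded random
    stream is consumed in a fixed particle-major order, so identical seed
    and inputs reproduce the result exactly.
    """
    if data.n_loci == 0:
        raise ValueError("empty input: at least one locus is required")
    rng = np.random.default_rng(config.seed)
    if config.proposal == "guided":
        particles, ess_trace = _run_guided(data, config, rng)
    else:
        particles, ess_trace = _run_prior(data, config, rng)
    weights = np.full(len(particles), 1.0 / len(particles))
    summary = summarize(particles, weights)
    summary.ess_trace = ess_trace
    return particles, summary


def summarize(
    particles: list[Particle], weights: np.ndarray
) -> PosteriorSummary:
    """Posterior summary of a weighted final ensemble.

    The pmf over subclone counts is the weighted frequency of per-particle
    column counts; its mode (ties broken toward the smaller count) is the
    MAP estimate of C.  Conditioning on the MAP-count particles, columns are
    aligned to the highest-weight such particle by minimum-L1 assignment on
    genotype columns, then genotypes are the weighted elementwise mode (ties
    toward the smaller genotype) and proportions the weighted mean,
    renormalized columnwise.
    """
    weights = np.asarray(weights, dtype=float)
    if len(particles) != weights.shape[0]:
        raise ValueError("one weight per particle required")
    weights = weights / weights.sum()
    counts = np.array([p.n_columns for p in particles])
    c_values = np.unique(counts)
    pmf = {int(c): float(weights[counts == c].sum()) for c in c_values}
    # argmax with ties toward smaller C
    c_map = max(sorted(pmf), key=lambda c: (pmf[c], -c))

    sel = np.flatnonzero(counts == c_map)
    sel_w = weights[sel]
    sel_w = sel_w / sel_w.sum()
    ref = particles[sel[np.argmax(sel_w)]]
    T = ref.Z.shape[0]

    if c_map == 0:
        Z_hat = np.zeros((T, 0))
        W_stack = np.stack([particles[i].W for i in sel])
        W_hat = np.einsum("i,ijk->jk", sel_w, W_stack)
        W_hat = W_hat / W_hat.sum(axis=0, keepdims=True)
    else:
        Zs = []
        Ws = []
        for i in sel:
            part = particles[i]
            perm = match_columns(part.Z, ref.Z)
            Zs.append(part.Z[:, perm])
            W = part.W
            Ws.append(np.vstack([W[0:1], W[1:][perm]]))
        Z_stack = np.stack(Zs)  # (n_sel, T, c_map)
        votes = np.stack(
            [np.einsum("i,ijk->jk", sel_w, (Z_stack == g).astype(float))
             for g in cibp.GENOTYPE_LEVELS]
        )
        # argmax over the level axis; levels are ordered increasing, and
        # argmax returns the first maximum, i.e. the smaller genotype on ties
        Z_hat = np.asarray(cibp.GENOTYPE_LEVELS)[np.argmax(votes, axis=0)]
        W_hat = np.einsum("i,ijk->jk", sel_w, np.stack(Ws))
        W_hat = W_hat / W_hat.sum(axis=0, keepdims=True)

    p_hat = float(np.sum(sel_w * np.array([particles[i].p for i in sel])))
    P_hat = success_probability_matrix(Z_hat, W_hat, p_hat)
    return PosteriorSummary(
        c_pmf=pmf,
        c_map=int(c_map),
        Z_hat=Z_hat,
        W_hat=W_hat,
        p_hat=p_hat,
        P_hat=P_hat,
    )
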