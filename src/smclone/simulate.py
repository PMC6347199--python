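"""Synthetic read-count datasets with known subclonal ground truth.

The generator follows the recipe used in the simulation study this package
reproduces: for T loci and S samples,

  i.   total depths v_ts ~ Poisson(r);
  ii.  each proportion column ~ Dirichlet([a_0, a_1, ..., a_C]) with
       a_0 = 0.1 (a weak noise weight) and each subclone concentration a_c
       drawn once per dataset, uniformly from {2, 4, 5, 6, 7, 8};
  iii. genotype entries i.i.d. over {0, 0.5, 1} with probabilities
       (0.5, 0.1, 0.4); the error rate is fixed at p = 0.02;
  iv.  success probabilities p_ts = w_0s p + sum_c z_tc w_cs;
  v.   variant counts y_ts ~ Binomial(v_ts, p_ts).

``mode="binary"`` restricts genotypes to {0, 0.5} with probabilities
(0.3, 0.7), the convention used when comparing against methods that model
only mutation presence/absence.

A zero Poisson depth gives y_ts = 0 deterministically (a binomial with zero
trials); such entries are retained rather than redrawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .observation import ReadCountData, success_probability_matrix

__all__ = ["SimConfig", "GroundTruth", "simulate_dataset"]


@dataclass(frozen=True)
class SimConfig:
    """Generative settings for one synthetic dataset.

    ``C`` true subclones, ``S`` samples, ``T`` loci, mean sequencing depth
    ``r``.  The remaining fields parameterize steps ii-iii above and default
    to the values of the simulation study.
    """

    C: int = 3
    S: int = 10
    T: int = 20
    r: float = 100.0
    p_noise: float = 0.02
    dirichlet_a0: float = 0.1
    dirichlet_choices: tuple[float, ...] = (2, 4, 5, 6, 7, 8)
    genotype_probs: tuple[float, float, float] = (0.5, 0.1, 0.4)
    binary_probs: tuple[float, float] = (0.3, 0.7)
    mode: str = "ternary"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.C, self.S, self.T) < 1 or self.r <= 0:
            raise ValueError("C, S, T and r must be positive")
        if self.mode not in ("ternary", "binary"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (0 < self.p_noise < 1):
            raise ValueError("p_noise must lie in (0, 1)")
        if abs(sum(self.genotype_probs) - 1) > 1e-12:
            raise ValueError("genotype_probs must sum to 1")
        if abs(sum(self.binary_probs) - 1) > 1e-12:
            raise ValueError("binary_probs must sum to 1")


@dataclass
class GroundTruth:
    """True latent quantities behind a simulated dataset."""

    Z_true: np.ndarray
    W_true: np.ndarray
    p_true: float
    P_true: np.ndarray


def simulate_dataset(config: SimConfig) -> tuple[ReadCountData, GroundTruth]:
    """Generate one dataset and its ground truth, reproducible per seed."""
    rng = np.random.default_rng(config.seed)
    T, S, C = config.T, config.S, config.C

    V = rng.poisson(config.r, size=(T, S))

    a_sub = rng.choice(config.dirichlet_choices, size=C)  # shared by all columns
    conc = np.concatenate([[config.dirichlet_a0], a_sub])
    W = rng.dirichlet(conc, size=S).T  # (C+1) x S, noise row first

    if config.mode == "ternary":
        levels = np.array([0.0, 0.5, 1.0])
        probs = np.asarray(config.genotype_probs)
    else:
        levels = np.array([0.0, 0.5])
        probs = np.asarray(config.binary_probs)
    Z = rng.choice(levels, size=(T, C), p=probs)

    P = success_probability_matrix(Z, W, config.p_noise)
    P = np.clip(P, 0.0, 1.0)  # guard rounding at the simplex boundary
    Y = rng.binomial(V, P)

    data = ReadCountData(Y=Y, V=V)
    truth = GroundTruth(Z_true=Z, W_true=W, p_true=config.p_noise, P_true=P)
    return data, truth
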