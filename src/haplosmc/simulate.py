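"""Synthetic variant-count generator with known ground truth.

Datasets mimic multi-sample tumor sequencing of T SNVs in S samples with
C latent haplotypes: per-cell depth ``v_ts ~ Pois(r)``; each column of
the proportion matrix W drawn from ``Dir([a_0, a_1, ..., a_C])`` with a
small background weight ``a_0`` and haplotype weights picked from a
candidate set; haplotype indicators ``z_tc ~ Bern(0.6)``; noise rate
``p = 0.02``; and variant counts ``y_ts ~ Binomial(v_ts, p_ts)`` with
``p_ts`` the expected VAF of the model.  The ground truth (Z, W, p, P) is
returned alongside the observable counts for recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import CountData

__all__ = ["SimulationConfig", "SimulationTruth", "simulate", "simulate_null"]


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; defaults follow the simulated-data regime
    (T=60 SNVs, S=10 samples, C=4 haplotypes)."""

    T: int = 60
    S: int = 10
    C: int = 4
    r: float = 200.0
    p_true: float = 0.02
    bernoulli_prob: float = 0.6
    dir_background: float = 0.2
    dir_choices: tuple = (2, 4, 5, 6, 7, 8)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T < 1 or self.S < 1 or self.C < 0:
            raise ValueError("T, S must be >= 1 and C >= 0")
        if self.r <= 0:
            raise ValueError("average depth r must be positive")
        for name in ("p_true", "bernoulli_prob"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.dir_background <= 0 or not self.dir_choices:
            raise ValueError("Dirichlet weights must be positive / non-empty")


@dataclass
class SimulationTruth:
    """Ground truth emitted by the generator."""

    Z_true: np.ndarray
    W_true: np.ndarray
    p_true: float
    P_true: np.ndarray


def _expected_vaf_matrix(Z: np.ndarray, W: np.ndarray, p: float) -> np.ndarray:
    return W[0] * p + Z.astype(float) @ W[1:]


def simulate(config: SimulationConfig) -> tuple[CountData, SimulationTruth]:
    """Generate one dataset plus its ground truth, reproducibly.

    The Dirichlet parameter vector ``[a_0, a_1, ..., a_C]`` is drawn once
    per dataset (``a_c`` uniform with replacement from
    ``config.dir_choices``) and shared by all S columns of W.
    """
    rng = np.random.default_rng(config.seed)
    a = np.empty(config.C + 1)
    a[0] = config.dir_background
    a[1:] = rng.choice(config.dir_choices, size=config.C, replace=True)
    W = rng.dirichlet(a, size=config.S).T  # (C + 1, S), columns on simplex
    Z = (rng.random((config.T, config.C)) < config.bernoulli_prob).astype(np.int8)
    P = _expected_vaf_matrix(Z, W, config.p_true)
    V = rng.poisson(config.r, size=(config.T, config.S))
    Y = rng.binomial(V, P)
    data = CountData(
        variant_counts=Y,
        total_counts=V,
        locus_ids=[f"snv_{t + 1:04d}" for t in range(config.T)],
        sample_ids=[f"sample_{s + 1}" for s in range(config.S)],
    )
    truth = SimulationTruth(Z_true=Z, W_true=W, p_true=config.p_true, P_true=P)
    return data, truth


def simulate_null(
    T: int, S: int, r: float, p_true: float = 0.02, seed: int = 0
) -> tuple[CountData, SimulationTruth]:
    """Degenerate generator with no haplotypes: every read is background
    noise, ``p_ts = p_true`` everywhere.  Used for null-recovery tests."""
    config = SimulationConfig(T=T, S=S, C=0, r=r, p_true=p_true, seed=seed)
    rng = np.random.default_rng(seed)
    W = np.ones((1, S))
    Z = np.zeros((T, 0), dtype=np.int8)
    P = np.full((T, S), p_true)
    V = rng.poisson(config.r, size=(T, S))
    Y = rng.binomial(V, P)
    data = CountData(
        variant_counts=Y,
        total_counts=V,
        locus_ids=[f"snv_{t + 1:04d}" for t in range(T)],
        sample_ids=[f"sample_{s + 1}" for s in range(S)],
    )
    return data, SimulationTruth(Z_true=Z, W_true=W, p_true=p_true, P_true=P)
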