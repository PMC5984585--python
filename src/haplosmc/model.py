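"""Probabilistic model tying latent haplotypes to variant read counts.

Observed data are two T x S count matrices: ``y_ts`` variant reads out of
``v_ts`` total reads at SNV ``t`` in sample ``s``.  The expected variant
allele frequency (VAF) decomposes over latent haplotypes,

    p_ts = w_0s * p + sum_c z_tc * w_cs,

where ``z_tc`` indicates whether haplotype ``c`` carries the variant at
SNV ``t``, ``w_cs`` is the proportion of haplotype ``c`` in sample ``s``,
and the background pseudo-haplotype ``c = 0`` contributes ``w_0s * p``
with ``p`` a small global noise rate.  Reads are binomial:
``y_ts ~ Binomial(v_ts, p_ts)``.

Proportions are re-parameterized through positive ``theta_cs`` with
``w_cs = theta_cs / sum_c' theta_c's`` so that columns of W stay on the
simplex while the number of haplotypes grows.  For sequential inference
the static parameters (theta, p) receive artificial Gaussian random-walk
dynamics with standard deviation ``sigma``, reflected at the support
boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln

__all__ = [
    "CountData",
    "ProportionParams",
    "NoiseParam",
    "PriorHyperparams",
    "expected_vaf",
    "binomial_logpmf",
    "log_likelihood_row",
    "propagate_params",
    "draw_initial_params",
    "reflect_positive",
    "reflect_unit",
]

#: Probabilities are clipped into (EPS, 1 - EPS) before taking logs.
EPS = 1e-12


@dataclass
class CountData:
    """Paired variant / total read-count matrices with labels."""

    variant_counts: np.ndarray
    total_counts: np.ndarray
    locus_ids: Sequence[str]
    sample_ids: Sequence[str]

    def __post_init__(self) -> None:
        Y = np.asarray(self.variant_counts)
        V = np.asarray(self.total_counts)
        if Y.shape != V.shape or Y.ndim != 2:
            raise ValueError("Y and V must be 2-d arrays of identical shape")
        if not (np.issubdtype(Y.dtype, np.integer) and np.issubdtype(V.dtype, np.integer)):
            raise ValueError("counts must be integer-valued")
        if (Y < 0).any() or (V < 0).any():
            raise ValueError("counts must be non-negative")
        if (Y > V).any():
            t, s = np.argwhere(Y > V)[0]
            raise ValueError(
                f"variant count exceeds total count at locus "
                f"{self.locus_ids[t]!r}, sample {self.sample_ids[s]!r}"
            )
        if len(self.locus_ids) != Y.shape[0] or len(self.sample_ids) != Y.shape[1]:
            raise ValueError("label lengths do not match matrix shape")
        self.variant_counts = Y
        self.total_counts = V
        self.locus_ids = list(self.locus_ids)
        self.sample_ids = list(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return self.variant_counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.variant_counts.shape[1]


@dataclass
class ProportionParams:
    """Positive (C+1) x S matrix theta; row 0 is the background haplotype."""

    theta: np.ndarray

    def __post_init__(self) -> None:
        theta = np.asarray(self.theta, dtype=float)
        if theta.ndim != 2 or theta.shape[0] < 1:
            raise ValueError("theta must be 2-d with at least the background row")
        if (theta <= 0).any():
            raise ValueError("theta entries must be strictly positive")
        self.theta = theta

    @property
    def n_haplotypes(self) -> int:
        return self.theta.shape[0] - 1

    @property
    def n_samples(self) -> int:
        return self.theta.shape[1]

    @property
    def weights(self) -> np.ndarray:
        """Derived W: columns sum to one."""
        return self.theta / self.theta.sum(axis=0, keepdims=True)


@dataclass
class NoiseParam:
    """Background relative mutation frequency p in (0, 1)."""

    p: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p < 1.0):
            raise ValueError(f"p must lie in (0, 1), got {self.p}")


@dataclass(frozen=True)
class PriorHyperparams:
    """Priors and random-walk scale for the static parameters.

    theta_0s ~ Gamma(a0, 1), theta_cs ~ Gamma(a1, 1) for c >= 1,
    p ~ Beta(a00, b00) with a00 << b00 so the noise rate is small a
    priori, and sigma is the per-step random-walk standard deviation.
    ``sigma_theta`` / ``sigma_p`` optionally override ``sigma`` for the
    two parameter blocks.
    """

    a0: float = 0.5
    a1: float = 1.0
    a00: float = 1.0
    b00: float = 30.0
    sigma: float = 0.05
    sigma_theta: float | None = None
    sigma_p: float | None = None

    def __post_init__(self) -> None:
        for name in ("a0", "a1", "a00", "b00", "sigma"):
            if getattr(self, name) < 0 or (name != "sigma" and getattr(self, name) == 0):
                raise ValueError(f"{name} must be positive")
        if not self.a00 < self.b00:
            raise ValueError("a00 < b00 is required to keep the noise rate small")

    @property
    def eff_sigma_theta(self) -> float:
        return self.sigma if self.sigma_theta is None else self.sigma_theta

    @property
    def eff_sigma_p(self) -> float:
        return self.sigma if self.sigma_p is None else self.sigma_p


def expected_vaf(
    z_row: np.ndarray, proportions: ProportionParams, noise: NoiseParam
) -> np.ndarray:
    """Expected VAF of one SNV in every sample.

    Returns ``w_0s * p + sum_c z_tc * w_cs`` for s = 1..S; the result is
    in [0, 1] because W columns are probability vectors and p < 1.
    """
    z_row = np.asarray(z_row)
    if z_row.shape[0] != proportions.n_haplotypes:
        raise ValueError(
            f"z_row has length {z_row.shape[0]} but theta implies "
            f"{proportions.n_haplotypes} haplotypes"
        )
    w = proportions.weights
    return w[0] * noise.p + z_row.astype(float) @ w[1:]


def binomial_logpmf(y, v, p, eps: float = EPS):
    """Elementwise log Binomial(y | v, p) with p clipped into (eps, 1-eps).

    Computed directly from log-gamma functions; broadcasts over any
    compatible shapes (used with particle-stacked arrays).
    """
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    p = np.clip(np.asarray(p, dtype=float), eps, 1.0 - eps)
    return (
        gammaln(v + 1.0)
        - gammaln(y + 1.0)
        - gammaln(v - y + 1.0)
        + y * np.log(p)
        + (v - y) * np.log1p(-p)
    )


def log_likelihood_row(y_row, v_row, p_row) -> float:
    """Log-likelihood of one SNV row: sum_s log Binomial(y_ts | v_ts, p_ts)."""
    y_row = np.asarray(y_row)
    v_row = np.asarray(v_row)
    if (y_row > v_row).any():
        raise ValueError("variant counts exceed total counts")
    return float(binomial_logpmf(y_row, v_row, p_row).sum())


def reflect_positive(x: np.ndarray) -> np.ndarray:
    """Fold a perturbed value back into (0, inf) by reflection at 0."""
    return np.maximum(np.abs(x), EPS)


def reflect_unit(x: np.ndarray) -> np.ndarray:
    """Fold a perturbed value back into (0, 1) by reflection at 0 and 1."""
    r = np.mod(x, 2.0)
    r = np.where(r > 1.0, 2.0 - r, r)
    return np.clip(r, EPS, 1.0 - EPS)


def propagate_params(
    current: tuple[ProportionParams, NoiseParam],
    hyper: PriorHyperparams,
    rng: np.random.Generator,
) -> tuple[ProportionParams, NoiseParam]:
    """One random-walk step on (theta, p), reflected into the support.

    Every entry receives an independent N(0, sigma^2) perturbation;
    reflection keeps the walk symmetric away from the boundaries and
    guarantees theta > 0 and 0 < p < 1.
    """
    props, noise = current
    sig_t = hyper.eff_sigma_theta
    sig_p = hyper.eff_sigma_p
    theta = props.theta
    if sig_t > 0:
        theta = reflect_positive(theta + rng.normal(0.0, sig_t, theta.shape))
    p = noise.p
    if sig_p > 0:
        p = float(reflect_unit(np.asarray(p + rng.normal(0.0, sig_p))))
    return ProportionParams(theta), NoiseParam(p)


def draw_initial_params(
    S: int, C: int, hyper: PriorHyperparams, rng: np.random.Generator
) -> tuple[ProportionParams, NoiseParam]:
    """Draw (theta, p) from their priors for S samples and C haplotypes."""
    if S < 1 or C < 0:
        raise ValueError("need S >= 1 and C >= 0")
    theta = np.empty((C + 1, S))
    theta[0] = rng.gamma(hyper.a0, 1.0, size=S)
    if C:
        theta[1:] = rng.gamma(hyper.a1, 1.0, size=(C, S))
    theta = np.maximum(theta, EPS)  # guard against underflow at tiny shapes
    p = float(rng.beta(hyper.a00, hyper.b00))
    p = min(max(p, EPS), 1.0 - EPS)
    return ProportionParams(theta), NoiseParam(p)
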