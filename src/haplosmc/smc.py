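"""Bootstrap particle filter for joint inference of haplotypes and proportions.

Each SNV row of the count matrices is one time step of a state-space
model: the hidden state at time ``t`` is the ``t``-th row of the binary
haplotype matrix Z (grown by the sequential IBP construction) and the
static parameters (theta, p) carry artificial Gaussian random-walk
dynamics.  Because the proposal is the state-transition prior, the
importance weight of a particle reduces to the binomial observation
likelihood of the current row (a bootstrap filter), and resampling is
performed at every step (:func:`step`).

A single forward pass leaves the early Z rows frozen at whatever the
first few selection steps happened to keep, and gives the parameters
only T jittered-selection steps — far too few to adapt in a blind
factorization.  Multiple passes therefore revisit every SNV with
*rejuvenation sweeps* (:func:`rejuvenation_sweep`): per-entry Gibbs
updates of each Z row under its IBP full conditional, Metropolis
random-walk moves on (theta, p), birth proposals for fresh columns,
posterior-based selection resampling of the cloud, and a greedy search
over column structures (merge / delete / split / residual birth) whose
candidates are scored with the proportions and row assignments profiled
out (NNLS refit plus exact 2^k-pattern row decode).  Sweeps run
interleaved with the forward pass while the running posterior is still
flat, and again after it, annealing a tempered likelihood toward the
exact one at high sequencing depth.  Independent forward restarts
(reporting the highest-evidence pass) remain available via
``FilterConfig(pass_mode="restart")``.

The cloud of N particles is stored *column-stacked*: one array per state
block with a leading particle axis, padded to a shared column capacity.
This is purely a performance representation — each particle evolves under
exactly the per-particle law defined in :mod:`haplosmc.ibp` and
:mod:`haplosmc.model`, and :meth:`ParticleCloud.particle` materializes any
single particle as a plain :class:`ParticleState`.  Row histories are kept
as per-step row records plus resampling ancestries and reconstructed on
demand, so resampling never copies the full Z block.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls
from scipy.special import expit, gammaln, logsumexp

from .ibp import HaplotypeMatrix, IBPConfig
from .model import (
    EPS,
    CountData,
    NoiseParam,
    PriorHyperparams,
    ProportionParams,
    binomial_logpmf,
    reflect_positive,
    reflect_unit,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FilterConfig",
    "ParticleState",
    "ParticleCloud",
    "FitResult",
    "init_particles",
    "step",
    "rejuvenation_sweep",
    "resample",
    "resample_indices",
    "run_filter",
    "summarize_posterior",
]


@dataclass(frozen=True)
class FilterConfig:
    """Settings of the particle filter.

    ``n_passes`` controls how often every SNV is visited.  With
    ``pass_mode="rejuvenate"`` (default) the first pass is the forward
    filter and each further pass is a warm-started rejuvenation sweep of
    the same cloud; with ``pass_mode="restart"`` the passes are
    independent forward runs from distinct sub-seeds and the pass with
    the highest accumulated log-evidence is reported.
    """

    n_particles: int = 500
    ibp: IBPConfig = field(default_factory=IBPConfig)
    hyper: PriorHyperparams = field(default_factory=PriorHyperparams)
    n_passes: int = 5
    seed: int = 0
    resampling: str = "multinomial"
    pass_mode: str = "rejuvenate"

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ValueError("need at least one particle")
        if self.n_passes < 1:
            raise ValueError("n_passes must be >= 1")
        if self.resampling not in ("multinomial", "systematic"):
            raise ValueError(f"unknown resampling scheme {self.resampling!r}")
        if self.pass_mode not in ("rejuvenate", "restart"):
            raise ValueError(f"unknown pass mode {self.pass_mode!r}")


@dataclass
class ParticleState:
    """One particle: its haplotype matrix, parameters and weight."""

    Z: HaplotypeMatrix
    params: ProportionParams
    noise: NoiseParam
    log_weight: float

    def __post_init__(self) -> None:
        if self.params.theta.shape[0] != self.Z.column_count + 1:
            raise ValueError(
                "theta must have one row per haplotype column plus background"
            )


class ParticleCloud:
    """Column-stacked cloud of N particles (see module docstring).

    Attributes
    ----------
    active : (N,) int
        Number of column slots ever opened per particle (monotone; slots
        whose count ``m_c`` has dropped to zero are dead but not reused).
    m : (N, Cmax) int
        Column popularity counts ``m_c`` (0 on padding and dead columns).
    theta : (N, Cmax + 1, S) float
        Positive proportion parameters; row 0 is the background.  Rows of
        dead or unopened slots are placeholders, re-drawn from the prior
        when a slot (re)activates.
    p : (N,) float
        Background noise rate per particle.
    """

    def __init__(self, n_particles: int, n_samples: int, capacity: int = 4):
        self.n = n_particles
        self.S = n_samples
        self.t = 0
        self.active = np.zeros(n_particles, dtype=np.int64)
        self.m = np.zeros((n_particles, capacity), dtype=np.int64)
        self.theta = np.ones((n_particles, capacity + 1, n_samples))
        self.p = np.full(n_particles, 0.01)
        self.weights = np.full(
            n_particles, 1.0 / n_particles if n_particles else 0.0
        )
        self.log_evidence = 0.0
        self.step_log_evidence: list[float] = []
        # row history: _rows[k] is the (N, width_k) pre-resampling row at
        # step k, _anc[k] the resampling indices applied after step k.
        self._rows: list[np.ndarray] = []
        self._anc: list[np.ndarray] = []
        self._base_Z: np.ndarray | None = None  # frozen history before t=1
        self._base_t = 0

    # -- capacity management -------------------------------------------------
    @property
    def capacity(self) -> int:
        return self.m.shape[1]

    def _grow(self, new_capacity: int) -> None:
        extra = new_capacity - self.capacity
        if extra <= 0:
            return
        self.m = np.concatenate(
            [self.m, np.zeros((self.n, extra), dtype=self.m.dtype)], axis=1
        )
        self.theta = np.concatenate(
            [self.theta, np.ones((self.n, extra, self.S))], axis=1
        )

    # -- derived quantities --------------------------------------------------
    def alive(self) -> np.ndarray:
        """(N, Cmax) mask of columns currently carried by at least one row."""
        return self.m > 0

    def n_columns(self) -> np.ndarray:
        """(N,) number of live haplotype columns per particle."""
        return self.alive().sum(axis=1)

    def row_mask(self) -> np.ndarray:
        """(N, Cmax + 1) mask of live theta rows (row 0 always)."""
        mask = np.empty((self.n, self.capacity + 1), dtype=bool)
        mask[:, 0] = True
        mask[:, 1:] = self.alive()
        return mask

    def weights_matrix(self) -> np.ndarray:
        """(N, Cmax + 1, S) derived W per particle; dead rows are 0."""
        masked = np.where(self.row_mask()[:, :, None], self.theta, 0.0)
        return masked / masked.sum(axis=1, keepdims=True)

    def reconstruct_Z(self) -> np.ndarray:
        """(N, t, Cmax) dense haplotype histories of the current particles,
        traced back through the resampling genealogy.  Dead columns appear
        as all-zero slots."""
        n_recorded = len(self._rows)
        Z = np.zeros((self.n, self.t, self.capacity), dtype=np.int8)
        cur = np.arange(self.n)
        for k in range(n_recorded - 1, -1, -1):
            cur = self._anc[k][cur]
            row = self._rows[k]
            Z[:, self._base_t + k, : row.shape[1]] = row[cur]
        if self._base_Z is not None and self._base_t:
            Z[:, : self._base_t, : self._base_Z.shape[2]] = self._base_Z[cur]
        return Z

    def particle(self, i: int) -> ParticleState:
        """Materialize particle ``i`` (live columns only, creation order)."""
        keep = self.alive()[i]
        Z = self.reconstruct_Z()[i][:, keep]
        theta_rows = np.concatenate([[True], keep])
        return ParticleState(
            Z=HaplotypeMatrix(Z),
            params=ProportionParams(self.theta[i][theta_rows].copy()),
            noise=NoiseParam(float(self.p[i])),
            log_weight=float(np.log(self.weights[i])),
        )

    def compact(self) -> "ParticleCloud":
        """Freeze the row history into a dense base matrix, allowing the
        cloud to be extended later with new SNVs (online updating)."""
        dense = self.reconstruct_Z()
        self._base_Z = dense
        self._base_t = self.t
        self._rows = []
        self._anc = []
        return self

    def copy(self) -> "ParticleCloud":
        out = ParticleCloud(self.n, self.S, self.capacity)
        out.t = self.t
        out.active = self.active.copy()
        out.m = self.m.copy()
        out.theta = self.theta.copy()
        out.p = self.p.copy()
        out.weights = self.weights.copy()
        out.log_evidence = self.log_evidence
        out.step_log_evidence = list(self.step_log_evidence)
        out._rows = [r.copy() for r in self._rows]
        out._anc = [a.copy() for a in self._anc]
        out._base_Z = None if self._base_Z is None else self._base_Z.copy()
        out._base_t = self._base_t
        return out


def init_particles(
    config: FilterConfig, n_samples: int, rng: np.random.Generator
) -> ParticleCloud:
    """N particles with empty Z and (theta_0, p) drawn from the priors."""
    cloud = ParticleCloud(config.n_particles, n_samples)
    hyper = config.hyper
    cloud.theta[:, 0, :] = np.maximum(
        rng.gamma(hyper.a0, 1.0, size=(cloud.n, n_samples)), EPS
    )
    cloud.theta[:, 1:, :] = np.maximum(
        rng.gamma(hyper.a1, 1.0, size=(cloud.n, cloud.capacity, n_samples)), EPS
    )
    cloud.p = np.clip(rng.beta(hyper.a00, hyper.b00, size=cloud.n), EPS, 1 - EPS)
    cloud.weights = np.full(cloud.n, 1.0 / cloud.n)
    return cloud


def resample_indices(
    weights: np.ndarray,
    n: int,
    rng: np.random.Generator,
    scheme: str = "multinomial",
) -> np.ndarray:
    """Offspring indices with expected multiplicity ``n * w_i``."""
    weights = np.asarray(weights, dtype=float)
    total = weights.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError("weights must sum to a positive finite value")
    w = weights / total
    if scheme == "multinomial":
        return rng.choice(w.shape[0], size=n, p=w)
    if scheme == "systematic":
        positions = (rng.random() + np.arange(n)) / n
        return np.searchsorted(np.cumsum(w), positions).clip(max=w.shape[0] - 1)
    raise ValueError(f"unknown resampling scheme {scheme!r}")


def resample(
    cloud: ParticleCloud,
    normalized_weights: np.ndarray,
    rng: np.random.Generator,
    scheme: str = "multinomial",
) -> ParticleCloud:
    """Replace the cloud by equally weighted offspring.

    Offspring state blocks are fresh copies, so mutating one offspring
    never affects a sibling that shares its parent.
    """
    idx = resample_indices(normalized_weights, cloud.n, rng, scheme)
    _apply_resample(cloud, idx)
    return cloud


def _apply_resample(cloud: ParticleCloud, idx: np.ndarray) -> None:
    cloud.active = cloud.active[idx]
    cloud.m = cloud.m[idx]
    cloud.theta = cloud.theta[idx]
    cloud.p = cloud.p[idx]
    cloud.weights = np.full(cloud.n, 1.0 / cloud.n)
    # keep the genealogy consistent: one ancestry record per stored row;
    # an extra resample between steps composes into the latest record.
    if len(cloud._anc) < len(cloud._rows):
        cloud._anc.append(idx)
    elif cloud._anc:
        cloud._anc[-1] = cloud._anc[-1][idx]
    elif cloud._base_Z is not None:
        cloud._base_Z = cloud._base_Z[idx]


def _open_new_columns(
    cloud: ParticleCloud,
    n_new: np.ndarray,
    include: np.ndarray,
    rng: np.random.Generator,
    hyper: PriorHyperparams,
) -> np.ndarray:
    """Place each particle's fresh columns in unused slots (growing the
    shared capacity as needed), draw their theta rows from the prior, and
    return the completed next Z row."""
    need = int((cloud.active + n_new).max(initial=0))
    if need > cloud.capacity:
        pad = need - include.shape[1] + 4
        cloud._grow(cloud.capacity + pad)
        include = np.concatenate(
            [include, np.zeros((cloud.n, cloud.capacity - include.shape[1]), bool)],
            axis=1,
        )
    col_idx = np.arange(cloud.capacity)[None, :]
    new_mask = (col_idx >= cloud.active[:, None]) & (
        col_idx < (cloud.active + n_new)[:, None]
    )
    z = include | new_mask
    cloud.active = cloud.active + n_new
    n_total = int(n_new.sum())
    if n_total:
        cloud.theta[:, 1:, :][new_mask] = np.maximum(
            rng.gamma(hyper.a1, 1.0, size=(n_total, cloud.S)), EPS
        )
    return z


def _random_walk(cloud: ParticleCloud, hyper: PriorHyperparams,
                 rng: np.random.Generator) -> None:
    sig_t = hyper.eff_sigma_theta
    if sig_t > 0:
        cloud.theta = reflect_positive(
            cloud.theta + rng.normal(0.0, sig_t, cloud.theta.shape)
        )
    sig_p = hyper.eff_sigma_p
    if sig_p > 0:
        cloud.p = reflect_unit(cloud.p + rng.normal(0.0, sig_p, cloud.n))


def _row_log_likelihood(
    cloud: ParticleCloud, z: np.ndarray, y_row: np.ndarray, v_row: np.ndarray
) -> np.ndarray:
    """(N,) log p(y_t | z_t, W, p) per particle for one SNV row."""
    W = cloud.weights_matrix()
    p_ts = W[:, 0, :] * cloud.p[:, None] + np.einsum(
        "nc,ncs->ns", z.astype(float), W[:, 1:, :]
    )
    return binomial_logpmf(y_row[None, :], v_row[None, :], p_ts).sum(axis=1)


def _weigh_and_resample(
    cloud: ParticleCloud,
    log_w: np.ndarray,
    t: int,
    config: FilterConfig,
    rng: np.random.Generator,
) -> None:
    if not np.isfinite(log_w).any():
        raise RuntimeError(
            f"all particle weights vanished at SNV index {t}; "
            "the data row is impossible under every particle"
        )
    log_norm = float(logsumexp(log_w))
    step_evidence = log_norm - np.log(cloud.n)
    cloud.log_evidence += step_evidence
    cloud.step_log_evidence.append(step_evidence)
    cloud.weights = np.exp(log_w - log_norm)
    idx = resample_indices(cloud.weights, cloud.n, rng, config.resampling)
    _apply_resample(cloud, idx)


def step(
    cloud: ParticleCloud,
    t: int,
    y_row: np.ndarray,
    v_row: np.ndarray,
    config: FilterConfig,
    rng: np.random.Generator,
) -> ParticleCloud:
    """Advance the filter by one SNV (1-based time index ``t``).

    Per particle: sample the next Z row from the IBP conditional
    (existing column ``c`` with probability ``m_c / t``, then
    ``Pois(alpha / t)`` fresh columns with prior theta rows), random-walk
    the pre-existing parameters, weight by the binomial likelihood of the
    row, normalize, and resample.  The per-step normalizing constant is
    accumulated into ``cloud.log_evidence``.
    """
    if t != cloud.t + 1:
        raise ValueError(f"expected time index {cloud.t + 1}, got {t}")
    alpha = config.ibp.alpha
    include = rng.random(cloud.m.shape) < cloud.m / t
    n_new = rng.poisson(alpha / t, size=cloud.n)
    capped = n_new > config.ibp.max_new_columns
    if capped.any():
        logger.warning(
            "Poisson innovation cap %d hit by %d particle(s) at t=%d",
            config.ibp.max_new_columns, int(capped.sum()), t,
        )
        n_new = np.minimum(n_new, config.ibp.max_new_columns)
    _random_walk(cloud, config.hyper, rng)
    z = _open_new_columns(cloud, n_new, include, rng, config.hyper)
    cloud.m += z
    cloud._rows.append(z.astype(np.int8))
    cloud.t = t
    log_w = _row_log_likelihood(cloud, z, y_row, v_row)
    _weigh_and_resample(cloud, log_w, t, config, rng)
    return cloud


def _weights_of(theta: np.ndarray, m: np.ndarray) -> np.ndarray:
    """(N, cap + 1, S) simplex weights from theta given live-column counts."""
    mask = np.concatenate(
        [np.ones((m.shape[0], 1), dtype=bool), m > 0], axis=1
    )
    masked = np.where(mask[:, :, None], theta, 0.0)
    return masked / masked.sum(axis=1, keepdims=True)


def _theta_log_prior(theta, m, hyper) -> np.ndarray:
    """(N,) Gamma log-density of the live theta rows."""
    lp = ((hyper.a0 - 1.0) * np.log(theta[:, 0, :]) - theta[:, 0, :]).sum(axis=1)
    live = (m > 0)[:, :, None]
    rest = (hyper.a1 - 1.0) * np.log(theta[:, 1:, :]) - theta[:, 1:, :]
    return lp + np.where(live, rest, 0.0).sum(axis=(1, 2))


def _log_posterior(cloud, Z_dense, Y, V, config) -> np.ndarray:
    """(N,) log p(Z, theta, p | Y) up to data-only constants, used as the
    selection score between sweeps."""
    hyper = config.hyper
    alpha = config.ibp.alpha
    T = cloud.t
    W = cloud.weights_matrix()
    P = W[:, None, 0, :] * cloud.p[:, None, None] + np.einsum(
        "ntc,ncs->nts", Z_dense.astype(float), W[:, 1:, :]
    )
    P = np.clip(P, EPS, 1.0 - EPS)
    ll = (Y[None] * np.log(P) + (V - Y)[None] * np.log1p(-P)).sum(axis=(1, 2))
    lp = _theta_log_prior(cloud.theta, cloud.m, hyper)
    lp += (hyper.a00 - 1.0) * np.log(cloud.p) + (
        hyper.b00 - 1.0
    ) * np.log1p(-cloud.p)
    live = cloud.m > 0
    c_plus = live.sum(axis=1)
    harmonic = float((1.0 / np.arange(1, T + 1)).sum())
    with np.errstate(divide="ignore"):
        ibp = np.where(
            live,
            gammaln(T - cloud.m + 1) + gammaln(np.maximum(cloud.m, 1)) - gammaln(T + 1),
            0.0,
        ).sum(axis=1)
    if alpha > 0:
        ibp += c_plus * np.log(alpha)
    ibp -= alpha * harmonic
    return ll + lp + ibp


def rejuvenation_sweep(
    cloud: ParticleCloud,
    data: CountData,
    config: FilterConfig,
    rng: np.random.Generator,
    beta: float = 1.0,
) -> ParticleCloud:
    """Revisit every SNV of an already-filtered dataset once.

    The sweep starts with one selection step (resampling by the full
    log-posterior, culling chains the forward pass left stuck), then for
    each row ``t`` in order applies per-particle moves:

    * Gibbs on the row's entries: ``P(z_tc = 1 | rest)`` combines the
      conditional IBP inclusion probability ``m_c^{-t} / T`` with the
      row's likelihood ratio; columns no other row carries die here.
    * a Metropolis birth proposal of ``Pois(alpha / T)`` fresh columns
      whose theta rows are matched to the row's unexplained VAF.
    * periodically, random-walk Metropolis on each sample's theta column
      and on ``p`` (scale mixture ``sigma * {1, .., 0.01}`` so moves
      survive both flat and razor-sharp posteriors), followed by
      selection.

    After the row loop, configuration-level refinement alternates an
    NNLS refit of the proportions with a greedy structure search whose
    merge / delete / split / birth candidates are scored after a short
    refit-and-decode polish (:func:`_polish_config` inside).

    ``beta < 1`` tempers the likelihood (counts scaled down), smoothing
    the landscape during exploration; ``cloud.log_evidence`` is replaced
    by the post-sweep mean full log-posterior at ``beta = 1``, a
    comparable per-pass score.
    """
    T = cloud.t
    if T > data.n_loci:
        raise ValueError("cloud has more rows than the data provides")
    N, S = cloud.n, cloud.S
    hyper = config.hyper
    alpha = config.ibp.alpha
    # beta < 1 tempers the likelihood (counts scaled down), smoothing the
    # posterior landscape so structural moves can cross barriers that a
    # full-depth likelihood would freeze; beta = 1 is the exact target
    Y = data.variant_counts[:T] * beta
    V = data.total_counts[:T] * beta

    # materialize the dense history once; the sweep edits it in place
    Z = cloud.reconstruct_Z().astype(np.int8)
    cloud._base_Z, cloud._base_t = Z, T
    cloud._rows, cloud._anc = [], []

    # drop column slots dead in every particle: they cost einsum time
    keep = cloud.m.any(axis=0)
    if keep.size and not keep.all() and keep.sum() >= 2:
        Z = np.ascontiguousarray(Z[:, :, keep])
        cloud.m = np.ascontiguousarray(cloud.m[:, keep])
        theta_keep = np.concatenate([[True], keep])
        cloud.theta = np.ascontiguousarray(cloud.theta[:, theta_keep, :])
        cloud.active[:] = int(keep.sum())
        cloud._base_Z = Z

    def _select() -> None:
        # cull stuck chains: resample by the full posterior score
        nonlocal Z
        score = _log_posterior(cloud, Z, Y[:T], V[:T], config)
        idx = resample_indices(
            np.exp(score - score.max()), N, rng, config.resampling
        )
        _apply_resample(cloud, idx)
        Z = cloud._base_Z

    _select()

    small = T <= 500
    param_interval = max(1, T // 25) if small else max(1, T // 6)
    scales = np.array([1.0, 0.3, 0.1, 0.03, 0.01])

    def _param_moves() -> None:
        Zf = Z.astype(float)
        # per-sample block move on theta[:, :, s]
        for s in range(S):
            scale = hyper.eff_sigma_theta * rng.choice(scales, size=N)
            th_old = cloud.theta[:, :, s]
            th_new = reflect_positive(
                th_old + scale[:, None] * rng.normal(size=th_old.shape)
            )
            mask = np.concatenate([np.ones((N, 1), bool), cloud.m > 0], axis=1)
            Zs = Zf

            def _ll_s(th):
                masked = np.where(mask, th, 0.0)
                Ws = masked / masked.sum(axis=1, keepdims=True)
                p_t = Ws[:, :1] * cloud.p[:, None] + np.einsum(
                    "ntc,nc->nt", Zs, Ws[:, 1:]
                )
                p_t = np.clip(p_t, EPS, 1.0 - EPS)
                return (
                    Y[None, :, s] * np.log(p_t)
                    + (V - Y)[None, :, s] * np.log1p(-p_t)
                ).sum(axis=1)

            def _lp_s(th):
                lp = (hyper.a0 - 1.0) * np.log(th[:, 0]) - th[:, 0]
                rest = (hyper.a1 - 1.0) * np.log(th[:, 1:]) - th[:, 1:]
                return lp + np.where(cloud.m > 0, rest, 0.0).sum(axis=1)

            log_ratio = _ll_s(th_new) - _ll_s(th_old) + _lp_s(th_new) - _lp_s(th_old)
            accept = np.log(rng.random(N)) < log_ratio
            cloud.theta[:, :, s] = np.where(accept[:, None], th_new, th_old)
        # global move on p
        scale = hyper.eff_sigma_p * rng.choice(scales, size=N)
        p_new = reflect_unit(cloud.p + scale * rng.normal(size=N))
        W = cloud.weights_matrix()
        base = np.einsum("ntc,ncs->nts", Zf, W[:, 1:, :])

        def _ll_p(p):
            P = np.clip(W[:, None, 0, :] * p[:, None, None] + base, EPS, 1 - EPS)
            return (Y[None] * np.log(P) + (V - Y)[None] * np.log1p(-P)).sum(
                axis=(1, 2)
            )

        log_ratio = (
            _ll_p(p_new)
            - _ll_p(cloud.p)
            + (hyper.a00 - 1.0) * (np.log(p_new) - np.log(cloud.p))
            + (hyper.b00 - 1.0) * (np.log1p(-p_new) - np.log1p(-cloud.p))
        )
        accept = np.log(rng.random(N)) < log_ratio
        cloud.p = np.where(accept, p_new, cloud.p)

    for t in range(1, T + 1):
        y_t = Y[t - 1].astype(float)
        vy_t = (V[t - 1] - Y[t - 1]).astype(float)
        old = Z[:, t - 1, :].astype(np.int64)
        m_minus = cloud.m - old
        # Gibbs over the row's entries: P(z_tc = 1 | rest) combines the
        # conditional IBP inclusion probability m_c^{-t} / T with the
        # row's likelihood ratio.  Columns nobody else carries get prior
        # probability 0 and die here; births are proposed separately.
        W = _weights_of(cloud.theta, m_minus)
        w0p = W[:, 0, :] * cloud.p[:, None]
        z = old.copy()
        z[m_minus == 0] = 0  # columns no other row carries die immediately
        base = w0p + np.einsum("nc,ncs->ns", z.astype(float), W[:, 1:, :])
        with np.errstate(divide="ignore"):
            prior_logodds = np.log(m_minus) - np.log(T - m_minus)
        for c in range(cloud.capacity):
            w_c = W[:, 1 + c, :]
            if not w_c.any():
                continue
            b0 = np.clip(base - z[:, c, None] * w_c, EPS, 1 - EPS)
            b1 = np.clip(b0 + w_c, EPS, 1 - EPS)
            delta = (y_t * np.log(b1 / b0) + vy_t * np.log((1 - b1) / (1 - b0))).sum(
                axis=1
            )
            logit = prior_logodds[:, c] + delta
            z_new = (rng.random(N) < expit(logit)).astype(np.int64)
            moved = z_new != z[:, c]
            if moved.any():
                base = base + (z_new - z[:, c])[:, None] * w_c
                z[:, c] = z_new
        # birth move: Pois(alpha / T) fresh columns with prior theta rows,
        # accepted by the row's likelihood ratio
        n_new = np.minimum(
            rng.poisson(alpha / T, size=N), config.ibp.max_new_columns
        )
        if n_new.any():
            need = int((cloud.active + n_new).max())
            if need > cloud.capacity:
                old_cap = cloud.capacity
                cloud._grow(need + 4)
                pad = cloud.capacity - old_cap
                Z = np.concatenate(
                    [Z, np.zeros((N, T, pad), dtype=np.int8)], axis=2
                )
                cloud._base_Z = Z
                z = np.concatenate([z, np.zeros((N, pad), dtype=z.dtype)], axis=1)
                m_minus = np.concatenate(
                    [m_minus, np.zeros((N, pad), dtype=m_minus.dtype)], axis=1
                )
            col_idx = np.arange(cloud.capacity)[None, :]
            new_mask = (col_idx >= cloud.active[:, None]) & (
                col_idx < (cloud.active + n_new)[:, None]
            )
            # residual-matched birth: the fresh column's theta is set so
            # its derived proportion approximates the row's unexplained
            # VAF, making a useful column immediately adoptable
            with np.errstate(divide="ignore", invalid="ignore"):
                f_obs = np.where(V[t - 1] > 0, Y[t - 1] / np.maximum(V[t - 1], 1), 0.0)
            resid = np.clip(f_obs[None, :] - base, 0.005, 0.9)
            mask_rows = np.concatenate(
                [np.ones((N, 1), bool), m_minus + z > 0], axis=1
            )
            theta_tot = np.where(mask_rows[:, :, None], cloud.theta, 0.0).sum(axis=1)
            w_target = resid * np.exp(rng.normal(0.0, 0.25, size=resid.shape))
            w_target = np.clip(w_target, 0.001, 0.9)
            theta_row = w_target / (1.0 - w_target) * theta_tot
            theta_prop = cloud.theta.copy()
            idx_n, idx_c = np.nonzero(new_mask)
            theta_prop[idx_n, 1 + idx_c, :] = np.maximum(theta_row[idx_n], EPS)
            m_prop = m_minus + z + new_mask
            W_prop = _weights_of(theta_prop, m_prop)
            p1 = np.clip(
                W_prop[:, 0, :] * cloud.p[:, None]
                + np.einsum(
                    "nc,ncs->ns", (z | new_mask).astype(float), W_prop[:, 1:, :]
                ),
                EPS, 1 - EPS,
            )
            p0 = np.clip(base, EPS, 1 - EPS)
            delta = (y_t * np.log(p1 / p0) + vy_t * np.log((1 - p1) / (1 - p0))).sum(
                axis=1
            )
            birth_penalty = n_new * (np.log(alpha) - np.log(T))
            accept = (n_new > 0) & (np.log(rng.random(N)) < delta + birth_penalty)
            if accept.any():
                grow_mask = new_mask & accept[:, None]
                z = z | grow_mask
                cloud.theta[:, 1:, :][grow_mask] = theta_prop[:, 1:, :][grow_mask]
                cloud.active = np.where(accept, cloud.active + n_new, cloud.active)
        Z[:, t - 1, :] = z
        cloud.m = m_minus + z
        if t % param_interval == 0:
            _param_moves()
            if small or (t // param_interval) % 2 == 0:
                _select()
    def _nnls_refit() -> None:
        # EM-flavored refinement: for each distinct particle
        # configuration, refit the proportions by depth-weighted NNLS of
        # the observed VAF on the haplotype pattern (intercept for the
        # background term), then propose the refit to every particle
        # carrying that configuration; kept only where the full
        # posterior improves.
        live = cloud.m > 0
        f_obs = np.where(V[:T] > 0, Y[:T] / np.maximum(V[:T], 1), 0.0)
        sw = np.sqrt(np.maximum(V[:T].mean(axis=1), 1.0))
        groups: dict = {}
        for i in range(N):
            groups.setdefault(
                (Z[i].tobytes(), live[i].tobytes()), []
            ).append(i)
        items = sorted(groups.items(), key=lambda kv: -len(kv[1]))[:50]
        th_prop = cloud.theta.copy()
        p_prop = cloud.p.copy()
        for _, idxs in items:
            i0 = idxs[0]
            cols = np.flatnonzero(live[i0])
            k = cols.size
            if k == 0:
                continue
            A = np.empty((T, k + 1))
            A[:, 0] = 1.0
            A[:, 1:] = Z[i0][:, cols]
            Aw = A * sw[:, None]
            Wt = np.zeros((k + 1, S))
            for s_i in range(S):
                coef, _ = nnls(Aw, f_obs[:, s_i] * sw)
                Wt[:, s_i] = coef
            b0 = Wt[0]
            w_rest = Wt[1:]
            col_sum = w_rest.sum(axis=0)
            over = col_sum >= 0.999
            if over.any():
                w_rest[:, over] *= 0.999 / col_sum[over]
                col_sum = w_rest.sum(axis=0)
            w0 = 1.0 - col_sum
            p_s = np.clip(b0 / np.maximum(w0, 1e-6), EPS, 0.5)
            p_new = float(np.median(p_s))
            for i in idxs:
                jitter = np.exp(rng.normal(0.0, 0.02, size=(k + 1, S)))
                th = np.maximum(np.vstack([w0[None, :], w_rest]) * jitter, 1e-4)
                th_prop[i, 0, :] = th[0]
                th_prop[i, 1 + cols, :] = th[1:]
                p_prop[i] = min(
                    max(p_new * float(np.exp(rng.normal(0.0, 0.05))), EPS), 0.5
                )
        saved_th, saved_p = cloud.theta, cloud.p
        score0 = _log_posterior(cloud, Z, Y[:T], V[:T], config)
        cloud.theta, cloud.p = th_prop, p_prop
        score1 = _log_posterior(cloud, Z, Y[:T], V[:T], config)
        accept = score1 > score0
        cloud.theta = np.where(accept[:, None, None], th_prop, saved_th)
        cloud.p = np.where(accept, p_prop, saved_p)

    def _refit_W(Zk: np.ndarray) -> tuple[np.ndarray, float]:
        # depth-weighted NNLS of observed VAF on the pattern columns
        f_obs = np.where(V[:T] > 0, Y[:T] / np.maximum(V[:T], 1), 0.0)
        sw = np.sqrt(np.maximum(V[:T].mean(axis=1), 1.0))
        k = Zk.shape[1]
        A = np.empty((T, k + 1))
        A[:, 0] = 1.0
        A[:, 1:] = Zk
        Aw = A * sw[:, None]
        Wt = np.zeros((k + 1, S))
        for s_i in range(S):
            coef, _ = nnls(Aw, f_obs[:, s_i] * sw)
            Wt[:, s_i] = coef
        b0 = Wt[0]
        w_rest = Wt[1:]
        col_sum = w_rest.sum(axis=0)
        over = col_sum >= 0.999
        if over.any():
            w_rest[:, over] *= 0.999 / col_sum[over]
            col_sum = w_rest.sum(axis=0)
        w0 = 1.0 - col_sum
        p_new = float(np.median(np.clip(b0 / np.maximum(w0, 1e-6), EPS, 0.5)))
        W = np.vstack([w0[None, :], w_rest])
        return np.maximum(W, 1e-6), p_new

    def _soft_score(Zk: np.ndarray, Wk: np.ndarray, pk: float) -> float:
        # Marginal configuration score: rows are summed (not maximized)
        # over all 2^k patterns, so surplus columns gain nothing from
        # per-row overfitting, plus the parameter priors and the IBP
        # column terms, minus a Laplace (BIC-flavored) correction of
        # (S/2) log(T S) per column for the S proportion parameters the
        # refit profiles out — without it a noise-tracking column's
        # fitted optimum can outscore the truth at intermediate depth.
        k = Zk.shape[1]
        mk = Zk.sum(axis=0)
        pats = (
            (np.arange(2 ** k)[:, None] >> np.arange(k)[None, :]) & 1
        ).astype(np.int8)
        pi = np.clip(mk / T, 1e-12, 1 - 1e-12)
        prior = pats @ np.log(pi) + (1 - pats) @ np.log1p(-pi)
        Pmat = np.clip(Wk[0][None, :] * pk + pats @ Wk[1:], EPS, 1 - EPS)
        ll = Y @ np.log(Pmat).T + (V - Y) @ np.log1p(-Pmat).T
        row_marginal = float(logsumexp(ll + prior[None, :], axis=1).sum())
        th = np.maximum(Wk, 1e-6)
        lp = float(((hyper.a0 - 1.0) * np.log(th[0]) - th[0]).sum())
        lp += float(((hyper.a1 - 1.0) * np.log(th[1:]) - th[1:]).sum())
        lp += (hyper.a00 - 1.0) * np.log(pk) + (hyper.b00 - 1.0) * np.log1p(-pk)
        harmonic = float((1.0 / np.arange(1, T + 1)).sum())
        mk_pos = mk[mk > 0]
        ibp = float(
            (gammaln(T - mk_pos + 1) + gammaln(mk_pos) - gammaln(T + 1)).sum()
        )
        if alpha > 0:
            ibp += mk_pos.size * np.log(alpha)
        ibp -= alpha * harmonic
        occam = 0.5 * k * S * np.log1p(float(V.mean()) / 50.0)
        return row_marginal + lp + ibp - occam

    def _polish_config(Zk: np.ndarray, iters: int):
        """Refit proportions and re-decode rows to a fixed point.

        The decode enumerates all 2^k row patterns (k <= 10) and assigns
        each SNV its MAP pattern under the refit proportions and the
        conditional IBP inclusion odds; all-zero columns are dropped.
        The returned score is the *marginal* one (:func:`_soft_score`),
        which is immune to the extra-pattern overfitting a MAP decode
        would reward."""
        for _ in range(iters):
            if Zk.shape[1] == 0 or Zk.shape[1] > 10:
                break
            Wk, pk = _refit_W(Zk)
            k = Zk.shape[1]
            pats = (
                (np.arange(2 ** k)[:, None] >> np.arange(k)[None, :]) & 1
            ).astype(np.int8)
            mk = Zk.sum(axis=0)
            with np.errstate(divide="ignore"):
                lo = np.log(np.maximum(mk, 1e-300)) - np.log(
                    np.maximum(T - mk, 1e-300)
                )
            prior = pats @ lo
            Pmat = np.clip(Wk[0][None, :] * pk + pats @ Wk[1:], EPS, 1 - EPS)
            ll = Y @ np.log(Pmat).T + (V - Y) @ np.log1p(-Pmat).T
            choice = np.argmax(ll + prior[None, :], axis=1)
            Zk_new = pats[choice]
            # drop empty columns and columns whose refit proportion is
            # below the resolvable scale in every sample (they only track
            # noise; the flat likelihood would otherwise keep them via
            # the m_c/T prior odds)
            keep = (Zk_new.sum(axis=0) > 0) & (Wk[1:].max(axis=1) >= 0.01)
            Zk_new = Zk_new[:, keep]
            done = Zk_new.shape == Zk.shape and (Zk_new == Zk).all()
            Zk = Zk_new
            if done:
                break
        if Zk.shape[1] == 0:
            Wk = np.maximum(np.ones((1, S)), 1e-6)
            f_obs = np.where(V > 0, Y / np.maximum(V, 1), 0.0)
            pk = float(np.clip(np.median(f_obs), EPS, 0.5))
            return Zk, Wk, pk, _soft_score(Zk, Wk, pk)
        Wk, pk = _refit_W(Zk)
        return Zk, Wk, pk, _soft_score(Zk, Wk, pk)

    def _structure_em_search() -> None:
        # Greedy search over column structures with both the proportions
        # and the row patterns profiled out: every delete / merge
        # candidate is scored after a short refit-and-decode polish, so a
        # good structural change is not masked by stale assignments.
        nonlocal Z
        live = cloud.m > 0
        groups: dict = {}
        for i in range(N):
            groups.setdefault((Z[i].tobytes(), live[i].tobytes()), []).append(i)
        items = sorted(groups.items(), key=lambda kv: -len(kv[1]))[:4]
        for _, idxs in items:
            i0 = idxs[0]
            cols = np.flatnonzero(live[i0])
            if cols.size > 10:
                continue
            Zk, Wk, pk, best = _polish_config(Z[i0][:, cols].astype(np.int8), 5)
            best_ever = (Zk, Wk, pk, best)
            kicks = 1
            for _ in range(max(cols.size, 1) + 2):
                k = Zk.shape[1]
                if k < 1:
                    break
                cands = [np.delete(Zk, b, axis=1) for b in range(k)]
                for a_i in range(k):
                    for b_i in range(a_i + 1, k):
                        Zm = np.delete(Zk, b_i, axis=1)
                        Zm[:, a_i] = Zk[:, a_i] | Zk[:, b_i]
                        cands.append(Zm)
                # residual-guided candidates: split one column in two by
                # residual similarity, or open a column on misfit rows
                # residual-guided candidates; the marginal score (with
                # its complexity correction) rejects noise-driven ones
                f_obs = np.where(V > 0, Y / np.maximum(V, 1), 0.0)
                P_hat = Wk[0][None, :] * pk + Zk.astype(float) @ Wk[1:]
                R = f_obs - P_hat
                if k < 10:
                    for c_i in range(k):
                        rows_c = np.flatnonzero(Zk[:, c_i])
                        if rows_c.size < 4:
                            continue
                        Rc = R[rows_c]
                        proj = Rc @ Rc.sum(axis=0)
                        half = proj > np.median(proj)
                        if half.all() or not half.any():
                            continue
                        Zs = np.hstack([Zk, np.zeros((T, 1), np.int8)])
                        Zs[rows_c[half], c_i] = 0
                        Zs[rows_c[half], k] = 1
                        cands.append(Zs)
                    miss = np.abs(R).sum(axis=1)
                    bad = miss > miss.mean() + 2.0 * miss.std()
                    if bad.sum() >= 3:
                        Zb = np.hstack([Zk, np.zeros((T, 1), np.int8)])
                        Zb[bad, k] = 1
                        cands.append(Zb)
                best_c = None
                for Zc in cands:
                    Zc2, Wc, pc, sc = _polish_config(Zc, 3)
                    if best_c is None or sc > best_c[3]:
                        best_c = (Zc2, Wc, pc, sc)
                if best_c is None:
                    break
                if best_c[3] <= best:
                    # no improving move: allow a bounded worsening "kick"
                    # so the search can cross small posterior barriers
                    if kicks == 0 or best_c[3] < best - 150.0:
                        break
                    kicks -= 1
                Zk, Wk, pk, best = best_c
                if best > best_ever[3]:
                    best_ever = (Zk, Wk, pk, best)
            Zk, Wk, pk, best = best_ever
            k = Zk.shape[1]
            if k > cloud.capacity:
                continue
            for i in idxs:
                Z[i] = 0
                Z[i][:, :k] = Zk
                cloud.m[i] = 0
                cloud.m[i, :k] = Zk.sum(axis=0) if k else 0
                cloud.active[i] = max(cloud.active[i], k)
                jitter = np.exp(rng.normal(0.0, 0.01, size=Wk.shape))
                cloud.theta[i, 0, :] = Wk[0] * jitter[0]
                if k:
                    cloud.theta[i, 1 : 1 + k, :] = Wk[1:] * jitter[1:]
                cloud.p[i] = pk
        cloud._base_Z = Z

    def _structure_moves(n_rounds: int) -> None:
        # Metropolis merge / delete proposals on whole columns; these fix
        # duplicated or fragmented haplotypes that entrywise Gibbs cannot
        # reorganize (any single-entry path crosses a likelihood barrier)
        nonlocal Z
        rows = np.arange(N)
        for _ in range(n_rounds):
            live = cloud.m > 0
            n_live = live.sum(axis=1)
            score0 = _log_posterior(cloud, Z, Y[:T], V[:T], config)
            # pick two distinct live columns per particle (random keys)
            keys = np.where(live, rng.random(live.shape), -1.0)
            order = np.argsort(-keys, axis=1)
            a, b = order[:, 0], order[:, 1]
            can = n_live >= 2
            # merge: column a absorbs b (union of rows, theta summed)
            Zm = Z.copy()
            za = Zm[rows, :, a]
            zb = Zm[rows, :, b]
            Zm[rows, :, a] = np.where(can[:, None], za | zb, za)
            Zm[rows, :, b] = np.where(can[:, None], 0, zb)
            m_m = Zm.astype(np.int64).sum(axis=1)
            th_m = cloud.theta.copy()
            th_m[rows, 1 + a] = np.where(
                can[:, None],
                cloud.theta[rows, 1 + a] + cloud.theta[rows, 1 + b],
                cloud.theta[rows, 1 + a],
            )
            saved_m, saved_th = cloud.m, cloud.theta
            cloud.m, cloud.theta = m_m, th_m
            score_m = _log_posterior(cloud, Zm, Y[:T], V[:T], config)
            cloud.m, cloud.theta = saved_m, saved_th
            accept = can & (np.log(rng.random(N)) < score_m - score0)
            if accept.any():
                Z[accept] = Zm[accept]
                cloud.m = np.where(accept[:, None], m_m, cloud.m)
                cloud.theta = np.where(accept[:, None, None], th_m, cloud.theta)
                cloud._base_Z = Z
                score0 = np.where(accept, score_m, score0)
            # merge variant with averaged theta: right move when a true
            # haplotype got fragmented into complementary partial columns
            th_m2 = saved_th.copy()
            th_m2[rows, 1 + a] = 0.5 * (
                saved_th[rows, 1 + a] + saved_th[rows, 1 + b]
            )
            th_m2 = np.where(accept[:, None, None], cloud.theta, th_m2)
            cloud_m_now = cloud.m
            cloud_th_now = cloud.theta
            Zm2 = Z.copy()
            za = Zm2[rows, :, a]
            zb = Zm2[rows, :, b]
            can2 = can & ~accept
            Zm2[rows, :, a] = np.where(can2[:, None], za | zb, za)
            Zm2[rows, :, b] = np.where(can2[:, None], 0, zb)
            m_m2 = Zm2.astype(np.int64).sum(axis=1)
            cloud.m, cloud.theta = m_m2, th_m2
            score_m2 = _log_posterior(cloud, Zm2, Y[:T], V[:T], config)
            cloud.m, cloud.theta = cloud_m_now, cloud_th_now
            accept2 = can2 & (np.log(rng.random(N)) < score_m2 - score0)
            if accept2.any():
                Z[accept2] = Zm2[accept2]
                cloud.m = np.where(accept2[:, None], m_m2, cloud.m)
                cloud.theta = np.where(accept2[:, None, None], th_m2, cloud.theta)
                cloud._base_Z = Z
                score0 = np.where(accept2, score_m2, score0)
            # delete: drop column b entirely
            live = cloud.m > 0
            can = live.sum(axis=1) >= 1
            keys = np.where(live, rng.random(live.shape), -1.0)
            b = np.argmax(keys, axis=1)
            Zd = Z.copy()
            Zd[rows, :, b] = 0
            m_d = Zd.astype(np.int64).sum(axis=1)
            saved_m = cloud.m
            cloud.m = m_d
            score_d = _log_posterior(cloud, Zd, Y[:T], V[:T], config)
            cloud.m = saved_m
            accept = can & (np.log(rng.random(N)) < score_d - score0)
            if accept.any():
                Z[accept] = Zd[accept]
                cloud.m = np.where(accept[:, None], m_d, cloud.m)
                cloud._base_Z = Z

    _nnls_refit()
    _structure_em_search()
    _select()
    for j in range(4 if small else 3):
        _param_moves()
        if small:
            _structure_moves(1)
        _nnls_refit()
        if small or j % 2 == 0:
            _select()
    _structure_em_search()
    _select()
    if small:
        _structure_moves(8)
    _nnls_refit()
    _param_moves()

    score = _log_posterior(
        cloud, Z, data.variant_counts[:T], data.total_counts[:T], config
    )
    cloud.log_evidence = float(score.mean())
    cloud.weights = np.full(N, 1.0 / N)
    return cloud


@dataclass
class FitResult:
    """Point estimates and the posterior particle cloud of one fit."""

    Z_hat: np.ndarray
    W_hat: np.ndarray
    p_hat: float
    C_hat: int
    particle_cloud: ParticleCloud
    log_evidence: float
    pass_log_evidences: list[float]
    config: FilterConfig


def _greedy_match(ref_Z: np.ndarray, Z_i: np.ndarray) -> np.ndarray:
    """Greedy column matching by history overlap (ties: creation order).

    Returns ``perm`` with ``perm[a] = b``: reference column ``a`` is
    matched to column ``b`` of the particle.
    """
    C = ref_Z.shape[1]
    agree = (ref_Z[:, :, None] == Z_i[:, None, :]).sum(axis=0)  # (C_ref, C_i)
    perm = np.empty(C, dtype=np.int64)
    free_a = np.ones(C, dtype=bool)
    free_b = np.ones(Z_i.shape[1], dtype=bool)
    work = agree.astype(float)
    for _ in range(C):
        masked = np.where(free_a[:, None] & free_b[None, :], work, -1.0)
        a, b = np.unravel_index(np.argmax(masked), masked.shape)
        perm[a] = b
        free_a[a] = False
        free_b[b] = False
    return perm


def summarize_posterior(
    cloud: ParticleCloud, weights: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, float, int]:
    """Point estimates (Z_hat, W_hat, p_hat, C_hat) from a weighted cloud.

    C_hat is the weighted mode of the per-particle live column counts.
    Among the particles with that count, columns are aligned to the
    highest-weight particle by greedy history overlap; an entry of Z_hat
    is 1 when its weighted mean inclusion is at least 1/2, and W_hat /
    p_hat are weighted means over the same subset.  Columns of Z_hat that
    end up all-zero are dropped together with their W rows (the remaining
    columns are renormalized to the simplex).
    """
    if cloud.n == 0:
        raise ValueError("empty particle cloud")
    w = cloud.weights if weights is None else np.asarray(weights, dtype=float)
    w = w / w.sum()
    counts = cloud.n_columns()
    levels, inverse = np.unique(counts, return_inverse=True)
    mass = np.bincount(inverse, weights=w)
    C_hat = int(levels[np.argmax(mass)])
    sub = np.flatnonzero(counts == C_hat)
    w_sub = w[sub]
    w_sub = w_sub / w_sub.sum()
    T = cloud.t
    S = cloud.S

    p_hat = float(w_sub @ cloud.p[sub])
    if C_hat == 0:
        return np.zeros((T, 0), dtype=np.int8), np.ones((1, S)), p_hat, 0

    dense = cloud.reconstruct_Z()
    Wmat = cloud.weights_matrix()
    live = cloud.alive()
    ref = sub[int(np.argmax(w_sub))]
    ref_Z = dense[ref][:, live[ref]]
    z_acc = np.zeros((T, C_hat))
    w_acc = np.zeros((C_hat + 1, S))
    for j, i in enumerate(sub):
        Z_i = dense[i][:, live[i]]
        perm = _greedy_match(ref_Z, Z_i)
        z_acc += w_sub[j] * Z_i[:, perm]
        w_acc[0] += w_sub[j] * Wmat[i, 0]
        w_i = Wmat[i, 1:][live[i]]
        w_acc[1:] += w_sub[j] * w_i[perm]

    Z_hat = (z_acc >= 0.5).astype(np.int8)
    keep = Z_hat.any(axis=0)
    Z_hat = Z_hat[:, keep]
    W_hat = np.vstack([w_acc[:1], w_acc[1:][keep]])
    W_hat = W_hat / W_hat.sum(axis=0, keepdims=True)
    return Z_hat, W_hat, p_hat, int(keep.sum())


def run_filter(
    data: CountData,
    config: FilterConfig,
    initial_cloud: ParticleCloud | None = None,
) -> FitResult:
    """Run the filter over all SNV rows of ``data``.

    In the default ``rejuvenate`` mode the first pass is the forward
    bootstrap filter and passes 2..n_passes are warm-started rejuvenation
    sweeps of the same cloud; the final cloud is summarized.  In
    ``restart`` mode the passes are independent forward runs from
    distinct sub-seeds and the pass with the highest accumulated
    log-evidence is summarized.  If ``initial_cloud`` is given (e.g., the
    cloud of a previous fit), the forward pass continues from a copy of
    it at ``t = initial_cloud.t + 1``, which realizes online updating
    with newly sequenced SNVs; rejuvenation sweeps then revisit the full
    combined history.
    """
    if data.n_loci < 1:
        raise ValueError("data must contain at least one SNV row")
    Y, V = data.variant_counts, data.total_counts
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_passes)

    def _forward(rng: np.random.Generator) -> ParticleCloud:
        if initial_cloud is None:
            cloud = init_particles(config, data.n_samples, rng)
        else:
            cloud = initial_cloud.copy().compact()
            cloud.log_evidence = 0.0
            cloud.step_log_evidence = []
        t0 = cloud.t
        for i in range(data.n_loci):
            step(cloud, t0 + i + 1, Y[i], V[i], config, rng)
        return cloud

    evidences: list[float] = []
    if config.pass_mode == "restart":
        best_cloud: ParticleCloud | None = None
        for k, seed in enumerate(seeds):
            cloud = _forward(np.random.default_rng(seed))
            evidences.append(cloud.log_evidence)
            logger.info("pass %d/%d (restart): log evidence %.3f",
                        k + 1, config.n_passes, cloud.log_evidence)
            if best_cloud is None or cloud.log_evidence > best_cloud.log_evidence:
                best_cloud = cloud
        final = best_cloud
    else:
        rng = np.random.default_rng(seeds[0])
        if initial_cloud is None:
            final = init_particles(config, data.n_samples, rng)
        else:
            final = initial_cloud.copy().compact()
            final.log_evidence = 0.0
            final.step_log_evidence = []
        t0 = final.t
        # interleaved rejuvenation: while the posterior over the first t
        # rows is still flat, sweeps are cheap and keep the cloud close
        # to the running posterior (resample-move filtering)
        mean_depth = max(float(data.total_counts.mean()), 1.0)
        beta_explore = min(1.0, 50.0 / mean_depth)
        next_sweep = 8
        for i in range(data.n_loci):
            step(final, t0 + i + 1, Y[i], V[i], config, rng)
            if (initial_cloud is None and config.n_passes > 1
                    and final.t == next_sweep and final.t < data.n_loci
                    and final.t <= 512):
                rejuvenation_sweep(final, data, config, rng, beta=beta_explore)
                next_sweep += 8 if next_sweep < 64 else next_sweep
        evidences.append(final.log_evidence)
        logger.info("pass 1/%d (forward): log evidence %.3f",
                    config.n_passes, final.log_evidence)
        # Rejuvenation sweeps need count rows for the cloud's entire
        # history; when continuing from an earlier cloud only the new
        # rows are at hand, so sweeps are skipped (pass the combined
        # matrices through a fresh run to sweep everything).
        if initial_cloud is None:
            n_sweeps = config.n_passes - 1
            for k, seed in enumerate(seeds[1:], start=2):
                # anneal the tempering towards the exact likelihood
                frac = (k - 1) / max(n_sweeps - 1, 1)
                beta = beta_explore ** (1.0 - frac) if n_sweeps > 1 else 1.0
                rejuvenation_sweep(final, data, config,
                                   np.random.default_rng(seed), beta=beta)
                evidences.append(final.log_evidence)
                logger.info("pass %d/%d (sweep, beta=%.3g): log evidence %.3f",
                            k, config.n_passes, beta, final.log_evidence)
        elif config.n_passes > 1:
            logger.info("continuing from an existing cloud: rejuvenation "
                        "sweeps skipped (full count history unavailable)")
    assert final is not None
    Z_hat, W_hat, p_hat, C_hat = summarize_posterior(final)
    return FitResult(
        Z_hat=Z_hat,
        W_hat=W_hat,
        p_hat=p_hat,
        C_hat=C_hat,
        particle_cloud=final,
        log_evidence=final.log_evidence,
        pass_log_evidences=evidences,
        config=config,
    )
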