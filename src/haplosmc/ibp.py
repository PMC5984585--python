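"""Indian buffet process (IBP) prior over binary haplotype matrices.

The latent haplotype matrix ``Z`` has one row per SNV and an unbounded
number of columns, one per haplotype.  The IBP builds ``Z`` sequentially:
row ``t`` activates each existing column ``c`` independently with
probability ``m_c / t`` (``m_c`` = number of earlier rows carrying that
column) and then opens ``Pois(alpha / t)`` brand-new columns, each seen
for the first time in row ``t``.  Marginally, the distribution over the
*left-ordered* equivalence class of the resulting matrix has the closed
form evaluated by :func:`ibp_log_pmf`:

    P(Z) = alpha^{C+} / (prod_h C_h!) * exp(-alpha * H_T)
           * prod_c (T - m_c)! (m_c - 1)! / T!

with ``C+`` non-zero columns, ``H_T`` the T-th harmonic number and
``C_h`` the multiplicity of the column history ``h``.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

logger = logging.getLogger(__name__)

__all__ = [
    "IBPConfig",
    "HaplotypeMatrix",
    "PriorEvaluation",
    "sample_next_row",
    "append_row",
    "sample_matrix",
    "left_order",
    "ibp_log_pmf",
]


@dataclass(frozen=True)
class IBPConfig:
    """Configuration of the IBP prior.

    Parameters
    ----------
    alpha:
        Mass (dispersion) parameter controlling the expected number of
        haplotypes, ``E[C+] = alpha * H_T``.  Must be positive
        (``alpha = 0`` is permitted only to exercise degenerate cases).
    max_new_columns:
        Cap on the Poisson number of new columns opened at a single row,
        bounding particle memory.  The untruncated tail mass above 20 is
        negligible for any ``alpha <= 2``; hitting the cap is logged.
    """

    alpha: float = 1.0
    max_new_columns: int = 20

    def __post_init__(self) -> None:
        if not np.isfinite(self.alpha) or self.alpha < 0:
            raise ValueError(f"alpha must be >= 0 and finite, got {self.alpha}")
        if self.max_new_columns < 1:
            raise ValueError("max_new_columns must be >= 1")


@dataclass
class HaplotypeMatrix:
    """A binary SNV-by-haplotype matrix with rows added sequentially."""

    entries: np.ndarray

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries)
        if entries.ndim != 2:
            raise ValueError("entries must be a 2-d array")
        if entries.size and not np.isin(entries, (0, 1)).all():
            raise ValueError("entries must be binary")
        self.entries = entries.astype(np.int8)

    @classmethod
    def empty(cls, n_rows: int = 0) -> "HaplotypeMatrix":
        return cls(np.zeros((n_rows, 0), dtype=np.int8))

    @property
    def row_count(self) -> int:
        return self.entries.shape[0]

    @property
    def column_count(self) -> int:
        return self.entries.shape[1]

    @property
    def column_counts(self) -> np.ndarray:
        """Number of ones ``m_c`` per column."""
        return self.entries.sum(axis=0)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HaplotypeMatrix):
            return NotImplemented
        return self.entries.shape == other.entries.shape and bool(
            (self.entries == other.entries).all()
        )


@dataclass(frozen=True)
class PriorEvaluation:
    """Result of evaluating the left-ordered IBP pmf on a matrix."""

    log_pmf: float
    c_plus: int
    harmonic_T: float
    history_counts: dict = field(default_factory=dict)


def sample_next_row(
    previous: HaplotypeMatrix,
    t: int,
    config: IBPConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Draw row ``t`` of ``Z`` given the first ``t - 1`` rows.

    Row indices are 1-based: the first row is ``t = 1`` and sees no
    existing columns.  Existing column ``c`` is included with probability
    ``m_c / t``; then ``n_new ~ Pois(alpha / t)`` new columns are opened,
    each set to 1 in this row.

    Returns
    -------
    (row, n_new):
        ``row`` has length ``previous.column_count + n_new``.
    """
    if t < 1 or t != previous.row_count + 1:
        raise ValueError(
            f"row index t={t} inconsistent with a matrix of "
            f"{previous.row_count} rows (expected t={previous.row_count + 1})"
        )
    m = previous.column_counts
    existing = (rng.random(m.shape[0]) < m / t).astype(np.int8)
    n_new = int(rng.poisson(config.alpha / t))
    if n_new > config.max_new_columns:
        logger.warning(
            "Poisson innovation %d at t=%d exceeds cap %d; truncating",
            n_new, t, config.max_new_columns,
        )
        n_new = config.max_new_columns
    row = np.concatenate([existing, np.ones(n_new, dtype=np.int8)])
    return row, n_new


def append_row(previous: HaplotypeMatrix, row: np.ndarray) -> HaplotypeMatrix:
    """Extend ``previous`` with a sampled row, zero-padding old rows for
    any newly opened columns."""
    row = np.asarray(row, dtype=np.int8)
    n_new = row.shape[0] - previous.column_count
    if n_new < 0:
        raise ValueError("row is shorter than the existing column count")
    padded = np.zeros((previous.row_count, row.shape[0]), dtype=np.int8)
    padded[:, : previous.column_count] = previous.entries
    return HaplotypeMatrix(np.vstack([padded, row[None, :]]))


def sample_matrix(
    n_rows: int, config: IBPConfig, rng: np.random.Generator
) -> HaplotypeMatrix:
    """Draw a full T-row matrix by running the sequential process."""
    Z = HaplotypeMatrix.empty()
    for t in range(1, n_rows + 1):
        row, _ = sample_next_row(Z, t, config, rng)
        Z = append_row(Z, row)
    return Z


def left_order(Z: HaplotypeMatrix | np.ndarray) -> HaplotypeMatrix | np.ndarray:
    """Sort columns by decreasing binary-history magnitude.

    The history of a column is the binary number it spells when read
    top-to-bottom with the first row as most significant bit.  Sorting is
    stable, so columns with identical histories keep their relative order.
    """
    entries = Z.entries if isinstance(Z, HaplotypeMatrix) else np.asarray(Z)
    order = sorted(
        range(entries.shape[1]),
        key=lambda c: tuple(entries[:, c]),
        reverse=True,
    )
    out = entries[:, order]
    return HaplotypeMatrix(out) if isinstance(Z, HaplotypeMatrix) else out


def ibp_log_pmf(Z: HaplotypeMatrix | np.ndarray, config: IBPConfig) -> PriorEvaluation:
    """Log pmf of the left-ordered equivalence class of ``Z``.

    ``Z`` may be given in any column order; it is left-ordered
    internally.  All-zero columns are a contract violation (the
    sequential construction never materializes them).
    """
    entries = Z.entries if isinstance(Z, HaplotypeMatrix) else np.asarray(Z)
    T = entries.shape[0]
    if T < 1:
        raise ValueError("Z must have at least one row")
    m = entries.sum(axis=0)
    if (m == 0).any():
        raise ValueError("Z contains an all-zero column")
    ordered = left_order(entries)
    c_plus = ordered.shape[1]
    harmonic = float((1.0 / np.arange(1, T + 1)).sum())
    histories = Counter(tuple(int(v) for v in ordered[:, c]) for c in range(c_plus))

    if config.alpha == 0.0:
        log_alpha_term = 0.0 if c_plus == 0 else -np.inf
    else:
        log_alpha_term = c_plus * np.log(config.alpha)
    log_hist = sum(gammaln(k + 1) for k in histories.values())
    m_sorted = np.sort(m)[::-1]  # any order; product is symmetric
    log_cols = float(
        (gammaln(T - m_sorted + 1) + gammaln(m_sorted) - gammaln(T + 1)).sum()
    )
    log_pmf = float(log_alpha_term - log_hist - config.alpha * harmonic + log_cols)
    return PriorEvaluation(
        log_pmf=log_pmf,
        c_plus=int(c_plus),
        harmonic_T=harmonic,
        history_counts=dict(histories),
    )
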