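"""Permutation-matched recovery errors against simulated ground truth.

Because the factorization P = [p Z] . W is blind, estimated haplotype
columns carry no canonical order.  The haplotype error is therefore
minimized over column permutations of the estimate,

    e_Z = (1 / (T C)) sum_t sum_c |zhat_tc - z_tc|,

and the selected permutation is reused for the proportion error

    e_W = (1 / (C S)) sum_{c=0..C} sum_s |what_cs - w_cs|

(the background row enters the sum; the denominator uses the true C, as
the formulas are printed) and for the expected-VAF error

    e_pts = (1 / (T S)) sum_t sum_s |phat_ts - p_ts|,

with ``phat_ts`` rebuilt from the matched point estimates.  When the
estimated and true column counts differ, the narrower matrix is
zero-padded (with matching zero W rows) before the permutation search,
so both missed and spurious haplotypes are penalized while the printed
denominators keep the errors on the original scale.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .simulate import SimulationTruth

logger = logging.getLogger(__name__)

__all__ = ["ErrorReport", "match_columns", "compute_errors", "compute_errors_arrays"]

#: largest padded column count for which the permutation search is exhaustive
MAX_EXHAUSTIVE = 9


@dataclass(frozen=True)
class ErrorReport:
    e_Z: float
    e_W: float
    e_pts: float
    best_permutation: tuple
    C_hat_vs_C: tuple
    e_W_denominator: str = "C*S over rows c=0..C"


def _pad_columns(Z: np.ndarray, width: int) -> np.ndarray:
    if Z.shape[1] >= width:
        return Z
    return np.hstack([Z, np.zeros((Z.shape[0], width - Z.shape[1]), dtype=Z.dtype)])


def match_columns(Z_hat: np.ndarray, Z_true: np.ndarray) -> tuple:
    """Permutation of Z_hat columns minimizing the entrywise mismatch.

    Both matrices are zero-padded to the wider column count first.  Up to
    :data:`MAX_EXHAUSTIVE` columns every permutation is tried and ties
    break lexicographically; beyond that an assignment solve on the
    Hamming-cost matrix is used instead.

    Returns ``perm`` such that ``Z_hat[:, perm]`` aligns with ``Z_true``.
    """
    Z_hat = np.asarray(Z_hat)
    Z_true = np.asarray(Z_true)
    if Z_hat.shape[0] != Z_true.shape[0]:
        raise ValueError("row counts differ")
    K = max(Z_hat.shape[1], Z_true.shape[1])
    A = _pad_columns(Z_hat, K).astype(np.int16)
    B = _pad_columns(Z_true, K).astype(np.int16)
    cost = np.abs(A[:, :, None] - B[:, None, :]).sum(axis=0)  # (hat, true)
    if K > MAX_EXHAUSTIVE:
        logger.warning(
            "padded column count %d > %d: using assignment solver instead of "
            "exhaustive permutation search", K, MAX_EXHAUSTIVE,
        )
        rows, cols = linear_sum_assignment(cost)
        perm = np.empty(K, dtype=np.int64)
        perm[cols] = rows
        return tuple(int(i) for i in perm)
    best_perm = None
    best_cost = None
    for perm in itertools.permutations(range(K)):
        c = int(cost[perm, range(K)].sum())
        if best_cost is None or c < best_cost:
            best_cost = c
            best_perm = perm
    return tuple(best_perm)


def compute_errors_arrays(
    Z_hat: np.ndarray,
    W_hat: np.ndarray,
    p_hat: float,
    truth: SimulationTruth,
) -> ErrorReport:
    """Errors of raw point-estimate arrays against a simulation truth."""
    Z_true = truth.Z_true
    W_true = truth.W_true
    if Z_hat.shape[0] != Z_true.shape[0]:
        raise ValueError(
            f"locus counts differ: estimate {Z_hat.shape[0]}, truth {Z_true.shape[0]}"
        )
    T = Z_true.shape[0]
    C_true = Z_true.shape[1]
    C_hat = Z_hat.shape[1]
    S = W_true.shape[1]
    K = max(C_true, C_hat, 1)

    Zh = _pad_columns(np.asarray(Z_hat, dtype=np.int8), K)
    Zt = _pad_columns(np.asarray(Z_true, dtype=np.int8), K)
    Wh = np.vstack([W_hat, np.zeros((K - C_hat, S))])
    Wt = np.vstack([W_true, np.zeros((K - C_true, S))])

    perm = match_columns(Zh, Zt)
    Zm = Zh[:, perm]
    Wm = np.vstack([Wh[:1], Wh[1:][list(perm)]])

    denom_C = max(C_true, 1)
    e_Z = float(np.abs(Zm - Zt).sum() / (T * denom_C))
    e_W = float(np.abs(Wm - Wt).sum() / (denom_C * S))
    P_hat = Wm[0] * p_hat + Zm.astype(float) @ Wm[1:]
    e_pts = float(np.abs(P_hat - truth.P_true).sum() / (T * S))
    return ErrorReport(
        e_Z=e_Z,
        e_W=e_W,
        e_pts=e_pts,
        best_permutation=perm,
        C_hat_vs_C=(int(C_hat), int(C_true)),
    )


def compute_errors(fit, truth: SimulationTruth) -> ErrorReport:
    """Errors of a :class:`~haplosmc.smc.FitResult` against ground truth."""
    return compute_errors_arrays(fit.Z_hat, fit.W_hat, fit.p_hat, truth)
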