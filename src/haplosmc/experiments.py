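"""Simulation-study harness: depth sweep and locus-count sweep.

``reproduce_table`` simulates datasets under the generator, fits the
particle filter and tabulates the permutation-matched errors, either
across average sequencing depth (``table1``: T=60, C=4, S=10,
r in {20, 40, 50, 200, 1000, 10000}) or across locus count (``table2``:
C=4, S=3, T in {1000, 2000} at depth r=1000).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .evaluate import compute_errors
from .ibp import IBPConfig
from .simulate import SimulationConfig, simulate
from .smc import FilterConfig, run_filter

logger = logging.getLogger(__name__)

__all__ = ["reproduce_table", "TABLE1_DEPTHS", "TABLE2_LOCI", "TABLE2_DEPTH"]

TABLE1_DEPTHS = (20, 40, 50, 200, 1000, 10000)
TABLE2_LOCI = (1000, 2000)
#: Depth used for the locus-count sweep.  The study design leaves it
#: open; 1000 (from the depth-sweep set) reproduces the reported
#: error regime, while shallower depths are decode-noise limited.
TABLE2_DEPTH = 1000


def _sub_seed(base_seed: int, *key: int) -> int:
    ss = np.random.SeedSequence([int(base_seed), *[int(k) for k in key]])
    return int(ss.generate_state(1)[0] % (2**31))


def _run_cell(
    sim_config: SimulationConfig, filter_config: FilterConfig
) -> dict:
    data, truth = simulate(sim_config)
    fit = run_filter(data, filter_config)
    report = compute_errors(fit, truth)
    return {
        "e_pts": report.e_pts,
        "e_Z": report.e_Z,
        "e_W": report.e_W,
        "C_hat": fit.C_hat,
        "p_hat": fit.p_hat,
        "log_evidence": fit.log_evidence,
    }


def reproduce_table(
    regime: str,
    n_seeds: int = 5,
    n_particles: int = 500,
    n_passes: int = 5,
    base_seed: int = 0,
    depths=None,
    loci=None,
    alpha: float = 1.0,
) -> pd.DataFrame:
    """Run one sweep and return a tidy per-seed DataFrame.

    Columns: the swept variable (``r`` or ``T``), ``seed``, and the three
    errors plus fit diagnostics.  Aggregate with a groupby-median.
    """
    if regime not in ("table1", "table2"):
        raise ValueError("regime must be 'table1' or 'table2'")
    records = []
    if regime == "table1":
        cells = list(depths) if depths is not None else list(TABLE1_DEPTHS)
        for ci, r in enumerate(cells):
            for k in range(n_seeds):
                sim = SimulationConfig(
                    T=60, S=10, C=4, r=float(r),
                    seed=_sub_seed(base_seed, 1, ci, k, 0),
                )
                cfg = FilterConfig(
                    n_particles=n_particles, n_passes=n_passes,
                    seed=_sub_seed(base_seed, 1, ci, k, 1),
                    ibp=IBPConfig(alpha=alpha),
                )
                rec = _run_cell(sim, cfg)
                rec.update({"r": r, "seed": k})
                records.append(rec)
                logger.info("table1 r=%s seed=%d: e_Z=%.4f e_W=%.4f e_pts=%.4f",
                            r, k, rec["e_Z"], rec["e_W"], rec["e_pts"])
    else:
        cells = list(loci) if loci is not None else list(TABLE2_LOCI)
        for ci, T in enumerate(cells):
            for k in range(n_seeds):
                sim = SimulationConfig(
                    T=int(T), S=3, C=4, r=float(TABLE2_DEPTH),
                    seed=_sub_seed(base_seed, 2, ci, k, 0),
                )
                cfg = FilterConfig(
                    n_particles=n_particles, n_passes=n_passes,
                    seed=_sub_seed(base_seed, 2, ci, k, 1),
                    ibp=IBPConfig(alpha=alpha),
                )
                rec = _run_cell(sim, cfg)
                rec.update({"T": T, "seed": k})
                records.append(rec)
                logger.info("table2 T=%s seed=%d: e_Z=%.4f e_W=%.4f e_pts=%.4f",
                            T, k, rec["e_Z"], rec["e_W"], rec["e_pts"])
    return pd.DataFrame.from_records(records)
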