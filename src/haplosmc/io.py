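"""Reading count matrices and writing fit results.

Count matrices are tab-separated text: first column a locus identifier,
header row of sample names, integer cells.  The variant matrix Y and
total matrix V must carry identical labels, and every cell must satisfy
``0 <= y_ts <= v_ts``; violations are reported with the offending locus
and sample.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .model import CountData

__all__ = [
    "CountDataError",
    "read_counts",
    "write_counts",
    "write_fit",
    "write_truth",
    "read_truth",
    "file_digest",
]


class CountDataError(ValueError):
    """Malformed or inconsistent count-matrix input."""


def _read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        df = df.astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise CountDataError(f"{path}: non-integer cell ({exc})") from None
    return df


def read_counts(path_Y, path_V) -> CountData:
    """Load and cross-validate the variant (Y) and total (V) matrices."""
    dfY = _read_matrix(path_Y)
    dfV = _read_matrix(path_V)
    if list(dfY.index) != list(dfV.index) or list(dfY.columns) != list(dfV.columns):
        raise CountDataError(
            f"locus/sample labels differ between {path_Y} and {path_V}"
        )
    Y = dfY.to_numpy()
    V = dfV.to_numpy()
    if (Y < 0).any() or (V < 0).any():
        t, s = np.argwhere((Y < 0) | (V < 0))[0]
        raise CountDataError(
            f"negative count at locus {dfY.index[t]!r}, sample {dfY.columns[s]!r}"
        )
    if (Y > V).any():
        t, s = np.argwhere(Y > V)[0]
        raise CountDataError(
            f"variant count exceeds total count at locus {dfY.index[t]!r}, "
            f"sample {dfY.columns[s]!r} (y={Y[t, s]}, v={V[t, s]})"
        )
    return CountData(
        variant_counts=Y,
        total_counts=V,
        locus_ids=[str(i) for i in dfY.index],
        sample_ids=[str(c) for c in dfY.columns],
    )


def write_counts(data: CountData, path_Y, path_V) -> None:
    for M, path in ((data.variant_counts, path_Y), (data.total_counts, path_V)):
        pd.DataFrame(M, index=data.locus_ids, columns=data.sample_ids).to_csv(
            path, sep="\t", index_label="locus"
        )


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_fit(
    fit,
    out_dir,
    locus_ids=None,
    sample_ids=None,
    manifest: dict | None = None,
) -> dict:
    """Write Z_hat.tsv, W_hat.tsv, summary.json (and manifest.json).

    Returns the summary dictionary.  Haplotype columns are named
    ``C1..C<C_hat>`` with ``C0`` the background proportion row.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    C_hat = fit.C_hat
    T, S = fit.Z_hat.shape[0], fit.W_hat.shape[1]
    loci = list(locus_ids) if locus_ids is not None else [
        f"snv_{t + 1:04d}" for t in range(T)
    ]
    samples = list(sample_ids) if sample_ids is not None else [
        f"sample_{s + 1}" for s in range(S)
    ]
    hap_cols = [f"C{c}" for c in range(1, C_hat + 1)]
    pd.DataFrame(fit.Z_hat, index=loci, columns=hap_cols).to_csv(
        out / "Z_hat.tsv", sep="\t", index_label="locus"
    )
    pd.DataFrame(
        fit.W_hat, index=[f"C{c}" for c in range(C_hat + 1)], columns=samples
    ).to_csv(out / "W_hat.tsv", sep="\t", index_label="haplotype")
    summary = {
        "p_hat": fit.p_hat,
        "C_hat": fit.C_hat,
        "log_evidence": fit.log_evidence,
        "pass_log_evidences": list(fit.pass_log_evidences),
        "n_particles": fit.config.n_particles,
        "n_passes": fit.config.n_passes,
        "seed": fit.config.seed,
        "alpha": fit.config.ibp.alpha,
        "resampling": fit.config.resampling,
        "hyperparams": asdict(fit.config.hyper),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    if manifest is not None:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return summary


def write_truth(truth, out_dir, config=None) -> None:
    """Write the simulator ground truth as TSV/JSON next to the counts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    C = truth.Z_true.shape[1]
    pd.DataFrame(
        truth.Z_true, columns=[f"C{c}" for c in range(1, C + 1)]
    ).to_csv(out / "truth_Z.tsv", sep="\t", index_label="locus")
    pd.DataFrame(
        truth.W_true, index=[f"C{c}" for c in range(C + 1)]
    ).to_csv(out / "truth_W.tsv", sep="\t", index_label="haplotype")
    meta = {"p_true": truth.p_true}
    if config is not None:
        meta["config"] = asdict(config)
    (out / "truth_meta.json").write_text(json.dumps(meta, indent=2))


def read_truth(truth_dir):
    """Load ground truth written by :func:`write_truth`."""
    from .simulate import SimulationTruth

    d = Path(truth_dir)
    Z = pd.read_csv(d / "truth_Z.tsv", sep="\t", index_col=0).to_numpy().astype(np.int8)
    W = pd.read_csv(d / "truth_W.tsv", sep="\t", index_col=0).to_numpy()
    meta = json.loads((d / "truth_meta.json").read_text())
    p = float(meta["p_true"])
    P = W[0] * p + Z.astype(float) @ W[1:]
    return SimulationTruth(Z_true=Z, W_true=W, p_true=p, P_true=P)
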