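"""Readers/writers: headerless CSV matrices, JSON/YAML run configuration,
and fit-result serialization."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .optimizer import RunConfig

__all__ = [
    "read_binary_matrix",
    "read_matrix",
    "write_matrix",
    "load_config",
    "save_config",
    "export_fit_result",
]


class DataFormatError(ValueError):
    """Malformed input file (carries row/column context in the message)."""


def read_matrix(path):
    """Read a headerless comma-separated numeric matrix."""
    try:
        df = pd.read_csv(path, header=None)
    except Exception as exc:
        raise DataFormatError(f"{path}: cannot parse CSV ({exc})") from exc
    if df.isna().any().any():
        r, c = np.argwhere(df.isna().to_numpy())[0]
        raise DataFormatError(f"{path}: missing/ragged entry at row {r + 1}, "
                              f"column {c + 1}")
    return df.to_numpy(dtype=float)


def read_binary_matrix(path):
    """Read a headerless CSV matrix and validate 0/1 entries."""
    M = read_matrix(path)
    bad = np.argwhere(~np.isin(M, (0.0, 1.0)))
    if bad.size:
        r, c = bad[0]
        raise DataFormatError(f"{path}: non-binary value {M[r, c]!r} at "
                              f"row {r + 1}, column {c + 1}")
    return M.astype(np.int8)


def write_matrix(path, M, fmt="%.17g"):
    np.savetxt(path, np.atleast_2d(M), fmt=fmt, delimiter=",")


def load_config(path):
    """RunConfig from a JSON or YAML file (keys mirror RunConfig fields)."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        d = yaml.safe_load(text)
    else:
        d = json.loads(text)
    return RunConfig.from_dict(d)


def save_config(path, config):
    d = config.to_dict()
    if str(path).endswith((".yaml", ".yml")):
        Path(path).write_text(yaml.safe_dump(d))
    else:
        Path(path).write_text(json.dumps(d, indent=2))


def _float_list(a):
    return [float(x) for x in np.asarray(a).ravel()]


def export_fit_result(outdir, result, kind, extra=None):
    """Write a fitted model to `outdir`: a JSON summary (config echo, seed,
    stopping iteration, flat estimate at 17 significant digits) plus CSV
    parameter blocks."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    trace = result.trace
    layout = result.model.layout
    from . import __version__

    summary = {
        "kind": kind,
        "lvprox_version": __version__,
        "config": result.config.to_dict(),
        "n_iterations": int(trace.n_iterations),
        "stop_iteration": (int(trace.stop_iteration)
                           if trace.stop_iteration else None),
        "variant": trace.variant,
        "blocks": {name: [int(sl.start), int(sl.stop)]
                   for name, sl in layout.block_map.items()},
        "estimate": _float_list(result.beta),
    }
    if extra:
        summary.update(extra)
    (outdir / "result.json").write_text(json.dumps(summary, indent=2))

    if trace.beta_history is not None:
        hist = pd.DataFrame(trace.beta_history,
                            columns=result.model.layout.param_names())
        hist.to_csv(outdir / "beta_history.csv", index=False)

    params = result.params
    if kind.startswith("ifa"):
        write_matrix(outdir / "d.csv", params.d)
        write_matrix(outdir / "A.csv", params.A)
        write_matrix(outdir / "B.csv", params.B)
        write_matrix(outdir / "Sigma.csv", params.sigma)
    else:
        write_matrix(outdir / "theta.csv", params.theta)
        write_matrix(outdir / "nu.csv", params.nu)
    return outdir / "result.json"
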