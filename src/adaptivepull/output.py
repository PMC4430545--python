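"""File round-trips and run manifests.

TSV with full repr-precision floats is the canonical numeric
interchange; every run directory gets a JSON manifest listing the
emitted files, the config hash, the seed and the package version, so a
run is reconstructible from the manifest alone.  Timestamps live only in
the manifest — the data files themselves are byte-deterministic for a
fixed seed and config.
"""

from __future__ import annotations

import json
import time
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import __version__
from .curves import PMFCurve
from .errors import ConfigurationError
from .jarzynski import WorkEnsemble

__all__ = [
    "write_pmf_tsv",
    "read_pmf_tsv",
    "write_ensemble_tsv",
    "read_ensemble_tsv",
    "write_worktrace_tsv",
    "write_outputs",
]

_F = "%.17g"


def _fmt(x: float) -> str:
    return _F % x


def write_pmf_tsv(pmf: PMFCurve, path: str | Path, n_traj: Optional[int] = None) -> None:
    with open(path, "w") as fh:
        fh.write("lambda\tF\tn_traj\n")
        for lam, F in zip(pmf.lambdas, pmf.F):
            fh.write(f"{_fmt(lam)}\t{_fmt(F)}\t{n_traj if n_traj is not None else ''}\n")


def read_pmf_tsv(path: str | Path) -> PMFCurve:
    lams, Fs = [], []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["lambda", "F"]:
            raise ConfigurationError(f"{path}: not a PMF TSV (header {header})")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            lams.append(float(parts[0]))
            Fs.append(float(parts[1]))
    lam = np.array(lams)
    F = np.array(Fs)
    return PMFCurve(lam, F - F[0], float(lam[0]))


def write_ensemble_tsv(ensemble: WorkEnsemble, path: str | Path) -> None:
    """Work matrix as TSV; the one-line comment header carries T and grid."""
    with open(path, "w") as fh:
        grid = ",".join(_fmt(v) for v in ensemble.lambda_grid)
        fh.write(f"# T={_fmt(ensemble.temperature)} grid={grid}\n")
        for row in ensemble.works:
            fh.write("\t".join(_fmt(w) for w in row) + "\n")


def read_ensemble_tsv(path: str | Path) -> WorkEnsemble:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# T="):
            raise ConfigurationError(f"{path}: missing ensemble header")
        meta = header[2:].split(" grid=")
        T = float(meta[0][2:])
        grid = np.array([float(v) for v in meta[1].split(",")])
        rows = [[float(v) for v in line.split("\t")] for line in fh if line.strip()]
    return WorkEnsemble(grid, np.array(rows), T)


def write_worktrace_tsv(trace, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("time\tlambda\txi\tW\n")
        for t, lam, xi, W in zip(trace.times, trace.lambdas, trace.xis, trace.W):
            fh.write(f"{_fmt(t)}\t{_fmt(lam)}\t{_fmt(xi)}\t{_fmt(W)}\n")


def write_outputs(
    stage_results: Sequence,
    global_pmf: Optional[PMFCurve],
    outdir: str | Path,
    config=None,
    seed: Optional[int] = None,
) -> dict:
    """Write per-stage ensembles/PMFs plus the assembled profile and a
    JSON manifest; re-running with identical inputs overwrites the same
    byte-identical data files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    stage_log = []
    for res in stage_results:
        sdir = outdir / f"stage{res.stage}"
        sdir.mkdir(exist_ok=True)
        epath = sdir / "works.tsv"
        write_ensemble_tsv(res.ensemble, epath)
        ppath = sdir / "pmf.tsv"
        write_pmf_tsv(res.pmf, ppath, n_traj=res.ensemble.n_traj)
        files += [str(epath.relative_to(outdir)), str(ppath.relative_to(outdir))]
        stage_log.append(dict(res.record, stage=res.stage))
    if global_pmf is not None:
        gpath = outdir / "pmf.tsv"
        write_pmf_tsv(global_pmf, gpath, n_traj=stage_results[0].ensemble.n_traj)
        files.append(str(gpath.relative_to(outdir)))
    manifest = {
        "files": sorted(files),
        "config_hash": config.content_hash() if config is not None else None,
        "config": config.model_dump(exclude_none=True) if config is not None else None,
        "seed": seed,
        "version": __version__,
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": stage_log,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
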