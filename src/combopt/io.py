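"""Result serialization: JSON for single runs, CSV for sweeps/fronts/PCA,
plus a run manifest capturing config hash, seed and software version.

Numeric CSV content is formatted to 6 significant digits, so re-running with
an identical config and seed reproduces byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

import combopt
from combopt.cmaes import OptimizationResult
from combopt.sweep import ParetoPoint, PcaReport, SweepResult

_FLOAT_FMT = "%.6g"


def _write_manifest(outdir: Path, files: list[str], config_hash: str, seed) -> dict:
    manifest = {
        "files": sorted(files),
        "config_hash": config_hash,
        "seed": seed,
        "version": combopt.__version__,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def write_results(
    obj,
    outdir,
    config_hash: str = "",
    seed: int | None = None,
    stem: str | None = None,
) -> dict:
    """Serialize an OptimizationResult, SweepResult, Pareto front, or
    PcaReport under ``outdir`` and write a run manifest.  Returns the
    manifest dict (its ``files`` key lists everything written)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[str] = []

    if isinstance(obj, OptimizationResult):
        name = stem or "result"
        with open(outdir / f"{name}.json", "w") as fh:
            json.dump(obj.to_dict(), fh, indent=2)
        files.append(f"{name}.json")
        trace = pd.DataFrame(
            obj.trace, columns=["iteration", "best_objective", "sigma", "mean_dose_nM"]
        )
        trace.to_csv(outdir / f"{name}_trace.csv", index=False, float_format=_FLOAT_FMT)
        files.append(f"{name}_trace.csv")
    elif isinstance(obj, SweepResult):
        name = stem or "sweep"
        obj.to_frame().to_csv(
            outdir / f"{name}.csv", index=False, float_format=_FLOAT_FMT
        )
        files.append(f"{name}.csv")
    elif isinstance(obj, PcaReport):
        name = stem or "pca"
        obj.to_frame().to_csv(
            outdir / f"{name}.csv", index=False, float_format=_FLOAT_FMT
        )
        files.append(f"{name}.csv")
        proj_rows = [
            {
                "lambda": g.lam,
                "run": i,
                **{f"pc{j + 1}": g.projections[i, j] for j in range(g.projections.shape[1])},
            }
            for g in obj.groups
            for i in range(g.projections.shape[0])
        ]
        pd.DataFrame(proj_rows).to_csv(
            outdir / f"{name}_projections.csv", index=False, float_format=_FLOAT_FMT
        )
        files.append(f"{name}_projections.csv")
    elif isinstance(obj, list) and all(isinstance(p, ParetoPoint) for p in obj):
        name = stem or "pareto"
        df = pd.DataFrame(
            [
                {
                    "total_dose_nM": p.total_dose,
                    "proliferation": p.proliferation,
                    "lambda": p.lam,
                    "seed": p.seed,
                }
                for p in obj
            ],
            columns=["total_dose_nM", "proliferation", "lambda", "seed"],
        )
        df.to_csv(outdir / f"{name}.csv", index=False, float_format=_FLOAT_FMT)
        files.append(f"{name}.csv")
    else:
        raise TypeError(f"don't know how to serialize {type(obj).__name__}")

    manifest = _write_manifest(outdir, files, config_hash, seed)
    return manifest
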