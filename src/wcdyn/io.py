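"""Readers and writers for the study's tabular formats and run configs.

All matrices are label-indexed; the row order of the connectome file is the
canonical region order used by every downstream array (no hidden sorting).
Formats: adjacency and FC as labelled square CSV, region/density tables as
TSV, configuration as YAML, sweep outputs as long-format TSV plus a JSON
run manifest.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .evaluate import FCMatrix, SweepResult
from .model import Connectome, DensityMap, zscore_densities

__all__ = [
    "read_adjacency", "write_adjacency",
    "read_region_table", "write_region_table",
    "read_densities", "write_densities",
    "read_fc", "write_fc",
    "read_config", "write_config", "DEFAULT_CONFIG",
    "write_sweep", "write_manifest",
    "diagram_to_frame", "write_diagram",
]


# ---------------------------------------------------------------------------
# connectome
# ---------------------------------------------------------------------------

def read_adjacency(path, region_table=None) -> Connectome:
    """Load a labelled square binary CSV into a :class:`Connectome`.

    ``region_table`` (optional path) supplies anatomical groupings; absent
    regions default to an empty group.  Non-square shape, non-binary
    entries, self-loops and duplicate labels each raise a distinct error.
    """
    df = pd.read_csv(path, index_col=0)
    labels = [str(x) for x in df.index]
    if list(df.columns.astype(str)) != labels:
        raise ValueError(f"{path}: row and column labels differ "
                         "(matrix must be square and label-aligned)")
    if len(set(labels)) != len(labels):
        raise ValueError(f"{path}: duplicate region labels")
    A = df.to_numpy(dtype=float)
    if not np.isin(A, (0.0, 1.0)).all():
        bad = A[~np.isin(A, (0.0, 1.0))][0]
        raise ValueError(f"{path}: non-binary adjacency entry {bad!r}")
    if np.diagonal(A).any():
        raise ValueError(f"{path}: self-loops on the diagonal")
    groups = [""] * len(labels)
    if region_table is not None:
        tbl = read_region_table(region_table)
        missing = [x for x in labels if x not in tbl]
        if missing:
            raise ValueError(f"regions missing from region table: {missing}")
        groups = [tbl[x] for x in labels]
    return Connectome(A=A, labels=tuple(labels), groups=tuple(groups))


def write_adjacency(path, c: Connectome) -> None:
    pd.DataFrame(c.A.astype(int), index=list(c.labels),
                 columns=list(c.labels)).to_csv(path)


def read_region_table(path) -> dict:
    """TSV with columns 'region' and 'group' -> {region: group}."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("region", "group"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return dict(zip(df["region"], df["group"]))


def write_region_table(path, c: Connectome) -> None:
    pd.DataFrame({"region": list(c.labels),
                  "group": list(c.groups)}).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------

def read_densities(path, c: Connectome) -> DensityMap:
    """TSV with columns region, e_density, i_density, aligned to ``c``.

    Rows may appear in any order; they are aligned to the connectome's
    label order before z-scoring (z-scores are over exactly the loaded
    regions).  Missing regions and non-positive densities raise.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("region", "e_density", "i_density"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    df = df.set_index(df["region"].astype(str))
    missing = [x for x in c.labels if x not in df.index]
    if missing:
        raise ValueError(f"{path}: no densities for regions {missing}")
    extra = [x for x in df.index if x not in c.labels]
    if extra:
        raise ValueError(f"{path}: regions absent from connectome: {extra}")
    df = df.loc[list(c.labels)]
    return zscore_densities(df["e_density"].to_numpy(float),
                            df["i_density"].to_numpy(float))


def write_densities(path, c: Connectome, d: DensityMap) -> None:
    pd.DataFrame({"region": list(c.labels), "e_density": d.e_raw,
                  "i_density": d.i_raw}).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FC matrices
# ---------------------------------------------------------------------------

def read_fc(path) -> FCMatrix:
    df = pd.read_csv(path, index_col=0)
    labels = tuple(str(x) for x in df.index)
    if tuple(df.columns.astype(str)) != labels:
        raise ValueError(f"{path}: row and column labels differ")
    return FCMatrix(values=df.to_numpy(float), labels=labels)


def write_fc(path, fc: FCMatrix) -> None:
    pd.DataFrame(fc.values, index=list(fc.labels),
                 columns=list(fc.labels)).to_csv(path, float_format="%.10g")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

#: every tunable surfaced with its default; unknown keys are rejected
DEFAULT_CONFIG = {
    "paths": {"connectome": None, "regions": None, "densities": None,
              "target_fc": None, "out_dir": "results"},
    "regime": "limit_cycle",
    "params": None,            # explicit NodeParams dict overrides regime
    "units": "mV",             # or "SI" (s / V / V*s inputs)
    "G": 0.7,
    "B_e": None,               # None = regime default
    "sigma": 0.0,
    "simulation": {"dt": 0.1, "T": 1.2e5, "transient": 1000.0,
                   "noise_mu": 0.0, "noise_s": 1.3e-5,
                   "initial_state": "mid", "noise_on_i": True,
                   "store_every": 1},
    "sweep": {"G": [0.0, 1.0, 21], "B_e": [1.0, 5.0, 41],
              "sigma": [0.0, 1.0, 11]},
    "n_rep": 5,
    "n_perm": 199,
    "seed": 0,
    "tolerances": {"root_residual": 1e-9, "bisection": 1e-6,
                   "duplicate_root": 1e-5, "oscillation_amplitude": 1e-4},
}


def _merge_checked(defaults: dict, given: dict, path: str = "") -> dict:
    out = {}
    for key, dval in defaults.items():
        if key in given and isinstance(dval, dict) and given[key] is not None:
            if not isinstance(given[key], dict):
                raise ValueError(f"config field {path}{key} must be a mapping")
            out[key] = _merge_checked(dval, given[key], f"{path}{key}.")
        elif key in given:
            out[key] = given[key]
        else:
            out[key] = dval
    unknown = set(given) - set(defaults)
    if unknown:
        raise ValueError(
            f"unknown config keys: {sorted(path + k for k in unknown)}")
    return out


def read_config(path) -> dict:
    """Load a YAML run config, apply defaults, and reject unknown keys."""
    with open(path) as fh:
        given = yaml.safe_load(fh) or {}
    cfg = _merge_checked(DEFAULT_CONFIG, given)
    for key in ("n_rep", "n_perm", "seed"):
        if not isinstance(cfg[key], int) or isinstance(cfg[key], bool):
            raise ValueError(f"config field {key} must be an integer")
    if cfg["sigma"] < 0:
        raise ValueError("config field sigma must be >= 0")
    return cfg


def write_config(path, cfg: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# result products
# ---------------------------------------------------------------------------

def write_sweep(path, sw: SweepResult) -> None:
    """Long-format TSV: one row per (cell, replicate) with its seed and rho."""
    names = list(sw.axes)
    rows = []
    it = np.ndindex(*[len(sw.axes[n]) for n in names])
    for idx in it:
        for k, seed in enumerate(sw.seeds):
            row = {n: float(sw.axes[n][i]) for n, i in zip(names, idx)}
            row["replicate"] = k
            row["seed"] = seed
            row["rho"] = float(sw.scores[idx + (k,)])
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_manifest(path, cfg: dict, extra: dict | None = None) -> None:
    """Run manifest: config copy, package version, wall-clock timestamp."""
    from . import __version__

    payload = {"config": cfg, "package_version": __version__,
               "written_at": time.strftime("%Y-%m-%dT%H:%M:%S")}
    payload.update(extra or {})
    Path(path).write_text(json.dumps(payload, indent=2, default=str))


def diagram_to_frame(d) -> pd.DataFrame:
    """Long-format table (J_tot, E, I, branch_id, stability) of a diagram."""
    rows = []
    for bid, br in enumerate(d.branches):
        for k in range(len(br)):
            rows.append({"J_tot": br.J[k], "E": br.E[k], "I": br.I[k],
                         "branch_id": bid, "stability": br.stability[k]})
    return pd.DataFrame(rows)


def write_diagram(prefix, d) -> None:
    """TSV of branches plus a JSON sidecar with folds/hopfs/envelope."""
    prefix = Path(prefix)
    diagram_to_frame(d).to_csv(prefix.with_suffix(".tsv"), sep="\t",
                               index=False)
    side = {"J_range": list(d.J_range),
            "folds": [list(x) for x in d.folds],
            "hopfs": [list(x) for x in d.hopfs],
            "envelope": (d.envelope.tolist()
                         if d.envelope is not None else None),
            "params": d.params.to_dict()}
    prefix.with_suffix(".json").write_text(json.dumps(side, indent=2))
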