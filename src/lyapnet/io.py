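"""File I/O: headered TSV/CSV matrices, prior masks, configs, manifests.

Conventions: data matrices are replicates × metabolites with a metabolite
header row; square matrices (covariance, adjacency) carry both a header row
and a label column; fluctuation vectors are two columns (name, value).
Delimiter is sniffed from the extension (.tsv → tab, .csv → comma). Values
round-trip at 12 significant digits. Edge lists and masks refer to
metabolites by name, never by position.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ensemble import CommunityBounds
from .ga import GAConfig, PriorMask
from .pipeline import InferenceResult, ReplicateDataset

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_prior_mask",
    "write_prior_mask",
    "read_config",
    "write_config_template",
    "write_inference_result",
    "write_manifest",
]

_FLOAT_FMT = "%.17g"  # full float64 precision; spec floor is 12 significant digits


def _sep(path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix == ".csv":
        return ","
    if suffix in (".tsv", ".tab", ".txt"):
        return "\t"
    raise ValueError(f"cannot infer delimiter from extension '{suffix}'")


def _check_frame(df: pd.DataFrame, path) -> None:
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicate metabolite name '{dup}'")
    if df.isna().any().any():
        row = int(np.argwhere(df.isna().values)[0][0])
        col = df.columns[int(np.argwhere(df.isna().values)[0][1])]
        raise ValueError(f"{path}: missing or non-numeric cell at row {row}, column '{col}'")


def read_matrix(path, kind: str = "data"):
    """Read a typed matrix/vector file.

    kind="data" → ReplicateDataset; kind="covariance"/"adjacency" →
    (values, names) with the label column enforced; kind="fluctuation" →
    (vector, names).
    """
    path = Path(path)
    sep = _sep(path)
    if kind == "data":
        df = pd.read_csv(path, sep=sep)
        df = df.apply(pd.to_numeric, errors="coerce")
        _check_frame(df, path)
        return ReplicateDataset(
            values=df.values, names=[str(c) for c in df.columns]
        )
    if kind in ("covariance", "adjacency"):
        df = pd.read_csv(path, sep=sep, index_col=0)
        df = df.apply(pd.to_numeric, errors="coerce")
        _check_frame(df, path)
        names = [str(c) for c in df.columns]
        if [str(i) for i in df.index] != names:
            raise ValueError(
                f"{path}: row labels do not match column labels; a square "
                "matrix must carry identical metabolite order on both axes"
            )
        return df.values, names
    if kind == "fluctuation":
        df = pd.read_csv(path, sep=sep, index_col=0)
        df = df.apply(pd.to_numeric, errors="coerce")
        _check_frame(df, path)
        return df.values.ravel(), [str(i) for i in df.index]
    raise ValueError(f"unknown kind '{kind}'")


def write_matrix(path, values, names, kind: str = "data") -> None:
    """Write a typed matrix/vector file (see :func:`read_matrix`)."""
    path = Path(path)
    sep = _sep(path)
    values = np.asarray(values)
    if kind == "data":
        df = pd.DataFrame(values, columns=names)
        df.to_csv(path, sep=sep, index=False, float_format=_FLOAT_FMT)
    elif kind in ("covariance", "adjacency"):
        df = pd.DataFrame(values, index=names, columns=names)
        df.to_csv(path, sep=sep, float_format=_FLOAT_FMT)
    elif kind == "fluctuation":
        df = pd.DataFrame({"fluctuation": values}, index=names)
        df.index.name = "metabolite"
        df.to_csv(path, sep=sep, float_format=_FLOAT_FMT)
    else:
        raise ValueError(f"unknown kind '{kind}'")


def read_prior_mask(path, names: list[str]) -> PriorMask:
    """Read a 3-column (source, target, zero|nonzero) mask file.

    An entry (s, t, kind) refers to the directed influence s → t, i.e. the
    Jacobian entry ∂(dC_t/dt)/∂C_s. Duplicate rows are deduplicated with a
    warning; contradictory rows and unknown names are errors.
    """
    path = Path(path)
    n = len(names)
    index = {name: i for i, name in enumerate(names)}
    try:
        df = pd.read_csv(path, sep=_sep(path), header=None, comment="#",
                         names=["source", "target", "kind"], skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        return PriorMask()
    if df.empty:
        return PriorMask()
    known_zero: set[int] = set()
    known_nonzero: set[int] = set()
    seen: set[tuple[int, str]] = set()
    for row in df.itertuples(index=False):
        for name in (row.source, row.target):
            if name not in index:
                raise ValueError(f"{path}: unknown metabolite '{name}'")
        kind = str(row.kind).strip().lower()
        if kind not in ("zero", "nonzero"):
            raise ValueError(f"{path}: mask kind must be zero|nonzero, got '{row.kind}'")
        pos = index[row.target] + index[row.source] * n  # J[target, source]
        if (pos, kind) in seen:
            warnings.warn(
                f"{path}: duplicate mask entry {row.source}->{row.target} ({kind})",
                stacklevel=2,
            )
            continue
        seen.add((pos, kind))
        (known_zero if kind == "zero" else known_nonzero).add(pos)
    overlap = known_zero & known_nonzero
    if overlap:
        raise ValueError(
            f"{path}: contradictory entries (both zero and nonzero) at "
            f"positions {sorted(overlap)}"
        )
    return PriorMask(known_zero=frozenset(known_zero), known_nonzero=frozenset(known_nonzero))


def write_prior_mask(path, mask: PriorMask, names: list[str]) -> None:
    # vector position = target + source*n, so source = pos // n, target = pos % n
    n = len(names)
    rows = []
    for pos in sorted(mask.known_zero):
        rows.append((names[pos // n], names[pos % n], "zero"))
    for pos in sorted(mask.known_nonzero):
        rows.append((names[pos // n], names[pos % n], "nonzero"))
    pd.DataFrame(rows).to_csv(path, sep=_sep(path), header=False, index=False)


def read_config(path) -> tuple[GAConfig, CommunityBounds]:
    """Load GA settings and community bounds from a YAML config file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    ga_raw = dict(raw.get("ga", {}))
    if "lambda_grid" in ga_raw:
        ga_raw["lambda_grid"] = tuple(float(x) for x in ga_raw["lambda_grid"])
    bounds_raw = raw.get("community", {})
    return GAConfig(**ga_raw), CommunityBounds(**bounds_raw)


def write_config_template(path, cfg: GAConfig | None = None,
                          bounds: CommunityBounds | None = None) -> None:
    """Write a config file with all tunable settings and their defaults."""
    cfg = cfg or GAConfig()
    bounds = bounds or CommunityBounds()
    payload = {
        "ga": {**dataclasses.asdict(cfg), "lambda_grid": [float(x) for x in cfg.lambda_grid]},
        "community": dataclasses.asdict(bounds),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def write_inference_result(outdir, result: InferenceResult) -> None:
    """Export a network: 0/1 adjacency TSV, SIF-style edge list, support.

    Edge list rows are (source, target, fitted elite Jacobian value): an
    edge source → target for every nonzero J[target, source] in the final
    structure.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    names = result.names
    n = len(names)
    write_matrix(outdir / "adjacency.tsv", result.structure.astype(int), names, kind="adjacency")
    write_matrix(outdir / "support.tsv", result.support, names, kind="adjacency")
    eliteJ = result.elite_jacobian()
    rows = []
    for i in range(n):  # J[i, j] != 0 means metabolite j influences i
        for j in range(n):
            if result.structure[i, j]:
                rows.append((names[j], names[i], eliteJ[i, j]))
    pd.DataFrame(rows, columns=["source", "target", "value"]).to_csv(
        outdir / "edges.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )


def write_manifest(outdir, config: dict, seed: int, inputs: dict | None = None) -> None:
    """Record config, seed, package version, and input checksums for a run."""
    from . import __version__

    checksums = {}
    for label, p in (inputs or {}).items():
        digest = hashlib.sha256(Path(p).read_bytes()).hexdigest()
        checksums[label] = {"path": str(p), "sha256": digest}
    manifest = {
        "package": "lyapnet",
        "version": __version__,
        "seed": seed,
        "config": config,
        "inputs": checksums,
    }
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
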