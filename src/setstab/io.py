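"""Text-file round-tripping for memberships, graphs, matrices, configs, and sweeps.

All text formats use 1-based species and set indices; the in-memory objects
are 0-based.  Dense matrices are headerless CSV with 17 significant digits
(lossless float round-trip); sparse matrices use Matrix Market coordinate
format.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

from .ensemble import EnsembleConfig
from .experiments import SweepPoint, SweepResult
from .structure import SetMembership, WithinSetGraph

__all__ = [
    "ParseError",
    "write_hyperedges",
    "read_hyperedges",
    "write_edges",
    "read_edges",
    "write_dense",
    "read_dense",
    "write_sparse",
    "read_sparse",
    "write_config",
    "read_config",
    "sweep_to_frame",
    "write_sweep",
    "read_sweep",
    "write_trajectories",
    "write_manifest",
]

FLOAT_FMT = "%.17g"


class ParseError(ValueError):
    """Malformed line in a text input, carrying the 1-based line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


# -- hyperedge lists ---------------------------------------------------------


def write_hyperedges(path, membership: SetMembership) -> None:
    """One line per set: ``set_id<TAB>member<TAB>member...`` (1-based indices)."""
    lines = []
    for g in range(membership.n_sets):
        members = membership.members_of(g) + 1
        lines.append("\t".join(str(v) for v in [g + 1, *members.tolist()]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_hyperedges(path, n_species: int | None = None) -> SetMembership:
    """Parse a hyperedge list and re-validate the row-sum-K invariant."""
    sets: dict[int, list[int]] = {}
    max_species = 0
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        fields = raw.split("\t")
        try:
            set_id = int(fields[0])
            members = [int(f) for f in fields[1:] if f != ""]
        except ValueError as exc:
            raise ParseError(path, lineno, f"non-integer field ({exc})") from None
        if set_id < 1 or any(m < 1 for m in members):
            raise ParseError(path, lineno, "indices must be 1-based positive integers")
        if set_id in sets:
            raise ParseError(path, lineno, f"duplicate set id {set_id}")
        sets[set_id] = members
        if members:
            max_species = max(max_species, max(members))
    if not sets:
        raise ParseError(path, 1, "no sets found")
    G = max(sets)
    S = n_species if n_species is not None else max_species
    incidence = np.zeros((S, G), dtype=np.int8)
    for set_id, members in sets.items():
        for m in members:
            incidence[m - 1, set_id - 1] = 1
    row_sums = incidence.sum(axis=1)
    K = int(row_sums[0])
    bad = np.flatnonzero(row_sums != K)
    if bad.size:
        raise ParseError(
            path, 1,
            f"species {bad[0] + 1} belongs to {int(row_sums[bad[0]])} sets "
            f"but species 1 belongs to {K}: row-sum-K invariant violated",
        )
    return SetMembership(incidence=incidence, sets_per_species=K)


# -- edge lists --------------------------------------------------------------


def write_edges(path, graphs: Iterable[WithinSetGraph]) -> None:
    """One line per edge: ``u<TAB>v<TAB>set_id`` (1-based indices)."""
    lines = []
    for g in graphs:
        for u, v in sorted(g.edges):
            lines.append(f"{u + 1}\t{v + 1}\t{g.set_id + 1}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_edges(path) -> list:
    """Parse an edge list back into one WithinSetGraph per set id."""
    by_set: dict[int, set] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        fields = raw.split("\t")
        if len(fields) != 3:
            raise ParseError(path, lineno, f"expected 3 fields, got {len(fields)}")
        try:
            u, v, set_id = (int(f) for f in fields)
        except ValueError as exc:
            raise ParseError(path, lineno, f"non-integer field ({exc})") from None
        if min(u, v, set_id) < 1:
            raise ParseError(path, lineno, "indices must be 1-based positive integers")
        by_set.setdefault(set_id - 1, set()).add((u - 1, v - 1))
    graphs = []
    for set_id in sorted(by_set):
        edges = by_set[set_id]
        members = tuple(sorted({n for e in edges for n in e}))
        graphs.append(WithinSetGraph(set_id=set_id, members=members, edges=frozenset(edges)))
    return graphs


# -- matrices ----------------------------------------------------------------


def write_dense(path, matrix) -> None:
    """Headerless CSV of S x S reals, 17 significant digits."""
    vals = getattr(matrix, "values", matrix)
    np.savetxt(path, np.asarray(vals, dtype=float), fmt=FLOAT_FMT, delimiter=",")


def read_dense(path) -> np.ndarray:
    arr = np.loadtxt(path, delimiter=",", ndmin=2)
    if arr.shape[0] != arr.shape[1]:
        raise ParseError(path, 1, f"matrix is not square: shape {arr.shape}")
    return arr


def write_sparse(path, matrix) -> None:
    """Matrix Market coordinate format (1-based row, col, value)."""
    vals = getattr(matrix, "values", matrix)
    scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(np.asarray(vals, dtype=float)))


def read_sparse(path) -> np.ndarray:
    arr = scipy.io.mmread(str(path)).toarray()
    if arr.shape[0] != arr.shape[1]:
        raise ParseError(path, 1, f"matrix is not square: shape {arr.shape}")
    return arr


# -- configs -----------------------------------------------------------------


def write_config(path, config: EnsembleConfig) -> None:
    """Flat YAML mapping mirroring the EnsembleConfig field names."""
    data = dataclasses.asdict(config)
    data["abundance_params"] = list(data["abundance_params"])
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def read_config(path) -> EnsembleConfig:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ParseError(path, 1, "config must be a flat key-value mapping")
    known = {f.name for f in dataclasses.fields(EnsembleConfig)}
    unknown = set(data) - known
    if unknown:
        raise ParseError(path, 1, f"unknown config keys: {sorted(unknown)}")
    if "abundance_params" in data and data["abundance_params"] is not None:
        data["abundance_params"] = tuple(data["abundance_params"])
    return EnsembleConfig(**data)


# -- sweeps & trajectories ---------------------------------------------------


def sweep_to_frame(sweep: SweepResult) -> pd.DataFrame:
    """Tidy table with one row per sweep point."""
    return pd.DataFrame(
        [
            {
                "n_sets": p.n_sets,
                "ratio": p.ratio,
                "mean_delta": p.mean_delta,
                "sd_delta": p.sd_delta,
                "n_replicates": p.n_replicates,
            }
            for p in sweep.points
        ]
    )


def write_sweep(path, sweep: SweepResult) -> None:
    sweep_to_frame(sweep).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_sweep(path) -> SweepResult:
    df = pd.read_csv(path, float_precision="round_trip")
    points = tuple(
        SweepPoint(
            n_sets=int(r.n_sets),
            ratio=float(r.ratio),
            mean_delta=float(r.mean_delta),
            sd_delta=float(r.sd_delta),
            n_replicates=int(r.n_replicates),
        )
        for r in df.itertuples()
    )
    return SweepResult(points=points)


def write_trajectories(path, result) -> None:
    """Long-format CSV: time, species (1-based), abundance."""
    S, T = result.trajectories.shape
    df = pd.DataFrame(
        {
            "time": np.repeat(result.time_grid, S),
            "species": np.tile(np.arange(1, S + 1), T),
            "abundance": result.trajectories.T.ravel(),
        }
    )
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def write_manifest(path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
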