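"""File I/O: parameter matrices, SAN specs, HT tensors, run orchestration.

Formats
-------
* Theta matrices: CSV/TSV (d rows x d columns, optional header row) or JSON
  ``{"d": ..., "theta": [[...]]}``.
* SAN specs: JSON with ``sizes``, ``transitions`` as ``[i, x_i, y_i]``
  triples (0-based) and per-transition dense effect tables.
* HT tensors: HDF5, one group per tree node holding the mode labels and the
  frame / transfer array; format tagged and versioned.
* Results: CSV logs (comma separator, '.' decimal, header row).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .models import (
    LocalTransition,
    ModelValidationError,
    SANSpec,
    ThetaMatrix,
    build_generator_cp,
    gamma_bound,
    mhn_to_san,
)
from .tree import DimensionTree, Node, balanced_tree
from .httensor import HTTensor, ht_unit
from .solver import SolverConfig, solve_marginal_lowrank
from .synthetic import BlockDesign, sample_theta

__all__ = [
    "read_theta",
    "write_theta",
    "read_sanspec",
    "write_sanspec",
    "save_ht",
    "load_ht",
    "RunConfig",
    "run_pipeline",
]

HT_FORMAT_TAG = "htmarginal-ht"
HT_FORMAT_VERSION = 1

logger = logging.getLogger("htmarginal")


def _parse_table(path: Path, sep: str) -> np.ndarray:
    raw = pd.read_csv(path, sep=sep, header=None, dtype=str, comment=None)
    values = raw.values
    # optional header row: drop it when any cell fails float conversion
    def row_numeric(row) -> bool:
        try:
            [float(c) for c in row]
            return True
        except (TypeError, ValueError):
            return False

    if values.shape[0] and not row_numeric(values[0]):
        values = values[1:]
    out = np.empty(values.shape, dtype=float)
    for i, row in enumerate(values):
        for j, cell in enumerate(row):
            try:
                out[i, j] = float(cell)
            except (TypeError, ValueError):
                raise ModelValidationError(
                    f"non-numeric cell at row {i}, column {j}: {cell!r}"
                ) from None
    return out


def read_theta(path: str | Path) -> ThetaMatrix:
    """Read a parameter matrix from CSV/TSV/JSON (validated on read)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        arr = np.asarray(data["theta"], dtype=float)
        if "d" in data and int(data["d"]) != arr.shape[0]:
            raise ModelValidationError("declared d does not match theta shape")
    else:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        arr = _parse_table(path, sep)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ModelValidationError(f"theta must be square, got shape {arr.shape}")
    neg = np.argwhere(arr < 0)
    if len(neg):
        i, j = map(int, neg[0])
        raise ModelValidationError(f"negative entry {arr[i, j]} at row {i}, column {j}")
    return ThetaMatrix(theta=arr)


def write_theta(theta: ThetaMatrix, path: str | Path) -> None:
    """Write a parameter matrix; format chosen by extension (CSV/TSV/JSON)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(
            json.dumps({"d": theta.d, "theta": theta.theta.tolist()}, indent=1)
        )
    else:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        np.savetxt(path, theta.theta, delimiter=sep, fmt="%.17g")


def read_sanspec(path: str | Path) -> SANSpec:
    """Read a generalized SAN spec from JSON."""
    data = json.loads(Path(path).read_text())
    transitions = [
        LocalTransition(automaton=int(i), source=int(x), target=int(y))
        for i, x, y in data["transitions"]
    ]
    effects = [
        [np.asarray(vec, dtype=float) for vec in table] for table in data["effects"]
    ]
    return SANSpec(
        sizes=[int(n) for n in data["sizes"]],
        transitions=transitions,
        effects=effects,
        is_mhn=bool(data.get("is_mhn", False)),
        theta=np.asarray(data["theta"], dtype=float) if "theta" in data else None,
    )


def write_sanspec(spec: SANSpec, path: str | Path) -> None:
    data = {
        "sizes": spec.sizes,
        "transitions": [[t.automaton, t.source, t.target] for t in spec.transitions],
        "effects": [[vec.tolist() for vec in table] for table in spec.effects],
        "is_mhn": spec.is_mhn,
    }
    if spec.theta is not None:
        data["theta"] = spec.theta.tolist()
    Path(path).write_text(json.dumps(data, indent=1))


def save_ht(x: HTTensor, path: str | Path) -> None:
    """Serialize an HT tensor to HDF5 (one group per tree node)."""
    with h5py.File(path, "w") as f:
        f.attrs["format"] = HT_FORMAT_TAG
        f.attrs["version"] = HT_FORMAT_VERSION
        f.attrs["d"] = x.tree.d
        f.attrs["sizes"] = x.sizes
        f.attrs["newick"] = x.tree.to_newick()
        for node in x.tree.nodes:
            g = f.create_group(f"node{node.index}")
            g.attrs["modes"] = list(node.modes)
            g.attrs["left"] = node.left
            g.attrs["right"] = node.right
            g.attrs["parent"] = node.parent
            if node.is_leaf:
                g.create_dataset("frame", data=x.frames[node.index])
            else:
                g.create_dataset("transfer", data=x.transfer[node.index])


def load_ht(path: str | Path) -> HTTensor:
    with h5py.File(path, "r") as f:
        if f.attrs.get("format") != HT_FORMAT_TAG:
            raise ValueError("not an HT tensor file")
        d = int(f.attrs["d"])
        sizes = [int(n) for n in f.attrs["sizes"]]
        n_nodes = len(f.keys())
        nodes = []
        frames: dict[int, np.ndarray] = {}
        transfer: dict[int, np.ndarray] = {}
        for idx in range(n_nodes):
            g = f[f"node{idx}"]
            nodes.append(
                Node(
                    index=idx,
                    modes=tuple(int(m) for m in g.attrs["modes"]),
                    left=int(g.attrs["left"]),
                    right=int(g.attrs["right"]),
                    parent=int(g.attrs["parent"]),
                )
            )
            if "frame" in g:
                frames[idx] = g["frame"][()]
            else:
                transfer[idx] = g["transfer"][()]
        tree = DimensionTree(d=d, nodes=nodes)
    return HTTensor(tree=tree, sizes=sizes, frames=frames, transfer=transfer)


@dataclass
class RunConfig:
    """End-to-end run: one model source, solver settings, output paths."""

    theta_path: str | None = None
    sanspec_path: str | None = None
    design: BlockDesign | None = None
    tol: float = 1e-4
    eps_trunc: float = 1e-7
    max_iter: int = 10_000
    residual_stride: int = 1
    leaf_order: tuple[int, ...] | None = None
    out_dir: str = "."
    seed: int = 0

    def __post_init__(self) -> None:
        sources = sum(
            x is not None for x in (self.theta_path, self.sanspec_path, self.design)
        )
        if sources != 1:
            raise ValueError("exactly one model source must be given")


def run_pipeline(cfg: RunConfig) -> dict:
    """Solve the configured model and write all artifacts; returns their paths.

    Deterministic given the seed: writes the parameter snapshot, a per-
    iteration solver log (iteration, residual, mass, max rank), the result
    tensor (HDF5) and a metrics CSV.
    """
    from .diagnostics import effective_rank, storage_counts

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cfg.theta_path is not None:
        theta = read_theta(cfg.theta_path)
        spec = mhn_to_san(theta)
    elif cfg.sanspec_path is not None:
        theta = None
        spec = read_sanspec(cfg.sanspec_path)
    else:
        theta = sample_theta(cfg.design.with_seed(cfg.seed))
        spec = mhn_to_san(theta)
    if theta is not None:
        write_theta(theta, out / "theta_snapshot.csv")
    else:
        write_sanspec(spec, out / "sanspec_snapshot.json")

    tree = balanced_tree(spec.d, cfg.leaf_order)
    q = build_generator_cp(spec)
    gamma = gamma_bound(spec)
    p0 = ht_unit(tree, spec.sizes, tuple([0] * spec.d))
    solver_cfg = SolverConfig(
        gamma=gamma,
        tol=cfg.tol,
        eps_trunc=cfg.eps_trunc,
        max_iter=cfg.max_iter,
        residual_stride=cfg.residual_stride,
    )
    logger.info("solving d=%d model, gamma=%.4g, tol=%g", spec.d, gamma, cfg.tol)
    result = solve_marginal_lowrank(q, p0, solver_cfg)
    for (k, res), mass, (_, rmax) in zip(
        result.residuals, result.masses, result.max_rank_history
    ):
        logger.info("iter %d: residual %.3e mass %.12f max rank %d", k, res, mass, rmax)

    log = pd.DataFrame(
        {
            "iteration": [k for k, _ in result.residuals],
            "residual": [r for _, r in result.residuals],
            "mass": result.masses,
            "max_rank": [r for _, r in result.max_rank_history],
        }
    )
    log.to_csv(out / "solver_log.csv", index=False)
    save_ht(result.p, out / "result.h5")
    ht_count, dense_count = storage_counts(result.p)
    metrics = pd.DataFrame(
        [
            {
                "d": spec.d,
                "gamma": gamma,
                "iterations": result.iterations,
                "converged": result.converged,
                "residual": result.final_residual,
                "mass": result.final_mass,
                "effective_rank": effective_rank(result.p),
                "storage_ht": ht_count,
                "storage_dense": dense_count,
                "seed": cfg.seed,
            }
        ]
    )
    metrics.to_csv(out / "metrics.csv", index=False)
    return {
        "result": result,
        "paths": {
            "log": out / "solver_log.csv",
            "tensor": out / "result.h5",
            "metrics": out / "metrics.csv",
        },
    }
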