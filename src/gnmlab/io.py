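"""File formats: TSV/CSV data, YAML/JSON configuration, JSON manifests.

Conventions: node indexing is 0-based everywhere, lengths are mm, edge
lists are written with i < j, and every output directory receives a JSON
manifest recording the seed, parameters, input/output digests and the
package version. No reader mutates its input file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .embedding import SpatialEmbedding
from .network import BinaryNetwork
from .synth import FeatureTable, SimilarityMatrix

log = logging.getLogger("gnmlab")

__all__ = [
    "write_coords", "read_coords", "write_network", "write_edgelist",
    "read_network", "write_features", "read_features", "write_similarity",
    "read_similarity", "load_config", "write_manifest", "file_digest",
]


# --- coordinates -----------------------------------------------------------

def write_coords(embedding: SpatialEmbedding, path) -> Path:
    path = Path(path)
    df = pd.DataFrame(embedding.coords, columns=["x", "y", "z"])
    df.insert(0, "node_id", embedding.node_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def read_coords(path, neighbor_k: int = 6) -> SpatialEmbedding:
    df = pd.read_csv(path, sep="\t")
    required = {"node_id", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"coords file must have columns {sorted(required)}")
    return SpatialEmbedding.from_coords(
        df[["x", "y", "z"]].to_numpy(float),
        node_ids=[str(v) for v in df["node_id"]], neighbor_k=neighbor_k)


# --- networks --------------------------------------------------------------

def write_network(net: BinaryNetwork, path, fmt: str = "dense") -> Path:
    """Write as dense 0/1 TSV matrix (``dense``) or edge-list TSV (``edges``)."""
    path = Path(path)
    if fmt == "dense":
        np.savetxt(path, net.A, fmt="%d", delimiter="\t")
    elif fmt == "edges":
        write_edgelist(net, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def write_edgelist(net: BinaryNetwork, path, order: np.ndarray | None = None,
                   ) -> Path:
    """Edge-list TSV, canonicalised i < j; optional growth-order column."""
    path = Path(path)
    edges = net.edges()
    df = pd.DataFrame(edges, columns=["i", "j"])
    if order is not None:
        # order: (m, 2) edge_order array from a growth trace
        pos = {tuple(sorted(e)): t for t, e in enumerate(np.asarray(order))}
        df["order"] = [pos[(int(a), int(b))] for a, b in edges]
    df.to_csv(path, sep="\t", index=False)
    return path


def read_network(path, n_nodes: int) -> BinaryNetwork:
    """Read a network from dense 0/1 TSV or 2-column edge-list TSV.

    Dense input is symmetrised by max; a nonzero diagonal is cleared with
    a warning. Edge-list duplicates are collapsed with a logged count; an
    edge referencing a node >= n_nodes is a hard error naming the line.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    tokens = first.strip().split("\t")
    looks_dense = len(tokens) == n_nodes and all(
        t.replace(".", "", 1).replace("-", "", 1).isdigit() for t in tokens)
    if looks_dense:
        A = np.loadtxt(path, delimiter="\t")
        if A.shape != (n_nodes, n_nodes):
            raise ValueError(f"dense matrix is {A.shape}, expected "
                             f"({n_nodes}, {n_nodes})")
        if not np.isin(A, (0, 1)).all():
            raise ValueError("dense adjacency must contain only 0/1")
        if np.any(np.diag(A) != 0):
            warnings.warn("nonzero diagonal in dense adjacency; cleared",
                          stacklevel=2)
            np.fill_diagonal(A, 0)
        if not np.array_equal(A, A.T):
            log.info("asymmetric 0/1 adjacency symmetrised by max")
        A = np.maximum(A, A.T)
        return BinaryNetwork(A.astype(np.int8))
    df = pd.read_csv(path, sep="\t")
    if not {"i", "j"}.issubset(df.columns):
        raise ValueError("edge list must have columns i and j")
    seen = set()
    edges = []
    dups = 0
    for line_no, (a, b) in enumerate(zip(df["i"], df["j"]), start=2):
        a, b = int(a), int(b)
        if a >= n_nodes or b >= n_nodes or a < 0 or b < 0:
            raise ValueError(f"{path}:{line_no}: edge ({a}, {b}) references "
                             f"a node outside 0..{n_nodes - 1}")
        key = (min(a, b), max(a, b))
        if key in seen:
            dups += 1
            continue
        seen.add(key)
        edges.append(key)
    if dups:
        log.info("%d duplicate edges collapsed while reading %s", dups, path)
    return BinaryNetwork.from_edges(n_nodes, edges)


# --- features & similarity --------------------------------------------------

def write_features(features: FeatureTable, path) -> Path:
    path = Path(path)
    cols = [f"f{i}" for i in range(features.n_features)]
    pd.DataFrame(features.values, columns=cols).to_csv(
        path, sep="\t", index=False, float_format="%.10g")
    return path


def read_features(path) -> FeatureTable:
    df = pd.read_csv(path, sep="\t")
    return FeatureTable(values=df.to_numpy(float),
                        provenance={"source": str(path)})


def write_similarity(sim: SimilarityMatrix, path) -> Path:
    path = Path(path)
    np.savetxt(path, sim.F, fmt="%.10g", delimiter="\t")
    return path


def read_similarity(path, orientation: str = "similarity") -> SimilarityMatrix:
    F = np.loadtxt(path, delimiter="\t")
    return SimilarityMatrix(F=F, orientation=orientation)


# --- config and manifests ---------------------------------------------------

def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        return path_or_dict
    path = Path(path_or_dict)
    with open(path) as fh:
        if path.suffix in (".yaml", ".yml"):
            return yaml.safe_load(fh)
        return json.load(fh)


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, *, command: str, config: dict,
                   master_seed, child_seeds: dict | None = None,
                   inputs: dict | None = None,
                   outputs: list | None = None) -> Path:
    """JSON manifest for one output directory/stage."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "gnmlab",
        "version": __version__,
        "command": command,
        "config": config,
        "master_seed": master_seed,
        "child_seeds": child_seeds or {},
        "input_digests": inputs or {},
        "output_digests": {str(Path(p).name): file_digest(p)
                           for p in (outputs or [])},
        "written_utc": datetime.now(timezone.utc).isoformat(),
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
    return path
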