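"""Plain-text persistence: delimited matrices with JSON sidecars, taxonomy
edge lists, and label-vector tables. All writers use fixed formatting so
outputs are byte-stable under fixed seeds."""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import LayeredFeatureSeries
from .semantics import Taxonomy

FLOAT_FMT = "%.17g"


def write_matrix(path, matrix: np.ndarray):
    np.savetxt(path, np.atleast_2d(np.asarray(matrix, dtype=float)),
               fmt=FLOAT_FMT, delimiter="\t")


def read_matrix(path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter="\t", ndmin=2))


def write_json(path, obj):
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def write_series(directory, name: str, series: LayeredFeatureSeries, meta: dict | None = None):
    """One TSV per layer plus a JSON sidecar with shapes and the time step."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for i, m in enumerate(series.layers, start=1):
        write_matrix(d / f"{name}_layer{i:02d}.tsv", m)
    sidecar = {"name": name, "n_layers": series.n_layers,
               "units_per_layer": list(series.units_per_layer),
               "n_rows": series.n_rows, "time_step": series.time_step}
    sidecar.update(meta or {})
    write_json(d / f"{name}.json", sidecar)


def read_series(directory, name: str) -> LayeredFeatureSeries:
    d = Path(directory)
    meta = read_json(d / f"{name}.json")
    layers = [read_matrix(d / f"{name}_layer{i:02d}.tsv")
              for i in range(1, meta["n_layers"] + 1)]
    return LayeredFeatureSeries(layers, time_step=meta["time_step"])


def write_labeled_matrix(path, matrix: np.ndarray, row_labels, col_labels=None):
    matrix = np.asarray(matrix, dtype=float)
    cols = list(col_labels) if col_labels is not None else (
        list(row_labels) if matrix.shape[0] == matrix.shape[1] else list(range(matrix.shape[1])))
    df = pd.DataFrame(matrix, index=list(row_labels), columns=cols)
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_labeled_matrix(path):
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return df.to_numpy(dtype=float), list(df.index)


def write_taxonomy(path, taxonomy: Taxonomy):
    lines = [f"{child}\t{parent}" for child, parent in sorted(taxonomy.edges)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_taxonomy(path, root: str = "root") -> Taxonomy:
    edges = []
    nodes = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        child, parent = line.split("\t")
        edges.append((child, parent))
        nodes.update((child, parent))
    return Taxonomy(nodes=nodes, edges=edges, root=root)


def write_vectors(path, vectors: dict):
    labels = sorted(vectors)
    mat = np.stack([np.asarray(vectors[l], dtype=float) for l in labels])
    df = pd.DataFrame(mat, index=labels)
    df.to_csv(path, sep="\t", float_format="%.17g", header=False)


def read_vectors(path) -> dict:
    df = pd.read_csv(path, sep="\t", index_col=0, header=None,
                     float_precision="round_trip")
    return {str(idx): row.to_numpy(dtype=float) for idx, row in df.iterrows()}
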