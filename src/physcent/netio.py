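"""Reading, validating and writing connectivity matrices and result tables.

A connectivity matrix is a symmetric, zero-diagonal, nonnegative weight
matrix over labelled nodes.  Weights are unitless connection strengths;
for diffusion-MRI structural networks they are mean fractional anisotropy
(FA) values in (0, 1], but any nonnegative weight is accepted.  An edge
exists iff its weight is strictly positive.

Two on-disk formats are supported:

* ``matrix`` — a square numeric grid (TSV or CSV), optionally preceded by a
  single header row of node labels;
* ``edgelist`` — three whitespace/tab-separated columns
  ``source  target  weight``, undirected, each unordered pair at most once.

Node-label tables follow the atlas convention of 1-based indices
(``index  abbrev  name  hemisphere``) and are converted to 0-based
indexing on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components as _cc

logger = logging.getLogger(__name__)

#: tolerance below which an asymmetric matrix is silently symmetrized
ASYMMETRY_TOL = 1e-9


class ValidationError(ValueError):
    """An input violates the connectivity-matrix contract."""


def _default_labels(n: int) -> tuple[str, ...]:
    return tuple(str(i + 1) for i in range(n))


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Validated symmetric weighted network.

    Attributes
    ----------
    weights:
        ``(n, n)`` float array, symmetric, zero diagonal, nonnegative.
    labels:
        ``n`` unique node identifiers, in matrix order.
    """

    weights: np.ndarray
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValidationError(f"weights must be square, got shape {w.shape}")
        labels = self.labels or _default_labels(w.shape[0])
        if len(labels) != w.shape[0]:
            raise ValidationError(
                f"{len(labels)} labels for {w.shape[0]} nodes"
            )
        if len(set(labels)) != len(labels):
            raise ValidationError("node labels must be unique")
        asym = np.abs(w - w.T)
        if asym.size and asym.max() > ASYMMETRY_TOL:
            i, j = np.unravel_index(np.argmax(asym), asym.shape)
            raise ValidationError(
                f"matrix asymmetric: max deviation {asym.max():.3g} at "
                f"({labels[i]}, {labels[j]})"
            )
        w = (w + w.T) / 2.0  # symmetrize sub-tolerance noise
        if np.any(w < 0):
            i, j = np.unravel_index(int(np.argmin(w)), w.shape)
            raise ValidationError(
                f"negative weight {w[i, j]:.6g} at ({labels[i]}, {labels[j]})"
            )
        if np.any(np.diag(w) != 0):
            logger.warning("nonzero diagonal entries forced to zero")
            np.fill_diagonal(w, 0.0)
        w.flags.writeable = False
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "labels", tuple(labels))

    # -- derived views -----------------------------------------------------

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    @property
    def edge_index(self) -> tuple[np.ndarray, np.ndarray]:
        """Endpoint arrays ``(u, v)`` of existing edges, upper triangle order."""
        u, v = np.nonzero(np.triu(self.weights, k=1))
        return u, v

    @property
    def edge_weights(self) -> np.ndarray:
        u, v = self.edge_index
        return self.weights[u, v]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, k=1)))

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown node label {label!r}") from None

    def permuted(self, perm: np.ndarray) -> "ConnectivityMatrix":
        """Relabel nodes: node ``i`` of the result is node ``perm[i]`` of self."""
        perm = np.asarray(perm)
        return ConnectivityMatrix(
            self.weights[np.ix_(perm, perm)],
            tuple(self.labels[i] for i in perm),
        )


@dataclass(frozen=True)
class NodeLabelTable:
    """Atlas-style node labels (1-based on disk, 0-based in memory)."""

    abbrevs: tuple[str, ...]
    names: tuple[str, ...]
    hemispheres: tuple[str, ...]

    def __post_init__(self) -> None:
        if not (len(self.abbrevs) == len(self.names) == len(self.hemispheres)):
            raise ValidationError("label table columns differ in length")
        if len(set(self.abbrevs)) != len(self.abbrevs):
            raise ValidationError("abbreviations must be unique")
        bad = set(self.hemispheres) - {"L", "R", "NA"}
        if bad:
            raise ValidationError(f"invalid hemisphere codes: {sorted(bad)}")

    @property
    def n(self) -> int:
        return len(self.abbrevs)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _sniff_delim(line: str) -> str | None:
    return "," if ("," in line and "\t" not in line) else None  # None: whitespace


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def read_connectivity(path: str | Path, format: str = "matrix") -> ConnectivityMatrix:
    """Read a connectivity matrix from ``matrix`` or ``edgelist`` format.

    Edgelist entries are mirrored to both triangles; pairs absent from the
    file get weight 0.  Duplicate pairs with conflicting weights are an error.
    """
    path = Path(path)
    if format == "matrix":
        return _read_matrix(path)
    if format == "edgelist":
        return _read_edgelist(path)
    raise ValueError(f"unknown format {format!r} (expected 'matrix' or 'edgelist')")


def _read_matrix(path: Path) -> ConnectivityMatrix:
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValidationError(f"{path}: empty file")
    token_rows = [ln.replace(",", " ").split() for ln in lines]
    widths = {len(r) for r in token_rows}
    n_cols = len(token_rows[0])
    labels: tuple[str, ...] = ()
    # a header row is present when the grid has one more row than columns,
    # or when the first row is non-numeric
    if (widths == {n_cols} and len(token_rows) == n_cols + 1) or not all(
        _is_number(t) for t in token_rows[0]
    ):
        labels = tuple(token_rows[0])
        token_rows = token_rows[1:]
    try:
        rows = [[float(t) for t in r] for r in token_rows]
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric entry ({exc})") from None
    if len({len(r) for r in rows}) != 1 or len(rows) != len(rows[0]):
        raise ValidationError(
            f"{path}: non-square grid ({len(rows)} rows, "
            f"row lengths {sorted({len(r) for r in rows})})"
        )
    return ConnectivityMatrix(np.array(rows, dtype=float), labels)


def _read_edgelist(path: Path) -> ConnectivityMatrix:
    seen: dict[tuple[str, str], float] = {}
    order: list[str] = []
    for ln in Path(path).read_text().splitlines():
        if not ln.strip() or ln.lstrip().startswith("#"):
            continue
        toks = ln.replace(",", " ").split()
        if len(toks) != 3:
            raise ValidationError(f"{path}: expected 3 columns, got {len(toks)}: {ln!r}")
        a, b, wtok = toks
        w = float(wtok)
        if w < 0:
            raise ValidationError(f"{path}: negative weight on ({a}, {b})")
        for lab in (a, b):
            if lab not in order:
                order.append(lab)
        key = (a, b) if a <= b else (b, a)
        if key in seen and seen[key] != w:
            raise ValidationError(
                f"{path}: conflicting duplicate edge ({a}, {b}): "
                f"{seen[key]} vs {w}"
            )
        seen[key] = w
    n = len(order)
    idx = {lab: i for i, lab in enumerate(order)}
    w = np.zeros((n, n))
    for (a, b), val in seen.items():
        i, j = idx[a], idx[b]
        if i == j:
            continue  # self edge, dropped by the zero-diagonal rule with a warning
        w[i, j] = w[j, i] = val
    if any(a == b for a, b in seen):
        logger.warning("self edges in %s ignored", path)
    return ConnectivityMatrix(w, tuple(order))


def write_connectivity(
    m: ConnectivityMatrix, path: str | Path, format: str = "matrix"
) -> None:
    """Write ``m`` so that :func:`read_connectivity` reproduces it to 1e-12."""
    path = Path(path)
    if format == "matrix":
        header = "\t".join(m.labels)
        body = "\n".join(
            "\t".join(f"{x:.17g}" for x in row) for row in m.weights
        )
        path.write_text(header + "\n" + body + "\n")
    elif format == "edgelist":
        u, v = m.edge_index
        lines = [
            f"{m.labels[i]}\t{m.labels[j]}\t{m.weights[i, j]:.17g}"
            for i, j in zip(u, v)
        ]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    else:
        raise ValueError(f"unknown format {format!r}")


def connected_components(m: ConnectivityMatrix) -> list[list[int]]:
    """Partition node indices by reachability over positive-weight edges."""
    ncomp, lab = _cc(csr_matrix(m.weights > 0), directed=False)
    return [sorted(np.flatnonzero(lab == c).tolist()) for c in range(ncomp)]


def read_node_labels(path: str | Path) -> NodeLabelTable:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] != 4:
        raise ValidationError(f"{path}: expected 4 columns, got {df.shape[1]}")
    idx = df[0].astype(int).to_numpy()
    if not np.array_equal(np.sort(idx), np.arange(1, len(idx) + 1)):
        raise ValidationError(f"{path}: indices must be contiguous 1..n")
    order = np.argsort(idx)
    return NodeLabelTable(
        tuple(df[1].to_numpy()[order]),
        tuple(df[2].to_numpy()[order]),
        tuple(df[3].to_numpy()[order]),
    )


# -- result tables ----------------------------------------------------------


def write_node_map(map_, path: str | Path) -> None:
    """Write a node centrality map as TSV ``node  measure  value``."""
    lines = [
        f"{lab}\t{map_.measure}\t{val:.17g}"
        for lab, val in zip(map_.labels, map_.values)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_node_map(path: str | Path):
    from .centrality import CentralityMap

    df = pd.read_csv(path, sep="\t", header=None, names=["node", "measure", "value"])
    measures = df["measure"].unique()
    if len(measures) != 1:
        raise ValidationError(f"{path}: mixed measures {list(measures)}")
    return CentralityMap(
        measure=str(measures[0]),
        values=df["value"].to_numpy(dtype=float),
        labels=tuple(df["node"].astype(str)),
    )


def write_edge_map(edge_map, path: str | Path) -> None:
    """Write an edge map as TSV ``source  target  measure  value``."""
    lines = [
        f"{edge_map.labels[i]}\t{edge_map.labels[j]}\t{edge_map.measure}\t{val:.17g}"
        for i, j, val in zip(edge_map.u, edge_map.v, edge_map.values)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_edge_map(path: str | Path):
    from .centrality import EdgeCentralityMap

    df = pd.read_csv(
        path, sep="\t", header=None, names=["source", "target", "measure", "value"]
    )
    measures = df["measure"].unique()
    if len(measures) != 1:
        raise ValidationError(f"{path}: mixed measures {list(measures)}")
    labels: list[str] = []
    for lab in pd.concat([df["source"], df["target"]]).astype(str):
        if lab not in labels:
            labels.append(lab)
    idx = {lab: i for i, lab in enumerate(labels)}
    u = np.array([idx[str(s)] for s in df["source"]])
    v = np.array([idx[str(t)] for t in df["target"]])
    return EdgeCentralityMap(
        measure=str(measures[0]),
        u=u,
        v=v,
        values=df["value"].to_numpy(dtype=float),
        labels=tuple(labels),
    )
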