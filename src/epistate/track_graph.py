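"""Analytics on the cell-type x feature measurement matrix.

Experimentally measured epigenetic tracks form a bipartite graph: cell types
and features are nodes, and an edge exists wherever a (cell type, feature)
track was measured.  Connectivity of this graph determines which unmeasured
tracks are in principle inferable from the available data; bicliques
(complete submatrices) provide balanced folds; the track-predictability
criterion decides which measured tracks may be held out of training while
remaining learnable from what is left.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd


@dataclass
class MeasurementMatrix:
    """Boolean availability mask over cell types (rows) and features (columns)."""

    cells: list
    features: list
    measured: np.ndarray  # bool, shape (n_cells, n_features)

    def __post_init__(self):
        self.measured = np.asarray(self.measured, dtype=bool)
        if len(set(self.cells)) != len(self.cells):
            raise ValueError("duplicate cell identifiers")
        if len(set(self.features)) != len(self.features):
            raise ValueError("duplicate feature identifiers")
        if self.measured.shape != (len(self.cells), len(self.features)):
            raise ValueError("measured shape does not match identifier lists")

    @property
    def n_measured(self) -> int:
        return int(self.measured.sum())

    def cell_index(self, cell) -> int:
        return self.cells.index(cell)

    def feature_index(self, feature) -> int:
        return self.features.index(feature)

    def copy(self) -> "MeasurementMatrix":
        return MeasurementMatrix(list(self.cells), list(self.features), self.measured.copy())

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.measured.astype(int), index=self.cells, columns=self.features)
        df.to_csv(path, sep="\t", index_label="cell_id")

    @classmethod
    def from_tsv(cls, path) -> "MeasurementMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), list(df.columns), df.values.astype(bool))


def _bipartite_graph(m: MeasurementMatrix) -> nx.Graph:
    g = nx.Graph()
    rows, cols = np.nonzero(m.measured)
    for r, c in zip(rows, cols):
        g.add_edge(("cell", m.cells[r]), ("feature", m.features[c]))
    return g


def is_connected(m: MeasurementMatrix) -> bool:
    """True iff all nodes with at least one measured track form one component."""
    if m.measured.size == 0:
        raise ValueError("empty measurement matrix")
    g = _bipartite_graph(m)
    if g.number_of_nodes() == 0:
        return False
    return nx.is_connected(g)


def is_predictable(m: MeasurementMatrix, cell_I, feature_X) -> bool:
    """Whether track (cell_I, feature_X) is inferable once removed.

    The track is predictable iff there exist a feature Y != X and a cell
    II != I such that Y is measured in both I and II and X is measured in
    II — evaluated on the matrix with (I, X) itself removed.
    """
    i = m.cell_index(cell_I)
    x = m.feature_index(feature_X)
    if not m.measured[i, x]:
        raise ValueError(f"track ({cell_I}, {feature_X}) is not measured")
    row_i = m.measured[i].copy()
    row_i[x] = False  # (I, X) removed; Y must be a different feature
    if not row_i.any():
        return False
    other = m.measured.copy()
    other[i, :] = False  # II must be a different cell
    shares_y = (other & row_i[None, :]).any(axis=1)
    has_x = other[:, x]
    return bool((shares_y & has_x).any())


def quality_filter(
    m: MeasurementMatrix,
    min_features_per_cell: int = 3,
    min_cells_per_feature: int = 3,
) -> MeasurementMatrix:
    """Iteratively drop under-characterized cells/features until a fixed point.

    Cells measured for fewer than `min_features_per_cell` features and
    features measured in fewer than `min_cells_per_feature` cells are removed;
    removals can cascade.  The fixed point is order-independent.
    """
    cells = list(m.cells)
    features = list(m.features)
    mat = m.measured.copy()
    while True:
        keep_rows = mat.sum(axis=1) >= min_features_per_cell
        keep_cols = mat.sum(axis=0) >= min_cells_per_feature
        if keep_rows.all() and keep_cols.all():
            break
        cells = [c for c, k in zip(cells, keep_rows) if k]
        features = [f for f, k in zip(features, keep_cols) if k]
        mat = mat[np.ix_(keep_rows, keep_cols)]
        if mat.size == 0:
            break
    return MeasurementMatrix(cells, features, mat)


def select_holdout_tracks(
    m: MeasurementMatrix,
    fraction: float = 0.10,
    seed: int = 0,
    max_restarts: int = 50,
) -> list:
    """Randomly pick `fraction` of measured tracks so that each is predictable
    from the remainder and every cell keeps at least one track.

    Greedy randomized selection with restarts: tracks are visited in shuffled
    order and accepted if, given all removals so far, the track is still
    predictable and its cell retains coverage; a final re-check confirms every
    selected track is predictable from the final remainder (removals can break
    earlier picks), retrying with a fresh shuffle otherwise.
    """
    if not is_connected(m):
        raise ValueError("measurement matrix must be connected")
    total = m.n_measured
    n_select = int(round(fraction * total))
    if n_select == 0:
        return []
    rng = np.random.default_rng(seed)
    pairs = [(m.cells[r], m.features[c]) for r, c in zip(*np.nonzero(m.measured))]

    for _ in range(max_restarts):
        order = rng.permutation(len(pairs))
        work = m.copy()
        selected = []
        for j in order:
            if len(selected) == n_select:
                break
            cell, feat = pairs[j]
            r, c = work.cell_index(cell), work.feature_index(feat)
            if work.measured[r].sum() <= 1:
                continue  # cell must retain >= 1 track
            if not is_predictable(work, cell, feat):
                continue
            work.measured[r, c] = False
            selected.append((cell, feat))
        if len(selected) != n_select:
            continue
        # removals may have invalidated earlier picks: verify on the remainder
        ok = True
        for cell, feat in selected:
            probe = work.copy()
            probe.measured[probe.cell_index(cell), probe.feature_index(feat)] = True
            if not is_predictable(probe, cell, feat):
                ok = False
                break
        if ok:
            return selected
    raise ValueError(
        f"could not select {n_select}/{total} predictable holdout tracks: "
        "the predictability or per-cell-coverage constraint is binding"
    )


@dataclass
class BicliqueResult:
    cells: list
    features: list
    exact: bool = True

    @property
    def n_tracks(self) -> int:
        return len(self.cells) * len(self.features)


def largest_biclique(m: MeasurementMatrix, enumeration_bound: int = 10**6) -> BicliqueResult:
    """Maximum-edge biclique (complete submatrix) of the measurement matrix.

    Exact when the search space permits: enumerate subsets of the smaller
    dimension (2^k candidate subsets, each costing n bits) as long as
    2^k * n <= enumeration_bound; otherwise greedy row/column elimination
    with restarts, flagged as not certified exact.
    """
    if m.measured.size == 0:
        raise ValueError("empty measurement matrix")
    mat = m.measured
    transposed = False
    if mat.shape[1] > mat.shape[0]:
        mat = mat.T
        transposed = True
    n_big, n_small = mat.shape  # enumerate subsets of the small dimension
    if (2 ** n_small) * n_big <= enumeration_bound:
        best, best_sets = -1, ([], [])
        for k in range(1, n_small + 1):
            for subset in itertools.combinations(range(n_small), k):
                rows = mat[:, subset].all(axis=1)
                score = int(rows.sum()) * k
                if score > best:
                    best = score
                    best_sets = (np.nonzero(rows)[0].tolist(), list(subset))
        row_idx, col_idx = best_sets
        exact = True
    else:
        row_idx, col_idx, exact = _greedy_biclique(mat), None, False
        row_idx, col_idx = row_idx
    if transposed:
        row_idx, col_idx = col_idx, row_idx
    return BicliqueResult(
        cells=[m.cells[i] for i in row_idx],
        features=[m.features[j] for j in col_idx],
        exact=exact,
    )


def _greedy_biclique(mat: np.ndarray, restarts: int = 20, seed: int = 0):
    """Row-seeded greedy: start from one row's measured columns and drop the
    column whose removal best grows the set of fully-covering rows, while the
    edge count improves."""
    rng = np.random.default_rng(seed)
    best_score, best = -1, ([], [])
    candidates = np.flatnonzero(mat.any(axis=1))
    if candidates.size == 0:
        return best
    seeds = rng.choice(candidates, size=min(restarts, candidates.size), replace=False)
    support = mat.sum(axis=0)
    for r in seeds:
        cols = np.flatnonzero(mat[r])
        # scan prefixes of the seed row's columns, densest columns first:
        # well-supported column sets retain many fully-covering rows
        cols = cols[np.argsort(-support[cols], kind="stable")]
        covered = np.ones(mat.shape[0], dtype=bool)
        for j, c in enumerate(cols, start=1):
            covered &= mat[:, c]
            score = int(covered.sum()) * j
            if score > best_score:
                best_score = score
                best = (np.flatnonzero(covered).tolist(), cols[:j].tolist())
    return best


def coverage_fraction(m: MeasurementMatrix) -> float:
    """Fraction of the cell x feature grid that was experimentally measured."""
    if m.measured.size == 0:
        raise ValueError("empty measurement matrix")
    return float(m.measured.sum()) / m.measured.size
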