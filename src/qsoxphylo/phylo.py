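"""Distance-based tree pipeline: ML pairwise distances, neighbor joining,
column bootstrap, consensus with supports, Robinson-Foulds comparison and
domain concatenation.

Distances under the "proportional" model use the closed form
``d = -(19/20) ln(1 - (20/19) p)``; under empirical models (Dayhoff, JTT) the
distance is the branch length maximising the likelihood
``sum_sites ln(pi_a P_ab(t))``, located on a log-spaced grid of transition
matrices and polished by bounded scalar optimisation.  Sites where either row
has a gap or 'X' are excluded pair by pair (pairwise deletion).  Saturated
pairs return a configurable cap (default 10 substitutions/site).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .align import Alignment
from .models import SubstitutionModel, encode_protein, get_model
from .trees import Node, Tree

log = logging.getLogger(__name__)

DEFAULT_CAP = 10.0


@dataclass
class DistanceResult:
    value: float
    saturated: bool
    n_sites: int


class DistanceMatrix:
    """Symmetric non-negative distances with a zero diagonal."""

    def __init__(self, labels: list[str], matrix: np.ndarray):
        matrix = np.asarray(matrix, dtype=float)
        n = len(labels)
        if matrix.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(matrix, matrix.T, atol=1e-8):
            raise ValueError("distance matrix is not symmetric")
        if (np.diag(matrix) != 0).any():
            raise ValueError("distance matrix diagonal must be zero")
        self.labels = list(labels)
        self.matrix = matrix

    def __getitem__(self, pair):
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return self.matrix[i, j]

    def write_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for lab, row in zip(self.labels, self.matrix):
                fh.write(lab.ljust(12) + " ".join(f"{v:.6f}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# pairwise distances


def _usable(ea: np.ndarray, eb: np.ndarray) -> np.ndarray:
    return (ea >= 0) & (eb >= 0)


class _MLGrid:
    """Cached log-transition grids per model for fast likelihood evaluation."""

    def __init__(self, model: SubstitutionModel, cap: float, n_grid: int = 160):
        self.model = model
        self.cap = cap
        self.ts = np.geomspace(1e-4, cap, n_grid)
        logp = np.empty((n_grid, 400))
        for k, t in enumerate(self.ts):
            P = model.transition_matrix(t)
            logp[k] = np.log(np.maximum(model.pi[:, None] * P, 1e-300)).ravel()
        self.logp = logp

    def loglik(self, counts: np.ndarray, t: float) -> float:
        P = self.model.transition_matrix(t)
        return float(counts @ np.log(np.maximum(
            self.model.pi[:, None] * P, 1e-300)).ravel())

    def estimate(self, counts: np.ndarray, refine: bool = True):
        ll = self.logp @ counts
        k = int(np.argmax(ll))
        if k == len(self.ts) - 1:
            return self.cap, True
        lo = self.ts[max(k - 1, 0)]
        hi = self.ts[min(k + 1, len(self.ts) - 1)]
        if refine:
            res = minimize_scalar(lambda t: -self.loglik(counts, t),
                                  bounds=(lo, hi), method="bounded",
                                  options={"xatol": 1e-10})
            return float(res.x), False
        if k == 0:
            return float(self.ts[0]), False
        # 3-point parabola vertex on the uniform-in-log grid
        x = np.log(self.ts[k - 1:k + 2])
        y = ll[k - 1:k + 2]
        denom = y[0] - 2 * y[1] + y[2]
        if denom >= 0:  # flat or degenerate: keep the grid point
            return float(self.ts[k]), False
        h = x[1] - x[0]
        xs = x[1] + 0.5 * h * (y[0] - y[2]) / denom
        return float(np.exp(np.clip(xs, x[0], x[2]))), False


_GRIDS: dict[tuple[str, float], _MLGrid] = {}


def _grid_for(model: SubstitutionModel, cap: float) -> _MLGrid:
    key = (model.name, cap)
    if key not in _GRIDS:
        _GRIDS[key] = _MLGrid(model, cap)
    return _GRIDS[key]


def _pair_counts(ea: np.ndarray, eb: np.ndarray) -> np.ndarray:
    m = _usable(ea, eb)
    return np.bincount(ea[m] * 20 + eb[m], minlength=400).astype(float)


def pairwise_distance_full(row_a: str, row_b: str, model: str | SubstitutionModel,
                           cap: float = DEFAULT_CAP,
                           refine: bool = True) -> DistanceResult:
    """Evolutionary distance between two gapped alignment rows, with flags."""
    if len(row_a) != len(row_b):
        raise ValueError("rows differ in length")
    if isinstance(model, str):
        model = get_model(model)
    ea, eb = encode_protein(row_a), encode_protein(row_b)
    m = _usable(ea, eb)
    n_use = int(m.sum())
    if n_use == 0:
        raise ValueError("no usable sites (all gapped or unknown)")
    if model.name == "proportional":
        p = float((ea[m] != eb[m]).mean())
        arg = 1.0 - 20.0 / 19.0 * p
        if arg <= 0:
            return DistanceResult(cap, True, n_use)
        return DistanceResult(-19.0 / 20.0 * float(np.log(arg)), False, n_use)
    if (ea[m] == eb[m]).all():
        return DistanceResult(0.0, False, n_use)
    counts = _pair_counts(ea, eb)
    d, sat = _grid_for(model, cap).estimate(counts, refine=refine)
    return DistanceResult(d, sat, n_use)


def pairwise_distance(row_a: str, row_b: str, model: str | SubstitutionModel = "proportional",
                      cap: float = DEFAULT_CAP) -> float:
    """Substitutions/site between two gapped rows (see pairwise_distance_full)."""
    return pairwise_distance_full(row_a, row_b, model, cap).value


def distance_matrix(msa: Alignment, model: str | SubstitutionModel = "proportional",
                    cap: float = DEFAULT_CAP, refine: bool = False) -> DistanceMatrix:
    """All-pairs distance matrix for an alignment.

    The matrix path uses the grid + parabolic-interpolation estimate by
    default (refine=False); per-pair accuracy is ~1e-3 relative, adequate for
    tree building, and keeps bootstrap loops fast.
    """
    if isinstance(model, str):
        model = get_model(model)
    enc = [encode_protein(r) for r in msa.rows]
    n = msa.n_rows
    D = np.zeros((n, n))
    grid = None if model.name == "proportional" else _grid_for(model, cap)
    for i in range(n):
        for j in range(i + 1, n):
            ea, eb = enc[i], enc[j]
            m = _usable(ea, eb)
            if not m.any():
                raise ValueError(f"no usable sites between rows {msa.ids[i]} "
                                 f"and {msa.ids[j]}")
            if model.name == "proportional":
                p = float((ea[m] != eb[m]).mean())
                arg = 1.0 - 20.0 / 19.0 * p
                d = cap if arg <= 0 else -19.0 / 20.0 * float(np.log(arg))
            elif (ea[m] == eb[m]).all():
                d = 0.0
            else:
                d, _ = grid.estimate(_pair_counts(ea, eb), refine=refine)
            D[i, j] = D[j, i] = d
    return DistanceMatrix(list(msa.ids), D)


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining on the Q-criterion.

    Ties are broken by the lowest (i, j) index pair in the current node list
    (new internal nodes are appended at the end).  Negative branch-length
    estimates are clamped to zero with the deficit logged.  Output is unrooted
    (trifurcating root).
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = dm.matrix.copy()
    nodes: list[Node] = [Node(name=lab) for lab in dm.labels]
    active = list(range(n))

    while len(active) > 3:
        k = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (k - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))  # row-major -> lowest (i, j) on ties
        i, j = divmod(flat, k)
        if i > j:
            i, j = j, i
        di = 0.5 * sub[i, j] + (r[i] - r[j]) / (2.0 * (k - 2))
        dj = sub[i, j] - di
        for name, v in (("left", di), ("right", dj)):
            if v < 0:
                log.debug("clamped negative NJ branch (%s, deficit %.3g)", name, -v)
        a, b = active[i], active[j]
        child_a, child_b = nodes[a], nodes[b]
        child_a.length = max(di, 0.0)
        child_b.length = max(dj, 0.0)
        new = Node(children=[child_a, child_b])
        # distances from the new node to the others
        d_new = 0.5 * (D[a, active] + D[b, active] - D[a, b])
        D = np.pad(D, ((0, 1), (0, 1)))
        idx_new = D.shape[0] - 1
        D[idx_new, active] = d_new
        D[active, idx_new] = d_new
        D[idx_new, idx_new] = 0.0
        nodes.append(new)
        active = [x for x in active if x not in (a, b)] + [idx_new]

    a, b, c = active
    # three-point formulas for the final star
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for x, lx in zip((a, b, c), (la, lb, lc)):
        nodes[x].length = max(float(lx), 0.0)
    root = Node(children=[nodes[a], nodes[b], nodes[c]])
    return Tree(root, rooted=False)


# ---------------------------------------------------------------------------
# bootstrap, consensus, comparison


def bootstrap_columns(msa: Alignment, n_replicates: int, seed: int) -> list[Alignment]:
    """Resample alignment columns with replacement, to the original width."""
    if msa.width == 0 or msa.n_rows == 0:
        raise ValueError("empty alignment")
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    arr = np.array([list(r) for r in msa.rows])
    out = []
    for _ in range(n_replicates):
        cols = rng.integers(0, msa.width, size=msa.width)
        rep = arr[:, cols]
        out.append(Alignment(list(msa.ids), ["".join(r) for r in rep]))
    return out


def bipartition_frequencies(trees: list[Tree]) -> dict[frozenset, float]:
    """Frequency of each non-trivial bipartition across trees."""
    if not trees:
        raise ValueError("no trees")
    leafset = trees[0].leaf_set
    counts: dict[frozenset, int] = {}
    for t in trees:
        if t.leaf_set != leafset:
            raise ValueError("trees do not share a leaf set")
        for bp in t.bipartitions():
            counts[bp] = counts.get(bp, 0) + 1
    return {bp: c / len(trees) for bp, c in counts.items()}


def _compatible(a: frozenset, b: frozenset, leafset: frozenset) -> bool:
    return (a.isdisjoint(b) or a <= b or b <= a
            or (leafset - a).isdisjoint(b))


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _tree_from_bipartitions(leafset: frozenset, chosen: dict[frozenset, float]) -> Tree:
    """Build the (possibly multifurcating) tree realising a compatible,
    laminar family of canonical bipartitions, with rounded percent supports."""
    sides = sorted(chosen, key=lambda s: (-len(s), sorted(s)))
    root = Node()
    leaf_nodes = {name: Node(name=name) for name in sorted(leafset)}
    clade_nodes: list[tuple[frozenset, Node]] = [(leafset, root)]
    for side in sides:
        parent = min((c for c in clade_nodes if side < c[0]),
                     key=lambda c: len(c[0]))
        node = Node(support=_round_half_up(100.0 * chosen[side]))
        parent[1].children.append(node)
        clade_nodes.append((side, node))
    for name, leaf in leaf_nodes.items():
        parent = min((c for c in clade_nodes if name in c[0]),
                     key=lambda c: len(c[0]))
        parent[1].children.append(leaf)
    return Tree(root, rooted=False)


def consensus(trees: list[Tree], rule: str = "majority") -> Tree:
    """Consensus of replicate trees with integer-percent supports.

    'strict' keeps bipartitions in every tree; 'majority' keeps those in
    > 50% of trees; 'majority_extended' greedily adds remaining compatible
    bipartitions by descending frequency (ties by lexicographic encoding).
    """
    if rule not in ("strict", "majority", "majority_extended"):
        raise ValueError(f"unknown consensus rule {rule!r}")
    freqs = bipartition_frequencies(trees)
    leafset = trees[0].leaf_set
    if rule == "strict":
        chosen = {bp: f for bp, f in freqs.items() if f >= 1.0 - 1e-12}
    else:
        chosen = {bp: f for bp, f in freqs.items() if f > 0.5}
        if rule == "majority_extended":
            rest = sorted((bp for bp in freqs if bp not in chosen),
                          key=lambda bp: (-freqs[bp], sorted(bp)))
            for bp in rest:
                if all(_compatible(bp, c, leafset) for c in chosen):
                    chosen[bp] = freqs[bp]
    return _tree_from_bipartitions(leafset, chosen)


def rf_distance(t1: Tree, t2: Tree) -> int:
    """Robinson-Foulds distance: |symmetric difference of bipartition sets|."""
    if t1.leaf_set != t2.leaf_set:
        raise ValueError("trees do not share a leaf set")
    return len(t1.bipartitions() ^ t2.bipartitions())


def concat_alignments(msa_a: Alignment, msa_b: Alignment,
                      lenient: bool = False) -> Alignment:
    """Row-wise concatenation of two alignments in fixed (first, second) order.

    Requires identical seqid sets; with lenient=True, ids present in only one
    alignment are dropped with a logged warning (the omission rule for
    truncated members).  Block boundaries are recorded in ``meta['blocks']``.
    """
    ids_a, ids_b = set(msa_a.ids), set(msa_b.ids)
    if ids_a != ids_b:
        if not lenient:
            raise ValueError("alignments do not share a seqid set")
        dropped = ids_a ^ ids_b
        log.warning("dropping %d seqids present in only one block: %s",
                    len(dropped), sorted(dropped))
    shared = [sid for sid in msa_a.ids if sid in ids_b]
    if not shared:
        raise ValueError("no shared seqids to concatenate")
    rows = [msa_a.row(sid) + msa_b.row(sid) for sid in shared]
    out = Alignment(shared, rows)
    out.meta["blocks"] = [(0, msa_a.width), (msa_a.width, msa_a.width + msa_b.width)]
    return out
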