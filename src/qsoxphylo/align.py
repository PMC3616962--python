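"""Pairwise and progressive multiple alignment.

The pipeline aligns domain sequences with its own deterministic aligner rather
than shelling out to an external program: global affine-gap pairwise alignment
(Gotoh) and a progressive profile aligner over a neighbor-joining guide tree.
A gap of length L costs ``gap_open + L * gap_extend``.  Traceback ties prefer
diagonal, then up (gap in the second sequence), then left, so output is
deterministic.

Substitution matrices come from Biopython (BLOSUM62 by default).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Align import substitution_matrices

NEG = -1e30  # acts as -inf without NaN arithmetic
GAP = "-"


def default_matrix():
    """BLOSUM62, the default scoring matrix."""
    return substitution_matrices.load("BLOSUM62")


@dataclass
class Alignment:
    """A multiple (or pairwise) alignment: ordered rows of equal length."""

    ids: list[str]
    rows: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in number")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError("alignment rows have unequal lengths")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seqid: str) -> str:
        return self.rows[self.ids.index(seqid)]

    def degapped(self, seqid: str) -> str:
        return self.row(seqid).replace(GAP, "")

    def column(self, j: int) -> str:
        return "".join(r[j] for r in self.rows)

    def select_columns(self, idx) -> "Alignment":
        idx = list(idx)
        return Alignment(list(self.ids),
                         ["".join(r[j] for j in idx) for r in self.rows])

    def to_fasta(self, path=None) -> str:
        text = "".join(f">{i}\n{r}\n" for i, r in zip(self.ids, self.rows))
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_clustal(self, path) -> None:
        from Bio.Align import MultipleSeqAlignment
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord
        msa = MultipleSeqAlignment(
            SeqRecord(Seq(r), id=i, description="") for i, r in zip(self.ids, self.rows))
        AlignIO.write(msa, path, "clustal")

    @classmethod
    def read(cls, path, fmt: str = "fasta") -> "Alignment":
        recs = list(AlignIO.read(path, fmt))
        return cls([r.id for r in recs], [str(r.seq).upper() for r in recs])


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, sequence) pairs."""
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(path, "fasta")]


def write_fasta(records: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for sid, seq in records:
            fh.write(f">{sid}\n{seq}\n")


def _gotoh(S: np.ndarray, gap_open: float, gap_extend: float):
    """Affine-gap global DP on a precomputed position-score matrix.

    S[i, j] scores pairing row-position i with column-position j.  Returns
    (score, ops) where ops is the traceback operation string over
    {'D': pair, 'U': gap in columns (consume row), 'L': gap in rows}.
    """
    m, n = S.shape
    go, ge = float(gap_open), float(gap_extend)
    H = np.full((m + 1, n + 1), NEG)
    U = np.full((m + 1, n + 1), NEG)  # gap in second profile (vertical)
    L = np.full((m + 1, n + 1), NEG)  # gap in first profile (horizontal)
    H[0, 0] = 0.0
    for j in range(1, n + 1):
        L[0, j] = -(go + ge * j)
        H[0, j] = L[0, j]
    for i in range(1, m + 1):
        U[i, 0] = -(go + ge * i)
        H[i, 0] = U[i, 0]

    ext = ge * np.arange(n + 1)
    for i in range(1, m + 1):
        D = H[i - 1, :-1] + S[i - 1, :]                       # diagonal, cols 1..n
        U[i, 1:] = np.maximum(U[i - 1, 1:], H[i - 1, 1:] - go) - ge
        G = np.maximum(np.concatenate(([NEG], D)), U[i])      # best non-L per col
        G[0] = H[i, 0]
        # L[j] = max_{k<j} (G[k] - go - (j-k) ge): prefix-max scan
        T = G + ext
        P = np.maximum.accumulate(T)
        L[i, 1:] = P[:-1] - go - ext[1:]
        H[i] = np.maximum(G, L[i])

    # traceback with stated preference: diagonal, then up, then left
    ops = []
    i, j = m, n
    state = None
    eps = 1e-9
    for s, M in (("D", None), ("U", U), ("L", L)):
        if s == "D":
            if i > 0 and j > 0 and abs(H[i - 1, j - 1] + S[i - 1, j - 1] - H[i, j]) < eps:
                state = "D"
                break
        elif abs(M[i, j] - H[i, j]) < eps:
            state = s
            break
    while i > 0 or j > 0:
        if i == 0:
            ops.append("L"); j -= 1; continue
        if j == 0:
            ops.append("U"); i -= 1; continue
        if state == "D":
            ops.append("D")
            i, j = i - 1, j - 1
        elif state == "U":
            ops.append("U")
            reopened = abs(H[i - 1, j] - go - ge - U[i, j]) < eps
            i -= 1
            if not reopened:
                state = "U"
                continue
        else:
            ops.append("L")
            reopened = abs(H[i, j - 1] - go - ge - L[i, j]) < eps
            j -= 1
            if not reopened:
                state = "L"
                continue
        # choose next state at (i, j) by preference
        if i > 0 and j > 0 and abs(H[i - 1, j - 1] + S[i - 1, j - 1] - H[i, j]) < eps:
            state = "D"
        elif abs(U[i, j] - H[i, j]) < eps:
            state = "U"
        elif abs(L[i, j] - H[i, j]) < eps:
            state = "L"
        elif i == 0:
            state = "L"
        else:
            state = "U"
    ops.reverse()
    return float(H[m, n]), "".join(ops)


def _matrix_lookup(matrix):
    """Index a Biopython substitution matrix: (alphabet->index map, ndarray)."""
    alpha = str(matrix.alphabet)
    arr = np.asarray(matrix, dtype=float)
    return {c: k for k, c in enumerate(alpha)}, arr


def _encode(seq: str, idx: dict[str, int], what: str) -> np.ndarray:
    try:
        return np.array([idx[c] for c in seq], dtype=int)
    except KeyError as e:
        raise ValueError(f"residue {e.args[0]!r} in {what} absent from the "
                         "substitution matrix") from None


def pairwise_align(a: str, b: str, matrix=None,
                   gap_open: float = 10.0, gap_extend: float = 1.0,
                   ids: tuple[str, str] = ("a", "b")):
    """Global affine-gap alignment of two sequences.

    Returns (Alignment, score).  A length-L gap costs gap_open + L*gap_extend.
    """
    if not a or not b:
        # all-gap vs sequence: single run of gaps
        if not a and not b:
            raise ValueError("both sequences empty")
        seq = a or b
        cost = -(gap_open + gap_extend * len(seq))
        rows = ([seq, GAP * len(seq)] if a else [GAP * len(seq), seq])
        return Alignment(list(ids), rows), cost
    if gap_open < 0 or gap_extend < 0:
        raise ValueError("gap costs must be non-negative")
    matrix = default_matrix() if matrix is None else matrix
    idx, arr = _matrix_lookup(matrix)
    ea = _encode(a.upper(), idx, "first sequence")
    eb = _encode(b.upper(), idx, "second sequence")
    S = arr[np.ix_(ea, eb)]
    score, ops = _gotoh(S, gap_open, gap_extend)
    ra, rb, ia, ib = [], [], 0, 0
    for op in ops:
        if op == "D":
            ra.append(a[ia]); rb.append(b[ib]); ia += 1; ib += 1
        elif op == "U":
            ra.append(a[ia]); rb.append(GAP); ia += 1
        else:
            ra.append(GAP); rb.append(b[ib]); ib += 1
    return Alignment(list(ids), ["".join(ra), "".join(rb)]), score


def _profile_freqs(aln: Alignment, idx: dict[str, int], n_sym: int) -> np.ndarray:
    """Per-column residue frequencies (gaps excluded; renormalised)."""
    F = np.zeros((aln.width, n_sym))
    for r in aln.rows:
        for j, c in enumerate(r):
            if c != GAP:
                if c not in idx:
                    raise ValueError(f"residue {c!r} absent from the substitution matrix")
                F[j, idx[c]] += 1.0
    tot = F.sum(axis=1, keepdims=True)
    tot[tot == 0] = 1.0
    return F / tot


def _merge(aln_a: Alignment, aln_b: Alignment, arr, idx,
           gap_open: float, gap_extend: float) -> Alignment:
    """Profile-profile alignment: mean substitution score over residue pairs."""
    FA = _profile_freqs(aln_a, idx, arr.shape[0])
    FB = _profile_freqs(aln_b, idx, arr.shape[0])
    S = FA @ arr @ FB.T
    _, ops = _gotoh(S, gap_open, gap_extend)
    rows_a = [[] for _ in aln_a.rows]
    rows_b = [[] for _ in aln_b.rows]
    ia = ib = 0
    for op in ops:
        if op in ("D", "U"):
            for k, r in enumerate(aln_a.rows):
                rows_a[k].append(r[ia])
            ia += 1
        else:
            for k in range(len(rows_a)):
                rows_a[k].append(GAP)
        if op in ("D", "L"):
            for k, r in enumerate(aln_b.rows):
                rows_b[k].append(r[ib])
            ib += 1
        else:
            for k in range(len(rows_b)):
                rows_b[k].append(GAP)
    return Alignment(aln_a.ids + aln_b.ids,
                     ["".join(r) for r in rows_a] + ["".join(r) for r in rows_b])


def _p_distance(aln: Alignment) -> float:
    a, b = aln.rows
    pairs = [(x, y) for x, y in zip(a, b) if x != GAP and y != GAP]
    if not pairs:
        return 1.0
    return sum(x != y for x, y in pairs) / len(pairs)


def progressive_align(records: list[tuple[str, str]], matrix=None,
                      gap_open: float = 10.0, gap_extend: float = 1.0) -> Alignment:
    """Progressive multiple alignment over an NJ guide tree.

    Guide tree from NJ on p-distances of all pairwise alignments; profiles are
    merged in guide-tree postorder with profile-profile affine alignment
    (arithmetic-mean substitution scores, gaps excluded).  Row order equals
    input order.  Deterministic.
    """
    ids = [sid for sid, _ in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    if len(records) < 2:
        raise ValueError("progressive alignment needs at least 2 records")
    matrix = default_matrix() if matrix is None else matrix
    if len(records) == 2:
        aln, _ = pairwise_align(records[0][1], records[1][1], matrix,
                                gap_open, gap_extend, ids=(ids[0], ids[1]))
        return aln

    idx, arr = _matrix_lookup(matrix)
    n = len(records)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln, _ = pairwise_align(records[i][1], records[j][1], matrix,
                                    gap_open, gap_extend)
            D[i, j] = D[j, i] = _p_distance(aln)

    from .phylo import DistanceMatrix, nj_tree  # deferred: phylo imports this module
    guide = nj_tree(DistanceMatrix(ids, D))

    profiles: dict[int, Alignment] = {}

    def build(node) -> Alignment:
        if node.is_leaf:
            sid = node.name
            return Alignment([sid], [dict(records)[sid]])
        parts = [build(c) for c in node.children]
        merged = parts[0]
        for p in parts[1:]:
            merged = _merge(merged, p, arr, idx, gap_open, gap_extend)
        return merged

    msa = build(guide.root)
    order = {sid: k for k, sid in enumerate(ids)}
    perm = sorted(range(len(msa.ids)), key=lambda k: order[msa.ids[k]])
    return Alignment([msa.ids[k] for k in perm], [msa.rows[k] for k in perm])
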