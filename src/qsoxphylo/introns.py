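"""Intron positions in protein coordinates and their conservation.

Gene models arrive as ordered exon CDS lengths (nucleotides, stop codon in
the last exon).  An internal exon boundary at cumulative CDS offset c maps to
intron phase c mod 3 and codon index floor(c / 3) — a phase-1/2 intron is
assigned to the codon it interrupts.  Positions are projected through a
multiple alignment (codon index k -> column of the (k+1)-th non-gap residue)
so that positional homology can be tested across sequences, and two groups of
projected positions can be partitioned into shared and group-specific sets
under a column tolerance and an optional phase-equality requirement.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .align import GAP


@dataclass(frozen=True)
class GeneModel:
    """Ordered exon CDS lengths for one gene; sum = 3 * protein length + 3."""

    seqid: str
    exon_lengths: tuple[int, ...]

    def __post_init__(self):
        if not self.exon_lengths or any(x <= 0 for x in self.exon_lengths):
            raise ValueError("exon CDS lengths must be positive")
        if sum(self.exon_lengths) % 3 != 0:
            raise ValueError("total CDS length must be a codon multiple")

    @property
    def protein_length(self) -> int:
        return sum(self.exon_lengths) // 3 - 1

    def validate_against(self, protein_length: int) -> None:
        if sum(self.exon_lengths) != 3 * protein_length + 3:
            raise ValueError(
                f"gene {self.seqid}: CDS length {sum(self.exon_lengths)} does "
                f"not match 3*{protein_length}+3")


@dataclass(frozen=True)
class IntronPosition:
    """An intron in protein coordinates, optionally projected to a column."""

    seqid: str
    codon_index: int          # 0-based codon containing/following the junction
    phase: int                # 0, 1 or 2 = CDS offset mod 3
    column: int | None = None

    @property
    def projected(self) -> bool:
        return self.column is not None


def protein_intron_positions(gene: GeneModel,
                             protein_length: int | None = None
                             ) -> list[IntronPosition]:
    """Intron positions of a gene model, sorted by CDS offset."""
    if protein_length is not None:
        gene.validate_against(protein_length)
    out = []
    c = 0
    for exon in gene.exon_lengths[:-1]:
        c += exon
        out.append(IntronPosition(gene.seqid, c // 3, c % 3))
    return out


def project_to_alignment(positions: list[IntronPosition],
                         msa_row: str) -> list[IntronPosition]:
    """Attach the alignment column holding each position's codon.

    Codon index k maps to the column of the (k+1)-th non-gap residue of the
    row; projection is strictly increasing in codon index.
    """
    cols = [j for j, c in enumerate(msa_row) if c != GAP]
    out = []
    for pos in positions:
        if pos.codon_index >= len(cols):
            raise ValueError(
                f"codon index {pos.codon_index} beyond degapped row length "
                f"{len(cols)} for {pos.seqid}")
        out.append(replace(pos, column=cols[pos.codon_index]))
    return out


def shared_intron_positions(group_a: list[IntronPosition],
                            group_b: list[IntronPosition],
                            tolerance: int = 0, require_phase: bool = True):
    """Partition two projected position groups into (shared, A-only, B-only).

    A position is shared when some position of the other group lies within
    +/- tolerance columns (equal phase if required); matching is one-to-one,
    greedy nearest-first, so |shared from A| = |shared from B|.  Returns
    (shared_pairs, a_only, b_only); the partition is exhaustive and disjoint.
    """
    for pos in list(group_a) + list(group_b):
        if not pos.projected:
            raise ValueError(f"position {pos} has not been projected")
    candidates = []
    for i, pa in enumerate(group_a):
        for j, pb in enumerate(group_b):
            if require_phase and pa.phase != pb.phase:
                continue
            d = abs(pa.column - pb.column)
            if d <= tolerance:
                candidates.append((d, i, j))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    shared: list[tuple[IntronPosition, IntronPosition]] = []
    for d, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        shared.append((group_a[i], group_b[j]))
    a_only = [p for i, p in enumerate(group_a) if i not in used_a]
    b_only = [p for j, p in enumerate(group_b) if j not in used_b]
    return shared, a_only, b_only


def element_summary(positions: list[IntronPosition],
                    elements: list[tuple[str, int, int]]) -> pd.DataFrame:
    """Count intron positions per user-annotated element.

    *elements* are (name, start, end) residue ranges (0-based half-open) on
    the same protein as the positions' codon indices — e.g. secondary
    structure elements supplied as annotation.  Positions outside every
    element are tallied under 'outside'.
    """
    counts = {name: 0 for name, _, _ in elements}
    counts["outside"] = 0
    for p in positions:
        for name, s, e in elements:
            if s <= p.codon_index < e:
                counts[name] += 1
                break
        else:
            counts["outside"] += 1
    return pd.DataFrame({"element": list(counts), "n_introns": list(counts.values())})


# ---------------------------------------------------------------------------
# IO


def read_gene_models(path) -> dict[str, GeneModel]:
    """TSV with columns seqid, comma-separated exon CDS lengths."""
    out = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            if not line.strip():
                continue
            seqid, lens = line.rstrip("\n").split("\t")
            out[seqid] = GeneModel(seqid, tuple(int(x) for x in lens.split(",")))
    return out


def write_sharing_report(shared, a_only, b_only, path,
                         group_names=("A", "B")) -> None:
    rows = []
    for pa, pb in shared:
        rows.append({"seqid": pa.seqid, "codon_index": pa.codon_index,
                     "phase": pa.phase, "column": pa.column,
                     "status": "shared", "group": group_names[0]})
        rows.append({"seqid": pb.seqid, "codon_index": pb.codon_index,
                     "phase": pb.phase, "column": pb.column,
                     "status": "shared", "group": group_names[1]})
    for name, only in zip(group_names, (a_only, b_only)):
        for p in only:
            rows.append({"seqid": p.seqid, "codon_index": p.codon_index,
                         "phase": p.phase, "column": p.column,
                         "status": f"{name}-only", "group": name})
    pd.DataFrame(rows, columns=["seqid", "codon_index", "phase", "column",
                                "status", "group"]).to_csv(path, sep="\t",
                                                           index=False)
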