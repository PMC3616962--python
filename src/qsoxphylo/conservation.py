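"""Per-column conservation scoring and its mapping onto structure.

The conservation score is sequence-logo information content: for a column
with residue distribution p, IC = log2(20) - H(p) bits, optionally reduced by
the small-sample correction e(n) = 19 / (2 ln2 n) and clamped at zero.  Gaps
and unknown residues are excluded from the counts; columns gappier than a
threshold are flagged unreliable.  Conserved regions are maximal runs of
high-IC columns (a bounded number of below-threshold columns may sit inside
a run), ranked by mean IC.

Scores can be written onto the temperature-factor field of a PDB coordinate
file for structure-painted display (read/written with Biopython's Bio.PDB).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import GAP, Alignment

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
MAX_IC = math.log2(20)


def small_sample_correction(n: int) -> float:
    """e(n) = (|alphabet| - 1) / (2 ln2 n)."""
    return 19.0 / (2.0 * math.log(2.0) * n)


def column_information(counts, correction: bool = False) -> float:
    """Information content (bits) of one column from residue counts.

    *counts* maps residue -> count; gaps and 'X' are ignored.  Raises on an
    all-gap column (no usable residues).
    """
    usable = {r: c for r, c in dict(counts).items()
              if r in ALPHABET and c > 0}
    n = sum(usable.values())
    if n < 1:
        raise ValueError("column has no usable residues")
    H = -sum((c / n) * math.log2(c / n) for c in usable.values())
    ic = MAX_IC - H - (small_sample_correction(n) if correction else 0.0)
    return max(ic, 0.0)


@dataclass
class ConservationProfile:
    """Per-column conservation of an alignment."""

    ic: np.ndarray                 # bits, 0 for all-gap columns
    gap_fraction: np.ndarray
    consensus: list[str]
    unreliable: np.ndarray         # gap fraction above threshold
    all_gap: np.ndarray
    counts: pd.DataFrame           # residues x columns (logo-ready)
    gap_threshold: float
    correction: bool

    @property
    def width(self) -> int:
        return len(self.ic)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "column": np.arange(self.width),
            "ic_bits": self.ic,
            "gap_fraction": self.gap_fraction,
            "consensus": self.consensus,
            "unreliable": self.unreliable,
            "all_gap": self.all_gap,
        })

    def write_tsv(self, path) -> None:
        df = self.to_frame()
        with open(path, "w") as fh:
            fh.write(f"# conservation = information content (bits), "
                     f"alphabet 20, correction={self.correction}, "
                     f"gap_threshold={self.gap_threshold}\n")
            df.to_csv(fh, sep="\t", index=False)

    def write_frequency_matrix(self, path) -> None:
        """Logo-ready residues-by-columns count matrix (tab-separated)."""
        self.counts.to_csv(path, sep="\t")


def conservation_profile(msa: Alignment, gap_threshold: float = 0.5,
                         correction: bool = False) -> ConservationProfile:
    """Score every column of an alignment."""
    if msa.n_rows == 0 or msa.width == 0:
        raise ValueError("empty alignment")
    W = msa.width
    ic = np.zeros(W)
    gapf = np.zeros(W)
    cons: list[str] = []
    allgap = np.zeros(W, dtype=bool)
    count_mat = pd.DataFrame(0, index=list(ALPHABET), columns=range(W))
    for j in range(W):
        col = msa.column(j)
        counts = Counter(col)
        n_gap = counts.get(GAP, 0) + counts.get("X", 0)
        gapf[j] = counts.get(GAP, 0) / msa.n_rows
        usable = {r: c for r, c in counts.items() if r in ALPHABET}
        for r, c in usable.items():
            count_mat.loc[r, j] = c
        if not usable:
            allgap[j] = True
            ic[j] = 0.0
            cons.append(GAP)
            continue
        ic[j] = column_information(usable, correction)
        cons.append(max(sorted(usable), key=lambda r: usable[r]))
    return ConservationProfile(
        ic=ic, gap_fraction=gapf, consensus=cons,
        unreliable=(gapf > gap_threshold) | allgap, all_gap=allgap,
        counts=count_mat, gap_threshold=gap_threshold, correction=correction)


@dataclass
class ConservedRegion:
    start: int          # column interval, 0-based half-open
    end: int
    mean_ic: float
    rank: int = 0

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def find_conserved_regions(profile: ConservationProfile,
                           ic_threshold: float = 3.0, min_len: int = 4,
                           max_gap: int = 1) -> list[ConservedRegion]:
    """Maximal high-IC column runs, ranked by mean IC.

    A run starts and ends at columns with IC >= ic_threshold and may contain
    at most *max_gap* below-threshold columns in total; runs shorter than
    *min_len* columns are discarded.  Two blocks separated by more than
    max_gap low columns are never merged.
    """
    if ic_threshold <= 0 or min_len <= 0 or max_gap < 0:
        raise ValueError("thresholds must be positive (max_gap >= 0)")
    high = profile.ic >= ic_threshold
    regions: list[ConservedRegion] = []
    j = 0
    W = profile.width
    while j < W:
        if not high[j]:
            j += 1
            continue
        start = j
        last_high = j
        budget = max_gap
        k = j + 1
        while k < W:
            if high[k]:
                last_high = k
                k += 1
            else:
                gap_run = 0
                while k < W and not high[k]:
                    gap_run += 1
                    k += 1
                if k < W and gap_run <= budget:
                    budget -= gap_run
                else:
                    break
        end = last_high + 1
        if end - start >= min_len:
            regions.append(ConservedRegion(
                start, end, float(profile.ic[start:end].mean())))
        j = max(k, end)
    regions.sort(key=lambda r: (-r.mean_ic, r.start))
    for rank, r in enumerate(regions, start=1):
        r.rank = rank
    regions.sort(key=lambda r: r.start)
    return regions


def linker_length_stats(annotations, band: tuple[int, int] = (20, 35)) -> dict:
    """Lengths of inter-domain linkers with outliers beyond *band* flagged.

    Outlying linkers in real data often arise from mispredicted gene models,
    so they are reported, not discarded.
    """
    lengths = {}
    for a in annotations:
        if getattr(a, "ok", True) and a.linker_span is not None:
            lengths[a.seqid] = a.linker_span[1] - a.linker_span[0]
    if not lengths:
        raise ValueError("no annotated linkers")
    vals = sorted(lengths.values())
    lo, hi = band
    return {
        "n": len(vals),
        "min": vals[0],
        "max": vals[-1],
        "median": float(np.median(vals)),
        "histogram": dict(sorted(Counter(vals).items())),
        "band": band,
        "outliers": {s: v for s, v in sorted(lengths.items())
                     if v < lo or v > hi},
    }


def map_profile_to_structure(profile: ConservationProfile, msa: Alignment,
                             ref_id: str, coords_path, chain: str | None = None,
                             out_pdb=None, offset_map: dict[int, int] | None = None
                             ) -> pd.DataFrame:
    """Map per-column scores onto a structure via an ungapped reference row.

    Alignment column -> reference residue index (skipping reference gaps) ->
    structure residue, in chain order.  Without an explicit *offset_map* the
    chain must have exactly as many residues as the degapped reference row.
    Scores go into the B-factor field of *out_pdb* (if given) and into the
    returned per-residue table.
    """
    from Bio.PDB import PDBIO, PDBParser

    row = msa.row(ref_id)
    ref_cols = [j for j, c in enumerate(row) if c != GAP]
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("ref", coords_path)
    model = next(structure.get_models())
    chains = {c.id: c for c in model.get_chains()}
    ch = chains[chain] if chain is not None else next(iter(chains.values()))
    residues = [r for r in ch.get_residues() if r.id[0] == " "]
    if offset_map is None:
        if len(residues) != len(ref_cols):
            raise ValueError(
                f"structure chain has {len(residues)} residues but the "
                f"degapped reference row has {len(ref_cols)}; supply an "
                "offset map")
        offset_map = {i: i for i in range(len(ref_cols))}

    rows = []
    for ref_idx, col in enumerate(ref_cols):
        if ref_idx not in offset_map:
            continue
        res = residues[offset_map[ref_idx]]
        score = float(profile.ic[col])
        for atom in res:
            atom.set_bfactor(score)
        rows.append({"column": col, "ref_index": ref_idx,
                     "residue_number": res.id[1], "residue": res.resname,
                     "score": score})
    if out_pdb is not None:
        io = PDBIO()
        io.set_structure(structure)
        io.save(str(out_pdb))
    return pd.DataFrame(rows)
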