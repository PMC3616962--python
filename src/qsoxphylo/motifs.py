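"""Domain annotation, redox-motif tabulation and percent similarity.

Family membership is pattern-defined: a sequence belongs to the two-domain
family iff it carries both a Trx-pattern match and a downstream Erv-pattern
match.  The Trx annotation is the FIRST pattern match (the N-terminal
catalytic copy, by the family's domain-order convention); the Erv annotation
is the first match starting after the Trx match ends.  Sequences lacking
either domain are reported as annotation failures with a reason, not as
exceptions.

The three CXXC motifs (Trx-CXXC, Erv-CXXC and the carboxy-terminal CT-CXXC),
the structural C-x(5,9)-C loop and the discriminant residue two positions
upstream of the Trx-CXXC are read directly off the match captures.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .align import pairwise_align, default_matrix
from .patterns import DomainPattern, erv_pattern, scan, trx_pattern

CXXC_SITES = ("trx_cxxc", "erv_cxxc", "ct_cxxc")


@dataclass
class DomainAnnotation:
    """Domain spans, motif sites and the discriminant residue of one sequence.

    ``failure`` is None for annotated sequences; otherwise it carries the
    reason ('missing Trx', 'missing Erv', 'Erv only upstream of Trx') and the
    coordinate fields are None.
    """

    seqid: str
    failure: str | None = None
    trx_span: tuple[int, int] | None = None
    erv_span: tuple[int, int] | None = None
    linker_span: tuple[int, int] | None = None
    motifs: dict[str, tuple[int, int, str]] = field(default_factory=dict)
    discriminant: tuple[int, str] | None = None
    non_cxxc: bool = False

    @property
    def ok(self) -> bool:
        return self.failure is None

    def motif_string(self, label: str) -> str | None:
        m = self.motifs.get(label)
        return m[2] if m else None


def _as_record(record) -> tuple[str, str]:
    if isinstance(record, str):
        return ("", record)
    sid, seq = record
    return sid, seq


def annotate(record, trx: DomainPattern | None = None,
             erv: DomainPattern | None = None) -> DomainAnnotation:
    """Annotate one sequence with its Trx and Erv domains and motif sites."""
    seqid, seq = _as_record(record)
    if not seq:
        raise ValueError("cannot annotate an empty sequence")
    trx = trx or trx_pattern()
    erv = erv or erv_pattern()
    tm = scan(trx, seq, mode="first", seqid=seqid)
    if not tm:
        return DomainAnnotation(seqid, failure="missing Trx")
    tmatch = tm[0]
    suffix = seq[tmatch.end:]
    em = scan(erv, suffix, mode="first", seqid=seqid)
    if not em:
        if scan(erv, seq, mode="first", seqid=seqid):
            return DomainAnnotation(seqid, failure="Erv only upstream of Trx")
        return DomainAnnotation(seqid, failure="missing Erv")
    off = tmatch.end
    ematch = em[0]
    erv_span = (ematch.start + off, ematch.end + off)

    motifs: dict[str, tuple[int, int, str]] = {}
    for lab, (s, e) in tmatch.captured.items():
        motifs[lab] = (s, e, seq[s:e])
    for lab, (s, e) in ematch.captured.items():
        motifs[lab] = (s + off, e + off, seq[s + off:e + off])
    d_pos = motifs["trx_cxxc"][0] - 2
    non_cxxc = any(not (motifs[lab][2].startswith("C") and motifs[lab][2].endswith("C"))
                   for lab in CXXC_SITES)
    return DomainAnnotation(
        seqid,
        trx_span=tmatch.span,
        erv_span=erv_span,
        linker_span=(tmatch.end, erv_span[0]),
        motifs=motifs,
        discriminant=(d_pos, seq[d_pos]),
        non_cxxc=non_cxxc,
    )


def annotate_family(records, trx: DomainPattern | None = None,
                    erv: DomainPattern | None = None):
    """Annotate many records; returns (annotated, failures)."""
    trx = trx or trx_pattern()
    erv = erv or erv_pattern()
    anns, fails = [], []
    for rec in records:
        a = annotate(rec, trx, erv)
        (anns if a.ok else fails).append(a)
    return anns, fails


def motif_table(annotations, clade_labels: dict[str, str]) -> pd.DataFrame:
    """One row per annotated sequence: clade, the three CXXC motif strings,
    the discriminant residue and the non-CxxC flag.

    Sequences absent from *clade_labels* are labeled 'unassigned'.
    """
    rows = []
    for a in annotations:
        if not a.ok:
            continue
        rows.append({
            "seqid": a.seqid,
            "clade": clade_labels.get(a.seqid, "unassigned"),
            "trx_cxxc": a.motif_string("trx_cxxc"),
            "erv_cxxc": a.motif_string("erv_cxxc"),
            "ct_cxxc": a.motif_string("ct_cxxc"),
            "discriminant": a.discriminant[1],
            "non_cxxc": a.non_cxxc,
        })
    return pd.DataFrame(rows, columns=["seqid", "clade", "trx_cxxc", "erv_cxxc",
                                       "ct_cxxc", "discriminant", "non_cxxc"])


def clade_consensus_motifs(table: pd.DataFrame) -> dict:
    """Per clade and motif site: frequency spectrum, modal motif, uniformity.

    Frequencies sum to 1 within each clade/site; the uniformity flag is true
    iff a single motif string occurs.  Empty clades are absent.
    """
    if table.empty:
        raise ValueError("empty motif table")
    out: dict[str, dict[str, dict]] = {}
    for clade, sub in table.groupby("clade", sort=True):
        sites = {}
        for site in CXXC_SITES:
            counts = Counter(sub[site])
            total = sum(counts.values())
            freqs = {m: c / total for m, c in sorted(counts.items())}
            modal = max(sorted(counts), key=lambda m: counts[m])
            sites[site] = {"freqs": freqs, "modal": modal,
                           "modal_frequency": counts[modal] / total,
                           "uniform": len(counts) == 1}
        out[clade] = sites
    return out


def percent_similarity(a, b, scoring=None, gap_open: float = 10.0,
                       gap_extend: float = 1.0) -> float:
    """Percent similarity of two sequences under a substitution matrix.

    The sequences are globally aligned (affine gaps); similarity is
    100 x (aligned residue pairs with a positive substitution score) /
    (alignment columns).  Symmetric and deterministic.
    """
    _, sa = _as_record(a)
    _, sb = _as_record(b)
    if not sa or not sb:
        raise ValueError("percent_similarity requires non-empty sequences")
    scoring = default_matrix() if scoring is None else scoring
    aln, _ = pairwise_align(sa, sb, scoring, gap_open, gap_extend)
    ra, rb = aln.rows
    positive = sum(
        1 for x, y in zip(ra, rb)
        if x != "-" and y != "-" and scoring[x, y] > 0
    )
    return 100.0 * positive / aln.width


# ---------------------------------------------------------------------------
# writers


def write_annotations(annotations, tsv_path, json_path=None) -> None:
    """BED-like TSV (0-based half-open) plus optional JSON detail."""
    with open(tsv_path, "w") as fh:
        fh.write("seqid\tstart\tend\tfeature\n")
        for a in annotations:
            if not a.ok:
                fh.write(f"{a.seqid}\t.\t.\tFAILED:{a.failure}\n")
                continue
            for (s, e), feat in [(a.trx_span, "trx"), (a.linker_span, "linker"),
                                 (a.erv_span, "erv")]:
                fh.write(f"{a.seqid}\t{s}\t{e}\t{feat}\n")
            for lab, (s, e, _) in a.motifs.items():
                fh.write(f"{a.seqid}\t{s}\t{e}\t{lab}\n")
    if json_path:
        detail = []
        for a in annotations:
            d = {"seqid": a.seqid, "failure": a.failure}
            if a.ok:
                d.update(trx_span=a.trx_span, erv_span=a.erv_span,
                         linker_span=a.linker_span,
                         motifs={k: list(v) for k, v in a.motifs.items()},
                         discriminant=list(a.discriminant),
                         non_cxxc=a.non_cxxc)
            detail.append(d)
        with open(json_path, "w") as fh:
            json.dump(detail, fh, indent=1)
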