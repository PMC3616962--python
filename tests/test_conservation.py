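"""Information-content conservation, region detection, structure mapping."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qsoxphylo.align import Alignment
from qsoxphylo.conservation import (ConservationProfile, column_information,
                                    conservation_profile,
                                    find_conserved_regions,
                                    linker_length_stats,
                                    map_profile_to_structure,
                                    small_sample_correction)
from qsoxphylo.models import AA_ORDER
from qsoxphylo.motifs import DomainAnnotation
from qsoxphylo.simulate import balanced_tree, simulate_alignment


def synthetic_pdb(path, sequence: str, chain: str = "A") -> None:
    """Write a synthetic CA-only PDB file for *sequence* (test stand-in for a
    real experimental structure)."""
    three = {"A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
             "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
             "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
             "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR"}
    with open(path, "w") as fh:
        for i, aa in enumerate(sequence, start=1):
            fh.write(f"ATOM  {i:5d}  CA  {three[aa]} {chain}{i:4d}    "
                     f"{float(i):8.3f}{0.0:8.3f}{0.0:8.3f}{1.00:6.2f}{0.00:6.2f}"
                     f"           C\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# column information


def test_information_closed_forms():
    assert column_information({"A": 7}) == pytest.approx(math.log2(20), abs=1e-12)
    uniform = {aa: 1 for aa in AA_ORDER}
    assert column_information(uniform) == pytest.approx(0.0, abs=1e-12)
    assert column_information({"G": 5, "H": 5}) == \
        pytest.approx(math.log2(20) - 1.0, abs=1e-12)


def test_small_sample_correction_form_and_clamp():
    assert small_sample_correction(100) == pytest.approx(19 / (2 * math.log(2) * 100))
    # with one sequence the correction exceeds the maximum -> clamped at 0
    assert column_information({"A": 1}, correction=True) == 0.0


def test_all_gap_column_raises():
    with pytest.raises(ValueError):
        column_information({"-": 5, "X": 2})


@given(st.dictionaries(st.sampled_from(list(AA_ORDER)),
                       st.integers(min_value=1, max_value=50),
                       min_size=1, max_size=20))
@settings(deadline=None, derandomize=True)
def test_ic_stays_within_logo_bounds(counts):
    ic = column_information(counts)
    assert 0.0 <= ic <= math.log2(20) + 1e-12


def test_adding_modal_residue_never_decreases_ic():
    rng = np.random.default_rng(2)
    for _ in range(50):
        ks = rng.integers(1, 10, size=rng.integers(2, 6))
        counts = {AA_ORDER[i]: int(k) for i, k in enumerate(ks)}
        base = column_information(counts)
        modal = max(counts, key=counts.get)
        counts[modal] += 1
        assert column_information(counts) >= base - 1e-12


# ---------------------------------------------------------------------------
# profiles


def test_profile_of_identical_sequences_is_maximal():
    msa = Alignment([f"s{i}" for i in range(6)], ["MKLV"] * 6)
    prof = conservation_profile(msa)
    assert np.allclose(prof.ic, math.log2(20))
    assert prof.consensus == list("MKLV")


def test_gappy_column_flagged_unreliable():
    rows = ["M-", "M-", "MA", "M-", "MA"]
    msa = Alignment([f"s{i}" for i in range(5)], rows)
    prof = conservation_profile(msa, gap_threshold=0.5)
    assert not prof.unreliable[0]
    assert prof.unreliable[1]          # 60% gaps
    assert prof.gap_fraction[1] == pytest.approx(0.6)


def test_all_gap_column_scored_zero_with_flag():
    msa = Alignment(["a", "b"], ["M-", "K-"])
    prof = conservation_profile(msa)
    assert prof.ic[1] == 0.0 and prof.all_gap[1] and prof.unreliable[1]


def test_planted_motif_columns_outscore_free_columns(family):
    _, truth = family
    msa = truth.alignment
    prof = conservation_profile(msa)
    motif_cols = set()
    sid0 = msa.ids[0]
    row0 = msa.row(sid0)
    nongap = [j for j, c in enumerate(row0) if c != "-"]
    t = truth.per_seq[sid0]
    for lab in ("trx_cxxc", "erv_cxxc", "ct_cxxc"):
        s, e, _ = t.motifs[lab]
        motif_cols.update(nongap[k] for k in range(s, e))
    free = [prof.ic[j] for j in range(msa.width)
            if j not in motif_cols and not prof.unreliable[j]]
    for j in motif_cols:
        assert prof.ic[j] > np.median(free)


# ---------------------------------------------------------------------------
# conserved regions


def _fake_profile(ic):
    ic = np.asarray(ic, dtype=float)
    W = len(ic)
    return ConservationProfile(ic=ic, gap_fraction=np.zeros(W),
                               consensus=["A"] * W,
                               unreliable=np.zeros(W, bool),
                               all_gap=np.zeros(W, bool), counts=None,
                               gap_threshold=0.5, correction=False)


def test_flat_low_profile_yields_no_regions():
    assert find_conserved_regions(_fake_profile([1.0] * 50)) == []


def test_regions_allow_bounded_internal_gaps_never_merge_distant_blocks():
    ic = [0.5] * 60
    for j in range(10, 14):
        ic[j] = 4.0
    for j in range(16, 20):
        ic[j] = 4.0          # separated by 2 low columns > max_gap=1
    regions = find_conserved_regions(_fake_profile(ic), 3.0, 4, 1)
    assert [(r.start, r.end) for r in regions] == [(10, 14), (16, 20)]
    # with budget 2 the same blocks fuse into one region
    fused = find_conserved_regions(_fake_profile(ic), 3.0, 4, 2)
    assert [(r.start, r.end) for r in fused] == [(10, 20)]


def test_short_runs_are_discarded():
    ic = [0.5] * 30
    ic[5:8] = [4.0, 4.0, 4.0]
    assert find_conserved_regions(_fake_profile(ic), 3.0, 4, 1) == []


def test_six_planted_blocks_recovered():
    """An alignment with six invariable blocks on a deep balanced tree yields
    exactly six conserved regions at the default thresholds."""
    blocks = [(30, 35), (80, 85), (130, 135), (180, 185), (230, 235), (280, 285)]
    rng = np.random.default_rng(99)
    inv = {p: AA_ORDER[rng.integers(20)] for s, e in blocks for p in range(s, e)}
    tree = balanced_tree(5, 0.5)       # 32 leaves, every pair >= 1.0 apart
    msa = simulate_alignment(tree, 300, "jtt", seed=1, invariable=inv)
    regions = find_conserved_regions(conservation_profile(msa))
    assert len(regions) == 6
    for r, (s, e) in zip(regions, blocks):
        assert r.start < e and r.end > s  # overlaps its planted block
    assert sorted({r.rank for r in regions}) == [1, 2, 3, 4, 5, 6]


# ---------------------------------------------------------------------------
# linker statistics


def _ann(seqid, length):
    return DomainAnnotation(seqid, trx_span=(10, 80),
                            erv_span=(80 + length, 240 + length),
                            linker_span=(80, 80 + length))


def test_linker_stats_of_default_family(family, family_annotations):
    anns, _ = family_annotations
    stats = linker_length_stats(anns)
    assert stats["min"] >= 20 and stats["max"] <= 35
    assert stats["outliers"] == {}
    assert stats["n"] == len(anns)


def test_planted_long_linker_flagged_outlier():
    stats = linker_length_stats([_ann("a", 25), _ann("b", 100)])
    assert stats["outliers"] == {"b": 100}


def test_single_annotation_degenerate_stats():
    stats = linker_length_stats([_ann("a", 22)])
    assert stats["min"] == stats["max"] == stats["median"] == 22


# ---------------------------------------------------------------------------
# structure mapping


def test_gapless_reference_maps_one_to_one(tmp_path):
    msa = Alignment(["r", "s"], ["MKLV", "MKIV"])
    prof = conservation_profile(msa)
    pdb = tmp_path / "synthetic.pdb"
    synthetic_pdb(pdb, "MKLV")
    df = map_profile_to_structure(prof, msa, "r", pdb)
    assert list(df.column) == [0, 1, 2, 3]
    assert list(df.residue_number) == [1, 2, 3, 4]


def test_gapped_reference_skips_gap_columns(tmp_path):
    msa = Alignment(["r", "s"], ["A-CD", "ABCD".replace("B", "K")])
    prof = conservation_profile(msa)
    pdb = tmp_path / "synthetic.pdb"
    synthetic_pdb(pdb, "ACD")
    df = map_profile_to_structure(prof, msa, "r", pdb)
    assert list(df.column) == [0, 2, 3]
    assert list(df.residue_number) == [1, 2, 3]


def test_length_mismatch_reports_both_lengths(tmp_path):
    msa = Alignment(["r"], ["MKLV"])
    prof = conservation_profile(msa)
    pdb = tmp_path / "synthetic.pdb"
    synthetic_pdb(pdb, "MK")
    with pytest.raises(ValueError, match="2 .*4|4 .*2"):
        map_profile_to_structure(prof, msa, "r", pdb)


def test_bfactor_roundtrip(tmp_path):
    from Bio.PDB import PDBParser
    msa = Alignment(["r", "s", "u"], ["MKLV", "MKLV", "MKLV"])
    prof = conservation_profile(msa)
    pdb = tmp_path / "synthetic.pdb"
    out = tmp_path / "scored.pdb"
    synthetic_pdb(pdb, "MKLV")
    df = map_profile_to_structure(prof, msa, "r", pdb, out_pdb=out)
    reread = PDBParser(QUIET=True).get_structure("x", out)
    b = [a.get_bfactor() for a in reread.get_atoms()]
    assert np.allclose(b, df.score, atol=0.01)   # PDB writes %6.2f
    assert np.allclose(df.score, math.log2(20), atol=1e-6)
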