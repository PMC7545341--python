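"""Tests for seed matching, duplex alignment and free-energy scoring."""

import numpy as np
import pytest

from ceraxis.containers import SequenceSet
from ceraxis.energy import ALLOWED_PAIRS, WC_PAIRS, WOBBLE_PAIRS, default_energy_table
from ceraxis.targets import (
    DEFAULT_DG_MAX,
    DEFAULT_S_MIN,
    duplex_align,
    duplex_dG,
    normalize_rna,
    predict_targets,
    seed_sites,
)

from _oracles import align_enum_oracle, align_oracle, dg_oracle, revcomp, seed_sites_oracle

RNA = "ACGU"


def _random_rna(rng, n):
    return "".join(RNA[i] for i in rng.integers(0, 4, size=n))


# ---------------------------------------------------------------------------
# normalize_rna


def test_normalize_rna():
    assert normalize_rna("acgt") == "ACGU"
    with pytest.raises(ValueError, match="position 2"):
        normalize_rna("ACXG")
    with pytest.raises(ValueError, match="empty"):
        normalize_rna("")


# ---------------------------------------------------------------------------
# seed_sites


MIR = "UGGAAUGUAAAGAAGUAUGUAU"  # 22 nt


def _flank(rng, n, mir):
    # random flank free of the 6mer core so constructed sites are unique
    core = revcomp(mir[1:7])
    while True:
        f = _random_rna(rng, n)
        if core not in f:
            return f


def test_seed_classes_by_construction(rng):
    core7 = revcomp(MIR[1:8])  # opposite positions 2-8
    core6 = revcomp(MIR[1:7])
    cases = {
        "8mer": core7 + "A",
        "7mer-m8": core7 + "C",
        "7mer-A1": "G" + core6 + "A",
        "6mer": "G" + core6 + "C",
    }
    for cls, insert in cases.items():
        tgt = _flank(rng, 30, MIR) + insert + _flank(rng, 30, MIR)
        found = seed_sites(MIR, tgt)
        assert len(found) == 1
        assert found[0].seed_class == cls
        s, e = found[0].start, found[0].end
        assert tgt[s:e] in insert


def test_seed_sites_validation():
    with pytest.raises(ValueError):
        seed_sites("ACGU", "ACGUACGU")  # miRNA too short
    with pytest.raises(ValueError):
        seed_sites(MIR, "ACGTZ")


def test_seed_sites_match_exhaustive_oracle(rng):
    n_cases = 0
    for _ in range(120):
        mir = _random_rna(rng, 22)
        # salt targets with the core so matches actually occur
        core = revcomp(mir[1:7])
        tgt = list(_random_rna(rng, 500))
        for _k in range(int(rng.integers(0, 5))):
            p = int(rng.integers(0, 490))
            tgt[p:p + 6] = core
        tgt = "".join(tgt)
        got = [(s.start, s.end, s.seed_class) for s in seed_sites(mir, tgt)]
        assert got == seed_sites_oracle(mir, tgt)
        n_cases += 1
    assert n_cases >= 100


# ---------------------------------------------------------------------------
# duplex_align


def test_perfect_complement_hits_analytic_maximum():
    window = revcomp(MIR)
    aln = duplex_align(MIR, window)
    assert aln.score == pytest.approx(5.0 * (7 * 2 + 15))  # = 145
    assert set(aln.pairing) == {"|"}
    assert len(aln.pairing) == 22


def test_seed_mismatch_strictly_decreases_score(rng):
    window = list(revcomp(MIR))
    # column k of the reversed window pairs miRNA position k+1; corrupt a
    # seed-paired target base (opposite miRNA position 4, 0-based index 3)
    pos_in_window = len(window) - 1 - 3
    original = window[pos_in_window]
    window[pos_in_window] = {"A": "C", "C": "A", "G": "A", "U": "C"}[original]
    corrupted = duplex_align(MIR, "".join(window))
    assert corrupted.score < 145.0


def test_window_length_bounds():
    with pytest.raises(ValueError):
        duplex_align(MIR, "ACGUA")  # 5 nt
    with pytest.raises(ValueError):
        duplex_align(MIR, "ACGU" * 11)  # 44 nt


def test_align_score_matches_gap_enumeration_oracle(rng):
    for _ in range(150):
        mir = _random_rna(rng, int(rng.integers(8, 16)))
        win = _random_rna(rng, int(rng.integers(6, 13)))
        aln = duplex_align(mir, win)
        assert aln.score == pytest.approx(align_oracle(mir, win))


def test_align_score_matches_full_path_enumeration(rng):
    for _ in range(60):
        mir = _random_rna(rng, int(rng.integers(4, 8)))
        win = _random_rna(rng, int(rng.integers(6, 8)))
        aln = duplex_align(mir, win)
        assert aln.score == pytest.approx(align_enum_oracle(mir, win))


def test_strand_role_swap_symmetry(rng):
    # with seed weighting disabled the duplex score is symmetric in the
    # two strands (the pairing rules are); reverse-complement relabeling is
    # NOT a symmetry because G:U wobble does not survive complementation
    for _ in range(50):
        a = _random_rna(rng, int(rng.integers(8, 20)))
        b = _random_rna(rng, int(rng.integers(8, 20)))
        s1 = duplex_align(a, b, seed_weight=1.0).score
        s2 = duplex_align(b, a, seed_weight=1.0).score
        assert s1 == pytest.approx(s2)


def test_alignment_rows_consistent(rng):
    for _ in range(50):
        mir = _random_rna(rng, 22)
        win = _random_rna(rng, 30)
        aln = duplex_align(mir, win)
        assert len(aln.mir_aln) == len(aln.tgt_aln) == len(aln.pairing)
        for m, t, c in zip(aln.mir_aln, aln.tgt_aln, aln.pairing):
            if c == "|":
                assert (m, t) in WC_PAIRS
            elif c == ":":
                assert (m, t) in WOBBLE_PAIRS
            else:
                assert "-" in (m, t) or (m, t) not in ALLOWED_PAIRS


# ---------------------------------------------------------------------------
# duplex_dG


def test_energy_table_invariants():
    table = default_energy_table()
    for (top, bottom), value in table.stacks.items():
        assert value < 0  # every allowed stack is stabilizing
        # symmetric under reading the duplex from the other end
        assert table.stacks[(bottom[::-1], top[::-1])] == pytest.approx(value)


def test_single_isolated_pair_energy():
    aln = duplex_align("AAAAAAUAAA", "GGGAGGGGG")  # lone U:A pair at best
    table = default_energy_table()
    if aln.pairing.count("|") + aln.pairing.count(":") == 1:
        dg = duplex_dG(aln, table)
        assert dg == pytest.approx(table.initiation + table.terminal_au_gu)


def test_extra_wc_stack_strictly_decreases_dg():
    prev = None
    for k in range(2, 12):
        mir = "G" * k
        aln = duplex_align(mir, "C" * max(6, k), seed_weight=1.0)
        dg = duplex_dG(aln)
        if prev is not None and aln.pairing.count("|") == k:
            assert dg < prev
        prev = dg


def test_dg_matches_sum_over_stacks_oracle(rng):
    table = default_energy_table()
    checked = 0
    for _ in range(150):
        mir = _random_rna(rng, 22)
        win = _random_rna(rng, int(rng.integers(10, 30)))
        aln = duplex_align(mir, win)
        if not aln.pairing.strip():
            continue
        dg = duplex_dG(aln, table)
        oracle = dg_oracle(aln.mir_aln, aln.tgt_aln, aln.pairing,
                           table.stacks, table.initiation, table.terminal_au_gu)
        assert dg == pytest.approx(oracle, abs=1e-9)
        checked += 1
    assert checked >= 100


# ---------------------------------------------------------------------------
# predict_targets


def _planted_pair(rng):
    mir = _random_rna(rng, 22)
    site = revcomp(mir[1:16]) + "A"
    lnc = _flank(rng, 100, mir) + site + _flank(rng, 100, mir)
    site_m = revcomp(mir[1:11]) + "A"
    mrna = _flank(rng, 100, mir) + site_m + _flank(rng, 100, mir)
    return mir, lnc, mrna


def test_planted_pairs_retained_decoys_rejected(rng):
    mir, lnc, mrna = _planted_pair(rng)
    decoy = _flank(rng, 200, mir)
    sites = predict_targets(
        SequenceSet({"MIR": mir}),
        SequenceSet({"LNC": lnc, "DECOY": decoy}),
        SequenceSet({"MR": mrna}),
    )
    assert set(sites["target"]) == {"LNC", "MR"}
    assert (sites["align_score"] >= DEFAULT_S_MIN).all()
    assert (sites["dG"] <= DEFAULT_DG_MAX).all()
    assert (sites["dG"] <= 0).all()


def test_smin_above_maximum_empties_output(rng):
    mir, lnc, mrna = _planted_pair(rng)
    sites = predict_targets(
        SequenceSet({"MIR": mir}), SequenceSet({"LNC": lnc}),
        SequenceSet({"MR": mrna}), s_min=146.0,
    )
    assert sites.empty


def test_predicted_pairs_subset_of_seed_pairs(rng):
    for _ in range(10):
        mir, lnc, mrna = _planted_pair(rng)
        tgts = {"LNC": lnc, "MR": mrna, "X": _random_rna(rng, 300)}
        sites = predict_targets(
            SequenceSet({"MIR": mir}), SequenceSet(tgts), None,
            s_min=0.0, dg_max=100.0,
        )
        seeded = {t for t, s in tgts.items() if seed_sites(mir, s)}
        assert set(sites["target"]) <= seeded


def test_predict_targets_validation(rng):
    with pytest.raises(ValueError):
        predict_targets(SequenceSet({}), SequenceSet({"L": "ACGUACGU"}), None)
    with pytest.raises(ValueError):
        predict_targets(SequenceSet({"M": MIR}), None, None)
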