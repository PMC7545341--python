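"""In-repo miRNA target prediction over lncRNAs and mRNA 3'UTRs.

Two complementary detectors, run in intersection the way the screening
pipeline combines a seed-based and an alignment/thermodynamics-based
predictor:

* :func:`seed_sites` -- canonical seed-match taxonomy (8mer, 7mer-m8,
  7mer-A1, 6mer) against miRNA positions 2-8;
* :func:`duplex_align` + :func:`duplex_dG` -- position-weighted
  complementarity alignment (Smith-Waterman/Gotoh with the seed region
  weighted x2) and a nearest-neighbor stacking free energy for the aligned
  duplex.

:func:`predict_targets` retains a (miRNA, target) pair only when some seed
site also clears the alignment-score and free-energy thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .containers import SequenceSet
from .energy import ALLOWED_PAIRS, EnergyTable, WC_PAIRS, WOBBLE_PAIRS, default_energy_table

TARGET_LNC = "lncRNA"
TARGET_UTR3 = "mRNA-3'UTR"

_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}

SEED_CLASSES = ("8mer", "7mer-m8", "7mer-A1", "6mer")

# miRanda-style scoring constants, adapted to this DP
MATCH_WC = 5.0
MATCH_GU = 1.0
MISMATCH = -3.0
GAP_OPEN = -9.0
GAP_EXTEND = -4.0
SEED_WEIGHT = 2.0  # multiplier on substitution scores at miRNA positions 2-8

DEFAULT_S_MIN = 80.0
DEFAULT_DG_MAX = -7.0


def normalize_rna(seq: str, name: str = "sequence") -> str:
    """Uppercase, map T->U, and validate the alphabet."""
    if not seq:
        raise ValueError(f"{name} is empty")
    out = seq.upper().replace("T", "U")
    for pos, c in enumerate(out):
        if c not in "ACGU":
            raise ValueError(f"illegal character {c!r} at position {pos} in {name}")
    return out


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


@dataclass
class TargetSite:
    """One predicted miRNA binding site on a target RNA.

    ``start``/``end`` are 0-based half-open coordinates of the seed-match
    region on the target sense strand.  ``align_score`` and ``dG`` are
    filled by the alignment stage; ``detected_by`` records which detectors
    support the site.
    """

    mirna: str
    target: str
    target_class: str
    start: int
    end: int
    seed_class: str
    align_score: float | None = None
    dG: float | None = None
    detected_by: set[str] = field(default_factory=lambda: {"seed"})


def seed_sites(mirna_seq: str, target_seq: str, mirna: str = "", target: str = "",
               target_class: str = TARGET_UTR3) -> list[TargetSite]:
    """All canonical seed-match sites of the miRNA on the target.

    Each occurrence of the 6mer core (complement of miRNA positions 2-7) is
    reported once, at its most specific class: 8mer (positions 2-8 paired
    plus target A opposite miRNA position 1), 7mer-m8 (2-8), 7mer-A1
    (2-7 plus A), 6mer (2-7).
    """
    mir = normalize_rna(mirna_seq, "miRNA")
    tgt = normalize_rna(target_seq, "target")
    if len(mir) < 8:
        raise ValueError("miRNA must be at least 8 nt")
    core6 = _revcomp(mir[1:7])  # complement of positions 2-7, target 5'->3'
    comp_m8 = _COMPLEMENT[mir[7]]  # base opposite miRNA position 8
    sites: list[TargetSite] = []
    i = tgt.find(core6)
    while i != -1:
        m8 = i >= 1 and tgt[i - 1] == comp_m8
        a1 = i + 6 < len(tgt) and tgt[i + 6] == "A"
        if m8 and a1:
            cls, start, end = "8mer", i - 1, i + 7
        elif m8:
            cls, start, end = "7mer-m8", i - 1, i + 6
        elif a1:
            cls, start, end = "7mer-A1", i, i + 7
        else:
            cls, start, end = "6mer", i, i + 6
        sites.append(TargetSite(mirna, target, target_class, start, end, cls))
        i = tgt.find(core6, i + 1)
    return sites


@dataclass
class DuplexAlignment:
    """Local alignment of a miRNA (5'->3') against a target window (3'->5').

    ``mir_aln`` and ``tgt_aln`` are gapped strings; ``tgt_aln`` is written
    3'->5' so the two rows are read antiparallel.  ``pairing`` marks each
    column '|' (Watson-Crick), ':' (G:U wobble) or ' ' (mismatch/gap).
    ``mir_offset`` is the 0-based miRNA index of the first alignment column;
    ``win_end`` is the window index paired at that column (the 3'-most
    paired window base, original window coordinates).
    """

    score: float
    mir_aln: str
    tgt_aln: str
    pairing: str
    mir_offset: int
    win_end: int


def _pair_symbol(m: str, t: str) -> str:
    if (m, t) in WC_PAIRS:
        return "|"
    if (m, t) in WOBBLE_PAIRS:
        return ":"
    return " "


def _sub_score(m: str, t: str, i: int, seed_weight: float) -> float:
    if (m, t) in WC_PAIRS:
        s = MATCH_WC
    elif (m, t) in WOBBLE_PAIRS:
        s = MATCH_GU
    else:
        s = MISMATCH
    if 1 <= i <= 7:  # 0-based miRNA indices 1..7 = positions 2-8
        s *= seed_weight
    return s


def duplex_align(mirna_seq: str, target_window: str,
                 seed_weight: float = SEED_WEIGHT) -> DuplexAlignment:
    """Optimal local complementarity alignment of miRNA vs. a target window.

    The window is reversed internally so the duplex is scored antiparallel.
    Scoring: Watson-Crick +5, G:U +1, mismatch -3, gap open -9, gap extend
    -4 (an open gap of length k costs -9 - 4(k-1)); substitution scores at
    miRNA positions 2-8 are multiplied by ``seed_weight``.
    """
    mir = normalize_rna(mirna_seq, "miRNA")
    win = normalize_rna(target_window, "target window")
    if not 6 <= len(win) <= 40:
        raise ValueError(f"window length {len(win)} outside [6, 40]")
    rev = win[::-1]
    M, N = len(mir), len(rev)
    NEG = float("-inf")
    # Gotoh: H ends in a substitution, E in a gap in the target (consumes
    # miRNA), F in a gap in the miRNA (consumes target); local (floor 0 on H)
    H = [[0.0] * (N + 1) for _ in range(M + 1)]
    E = [[NEG] * (N + 1) for _ in range(M + 1)]
    F = [[NEG] * (N + 1) for _ in range(M + 1)]
    ptr_h: dict[tuple[int, int], tuple | None] = {}
    ptr_e: dict[tuple[int, int], tuple] = {}
    ptr_f: dict[tuple[int, int], tuple] = {}
    best, bi, bj = 0.0, 0, 0
    for i in range(1, M + 1):
        for j in range(1, N + 1):
            cand_e = (H[i - 1][j] + GAP_OPEN, E[i - 1][j] + GAP_EXTEND)
            E[i][j] = max(cand_e)
            ptr_e[(i, j)] = ("H", i - 1, j) if cand_e[0] >= cand_e[1] else ("E", i - 1, j)
            cand_f = (H[i][j - 1] + GAP_OPEN, F[i][j - 1] + GAP_EXTEND)
            F[i][j] = max(cand_f)
            ptr_f[(i, j)] = ("H", i, j - 1) if cand_f[0] >= cand_f[1] else ("F", i, j - 1)
            s = _sub_score(mir[i - 1], rev[j - 1], i - 1, seed_weight)
            prev = (H[i - 1][j - 1], E[i - 1][j - 1], F[i - 1][j - 1], 0.0)
            k = max(range(4), key=lambda q: prev[q])
            val = prev[k] + s
            if val <= 0.0:
                H[i][j] = 0.0
                ptr_h[(i, j)] = None
            else:
                H[i][j] = val
                ptr_h[(i, j)] = (
                    None if k == 3 or prev[k] == 0.0
                    else (("H", "E", "F")[k], i - 1, j - 1)
                )
            if H[i][j] > best:
                best, bi, bj = H[i][j], i, j

    mir_aln: list[str] = []
    tgt_aln: list[str] = []
    pairing: list[str] = []
    first_i, first_j = bi, bj
    if best > 0:
        state, i, j = "H", bi, bj
        while True:
            if state == "H":
                mir_aln.append(mir[i - 1])
                tgt_aln.append(rev[j - 1])
                pairing.append(_pair_symbol(mir[i - 1], rev[j - 1]))
                first_i, first_j = i, j
                nxt = ptr_h[(i, j)]
                if nxt is None:
                    break
                state, i, j = nxt
            elif state == "E":
                mir_aln.append(mir[i - 1])
                tgt_aln.append("-")
                pairing.append(" ")
                state, i, j = ptr_e[(i, j)]
            else:
                mir_aln.append("-")
                tgt_aln.append(rev[j - 1])
                pairing.append(" ")
                state, i, j = ptr_f[(i, j)]
    mir_aln.reverse()
    tgt_aln.reverse()
    pairing.reverse()
    # original-window coordinate of the 3'-most window base in the alignment
    win_end = N - first_j if best > 0 else 0
    return DuplexAlignment(
        score=float(best),
        mir_aln="".join(mir_aln),
        tgt_aln="".join(tgt_aln),
        pairing="".join(pairing),
        mir_offset=first_i - 1 if best > 0 else 0,
        win_end=win_end,
    )


def duplex_dG(alignment: DuplexAlignment, table: EnergyTable | None = None) -> float:
    """Stacking free energy of the aligned duplex (kcal/mol).

    dG = initiation + sum of nearest-neighbor stack energies over runs of
    consecutive paired columns + a terminal penalty for every helix end
    closed by an A:U or G:U pair.  Interior loops and bulges contribute no
    stacks (a conservative simplification for comparative use).
    """
    table = table or default_energy_table()
    cols = list(zip(alignment.mir_aln, alignment.tgt_aln, alignment.pairing))
    if not (len(alignment.mir_aln) == len(alignment.tgt_aln) == len(alignment.pairing)):
        raise ValueError("alignment rows and pairing string differ in length")
    paired = [c for c in range(len(cols)) if cols[c][2] in "|:"]
    if not paired:
        return 0.0
    dg = table.initiation
    # maximal runs of consecutive paired columns (no gap/mismatch between)
    runs: list[list[int]] = [[paired[0]]]
    for c in paired[1:]:
        if c == runs[-1][-1] + 1:
            runs[-1].append(c)
        else:
            runs.append([c])
    for run in runs:
        for c0, c1 in zip(run, run[1:]):
            top = cols[c0][0] + cols[c1][0]
            bottom = cols[c0][1] + cols[c1][1]
            dg += table.stack(top, bottom)
        for end in {run[0], run[-1]}:  # a lone pair is penalized once
            if table.is_terminal_penalized((cols[end][0], cols[end][1])):
                dg += table.terminal_au_gu
    return float(dg)


def _best_site_key(site: TargetSite):
    return (-site.align_score, site.dG, site.start)


def predict_targets(
    mirnas: SequenceSet,
    lnc_targets: SequenceSet | None = None,
    utr3_targets: SequenceSet | None = None,
    s_min: float = DEFAULT_S_MIN,
    dg_max: float = DEFAULT_DG_MAX,
    energy_table: EnergyTable | None = None,
) -> pd.DataFrame:
    """Intersection-of-detectors target table.

    A (miRNA, target) pair is retained iff at least one seed site also
    passes the alignment stage (score >= ``s_min`` and dG <= ``dg_max``).
    One row per retained pair: the best site (max score, then min dG, then
    leftmost).  lncRNAs are scanned over the full transcript, mRNAs over the
    supplied 3'UTR.
    """
    if len(mirnas) == 0:
        raise ValueError("empty miRNA sequence set")
    if (lnc_targets is None or len(lnc_targets) == 0) and (
        utr3_targets is None or len(utr3_targets) == 0
    ):
        raise ValueError("no target sequences supplied")
    table = energy_table or default_energy_table()
    rows = []
    target_sets = []
    if lnc_targets is not None:
        target_sets.append((TARGET_LNC, lnc_targets))
    if utr3_targets is not None:
        target_sets.append((TARGET_UTR3, utr3_targets))
    for mir_id, mir_seq in mirnas.items():
        mir_seq = normalize_rna(mir_seq, mir_id)
        for tclass, targets in target_sets:
            for tgt_id, tgt_seq in targets.items():
                tgt_seq = normalize_rna(tgt_seq, tgt_id)
                candidates = []
                for site in seed_sites(mir_seq, tgt_seq, mir_id, tgt_id, tclass):
                    # align a window spanning the seed site plus enough
                    # upstream target sequence for 3'-supplementary pairing
                    w0 = max(0, site.start - (len(mir_seq) - 6))
                    window = tgt_seq[w0:site.end]
                    if len(window) < 6:
                        continue
                    aln = duplex_align(mir_seq, window)
                    site.align_score = aln.score
                    site.dG = duplex_dG(aln, table)
                    if site.align_score >= s_min and site.dG <= dg_max:
                        site.detected_by = {"seed", "alignment"}
                        candidates.append(site)
                if candidates:
                    best = min(candidates, key=_best_site_key)
                    rows.append(
                        {
                            "mirna": best.mirna,
                            "target": best.target,
                            "target_class": best.target_class,
                            "seed_class": best.seed_class,
                            "start": best.start,
                            "end": best.end,
                            "align_score": best.align_score,
                            "dG": best.dG,
                            "detected_by": "seed+alignment",
                        }
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "mirna",
            "target",
            "target_class",
            "seed_class",
            "start",
            "end",
            "align_score",
            "dG",
            "detected_by",
        ],
    )
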