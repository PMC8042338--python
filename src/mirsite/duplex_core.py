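"""Hydrogen-bond scoring of gapless, antiparallel miRNA:mRNA duplexes.

The model counts hydrogen bonds per opposed base pair — canonical G-C (3)
and A-U (2) plus the non-canonical wobble G-U (1) and A-C (1) pairs — and
converts the window total into a free energy ΔG = −e_hb × bonds.  Site
quality is the ratio ΔG/ΔGm expressed as a percentage, where ΔGm is the
energy of the miRNA bound to its perfect Watson–Crick complement; the ratio
is independent of the energy constant, which therefore only sets the kJ/mol
scale of reports.

Admitting the non-canonical pairs means a purine↔purine (A↔G) or
pyrimidine↔pyrimidine (C↔U) substitution inside a canonical pair never
abolishes pairing — the duplex keeps a bubble-free double helix — which is
the property the ortholog-conservation analysis leans on.

The per-pair inter-base distances (A-C 1.04 nm, G-C and A-U 1.03 nm,
G-U 1.02 nm) are carried as documented constants only; no geometry is
computed from them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AlphabetError, ContractError
from .io_formats import MiRNA, reverse_complement

#: Hydrogen bonds per unordered base pair; every pair not listed (including
#: any pair involving N) contributes zero bonds.
PAIR_BONDS: dict[frozenset, int] = {
    frozenset("GC"): 3,
    frozenset("AU"): 2,
    frozenset("GU"): 1,
    frozenset("AC"): 1,
}

#: Documented inter-base distances in nanometers (metadata, never computed on).
PAIR_DISTANCES_NM: dict[str, float] = {"A-C": 1.04, "G-C": 1.03, "A-U": 1.03, "G-U": 1.02}

#: Bonds contributed to ΔGm by each miRNA base via its Watson–Crick partner.
_WC_BONDS = {"A": 2, "U": 2, "G": 3, "C": 3}

BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}

#: 5×5 integer bond matrix over (A, C, G, U, N) — the vectorized PairRule.
BOND_MATRIX = np.zeros((5, 5), dtype=np.int64)
for _pair, _n in PAIR_BONDS.items():
    _a, _b = tuple(_pair)
    BOND_MATRIX[BASE_INDEX[_a], BASE_INDEX[_b]] = _n
    BOND_MATRIX[BASE_INDEX[_b], BASE_INDEX[_a]] = _n


def encode(sequence: str) -> np.ndarray:
    """Encode an RNA string as int8 indices into BOND_MATRIX."""
    try:
        return np.fromiter((BASE_INDEX[b] for b in sequence), dtype=np.int8, count=len(sequence))
    except KeyError as exc:
        raise AlphabetError(f"base {exc.args[0]!r} outside ACGUN") from None


def pair_bonds(mrna_base: str, mirna_base: str) -> int:
    """Hydrogen bonds of one opposed base pair (symmetric in its arguments)."""
    for b in (mrna_base, mirna_base):
        if b not in BASE_INDEX:
            raise AlphabetError(f"base {b!r} outside ACGUN")
    return int(BOND_MATRIX[BASE_INDEX[mrna_base], BASE_INDEX[mirna_base]])


def max_bonds(mirna: MiRNA | str) -> int:
    """Bond total of the miRNA paired with its perfect complement (defines ΔGm)."""
    seq = mirna.sequence if isinstance(mirna, MiRNA) else mirna
    if "N" in seq:
        raise AlphabetError("a miRNA containing N has no defined maximal duplex")
    return sum(_WC_BONDS[b] for b in seq)


@dataclass(frozen=True)
class EnergyModel:
    """Energy parameterization: kJ/mol per hydrogen bond.

    The default 2.1 kJ/mol per bond puts ΔG of GC-rich ~22-mers in the
    −100…−140 kJ/mol range typical of reported efficient sites; the ratio
    ΔG/ΔGm does not depend on it.
    """

    e_hb: float = 2.1

    def __post_init__(self) -> None:
        if not self.e_hb > 0:
            raise ContractError(f"e_hb must be positive, got {self.e_hb}")

    def delta_g(self, bonds: int) -> float:
        return -self.e_hb * bonds


DEFAULT_ENERGY_MODEL = EnergyModel()


@dataclass(frozen=True)
class DuplexScheme:
    """Per-position pairing of one mRNA window with one miRNA.

    ``per_position_bonds[k]`` pairs mRNA window position ``k`` (5'→3') with
    miRNA position ``L−1−k`` — the strands are antiparallel and gapless.
    """

    mirna_id: str
    mirna_sequence: str
    window: str
    per_position_bonds: tuple[int, ...]
    total_bonds: int
    delta_g: float
    ratio: float


def score_window(
    mirna: MiRNA, window: str, model: EnergyModel = DEFAULT_ENERGY_MODEL
) -> DuplexScheme:
    """Score one gapless antiparallel duplex window against a miRNA."""
    if len(window) != len(mirna):
        raise ContractError(
            f"window length {len(window)} != miRNA length {len(mirna)}"
        )
    mseq = mirna.sequence
    L = len(mseq)
    bonds = tuple(pair_bonds(window[k], mseq[L - 1 - k]) for k in range(L))
    total = sum(bonds)
    mb = max_bonds(mirna)
    return DuplexScheme(
        mirna_id=mirna.id,
        mirna_sequence=mseq,
        window=window,
        per_position_bonds=bonds,
        total_bonds=total,
        delta_g=model.delta_g(total),
        ratio=100.0 * total / mb,
    )


#: Pairing glyphs of the text schemes: 3 bonds "|", 2 bonds ":", 1 bond ".",
#: no pairing a space.
GLYPHS = {3: "|", 2: ":", 1: ".", 0: " "}


def render_scheme(scheme: DuplexScheme) -> str:
    """Three-line fixed-width diagram: mRNA 5'→3', glyphs, miRNA 3'→5'."""
    glyph_line = "".join(GLYPHS[b] for b in scheme.per_position_bonds)
    return (
        f"5'-{scheme.window}-3' mRNA\n"
        f"   {glyph_line}\n"
        f"3'-{scheme.mirna_sequence[::-1]}-5' {scheme.mirna_id}"
    )


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (report convention)."""
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


__all__ = [
    "PAIR_BONDS",
    "PAIR_DISTANCES_NM",
    "BOND_MATRIX",
    "BASE_INDEX",
    "encode",
    "pair_bonds",
    "max_bonds",
    "EnergyModel",
    "DEFAULT_ENERGY_MODEL",
    "DuplexScheme",
    "score_window",
    "render_scheme",
    "round_half_away",
    "reverse_complement",
]
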