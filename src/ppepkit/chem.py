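"""Peptide mass chemistry for PPEP substrate-profiling experiments.

The combinatorial libraries used to profile Pro-Pro endopeptidases extend the
20-residue alphabet with two non-proteinogenic monomers:

* ``Z`` — 6-aminohexanoic acid (Ahx), a flexible spacer. Its residue formula
  (C6H11NO) makes it exactly isobaric with Leu/Ile.
* ``O`` — Lys carrying a biotin on its side chain, used as the C-terminal
  capture handle of the non-prime-side library.

All arithmetic is monoisotopic; average masses are deliberately unsupported
because product quantification operates on monoisotopic m/z values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

from pyteomics import mass as _pmass

__all__ = [
    "WATER_MONO",
    "PROTON_MASS",
    "MONOMER_MASSES",
    "STANDARD_RESIDUES",
    "BIOTIN_MONOMERS",
    "MODIFICATION_DELTAS",
    "Peptide",
    "MzTarget",
    "neutral_monoisotopic_mass",
    "mz",
    "neutral_mass_from_mz",
    "ppm_window",
    "extinction_coefficient_280",
]

#: Monoisotopic mass of H2O in Da (one water is added per peptide chain).
WATER_MONO: float = 18.0105646863

#: Monoisotopic mass of a proton in Da, used for m/z computation.
PROTON_MASS: float = 1.007276466

#: The 20 standard amino-acid one-letter codes.
STANDARD_RESIDUES: frozenset[str] = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Monomers that carry a biotin moiety.
BIOTIN_MONOMERS: frozenset[str] = frozenset("O")

# Residue (i.e. dehydrated) monoisotopic masses. The 20 standard values come
# from the curated table shipped with pyteomics; the extended monomers are
# appended here. Z (Ahx, C6H11NO) shares the exact Leu/Ile residue mass;
# O = Lys(biotin) is the lysine residue plus the biotinyl delta.
_BIOTIN_DELTA = 226.077598394

_monomers = dict(_pmass.std_aa_mass)
for _sym in ("B", "J", "O", "U", "X", "Z"):  # drop pyteomics extras we redefine
    _monomers.pop(_sym, None)
_monomers["Z"] = _monomers["L"]
_monomers["O"] = _monomers["K"] + _BIOTIN_DELTA

#: Immutable symbol -> monoisotopic residue mass table (Da).
MONOMER_MASSES: Mapping[str, float] = MappingProxyType(_monomers)

#: Named terminal/side-chain modification deltas in Da. ``amide`` is the
#: C-terminal amidation (-OH -> -NH2); ``dabcyl``/``edans`` are the FRET
#: quencher/fluorophore adducts and are registered for completeness only.
MODIFICATION_DELTAS: Mapping[str, float] = MappingProxyType(
    {
        "biotin": _BIOTIN_DELTA,
        "acetyl": 42.0105646863,
        "amide": -0.984016,
        "dabcyl": 251.105862,
        "edans": 248.061948,
    }
)


def _mod_delta(mod: str | None) -> float:
    if mod is None:
        return 0.0
    try:
        return MODIFICATION_DELTAS[mod]
    except KeyError:
        raise KeyError(
            f"unknown modification {mod!r}; known: {sorted(MODIFICATION_DELTAS)}"
        ) from None


@dataclass(frozen=True)
class Peptide:
    """A peptide over the extended monomer alphabet with optional terminal mods.

    Parameters
    ----------
    sequence
        One-letter monomer string; every symbol must be in
        :data:`MONOMER_MASSES`.
    n_term_mod, c_term_mod
        Named modification from :data:`MODIFICATION_DELTAS`, or ``None``.
    """

    sequence: str
    n_term_mod: str | None = None
    c_term_mod: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        for sym in self.sequence:
            if sym not in MONOMER_MASSES:
                raise KeyError(f"unknown monomer symbol {sym!r} in {self.sequence!r}")
        _mod_delta(self.n_term_mod)
        _mod_delta(self.c_term_mod)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def has_biotin(self) -> bool:
        """True iff any monomer or terminal modification carries biotin."""
        return bool(BIOTIN_MONOMERS.intersection(self.sequence)) or "biotin" in (
            self.n_term_mod,
            self.c_term_mod,
        )


def neutral_monoisotopic_mass(peptide: Peptide | str) -> float:
    """Neutral monoisotopic mass in Da.

    Sum of residue masses plus one water plus any terminal-modification
    deltas. Accepts a bare sequence string as shorthand for an unmodified
    peptide.
    """
    if isinstance(peptide, str):
        peptide = Peptide(peptide)
    total = WATER_MONO + _mod_delta(peptide.n_term_mod) + _mod_delta(peptide.c_term_mod)
    for sym in peptide.sequence:
        total += MONOMER_MASSES[sym]
    return total


def mz(neutral_mass: float, charge: int) -> float:
    """m/z of the ``[M + zH]^z+`` ion of a neutral mass."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    if neutral_mass <= 0:
        raise ValueError(f"neutral mass must be positive, got {neutral_mass}")
    return (neutral_mass + charge * PROTON_MASS) / charge


def neutral_mass_from_mz(mz_value: float, charge: int) -> float:
    """Invert :func:`mz`: recover the neutral mass from an observed m/z."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return mz_value * charge - charge * PROTON_MASS


def ppm_window(mz_value: float, tol_ppm: float) -> tuple[float, float]:
    """Symmetric extraction window ``(low, high)`` around an m/z target."""
    if mz_value <= 0:
        raise ValueError(f"m/z must be positive, got {mz_value}")
    if tol_ppm < 0:
        raise ValueError(f"ppm tolerance must be non-negative, got {tol_ppm}")
    half = mz_value * tol_ppm * 1e-6
    return (mz_value - half, mz_value + half)


@dataclass(frozen=True)
class MzTarget:
    """An extracted-ion-chromatogram target: one m/z, charge and ppm window."""

    mz: float
    charge: int
    tol_ppm: float
    window: tuple[float, float] = field(init=False)

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.charge}")
        object.__setattr__(self, "window", ppm_window(self.mz, self.tol_ppm))

    @classmethod
    def from_neutral_mass(
        cls, neutral_mass: float, charge: int, tol_ppm: float = 5.0
    ) -> "MzTarget":
        return cls(mz=mz(neutral_mass, charge), charge=charge, tol_ppm=tol_ppm)


def extinction_coefficient_280(sequence: str, cystine_pairs: int = 0) -> int:
    """Molar extinction coefficient at 280 nm (M^-1 cm^-1).

    Uses the standard additive rule 5500*(#Trp) + 1490*(#Tyr) + 125*(#cystine
    bridges). Cysteines are assumed reduced by default (``cystine_pairs=0``);
    pass the number of disulfide bridges explicitly for the oxidised form.
    """
    seq = sequence.upper()
    for sym in seq:
        if sym not in STANDARD_RESIDUES:
            raise KeyError(f"unknown residue {sym!r} in protein sequence")
    if cystine_pairs < 0:
        raise ValueError("cystine_pairs must be >= 0")
    if cystine_pairs * 2 > seq.count("C"):
        raise ValueError(
            f"{cystine_pairs} cystine pairs need {cystine_pairs * 2} Cys, "
            f"sequence has {seq.count('C')}"
        )
    return 5500 * seq.count("W") + 1490 * seq.count("Y") + 125 * cystine_pairs
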