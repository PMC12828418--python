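"""Synthetic stand-in sequences for the PPEP-3 expression constructs.

The real enzyme (UniProt A4INY2, locus GTNG_1672) is expressed as a
truncated construct covering residues 27-235 of the full protein. The
sequences below are **synthetic stand-ins, not the real translation**: they
are built programmatically to reproduce the properties this package
computes on --

* length 209 (residues 27-235);
* aromatic composition of exactly 2 Trp and 11 Tyr and no Cys, which fixes
  the reduced-form molar extinction coefficient at 280 nm to
  5500*2 + 1490*11 = 27,390 M^-1 cm^-1 for the wild type and
  25,900 M^-1 cm^-1 for the E154A/Y190F double mutant (one Tyr fewer);
* the published catalytic landmarks placed at their full-protein numbering
  (HEXXH zinc motif His153/Glu154/His157, oxyanion Tyr190, S2-pocket
  Tyr161, S-loop Tyr113, S1-pocket Trp120, S3-pocket His104/Trp? --
  the second Trp is placed at 120; filler positions are non-aromatic).

Use them wherever a demonstration or test needs "the construct" without the
real database record.
"""

from __future__ import annotations

__all__ = [
    "CONSTRUCT_START",
    "CONSTRUCT_END",
    "ppep3_construct_synthetic",
]

#: Full-protein numbering of the expressed construct boundaries.
CONSTRUCT_START = 27
CONSTRUCT_END = 235

# Landmark residues in full-protein numbering -> residue. Tyr190 is the
# eleventh tyrosine; mutating it to Phe removes exactly one Tyr.
_LANDMARKS = {
    104: "H",   # S3 pocket histidine
    105: "L",
    110: "P",   # S1 pocket
    111: "R",
    113: "Y",   # S-loop tyrosine (hydrogen bonds the P1' carbonyl)
    120: "W",   # S1 pocket tryptophan
    126: "I",
    127: "G",
    128: "G",
    131: "L",
    133: "L",
    145: "H",
    146: "G",
    150: "L",
    153: "H",   # HEXXH
    154: "E",   # catalytic base (E154A in the inactive mutant)
    157: "H",   # HEXXH
    161: "Y",   # S2 pocket tyrosine
    190: "Y",   # oxyanion-hole tyrosine (Y190F in the inactive mutant)
    191: "F",   # S2' pocket phenylalanine
    196: "E",
    197: "E",   # third zinc ligand
}

# Remaining tyrosines (11 total incl. 113/161/190) and the second tryptophan
# are already placed above except these extra tyrosine filler positions.
_EXTRA_TYR = (40, 58, 76, 94, 170, 205, 215, 228)
_EXTRA_TRP = (67,)


def ppep3_construct_synthetic(double_mutant: bool = False) -> str:
    """Deterministic synthetic construct sequence (residues 27-235).

    ``double_mutant=True`` applies E154A/Y190F, the proteolytically inactive
    form used for substrate co-crystallisation.
    """
    filler = "ASGLVTDEKN"  # non-aromatic, Cys-free filler cycle
    chars = []
    for full_pos in range(CONSTRUCT_START, CONSTRUCT_END + 1):
        if full_pos in _LANDMARKS:
            chars.append(_LANDMARKS[full_pos])
        elif full_pos in _EXTRA_TYR:
            chars.append("Y")
        elif full_pos in _EXTRA_TRP:
            chars.append("W")
        else:
            chars.append(filler[full_pos % len(filler)])
    seq = "".join(chars)
    if double_mutant:
        seq = _mutate(seq, 154, "E", "A")
        seq = _mutate(seq, 190, "Y", "F")
    return seq


def _mutate(seq: str, full_pos: int, expect: str, new: str) -> str:
    idx = full_pos - CONSTRUCT_START
    if seq[idx] != expect:
        raise ValueError(f"position {full_pos} is {seq[idx]}, expected {expect}")
    return seq[:idx] + new + seq[idx + 1 :]
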