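"""Scan proteomes for candidate Pro-Pro endopeptidase cleavage motifs.

A motif constrains some of the six substrate positions P3..P3' around the
scissile bond (P1-P1' must be Pro-Pro for PPEP motifs). Hits report the
1-based coordinate of P1 and the P3..P3' hexamer context. Secretion
filtering consumes a plain list of protein ids produced by an external
signal-peptide predictor; prediction itself is out of scope here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "SCAN_POSITIONS",
    "MotifSpec",
    "MotifHit",
    "PRIME_PROLINE_MOTIF",
    "NONPRIME_CONTEXT_MOTIF",
    "scan_motif",
    "filter_secreted",
    "read_id_list",
    "hits_to_frame",
    "synthetic_proteome",
]

logger = logging.getLogger(__name__)

#: Substrate positions, with their offset from the P1 coordinate.
SCAN_POSITIONS: dict[str, int] = {
    "P3": -2,
    "P2": -1,
    "P1": 0,
    "P1'": 1,
    "P2'": 2,
    "P3'": 3,
}

_STANDARD = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class MotifSpec:
    """Per-position residue sets defining a cleavage-site motif.

    Unlisted positions are unconstrained. For PPEP motifs the P1 and P1'
    sets, when given, must be subsets of {P}.
    """

    name: str
    constraints: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        clean: dict[str, frozenset[str]] = {}
        for pos, residues in self.constraints.items():
            if pos not in SCAN_POSITIONS:
                raise KeyError(f"unknown substrate position {pos!r}")
            residues = frozenset(residues)
            if not residues:
                raise ValueError(f"empty residue set at {pos}")
            if not residues <= _STANDARD:
                raise ValueError(f"non-standard residues in constraint at {pos}: {residues}")
            clean[pos] = residues
        if not clean:
            raise ValueError("motif needs at least one constrained position")
        for pos in ("P1", "P1'"):
            if pos in clean and not clean[pos] <= {"P"}:
                raise ValueError(f"PPEP motifs require {pos} to be Pro")
        object.__setattr__(self, "constraints", clean)


#: Four consecutive prolines spanning P1-P3' (prime-side preference motif).
PRIME_PROLINE_MOTIF = MotifSpec(
    name="P|PPP",
    constraints={p: frozenset("P") for p in ("P1", "P1'", "P2'", "P3'")},
)

#: (L/F)(H/R/K/S)P|P spanning P3-P1' (non-prime-side preference motif).
NONPRIME_CONTEXT_MOTIF = MotifSpec(
    name="(L/F)(H/R/K/S)P|P",
    constraints={
        "P3": frozenset("LF"),
        "P2": frozenset("HRKS"),
        "P1": frozenset("P"),
        "P1'": frozenset("P"),
    },
)


@dataclass(frozen=True)
class MotifHit:
    """One candidate cleavage site.

    ``cleavage_position`` is the 1-based index of P1; ``context`` is the
    P3..P3' hexamer, '-'-padded where the site sits within two residues of a
    terminus.
    """

    protein_id: str
    cleavage_position: int
    context: str


def _records(source) -> Iterable[tuple[str, str]]:
    if isinstance(source, (str, Path)):
        path = Path(source)
        try:
            parsed = list(SeqIO.parse(str(path), "fasta"))
        except (ValueError, FileNotFoundError) as exc:
            raise ValueError(f"unreadable FASTA {path}: {exc}") from exc
        if not parsed:
            raise ValueError(f"unreadable FASTA {path}: no records found")
        return [(rec.id, str(rec.seq)) for rec in parsed]
    out = []
    for item in source:
        if hasattr(item, "id") and hasattr(item, "seq"):
            out.append((item.id, str(item.seq)))
        else:
            pid, seq = item
            out.append((pid, str(seq)))
    return out


def scan_motif(
    source,
    motif: MotifSpec,
    mode: str = "per_site",
) -> list[MotifHit] | list[str]:
    """Find all motif occurrences in a protein FASTA (or (id, seq) pairs).

    ``per_site`` reports every (possibly overlapping) site; ``per_protein``
    returns the ordered list of unique protein ids with at least one site.
    Non-standard letters (X, B, Z, U, ...) never satisfy a constrained
    position and are logged once per sequence.
    """
    if mode not in ("per_site", "per_protein"):
        raise ValueError(f"mode must be per_site|per_protein, got {mode!r}")
    hits: list[MotifHit] = []
    proteins: list[str] = []
    for pid, seq in _records(source):
        seq = seq.upper().rstrip("*")
        odd = sorted(set(seq) - _STANDARD)
        if odd:
            logger.warning("%s: non-standard letters %s match nothing", pid, odd)
        n = len(seq)
        found_in_protein = False
        for p1 in range(1, n + 1):  # 1-based index of P1
            ok = True
            for pos, residues in motif.constraints.items():
                idx = p1 + SCAN_POSITIONS[pos]  # 1-based
                if idx < 1 or idx > n or seq[idx - 1] not in residues:
                    ok = False
                    break
            if not ok:
                continue
            found_in_protein = True
            if mode == "per_site":
                context = "".join(
                    seq[p1 + off - 1] if 1 <= p1 + off <= n else "-"
                    for off in range(-2, 4)
                )
                hits.append(MotifHit(protein_id=pid, cleavage_position=p1, context=context))
            else:
                break
        if found_in_protein and mode == "per_protein":
            proteins.append(pid)
    return hits if mode == "per_site" else proteins


def filter_secreted(hits: Sequence[MotifHit], secreted_ids: Iterable[str]) -> list[MotifHit]:
    """Keep hits in proteins predicted (externally) to be secreted."""
    allowed = set(secreted_ids)
    return [h for h in hits if h.protein_id in allowed]


def read_id_list(path: str | Path) -> list[str]:
    """Read a one-id-per-line text file (e.g. post-processed predictor output)."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line.split()[0])
    return out


def hits_to_frame(hits: Sequence[MotifHit]):
    """Hits as a DataFrame (protein_id, cleavage_position, context)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "protein_id": h.protein_id,
                "cleavage_position": h.cleavage_position,
                "context": h.context,
            }
            for h in hits
        ],
        columns=["protein_id", "cleavage_position", "context"],
    )


def synthetic_proteome(
    n_proteins: int = 200,
    seed: int = 0,
    length_range: tuple[int, int] = (120, 450),
    proline_weight: float = 3.0,
) -> list[tuple[str, str]]:
    """A synthetic, proline-enriched toy proteome for scanner exercises.

    Not a real organism's annotation: sequences are drawn i.i.d. from a
    residue distribution with Pro upweighted so that Pro-Pro motifs occur at
    workable rates. Ids follow a locus-tag-like pattern SYNP_0001...
    """
    rng = np.random.default_rng(seed)
    residues = np.array(sorted(_STANDARD))
    weights = np.ones(len(residues))
    weights[residues == "P"] = proline_weight
    weights = weights / weights.sum()
    out = []
    for i in range(n_proteins):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = "".join(rng.choice(residues, size=length, p=weights))
        out.append((f"SYNP_{i + 1:04d}", seq))
    return out


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) pairs as a FASTA file."""
    with open(path, "w") as handle:
        for pid, seq in records:
            handle.write(f">{pid}\n")
            for start in range(0, len(seq), 70):
                handle.write(seq[start : start + 70] + "\n")
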