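"""Filtering, isobaric merging and quantification of PPEP cleavage products.

The search-engine output for a mixed-library digest contains one row per
identified peptide with a reported abundance. This module applies the
product-peptide filters (9-mer length, library-anchor substring, no biotin),
collapses identifications that share an exact neutral mass (the engine lists
the combined abundance once per isobaric member), selects the most abundant
products that jointly exceed a cumulative-abundance threshold, and emits the
m/z targets used to draw extracted ion chromatograms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chem import MzTarget, mz, neutral_monoisotopic_mass

__all__ = [
    "IDENTIFICATION_COLUMNS",
    "MASS_KEY_DECIMALS",
    "MergedProduct",
    "mass_key",
    "filter_products",
    "merge_isobaric",
    "select_top_cumulative",
    "eic_targets",
    "eic_target_table",
    "annotate_isomers_by_rt",
]

#: Canonical identification-table columns.
IDENTIFICATION_COLUMNS = (
    "sequence",
    "side",
    "abundance",
    "retention_time",
    "has_biotin",
)

#: Neutral-mass rounding used to group isobaric products. Four decimals keep
#: exact elemental isobars together (Leu/Ile; Gly+Glu vs Ala+Asp residue-pair
#: permutations) while the nearest near-isobars (Gln vs Lys, 0.036 Da) stay
#: separate.
MASS_KEY_DECIMALS = 4

_NON_PRIME_ANCHOR = "PTEDAV"
_PRIME_ANCHOR = "GGLEEF"


def mass_key(sequence: str) -> float:
    """Neutral monoisotopic mass rounded to the isobaric-grouping precision."""
    return round(neutral_monoisotopic_mass(sequence), MASS_KEY_DECIMALS)


@dataclass(frozen=True)
class MergedProduct:
    """A group of identifications sharing one exact neutral mass.

    ``abundance`` is the single shared value the search engine reported for
    every member (already the combined abundance of the group), not a sum.
    ``representative`` writes ambiguous slots in bracket notation, e.g.
    ``PTEDAV[IL][IL]P``.
    """

    side: str
    mass_key: float
    member_sequences: tuple[str, ...]
    representative: str
    abundance: float
    retention_time: float

    @property
    def neutral_mass(self) -> float:
        """Full-precision neutral mass of the group (via its first member)."""
        return neutral_monoisotopic_mass(self.member_sequences[0])


def _as_frame(table: pd.DataFrame | Iterable[dict]) -> pd.DataFrame:
    if not isinstance(table, pd.DataFrame):
        table = pd.DataFrame(list(table))
    missing = [c for c in IDENTIFICATION_COLUMNS if c not in table.columns and c != "retention_time"]
    if missing:
        raise ValueError(f"identification table is missing column(s) {missing}")
    return table


def filter_products(table: pd.DataFrame) -> pd.DataFrame:
    """Keep genuine 9-mer cleavage products and assign the library side.

    A row survives iff its sequence is 9 residues long, contains exactly one
    of the anchors PTEDAV (non-prime product) or GGLEEF (prime product), and
    carries no biotin. The side column is (re)assigned from the matching
    anchor. Idempotent.
    """
    table = _as_frame(table)
    seq = table["sequence"].astype(str)
    has_np = seq.str.contains(_NON_PRIME_ANCHOR, regex=False)
    has_pr = seq.str.contains(_PRIME_ANCHOR, regex=False)
    both = has_np & has_pr
    if both.any():
        offending = seq[both].iloc[0]
        raise ValueError(
            f"sequence {offending!r} matches both library anchors; malformed input"
        )
    keep = (seq.str.len() == 9) & (has_np | has_pr) & (~table["has_biotin"].astype(bool))
    out = table.loc[keep].copy()
    out["side"] = np.where(has_np[keep], "non_prime", "prime")
    return out.reset_index(drop=True)


def _bracket_representative(members: Sequence[str]) -> str:
    lengths = {len(m) for m in members}
    if len(lengths) != 1:
        raise ValueError(f"cannot build a representative for mixed lengths: {members}")
    out = []
    for column in zip(*members):
        letters = sorted(set(column))
        out.append(letters[0] if len(letters) == 1 else "[" + "".join(letters) + "]")
    return "".join(out)


def merge_isobaric(
    table: pd.DataFrame, rel_tol: float = 1e-6
) -> list[MergedProduct]:
    """Collapse identifications with identical exact mass into one product.

    The search engine reports, for each member of a coeluting isobaric group,
    the *combined* abundance of the group; the duplicate listings therefore
    carry the same value, which is kept once. Abundances disagreeing by more
    than ``rel_tol`` (relative) within one mass group signal input that did
    not come from such an engine and raise ``ValueError``.

    Grouping is per library side on the neutral mass rounded to
    :data:`MASS_KEY_DECIMALS` decimals.
    """
    table = _as_frame(table)
    if "retention_time" not in table.columns:
        table = table.assign(retention_time=np.nan)
    merged: list[MergedProduct] = []
    keys = [
        (side, mass_key(s))
        for side, s in zip(table["side"].astype(str), table["sequence"].astype(str))
    ]
    work = table.assign(_side=[k[0] for k in keys], _mk=[k[1] for k in keys])
    for (side, mk), grp in work.groupby(["_side", "_mk"], sort=True):
        abund = grp["abundance"].astype(float).to_numpy()
        ref = abund[0]
        scale = max(abs(ref), 1e-300)
        if np.any(np.abs(abund - ref) / scale > rel_tol):
            seqs = sorted(grp["sequence"])
            raise ValueError(
                f"inconsistent abundances within mass group {mk} ({seqs}): "
                "isobaric members must share one reported abundance"
            )
        members = tuple(sorted(set(grp["sequence"].astype(str))))
        rts = grp["retention_time"].to_numpy(dtype=float)
        rt = float(np.nanmean(rts)) if np.any(~np.isnan(rts)) else float("nan")
        merged.append(
            MergedProduct(
                side=side,
                mass_key=float(mk),
                member_sequences=members,
                representative=_bracket_representative(members),
                abundance=float(ref),
                retention_time=rt,
            )
        )
    return merged


def select_top_cumulative(
    products: Sequence[MergedProduct], fraction: float = 0.90
) -> list[MergedProduct]:
    """Most abundant products jointly accounting for more than ``fraction``.

    Products are sorted by decreasing abundance (ties broken by
    lexicographic representative) and the shortest prefix whose cumulative
    abundance share strictly exceeds ``fraction`` is returned. Intended to be
    called per library side, mirroring the per-library selection rule.
    """
    if not 0 <= fraction < 1:
        raise ValueError(f"fraction must be in [0, 1), got {fraction}")
    products = list(products)
    if not products:
        raise ValueError("cannot select from an empty product list")
    total = sum(p.abundance for p in products)
    if total <= 0:
        raise ValueError("total abundance must be positive")
    ranked = sorted(products, key=lambda p: (-p.abundance, p.representative))
    cumulative = 0.0
    selected: list[MergedProduct] = []
    for prod in ranked:
        selected.append(prod)
        cumulative += prod.abundance
        if cumulative / total > fraction:
            break
    return selected


def eic_targets(
    products: Sequence[MergedProduct],
    charges: Sequence[int] = (1, 2),
    tol_ppm: float = 5.0,
) -> list[MzTarget]:
    """One extraction target per unique neutral mass and charge state."""
    if not products:
        raise ValueError("no products to derive EIC targets from")
    seen: dict[float, float] = {}
    for prod in products:
        seen.setdefault(prod.mass_key, prod.neutral_mass)
    targets = []
    for _, neutral in sorted(seen.items()):
        for charge in charges:
            targets.append(MzTarget(mz=mz(neutral, charge), charge=charge, tol_ppm=tol_ppm))
    return targets


def eic_target_table(
    products: Sequence[MergedProduct],
    charges: Sequence[int] = (1, 2),
    tol_ppm: float = 5.0,
) -> pd.DataFrame:
    """EIC targets as a table ready for manual import into an EIC viewer."""
    if not products:
        raise ValueError("no products to derive EIC targets from")
    rows = []
    seen: set[tuple[float, int]] = set()
    for prod in sorted(products, key=lambda p: p.mass_key):
        for charge in charges:
            key = (prod.mass_key, charge)
            if key in seen:
                continue
            seen.add(key)
            target = MzTarget(mz=mz(prod.neutral_mass, charge), charge=charge, tol_ppm=tol_ppm)
            rows.append(
                {
                    "representative": prod.representative,
                    "side": prod.side,
                    "neutral_mass": prod.neutral_mass,
                    "charge": charge,
                    "mz": target.mz,
                    "window_low": target.window[0],
                    "window_high": target.window[1],
                }
            )
    return pd.DataFrame(rows)


def annotate_isomers_by_rt(
    observed: Sequence[tuple[float, float]],
    standards: Sequence[tuple[str, float]] | None = None,
    tol_min: float = 0.2,
) -> pd.DataFrame:
    """Assign isobaric signals to sequences via synthetic-standard retention.

    Leu/Ile exchanges are invisible to both precursor mass and fragment
    spectra, but on reversed phase an Ile-for-Leu substitution elutes
    earlier. Given the retention times of synthesized standards that share
    the signals' mass, each observed signal is assigned to the nearest
    standard within ``tol_min`` minutes. Without standards only the elution
    rank is reported (all-Ile earliest ... all-Leu latest), never a sequence
    call.

    Parameters
    ----------
    observed
        ``(mass_key, retention_time)`` pairs.
    standards
        ``(sequence, retention_time)`` pairs sharing the observed mass.
    """
    obs = pd.DataFrame(observed, columns=["mass_key", "retention_time"])
    obs = obs.sort_values("retention_time", kind="stable").reset_index(drop=True)
    obs["elution_rank"] = np.arange(1, len(obs) + 1)
    if not standards:
        obs["assigned_sequence"] = pd.array([None] * len(obs), dtype="object")
        return obs
    std_rts = [rt for _, rt in standards]
    if len(set(np.round(std_rts, 12))) != len(std_rts):
        raise ValueError("standards must have distinct retention times")
    std_keys = {mass_key(seq) for seq, _ in standards}
    if len(std_keys) != 1:
        raise ValueError(f"standards are not isobaric: masses {sorted(std_keys)}")
    (std_key,) = std_keys
    bad = set(np.round(obs["mass_key"], MASS_KEY_DECIMALS)) - {std_key}
    if bad:
        raise ValueError(f"observed masses {sorted(bad)} do not match standards ({std_key})")
    assigned = []
    for rt in obs["retention_time"]:
        deltas = [(abs(rt - srt), seq) for seq, srt in standards]
        best_delta, best_seq = min(deltas)
        assigned.append(best_seq if best_delta <= tol_min else None)
    obs["assigned_sequence"] = pd.array(assigned, dtype="object")
    return obs


def exact_mass_collisions(sequences: Iterable[str]) -> list[tuple[str, ...]]:
    """Groups of distinct sequences sharing one exact (rounded) neutral mass.

    A convenience used to audit a product database for elemental isobars
    before interpreting merged abundances.
    """
    groups: dict[float, list[str]] = {}
    for seq in sequences:
        groups.setdefault(mass_key(seq), []).append(seq)
    return [tuple(sorted(v)) for v in groups.values() if len(set(v)) > 1]
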