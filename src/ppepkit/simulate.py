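"""Synthetic LC-MS/MS identification tables from a ground-truth model.

This generator stands in for a real library digest + search-engine run so
that the whole downstream pipeline (filtering, isobaric merging, cumulative
selection, logos) is testable end to end. It emulates the statistical
structure of the real experiment:

* **Marginalisation over unread positions.** Each library reads only one
  side of the cleavage site; the varied residues on the biotinylated side
  still modulate how much of each observed product is produced, so an
  observed product's true abundance sums the cleavage extents over all 19^2
  unread contexts.
* **Isobaric co-listing.** The search engine reports, for every member of a
  group of products sharing one exact mass, the combined abundance of the
  group (each member row lists the group total).
* **Ionisation bias.** Basic residues (His/Arg/Lys) ionise more readily and
  are overrepresented in intensity-based readouts; a per-residue response
  factor models this.
* **Multiplicative lognormal noise** on abundances, **detection dropout**
  below a limit of detection, and a handful of contaminant rows (wrong
  length or biotinylated) that the filters must remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .library import (
    NON_PRIME_DESIGN,
    PRIME_DESIGN,
    VARIABLE_ALPHABET,
    LibraryDesign,
)
from .logo import SpecificityProfile, combine_profiles, relative_occurrence
from .quantify import mass_key, merge_isobaric

__all__ = [
    "MODEL_POSITIONS",
    "SpecificityModel",
    "IonizationModel",
    "RunConfig",
    "GroundTruth",
    "default_specificity_model",
    "generate_identifications",
    "expected_product_abundances",
    "ground_truth_logo",
]

#: The four varied substrate positions of the standard library pair.
MODEL_POSITIONS = ("P3", "P2", "P2'", "P3'")


@dataclass(frozen=True)
class SpecificityModel:
    """Per-position cleavage efficiencies with multiplicative coupling.

    ``efficiency`` maps each varied substrate position to a vector over the
    19-residue variable alphabet with entries in [0, 1]. The cleavage extent
    of a full substrate is the product of its four position efficiencies;
    with ``floor > 0`` the extent drops to exactly zero whenever any single
    position efficiency is below the floor (a hard veto modelling substrates
    whose products stay under the limit of detection).
    """

    efficiency: pd.DataFrame  # index: residues, columns: positions
    floor: float = 0.0

    def __post_init__(self) -> None:
        eff = self.efficiency
        if not set(eff.index) == set(VARIABLE_ALPHABET):
            raise ValueError("efficiency index must be the 19-residue variable alphabet")
        arr = eff.to_numpy(dtype=float)
        if np.any(arr < 0) or np.any(arr > 1):
            raise ValueError("efficiencies must lie in [0, 1]")
        if np.any((arr > 0).sum(axis=0) == 0):
            dead = [c for c in eff.columns if (eff[c] > 0).sum() == 0]
            raise ValueError(f"position(s) {dead} have no nonzero efficiency")
        if not 0 <= self.floor <= 1:
            raise ValueError("floor must be in [0, 1]")

    def vector(self, position: str) -> np.ndarray:
        """Efficiency vector at one position, with the hard floor applied."""
        if position not in self.efficiency.columns:
            raise KeyError(f"position {position!r} not in the specificity model")
        vec = self.efficiency[position].to_numpy(dtype=float).copy()
        if self.floor > 0:
            vec[vec < self.floor] = 0.0
        return vec


@dataclass(frozen=True)
class IonizationModel:
    """Per-residue multiplicative electrospray response factors.

    The factor applies once per occurrence of the residue in the *observed*
    product. Defaults boost His/Arg/Lys two-fold; the direction of the bias
    is established, its magnitude is a declared, configurable stand-in.
    """

    response_factor: dict[str, float] = field(
        default_factory=lambda: {"H": 2.0, "K": 2.0, "R": 2.0}
    )

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.response_factor.values()):
            raise ValueError("response factors must be positive")

    def factor(self, sequence: str) -> float:
        out = 1.0
        for residue in sequence:
            out *= self.response_factor.get(residue, 1.0)
        return out


@dataclass(frozen=True)
class RunConfig:
    """Reproducibility and noise settings for one synthetic run."""

    seed: int
    noise_sigma: float = 0.3
    lod: float = 0.0
    contaminant_rows: int = 12

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.lod < 0:
            raise ValueError("lod must be >= 0")
        if self.contaminant_rows < 0:
            raise ValueError("contaminant_rows must be >= 0")


def default_specificity_model() -> SpecificityModel:
    """The study-condition ground truth used throughout tests and examples.

    Encodes the qualitative PPEP-3 picture: a large hydrophobic S3 pocket
    (Leu/Phe preferred at P3), basic residues and Ser tolerated at P2 (Ser
    favoured among the FRET-confirmed residues, basic residues moderate --
    their prominence in measured logos comes from ionisation bias on top),
    and a strong requirement for Pro at P2'/P3' with minor tolerance of Ala
    (and barely Val/His) at P2'.
    """
    base = {r: 0.05 for r in VARIABLE_ALPHABET}
    eff = pd.DataFrame(
        {
            "P3": {**base, "L": 0.90, "F": 0.70, "I": 0.55, "V": 0.45, "M": 0.40,
                   "G": 0.25, "Q": 0.25, "H": 0.20, "A": 0.15},
            "P2": {**base, "S": 0.80, "R": 0.60, "K": 0.55, "H": 0.50, "L": 0.30,
                   "N": 0.15},
            "P2'": {**{r: 0.02 for r in VARIABLE_ALPHABET}, "P": 1.00, "A": 0.30,
                    "V": 0.08, "H": 0.04},
            "P3'": {**{r: 0.04 for r in VARIABLE_ALPHABET}, "P": 1.00},
        }
    ).loc[list(VARIABLE_ALPHABET)]
    return SpecificityModel(efficiency=eff)


def _design_position_labels(design: LibraryDesign) -> list[str]:
    return [
        design._substrate_position(i)  # noqa: SLF001 - same-package helper
        for i in design.variable_positions
    ]


def expected_product_abundances(
    model: SpecificityModel,
    ion: IonizationModel,
    design: LibraryDesign,
) -> pd.DataFrame:
    """Noise-free expected abundance of every observable product of a design.

    Columns: sequence, side, true_abundance (cleavage extent summed over the
    unread contexts, times the product's ionisation factor) and mass_key.
    """
    labels = _design_position_labels(design)
    readout = list(design.readout_positions())
    missing = [p for p in readout if p not in model.efficiency.columns]
    if missing:
        raise KeyError(f"design {design.name!r} reads position(s) {missing} absent from model")
    unread = [p for p in labels if p not in readout]
    missing = [p for p in unread if p not in model.efficiency.columns]
    if missing:
        raise KeyError(f"design {design.name!r} varies position(s) {missing} absent from model")

    vectors = {p: model.vector(p) for p in labels}
    # Multiplicative coupling factorises: the sum over unread contexts is the
    # product of the unread vectors' sums (the hard floor is a per-position
    # veto, already applied inside vector()).
    unread_sum = float(np.prod([vectors[p].sum() for p in unread])) if unread else 1.0
    tmpl = design.product_template()
    slots = [s - 1 for s in tmpl.variable_slots]
    alphabet = list(VARIABLE_ALPHABET)
    rows = []
    n = len(alphabet)
    read_vecs = [vectors[p] for p in readout]
    for i in range(n):
        for j in range(n) if len(readout) == 2 else [None]:
            chars = list(tmpl.pattern)
            chars[slots[0]] = alphabet[i]
            extent = read_vecs[0][i]
            if j is not None:
                chars[slots[1]] = alphabet[j]
                extent *= read_vecs[1][j]
            seq = "".join(chars)
            rows.append(
                {
                    "sequence": seq,
                    "side": design.name,
                    "true_abundance": extent * unread_sum * ion.factor(seq),
                    "mass_key": mass_key(seq),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GroundTruth:
    """Pre-noise expectations paired with the generating models."""

    products: pd.DataFrame  # sequence, side, true_abundance, mass_key
    model: SpecificityModel
    ionization: IonizationModel


def generate_identifications(
    model: SpecificityModel,
    ion: IonizationModel | None = None,
    designs: Sequence[LibraryDesign] = (NON_PRIME_DESIGN, PRIME_DESIGN),
    cfg: RunConfig = RunConfig(seed=0),
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a post-search-engine identification table.

    Returns the table (columns sequence, side, abundance, retention_time,
    has_biotin, length) and the ground truth for oracle comparisons.
    Deterministic given ``cfg.seed``.
    """
    ion = ion if ion is not None else IonizationModel()
    rng = np.random.default_rng(cfg.seed)
    truth_frames = [expected_product_abundances(model, ion, d) for d in designs]
    truth = pd.concat(truth_frames, ignore_index=True)

    rows = []
    for frame in truth_frames:
        # One reported (combined) abundance and one apex retention time per
        # exact-mass group: the engine cannot split isobaric coelutions.
        # Products that are never produced (zero extent) yield no
        # identification and do not appear as co-listed members.
        for (_, _), grp in frame.groupby(["side", "mass_key"], sort=True):
            grp = grp[grp["true_abundance"] > 0]
            if grp.empty:
                continue
            total = float(grp["true_abundance"].sum())
            noise = float(np.exp(cfg.noise_sigma * rng.standard_normal())) if cfg.noise_sigma else 1.0
            listed = total * noise
            rt = float(rng.uniform(8.0, 45.0))
            if listed < cfg.lod:
                continue
            for seq in grp["sequence"]:
                rows.append(
                    {
                        "sequence": seq,
                        "side": grp["side"].iloc[0],
                        "abundance": listed,
                        "retention_time": rt,
                        "has_biotin": False,
                    }
                )

    # Contaminants: truncated products and intact biotinylated library
    # members that the downstream filters must reject.
    median_abund = float(np.median([r["abundance"] for r in rows])) if rows else 1.0
    for k in range(cfg.contaminant_rows):
        design = designs[k % len(designs)]
        if k % 2 == 0:
            tmpl = design.product_template()
            seq = "".join(
                rng.choice(list(VARIABLE_ALPHABET)) if c == "X" else c
                for c in tmpl.pattern
            )[1:]  # truncated: wrong length
            biotin = False
        else:
            chars = [
                rng.choice(list(VARIABLE_ALPHABET)) if c == "X" else c
                for c in design.monomers
            ]
            seq = "".join(chars)
            biotin = True
        rows.append(
            {
                "sequence": seq,
                "side": "unknown",
                "abundance": median_abund * float(np.exp(rng.standard_normal())),
                "retention_time": float(rng.uniform(8.0, 45.0)),
                "has_biotin": biotin,
            }
        )

    table = pd.DataFrame(
        rows, columns=["sequence", "side", "abundance", "retention_time", "has_biotin"]
    )
    table["length"] = table["sequence"].str.len()
    return table, GroundTruth(products=truth, model=model, ionization=ion)


def ground_truth_logo(
    model: SpecificityModel,
    ion: IonizationModel | None = None,
    designs: Sequence[LibraryDesign] = (NON_PRIME_DESIGN, PRIME_DESIGN),
    merge_aware: bool = True,
) -> SpecificityProfile:
    """Analytic expectation of the pipeline's logo under the generative model.

    With ``merge_aware=True`` (default) the expectation includes the
    exact-mass merging step: products sharing a mass are co-listed with their
    combined abundance and the logo splits that abundance equally among
    members, exactly as the noise-free pipeline does. With
    ``merge_aware=False`` the plain marginal (efficiency x ionisation,
    normalised per position) is returned.
    """
    ion = ion if ion is not None else IonizationModel()
    per_side: dict[str, SpecificityProfile] = {}
    for design in designs:
        frame = expected_product_abundances(model, ion, design)
        if float(frame["true_abundance"].sum()) <= 0:
            raise ValueError(f"model yields zero total abundance for side {design.name!r}")
        if merge_aware:
            table = frame.rename(columns={"true_abundance": "abundance"}).copy()
            table = table[table["abundance"] > 0]
            table["abundance"] = table.groupby(["side", "mass_key"])["abundance"].transform("sum")
            table["has_biotin"] = False
            merged = merge_isobaric(table)
            per_side[design.readout_side] = relative_occurrence(merged, design.product_template())
        else:
            tmpl = design.product_template()
            slots = [s - 1 for s in tmpl.variable_slots]
            counts = pd.DataFrame(
                0.0, index=list(VARIABLE_ALPHABET), columns=list(tmpl.positions())
            )
            for _, row in frame.iterrows():
                for slot, pos in zip(slots, tmpl.positions()):
                    counts.loc[row["sequence"][slot], pos] += row["true_abundance"]
            matrix = counts / counts.sum(axis=0)
            per_side[design.readout_side] = SpecificityProfile(
                matrix=matrix,
                source_side={p: design.name for p in tmpl.positions()},
            )
    return combine_profiles(
        non_prime=per_side.get("non_prime"), prime=per_side.get("prime")
    )
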