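"""Intensity-weighted specificity profiles (sequence logos) for PPEPs.

The logo's numeric content is a position x residue matrix of *relative
occurrence*: the abundance-weighted frequency of each residue at each
substrate position among the observed cleavage products. Letter height in
the rendered logo equals that frequency directly (an information-content
mode in bits is available behind a flag, but occurrence is the native
scale of this assay).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .library import VARIABLE_ALPHABET, ProductTemplate
from .quantify import MergedProduct

__all__ = [
    "POSITION_ORDER",
    "SpecificityProfile",
    "relative_occurrence",
    "combine_profiles",
    "export_profile",
    "plot_profile",
]

#: Canonical substrate-position ordering around the scissile Pro-Pro bond.
POSITION_ORDER = ("P3", "P2", "P1", "P1'", "P2'", "P3'")


@dataclass(frozen=True)
class SpecificityProfile:
    """Residue x position matrix of relative occurrence.

    Every position column sums to 1; P1/P1' columns, when present, are the
    indicator of Pro (the scissile bond is fixed by the assay design).
    """

    matrix: pd.DataFrame  # index: residues, columns: position labels
    source_side: dict[str, str]  # position label -> library side / "fixed"

    def __post_init__(self) -> None:
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError(f"profile columns must sum to 1, got {sums.to_dict()}")
        for pos in ("P1", "P1'"):
            if pos in self.matrix.columns:
                col = self.matrix[pos]
                if not (col.get("P", 0.0) == 1.0 and np.isclose(col.sum(), 1.0)):
                    raise ValueError(f"{pos} must be the indicator of Pro")

    @property
    def positions(self) -> tuple[str, ...]:
        return tuple(self.matrix.columns)


def relative_occurrence(
    products: Sequence[MergedProduct], template: ProductTemplate
) -> SpecificityProfile:
    """Abundance-weighted residue frequencies at the readout positions.

    Each merged product contributes its abundance to the residues it carries
    at the template's variable slots; ambiguity groups (several member
    sequences behind one mass) split their abundance equally among members.
    """
    products = list(products)
    if not products:
        raise ValueError("no products supplied")
    sides = {p.side for p in products}
    if len(sides) != 1:
        raise ValueError(f"profile must be built per library side, got {sorted(sides)}")
    (side,) = sides
    positions = template.positions()
    slots = template.variable_slots
    counts = pd.DataFrame(0.0, index=list(VARIABLE_ALPHABET), columns=list(positions))
    total = 0.0
    for prod in products:
        share = prod.abundance / len(prod.member_sequences)
        for member in prod.member_sequences:
            if len(member) != len(template.pattern):
                raise ValueError(
                    f"member {member!r} does not fit template {template.pattern!r}"
                )
            total += share
            for slot, pos in zip(slots, positions):
                residue = member[slot - 1]
                if residue not in counts.index:
                    raise KeyError(f"residue {residue!r} not in the variable alphabet")
                counts.loc[residue, pos] += share
    if total <= 0:
        raise ValueError("total abundance is zero; cannot normalise a profile")
    matrix = counts / counts.sum(axis=0)
    return SpecificityProfile(matrix=matrix, source_side={p: side for p in positions})


def _pro_indicator(index: Sequence[str]) -> pd.Series:
    col = pd.Series(0.0, index=list(index))
    col.loc["P"] = 1.0
    return col


def combine_profiles(
    non_prime: SpecificityProfile | None = None,
    prime: SpecificityProfile | None = None,
    include_core: bool = True,
) -> SpecificityProfile:
    """Concatenate per-library profiles into the full P3..P3' picture.

    Each side keeps its own normalisation (selection thresholds are applied
    per library); the fixed P1/P1' columns are Pro indicators.
    """
    pieces: dict[str, pd.Series] = {}
    sides: dict[str, str] = {}
    for prof in (non_prime, prime):
        if prof is None:
            continue
        for pos in prof.positions:
            pieces[pos] = prof.matrix[pos]
            sides[pos] = prof.source_side[pos]
    if not pieces:
        raise ValueError("at least one side profile is required")
    index = next(iter(pieces.values())).index
    if include_core:
        for pos in ("P1", "P1'"):
            pieces[pos] = _pro_indicator(index)
            sides[pos] = "fixed"
    ordered = [p for p in POSITION_ORDER if p in pieces]
    matrix = pd.DataFrame({p: pieces[p] for p in ordered})
    return SpecificityProfile(matrix=matrix, source_side=sides)


def to_information_content(profile: SpecificityProfile) -> pd.DataFrame:
    """Per-position information content (bits) scaled letter heights.

    Height(r, pos) = f(r, pos) * (log2 N - H(pos)) with N the residue
    alphabet size of the profile.
    """
    mat = profile.matrix
    n = mat.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(mat > 0, mat * np.log2(mat.where(mat > 0, 1.0)), 0.0)
    entropy = -plogp.sum(axis=0)
    ic = np.log2(n) - entropy
    return mat.mul(ic, axis=1)


def export_profile(profile: SpecificityProfile, path: str, fmt: str = "tsv") -> None:
    """Write a profile as a TSV matrix or a stacked-letter logo image."""
    if fmt == "tsv":
        profile.matrix.rename_axis("residue").to_csv(path, sep="\t", float_format="%.10g")
    elif fmt in ("png", "svg", "pdf"):
        fig = plot_profile(profile)
        fig.savefig(path, dpi=150, bbox_inches="tight")
        import matplotlib.pyplot as plt

        plt.close(fig)
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def read_profile_tsv(path: str) -> pd.DataFrame:
    """Read back a TSV matrix written by :func:`export_profile`."""
    return pd.read_csv(path, sep="\t", index_col="residue")


_LETTER_COLORS = {
    # Simple physicochemical colouring: basic blue, acidic red, polar green,
    # proline/glycine orange, hydrophobic black.
    **{r: "#1f4da1" for r in "HKR"},
    **{r: "#c02020" for r in "DE"},
    **{r: "#2e8b57" for r in "STNQY"},
    **{r: "#e28a12" for r in "PG"},
}


def plot_profile(profile: SpecificityProfile, mode: str = "frequency"):
    """Render a stacked-letter logo; letter heights equal matrix entries.

    ``mode='bits'`` rescales columns to information content.
    """
    import matplotlib.pyplot as plt
    from matplotlib.font_manager import FontProperties
    from matplotlib.patches import PathPatch
    from matplotlib.textpath import TextPath
    from matplotlib.transforms import Affine2D

    if mode == "frequency":
        heights = profile.matrix
        ylabel = "relative occurrence"
        ymax = 1.0
    elif mode == "bits":
        heights = to_information_content(profile)
        ylabel = "bits"
        ymax = max(1.0, float(heights.sum(axis=0).max()) * 1.05)
    else:
        raise ValueError(f"unknown logo mode {mode!r}")

    fig, ax = plt.subplots(figsize=(1.1 * len(heights.columns) + 1, 3.2))
    font = FontProperties(family="DejaVu Sans", weight="bold")
    for x, pos in enumerate(heights.columns):
        bottom = 0.0
        column = heights[pos].sort_values()
        for residue, h in column.items():
            if h <= 0:
                continue
            tp = TextPath((0, 0), residue, size=1.0, prop=font)
            bbox = tp.get_extents()
            if bbox.width == 0 or bbox.height == 0:
                continue
            transform = (
                Affine2D()
                .translate(-bbox.x0, -bbox.y0)
                .scale(0.9 / bbox.width, h / bbox.height)
                .translate(x + 0.05, bottom)
            )
            ax.add_patch(
                PathPatch(
                    transform.transform_path(tp),
                    facecolor=_LETTER_COLORS.get(residue, "#222222"),
                    edgecolor="none",
                )
            )
            bottom += h
    ax.set_xlim(-0.2, len(heights.columns) + 0.2)
    ax.set_ylim(0, ymax)
    ax.set_xticks([x + 0.5 for x in range(len(heights.columns))])
    ax.set_xticklabels(heights.columns)
    ax.set_ylabel(ylabel)
    ax.set_xlabel("substrate position")
    ax.spines[["top", "right"]].set_visible(False)
    return fig
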