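"""Combinatorial peptide library models for PPEP specificity profiling.

Two one-bead-one-compound libraries probe the six subsites around the
scissile Pro-Pro bond (Schechter-Berger positions P3..P3'):

* the **non-prime** library ``PTEDAVXXPPXXEZZO`` varies P3/P2 (read out) and
  P2'/P3' (leaving with the biotinylated fragment), and
* the **prime** library ``JZEXXPPXXGGLEEF`` varies P2'/P3' (read out) and
  P3/P2 (on the biotin side).

``X`` is any standard residue except Cys, ``Z`` is the Ahx spacer, ``O`` is
Lys(biotin)-amide, and a leading ``J`` denotes an N-terminal biotin. After
cleavage between the two core prolines and streptavidin depletion of
biotinylated fragments, the observable products are the 9-mers ``PTEDAVXXP``
and ``PXXGGLEEF``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .chem import Peptide, neutral_monoisotopic_mass

__all__ = [
    "VARIABLE_ALPHABET",
    "LibraryDesign",
    "ProductTemplate",
    "CoverageReport",
    "NON_PRIME_DESIGN",
    "PRIME_DESIGN",
    "enumerate_variants",
    "iter_variants",
    "product_database",
    "simulate_split_pool",
    "export_product_database",
]

#: The 19 standard residues allowed at variable positions (Cys excluded to
#: avoid disulfide chemistry during split-pool synthesis).
VARIABLE_ALPHABET: tuple[str, ...] = tuple(sorted(set("ACDEFGHIKLMNPQRSTVWY") - {"C"}))


@dataclass(frozen=True)
class ProductTemplate:
    """The observed 9-mer cleavage product: fixed residues plus variable slots.

    ``pattern`` keeps ``X`` at variable slots; ``position_labels`` maps each
    1-based variable slot to its substrate position (e.g. P3, P2').
    """

    pattern: str
    position_labels: dict[int, str]

    def __post_init__(self) -> None:
        if len(self.pattern) != 9:
            raise ValueError(f"product pattern must be 9 residues, got {self.pattern!r}")
        for slot in self.position_labels:
            if self.pattern[slot - 1] != "X":
                raise ValueError(f"slot {slot} of {self.pattern!r} is not variable")

    @property
    def variable_slots(self) -> tuple[int, ...]:
        return tuple(sorted(self.position_labels))

    def positions(self) -> tuple[str, ...]:
        """Substrate-position labels in slot order."""
        return tuple(self.position_labels[s] for s in self.variable_slots)


@dataclass(frozen=True)
class LibraryDesign:
    """A combinatorial library template with a designated Pro-Pro core.

    The template string may start with ``J`` (N-terminal biotin). The Pro-Pro
    core is located automatically among the fixed residues and must be
    unique; ``cleavage_core`` is the 1-based template index of P1.
    """

    name: str
    template: str
    readout_side: str  # "non_prime" | "prime"
    variable_alphabet: tuple[str, ...] = VARIABLE_ALPHABET
    n_term_mod: str | None = None
    c_term_mod: str | None = None
    monomers: str = field(init=False)
    cleavage_core: int = field(init=False)

    def __post_init__(self) -> None:
        template = self.template
        n_mod = self.n_term_mod
        if template.startswith("J"):
            if n_mod not in (None, "biotin"):
                raise ValueError("leading J conflicts with an explicit N-terminal mod")
            n_mod = "biotin"
            template = template[1:]
        object.__setattr__(self, "n_term_mod", n_mod)
        object.__setattr__(self, "monomers", template)
        if self.readout_side not in ("non_prime", "prime"):
            raise ValueError(f"readout_side must be non_prime|prime, got {self.readout_side!r}")
        if "C" in self.variable_alphabet:
            raise ValueError("variable alphabet must exclude Cys")
        if "X" not in template:
            raise ValueError("library template needs at least one variable position")
        cores = [
            i + 1
            for i in range(len(template) - 1)
            if template[i] == "P" and template[i + 1] == "P"
        ]
        if len(cores) != 1:
            raise ValueError(
                f"template {template!r} must contain exactly one Pro-Pro core, "
                f"found {len(cores)}"
            )
        object.__setattr__(self, "cleavage_core", cores[0])

    @property
    def variable_positions(self) -> tuple[int, ...]:
        """1-based template indices of all variable (X) positions."""
        return tuple(i + 1 for i, c in enumerate(self.monomers) if c == "X")

    def _substrate_position(self, index: int) -> str:
        """Schechter-Berger label of a 1-based template index."""
        p1 = self.cleavage_core
        if index <= p1:
            return f"P{p1 - index + 1}"
        return f"P{index - p1}'"

    @property
    def readout_slice(self) -> slice:
        """Template slice of the non-biotinylated, observed cleavage product."""
        if self.readout_side == "non_prime":
            return slice(0, self.cleavage_core)
        return slice(self.cleavage_core, len(self.monomers))

    def product_template(self) -> ProductTemplate:
        sl = self.readout_slice
        pattern = self.monomers[sl]
        labels = {
            i - sl.start + 1: self._substrate_position(i + 1)
            for i, c in enumerate(self.monomers)
            if c == "X" and sl.start <= i < sl.stop
        }
        return ProductTemplate(pattern=pattern, position_labels=labels)

    def readout_positions(self) -> tuple[str, ...]:
        """Substrate positions observable in this library's products."""
        return self.product_template().positions()


NON_PRIME_DESIGN = LibraryDesign(
    name="non_prime", template="PTEDAVXXPPXXEZZO", readout_side="non_prime",
    c_term_mod="amide",
)

PRIME_DESIGN = LibraryDesign(
    name="prime", template="JZEXXPPXXGGLEEF", readout_side="prime",
)


def enumerate_variants(design: LibraryDesign) -> int:
    """Number of distinct full-length library members."""
    return len(design.variable_alphabet) ** len(design.variable_positions)


def iter_variants(design: LibraryDesign) -> Iterator[str]:
    """Lazily yield every full-length variant sequence (X positions filled)."""
    template = design.monomers
    var_idx = [i - 1 for i in design.variable_positions]
    for combo in itertools.product(design.variable_alphabet, repeat=len(var_idx)):
        chars = list(template)
        for i, aa in zip(var_idx, combo):
            chars[i] = aa
        yield "".join(chars)


def cleave_at_core(design: LibraryDesign, variant: str) -> tuple[str, str]:
    """Split a full-length variant at the designated Pro-Pro bond."""
    p1 = design.cleavage_core
    return variant[:p1], variant[p1:]


def product_database(design: LibraryDesign) -> list[Peptide]:
    """All observable cleavage products of one library.

    One 9-mer per combination of the readout-side variable positions
    (19^2 = 361 for either standard design). Products are unmodified: the
    biotinylated half, together with any terminal modification it carries,
    is removed by the streptavidin depletion step.
    """
    tmpl = design.product_template()
    slots = [s - 1 for s in tmpl.variable_slots]
    products = []
    for combo in itertools.product(design.variable_alphabet, repeat=len(slots)):
        chars = list(tmpl.pattern)
        for i, aa in zip(slots, combo):
            chars[i] = aa
        products.append(Peptide("".join(chars)))
    return products


@dataclass(frozen=True)
class CoverageReport:
    """Outcome of a split-pool synthesis simulation."""

    n_variants: int
    n_beads: int
    n_distinct: int
    coverage: float
    expected_coverage: float
    copies_histogram: dict[int, int]  # copies-per-variant -> number of variants


def expected_split_pool_coverage(n_variants: int, n_beads: int) -> float:
    """Closed-form occupancy expectation 1 - (1 - 1/K)^B."""
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    return 1.0 - (1.0 - 1.0 / n_variants) ** n_beads


def simulate_split_pool(
    design: LibraryDesign | int, n_beads: int, seed: int
) -> CoverageReport:
    """Simulate one-bead-one-compound synthesis as i.i.d. uniform draws.

    Each bead independently receives one of the K possible variants with
    equal probability; the report gives the realised fraction of variants
    present on at least one bead next to the closed-form expectation
    ``1 - (1 - 1/K)^B``.
    """
    if n_beads < 0:
        raise ValueError(f"n_beads must be >= 0, got {n_beads}")
    k = design if isinstance(design, int) else enumerate_variants(design)
    if k < 1:
        raise ValueError("library must have at least one variant")
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, k, size=n_beads)
    copies = np.bincount(draws, minlength=k)
    n_distinct = int((copies > 0).sum())
    hist_vals, hist_counts = np.unique(copies, return_counts=True)
    return CoverageReport(
        n_variants=k,
        n_beads=n_beads,
        n_distinct=n_distinct,
        coverage=n_distinct / k,
        expected_coverage=expected_split_pool_coverage(k, n_beads),
        copies_histogram={int(v): int(c) for v, c in zip(hist_vals, hist_counts)},
    )


def export_product_database(
    designs: Sequence[LibraryDesign], path: str, fmt: str = "tsv"
) -> None:
    """Write the merged product database as FASTA or TSV.

    TSV columns: sequence, side, neutral_mass, positions (comma-joined
    substrate-position labels of the variable slots).
    """
    rows = []
    for design in designs:
        labels = ",".join(design.readout_positions())
        for pep in product_database(design):
            rows.append(
                {
                    "sequence": pep.sequence,
                    "side": design.name,
                    "neutral_mass": neutral_monoisotopic_mass(pep),
                    "positions": labels,
                }
            )
    if fmt == "tsv":
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6f")
    elif fmt == "fasta":
        with open(path, "w") as handle:
            for row in rows:
                handle.write(f">{row['sequence']} side={row['side']}\n{row['sequence']}\n")
    else:
        raise ValueError(f"unknown export format {fmt!r}")
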