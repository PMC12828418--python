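# Methods

## The assay being modelled

Pro-Pro endopeptidases hydrolyse Xaa-Pro-Pro-Xaa bonds; their active-site
cleft reads six substrate residues, P3–P3′ in Schechter–Berger notation,
with P1 and P1′ fixed as prolines. Specificity is profiled with two
split-pool combinatorial libraries that vary P3/P2 and P2′/P3′
(19 residues per position, Cys excluded; 19⁴ = 130,321 members per
library). Cleavage products that have lost the biotinylated half are
enriched by streptavidin depletion and identified/quantified by LC-MS/MS;
the observable products are the 9-mers `PTEDAVxxP` (non-prime readout) and
`PxxGGLEEF` (prime readout), 19² = 361 per side.

## Mass chemistry

All arithmetic is monoisotopic (quantification targets monoisotopic m/z).
Residue masses come from the standard table shipped with pyteomics; the
extended monomers are Z = 6-aminohexanoic acid (residue mass identical to
Leu/Ile, C6H11NO) and O = Lys(biotin) (Lys + 226.077598 Da). Constants:
water 18.0105647 Da, proton 1.007276466 Da. Terminal modifications are a
named registry (biotin +226.077598, acetyl +42.0105647, C-terminal amide
−0.984016; Dabcyl/EDANS nominal deltas are registered for completeness but
never used in quantitative paths). m/z = (M + z·m_p)/z. Extraction windows
are symmetric ±tol·1e-6·m/z; the default tolerance is 5 ppm with charges
1+ and 2+, matching the acquisition-side conventions of the assay.

The 280-nm extinction coefficient uses the additive rule
ε = 5500·n(Trp) + 1490·n(Tyr) + 125·n(cystine). Cysteines are treated as
reduced by default because the wild-type/double-mutant coefficient pair of
the PPEP-3 construct (27,390 vs 25,900 M⁻¹cm⁻¹) is exactly reproduced by
the Trp/Tyr terms alone; an explicit `cystine_pairs` argument covers the
oxidised convention. `ppepkit.synthetic_constructs` provides a clearly
labelled *synthetic* stand-in for the expression construct (residues
27–235): a programmatically built sequence whose aromatic composition
(2 Trp, 11 Tyr, no Cys) is implied by that coefficient pair, with the
catalytic landmarks (HEXXH at 153–157, oxyanion Tyr190, S2-pocket Tyr161)
at their published numbering. It is **not** the real translation and must
not be used for anything but composition-level utilities.

## Library model and split-pool coverage

A library template designates exactly one fixed Pro-Pro core; the bond
between those prolines is the cleavage site, and coordinates are 1-based
with the core reported as the index of P1. The readout side of each design
determines the observed product (the non-biotinylated fragment). Templates
with zero variable positions are rejected: a library without diversity is
a synthesis order, not a library.

Split-pool synthesis is modelled as B i.i.d. uniform draws over the K
variants (one bead, one compound). This is the minimal stochastic model —
coupling-efficiency differences and bead-loading variance are deliberately
out of scope — and the coverage report always prints the closed-form
expectation 1 − (1 − 1/K)^B next to the realised value. At the production
scale (K = 130,321, B = 10⁶) the expectation is ≈ 0.99954, i.e. roughly 60
of the 130,321 sequences are expected to be absent from any given
synthesis batch.

## Synthetic identification generator

The generator emulates *post-search-engine* output, not spectra. Its
ground truth is a `SpecificityModel`: per-position cleavage efficiencies
in [0, 1] over the 19-residue alphabet at P3, P2, P2′, P3′, combined
multiplicatively into a per-substrate cleavage extent; an optional hard
floor zeroes the extent when any single position falls below it (a veto
modelling substrates whose products never reach the limit of detection).
Because each library reads only one side, an observed product's true
abundance marginalises the extent over the 19² unread-side contexts; with
the multiplicative rule this factorises into the product of the unread
positions' efficiency sums.

Reported abundances then incorporate, in order:

1. **Ionisation bias** — a per-residue response factor applied once per
   occurrence in the observed product. Default: His/Arg/Lys ×2.0, others
   ×1.0. The direction of this bias is established for electrospray; the
   magnitude is a declared stand-in and stays configurable.
2. **Isobaric co-listing** — products sharing one exact neutral mass are
   reported with the *combined* abundance of the group on every member
   row (this is how exported search-engine tables list indistinguishable
   isomers). Products with zero true extent are never identified and do
   not appear as members. One lognormal noise factor (default σ = 0.3,
   multiplicative, reflecting roughly log-normal MS intensities) and one
   retention time are drawn per mass group.
3. **Dropout** — rows below the configured limit of detection (default 0,
   i.e. off) are removed.
4. **Contaminants** — a configurable number of rows (default 12) with the
   wrong length or with biotin, exercising the downstream filters.

All randomness flows through one `numpy` generator seeded from the
mandatory `RunConfig.seed`; identical configs give byte-identical tables.

What the generator does *not* emulate: chromatographic peak shape, MS2
fragmentation and scoring, FDR/decoy structure, or retention behaviour
correlated with hydrophobicity (retention times are uniform draws, except
that isobaric co-elutions share one apex). Tests passing on this generator
therefore validate the *bookkeeping* of the pipeline — filtering, merging,
normalisation, recovery under multiplicative noise — not robustness to
search-engine artefacts.

## Filtering, merging and selection

* **Filter**: keep rows that are 9 residues long, contain exactly one of
  the anchors `PTEDAV`/`GGLEEF` (which assigns the side; a row matching
  both anchors is malformed input and raises), and carry no biotin.
* **Isobaric merge**: group per side by neutral mass rounded to 1e-4 Da.
  This groups exact elemental isobars — Leu/Ile exchanges, and residue-pair
  collisions such as Gly+Glu ≡ Ala+Asp (the 361 non-prime products contain
  142 such multi-member groups, 159 distinct masses) — while the closest
  near-isobars (Gln vs Lys, 0.036 Da) stay separate. Within a group the
  shared listed abundance is kept once, not summed (the engine already
  reports the combined value); members disagreeing by more than 1e-6
  relative raise an error. Representatives use bracket notation
  (`PTEDAV[IL][IL]P`).
* **Cumulative selection**: sort descending by abundance (ties broken by
  lexicographic representative) and keep the minimal prefix whose share
  *strictly exceeds* the threshold (default 0.90). The strictness matters
  at the boundary: ten equal products all survive a 0.90 threshold because
  nine reach exactly 0.90.
* **Leu/Ile annotation**: isobaric signals can be assigned from the
  retention times of synthesized standards (nearest standard within 0.2
  min, configurable); without standards only the elution rank is reported,
  relying on Ile-for-Leu substitutions eluting earlier on C18.

## Logos and the merge-aware expectation

The logo's numeric content is relative occurrence: per position, the
abundance-weighted frequency of each residue among the products, with
ambiguity groups splitting their abundance equally among member sequences.
Letter height equals frequency (an information-content mode in bits exists
behind a flag). Sides are normalised independently; the combined P3…P3′
profile fixes P1/P1′ as Pro indicators.

A consequence of mass-level grouping deserves emphasis: positional
isomers (the same residue pair swapped between the two readout slots) are
exact isobars, so equal splitting mixes the two readout columns of a side
to a degree that grows with the model's position asymmetry (maximum entry
shift ≈ 0.10 under the default model). `ground_truth_logo` is therefore
defined as the analytic expectation of the *pipeline output* — it applies
the same merge-and-split step to the noise-free abundances (default,
`merge_aware=True`) — while `merge_aware=False` returns the plain
efficiency × ionisation marginal. In the real assay this ambiguity is
partly resolved by MS2 fragment spectra and retention-time standards,
which are outside this package's scope; the annotation hook in
`quantify.annotate_isomers_by_rt` is the supported path for injecting such
external resolutions.

Measured behaviour under the defaults (σ = 0.3, H/K/R ×2, lod 0): the
noise-free pipeline logo equals the merge-aware expectation to machine
precision, and across ten seeds the mean maximum entry error is ≈ 0.04.

## Motif scanning

Scanning is a direct position-by-position match of per-position residue
sets over P3…P3′ (offsets −2…+3 from P1). All overlapping sites are
reported in `per_site` mode (`PPPP` on `PPPPP` yields two sites);
`per_protein` mode counts each protein once, which is the headline mode
for candidate-substrate searches. Coordinates are 1-based at P1; contexts
are '-'-padded at termini, and terminal sites still count. Ambiguous
letters (X, B, Z, U…) never match a constrained position and are logged.
The secreted-protein filter is a plain id-set intersection; signal-peptide
prediction is consumed, never performed. The packaged `synthetic_proteome`
is an explicitly synthetic, proline-enriched toy used for oracle testing
and demonstrations — counts on it say nothing about any real organism's
annotation, and real-proteome counts shift with annotation version.

## FRET kinetics

Traces are per-replicate fluorescence time courses (typically 0–30 min at
1-min steps, three replicates). The comparison metric is the trapezoidal
area under the baseline-corrected curve, with the baseline defined as the
T = 0 reading — this absorbs any constant offset. Two groups are compared
with the classical equal-variance two-tailed Student's t test (Welch
behind a flag); three or more with one-way ANOVA followed by Tukey's HSD
pairwise p-values (via statsmodels). Stars: p < 0.05 (\*), < 0.01 (\*\*),
< 0.001 (\*\*\*), else ns; boundary values belong to the less significant
class (p = 0.05 → ns). Degenerate inputs — a single group, or zero
within-group variance everywhere — raise rather than returning p-values.
No kinetic modelling (Michaelis–Menten, progress curves) is attempted.

## Problem sizes and numeric conventions

The default verification sizes are chosen to exercise the real
combinatorics while staying desk-scale: full 361-product databases per
side everywhere; split-pool coverage at the production scale (10⁶ beads,
130,321 variants) averaged over 50 seeded replicates; logo recovery over
10 seeds; oracle proteome scans on ~120 synthetic proteins. Mass-group
rounding is 1e-4 Da; profile column sums are enforced to 1e-9; the m/z
round trip is exact to 1e-9 Da. All stochastic components take explicit
seeds; nothing draws unseeded randomness.

## Known limitations

* Mass-only isobaric grouping mixes positional isomers (above); MS2-level
  disambiguation is not modelled.
* The ionisation-bias magnitude (×2) is a stand-in; only its direction is
  grounded.
* The split-pool model ignores coupling-efficiency and bead-loading
  heterogeneity, so real coverage is likely slightly below the occupancy
  expectation.
* The synthetic construct sequence is composition-faithful, not
  sequence-faithful; likewise the synthetic proteome.
* EIC targets are computed, but peak integration from raw chromatograms is
  out of scope.
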