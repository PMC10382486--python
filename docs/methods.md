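# Methods

## Scope and data model

The package analyzes protein backbone geometry and PET-depolymerization
assay data. Structures are held as ordered chains of residues keyed by PDB
*author* numbering plus insertion code (never renumbered — practitioners
discuss these enzymes by author numbers, e.g. a catalytic Ser/His/Asp triad),
with only the backbone atoms N/CA/C/O of standard amino acids retained; MSE
backbones are kept for geometry but map to 'X' in sequences. Parsing is
delegated to gemmi; altloc resolution (highest occupancy, ties broken by
altloc letter so record order never matters) and chain-break flagging are
applied on top. A chain break is flagged when C(i)–N(i+1) exceeds 2.5 Å —
roughly twice a peptide bond length — and no torsion is ever computed across
a break; disordered stretches in crystal structures thus degrade gracefully
into undefined angles rather than garbage ones.

## Backbone torsions and reconstruction

Dihedrals follow the IUPAC sign convention (clockwise positive viewed along
the central bond), in degrees on (−180, 180]. φ(i), ψ(i), ω(i) are the
standard four-atom dihedrals; φ is undefined at a segment start, ψ/ω at a
segment end. Three consecutive points are declared collinear — dihedral
undefined — when the cross-product norm falls below 1e−9 times the product
of segment norms.

`build_backbone` inverts the measurement: atoms are placed sequentially by
natural-extension-reference-frame (NeRF) internal-coordinate extension with
idealized bonds and angles (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å;
N–CA–C 111.2°, CA–C–N 116.2°, C–N–CA 121.7°, standard restraint-library
values), the first three atoms in a canonical frame. The build∘measure round
trip is the package's core geometric invariant (tested to 1e−6°, measured
≈1e−13°) and makes every synthetic-structure test self-validating.

A note on a tempting but false "invariant": the torsion of a four-point
chain is *unchanged* when the points are read in reverse order (reversal
maps the bond vectors (b1,b2,b3) → (−b3,−b2,−b1), leaving both the cosine
and the signed sine intact). The sign genuinely flips under mirror
reflection, and both properties are tested.

## Ramachandran divergence

For each aligned residue pair the statistic is the Euclidean distance
between (φ, ψ) points, d = √(Δφ² + Δψ²). Differences are minimal-image
("wrapped") by default: (φ, ψ) lives on a torus and a naive difference
inflates divergence across the ±180° seam, which cannot be what a
Ramachandran comparison intends; the unwrapped mode is retained behind a
flag for literal reproduction of naive pipelines. ω is computed and
exported but excluded from the distance — the statistic is about
Ramachandran (φ-ψ) space, and trans peptides make ω nearly constant anyway.
Correspondence comes from the global sequence alignment; pairs with any
undefined angle are flagged rather than zero-filled. Region summaries
(mean, max, defined-count) run over user-supplied named ranges because loop
definitions are secondary-structure-relative and structure-specific; an
empty region reports count 0 with NaN statistics, not an error.

Per-residue distances can be written into the B-factor column (F6.2,
two decimals, 0.00 for missing; values outside the column's width are a
hard error naming the residue) so molecular viewers render them directly as
putty thickness/color.

## Superposition

`kabsch` computes the optimal proper rotation by SVD of the weighted
covariance, reflections excluded by forcing det = +1; degenerate (collinear)
clouds and fewer than 3 pairs are errors. The independent check in the test
suite and acceptance script is Horn's quaternion method — RMSD from the
largest eigenvalue of the 4×4 key matrix — agreeing to ~1e−15 Å.

`superpose_structures` seeds Cα correspondence from the sequence alignment,
fits, then iteratively drops pairs farther than `trim_factor × RMSD`
(default 2.0, max 5 iterations) and refits. For trim_factor ≥ 1 every
dropped pair lies above the current RMSD, so the trimmed RMSD is
non-increasing across iterations; a small absolute floor (1e−8 Å) keeps
numerically-zero fits from shedding pairs on rounding noise. `trim_factor =
inf` reduces exactly to one untrimmed Kabsch fit. CA-only fitting is the
default atom selection.

## RMSF

Given frames of a fixed Cα selection, each frame is optionally Kabsch-fitted
to the reference over the full selection (default on, standard trajectory
practice), and RMSF_i = √(mean_t |r_i(t) − ⟨r_i⟩|²) about the per-residue
mean of the fitted frames. For isotropic per-coordinate noise of SD σ and no
presuperposition the analytic value is σ√3 (0.866 Å at σ = 0.5 Å), which the
generator/analyzer pair reproduces within sampling error — the calibration
used in the acceptance script.

## Sequence alignment and identity

Global pairwise alignment is a three-state affine-gap (Gotoh) dynamic
program written in the suffix formulation so the deterministic tie-break can
be applied while tracing *forward*: among co-optimal alignments the one
preferring, left to right, a diagonal column, then a gap in B, then a gap in
A. Scoring is BLOSUM62 with all 'X' scores forced to 0; a gap of length L
costs open + (L−1)·extend, defaults 11/1. Two independent oracles back this
in the tests: exhaustive enumeration of every global alignment (short
sequences) and Biopython's PairwiseAligner score under the same convention.

Percent identity divides identical aligned pairs by aligned (non-gap-both)
columns — the common "Clustal-method" reading; shorter-sequence and
full-alignment denominators are selectable. Identity matrices are built
pair-by-pair, symmetric with an exact 100.0 diagonal. Because these are
pairwise alignments, not a guide-tree multiple alignment, matrix values can
differ slightly from MSA-derived identity tables.

## Assay reductions

**T_m.** The melt signal is smoothed by a centered moving average (default
window 5 points; edges handled by nearest-value extension), differentiated
by central differences on the temperature grid, and the derivative maximum —
excluding the outermost window//2 points — is refined by a parabola through
the peak and its neighbours (shift clamped to ±half a grid step). A peak
must stand above the derivative's noise floor (3 × the robust MAD scale,
with a tiny absolute floor); flat or purely linear signals raise an
ambiguous-peak error instead of returning an arbitrary grid point.

**DSC crystallinity.** (ΔH_m − ΔH_c)/ΔH_f × 100 with ΔH_f = 140.1 J/g for
fully crystalline PET. Negative results (cold crystallization exceeding
fusion) are reported as-is with a warning — they flag a measurement problem
the analyst should see, not silently clip.

**HPLC quantification.** Per-analyte ordinary least squares with intercept
(calibration lines are not forced through the origin; small constant
offsets are routine), sample concentration = (area − intercept)/slope ×
dilution factor, negative estimates clipped to zero with a warning.

**Depolymerization extent.** 100 × (mol TPA + mol MHET) × 192.17 / m_PET:
each mole of released aromatic product accounts for one PET repeat unit
(TPA–ethylene-glycol ester, 192.17 g/mol). BHET is excluded by default —
the convention counts terminal hydrolysis products — and included behind a
flag; no default guess is encoded where conventions differ. Extents above
100 % warn rather than error.

**pH-stat.** Acid equivalents = titrant molarity × cumulative volume
(default 0.3575 M NaOH, a typical concentrated feed). The companion
stoichiometry helper converts product moles to expected equivalents at
TPA:MHET:BHET = 2:1:0 carboxyls, letting titrant consumption cross-check
HPLC product totals.

## Synthetic-data generators

All generators are deterministic functions of an explicit seed
(`GeneratorConfig`, one independent stream per generator; no global RNG
state). They emulate the statistical structure each analyzer assumes, not
the physics behind it:

- **Ideal structures**: NeRF-built helices (φ/ψ = −57/−47) and strands
  (−139/135), ω = 180.
- **Torsion perturbations**: Gaussian offsets (SD σ) applied to φ/ψ of named
  residues only, then the chain rebuilt — divergence is local in torsion
  space *by construction*, which is exactly what makes the localization test
  meaningful. In Cartesian space the same perturbation swings the downstream
  arm, mimicking how real loop divergence degrades a global superposition.
- **Ensembles**: reference Cα plus isotropic, frame-independent Gaussian
  noise with a per-residue SD profile. Real MD trajectories are
  autocorrelated and anisotropic; this generator deliberately is not, so
  passing RMSF tests demonstrates the estimator, not realism of dynamics.
- **Melt curves**: two-state logistic between linear folded/unfolded
  baselines plus Gaussian noise, default scan 25–99 °C in 0.5 °C steps. The
  logistic scale defaults to 1.0 °C, i.e. a 10–90 % transition width of
  ≈4.4 °C — the width a cooperative two-state melt of a small globular
  protein shows in dye-based thermal-shift assays (van't Hoff ΔH on the
  order of 500 kJ/mol at T_m ≈ 340 K). Much broader transitions leave the
  first derivative too flat for half-degree localization at realistic noise,
  which is a property of the data, not the estimator.
- **Depolymerization**: total conversion follows plateau/(1 + e^{−k(t−t½)})
  — extent at the midpoint is exactly half the plateau — with product moles
  allocated by a TPA/MHET/BHET split. Defaults model a bioreactor charged
  with 3.75 g post-consumer PET in 0.150 L reaching a ≈94 % plateau with
  half-conversion near 4 h. No lag phase or substrate-depletion kinetics are
  modelled; the generator supplies the sigmoidal shape the extent analyzer
  consumes, nothing more.

## Problem sizes and numerical choices

Test and acceptance runs use 30-residue synthetic chains, 100-replicate
localization sweeps, 10,000-frame ensembles, 200 melt curves, 10,000
torus-metric triples and 500 enumeration-checked alignments — sizes at which
the sampling error of every Monte-Carlo check sits well inside its assertion
tolerance while the whole suite runs in seconds. Key tolerances: torsion
round trip 1e−6°, Kabsch-vs-quaternion 1e−9 Å, RMSF analytic limit 2 %
relative, T_m recovery 0.5 °C at 2 % amplitude noise.

## Known limitations

- Pairwise (not multiple) alignment; identity values are not promised to
  equal guide-tree MSA tables.
- The superposition trimming schedule is one reasonable convention; tools
  differ in their outlier rejection, so core-RMSD values are comparable only
  under stated trim settings.
- mmCIF, ligands, waters, symmetry expansion and side-chain geometry are out
  of scope; O-atom placement in synthetic builds is not refined beyond what
  torsion round trips require.
- The generators validate analyzers, not biology: no force-field dynamics,
  no chromatogram peak integration (areas are instrument outputs), no enzyme
  kinetics model.
- Comparing deposited homolog structures (e.g. a PETase against distinctive
  PET hydrolases from the PDB) works through the same `compare`/`superpose`
  CLI on local PDB files; reproducing any particular published core-RMSD
  number additionally depends on that tool's unstated correspondence and
  trimming choices.
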