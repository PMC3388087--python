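# Methods

## The quantification problem

Heme proteins overexpressed in *E. coli* come off the column as a mixture
of holo and apo species, because heme biosynthesis cannot keep pace with
induction even when δ-aminolevulinic acid is supplemented. For a complex
with fixed stoichiometry — here a protein dimer binding one Fe(III) heme,
as in the DGCR8 heme-binding domain — three quantities characterize a
preparation: the absolute heme concentration, the extinction coefficients
of the intact complex, and the fraction of protein dimers that carry heme
(the occupancy). `hemequant` computes all three from electronic absorption
spectra, plus two auxiliary analyses (MALDI fragment-mass matching and Cα
superposition) used when characterizing crystallized material.

## Pyridine hemochromogen assay

The assay model is pure Beer's-law bookkeeping. The reduced bis-pyridine
Fe(II) hemochrome band at 557 nm has ε₅₅₇ = 34.53 mM⁻¹cm⁻¹ (protoheme IX);
A₅₅₇ is read by linear interpolation from the reduced spectrum (default) or
from the reduced-minus-oxidized difference spectrum, which cancels
redox-insensitive background. The cuvette heme concentration is
A₅₅₇/(ε₅₅₇·l); the original-solution concentration multiplies by the
volume dilution (v_stock + v_ferricyanide + v_protein)/v_protein, which is
1003/500 = 2.006 exactly at the standard 500/3/500 µL volumes. The 3-µL
ferricyanide aliquot is included in the denominator sum on mass-balance
grounds; dithionite is added as crystals and treated as volume-free.
A₅₅₇ values in (−0.005, 0) AU are clamped to zero silently (baseline
noise); more negative values clamp with a warning. No baseline correction
is applied by default.

## Extinction coefficients

Given the heme concentration C of the same stock, ε(λ) = A(λ)/(C·l) at
wavelengths where only the heme absorbs — 367, 450 and 556 nm for the
bis-thiolate Fe(III) complex. With one heme per dimer the per-heme and
per-holo-dimer bases coincide; the stoichiometry is configurable. All ε are
reported in mM⁻¹cm⁻¹ and rounded only in reports. ε₂₈₀,holo = A₂₈₀/C is
meaningful only for a fully occupied preparation (both protein and heme
absorb at 280 nm), and the API documents that the caller asserts occupancy
≈ 1. The apo-dimer ε₂₈₀ is computed from the sequence with the
Trp/Tyr/cystine increments 5500/1490/125 M⁻¹cm⁻¹ per chain; cystine counts
default to 0 because preparations are handled with reducing agent present.

## Occupancy model

The native spectrum of a mixture is modeled as two Beer's-law components:
only holo dimers (concentration H) absorb at 450 nm, both species absorb
at 280 nm:

    A450 = ε450·H·l        A280 = (ε280,holo·H + ε280,apo·P)·l

Writing RZ = A450/A280 and solving for O = H/(H+P):

    O = ε280,apo·RZ / (ε280,apo·RZ + ε450 − ε280,holo·RZ)

The two algebraic fixed points — O(0) = 0 and O(ε450/ε280,holo) = 1 — are
what pin the functional form, and the tests assert them for arbitrary
valid extinction sets; the float evaluation special-cases
RZ = ε450/ε280,holo so the upper fixed point is exact in floating point.
Raw occupancies are clamped to [0, 1] for downstream use with the raw
value retained for QC; RZ above the pure-holo ratio by more than 0.02
triggers a super-stoichiometric-signal warning, and RZ below −0.02
(possible only through pathological inputs, since baseline noise produces
only slightly negative A450) is rejected. When the absolute A280 is
supplied the model also returns the holo and apo concentrations
themselves. The direct estimate heme/protein-dimer molar ratio is left
unclamped: values slightly above 1 carry information about combined assay
error.

## Fragment-mass matching

Intact masses use IUPAC average residue masses (4 decimals) plus one water
(18.0153 Da) per chain; average, not monoisotopic, because linear-mode
MALDI-TOF of 4–30 kDa species does not resolve isotopes. Monoisotopic
tables sit behind a flag. [M+H]⁺ ions convert to neutral masses with the
average proton mass 1.008. The fragment search evaluates every contiguous
window of the construct via prefix sums (O(1) mass per window, O(L²)
windows), returns all windows within tolerance of each target, and sorts
by |Δ| ascending with ties broken by longer fragment, then smaller start
residue. The default tolerance is 0.15% of the target mass (≈10 Da at
6.8 kDa), the scale of calibration error accepted when assigning
linear-mode intact masses; it is always overridable. Constructs carry
reference residue numbering (both ends inclusive); an initiator Met is
numbered 0 and C-terminal tag residues get negative sentinels, so
tag-spanning matches are representable while the native span stays
strictly increasing. Cys residues are treated reduced; matrix adducts and
oxidation variants are out of scope.

## Superposition

Cα traces are read from PDB files with gemmi (first conformer per residue,
waters and non-CA HETATM ignored). Residues are paired by a constant
numbering offset — the right tool for colinear homologues that differ by a
two-residue numbering shift — with an explicit pair list possible through
the coordinate-level API. The optimal rotation is the Kabsch/SVD
construction U = V·diag(1,1,det)·Wᵀ; the determinant correction guarantees
a proper rotation even for chirally mismatched inputs. All paired atoms
are weighted equally, no outlier rejection, and the result reports n_atoms
and per-residue deviations (which aggregate exactly to the RMSD) so that
subset discrepancies are diagnosable. Degenerate inputs (fewer than 3
pairs, collinear sets) are rejected. Tests cross-check against scipy's
rotation alignment and, on a 4-point toy, a brute-force grid-plus-refine
minimization over rotation space.

## Synthetic data

Bands are Gaussians in wavelength. Amplitudes are calibrated by solving the
small linear system that makes the *total* extinction at every band center
equal the configured value, so noise-free spectra obey Beer's law exactly
at the centers — the property the two-point arithmetic relies on. Defaults:
holo bands at 367/450/556 nm with ε 59/70/12.9 mM⁻¹cm⁻¹ and total
ε₂₈₀,holo 91; apo band at 280 nm with ε 48; widths 15 nm (280), 20 nm
(Soret region), 12 nm (556), resolved on the default 1-nm grid over
250–700 nm (the sampling interval is a package choice; instruments vary).
The hemochrome simulator emits a sharp 557-nm band (ε₅₅₇ = 34.53, width
6 nm) plus a weak β band near 525 nm for the reduced state and a broad
featureless ferric band for the oxidized state, at the cuvette
concentration implied by the 2.006 dilution. Noise is additive Gaussian in
AU; every generator is a pure function of its parameters and seed. Typical
noise settings: 0.5 mAU for a research-grade double-beam instrument
(hemochrome/extinction round trips), 2 mAU for the occupancy-recovery
stress tests. The degradation simulator plants random contiguous fragments
and emits [M+H]⁺ peaks with multiplicative calibration error.

What the simulations do **not** emulate: realistic lineshapes (Voigt),
light scattering and baseline drift, incomplete heme extraction in the
assay, protein-assay bias, matrix adducts, or isotope envelopes. Passing
round-trip tests therefore demonstrates the correctness of the
quantification arithmetic under the stated noise model, not robustness to
instrument systematics.

## Problem sizes and numerical choices

Property suites use ~10³ random mixture draws for the occupancy oracle,
constructs of 80–220 residues for mass-search oracles, and 56-residue
synthetic traces for superposition — sizes at which brute-force oracles
are exact and fast. Interpolation is always linear and never implicit
smoothing; peak finding operates on raw points unless an explicit boxcar
width is passed. ε values and masses are rounded only at reporting
boundaries.

## Reference-data checks

Three checks compare against deposited reference data — the sequence-based
ε₂₈₀ of a specific natural construct (NCBI GQ397480), fragment masses from
a deposited coordinate set (PDB 4E5R), and the homologue superposition
RMSD against PDB 3LE4. These run only when the corresponding files are
present under `tests/data/`; the distribution does not bundle them, and in
an offline environment those three tests report the missing data as
failures rather than silently passing. All other functionality is covered
by synthetic fixtures.
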