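# Methods

This note documents the models, default parameters and numerical choices
behind the two arms of the package, what the synthetic-data generators do
and do not emulate, and the known limitations.

## qNMR arm

### Spectrum model

Simulated spectra live on a uniform ascending ppm grid (default δ −0.5 to
10.5, 2¹⁶ points, ~1.7·10⁻⁴ ppm spacing) at a spectrometer frequency of
400 MHz. Every resonance is a pure Lorentzian line

L(x) = (A/π) · (w/2) / ((x − c)² + (w/2)²),

with full width at half maximum w = 1.0 Hz by default (configurable per
peak) — the simplest lineshape consistent with solution-state NMR. A
doublet is rendered to first order as two equal-area lines at c ± J/2 Hz
(i.e. J/frequency ppm); no roofing or second-order effects are modelled,
which is adequate here because the chemical-shift separations of all
signals of interest are large against J at 400 MHz.

Analyte signatures (positions, multiplicities, couplings, proton counts):

| compound | signals | quantification signal |
|---|---|---|
| hydroxycitric acid (HCA), MW 208.12 | d 3.07 (J 16.6 Hz, 1H), d 3.16 (J 16.6 Hz, 1H), s 4.45 (1H) | window 3.12–3.20 ppm, 1H |
| HCA lactone, MW 190.11 | d 2.92 (J 18.0 Hz, 1H), d 3.29 (J 18.0 Hz, 1H), s 5.00 (1H) | window 3.25–3.33 ppm, 1H |
| maleic acid (internal standard), MW 116.07, purity 0.9994, 1 mg per 10 mg aliquot | s 6.37 (2H) | window 6.33–6.41 ppm, 2H |
| TSP (shift reference), MW 172.26 (d₄ sodium salt; not printed in the source tables, standard value) | s 0.00 (9H) | — |
| garcinol marker (methanol extracts) | aromatic s 6.7 / 7.0 / 7.2 (1H each), methyl singlets 1.52–1.70 (3H each) | detection only |

An analyte's total rendered area is (mass_mg / MW) · Σ protons, distributed
over its multiplets by proton count — the proportionality of area to moles
of nuclei that internal-standard qNMR rests on. The absolute area unit
cancels in the mass-fraction ratio.

Interference and noise: an optional sugar background (on by default —
fruit-rind water extracts are dominated by sugars) is modelled as three
broad Lorentzian humps (FWHM 40 Hz) at δ 3.4, 3.7 and 4.0 with a
configurable total area (default 0.05 area units, ≈3× the internal-standard
area); this is a deliberately coarse stand-in, not an assignment of real
sugar multiplets. Noise is i.i.d. Gaussian per grid point from a seeded
generator; a polynomial baseline can be added. Ground-truth masses, areas
and the seed are recorded in the spectrum metadata.

### Integration and quantification

Windows are integrated by the trapezoid rule after subtracting a local
linear baseline: the chord through the mean intensity of two flanking
margins of 0.025 ppm (~150 grid points) immediately outside the window.
The margin width is a noise-propagation choice: the chord's area error
scales as window_width · σ/√(margin points), and ~150 points per margin
make it subdominant to the integral's own noise while the margins stay
local against the 0.1-ppm-wide sugar humps and stop short of the nearest
neighbouring line core (the 3.091 ppm HCA line sits just outside the HCA
window's left margin). The margin statistic is a mean, not a median: a
mean is linear in every spectral component, so deterministic leakage of a
known signature's own tails into the margins is compensated exactly by the
capture correction below, whereas a median interacts nonlinearly with
noise when a sharp line's tail spans the margin.

A ±0.04 ppm window captures only ~89–97 % of a 1-Hz Lorentzian multiplet's
area (tails fall outside, and the baseline chord — whose margins sit on
those tails — subtracts a little more). Both effects are deterministic
given the lineshape, the window and the integration procedure, so
quantification divides each measured area by an exact *capture factor*,
computed by rendering the signature at unit area per proton on the
spectrum's own grid and pushing it through the identical integration. For
real spectra this correction is exact only insofar as the true linewidth
matches the signature's; linewidths are configurable per peak.

Mass fractions follow the internal-standard equation (see README). S/N is
ICH-style: baseline-corrected peak height over twice the noise SD, with
noise estimated as the SD of linearly detrended intensity in a signal-free
window (default δ 9.5–10.3). LOD and LOQ scale linearly from a measured
S/N: LOD = 3c/SN, LOQ = 10c/SN. Signals with S/N below 10 are flagged
`below_loq`, below 3 `not_detected`; values are reported with the flag,
never censored to zero, because supplement surveys distinguish "detectable"
from "quantifiable" amounts. Replicate spectra are averaged, with the SD
across replicates reported; noise-free synthetic spectra, whose S/N is
formally undefined, are treated as cleanly above both limits. Report
percentages are rounded to one decimal, half away from zero, matching the
source tables' presentation.

Per-dose arithmetic: the measured fraction refers to the *extract* in the
NMR tube, so mg per capsule/tablet = fraction × unit content mass ×
extraction yield (supplements are extracted before analysis). The
label-implied dose is Σ ingredient mass × labeled HCA fraction, undefined
when no ingredient states a percentage.

### The recovery study

The end-to-end calibration study simulates 20 samples with true HCA and
lactone mass fractions drawn uniformly from [0.02, 0.25], each measured as
triplicate spectra (the standard qNMR protocol) at noise SD equal to 1 % of
the internal-standard peak height, sugar background off (the controlled
calibration condition; sugar robustness is exercised separately). Under
these conditions the mean absolute recovery error is ≈0.003 mass-fraction
units; single-spectrum (non-replicated) measurement roughly doubles the
noise-driven error. With the default sugar background switched on the
coarse hump model's Lorentzian tails bias the lactone window (its 3.4 ppm
hump neighbour) low by several percent relative even noise-free — an
artifact of the 40-Hz hump stand-in rather than of real sugar multiplets;
the local baseline still removes most of the interference compared with
naive integration, which is what the sugar-robustness test asserts.

### What the simulator does not emulate

No FID-domain effects (apodization, phasing, truncation), no vendor binary
formats, no pH-dependent shift drift (real spectra show slight shift
variation with pH; the integration windows are user-overridable for that
reason), no ¹³C satellites, no correlated (1/f) noise. Published
validation figures measured on real instrument spectra (regression
coefficients, printed LOD/LOQ values) are therefore not reproduction
targets; the machinery that would compute them from real data is.

## Barcode arm

### Distances and summaries

K2P distances use pairwise deletion: any site where either sequence
carries a gap or an ambiguity code (anything outside ACGT) is dropped for
that pair only — this maximizes comparable sites and avoids fractional
substitution counting. d = −½ln(1 − 2P − Q) − ¼ln(1 − 2Q); a non-positive
log argument (saturation) yields an undefined distance carried as a
flagged NaN cell rather than aborting the matrix. Intra- and interspecific
summaries are means ± population SDs (n denominator; the SD convention is
recorded here because sources rarely state theirs) over all defined pairs;
a marker is `suitable` only when inter-mean > intra-mean. Parsimony-
informative sites are columns with ≥2 unambiguous states each present in
≥2 sequences.

### Trees and assignment

Neighbor joining is the canonical Saitou–Nei algorithm on the K2P matrix.
Maximum-likelihood inference was deliberately replaced by NJ: it keeps the
package self-contained, is exact on additive matrices, and exercises the
same clade-membership authentication logic. Ties in the Q criterion are
broken deterministically toward the lexicographically smallest pair of
cluster labels (each cluster labeled by its smallest member leaf).
Negative branch-length estimates are clamped to zero with the deficit
moved to the sibling branch. Trees serialize to Newick with branch
lengths.

A query is assigned to species S only when two criteria agree:
(a) nearest neighbor — the closest reference belongs to S and every other
species' nearest reference is strictly farther; and (b) clade membership —
in the NJ tree of references plus query, the smallest clade containing the
query and at least one reference (the query side of each tree edge,
minimized over edges) holds only S references. Exact ties or conflicts
give "ambiguous"; a nearest distance above a ceiling (default 0.2
substitutions/site) gives "no-match".

### Sequence simulator

Sequences evolve site-independently under K2P with transition rate
α = κ/(κ+2) and transversion rate β = 1/(κ+2), so branch lengths are in
expected substitutions per site. κ defaults to 2.0 (a typical plant
nuclear/chloroplast value; recorded in the truth table since no empirical
κ is available here). Reference libraries use a star species tree: species
roots at `inter_depth` from a uniform-random ancestor, individuals (and
queries) at `intra_depth` from their species root, so conspecific pairs
are separated by ≈2·intra_depth and heterospecific pairs by
≈2·(inter_depth + intra_depth). Defaults (6 species × 3 individuals,
600 bp, intra 0.005, inter 0.08) produce the clean intra/inter structure
of a curated reference library of moderately divergent congeners. No
coalescent process, no indels, no rate heterogeneity across sites, no
nested phylogenetic structure (a user-supplied tree can replace the star);
real libraries with introgression, shared haplotypes or paralogy will be
harder than these simulations, so the ≥99 % assignment accuracy measured
here bounds the method's behaviour only under its own assumptions.

## Embedded study tables

The 24 fruit-rind rows (18 Kodampuli, 6 Kokum) and 10 supplement rows are
embedded verbatim and guarded by a SHA-256 checksum; every derived summary
(species means/ranges, row totals, label-implied doses) is recomputed, not
restated. Two rounding artifacts are surfaced deliberately: a few printed
row totals differ from the sum of their rounded components by 0.1 (the
source evidently summed unrounded values), and the Kokum species means of
rounded table entries (HCA 4.25 → 4.3, lactone 7.883 → 7.9) can disagree
in the last decimal with means of the unrounded instrument values. These
are flagged in the reports and excluded from hard pass/fail comparisons;
display rounding is one decimal, half away from zero.

## Verification strategy

Every closed form is tested against an independent oracle: the
quantification equation against exact rational arithmetic, K2P distances
against brute-force formula evaluation on substitution-count grids and the
Jukes–Cantor reduction at κ=1, K2P transition probabilities against the
matrix exponential of the rate matrix, NJ against additive matrices from
known trees and against scikit-bio's implementation, Newick output against
dendropy round-trip parsing, and the simulators against their own analytic
expectations (proton-count area ratios, expected p-distances, distance
unbiasedness). Statistical assertions use seeded generators and 3·SE
bounds.
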