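# Methods

## Scope and model

`breathvoc` annotates oxygenated breath VOCs (ketones, saturated and
unsaturated aldehydes, carboxylic acids, primary alcohols, phenols and
substituted-benzene aromatics) by *forward prediction*: given a
candidate's elemental formula and chemical class, predict the diagnostic
ions it must show on each platform, and demand that observed spectra
contain them. This inverts the usual library-search direction and is what
makes weak-library-hit features decidable — the predictions are
class-level chemistry, not compound-level reference spectra.

All mass arithmetic is on nominal (unit) masses — C=12, H=1, N=14, O=16,
S=32 — because the modelled instruments are unit-resolution quadrupoles
and every diagnostic ion is an integer m/z. All ions are singly charged;
the electron mass is ignored. Monoisotopic/accurate-mass support is out
of scope, as is isotope-pattern simulation.

One deliberate quirk is preserved: the β-cleavage fragment of longer
unsaturated aldehydes is predicted at the literature's printed m/z 41
even though the nominal mass of the ketene-type formula C2H2O is 42. The
rule tables carry the printed value; "correcting" either silently would
misrepresent the source chemistry this package encodes.

## Rule tables

EI and PCI rules are declarative tables shipped as package data
(`data/ei_rules.csv`, `data/pci_rules.csv`): one row per (class,
carbon-range, transform) with a three-level intensity class (base = 100%,
major = 30–100%, minor = < 30% relative intensity — the < 30% figure is
the documented cut for the weak [M+H]⁺ of longer saturated aldehydes).
Serialising and reloading a table reproduces identical predictions, and
users can extend classes without touching code. Carbon-range boundaries
follow a strict reading of the chain-length notation: "> C4" means
carbon count ≥ 5, "> C3" means ≥ 4; short-chain acids are C ≤ 3 (the
named examples are acetic and propanoic acid). Short-chain acids predict
both M⁺ and [M−17]⁺ under EI — for acetic acid M⁺ is m/z 60, the same
integer as the McLafferty enol of longer acids, which is why EI alone
cannot separate these hypotheses and the cross-platform step matters.

Only the water CI reagent carries an ion rule set. Methane (PA 552
kJ mol⁻¹) and methanol (PA 761, dimer/trimer-forming) exist as reagent
metadata for the proton-transfer-favourability check
(`analyte PA > reagent PA`, strict; unknown analyte PA returns an
explicit indeterminate, never a default). The ketone proton-bound dimer
[2M+H]⁺ is emitted only under an explicit `dimer_audit` flag and flagged
*absent*: water-reagent PCI does not form it, so observing one argues
against the assignment.

SIFT-MS channels are class/precursor functions, independent of any
intensity data. Water-adduct series are capped at n = 2 hydrates
(configurable) — the regime unit-resolution breath work actually
resolves. Interpretation choices where the channel chemistry is stated
only qualitatively: NO⁺ "water adduct formation" for phenols is realised
as M+18n on the electron-transfer product, the only mass-consistent
reading; saturated aldehydes with H₃O⁺ get plain protonation (no
dehydration), the default for VOCs; aromatics have no NO⁺ channel and
alcohols' NO⁺ chemistry is not predicted — both raise an
unsupported-channel error, and the annotation engine simply skips such
platforms rather than guessing. Dissociative ionisation of acids with
NO⁺ is *flagged*, with fragment m/z left to a user-supplied kinetic
library entry: predicting those fragments from class would be invention.

MIM quantitation is standard flow-tube kinetics:
`ppbv = 1e9 · I_product / (I_precursor · k · t · N)` with k in cm³ s⁻¹,
reaction time t in s and carrier number density N in cm⁻³. It is
homogeneous of degree +1 in product counts and −1 in precursor counts;
averaging over the acquisition window is the caller's concern.

## Annotation engine

* Retention index: van den Dool/Kratz linear interpolation on the C5–C20
  alkane ladder; no extrapolation outside the ladder span.
* m/z tolerance ± 0.3 (unit-resolution quadrupole); RI tolerance ± 15
  index units — wide enough for run-to-run drift, narrow enough to
  separate 2-ethylphenol (RI 1286) from 4-ethylphenol (RI 1323). Both
  configurable.
* Library gate: cross-platform workup is required iff
  min(match, reverse match) < 800, strict at the boundary.
* A platform's evidence is `matched` when every base-class prediction is
  observed and at least one base/major ion matched; whether the base
  prediction is also the most intense matched peak is recorded but not
  required (co-eluting background makes intensity ordering unreliable).
* Contradiction — the rejection trigger — requires a spectrum with at
  least 3 peaks above the intensity floor and zero base/major matches,
  so sparse spectra cannot reject. A contradiction on any platform
  forces `rejected` even when another platform matched coincidentally
  (the ammonium-acetate case: its [M−17]⁺ 60 matches the acetic-acid EI
  spectrum, but the H₃O⁺ spectrum contradicts it).
* The two SIFT precursors count as two independent platforms for tier
  thresholds; zero matched platforms without contradiction yields
  `tentative` (rejection always requires positive contradiction).
* Candidates with identical SIFT product-ion signatures (isomers) carry
  each other in `ambiguity_set` unless the RI comparison separates them.
* Ranking: tier, then matched-ion count, then name — deterministic under
  candidate permutation.

EI/PCI retention *times* are never compared across runs; grouping uses
the RI scale only.

## Synthetic generator

The generator emulates the documented measurement conditions so every stage is testable
without instrument data: intensity noise is multiplicative with CV 0.09
(the documented 9% replicate RSD of the SIFT method), m/z jitter is
gaussian with σ 0.1, a compound's fragments share one per-platform RI
jitter draw (σ 5 index units — fragments co-elute), and decoy background
peaks arrive Poisson (mean 5 per feature) uniform over the 20–250 m/z
acquisition window with low intensities. The default library is a
16-compound authentic-standard-style mixture spanning all classes; the
propanal/acetone (RI 489/498) and 2-/4-ethylphenol (1286/1323) pairs are
the printed benchmark values, remaining RIs are representative mid-polar
624-phase values. Calibration series emulate paired sorbent tubes loaded
from one permeation source (shared loadings, independent 9% noise per
platform); cohorts draw per-sample class fractions from a Dirichlet
centred on the published medians (ketone 77, aldehyde 10, acid 9,
phenol 3, alcohol 1, renormalised) with concentration 50 — the source
reports only medians and a box plot, so the dispersion is a choice.
Every output is a pure function of (config, seed).

What passing tests on this data do **not** show: real chromatographic
peak shapes, deconvolution artefacts, humidity effects on SIFT
hydration, matrix suppression, or compounds outside the seven modelled
classes (notably bifunctional compounds, for which the caller must pick
a single class).

## Numerical and statistical choices

* Paired-response regression is ordinary least squares; zero predictor
  variance is a hard error. Because *both* platforms measure with ~9%
  noise, a single 6-point paired experiment carries roughly 10% sampling
  standard deviation on the slope; recovery of the true slope is
  therefore a property of the estimator's mean over repeated
  experiments, and the tests check it that way (the estimator is
  unbiased to well under a percent in that regime).
* RSD is the sample (ddof = 1) standard deviation over the mean, in
  percent; undefined at zero mean. Note that for n = 3 gaussian
  replicates the *expected* sample RSD sits a few percent below the true
  CV (small-sample bias of the sd estimator) — the tests allow for this.
* LOD = 3.3 σ_blank / slope (ICH-style), converted to ppbv through the
  series' loading-to-mixing-ratio factor; the estimator is documented
  and swappable since detection limits are reported in the field without
  a standard formula.
* Class composition normalises per sample to exactly 100%; cohort
  summaries are median + IQR, matching box-plot reporting. The
  composition table is plain tidy data so any stats package can consume
  it downstream — demographic hypothesis testing is deliberately out of
  scope.
* Tie-breaks everywhere are lexicographic by compound name, for
  determinism.

## Problem sizes

The test suite and examples run the full pipeline at desk scale: 16
compounds × 4 platforms per recovery run, 5 independent runs for the
≥ 90% top-1 recovery check; 200 samples for cohort-median recovery; 20
paired experiments for regression recovery; 500 triplicates for RSD
recovery. Each completes in seconds on one CPU.

## Known limitations

* Rule coverage is the seven modelled classes; bifunctional compounds
  need a caller-chosen primary class.
* SIFT isomer blindness is represented, not resolved: the ambiguity set
  is only emptied by GC retention-index evidence.
* No raw-file ingestion (mzML is a future adapter); peak tables arrive
  as delimited text.
* The EI m/z 41 / C2H2O = 42 inconsistency is carried as printed (see
  above).
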