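# Methods

This note records the models behind each pipeline stage, the defaults that
matter, what the synthetic-data generator does and does not emulate, and the
design choices made where the design was genuinely open.

## Peak-shape model

FT analyzers lose resolving power as m/z^(-1/2), so the absolute Gaussian
peak width grows as σ(m/z) = σ_ref · (m/z / m/z_ref)^1.5. The default PSF is
anchored at resolving power 240,000 (FWHM) at m/z 200, the acquisition
setting typical of high-resolution native MS² work. `PsfModel.exponent` is
exposed because TOF-like data would want exponent ≈ 1.

## Spectral enhancement

*Extensive* workflow: Richardson–Lucy deconvolution applied in windows of
100 Th so the kernel can track the m/z-dependent width. Windows overlap by
10% and are blended with a linear cross-fade; each window's flux is
conserved (renormalised after the multiplicative iterations) and the
iterate is non-negative by construction. Defaults: 50 iterations with early
stop when the relative change drops below 1e-5; more iterations sharpen
further (the two-Gaussian valley deepens monotonically) at the cost of
noise amplification.

*Rapid* workflow: Mexican-hat continuous-wavelet responses at six scales
spanning the PSF widths across the spectrum; local maxima are linked into
ridges across scales and kept when the best response exceeds `snr_min`
times the noise (median absolute response at the smallest scale, floored so
numerically-zero regions of noiseless input cannot seed ghost ridges).
Centroids are intensity-weighted means over the apex region.

## Envelope detection

The iterative detector repeatedly takes the most intense unexplained peak,
estimates the charge from the autocorrelation of the surrounding ±1.2 Th
window (lags at 1.00286/z for z up to `charge_max`), fits the averagine
isotope template for the implied mass and, if the fit clears the threshold,
subtracts the fitted Gaussian profile and continues until the apex falls
below the noise floor (3 × the modal local-maximum intensity, capped at 30%
of the base peak so sparse spectra still yield their apexes). Because
subtraction reorders what is "most intense", runs at different fit
thresholds find different envelope sets; the detector is therefore run at
thresholds {0.60, 0.70, 0.80, 0.90} and the union merged. These four values
are this package's choice; only the *varied-thresholds* strategy itself is
standard.

The graph-style detector scores an averagine-envelope hypothesis for every
(centroid, charge) pair — an additive score rewarding matched-peak count,
m/z agreement and intensity agreement — and greedily selects the best
non-conflicting set, so no centroid is explained twice.

**Monoisotopic-mass determination.** Aligning an averagine template to a
heavy ion by its apex alone is ambiguous to ±1 neutron. Both detectors
therefore compare the abundance-weighted mean position of the observed
peaks with the template's weighted mean offset over the same isotopologue
bins and snap the implied continuous mass to the isotopologue lattice. The
residual failure mode is real: fragments whose sulfur content deviates far
from the averagine average (e.g. cysteine-rich stretches) shift their
isotope pattern by more than half a neutron and are recorded one neutron
off. This is a known limitation of composition-agnostic deconvolution, and
it is why open-search results show satellite offsets at +1.003 Da
("monoisotopic errors") next to genuine modification offsets — the
satellites are expected and are annotated as such.

**Fit score.** The bounded similarity fit = max(0, 1 − Σ|obs − s·theo| /
Σ obs) with least-squares scale s over matched isotopologues (1 = perfect)
is this package's definition; it is documented here because published
descriptions of "custom fit scores" rarely state a formula.

**Features.** Per envelope: signal-to-noise (apex / modal peak intensity of
the spectrum — the modal local maximum is a robust noise proxy in dense
fragment spectra), the fit score, interference (model-explained intensity /
total intensity within the envelope span), missing-peak fraction over
isotopologues expected at ≥1% relative abundance, per-isotopologue mass
errors, χ² statistic with p-value, and the Pearson correlation between
scaled theoretical and observed intensities. Training uses these seven
plus charge and log total intensity.

## Envelope filtering

A logistic regression (z-scored features, C over a log grid) and a gradient
boosting classifier (depth {2,3,4} × learning rate {0.05,0.1,0.2} × trees
{100,300}), each tuned by stratified cross-validation with **recall** as
the selection metric: in native work a lost true envelope is costlier than
a retained artifact. An envelope is discarded only when both models predict
false; set-theoretically the veto's false-negative count can never exceed
either member's. Models are trained per spectrum — no cross-instrument
generality is claimed — and can be saved/reloaded (joblib bundle with a
format-version field) for related spectra.

## Identification

Sequence tags: a directed graph over neutral masses with an edge when a gap
matches a residue mass (I/L merged, reported as `[L/I]`), or, bracketed, a
two-residue sum; two-residue edges carry weight 1.99 against 2 × 1 for two
single steps so unambiguous readings win ties. Tags of ≥8 residues are
flagged high-confidence.

Open database search: terminal ions of every supplied isoform (callers
should include both mature and unprocessed precursor forms), no intact-mass
prefilter, no side-chain modifications — the search space stays linear and
the modifications are found later by the open search. Ranking uses a
propensity score: Σ over matched cleavage sites of (base credit + log-odds
weights for the flanking residues, favouring cleavage C-terminal to Asp and
N-terminal to Pro), normalised by log(sequence length). The weight table is
a documented surrogate for published native-fragmentation propensity
scores, and is user-replaceable.

## Hierarchical assignment and recalibration

Unmodified terminal ions are matched at a coarse 10 ppm (analyzers drift);
every mass match is validated by fitting the ion's exact-composition
isotope pattern, and is auto-accepted only when fit ≥ 0.75 **and** the mass
error is inside tolerance — otherwise it goes to a review TSV rather than
being silently assigned (the batch-mode stand-in for interactive review).
Degenerate matches resolve deterministically: smaller |ppm|, then lower
cleavage index, then series order b < y < c < z•. Each assigned envelope
leaves the pool, so nothing is explained twice.

Variants (dehydration −18.01056, deamidation +0.98402, sodiation
+21.98194) are then searched at 3 ppm *relative to assigned ions*,
correcting for the current median systematic error, iterating until no new
assignments appear.

Recalibration fits observed-vs-theoretical m/z error as a + b·m/z by
weighted least squares with weights 1/m/z — the correct heteroscedastic
model when mass errors are ppm-scale — and drops assignments whose
post-calibration error exceeds the fine tolerance. Fitting in m/z versus
ppm space differs negligibly at the 3-ppm scale; m/z space was chosen.
The calibration benchmark uses 120 calibrant ions, matching the hundreds of
assignments a real averaged spectrum provides; with far fewer calibrants
the intercept recovery becomes noise-limited rather than method-limited.

## Fragment-level open search

E value = λᵏ e^(−λ) / k! × n, computed in log space (gammaln). λ is the
plain mean match count across the scan, including any significant offsets
— true modified-ion sets are rare enough that the mean approximates the
null; a trimmed-mean option exists but is off by default. n is the number
of offsets evaluated, which makes the E-value a Bonferroni-style expected
count: at threshold α the long-run number of significant offsets per null
scan stays at the order of α (measured ≤ 0.015 at α = 0.01 over 1000
random-mass scans).

The continuous grid step is the ppm tolerance at the median theoretical
mass divided by 4 (4× oversampling; the oversampling factor is this
package's choice). Match counting is by interval coverage: each
(observed, theoretical) pair contributes an offset interval of ±tol around
its delta, intervals of one observed ion are merged so an ion counts once
per offset — linear in pairs, which is what makes 1000-scan null
calibration cheap. Adjacent significant grid points collapse to the local
count maximum and the reported offset is the median matched delta, so
annotation works at the mDa level. Negative offsets (losses) are handled
identically. Ranges beyond 5000 Da are refused in the continuous scan —
that regime belongs to the multinotch search, which shares the identical
statistical contract with n = notch count.

Internal fragments: an internal b/y-type ion spanning residues [i, j] is a
plain residue-sum mass; a set sharing the N-side cleavage at i appears as
the backbone-loss notch −prefix(i−1) applied to terminal b ions, and
symmetrically for shared C-side sets against y ions (with the water offset
of the y series). With the shared-termini filter only sets with E < 0.01
yield assignments; degenerate candidates resolve by (1) a shared cleavage
site already evidenced by an assigned terminal ion, (2) smaller |ppm|,
(3) shorter fragment — a deterministic surrogate for likelihood-based
prioritisation.

Decoy FDR: the four decoy offsets H₅, H₅O₂, H₇O₉, H₉O₃ are applied to the
theoretical ions and the multinotch search repeated. Unfiltered FDR = mean
per-notch decoy/target ratio over notches with ≥1 target match, averaged
over decoys (the ratio is undefined at zero-target notches, so those are
excluded). Filtered FDR = (mean decoy matches per notch × number of
significant target notches) / target matches within significant notches.
Both are capped at 1.

Localization: with a significant offset treated as a fixed modification,
modified and unmodified ions of one terminus bracket the smallest residue
interval containing the site: for C-terminal ions, from the span start of
the smallest modified index to the residue just inside the largest
unmodified index below it.

## Quantification

All comparisons are between differently modified forms of the *same*
sequence ion, under the assumption that a small modification does not
change fragmentation efficiency at that site. Mixture fits render each
candidate species' exact-composition isotope pattern, convolve with the
PSF, and solve non-negative least squares on the raw profile; NNLS (rather
than unconstrained LS) because abundances are physical. Fitted amplitudes
are divided by charge before fractions are reported. When several ions are
fit independently, the reported fractions are the per-species medians
across fits, renormalised — robust to the occasional region corrupted by a
coeluting interferer — and the spread across fits is the uncertainty, as
variance between independent envelope fits rather than a bootstrap.
Truncation fractions are mean charge-normalised intensities over ions
sharing the cleavage site. Phosphorylation profiles group differentially
phosphorylated states of each sequence ion across spectra, drop groups
seen in fewer than 3 spectra, treat a missing state as abundance 0, and
report per-residue means toward the nearest terminus, intensity-weighted
over the covering ions, with s.d. across spectra.

## Synthetic data

The generator emulates: FT profile rendering at the declared resolution
model on a uniform grid; terminal ions drawn from per-site cleavage
probabilities (4× boost C-terminal to Asp, 2× N-terminal to Pro); charges
biased toward mid-window m/z; lognormal intensities (σ = 0.8);
dehydration/deamidation/sodiation side products; modified-fragment subsets
with per-species fractions; internal fragments sharing hot secondary
cleavage sites; linear m/z drift plus 0.3 ppm random mass error; averagine
impostor and half-charge ghost artifacts; additive |Gaussian| noise.
Sequences are drawn at natural amino-acid frequencies (uniform sampling
would triple the sulfur content and systematically distort isotope
patterns). Everything is deterministic under the seed.

It does **not** emulate: coalescence and space-charge effects, non-Gaussian
FT line shapes or phase artifacts, charge-state-correlated fragmentation
physics, glycan fragmentation cascades, chemical (structured) noise, or
detector saturation. Passing tests therefore demonstrate the statistical
machinery and bookkeeping on idealised spectra, not instrument-specific
robustness.

Mass-list-level simulators (random masses, planted offset subsets,
internal-fragment sets among uniform noise) drive the statistical
benchmarks at volumes where profile rendering would be waste. The
benchmark problem sizes — 1000 null scans, 50 offset-recovery spectra, 20
internal-fragment datasets, 100 mixtures, one full end-to-end case study on
a 3.2-million-point spectrum — were chosen to give stable statistics in a
few minutes on one CPU.

## Standard settings

| parameter | default | meaning |
|---|---|---|
| coarse tolerance | 10 ppm | first-pass terminal-ion matching |
| fine tolerance | 3 ppm | post-calibration matching, variants, open search |
| fit threshold | 0.75 | auto-accept boundary for envelope fits |
| E-value threshold | 0.01 | open-search significance |
| oversampling | 4× | continuous-scan grid vs tolerance |
| decoys | H₅, H₅O₂, H₇O₉, H₉O₃ | FDR estimation offsets |
| resolution | 240,000 @ m/z 200 | PSF anchor |

## Known limitations

- Mono-mass off-by-one on strongly sulfur-enriched fragments (see above);
  downstream searches surface these as +1.003 Da satellite offsets.
- Closely spaced acyl species (18:1 vs 18:0, 2.016 Da apart) are not
  separable at detection time — their envelopes interleave on nearly the
  same lattice; they are resolved at quantification time by mixture
  fitting, which is why the open search may report only the dominant
  species' offset while the mixture fit still recovers all fractions.
- One offset per ion per pass; combinatorial multi-modification placement
  is out of scope (repeated passes are the supported route).
- The propensity-score weight table and the degenerate-assignment priority
  are documented surrogates, not validated reimplementations of any
  published scoring function.
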