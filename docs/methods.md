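# Methods

## Survival model and fitting

Germination counts after `p` days of storage are modelled as
`germinated ~ Binomial(total, π(p))` with `π(p) = Φ(Ki − p/σ)` — the seed
viability equation on the probit scale — or, for lots with dormancy,
`π(p) = Φ(Knd + p/σ_nd) · Φ(Ki − p/σ)`, the product of the non-dormant and
viable proportions. `Ki` is initial viability in NED, `σ` the days per
probit of viability loss (reported as its reciprocal `σ⁻¹`, NED/day), and
`Knd`, `σ_nd` the corresponding intercept and timescale of dormancy
release. `P50 = Ki·σ` is defined on the viability component alone; the
dormancy line shifts observed germination, not survival.

Fitting maximises the exact binomial log-likelihood:

* **Reduced model** — BFGS with analytic gradient from three deterministic
  starts; the primary start is a least-squares line through the empirical
  probits of the non-degenerate observations. Because the likelihood is
  that of a probit-link binomial GLM, the fit is cross-checked against an
  independent IRLS implementation in the test suite.
* **Combined model** — L-BFGS-B over `(Knd, 1/σ_nd, Ki, 1/σ)` with analytic
  gradient from a fixed 8-point lattice of starts (`Knd ∈ {−1, 0, 1, 3}`,
  `σ_nd ∈ {5, 20}` d), `(Ki, 1/σ)` seeded from the reduced fit. Bounds:
  `Knd ∈ [−8, 12]`, `1/σ_nd ∈ [0, 5]`, `Ki ∈ [−5, 8]`, `1/σ ∈ [1e−6, 2]`;
  parameters pinned at a bound are flagged. A likelihood-ratio comparison
  against the reduced model (χ², 2 df, α = 0.05) flags whether the data
  actually support the dormancy component; model choice per lot is the
  user's (`reduced`/`combined`/`auto`), with `auto` applying the LR screen.

Standard errors come from the observed information matrix (numerical
Hessian of the negative log-likelihood at the optimum). They differ
slightly (≲1%) from expected-information IRLS standard errors because the
probit link is non-canonical.

Proportions of exactly 0 or 1 enter the likelihood directly — no empirical
probit transform and no continuity correction, since the binomial
likelihood is well defined at the boundary. Data that are all-0% or
all-100%, or observed at fewer than two distinct storage times, are
rejected as non-identifiable. If germination *increases* with time and no
dormancy model was requested, the fit is returned with a warning flag and
an undefined P50.

Reported rounding follows the conventional longevity-table layout: `Ki` to
2 d.p., `σ⁻¹` to 3 d.p., `P50` to 1 d.p. Recomputing `P50` from rounded
published parameters can deviate up to ±0.3 d from the originally printed
value on some rows; exact-agreement checks use only rounding-stable rows.

## Storage physics

Oxygen partial pressure is Dalton's law (`P·x_O2`, dry-air `x_O2 = 0.21`).
The water-activity rise under tank pressure is the Poynting factor
`exp(V_w (P − P0) / (R T))` with `V_w = 1.8066×10⁻⁵ m³/mol`,
`P0 = 0.1 MPa`, `R = 8.314 J/(mol·K)`; the temperature dependence of `V_w`
is ignored over 20–35 °C. This constant reproduces both calibration
anchors of the 20 MPa system (a_w 0.40 → 0.46 at 20 °C; ERH 43.5% → ≈50%
at 35 °C). Whether the correction should use `P` or `P − P0` cannot be
discriminated by those anchors at 2 d.p.; the pressure *difference* from
the ambient reference state is used, which makes ambient pressure an exact
fixed point. Results are capped at saturation (a_w = 1). Real-gas
corrections and gas solubility in seed tissue are out of scope.

## Germination kinetics and the ΔEPPO correction

Cumulative within-test germination is summarised by the Hill curve
`G(t) = Gmax·t^h/(t50^h + t^h)` fitted by bounded least squares on the
percentage scale (`h ∈ [1, 20]`, start `h = 4`, `Gmax` from the last
scoring, `t50` from the first half-maximum crossing). `t50` is defined
relative to the fitted `Gmax`, not to seeds sown, so it stays meaningful
for partially viable lots. Zero-germination tests return `Gmax = 0` with
undefined `t50`; tests where all germination happened before the first
scoring are flagged left-censored (`t50` only bounded above by the first
scoring time).

The ΔEPPO correction removes lot-specific pressure sensitivity:
`corrected = EPPO + (ambient_ctrl − EPPN_ctrl)`, strictly per (lot,
replicate), with the 21-day controls. Percentage traits are clipped to
[0, 100] after correction (and never after averaging — corrections are
replicate-wise by definition). The same additive rule is applied to `t50`
(hours, unclipped); this uniform treatment is a package choice recorded in
the output metadata. Missing controls propagate as explicit missing
values, never imputed. For probit fitting of the corrected series, the
corrected percentages are converted back to pseudo-counts by rounding
against the test size.

## Metabolomics screens

Feature tables are samples × compounds relative intensities. The
reproducibility filter keeps compounds detected in ≥3 samples strictly
above 15,000 counts (three times a typical peak-picking detection
threshold; strict inequality deliberately). Internal-standard
normalisation divides each sample by its IS intensity and rescales by the
panel-mean IS, making all downstream statistics invariant to per-sample
multiplicative factors. Missing intensities count as not-detected for
filtering but are excluded pairwise for correlation — detection and
covariation are different questions.

Screens are Pearson correlations of each compound against the sample's
mean germination percentage (viability) or storage days; selection rules
are data (`column, op, threshold`) with strict inequalities, defaults
`r < −0.5` / `r > 0.5` and the stricter `r < −0.98` / `r > 0.85` available
for top-compound tables. "Percent of initial" is `100 × mean(timepoint) /
mean(initial control)` — values below 100 mean decline (e.g. antioxidant
channels); note this quantity is a ratio, not an increase, even where
column headers elsewhere say "increase". Cross-condition comparisons use
exact inclusion–exclusion partitions of up to four compound sets. Kovats
retention indices interpolate linearly on a C8–C22 alkane ladder with no
silent extrapolation. PCA (mean-centred, optional log10) is standard and
delegated to scikit-learn.

## Accurate-mass lipid annotation

Monoisotopic masses come from IUPAC isotope tables (via pyteomics); adduct
m/z adds a fixed delta per singly charged adduct (H⁺ 1.007276, NH₄⁺
18.034374, Na⁺ 22.989218 Da — electron mass folded in, so no separate
charge correction). Matching accepts candidates within 3 ppm, sorted by
|ppm| (grouped at 10⁻⁴ ppm so float dust cannot split true ties), ties
broken by fewer added oxygens then fewer double bonds.

Class readings follow fixed backbone rules — TAG: base O=6, c=C−3,
d=DBE−3; DAG: base O=5, c=C−3, d=DBE−2; free FA: base O=2, c=C, d=DBE−1;
optional fatty-acid ethanolamide (N=1, base O=2) — with
DBE = (2C+2+N−H)/2. When several classes fit a formula, candidates whose
acyl-carbon count falls in the class's typical range (TAG 30–66, DAG
20–44, FA 8–28) rank first, then TAG > DAG > FA: this is what makes
C18H34O5 read as "Oleic acid + 3 O" rather than an implausible odd-chain
"DAG 15:0", while keeping every TAG reading (odd chains included)
round-trip stable. Common free fatty acids get trivial names. Candidate
generation is library-based (enumerated base species × 0–4 added oxygens),
not free formula decomposition, mirroring database-driven lipidomics
matching and avoiding combinatorial false positives. Features matching
nothing stay "unknown"; the engine reports the best-fitting adduct even
when a source label disagrees, and published feature lists do contain rows
whose printed adduct or formula is internally inconsistent — those simply
fail the 3 ppm gate. MS/MS interpretation, sn-position assignment and
isotope-pattern scoring are out of scope.

## Synthetic data

The generators define the study conditions the tests exercise:

* **Survival panels** — default 20 accessions × 4 treatments (ambient,
  EPPN, EPPO, CD) × days {0, 14, 21, 28, 42, 56} × 2 replicates × 45
  seeds. Truth values are the published EPPO longevity parameters of the
  bundled rice panel (Ki 0.70–3.97 NED, σ⁻¹ 0.062–0.123 NED/day); the
  three lots known to after-ripen carry a dormancy component (Knd 0.5 NED,
  σ_nd 10 d). Treatment aging-rate multipliers scale the viability dose:
  EPPO 1.0, CD 0.8, EPPN 0.15, ambient 0.10 — chosen once so that ambient
  and pressure controls decline only mildly over 56 days while EPPO ages
  lots to near-zero viability, matching the qualitative contrast such
  experiments show. Counts are binomial draws; dormancy release runs on
  calendar time, viability loss on dose time.
* **Time courses** — each germinating seed draws its germination time from
  the Hill-implied distribution (baseline t50 = 64 h, h = 4), truncated at
  the 336 h test end, with t50 inflated by `1 + 3·dose/56` so a fully
  EPPO-aged lot germinates ~4× slower — the order of slowdown observed in
  aged seed.
* **Feature tables** — 200 compounds (10 aging-responsive, 5 antioxidant),
  log-normal baselines spanning 10³·⁷–10⁵·⁷ counts, responsive channels
  adding 0.8–1.6 log10 units over full viability loss, antioxidants
  −0.3 to −0.6, intensity noise CV 20%, a per-sample instrument factor
  (CV 15%) recorded by the internal-standard channel, and oxidized-TAG m/z
  metadata (±1.5 ppm jitter) on responsive channels so annotation has
  real work to do.

What the generator does *not* emulate: correlated noise between
co-eluting features, drift with injection order, censored/missing peaks,
seed-lot heterogeneity beyond the binomial, or real lipidome composition.
Passing recovery tests therefore shows the estimators are correct under
their assumed model at realistic sizes — not that real instruments behave
this nicely.

All generators are deterministic given their recorded seeds.

## Pipeline

`run_pipeline` sequences simulate → kinetics → ΔEPPO → viability fits →
longevity tables (EPPO and ΔEPPO, with Maximum/Minimum/Mean rows) → P50
Pearson matrix across aging treatments (significance at two-sided 0.05 —
reported, but low-powered at panel sizes of ~20 lots and labelled so) →
metabolomics screen on a focal accession → annotation → Venn partition →
run log. Output uses dot decimals, fixed column order and `%.6g`
formatting, so identical config + seed reproduce byte-identical tables.
Stage failures abort with the stage name and remove partial outputs.

## Problem sizes

Default test-suite simulations use 200 survival panels for recovery and
coverage checks, 100 feature-table replicates for the planted-signal
screen, 50 Monte-Carlo germination tests for t50 recovery, and a 781×781
likelihood lattice as the brute-force oracle — sizes at which the checked
medians and coverages are stable to reruns.

## Known limitations

* Wald standard errors and intervals; no profile likelihood or bootstrap.
* The combined model's dormancy timescale is weakly identified when
  after-ripening completes before the second storage time.
* ΔEPPO pseudo-count rounding loses sub-seed resolution for very small
  test sizes.
* The annotation library covers TAG/DAG/FA(+amide) classes; phospholipids
  and sterol esters must be supplied as explicit candidates.
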