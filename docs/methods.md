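# Methods

## The two-state clonal model

Every cell carries a heritable barcode (clone label) and occupies one of two
reporter-defined states: `H` (mTORC1-high, probe degraded, mVenus-dim) or
`L` (mTORC1-low, probe stable, mVenus-bright). Per-cell, per-day hazards:

| event | H | L | notes |
| --- | --- | --- | --- |
| birth | `birth_H` | `birth_L` | `birth_H > birth_L`: high cells cycle faster |
| death | `death_H` | `death_L` | baseline turnover |
| chemo kill | `kill_H` | `kill_L` | only inside the treatment window |
| transition | `trans_HL` | `trans_LH · (1 + c·ν)` | ν = nutrient, c = coupling gain |

Nutrient availability is a deterministic function of total marrow burden,
`ν = K/(K + burden)` with half-saturation `capacity_K`: an empty marrow has
ν = 1, a marrow at carrying scale K has ν = 1/2. Coupling the L→H rate to ν
encodes the observed burden-dependent suppression of mTORC1 without
introducing independent nutrient kinetics, for which no data exist.

Two mechanistic templates are derived from a single base rate set:

* **selection** — `trans_HL = trans_LH = 0`, nutrient coupling 0, kill rates
  oriented so `kill_L > kill_H` (the surviving pool reads "high" purely by
  differential survival). Clones are frozen in their founder state forever.
* **induction** — transitions symmetrised to the mean of the base rates,
  positive nutrient coupling, kill per state as configured.
* **mixed** — elementwise convex combination, weight on induction; provided
  for power analysis only.

### Default rates (calibration)

Absolute rates are not identified by the underlying biology alone; the
defaults in `clonfate.config.DEFAULT_RATES` are calibrated so that

1. untreated burden grows roughly 10-fold per week
   (`birth_H=0.5, birth_L=0.3, death=0.05`/day → net ≈ 0.35/day),
2. a 5-day treatment window with `kill_H=0.8, kill_L=1.1`/day produces the
   burden nadir near treatment day 7 on the day-0/5/7/14 sampling grid,
3. high-state cells cycle faster (`birth_H > birth_L`),
4. `capacity_K = 2e8` cells puts late disease in the nutrient-suppressed
   regime.

The experiment defaults mirror the published workflow: 2×10⁶ cells exposed
to the barcode library at 10% infection probability (~2×10⁵ barcoded
founders; multi-integration cells, ~5% of founders by the zero-truncated
Poisson, are tracked under a single barcode and counted), 10⁶ cells
transplanted per animal, a 21-day engraftment phase before the treatment
clock starts, cytarabine for 5 days with doxorubicin concurrent for 3 (one
constant kill hazard inside the 5-day window; no pharmacokinetics), and
400,000 cells sorted per mTORC1 gate on days 0/5/7/14.

Founder barcodes are drawn from the library *without replacement* whenever
the library is large enough (rejection redraw of duplicates). This keeps
clone identity exact — and makes the selection template's shared-barcode
fraction exactly zero — at the cost of ignoring the vanishing collision
probability of a high-complexity library; if more founders than library
sequences are requested, collisions are allowed, merged and counted.

## Integrator numerics

Populations of 10⁵–10¹⁰ cells are advanced by discrete-time tau-leaping,
default `dt = 0.1` day inside the chemotherapy window (where hazards peak at
~1.15/day) and `dt_growth = 0.25` day elsewhere; sampling days always land
exactly on grid points. Within a step:

* **Removals** (death + kill + transition out) are cause-specific Poisson
  channels with the exact competing-risks means
  `n·(h_c/out)·(1 − e^(−out·dt))`. Wherever the drawn totals would exceed a
  clone's cell count (possible only at small counts) those clones are
  redrawn exactly: a binomial total split by conditional binomials.
* **Births** are Poisson with survivor-adjusted intensity
  `n·(e^(b·dt) − 1)·e^(−out·dt)`. This makes the one-step mean of the
  linear birth–death system exact at any `dt` (a plain
  `Binomial(n, 1 − e^(−b·dt))` draw underestimates 4-day exponential growth
  by ~9%), so simulated means track `N₀·e^((b−d)t)` to Monte-Carlo error.
* Draws with variance above 25 use a rounded, range-clipped normal — exact
  mean and variance, skewness < 0.2 at the threshold. Low-variance,
  low-probability draws use count-clipped Poisson; the remainder exact
  binomial.
* A step raising any total per-cell event probability above 1 raises a
  step-size error rather than silently clipping.

An exact Gillespie stochastic simulation algorithm (`step_gillespie`) is
provided for populations ≤ 10⁴ cells and is used as the cross-validation
oracle for the leap integrator in the test suite.

Gate sorting is multivariate hypergeometric across clones (sampling cells
without replacement). Above numpy's 10⁹-population limit the sequential
conditional draw substitutes a range-clipped binomial per category; at that
scale the sorted sample is < 0.1% of the pool and the finite-population
variance correction is below 10⁻⁴ relative. If a gate holds fewer cells than
requested, all are returned and the sample is flagged truncated.

Each experiment consumes one seed; library seeding, transplant, dynamics and
sorting use independent spawned substreams so identical configurations
reproduce bit-identical trajectories.

## Synthetic raw data

The generators provide the downstream pipeline's inputs with known truth:

* **Reads** — `flank(20 nt) + barcode(30 nt, alternating weak A/T and strong
  C/G) + flank(20 nt)`; per-barcode read counts Poisson in
  `count × depth_per_cell` (or exact, for round-trip tests); uniform
  substitution errors; flat Q30 qualities with dips at error-injected bases.
  Barcode sequences are a deterministic function of (seed, clone id), so the
  generating table is recoverable.
* **Cytometry** — log-normal channel intensities; the mVenus geometric-mean
  ratio between the pure-L and pure-H states equals the reporter's dynamic
  range, default 3.5 (midpoint of the reported 3–4×). The rapamycin-style
  reference sample is drawn broader (σ = 0.5 log-units) than in-vivo
  populations (σ = 0.25), reflecting its independent culture conditions;
  this separation is what lets percentile gates recover mixture fractions
  within ±2%.
* **FRET** — Amcyan (donor) and FRET channels; apoptotic cells carry a
  cleaved probe with FRET/Amcyan geometric mean 0.4 versus 2.0 intact.
* **Images** — bone as a plane or curved sheet in a dedicated channel, cells
  as isotropic Gaussian blobs (σ = 1 voxel; the real point-spread function
  is unspecified), anisotropic voxels (default 2×1×1 µm), per-cell
  intensities drawn conditional on the mVenus/TdTomato ratio respecting the
  0.4 classification rule, and ground-truth distances computed exactly
  against bone voxel centres.

What the generators deliberately do **not** emulate: PCR amplification bias
and chimeras, instrument-specific quality profiles, spectral spillover and
compensation, microscope noise and anisotropic PSFs, spatial clustering of
cells. Passing round-trip tests therefore demonstrates the estimators invert
this generative family, not that they are robust to every artefact of real
instruments.

## Barcode extraction and collapse

A read is accepted when both flanks match at their anchored positions with
at most one mismatch each (no indels — the amplicon is fixed-length), the
barcode has no N, all barcode bases are ≥ Q20, and the weak/strong pattern
holds at every position; rejections are tagged in that order and counted so
accepted + rejected = input reads. Collapse is greedy by descending
abundance (lexicographic tie-break): a barcode within Hamming distance 2 of
an already-accepted, more abundant barcode merges into it (ties to the most
abundant acceptor). Counts are conserved exactly, accepted barcodes end up
mutually > 2 apart, and the operation is idempotent. Candidates are found by
a pigeonhole segment index, keeping the pass near-linear; an O(n²) oracle
checks equivalence in the tests.

## The mechanism decision rule

Per post-treatment day, with H and L count tables:

* **selection** if the shared-barcode fraction (union denominator,
  detection = count ≥ 1 after collapse) is below 0.05, **or** the H-vs-L
  cumulative-curve gap exceeds the 95th percentile of its pooled-resampling
  null *and* |median LOR| > ln 3;
* **induction** if the shared fraction is ≥ 0.2, the curve gap is within the
  null, and the sign test for LOR median 0 is not rejected at α = 0.05;
* **indeterminate** otherwise.

Days are aggregated by majority vote over post-treatment days; ties go to
the day nearest the burden nadir (day 7). All thresholds sit in
`StatsConfig` and were fixed by simulation calibration — the qualitative
argument they quantify does not supply numeric boundaries. The divergence
null uses Poissonized multinomial resampling (50 replicates by default); the
gap statistic is normalised by realised depth, so Poissonization agrees with
exact multinomial resampling to O(depth^−1/2) while running several-fold
faster. Bootstrap confidence intervals for the shared fraction use exact
multinomial resampling at original depth.

Known small-sample behaviour: when post-treatment clones hold only a handful
of sequenced cells each, the pseudocount makes the within-barcode log-odds
lattice too coarse to represent the global H/L imbalance and the sign test
can reject under genuine induction; individual days then read
`indeterminate` (never `selection`, since the shared fraction stays high)
and the majority vote absorbs them. At the default design (hundreds of
cells per clone per gate) the effect is negligible.

The gene-set overlap test is the standard hypergeometric tail
`P(X ≥ k)` with the universe size as an explicit required argument, since
overlap p-values are meaningless without one.

## Reporter quantification conventions

* Percentiles interpolate linearly between order statistics.
* The mTORC1 gate threshold is the lower 10th percentile of the
  rapamycin-treated reference; events strictly above it are mTORC1-low
  ("higher than" is strict, so a boundary event reads mTORC1-high).
* The image ratio rule is inclusive on the low side: mVenus/TdTomato ≥ 0.4
  → mTORC1-low.
* Inhibition rate is a ratio of geometric means (fluorescence is
  log-distributed); an arithmetic option exists.
* Burden–activity association uses Spearman rank correlation (robust to
  intensity scale); both the mVenus-vs-burden and the negated
  activity-vs-burden coefficients are reported, since the probe is inverse.
* The apoptosis cutoff is the 1st percentile of the untreated control's
  FRET/Amcyan ratio — a declared construction, configurable.
* Distances are measured from cell centroids to bone voxel centres
  (anisotropic voxels supported); sub-voxel surface interpolation is out of
  scope. The implementation (k-d tree) is checked against an exhaustive
  voxel scan.
* Cell detection is Gaussian smoothing plus local maxima with
  centre-of-mass refinement — adequate for the non-overlapping synthetic
  blobs it is specified for (recall ≥ 0.95, centroid error ≤ 1 voxel), not
  a general segmentation method.

## Problem sizes in the test and acceptance runs

The acceptance suite runs the mechanism-recovery study at the full default
design (20 induction + 20 selection experiments, ~10⁹ cells at peak burden)
and the log-odds stationarity study at ~2×10⁵ founders × 20 seeds; both
complete in minutes on one core thanks to the vectorised leap integrator.
Unit and property tests use smaller populations (10³–10⁵ cells) where the
property under test is scale-free; the pipeline round-trip test uses a
1,000-founder design so the FASTQ stage stays small.

## Limitations

* Two discrete states stand in for a continuous mTORC1 activity axis; the
  3–4× reporter dynamic range is collapsed into the gate dichotomy.
* Kill hazards are constant within the treatment window — no
  pharmacokinetics, no cell-cycle phase structure (the cycling asymmetry is
  carried by `birth_H > birth_L` and `kill_H`/`kill_L` only).
* Nutrient is a deterministic mean-field function of burden; no spatial
  niche structure inside the simulator (space appears only in the imaging
  module).
* The decision rule is validated against the simulator's own generative
  templates; on real data its thresholds should be re-examined, and the
  `mixed` template exists precisely to probe its resolution.
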