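# Methods

`hybridtox` models categorical acute rat toxicity (LD50) from two descriptor
families: conventional chemical descriptors and "biological descriptors"
derived point-by-point from quantitative high-throughput screening (qHTS)
cell-viability concentration–response curves. This note documents the models
and procedures, the choices made where the design was genuinely open, and
what the synthetic-data generator does and does not emulate.

## Data model

A **concentration–response profile** is one compound's viability curve in one
cell line: 14 responses at strictly increasing micromolar concentrations
(default grid: geometric series, 0.006–92 μM; the assay range is fixed, the
exact spacing of the published screen is not, so a geometric series — the
standard qHTS dilution design — is the default and is configurable).
Responses are stored as percent **loss** of viability: 0 = baseline, 100 =
complete loss. Files that record signed percent change versus vehicle are
negated on read (`negate_responses=True`). The assay panel is the 13
cell lines of the viability screen (BJ, Jurkat, HEK293, HepG2, MRC-5,
SK-N-SH, N2a, NIH3T3, HUV-EC-C, H-4-II-E, SH-SY-5Y, renal proximal tubule,
mesenchymal).

Toxicity classes follow the acute-toxicity guideline cutoffs on the
−log₁₀ LD₅₀ (mol/kg) scale: > 3 "toxic", < 2 "nontoxic", the band between
"marginal". Marginal compounds are excluded from classification modeling.
The cutoff values themselves fall in the marginal band, making the mapping a
partition of the real line.

## Noise filter (THR / MXDV)

For a cytotoxicant the idealized response is non-decreasing with
concentration; the filter repairs departures from that shape instead of
fitting a parametric curve.

1. **Baseline threshold (THR, percent).** Any response with |r| < THR is set
   to 0; surviving negative responses (apparent viability increase) are
   clipped to 0 so that all descriptors live on the 0–100 toxicity scale.
   THR = 0 is the no-threshold setting (only the clip applies).
2. **Monotonicity repair (MXDV, percent).** Scanning from low to high
   concentration, a point is flagged when it falls more than MXDV below the
   running maximum of the preceding *non-flagged* points. The running-max
   criterion (rather than pairwise adjacent comparison) flags a multi-point
   dip as a unit, so repairs cannot leave non-monotone staircases. Each
   maximal flagged run is replaced by linear interpolation between its
   nearest non-flagged neighbors; a flagged run at the high-concentration end
   is replaced by the last non-flagged value (constant extension). The exact
   replacement arithmetic was an open design point; linear interpolation is
   the simplest rule consistent with "computed from the adjacent points".

Order is fixed (THR first): thresholding prevents baseline jitter from
seeding a false running maximum. The composite filter is idempotent, keeps
`r[i+1] ≥ r[i] − MXDV` everywhere, never produces values below 0 or above the
input maximum, and is the identity on clean non-decreasing curves whose
nonzero values are ≥ THR. The standard sweep is THR ∈ {0, 5, 15, 25} with
MXDV = 5; THR = 15 / MXDV = 5 is the reference setting.

A known property of this rule family: an isolated *upward* spike on an
otherwise flat curve is treated as signal (it raises the running maximum),
so the points after it are flagged and pulled up toward it — a single
spurious high point can lift the whole filtered tail. See "Limitations".

## Descriptors

* **Biological:** one column per (cell line, concentration) — 13 × 14 = 182
  columns per THR/MXDV setting, named `<line>@<concentration>`; the value is
  the filtered response. Compounds missing a cell line get zeros in those
  columns and are flagged rather than dropped. Before modeling, biological
  values are divided by 100 so all descriptors share the [0, 1] range that
  Euclidean kNN distances assume.
* **Chemical:** supplied externally (any engine producing a compound ×
  named-descriptor table). Curation removes columns that are constant or
  constant for all but one compound, then walks all pairs with squared
  Pearson correlation > 0.95 in descending r² order, removing one member of
  each still-intact pair by a seeded coin flip (this makes the reduction
  reproducible); survivors are range scaled to [0, 1]. The fitted per-column
  min/max transform external compounds, clipped to [0, 1] — external
  compounds never influence the scaling. The r² filter is applied to the
  chemical block only, not to the hybrid matrix.
* **Hybrid:** column-wise concatenation of the two scaled blocks.
* **Curve fingerprints** (two bits per concentration, bins [0,25), [25,50),
  [50,75), ≥75 percent of the full 0–100 scale, low concentration first;
  integer value read most-significant-bit first) summarize curve shape for
  reporting only — they are never model inputs. The bins are fractions of
  the full response scale rather than the per-curve maximum, so weak and
  strong toxicants encode differently; bin edges are closed on the left to
  make the mapping total.

## Dataset assembly and splitting

* **External validation** is n-fold (default 5): a seeded random partition
  into nearly equal subsets; fold *i*'s subset is the external test set, the
  rest the modeling pool. External compounds never enter balancing,
  descriptor-curation fits, or training; the chemical curation is re-fit
  inside every fold.
* **Balancing** removes the nontoxic compounds most structurally dissimilar
  from any toxic compound: for each nontoxic compound, the Euclidean distance
  (scaled *chemical* descriptors only — "structurally dissimilar" refers to
  structure, and this keeps balancing identical across descriptor
  configurations) to its nearest toxic compound is computed, and the farthest
  are removed until the classes reach the 1:1 target. Toxic compounds are
  never removed; ties break by compound id, so the procedure is
  deterministic.
* **Sphere exclusion** subdivides each balanced pool into (default 20)
  training/test pairs. The probe radii are evenly spaced quantiles of the
  pool's nearest-neighbor-distance distribution, which adapts the schedule to
  any dataset density. At a given radius: repeatedly pick the unassigned
  compound farthest from all selected centers (first pick: greatest mean
  distance to all compounds; ties by id), put it in training, and assign its
  unassigned neighbors within the radius alternately to test and train,
  nearest first. Every test compound therefore has a training compound
  within the radius — the interpolation regime kNN assumes. A radius whose
  split leaves the test fraction outside [10%, 40%] is adjusted
  geometrically and logged; if a class is missing from training, the nearest
  test compound of that class is moved over (logged).

## Models

* **kNN ensemble.** For each internal split and each k (default 1–5), a
  simulated-annealing search over descriptor subsets (sizes 5–40 by default)
  maximizes leave-one-out training CCR: single-descriptor add / remove /
  swap proposals, Metropolis acceptance, geometric cooling ×0.9, stop below
  1% acceptance. The initial temperature is calibrated from the magnitude
  of early worsening moves so that roughly half of them would be accepted.
  Models whose CCR on the internal *test* split reaches `accept_ccr`
  (default 0.70) are retained. Retention CCR is computed without
  applicability-domain gating so that retention is independent of the AD
  multiplier. Neighbor votes: simple majority for odd k;
  inverse-distance-weighted for even k, exact ties resolved toward nontoxic
  (deterministic and conservative).
* **Applicability domain.** Each model's cutoff is `D = d̄ + Z·s`, where d̄
  and s are the mean and standard deviation over training compounds of their
  mean distance to their k nearest other training compounds, in the model's
  own descriptor subspace (the same statistic computed at prediction time).
  Z defaults to 0.5 and is configurable. A query whose mean k-nearest
  training distance exceeds D is outside the domain and receives no vote
  from that model.
* **Consensus.** The score is the mean binary vote (nontoxic = 0, toxic = 1)
  over covering models; no covering model → "not covered". Dual thresholds
  T1 ≤ T2 classify: ≤ T1 nontoxic, ≥ T2 toxic, between inconclusive. At
  T1 = T2 (single-threshold classification) the comparisons become strict
  and a score exactly at the threshold is inconclusive.
* **Random forest** (scikit-learn) is the off-the-shelf companion learner
  behind the same [0, 1] scoring scale; kNN and forest results are reported
  separately by default.

**Evaluation.** CCR = 0.5 × (sensitivity + specificity), computed over
covered, conclusive compounds; coverage is the conclusive fraction of all
evaluated compounds. Threshold heat maps tabulate CCR and coverage over the
full (T1, T2) lattice; the diagonal reproduces single-threshold
classification, and widening the inconclusive zone can only lower coverage.

**y-Randomization.** Per repeat, modeling-pool labels are shuffled
(count-preserving, externals untouched) and the entire pipeline is retrained;
the repeat's CCR is the mean over external folds. A one-sample, one-tailed
t-test compares the randomized CCRs with the real mean CCR; p < 0.05 means
the randomized models are significantly worse ("pass"), otherwise the real
models are flagged "discard". The test is per configuration, pooling fold
means; with zero variance among randomized CCRs the comparison is exact
(all equal → p = 0.5, all below → 0, all above → 1, logged).

**Descriptor frequencies.** The fraction of retained models containing each
descriptor; descriptors above the mean frequency are flagged, and biological
frequencies pivot to a cell line × concentration grid. The counting identity
`mean frequency × descriptor count = mean subset size` holds by construction.

## Synthetic data generator

The generator emulates the pipeline's three inputs with controllable signal:

* Latent chemical toxicity `u ~ N(0,1)` loads (0.6–0.9) on 10 of 100
  chemical descriptors; the rest are correlated nuisance from a 5-factor
  model.
* Latent in vitro potency `v ~ U(0,1)` places each compound's per-line
  log₁₀ AC50 log-uniformly over the assay span *extended 2.5 decades beyond
  the top concentration*, with per-line jitter (sd 0.5 log units). The
  extension leaves roughly 40% of compounds without a half-maximal response
  inside the tested range — mirroring a real viability screen, where most
  library compounds are inactive and in vitro responses alone are weak
  classifiers of in vivo toxicity.
* Responses follow a Hill curve (slope 1–3, Emax 60–100%) plus Gaussian
  baseline noise (sd 10%) and isolated ±60% spike artifacts (probability
  0.15 per point) — the single-point excursions the filter is designed to
  repair.
* Potency is `−log₁₀ LD₅₀ = 2.18 + 0.50·u + 0.30·v_std + N(0, 0.3)`, so the
  guideline cutoffs (2, 3) apply verbatim and the toxic / marginal /
  nontoxic mix (~11 / 50 / 39%) approximates the real qHTS–LD50
  collection's ~13 / 47 / 40%. The chemical weight exceeds the biological
  weight, matching the observation that chemical-only models are strong and
  hybrid descriptors add a modest increment.

What the generator does **not** emulate: real assay noise spectra
(plate/edge effects, correlated drift), real chemical-descriptor marginals,
mechanistic outliers (metabolic activation, volatility), and inter-line
biology beyond a shared potency latent with jitter. Passing tests on this
generator therefore demonstrate the pipeline's correctness and the
qualitative value of in vitro descriptors under these assumptions — not
quantitative performance on any real collection.

## Problem sizes used in tests and the acceptance script

The shipped experiments are desk scale, chosen so a full run completes in
minutes on one CPU: synthetic studies of 120–1,800 compounds, 3–5 external
folds, 5–8 internal sphere-exclusion splits, k ∈ {1..3}, subset sizes 5–15,
30 annealing proposals per temperature and at most 10 temperature levels.
All sizes are configuration parameters; the defaults recorded in
`KnnConfig` (k 1–5, subsets 5–40, 100 proposals, 30 levels) reflect standard
variable-selection kNN practice for full-size studies.

## Numerical choices and degenerate inputs

* Distances are plain Euclidean on [0, 1]-scaled matrices (scipy
  `pdist`/`cdist`); inverse-distance weights add 1e-12 to avoid division by
  zero at duplicate points.
* The AD cutoff is clamped to a small positive floor so duplicate-heavy
  training sets still yield a valid domain.
* Sphere-exclusion radii are clamped to a positive floor when the
  nearest-neighbor distribution contains zeros (duplicate compounds).
* Correlations undefined after the variance filter (numerically constant
  columns) are treated as violations and removed.
* All stochastic components (fold assignment, annealing, redundancy-filter
  coin flips, label permutation, the generator) draw from seeded NumPy
  generators; a run is bit-reproducible from its configuration.

## Known limitations

* The monotonicity repair trusts high responses: a spurious isolated high
  point lifts the filtered tail of an otherwise flat curve (see above).
  Under symmetric spike noise this can offset the filter's benefit for
  Euclidean-distance models — consensus kNN is itself quite robust to
  isolated descriptor noise — so the filtered-vs-unfiltered accuracy margin
  on synthetic data is small and can be seed-dependent, even though the
  filtered hybrid reliably beats chemical-only models.
* Balancing assumes the nontoxic class is the majority; pools with a toxic
  majority are returned unchanged apart from the ratio cap.
* The annealer is a stochastic search: it makes no optimality guarantee for
  subset selection beyond the exhaustive case of very small descriptor
  spaces.
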