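# Methods

## The model

`dpsir-eri` builds a composite environmental risk index (ERI) on a DPSIR
indicator hierarchy — five causal indices (Driving forces, Pressure, State,
Impacts, Response; codes A1–A5) whose sub-indicators form small trees of up
to four further layers (B, C, D, E). The chain is:

1. **Expert elicitation.** Each expert scores each hierarchy element on the
   1–9 Saaty importance scale; scores are averaged per element over
   whoever answered (arithmetic mean; no group-consensus model beyond
   that).
2. **Pairwise comparison and weights (AHP).** For a sibling group with
   mean scores *s*, the comparison matrix is the ratio matrix
   C<sub>ij</sub> = s<sub>i</sub>/s<sub>j</sub>. Weights come from the
   row-geometric-mean method: row products M<sub>i</sub> = ∏<sub>j</sub>
   C<sub>ij</sub>, then V<sub>i</sub> = M<sub>i</sub><sup>1/n</sup> /
   Σ<sub>j</sub> M<sub>j</sub><sup>1/n</sup>. For ratio-constructed
   matrices this reduces exactly to score normalization
   s<sub>i</sub>/Σs<sub>j</sub>; the matrix path is kept because the same
   machinery must accept directly elicited (generally inconsistent)
   judgment matrices.
3. **Consistency control.** CI = (λ<sub>max</sub> − n)/(n − 1),
   CR = CI/RI, with judgments accepted iff CR ≤ 0.1 (inclusive at the
   boundary). An overall ratio Σa<sub>i</sub>CI<sub>i</sub> /
   Σa<sub>i</sub>RI<sub>i</sub> combines sub-matrices across a level.
   The pipeline refuses to use any weight derived from a rejected matrix.
4. **Standardization.** Each raw yearly series is min-max rescaled to
   [0, 1]; negative-polarity indicators (growth reduces risk — the
   response side) are reversed, Z = 1 − (x − x<sub>min</sub>)/(x<sub>max</sub>
   − x<sub>min</sub>).
5. **Aggregation.** Child scores combine as weighted sums
   S = Σ<sub>j</sub> X<sub>j</sub>W<sub>j</sub> recursively up the tree;
   the composite is ERI = Σ<sub>i=1..5</sub> S<sub>i</sub>W<sub>i</sub>.
   Convexity of every weight vector keeps all scores in [0, 1].
6. **Classification.** Five bands: I [0, 0.2), II [0.2, 0.4), III
   [0.4, 0.6), IV [0.6, 0.8), V [0.8, 1.0]. Bands are half-open with the
   top band closed; 0.8 is the critical point above which the state is
   considered extreme.

## Numerical choices

- **λ<sub>max</sub>** is the true principal eigenvalue, computed by power
  iteration started from the geometric-mean weight vector (Perron–Frobenius
  guarantees a simple dominant eigenvalue with positive eigenvector for
  positive matrices; convergence tolerance 1e-12, cap 500 iterations). The
  classic textbook estimate mean<sub>i</sub>[(Aw)<sub>i</sub>/w<sub>i</sub>]
  is exposed as `lambda_max_saaty` for reference: it coincides with the
  eigenvalue on consistent matrices and for n = 3, but drifts on larger
  inconsistent matrices, which would blur the CR gate. The test suite
  checks the power iteration against `numpy.linalg.eigvals` to 1e-6.
- **Random-index table.** The default RI constants (0, 0, 0.52, 0.89,
  1.11, 1.24, 1.35, 1.40, 1.45, … up to n = 15) are the large-sample
  estimates of the mean CI of uniform random Saaty-scale reciprocal
  matrices; the test suite reproduces the n = 3 and n = 5 entries with a
  10⁵-draw Monte-Carlo simulation to ±0.02. The older 1980 table (0.58 at
  n = 3, 0.90 at n = 4, 1.12 at n = 5) is materially off that simulated
  mean at n = 3 — small original sample — but remains available via
  `random_index(n, table="saaty1980")` for comparability with studies that
  used it. The choice barely matters for ratio-built matrices (CR = 0
  either way).
- **n ≤ 2 matrices** are consistent by construction: CI = CR = 0 by
  convention, and CR with RI = 0 but CI > 0 raises rather than returning
  infinity.
- **Ratio entries beyond [1/9, 9]** (possible when mean scores differ by
  more than the scale span) produce a warning; clipping is available but
  off by default because it destroys exact consistency.
- **Constant series** (x<sub>max</sub> = x<sub>min</sub>) standardize to a
  neutral 0.5 — configurable — with a logged warning; min-max rescaling is
  undefined there and the midpoint is the least-informative choice. The
  neutral value is applied as-is, without polarity reflection.
- **Standardization bounds** default to the analyzed window's own min/max,
  which is what makes a single-window assessment self-contained; fixed
  per-factor bounds can be supplied so that runs over different windows are
  comparable and monotonicity statements ("raising this raw value raises
  the composite") are well-defined. Values outside fixed bounds are an
  error, not silently clipped.
- **Ties and edges.** Band edges classify into the upper band (0.4 → III);
  values in [0, 0.1), below the published table's floor, fold into band I
  with a log note so classification is total on [0, 1].
- **Rounding.** CSV reports are written at 4 decimals (the precision of the
  published weight tables); full-precision values go to sidecar JSON.

## Weights where the data are silent

Questionnaire data cover the A and B layers. Below B, sibling weights
default to equal shares, overridable with user score vectors per parent.
For the five indices themselves two modes exist:

- `derived` (default): AHP weights from the A-layer mean scores
  (3.0, 8.5, 7.5, 5.0, 5.5 → 0.1017, 0.2881, 0.2542, 0.1695, 0.1864).
- `paper-table`: the published per-index weight column (0.157, 0.447,
  0.354, 0.285, 0.314). That column sums to 1.557 — it is not a normalized
  weight vector and is not reproducible from the printed scores by any
  normalization — so it is renormalized by its sum before use. It is kept
  only as a documented compatibility mode.

A related source discrepancy: the study's displayed A-layer matrix uses
7.7 for the State index where its score table prints 7.5; the package
follows the score table, and the 7.7 variant is reachable by passing that
score explicitly. Similarly the published B-layer table prints 0.2332
where the ratio path gives 3.5/15 = 0.2333; treated as source rounding.

## The synthetic generator

Real multi-year indicator panels for this kind of assessment are rarely
published; the generator emulates the study conditions so the whole
pipeline is testable end to end:

- **Expert panel:** 38 questionnaires with a 92% return rate → 35
  respondents (non-respondents dropped uniformly at random). Each
  respondent reports the latent consensus score plus Gaussian noise rounded
  to whole scale points (sd 1.0 point by default), clamped to [1, 9]. The
  latent A- and B-layer consensus defaults are the published mean scores,
  so the default run reproduces the published weight layer. No elicitation
  error model was published; integer-rounded Gaussian is a convention.
- **Indicator panel:** one unitless series per hierarchy leaf over
  2006–2017, linear trend plus Gaussian noise. Leaves under A1–A4 rise
  (+0.05/yr) and response-side leaves fall (−0.05/yr), mirroring the
  reported qualitative trends; base levels are drawn once per leaf from
  U(0.2, 0.6). Default noise sd 0.05 is about 10% of the 12-year trend
  range (0.55). Units are irrelevant because standardization removes scale.
- **Ground truth** (latent scores, per-leaf slopes and polarities, expected
  per-index score-trend signs) is emitted alongside every dataset for
  recovery tests. Note the sign convention: a falling raw series under
  negative polarity yields a *rising* standardized risk contribution, so
  under the defaults all five index score series trend upward, as does the
  composite.
- Everything is seeded (`numpy` `SeedSequence` spawning, one stream for the
  expert panel and one for the indicator panel); equal seed and config give
  byte-identical datasets.

What passing tests on synthetic data do **not** show: that the package
reproduces any real city's published yearly trajectory. The raw 2006–2017
series behind the original assessment are not public, so the yearly
composite values (0.3489 … 0.5606) cannot be recomputed from data; what is
recomputable — the weight tables, the per-year drift arithmetic, the
classification of reported composites — is pinned in the test suite at the
published precision. Clamping at the scale edges also biases recovered
means slightly toward the centre for latent scores near 9; recovery tests
use mid-range latents.

Problem sizes in the shipped tests: the full default hierarchy (100 nodes,
70 leaf series × 12 years), 200 seeded replicates for trend-sign recovery,
10⁵ Monte-Carlo draws per matrix size for the RI oracle.

## Known limitations

- No forecasting: the pipeline describes the assessed window only.
- No fuzzy-AHP, incomplete-matrix completion, or consensus models beyond
  the arithmetic mean.
- Window-relative standardization makes scores comparable only within a
  run unless fixed bounds are supplied; the composite necessarily touches
  the extremes of [0, 1] somewhere in the window when every leaf attains
  its own min and max there.
- One known source inconsistency is left unresolved by design: the study
  numbers the response-side indicators B15–B18 in its hierarchy table but
  B18–B21 elsewhere; the package follows the hierarchy table.
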