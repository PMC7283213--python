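# Methods

## The feedback model

The package treats a fast ecological variable — monthly regional fire carbon
emission F(t) (kg C m⁻² month⁻¹) or burned-area fraction — as the sum of an
instantaneous linear response to slowly evolving environmental forcings and
internal noise:

    F(t) = R O(t) + N(t)

O(t) is a time × forcing matrix; in the canonical layout it holds 18
standardized columns: the leading two EOF principal components of sea-surface
temperature anomalies from eight ocean basins (tropical Pacific, tropical
Atlantic, tropical Indian, North Pacific, North Atlantic, South Pacific,
South Atlantic, South Indian), plus area-averaged leaf area index (LAI, fuel
supply) and 0–10 cm soil moisture (SM, burning conditions). R is the response
vector in fire units per one standard deviation of forcing
(kg C m⁻² month⁻¹ σ_forcing⁻¹).

Identification rests on a separation of memory scales. The forcings are red
(months of persistence); the fire noise is short-lived. Multiplying by
Oᵀ(t − τ) and taking covariances,

    C_FO(τ) = R C_OO(τ) + C_NO(τ),

and because slow ocean/land anomalies cannot be driven by subsequent fire
noise, C_NO(τ) ≈ 0 for τ exceeding the fire persistence time, so

    R = C_FO(τ) C_OO(τ)⁻¹.

The lag is τ = 1 month by default. All series are deseasonalized (per
calendar-month climatology removed) and linearly detrended before
estimation; for seasonal analyses, samples from the three months of each
overlapping 3-month season (index 1 = JFM … 12 = DJF) are pooled, giving up
to 3 × n_years pairs per season, with the lagged forcing allowed to come
from the month preceding the season. Boundary pairs without a lagged month
and pairs with missing components are dropped and counted.

### Selection and significance

Inverting C_OO with 18 simultaneously considered forcings on 60 pooled
samples is sampling-error dominated, so the estimator is stepwise: starting
from the full matrix, the single forcing whose removal most decreases the
Akaike information criterion is dropped, until no removal decreases it. The
AIC uses the Gaussian concentrated form

    AIC = n ln(RSS/n) + 2(k + 1),   RSS = Σ (F(t) − R_S O_S(t − 0))²

evaluated with the lagged-covariance estimator on the candidate subset S
(the +1 counts the noise variance; residuals use the contemporaneous
forcing, matching the model equation). Exact AIC ties are broken by dropping
the forcing with the smaller |R̂|/SE, with a plug-in sandwich standard
error; ties are measure-zero in practice.

Significance of each retained response is assessed with a Monte Carlo
permutation bootstrap: the pooled fire sample vector is randomly permuted
(forcing samples fixed) and R re-estimated, 1000 iterations by default;
the two-sided p-value is (1 + #{|R*| ≥ |R̂|})/(n_iter + 1), tested at the
90% confidence level (p < 0.1). Whole-vector permutation is the default
because pooled seasonal fire samples are nearly exchangeable under the null
(the fire variable's persistence is below τ); a block-permutation option
(consecutive blocks shuffled, within-block order kept) is available for
fire series with residual autocorrelation. The permutation null preserves
the fire marginal
distribution exactly, and p-values inherit exact finite-sample calibration
(verified empirically at α = 0.1 in the test suite).

Summaries mirror common reporting products: the per-season response cycle
(response absent where insignificant), the season of maximum |R| per forcing
among significant seasons, robustness counts of significant responses across
input-dataset combinations, and per-grid-cell response maps with
insignificant cells masked (full-matrix estimation per cell; no per-cell
stepwise).

### Numerical choices

- Covariances use the n − 1 denominator with sample means removed.
- C_OO(τ) is solved directly unless its condition number exceeds 1e8, in
  which case a pseudo-inverse is used with a warning; stepwise reduction is
  the primary guard against ill-conditioning.
- EOFs use an SVD of the √cos(latitude)-weighted anomaly data matrix, so
  explained variance fractions are area-true; cells missing at any time are
  excluded entirely. Mode signs are fixed by requiring a non-negative
  area-weighted spatial mean of the pattern (signs are otherwise arbitrary;
  flipping a mode and its PC together never changes reconstructions or
  |R|). PCs are standardized to unit sample variance, with σ_forcing
  recorded for unit back-conversion. EOFs are computed once per basin over
  the full record, not per season.
- Preprocessing order is climatology first, then linear detrend, applied per
  grid cell for fields; longitudes are handled internally in [0, 360) so
  dateline-spanning basins (tropical/North/South Pacific) are contiguous.
- Anomaly and detrend operators are idempotent; pooling counts are exactly
  accounted (3 × n_years minus enumerated boundary/missing losses).

## The prediction system

Seasonal predictability is quantified with five learner families behind one
contract — random forest, RBF support-vector regressor, a small feed-forward
network (one hidden layer of 16 units, lbfgs), L1-penalized linear
regression (lasso), and gradient-boosted trees. A predictor table for lead
L holds every environmental predictor at lags L…L+2 months (no column may
use information later than t − L) and annual socioeconomic predictors at
the value reported for the antecedent year, constant within each calendar
year. Predictors are standardized using training-set statistics only.

Each ensemble member randomly splits the record — 5 whole held-out years
(the 15-yr/5-yr split; 60 all-season or 15 season-specific test rows on a
20-year record) or, as a robustness variant, 25% of months irrespective of
year — fits every learner with hyperparameters chosen by minimum-RMSE
10-fold cross-validation on the training rows, and scores the squared
Pearson correlation between observed and predicted test values (undefined
scores from constant predictions are recorded as 0 and logged; note that
squared correlation scores anti-correlated predictions as 1 — documented
semantics of the metric). Predictability is the ensemble-mean R² of the
best learner, where "best" is chosen on the ensemble mean, never per member,
to avoid selection optimism; its 10th/90th percentile range quantifies
split-to-split spread. The default ensemble has 100 members.

The CV grids are fixed and deliberately small (lasso α ∈ {0.01, 0.05, 0.2};
SVR C ∈ {1, 10}; RF min_samples_leaf ∈ {2, 8} with 40 trees; GBM depth ∈
{2, 3} with 60 trees and learning rate 0.08; MLP α = 0.1, a single point).
With ≤ 240-row monthly tables, larger forests or grids change scores by
less than the split-to-split spread while multiplying cost across the
member × learner × fold protocol; reproducibility is preferred over
exhaustiveness, and the grids are part of the documented configuration.
Permutation importance (mean test-R² drop when one predictor column is
shuffled) is computed for the best learner; collinear predictors split
their importance, so grouped predictors should be read jointly.

## The synthetic generator

The generator produces the statistical world the estimator assumes, with
known truth: per-forcing AR(1) series with lag-1 autocorrelation 0.6–0.9
(defaults spread over the 18 forcings) and prescribed instantaneous
cross-correlations decaying as 0.5^distance — within a basin the two PC
truth series are kept uncorrelated, as EOF PCs are orthogonal by
construction. Correlation is induced by a Cholesky factor applied to the
AR(1) innovations with the memory-adjusted innovation covariance
S_ij = corr_ij (1 − a_i a_j), which yields the target stationary
correlations exactly while preserving each forcing's marginal memory.
Basin SST fields carry two prescribed orthonormal spatial modes with
variance shares 60%/25% plus spatially white noise, a seasonal cycle, and a
linear trend, so EOF recovery can be checked against known shares. The fire
series applies a known response vector to the standardized forcings —
defaults put +1.0 on the tropical Pacific leading mode, +0.5 on the
tropical Atlantic leading mode, and −0.7 on soil moisture, magnitudes in
the 0.5–1 range — plus i.i.d. Gaussian noise of unit standard deviation
(the white-noise choice is the minimal one consistent with C_NO = 0; the
estimator only requires noise memory ≪ τ), a dry-season burning climatology
and a gentle negative trend. An optional generative lag shifts the response
for robustness experiments (default 0, instantaneous). Default record
length is 20 years (240 months), matching a typical satellite fire-record
analysis period. Atmospheric predictor series have configurable
contemporaneous correlation with fire (default 0.3) and short memory;
socioeconomic series are annual random walks at antecedent-year cadence.

What the generator does not emulate: real-world SST teleconnection
geography, satellite retrieval error, non-Gaussian fire size distributions,
zero-inflation of burned area, or human ignition dynamics. Passing tests
therefore demonstrate that the estimators recover truth under their stated
assumptions — not that those assumptions hold for any particular
observational dataset.

## Validation problem sizes

The validation suite and the acceptance script size their simulations as
follows, chosen so each check's sampling error is small relative to the
property being asserted: support recovery over 100 generator replicates at
240 months; bootstrap calibration over 200 null simulations with 500
permutations each; consistency over records of 120–2400 months;
predictability ceilings averaged over 4 generator replicates × 8 ensemble
members (one 240-month realization of high-memory forcings has a realized
signal fraction several points away from the population value, so replicate
averaging estimates the expected predictability); predictor-set ordering
over 3 replicates; lead decay over 2 replicates per lead.

## Known limitations

- The estimator is linear and instantaneous; lagged or nonlinear true
  responses bias R toward the best linear instantaneous approximation.
- With strongly correlated forcings and short records, stepwise selection
  can retain a correlated proxy instead of the true driver; robustness
  counts across dataset combinations are the intended mitigation.
- Squared-correlation predictability ignores bias and amplitude errors in
  predictions.
- Regional masks are user-supplied boxes or boolean grids; no regridding is
  performed, so all gridded inputs of one variable must share a grid.
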