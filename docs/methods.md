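# Methods

## Model

Unisensory response times are modelled as inverse Gaussian (Wald),
`RT ~ IG(μ, λ)` with mean `μ`, shape `λ`, variance `μ³/λ` — the
first-passage-time law of a drift-to-bound accumulator and the standard
positively skewed RT distribution. All times are milliseconds,
probabilities live in [0, 1].

The relay model splits each channel into sequential latent stages with an
RT-share partition: weights `w_i ≥ 0`, `Σ w_i = 1`, stage `i` distributed
`IG(μ w_i, λ w_i²)`. This is the unique scaling under which the stages sum
back to the parent IG (the family is closed under addition exactly when the
ratio `λ/μ²` is shared), so the partition is lossless: `recombine(partition(p, w)) = p`.
It implies stage SD `√w_i · SD_total`; note that published stage SDs
accompanying fitted shares elsewhere correspond to `w · SD_total` instead,
so we treat stage *means* (`w_i μ`) as the partition's interpretable summary
and do not report stage SDs.

In the multisensory condition each stage is a race,
`F_i(t) = 1 − S_Ai(t) S_Vi(t)`, and the stage winner initiates the next
stage in both modalities. Stages are assumed mutually independent, so the
total CDF is the convolution of the stage-1 race CDF with the later stage
race distributions. A zero-weight stage is an explicit zero-duration marker
(`None` from `partition`): with `w₁ = 0` or `w₁ = 1` the relay collapses to
the classical race model, and predictions are symmetric in `w₁` about 0.5
(the two stage sizes swap roles), which is why fitting bounds the share to
[0, 0.5].

### Asynchronous onsets

With onset lag `τ` (sign convention: positive SOA = auditory lags visual
onset), the lagging channel's stage-1 clock starts at its own onset,
`T_AV1 = min(T_L1, T_G1 + τ)`, and if stage 2 is initiated before that
onset the lagging channel enters stage 2 with the residual lag
`max(0, τ − T_AV1)`. The analytic CDF is the sum of an early-initiation
integral (stage 1 completed by the leading channel alone, lagging stage-2
survival evaluated on its own clock `t − τ`) and a late-initiation integral
(lagged stage-1 race density times the plain stage-2 race). At `τ = 0` this
reduces to the synchronous relay; for `τ` beyond the leading channel's
total RT it converges to the leading unisensory distribution, so the model
transitions between multisensory and unisensory regimes with no extra
parameters. The generative sampler applies the same lag logic trial by
trial and is the master oracle: every analytic curve is validated against
200 000 simulated trials (sup-distance < 0.01) in the test suite.

## Effect-size measures

Effect sizes are horizontal (time-axis) quantile differences in ms:

- **RSE (geometric)**: mean over probability levels of
  `Q_ref(p) − Q_AV(p)`, where the faster-signal reference is the pointwise
  max of the unisensory CDFs (equivalently the min of their quantiles).
- **RMI violation (geometric)**: mean positive part of
  `Q_bound(p) − Q_AV(p)` with bound CDF `min(1, F_A + F_V)`; zero for any
  prediction respecting the bound, strictly positive where the bound is
  beaten.

Whole-distribution measures use 200 evenly spaced levels `(i−0.5)/200`;
measures "at the ten quantiles" use `(i−0.5)/10`, the levels of
block-Vincentised ten-trial data (the exact levels of the benchmark group
distribution are not published; these midpoints are the natural choice).
The mean-RT RSE compares SOA-adjusted unisensory means (the lag is added to
the lagging channel) with the multisensory mean; model curves are
discretised at 200 evenly spaced inverse-CDF values. Vincent averaging
rank-orders equal-length blocks and averages rank-for-rank.

## Numerics

- Time grid: uniform 0.25 ms from 0 to `μ_slowest + 8·SD_slowest`; this
  resolves the fast tail where RMI violations live. Asynchronous and
  fitting grids are padded by `|τ| + 2·SD_max` because under large lags the
  relay CDF tends to the leading unisensory CDF, which needs ~10 SD to pass
  the coverage check (a curve must reach CDF ≥ 0.999 on its grid or a
  coverage error is raised).
- Convolutions are Lebesgue–Stieltjes on the uniform grid: trapezoid in the
  integrand, exact CDF cell masses as the measure. With small RT shares the
  stage-1 IG is sub-millisecond-scale and any sampled-density quadrature
  loses mass; CDF-increment masses are exact at every resolution. The
  split at `u = τ` uses half-open cells with linear apportioning of the
  straddling cell, so no mass is double-counted.
- IG quantiles invert the CDF by bracketed Brent root-finding (relative
  tolerance 1e-8), robust at extreme levels; tabulated curves invert by
  linear interpolation. Sampling uses the Michael–Schucany–Haas transform
  with an explicit `numpy` Generator passed by value — no global state.
- Iterative share/shift searches run on a 1.0 ms grid (prediction-grade
  output uses 0.25 ms); fitted shares agree with 0.25 ms fits to the
  optimiser tolerance (1e-4).

## Fitting protocols

Unisensory IG parameters can be fitted three ways, matching the data each
benchmark design provides: CDF-RMSE against quantile summaries
(`μ ∈ [50, 2000]`, `λ ∈ [100, 1e6]`, L-BFGS-B with five multi-starts);
method of moments (`μ = mean`, `λ = mean³/sd²`, with `sd = se·√n` for
published standard errors); and QMPE for raw samples — five sample
quantiles (levels {0.1, 0.3, 0.5, 0.7, 0.9}; configurable) define six bins
and the fit minimises the multinomial negative log-likelihood of the bin
counts (model bin probabilities floored at 1e-12).

Multisensory fitting always holds the unisensory parameters fixed and
adjusts one parameter by bounded scalar minimisation (tolerance 1e-4):

- `cdf_rmse` — RMSE between empirical quantile probabilities and the relay
  CDF (synchronous designs);
- `qmpe_nll_joint` — joint NLL summed over any number of SOA conditions,
  one shared share;
- `rse_rmse` — RMSE between empirical and model mean-RT RSEs across SOAs;
- shifted race `δ` — CDF-RMSE, upper bound 500 ms, lower bound set per
  condition so shifted times stay strictly positive (clips at the bound are
  flagged).

A single RT share is used for both modalities (per-modality shares are a
straightforward extension but are not exposed). Inference uses sign-flip
permutation for one-sample tests and permutation of one vector for Pearson
correlations, both two-sided with add-one smoothing so p is never zero.

## Synthetic studies

`preset(name)` reproduces the structure of four benchmark designs —
`miller1982` (74 participants × 2 blocks × 10 trials, A/V/AV),
`miller1986_soa` (1 participant × 40 blocks × 10 trials, 11 SOAs in 33 ms
steps), `otto_soa` (10 × 4 × 40, SOAs ±60/±30/0) and `otto_intensity`
(20 × 2 × 50, five unisensory intensity levels crossed 3×2) — with the
published unisensory IG parameters and best-fitting shares as generating
values. Participant heterogeneity is independent multiplicative lognormal
jitter on `μ` and `λ` (default sd 10%, chosen so simulated between-subject
scatter is the order of the published cross-participant SEMs). Catch
trials, misses, outliers and trial-history effects are **not** simulated:
the modelling framework assumes ceiling performance on clean data, so
passing tests speak to the estimators and predictions under those
assumptions, not to robustness against real-data contamination.

`recovery_experiment` regenerates a study at a known share and refits it
end to end (pooled QMPE unisensory fits, then the joint-NLL share fit).
Recovery is estimator validation, so it should be run on data generated
under the estimator's assumptions — in particular with homogeneous
participants when fitting pooled data; with heterogeneous participants the
pooled single-IG assumption is violated and the recovered share is
attenuated at larger shares. Per-participant fitting avoids that mismatch
but at 160 trials per condition the share is too weakly identified for a
single participant's likelihood to constrain it.

## Known limitations

- **Identifiability near 0.5.** Predictions are symmetric in the share
  about 0.5, so their derivative with respect to the share vanishes there;
  near the upper bound the likelihood is nearly flat and estimates scatter
  widely at realistic trial counts. Recovery at shares ≲ 0.25 is accurate
  to ±0.03 at 1600 trials/condition; at 0.45 it is not.
- The IG underestimates the extreme fast tail of some empirical RT
  distributions — exactly where RMI violations concentrate — so
  ten-quantile violation measures computed from IG fits run slightly below
  values obtained from empirical quantiles.
- Two-stage lag logic only: asynchronous predictions are implemented for
  two-stage relays (the N-stage synchronous model has no SOA variant).
- Trimodal designs, focused-attention variants, per-modality shares and
  trial-history mechanisms are out of scope.
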