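# zerolag

Zero-phase-delay functional connectivity analysis for EEG/MEG source-space
data, with a fully synthetic cohort generator so every stage can be
exercised and validated end to end.

## The problem

Neural populations synchronise either with a phase delay (one region's
oscillation follows the other's) or at zero phase delay (simultaneously,
e.g. between homotopic regions coupled through the corpus callosum).
Signal leakage and volume conduction also produce *artefactual*
connectivity at exactly zero lag, so contemporary pipelines often use
zero-phase-**exclusive** estimators — the imaginary part of coherency
(ImgCoh), the weighted phase lag index (wPLI), orthogonalised amplitude
envelope correlation (orthAEC) — that suppress all zero-lag
interdependence.  The cost is that genuine zero-phase synchrony is
suppressed too.  This package quantifies that trade-off: it classifies
near-zero-phase-delay connectivity, locates the inter-region distance
beyond which leakage is negligible, and compares matched
inclusive/exclusive estimator pairs on test–retest reliability,
structure–function concordance, network pathlength, and out-of-sample
predictive ΔR².

It is a library for people who analyse region-by-time source
reconstructions (EEG/MEG) or need a ground-truthed benchmark for
connectivity estimators; the public face is the importable API plus the
narrative scripts in `examples/`.

## The quantities at its core

* **Mean phase delay** of a region pair over an epoch, from Hilbert phases:
  `tau_ij = angle( (1/N) * sum_t exp(i * (theta_i(t) - theta_j(t))) )`,
  with *near-zero* defined as within 0.3 rad of 0 or ±π (19.1% of the unit
  circle).  For comparison, conduction along a 128 mm tract at 4.5 m/s plus
  a 0.75 ms synaptic delay shifts a 10 Hz oscillation by ≈ 1.83 rad.
* **Six estimators** in matched pairs: coherence `|S_ij| / sqrt(S_ii S_jj)`
  vs. `|Im(S_ij)| / sqrt(S_ii S_jj)`; PLV `(1/N)|sum exp(i dtheta)|` vs.
  wPLI `|E{Im S_ij}| / E{|Im S_ij|}` (expectation over Welch segments);
  AEC (|Pearson r| of Hilbert envelopes) vs. orthAEC (epoch-wide OLS
  orthogonalisation, squared/log power envelopes, mean of both directions).
* **Penalisation scale** `||tau| - pi/2| / (pi/2)` ∈ [0, 1]: how strongly a
  pair's mean delay is down-weighted by exclusive estimators (1 at 0 and
  ±π, 0 at ±π/2).
* **Normalised weighted pathlength** `L' = L / L_rand`: shortest paths on
  inverted weights, normalised by 500 degree- and strength-preserving null
  networks.
* **Edgewise ICC(2,1)** (two-way random effects, absolute agreement) for
  test–retest reliability; Spearman concordance with log streamline counts;
  percentile-bootstrap mediation of streamline count → transmission-time
  proxy (tract length / HMOA) → penalisation; cross-validated ΔR² with
  permutation contrasts.

The synthetic cohort encodes the biology these analyses assume:
transmission-time-dependent phase lags (velocity ∝ HMOA), homotopic and
distance-independent zero-lag coupling, Gaussian signal-leakage mixing, and
covariate-linked outcomes with recorded planted effect sizes.

## Worked example

`python examples/02_estimators_and_attenuation.py` builds two noiseless
10 Hz signals offset by 0.3 rad and runs all estimators:

```
planted lag: 0.3 rad; measured mean phase delay: 0.300 rad
coherence        = 1.0000   (inclusive: full strength)
PLV              = 1.0000   (inclusive: full strength)
imag. coherency  = 0.2955   (exclusive: = coh * |sin lag|)
wPLI             = 0.7850   (exclusive: sign-consistent Im only)
measured ImgCoh reduction: 70.4%  (analytic 100*(1-|sin phi|) = 70.4%)
```

The pair is perfectly interdependent (coherence and PLV are 1) at a lag far
smaller than axonal conduction would produce, yet the imaginary part of
coherency reports 70% less connectivity — the `|sin(lag)|` attenuation law
that motivates the penalisation scale.  The other examples cover cohort
simulation, the leakage distance profile (flat beyond ~60 mm with a 20 mm
mixing kernel), reliability contrasts, the mediation chain, and the
pathlength/ΔR² analyses; each prints its numbers with a line on what they
mean.

A thin CLI covers shell use: `zerolag simulate --out DIR` writes a cohort,
`zerolag run-all --out DIR` runs every stage and writes the tab-delimited
report bundle.

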