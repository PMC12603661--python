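# Methods

This note documents the models, parameter choices and numerical decisions
behind `zerolag`, and what the synthetic validation does and does not show
about real data.

## Signal model and estimators

Epochs are region-by-time blocks at 250 Hz (default 20 s).  Band filtering
uses sequential high-pass and low-pass windowed-sinc FIR filters (order
250, Hamming window) applied forward and backward, so the amplitude
response is squared and the net phase response is exactly zero; 500 reflect
-padded samples surround both filtering and the Hilbert transform to
suppress edge transients.  Bands: delta 1–4, theta 4–8, alpha 8–13,
low-beta 13–20, high-beta 20–32 Hz.

Cross-spectra come from Welch segmentation — 2 s Hann segments, 50%
overlap (19 segments per 20 s epoch), no detrending, scipy density
scaling.  Segment spectra are retained because the wPLI expectation runs
over segments; the epoch is otherwise treated as a single window.  These
Welch parameters are declared defaults (configurable), chosen for ≥ 1 Hz
resolution with enough segments for stable expectation operators.

Per-bin estimator values are averaged over the band's bins *after* the
estimator's bin-wise formula (for ImgCoh: per-bin magnitude, then mean), a
single aggregation rule applied to all spectral estimators so comparisons
are fair.  Bins where the product of autospectra is numerically zero are
skipped with a warning.  Conventions for degenerate inputs: wPLI is 0 when
E{|Im|} = 0 (pure zero-lag); orthAEC is 0 for (near-)collinear pairs
(relative residual norm < 1e-8); AEC is NaN for flat envelopes; the mean
phase delay is NaN when the circular resultant is below 1e-12.  orthAEC
uses one epoch-wide OLS coefficient per direction (the mild, time-domain
form of orthogonalisation), squares and log-transforms the Hilbert
envelopes, and averages the two directed correlations.

The penalisation scale `||tau| - pi/2| / (pi/2)` maps each pair's mean
delay onto [0, 1] (1 at 0/±π, 0 at ±π/2): the degree to which zero-phase-
exclusive estimators down-weight that pair.

## Synthetic cohort generator

The generator's role is to encode, with known ground truth, the biology the
downstream analyses assume.  Key components and their defaults:

| parameter | default | meaning |
|---|---|---|
| n_regions / n_participants | 68 / 153 | bilateral layout, mirror-image homotopic partners |
| sampling_rate / epoch_seconds | 250 Hz / 20 s | paired test–retest epochs per participant |
| conduction_velocity | 4.5 m/s | nominal white-matter speed at reference HMOA |
| synaptic_delay | 0.75 ms | added to every tract delay |
| hmoa_reference | 0.05 | HMOA mapping to the nominal velocity (v ∝ HMOA) |
| leakage_sigma | 20 mm | Gaussian mixing-kernel width; 0 disables leakage |
| coupling_strength | 1.0 | global gain on directed (delayed) coupling |
| coupling_strength_range | (0.5, 1.5) | per-pair gain jitter, fixed within participant |
| noise_level | 0.5 | broadband noise SD per unit-SD oscillation |
| homotopic_gain | 2.2 | zero-lag shared-driver gain on homotopic pairs |
| zero_lag_fraction / zero_lag_gain | 0.5 / 1.5 | random matching of regions with resonance-like zero-lag drivers |
| age_coupling_slope | 1.0 | coupling gain rises ~3× from age 6 to 31 |
| coupling_individual_sd | 0.25 | age-independent per-person gain variation |
| swm_beta / swm_noise | 8 / 2 | outcome change per SD of planted pathlength; residual SD |

Oscillations are band-limited Gaussian noise carriers (filtered white
noise), not pure tones, so estimators face realistic phase jitter.  For
each structurally connected pair the follower receives the leader's
oscillation delayed by `tract_length / (v · HMOA/HMOA_ref) + synaptic
delay` with gain proportional to the normalised log streamline count —
stronger, microstructurally faster tracts plant phase delays closer to
zero, which is the causal chain the mediation analysis recovers.  Homotopic
pairs and a random *matching* of further region pairs share zero-lag
drivers (a desk-scale stand-in for resonance-induced synchrony; a matching,
rather than independent random pairs, bounds the number of strong shared
components per region so planted pairs remain detectable at any distance).
The homotopic gain is calibrated so that 80–90% of homotopic connectivity
is measured at near-zero delay.  Leakage multiplies the signals with a
row-normalised Gaussian mixing matrix over centroid distance; since two
mixed regions also share mid-lying sources, the pair-level artefact kernel
is up to √2 wider than the mixing kernel, i.e. negligible beyond roughly
3–4 σ.

The structural connectome draws streamline counts as Poisson variates of an
exponentially distance-decaying mean (amplitude 300, decay 12 mm,
homotopic boost 60).  With coupling gain ∝ normalised log count, directed
coupling therefore dies out at about `decay · ln(amplitude) ≈ 65 mm` —
chosen so homotopic/callosal edges at 60–110 mm separations survive while
the near-zero-versus-distance profile keeps the shape the leakage logic
assumes.  Tract length is centroid distance times a tortuosity factor ≥ 1;
HMOA rises with normalised log count plus lognormal noise, making count and
HMOA positively rank-correlated.

Outcomes: ages are uniform on 6–31 y; head circumference follows a logistic
growth curve plus noise; the change in working-memory errors is planted on
the normalised pathlength of the participant's *expected-coherence*
network (the closed-form noise-free limit of the measured coherence under
the linear generative model, with a floor of 0.2 for the finite-sample
Welch coherence bias) over the 28-region working-memory subnetwork, plus an
age term and noise.  Planted effect sizes and per-participant planted
pathlengths are returned with the cohort for recovery tests.  All
randomness flows from one master seed via `numpy.random.SeedSequence`
spawning in a fixed order, so identical specs are bit-identical.

## Phase-delay analysis

Near-zero classification uses a 0.3 rad threshold from 0 or ±π (19.1% of
the circle; thresholds are linear in circle fraction).  The distance
profile pools participant × pair observations into 10 mm Euclidean-distance
bins.  The leakage-negligibility distance is operationalised as the left
edge of the first *flat suffix* of bins, where a suffix is flat when (i)
there is no material decreasing trend — a Spearman rank correlation
between bin distance and proportion that is significantly negative at
α = 0.05 **and** whose count-weighted fitted decline across the suffix
exceeds 0.05 — and (ii) the start bin lies within 0.05 of the
count-weighted tail level.  The magnitude conditions exist because a pure
rank test is sample-size-sensitive in both directions: underpowered on
steep-decline-then-flat profiles, and, with enough pooled pairs, triggered
by arbitrarily small declines that a graphical reading would call flat.
Bins holding under 5% of the best-populated bin's pairs are excluded from
the scan (binomial noise).  All three tolerances are parameters.

The homotopic contrast pools participant × pair near-zero outcomes for
homotopic versus an equal-size seeded sample of heterotopic
interhemispheric pairs into a 2×2 table and applies Pearson's chi-squared
(df = 1, no continuity correction); zero- and π-lag are pooled throughout
because exclusive estimators suppress both.

## Reliability, structure–function, networks, prediction

*Reliability.*  Edgewise ICC(2,1) is the Shrout–Fleiss two-way-random,
absolute-agreement, single-measurement form, vectorised over edges, with
negative estimates clamped to 0 and degenerate (zero-variance) edges set to
0 with a warning; edges with sentinel values are dropped whole.  Matrix
consistency is the Spearman correlation of strict upper triangles.

*Structure–function.*  Concordance correlates each participant's
functional matrix with log(1 + streamline count) (the `+1` keeps
zero-streamline pairs defined); count normalisation "to 1" is by the
per-participant maximum of the log counts.  The group location test
screens normality with Shapiro–Wilk at 0.05 to choose between a one-sample
t-test and Wilcoxon signed-rank, with Bonferroni correction at the family
size declared by the caller (one family per method × band grid).  The
transmission-time proxy is tract length / HMOA (HMOA ≤ 0 pairs excluded).
Mediation fits the three linear paths (Y~X; M~X; Y~X+M), so c = c′ + a·b
holds exactly; the 95% CI of a·b comes from 1000 percentile-bootstrap
resamples (closed-form normal equations, vectorised).  Mediation
observations are region pairs with ≥ 1 streamline pooled across
participants; whether to pool pairs or model participants hierarchically
is a genuinely open design point — pooling is the default here, and
per-participant estimation is available by calling the function per
participant.

*Networks.*  Weights are inverted to lengths (1/w, the cited toolbox
convention), all-pairs shortest paths by Dijkstra, disconnection is an
error naming the components (the dense FC subnetworks this targets are
complete-weighted).  Null networks use Maslov–Sneppen degree-preserving
swaps (5 accepted swaps per edge; a complete graph admits none, so only
weight placement is randomised there) followed by a one-shot rank
assignment of the sorted weight multiset against jittered expected-strength
scores (1 SD of jitter).  The jitter level balances strength preservation
(nodal strength correlation ≈ 0.96 on dense graphs) against the placement
bias of exact monotone matching, which otherwise lengthens surrogate paths
and pushes L′ of a random graph down to ≈ 0.95.  Degree sequences and
weight multisets are preserved exactly.  The 28-region working-memory
subnetwork (14 prefrontal, posterior-parietal, anterior-cingulate and
entorhinal regions per hemisphere) ships as an editable plain-text list;
the exact membership is a declaration, not an empirical claim.

*Prediction.*  Out-of-fold R² is 1 − SSE/SST on pooled held-out
predictions (can be negative); both models always see the identical fold
split, which depends only on (n, k, seed).  LOOCV uses the closed-form
leverage residuals.  Permutation contrasts permute the outcome and are
Benjamini–Hochberg corrected across the declared method-pair × band
family.  AIC covariate selection is an exhaustive search over declared
candidates, intended to be frozen per age group.  Folds are unstratified.

## What passing tests do and do not show

The generator validates the *machinery*: that each estimator computes its
defining formula, that planted phase lags, mediation chains, reliability
contrasts and outcome effects are recovered when they are present, and
that null configurations are correctly null-calibrated.  It does not
reproduce empirical effect sizes; points worth naming:

* The far-distance floor of near-zero connectivity is near the 19% chance
  level, far below the ~50% observed in resting EEG; consequently leakage
  halos of the planted zero-lag drivers are relatively more visible here
  than in real data.  The full generator's directed coupling additionally
  creates mid-phase "halo" structure extending to ~90–110 mm, beyond the
  leakage range, so the plateau property is validated on a
  leakage-isolating configuration (drivers and coupling off), where the
  detected knee (60–70 mm with σ = 20 mm) reflects the mixing kernel
  alone.
* Single-epoch estimates of normalised pathlength carry very little stable
  individual signal at 10–20 s epochs (measured test–retest correlations
  ≈ 0–0.1 across configurations), so no planted outcome effect can be
  recovered *through* the estimated pathlength at desk scale; the
  outcome-recovery tests therefore use the recorded planted pathlength,
  while the full estimation chain is validated for null calibration, and
  the age link is recovered end to end through mean strength (its
  estimator noise is far lower).
* Permutation p-values for the ΔR² contrast are exactly calibrated only
  under an exchangeable null; when the baseline covariate is informative,
  outcome permutation is conservative — a property of outcome-permutation
  schemes generally.
* There is no forward model, sensor space, or realistic head geometry:
  leakage is an abstract mixing matrix, and homotopic zero-lag synchrony is
  planted directly rather than emerging from loop dynamics.

Problem sizes used by the test suite are deliberate desk-scale choices:
shared fixtures of 12 participants × 16 regions × 10 s and 10 participants
× 68 regions × 10 s; the homotopic bookkeeping check runs 153 participants
at 4 s epochs (the pooled-count arithmetic is epoch-length-independent);
plateau replicates pool 12 participants each; bootstrap coverage uses 200
replicates at n = 500.
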