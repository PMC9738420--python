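# Methods

This note documents the models, the simulator's assumptions, the numerical
choices, and the limits of what the synthetic components can show.

## 1. Ordinal mixed-model analysis

### Model

Ratings are analyzed at their ordinal levels 1–7 (the normalized 0–1 values
seen in displays are recoded by `level = round(1 + 6v)`, the exact inverse
of the normalization; AIC and likelihoods are invariant to any strictly
monotone relabeling, which a test verifies). The cumulative logit model
with a participant random intercept is

P(y_ij ≤ k | b_i) = logistic(θ_k − x_ij'β − b_i),  b_i ~ N(0, σ²),

with flexible (unconstrained increasing) thresholds. Positive β means a
covariate shifts mass toward higher categories. Condition enters as three
indicator contrasts against the no-help condition.

### Estimation

The marginal likelihood per subject, ∫ Π_j P(y_ij | b) φ(b; 0, σ²) db, is
approximated by a Laplace expansion at the conditional mode of b. The mode
is found by a damped per-subject Newton iteration (the cumulative-logit
log-likelihood is concave in b), run vectorized across subjects to a
gradient tolerance of 1e-10. The outer maximization over (θ₁, log threshold
increments, β, log σ) uses L-BFGS-B with central-difference gradients
(step 1e-6 relative); the practical outer gradient tolerance is ~1e-6 —
the finite-difference noise floor — which moves log-likelihoods at far
below 1e-3, two orders under any comparison made with them. Three optimizer
starts are used for study fits: the fixed-effects solution with σ = 1, plus
two seeded jitters; the best likelihood wins. Start values for the
fixed-effects-only ordered logit (also implemented here; it doubles as the
σ = 0 reference) are the empirical cumulative-logit cut-points with β = 0.

Standard errors come from the observed information (central-difference
Hessian in (θ, β, log σ)) at the optimum; Wald z and two-sided normal
p-values are reported per fixed effect.

Parameter count is k = (J−1) + |β| + 1. The variance parameter counts even
when σ̂ sits at the boundary (a boundary fit is flagged, not re-counted):
this is the convention under which the published AIC/logL pairs of this
design reconcile exactly (e.g. 2·8 − 2·(−106.71) = 229.42).

### Model comparison

`lr_test` computes LR = 2(ℓ_alt − ℓ_null) with χ² df = k_alt − k_null for
nested fits on identical rows. `forward_stepwise` starts from the
subject-only null and repeatedly adds the candidate with the lowest AIC
among additions whose LR test has p < 0.05; AIC ties break by larger LR,
then term name. A brute-force enumeration over the candidate lattice at
depth ≤ 2 serves as the selection oracle in tests.

### Accuracy of the Laplace approximation

Tests compare the Laplace evaluation against 50-node Gauss–Hermite
quadrature (itself within ~1e-10 of adaptive quadrature) at fixed
parameters on 10-subject × 4-observation datasets with σ = 0.5, where the
approximation error is ~0.01 and any implementation error would surface.
The intrinsic Laplace error grows with σ²/n_j: at σ ≈ 1 with only 4
observations per subject it reaches ~0.05–0.13 in total log-likelihood
regardless of implementation. This does not affect model *comparison* on
the packaged study data, where all candidate fits share the same
approximation and the published values were produced by the same
approximation.

### Study data

The packaged table holds the 18 participants × 4 conditions of the game
study (participant 2 excluded at source; the participant-14
mitigated-failure cell missing, kept as an explicit marker row → 71
complete rows). The loader validates the structural grid: ratings on the
1/6 grid of a normalized 7-point scale, percentages in whole multiples of
5 (consistent with 20-trial conditions), reference-condition positive
feedback equal to the MI conversion rate, and recomputes the per-
participant means against the printed summary rows as a transcription
guard. Participant 1's fish counts are printed as 0 in all conditions
despite high positive feedback; they are transcribed as printed (the
published grand means include them). Per-cell help (PAM) rate and
reel/unreel counts are not printed, so models using them can only be
explored on simulated cohorts, not reproduced from the table.

## 2. Synthetic EEG and decoder

`generate_synthetic_eeg` emulates a calibration run: 30 MI + 30 idle
epochs, 4 s at 250 Hz, channels F3 F4 C3 Cz C4 P3 P4. Each channel is
white noise (σ = 1 µV default) plus band-limited mu (8–12 Hz, RMS 3 µV on
the central row, 1–1.5 µV elsewhere) and beta (13–30 Hz, half the mu RMS)
rhythms. Motor imagery attenuates the rhythm amplitude on C3 and Cz by
√(1−erd_depth), i.e. band power by (1−erd_depth) — the ERD of a right-hand
palmar-grasp imagery over contralateral/midline motor cortex. `erd_depth`
= 0 makes the classes exchangeable (chance decoding); 0.8 makes them
strongly separable. The generator does not model 1/f background structure,
eye/muscle artifacts, nonstationarity, or inter-session drift, so passing
tests bound decoder behavior only on clean stationary rhythms; real-EEG
performance will be lower and noisier.

Calibration is the standard pipeline: causal 5th-order Butterworth
band-pass 8–30 Hz → CSP (6 components, 3 per spectrum end; class
covariances averaged per epoch with 1e-6·trace diagonal loading) →
log-variance features → LDA, with stratified 5-fold cross-validated
accuracy and a final refit on all epochs. The CSP eigenbasis whitens the
pooled class covariance (W(S_a+S_b)Wᵀ = I), the property tests rely on.

Online operation emits one value in [0,1] every 1/16 s: a 1-s analysis
buffer slides over the causally filtered signal, and the value is the
logistic of the signed LDA score. Two corrections matter here:

- the LDA intercept is recentered on buffer-length segments of the
  calibration epochs — log-variance features shift with window length, and
  without recentering a chance-level decoder sits systematically off 0.5;
- detection requires the value to stay ≥ threshold for 0.5 consecutive
  seconds (8 decisions), scanning left to right; latency is the time of the
  dwell run's last decision.

The probability threshold defaults to 0.5 and is re-tuned per user by an
emulated short online test: held-out MI and idle windows are played
through the full loop and the grid (0.20…0.95, step 0.05) is searched for
the lowest threshold whose idle-window (false-positive) detection rate is
≤ 0.15, falling back to the highest grid point. This criterion — minimize
false positives while keeping activation possible — is what makes a
chance-level user land at a low but nonzero per-trial success rate; a
Youden-J criterion is available as an option but is uninformative at
chance level, where TPR−FPR is pure noise. With tuning, a strong-ERD
simulated user succeeds in >80% of trials and a no-ERD user in roughly
15–45%, inside the 5–100% conversion-rate range the study population
showed.

## 3. Game and urn scheduler

The game is deterministic given feedback: a fish in lane d needs d reels
(positive +1, extra-positive +2 capped at the requirement, no carry-over),
escapes at 3 unreels, neutral changes nothing; a trial is 2 s preparation
+ a 2-s input window that closes at detection or timeout. Hook steering is
abstracted away (the simulated player always hooks); a fish still hooked
when the 20 trials run out counts as lost.

Helped conditions plan round(0.30·20) = 6 special trials uniformly
shuffled among normals (round half up for other configs). Outcome
resolution follows the help taxonomy: input override delivers one regular
positive regardless of input; mitigated failure delivers neutral
regardless; augmented success delivers extra-positive but *requires* a
genuine success — on failure the trial resolves as a normal failure and
the owed special is re-inserted uniformly among the remaining normal slots
(dropped with a logged deficit if none remain). In `deployment` mode,
override/mitigation specials fire only on failures and are likewise
rescheduled on success. Forced rejections turn a successful attempt into
negative feedback ("Positive to Negative"); rejections never consume
special slots.

The 70% control cap is enforced after every resolved trial by two tiers:

1. *Soft projection*: the final positive count is projected as delivered
   positives + r̂·(remaining normals) + positive-capable specials (all for
   input override, r̂-weighted for augmented success, none for mitigated
   failure), where r̂ = successes/(trials+2) — a shrunk running success
   rate whose two pseudo-failures keep one early lucky success from
   projecting a weak user over the cap. Normal slots are converted to
   rejections until the projection is ≤ floor(0.7·20)+1 = 15.
2. *Hard backstop*: once delivered positives plus remaining
   positive-capable specials reach 15, every remaining normal slot becomes
   a rejection — this guarantees a perfect user ends at exactly 75%
   positive feedback (70% under mitigated failure, whose specials are
   neutral) with no stochastic escape.

Under this policy a 10%-success user triggers a rejection in roughly 1 in
10⁴ trials (an always-failing user never does): with any projection based
on observed play, a run of early lucky successes is indistinguishable from
a strong user. The projection is injectable (`projector=` hook) so
alternative readings can be compared. The published AS-column outcome
frequencies (12% forced rejections, 14% delivered specials) depend on the
un-logged interplay of rejection pressure and rescheduling in the original
sessions and are not targets; the simulator exposes the knobs instead.

`simulate_cohort` replays participant × condition grids with
Bernoulli(rate) attempt models (rates default to the packaged
reference-condition MI conversion rates, mean 0.575) or a full
decoder-in-the-loop user, and reduces each condition with
`summarize_condition`: MI conversion = genuine successes/20, positive
feedback = (positive or extra-positive trials)/20 — an augmented trial
counts once here but advances the reel count by two — help rate =
delivered specials/20.

## 4. Problem sizes in tests

Scheduler properties run 100–300 seeded conditions per claim; cohort-level
frequency checks use 10–30 cohort replications (≥3,600 trials each
aggregate); parameter recovery uses 50 replicates of 100 subjects × 4
observations (β = 0.6, σ = 1), recovering β with mean absolute error
≈ 0.08; decoder end-to-end checks average 3–6 calibration seeds × 30–40
trials. These sizes put Monte-Carlo error well inside the asserted
margins while keeping the default suite around a minute of compute.

## 5. Known limitations

- No human-rating model: simulated cohorts produce game variables only, so
  rating analyses always run on the packaged (real) table.
- The synthetic EEG omits artifacts and nonstationarity (see §2); decoder
  accuracies near 1.0 at deep ERD are a property of the clean generative
  model, not a claim about real signals.
- The Laplace likelihood inherits the approximation's σ²/n_j error; for
  designs with few observations per subject and large σ, quadrature-based
  fitting would be preferable (out of scope here).
- The scheduler cannot reproduce session-level outcome tables that depend
  on un-logged trial streams; it reproduces the stated scheduling *rules*
  and their aggregate consequences.
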