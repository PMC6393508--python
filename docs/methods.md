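# Methods

## The capacity model

The masked majority-function task shows five arrows for a limited exposure
time `ET`; the subject reports the majority direction. Under the
grouping-search strategy the observer draws random samples of
`group_size = 3` arrows until one is unanimous. For majority:minority ratio
`m:k` the probability that a sample is unanimous is

    P_group = [C(m,3) + C(k,3)] / C(5,3)

(1, 0.4 and 0.1 for 5:0, 4:1 and 3:2), the expected number of scanned
arrows is `N = 3 / P_group`, and the condition's information load is
`log2 N` bits (1.58, 2.91, 4.91). Exposure time turns load into a rate,
`log2(N / ET)`, spanning 0.58–6.91 bps over the 12-cell design (3
congruencies x ET in {0.25, 0.5, 1, 2} s). Note the two rate extremes both
have mantissa .58496…; we round half-up once, to 0.58 and 6.91.

A subject with capacity `C` bits/s completes `k = 2^C * ET / 3` sampling
attempts within the exposure. The trial then terminates *voluntarily* (a
unanimous sample found; the response is correct with baseline probability
`p0`) with probability `1 - (1 - P_group)^k`, or is *forced* to a guess
(correct with `p_guess = 0.5`). Expected accuracy is therefore

    E[acc] = p0 - (1 - P_group)^k * (p0 - p_guess),

continuous and nondecreasing in `C` and `ET`, bounded in `[p_guess, p0]`.
The exponent is real-valued; an integer-attempt mode (`floor(k)` explicit
group draws) is available in the simulator as the brute-force process the
closed form idealises, and the two agree within Monte-Carlo error.

### Estimation

Estimation is two-stage, reflecting the definition of `p0` as congruent
(5:0) performance:

1. `p0` = trial-weighted mean accuracy over all congruent cells, pooled
   across exposure times (the congruent cells are constant in `C` and enter
   the likelihood nowhere else);
2. `C` maximises the binomial log-likelihood of the incongruent cell counts
   `sum n_correct*ln(p_hat) + (n-n_correct)*ln(1-p_hat)` with
   `p_hat = E[acc]` clamped to `[1e-6, 1-1e-6]`.

"Optimal likelihood" is ambiguous between a binomial likelihood and least
squares on cell accuracies; both are implemented (`objective=` on
`CapacityModel`), binomial is the default, and the two agree within ~0.1
bps on clean data. The search interval is `C` in [0.1, 10] bps — generous
around the 2–5 bps range real subjects occupy — scanned on a 128-point grid
before bounded Brent refinement, because the objective is flat near the
bounds when cells sit at ceiling or chance. Fits where every incongruent
cell is at or below chance, or at or above `p0`, carry no information about
`C`: they are returned at the relevant bound with `converged=False,
at_bound=True`.

At the published design (36 trials per congruency x ET cell, `p0 = 0.99`)
the median absolute estimation error is below 0.25 bps for true capacities
between 2 and 5 bps (200 simulated subjects per level), and bias shrinks
as trials per cell grow.

## Battery scoring

* **Conflict effect (flanker):** error trials are removed first; then, per
  congruency condition, trials with RT beyond ±3 SD of that condition's
  correct-trial mean are dropped in a single pass (no re-trimming; the
  mean/SD base is the correct trials, a choice the source description
  leaves open). The score is `mean RT(congruent) - mean RT(incongruent)`,
  reverse-coded so that values nearer zero mean better control. A condition
  with fewer than two correct trials passes through untrimmed with a
  warning.
* **N-back indices:** hardest level minus 0-back accuracy — 2-back for the
  spatial task, 3-back for the verbal task, fixed per task rather than
  auto-detected.
* **Span scores:** all-or-nothing load — a trial contributes its full set
  size only when every element was recalled in correct serial order,
  normalised by the total elements; in [0, 1].
* **Exclusion filter:** valid-response proportion in the majority task
  < 95%, overall flanker accuracy < 90%, any 0-back accuracy < 90%, any
  span distractor accuracy < 85%, or under 15 years of US education. All
  thresholds are strict inequalities (a subject exactly at a threshold is
  kept); removal is the union over rules and the filter is idempotent.

## Correlation inference

One-tailed Pearson tests use the t transform on n−2 df. The Bayes factor
for a correlation is the default Jeffreys–Zellner–Siow test, reduced to a
one-dimensional integral over the g-prior's mixing variable and evaluated
by adaptive quadrature (integrand computed in log space; relative
quadrature error below 1e-4 enforced). It is a function of (|r|, n) only,
so equal printed correlations always show equal Bayes factors; reported
table BFs are computed on r rounded to two decimals for exactly that
reason. Evidence bands: > 100 decisive, > 3 substantial, < 1/3 substantial
evidence for the null, otherwise insensitive, with boundary values mapped
to the weaker category. A one-sided variant (twice the posterior mass on
the observed sign) is available behind a flag.

Dependent correlations sharing an outcome are compared with Steiger's Z1*
(pooled-correlation covariance estimate) by default; the
Meng–Rosenthal–Rubin form is available via `method="meng"`. On rounded
published inputs the two differ by up to ~0.2 in z with Steiger slightly
closer to values reported from unrounded data, which is why it is the
default; no printed z value is hard-coded anywhere.

## Covariance-structure engine

Models are specified as manifest variables, first- and second-order
latents, loading edges, latent (co)variances, error variances and
error-covariance links. With loadings Λ, latent regressions B, disturbance
covariance Ψ and error covariance Θ,

    Sigma(theta) = Λ (I−B)⁻¹ Ψ (I−B)⁻ᵀ Λᵀ + Θ.

Fitting minimises the Wishart discrepancy
`F = ln|Σ| + tr(SΣ⁻¹) − ln|S| − p`; `χ² = (n−1) F_min`. Internally the
problem is solved in the correlation metric (manifests scaled by sample
SDs, fixed values carried into the same metric, θ mapped back afterwards)
— F is invariant under this rescaling and the optimisation is far better
conditioned, since raw battery measures differ in variance by four orders
of magnitude. L-BFGS-B with error variances bounded at zero, five starts
(sample-scaled anchor-ratio starts, multiplicatively jittered) and gradient
tolerance 1e-8.

Fit indices: `RMSEA = sqrt(max(χ²−df,0)/(df(n−1)))`, TLI and CFI against
the independence baseline (free variances only), `BIC = χ² + q ln n`.
The BIC convention differs across SEM packages; only BIC *differences*
under the same convention are interpreted (bands: >2 positive, >6 strong,
>10 very strong). Cut-off verdicts attached: χ²/df < 2, RMSEA < 0.06,
TLI/CFI > 0.95.

### The four battery models and identification

1. `iq_cc_wm` — second-order IQ over Gf (PRI, WMI, PSI) and Gc (VCI),
   second-order WM over N-back and span factors, first-order CC (CCC, EC);
   error-covariance links WMI~~CCC and WMI~~OSpan; df = 39.
2. `gc_gf_cc` — Gc, Gf, CC correlated; WMI~~CCC link; VCI error fixed to 0;
   df = 7.
3. `gc_gf_wm` — Gc, Gf, second-order WM; WMI~~OSpan link; VCI error fixed
   to 0; df = 25.
4. `cc_wm` — CC and second-order WM; df = 13.

Identification: one loading fixed to 1 per latent; first-order latents
under a second-order factor carry zero disturbance variance; the
single-indicator latent Gc (error fixed to 0) has its variance fixed to the
indicator's sample variance, i.e. Gc ≡ VCI. These conventions were chosen
as the set consistent with the published degrees of freedom of all four
models; published figures typically omit identification constraints, and
other choices (e.g. free first-order disturbances) yield different df.
The two error-covariance links are fixed model features here; modification
indices are not computed.

Parameter recovery: on data simulated from model 1 with latent correlations
(0.84, 0.87, 0.96) at n = 500, the median absolute error of the recovered
latent correlations over 50 replicates is ~0.02, well inside the ±0.08
acceptance surface.

## Synthetic cohort

Subjects draw latent (IQ, CC, WM) scores from a configurable correlation
matrix (default: the strong-overlap structure above). Each measure is
`loading * factor + unique noise` on the standard scale, then mapped to its
task's parameter space: capacity `C = 3.82 + 0.62 z` clipped to [0.5, 8]
bps, conflict shift `144 − 42 z` ms, hardest-level N-back accuracies and
per-element span recall probabilities through clipped linear/logistic
links, composites on the IQ metric (mean 100, SD 15). Trial counts follow
the task designs: 432 majority-task trials (12 blocks x 36), 288 flanker
trials (4 x 72), 240 spatial N-back trials, 18 verbal trials per level,
10/8/8 span trials with set sizes 2–7, 3–7 and 2–5.

Only the majority-task generator is a process model (the VT/FT mechanism
itself, so simulated cell accuracies match the closed form by
construction in expectation — the Monte-Carlo tests check the sampling
machinery, and the integer-attempt mode checks the idealisation). Flanker,
N-back and span generators are simple parametric stand-ins (shifted-normal
RTs, binomial accuracies, Bernoulli(q^set_size) recall): passing tests show
the *scoring and inference machinery* is correct under a known truth, not
that these forms capture real response processes (no sequential effects, no
RT–accuracy tradeoffs, no serial-position effects). Default noise levels
were set once so that simulated summary tables land near the published
ranges (capacity ~2–5 bps, conflict effect ~ −144 ± 42 ms, span scores
~0.45–0.55); 0-back accuracies default to 0.99 because the verbal 0-back
has only 18 trials and a lower true ceiling would trip the 90% exclusion
rule through sampling noise alone. Deliberate rule violators can be
injected per criterion (`inject_violations`), and one global seed fans out
to stable per-task substreams so adding a task does not perturb existing
streams.

## Numerical choices and limitations

* Binomial likelihood clamp 1e-6; capacity grid 128 points before Brent.
* SEM: starts jittered U(0.8, 1.2), first start unjittered; f below 1e-12
  short-circuits the multi-start loop; non-PD sample covariances are
  rejected rather than ridged.
* Listwise-complete subjects enter the SEM stage; the correlation table is
  pairwise-complete with per-cell n.
* The engine offers ML only — no robust/weighted estimators, missing-data
  FIML, or bootstrap standard errors — and no modification indices.
* Majority-task modelling is accuracy-only (no RT model) and assumes the
  grouping-search strategy with the five-arrow design; other set sizes are
  configurable but untested against published constants.
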