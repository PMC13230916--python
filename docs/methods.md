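# Methods

## Problem setting

High-dimensional expression classification datasets (microarray, RNA-seq)
typically carry tens of samples and thousands to tens of thousands of
features, of which only a handful are class-discriminative. `coopfs`
implements a two-stage wrapper feature-selection procedure for this regime:

1. **Filter stage.** Every feature is scored by the Fisher ratio of
   between-class to within-class variance,

       FS_i = Σ_c n_c (μ_{c,i} − μ_i)² / (Σ_c n_c σ²_{c,i} + ε),

   with population (ddof = 0) class variances — the `n_c` weighting of the
   numerator matches the population convention — and a denominator guard
   ε = 1e−12 so a feature with zero within-class variance receives a very
   large, finite score and ranks first. The top |S| features (default 300,
   capped at the feature count) proceed to stage 2.

2. **Wrapper stage.** A candidate subset is encoded as a continuous vector
   x ∈ [L, U]^n over the filtered features. The S-shaped transfer function
   ST(x) = 1/(1 + e^{−x/2}) maps each coordinate to a selection
   probability; a uniform draw per coordinate turns it into a 0/1 mask
   (all-zero masks are repaired by switching on the arg-max-probability
   feature, ties to the lowest index). The mask is scored by

       f(x) = α (1 − Acc(x)) + (1 − α) |S(x)|/n,

   where Acc is the mean stratified 5-fold cross-validated accuracy of a
   linear SVM (C = 1.0; an XGBoost alternative with 100 trees, depth 6,
   learning rate 0.1, subsample 0.8 is available) restricted to the
   selected columns. α defaults to 0.99: accuracy-dominant with a non-zero
   size penalty. Folds are frozen per run and mask evaluations are cached,
   so a mask maps to exactly one fitness value within a run.

## The cooperative optimizer

The population of NP individuals (default 30) is split into three contiguous
equal groups with distinct roles (a remainder joins the last group; 2- and
4-group structural variants exist, the extra fourth group cloning the
balance role):

* **exploration** — v = x + F r ⊙ (x_{r1} − x_{r2}) + 0.5 F Levy(n) ⊙ (x −
  x_pbest) + λ(x_pbest − x), followed by dimension-wise uniform reset with
  probability p_e = 0.3;
* **exploitation** — v = x + F r ⊙ (x_best − x) + 0.5 F (x_{grp,best} − x) +
  λ(x_pbest − x), plus Gaussian noise N(0, σ(U − L)) with probability
  p_x = 0.1;
* **balance** — v = x + E/2 + D/2 + λ(x_pbest − x) with E the exploratory
  increment (difference step plus Lévy) and D = F r ⊙ (x_best − x), plus
  Gaussian noise with probability p_b = 0.2.

x_pbest is drawn uniformly from the top ⌈0.2·NP⌉ of the whole population;
λ = 0.7. Trials are clipped to the box and accepted by strictly-greedy
replacement (equal fitness keeps the parent), so the incumbent best is
non-increasing through the entire run. Replacement is asynchronous: each
trial sees all replacements made before it, and the elite pool is refreshed
per trial.

The differential weight is bi-adaptive, F = F_base (0.5 + 0.5 R̄_k)(0.4 +
0.6 p) with progress p = 1 − t/T_max and R̄_k an exponential moving average
(weights 0.7 old / 0.3 new, initialized at 0.5) of the group's per-iteration
success ratio R_k = s/(s + f + 1e−9). Base weights are 2.0 / 0.5 / 1.0 for
the exploration / exploitation / balance roles.

**Lévy steps.** Steps are Mantegna-generated, s_j = u_j/|v_j|^{1/β} with
β = 1.5, and enter the updates scaled element-wise by the displacement to
the sampled elite, Levy(n) ⊙ (x − x_pbest). This is the package's design
choice: raw box-scale heavy-tailed steps freeze exploration at a fixed
absolute scale, so every late-stage exploratory trial is rejected, whereas
elite-displacement scaling keeps jumps landscape-scaled — large while the
population is spread, fine once it contracts — and reproduces the expected
late-stage behaviour of the balance group (sustained ~0.4–0.6 success
ratio) together with much better final precision on unimodal benchmarks.

**Cooperation.** Four periodic mechanisms couple the groups:

| mechanism | period | action |
|---|---|---|
| hybridization | T_hyb = 5 | C = 4 elite pairs across distinct groups blend h = r x_a + (1 − r) x_b; h replaces the worse parent iff strictly better than both |
| reorganization | T_reorg = 12 | the group with the highest mean fitness is regenerated around its own best: seed + 0.25(u − ½)(U − L) |
| elite local search | T_local = 8 | top ⌈0.1·NP⌉ spawn one Gaussian probe N(0, ρ(U − L)), ρ = 0.12(1 − t/T_max); accepted only on strict improvement |
| cyclic transfer | T_coop = 6 | each group's worst becomes 0.7·best(previous group) + 0.3·worst + N(0, σ(U − L)) in the fixed exploration→exploitation→balance cycle |

When the best fitness improves by less than 1e−12 for T_stag = 30
consecutive iterations, the worst ⌈0.2·NP⌉ members (never the incumbent
best) are reseeded at x_best + δ·N(0, σ(U − L)), δ = max(0.05, 1 − t/T_max),
with σ = 0.05. Hybrid pairs round-robin over the group pairs, the k-th
visit to a pair using each group's (k+1)-th ranked member. The
within-iteration order is: group updates → hybridization → reorganization →
local search → transfer → stagnation check/restart → success-memory update.
Total cost is O(T_max · NP · C_fit) candidate evaluations plus the logged
event evaluations, with C_fit one cross-validated classifier fit in
feature-selection mode.

**Search box.** Feature-selection mode uses [−4, 4] per dimension
(configurable), giving transfer probabilities spanning ≈ [0.12, 0.88] so
both compact and large subsets are representable. Continuous benchmark
mode uses the function's own box ([−100, 100]).

**Decoding.** The final best vector is decoded through a dedicated seeded
stream so the reported subset is reproducible independent of the search's
own draw history; a deterministic alternative (select iff x_j > 0) is
available via `deterministic_decode`.

## Benchmark suite

Continuous validation uses f(x) = base(M(x − o)) + bias with seeded random
orthogonal rotations (QR of a Gaussian matrix, sign-fixed), uniform shifts
in [−80, 80]^D inside the [−100, 100] box, and the bias as the exactly
known optimum value. Bases: sphere, Zakharov, Rosenbrock (optimum moved to
the origin), Rastrigin, and expanded Schaffer F7 composed cyclically over
consecutive coordinate pairs, g(s) = √s (1 + sin²(50 s^{0.2})), f =
(mean g)².

## Synthetic expression generator

The generator emulates the shape of public microarray datasets: tens of
samples, 10³–10⁴ features, 2–4 roughly balanced classes (largest-remainder
apportionment makes the class counts exact). Informative features separate
consecutive class means by `effect_size` noise-SDs; redundant features are
positive mixtures of informative ones plus N(0, redundancy_noise); the rest
is standard Gaussian noise. It does **not** model heavy-tailed or
log-normal expression intensities, probe-level measurement error, batch
effects, or biological co-regulation beyond the planted redundancy, so
passing recovery tests demonstrates algorithmic behaviour under a
controlled null, not clinical-grade marker discovery.

One property of the small-sample regime deserves emphasis because it shapes
what recovery experiments can show: with 60 samples and 1,000 features,
hundreds of pure-noise features correlate with the labels by chance, the
Fisher filter retains exactly those, and cross-validation *within* the same
60 samples genuinely rewards them. Measured on generated data, ~150-feature
masks reach CV accuracy 1.000 while the planted 5-feature subset scores
≈ 0.95, so with α = 0.99 the fitness optimum is a large mask, not the
planted set. High Jaccard recovery of a small planted set at these sample
sizes is therefore not implied by correct optimization of f; the package's
recovery test reports this honestly.

## Evaluation protocol and statistics

`nested_evaluation` gives leakage-free accuracy estimates: per run
(seed = base + run index) a stratified 5-fold outer split; the filter and
wrapper see only the training rows of each fold; a fresh classifier is
fitted on the training rows restricted to the selected columns and scored
on the untouched fold. The test suite audits this with row-fingerprint
instrumentation and demonstrates the alternative (filtering on the full
data) inflating accuracy on pure-noise data.

Method comparison uses the Wilcoxon signed-rank test with zero-splitting —
zero differences keep their tie-averaged lowest ranks, half of that rank
mass added to each of R+ and R−, so R+ + R− = n(n+1)/2 identically; the
statistic is min(R+, R−) and p-values come from scipy (exact for small
tie-free samples, normal approximation otherwise) — Holm's step-down
correction (statsmodels), and Friedman mean ranks (rank 1 = best, average
ranks on ties; the classical chi-square statistic, cross-checked against
scipy on tie-free data). Confidence intervals in the Friedman summary are
95% t-intervals on each method's per-dataset accuracies, an interpretation
choice. Both harness entry points (ablation variants as config toggles and
one-factor-at-a-time sensitivity sweeps) run all variants under identical
derived seeds.

## Problem sizes used by the test suite

The suite exercises the full benchmark protocol (30 runs × 1000 iterations,
population 30, 20-D) for the Schaffer-F7 and sphere convergence checks, and
the planted-recovery experiment at 20 generator seeds with population 30
and 60 wrapper iterations per run — the package's chosen problem size for
this experiment; the recovery verdict is insensitive to the iteration
budget (see the generator discussion above). Unit tests use miniature
configurations (population ≈ 12, ≤ 40 iterations) throughout.

## Known limitations

* On strongly multimodal rotated landscapes, the elite attraction shared by
  all three update rules (λ = 0.7) commits the population to a basin early;
  the method polishes well within the basin but is weaker than
  crossover-based differential evolution at locating a distant global
  funnel at the same evaluation budget.
* Under stochastic mask decoding, the subset-size term of f is observed
  through binomially noisy draws (SD ≈ √(Σ ST(1 − ST)) features), so
  subset-size descent is slow when accuracy is saturated.
* The Fisher filter is univariate and linear; feature pairs that are only
  jointly informative are invisible to stage 1.
* Wall-clock performance of feature-selection mode is dominated by
  classifier fits (~5 cross-validation fits per candidate evaluation);
  mask caching removes repeats within a run but distinct masks always
  refit.
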