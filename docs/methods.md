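# Methods

## The model

`gapcircuit` implements a gene-circuit model of the trunk gap genes *hb*,
*Kr*, *gt* and *kni* in the posterior half of the *Drosophila* blastoderm
(47–92% egg length, %EL, anterior = 0%).  The state is the protein
concentration v^a_i of gene *a* in nucleus *i* on a 1-D row of
nuclei, on the 0–255 fluorescence scale of integrated expression data.
During interphase

    dv^a_i/dt = R_a g(u^a_i) + D_a (v^a_{i-1} - 2 v^a_i + v^a_{i+1}) - lambda_a v^a_i

with total regulatory input

    u^a_i = sum_b T[a,b] alpha_b v^b_i + sum_e E[a,e] y_e(i,t) + h_a

and the sigmoid regulation–expression function
g(u) = (u/sqrt(1+u²) + 1)/2 of the connectionist gene-circuit lineage.
T (4×4) and E (4×3) are the genetic inter-connectivity matrices; the sign
of an element encodes activation, repression or (near zero) no
interaction.  y_e are the external inputs Bcd, Cad and Tll — regulators of
the gap genes that are not themselves modeled, supplied as data anchored
at the midpoints of cycles 12 and 13 and the eight cycle-14A time classes
and interpolated piecewise-linearly in time (clamped outside the anchors).
Boundaries are zero-flux (the missing neighbour term is dropped).

The circuit runs by three rules on the experimental schedule, with time in
minutes from the start of cycle 13: interphase dynamics on [0, 16.0],
mitosis (synthesis switched off) on [16.0, 21.1], nuclear division at
21.1 min (each nucleus is replaced by two daughters inheriting its state;
spacing halves; 23 → 46 nuclei), then interphase to gastrulation at
71.1 min.  Cycle 14A is divided into eight 6.25-min classes T1–T8; the
model is compared to data at nine time points — the cycle-13 midpoint
(t = 10.55) and the eight class midpoints t = 21.1 + (k − ½)·6.25.
Comparison states are obtained by stopping the integrator exactly at these
times, never by interpolation.

Initial conditions: *Kr*, *gt*, *kni* are exclusively zygotic and start at
zero; *hb* starts from the cycle-12 profile of the dataset.

**Genotypes.**  A genotype is a vector of per-gene scaling coefficients
alpha ∈ [0, 1] applied to the gene's regulatory output (the alpha_b v^b
terms).  Wild type has all alpha = 1.  A null mutant sets alpha = 0, which
removes the gene from the network; because the gene's protein is absent in
a null, the alpha = 0 channel is also clamped to zero rather than
integrated.  Graded knockouts (0 < alpha < 1) scale the regulatory output
while the protein channel itself keeps running — the weight-scaling and
concentration-scaling formulations are algebraically equivalent in this
model, and the weight-scaling form is implemented.  Multi-gene nulls
(e.g. *Kr*;*kni*) are expressed the same way.

## Free parameters and units

The fit estimates 40 parameters in four 10-parameter target-gene blocks:
per gene, four T weights, three E weights, the maximum synthesis rate R
(units·min⁻¹), the diffusion coupling D (min⁻¹, as it appears in the
equations; the same value in both cycles), and the decay rate lambda
(min⁻¹, half-life ln 2/lambda).  The promoter threshold h is fixed at
−3.5 for all genes, which removes a scale degeneracy from the search.
Default search bounds: T, E ∈ [−0.1, 0.1] (units⁻¹); R ∈ [0.5, 30];
D ∈ [0, 0.3]; lambda bounded so the half-life lies in [5, 20] min.  These
are order-of-magnitude choices consistent with the parameter scales of
fitted gap-gene circuits; the container accepts R = 0 or lambda = 0 so
degenerate diagnostic circuits (pure decay, conservative transport) can be
simulated, but fitted circuits always have both positive.

## Numerics

The right-hand side is smooth between rule changes, so the integrator is a
Dormand–Prince 5(4) adaptive pair with rtol 10⁻⁶ / atol 10⁻⁸, with hard
stops at 16.0, 21.1 and every output time so events are never stepped
over.  Both steppers are compiled (numba): parameter fitting evaluates on
the order of 10⁵ trajectories, which rules out interpreter-level stepping.
Inside the optimizer's objective a fixed-step classical RK4 with nominal
step 1.0 min (shortened to land exactly on segment ends) is used instead;
its accuracy floor against the reference integrator is an RMS of order
10⁻³ fluorescence units — three orders of magnitude below the fit's
acceptance threshold — while roughly doubling throughput.  Reference
simulations, reported costs and RMS values always use the adaptive
integrator.  The integration schedule was cross-checked against
scipy's `solve_ivp` on the NumPy right-hand side (tests).

Dense output for contribution plots is recorded at 0.5-min resolution.

## Cost function and fitting

The cost is the unweighted sum of squared differences between model and
data over the wild-type observations (4 genes × 9 time points) and the
Kr-null observations (*hb*, *gt*, *kni* only — there is no Kr product to
stain in the null), both genotypes simulated from the same parameter
vector.  RMS = sqrt(Phi/N).  Observation rows are compiled once into
gather indices, so an evaluation is two forward simulations plus an array
subtraction (~1.6 ms).

**DEEP.**  The optimizer is Differential Evolution Entirely Parallel: the
population (default 200) is split into branches on a ring; each branch
runs DE with binomial crossover and greedy selection; every communication
period (default 5 iterations) the best member of branch k replaces the
oldest member of branch k+1, with the last branch feeding the first.  A
member's age is the number of iterations it has survived unchanged; a
high age marks a parameter set parked in a local minimum, which is exactly
what migration overwrites.  Execution is serial and fully determined by
the seed; migration happens at iteration boundaries, so the result equals
a barrier-synchronized parallel run.

The mutation base is configurable.  The classical rand/1/bin and
best/1/bin variants (F = 0.8 with optional dither to 0.5, CR = 0.9) are
provided, but the default engine is current-to-pbest/1 with
success-history adaptation of F and CR per branch (Cauchy/normal sampling
around improvement-weighted means, Lehmer-mean update, p = 0.10 pbest
pool, archive of replaced parents).  On this 40-parameter least-squares
landscape the classical variants stagnate one to two orders of magnitude
above the optimum within a 2000-iteration budget, while the adaptive
engine reaches a numerically negligible cost; the adaptive core sits
unchanged inside the DEEP branch/migration structure.

**Ensemble.**  Candidate fits pass two filters: (1) RMS below 5% of the
maximal expression level (12.75 on the 0–255 scale); (2) a deterministic
pattern screen that replaces visual inspection of the fitted patterns —
the Kr-null gt peak must shift anterior by more than the wild-type gt peak
and lie anterior of it at T8, mutant *hb*/*gt*/*kni* peak levels at T7
must fall below their own mid-cycle (T3–T5) maxima, and model peak
positions must stay within 3 %EL of the data peaks wherever the data show
a domain above 20 units.  Both decisions are logged per candidate.  All
screen thresholds are configurable; the defaults encode the qualitative
Kr-null phenotype.

**Variance-stabilized refit.**  Fluorescence error grows roughly linearly
with the mean (Poisson-like), violating the homoscedasticity behind
least-squares confidence intervals.  `vst_refit` minimizes
Σ(√model − √data)² warm-started at an accepted optimum of the plain cost
(trust-region reflective within the search bounds), clipping negative
model values at zero before the transform and reporting the clip count
and the parameter displacement.  On synthetic heteroscedastic data the
transform removes the level-versus-spread trend of the residuals (tests).

## Topology classification

Each element of T and E is classified by sign against a threshold of
0.005: activation above, repression below −0.005, no interaction inside
the closed interval [−0.005, 0.005] (boundary values conservatively map to
no interaction).  Votes across an ensemble give per-cell counts and a
majority category (ties → ambiguous); consensus circuits are members
whose classifications match the majority everywhere.  Refinement with
per-circuit confidence intervals: a majority-activation cell whose
estimates are positive in at least 80% of circuits ("almost all";
configurable) but whose intervals contain zero in at least 80% of them is
downgraded to insignificant activation (symmetrically for repression);
cells whose estimate signs are mixed beyond that fraction become
ambiguous.  Refinement can only downgrade significance or flag ambiguity,
never flip activation and repression.

## Identifiability

The sensitivity matrix S is the N×40 Jacobian of the (√-transformed, to
match the stabilized objective) model solution at every observation with
respect to the parameters, by central finite differences with step
10⁻⁴·max(|theta_j|, bound width).  Confidence intervals use the
joint-projection form theta_j ± sqrt(m F(alpha; m, N−m) s² [(SᵀS)⁻¹]_jj)
with s² = Phi/(N−m) and alpha = 0.05; a parameter whose interval excludes
zero has an identifiable sign.  Rank-deficient SᵀS falls back to the
pseudo-inverse with the affected parameters flagged.  Because the Kr
channel is absent from the mutant, the sensitivities of the ten Kr-block
parameters vanish on the mutant rows — those parameters are effectively
estimated from the wild-type half of the data, as the block structure of
SᵀS then implies.

The collinearity index of a parameter subset is
gamma = 1/sqrt(lambda_min) of the Gram matrix of the unit-normalized
(uncentered) sensitivity columns; gamma ≥ 1, invariant to column scaling,
and gamma = 10 corresponds to a pairwise cosine of 0.99.  Subsets of
dimension 2 and 3 are enumerated exhaustively (C(40,2)=780, C(40,3)=9880 —
no heuristics needed); subsets with gamma above 7 are flagged, and a
triple is suppressed when one of its pairs is already flagged.  The same
screening restricted to the wild-type rows ("upper half" of S) shows the
benefit of the two-genotype fit: on the synthetic reference it flags at
least as many subsets as the full matrix (tests).

## Contributions, features, knockout scan

The regulatory input is additive, so each interaction's strength at any
point is its term T[a,b]·alpha_b·v^b or E[a,e]·y_e; the decomposition
reassembles u exactly (checked to 10⁻¹⁰).  Domain features: the peak is
the anterior-most global maximum refined by a 3-point parabola; half-max
boundaries by linear interpolation; profiles with no level above a floor
report features as absent, not zero; equal-maximum ties resolve to the
anterior peak and set a multimodality flag (shifts in this system are
anterior-ward, so a consistent anterior bias avoids sign flips).  Shifts
are peak(T1) − peak(T8), positive = anterior (toward lower %EL).  The
knockout scan re-simulates the circuit over a descending alpha sequence
(default 1, 0.6, 0.4, 0.025, 0) and summarizes each gene's level at its
wild-type T8 peak position; endpoints reproduce the wild-type and null
simulations exactly, and monotonicity in alpha is checked per gene.

## Synthetic data

Two generators serve different purposes.  The **mechanistic** generator
simulates a known ground-truth circuit forward and samples it at the
observation layout (wild type: 4 genes × (23 + 8×46) = 1564 rows; mutant:
3 genes × 391 = 1173 rows; N = 2737), so recovery and identifiability
analyses have an exact truth.  The **phenomenological** generator builds
sum-of-Gaussian domains with prescribed geometry — mutant gt drifting
exactly 15 %EL anterior (ending ~10 %EL anterior of wild type), mutant kni
drifting 1.8 %EL, mutant hb falling to half the wild-type level by T7 —
for feature-extraction and screen tests independent of any parameter set.

External inputs emulate the measured dynamics: Bcd is an exponential
gradient (length constant 21 %EL) whose amplitude declines linearly to
half between T1 and T8; Cad is a broad abdominal profile that decays from
mid-cycle while a posterior stripe spanning roughly 75–88 %EL emerges and
dominates by gastrulation; Tll is a posterior terminal sigmoid.  The hb
initial condition is an anterior-high maternal step.  Observation noise is
Gaussian with Var = c·mean + sigma0² (defaults c = 0.5, sigma0 = 2 — a
standard deviation of ~10 units at level 200, typical of integrated
fluorescence data), truncated to [0, 255].

The ground-truth parameters are a hand-tuned fixture reproducing the
qualitative posterior-half topology: Cad activation of all zygotic genes,
autoactivation, mutual *hb*–*kni* and *Kr*–*gt* repression, asymmetric
repression driving anterior shifts, Tll repression of *Kr* and *kni*, Gt
activation of posterior *hb*.  Mechanistically, Bcd+Cad would support *gt*
throughout 55–70 %EL but the Kr domain blocks it there in wild type
(Kr⊣gt strong, gt⊣Kr weak keeps the wall stable); in the null, *gt*
invades that region, overruns *kni* (gt⊣kni ≫ kni⊣gt) and its domain ends
up several %EL anterior while the advancing posterior *hb* flank erodes
its old position — reproducing the larger mutant shift.  Late-cycle level
decline follows from the decaying broad Cad input, which the invaded
region (outside the late Cad stripe) no longer compensates.  All truth
parameters are nonzero so per-parameter relative error is well defined;
four weights are deliberately inside the ±0.005 no-interaction band.

What the generators do **not** emulate: embryo-to-embryo variability and
registration error, missing observations, spatially correlated noise, the
anterior half of the embryo, *hkb* and the posterior *hb* border, and
mRNA-level delays.  Passing tests therefore demonstrate correctness of
the machinery and self-consistent recoverability, not fit quality on real
embryos.

## Problem sizes and design choices of record

- Nucleus counts 23/46 (≈1 nucleus per %EL in cycle 14A, centers at
  47 + (i−½)·45/n) follow blastoderm nuclear-density conventions; counts
  are not printed in the source material for this region.
- Cycle-14A duration is 50.0 min (8 × 6.25 min classes), giving
  gastrulation at t = 71.1 min.
- The recovery experiment estimates in two phases, mirroring the fitting
  workflow (global DEEP fit, then a warm-started local re-minimization as
  in the variance-stabilized refit).  Phase 1: DEEP with population 200 on
  2 branches for up to 1000 iterations (~2·10⁵ cost evaluations, about
  5–6 min on one core), stopping early if the cost falls below 50
  (RMS < 0.14 units).  Phase 2: bounded trust-region least-squares descent
  of the same cost warm-started at the DEEP best (~30–60 residual
  evaluations plus finite differences — well under 1% of the phase-1
  budget).  The two phases divide the labour: measured across seeds and
  DE variants (rand/1/bin, best/1/bin, adaptive with and without archive
  and with population reduction), the evolutionary phase always reaches
  the optimum's basin but ends one to two orders of magnitude short of
  convergence within a desk-scale iteration budget on this strongly
  correlated landscape — its identifiability analysis itself shows
  collinearity indices above 20 — while the local descent from any of
  those endpoints converges immediately to the same optimum.  Relative
  error is |estimate − truth|/|truth| per parameter; the median over the
  40 parameters is reported.  Weakly identifiable weights (the deliberate
  near-zero ones) carry the largest relative errors; the median
  summarizes typical parameter accuracy and lands far below 1%.
- D is not rescaled after division: the fitted coupling applies in both
  cycles, consistent with treating D in equation form.
- The package is a library: its interface is the importable API plus the
  narrative scripts in `examples/`; the readers/writers in `gapcircuit.io`
  (long-format profile CSVs, Table-style parameter CSVs, JSON run
  manifests) are the exchange surface, and `scripts/acceptance.py` is the
  one batch entry point.

## Known limitations

- The pattern screen is a fixed-threshold proxy for expert inspection;
  circuits with unusual but valid geometry could be misjudged.
- Confidence intervals assume independent, normally distributed residuals
  after the transform; strongly correlated parameters make the intervals
  conservative (overestimated), which is precisely what the collinearity
  screening is for.
- The graded-knockout monotonicity check uses fixed reference points; a
  domain that moves across a reference point could register
  non-monotonically even for a monotone underlying response.
- Recovery accuracy is assessed on noise-free data; with realistic noise
  the optimum itself moves, and parameter uncertainty is then the subject
  of the identifiability machinery rather than the recovery experiment.
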