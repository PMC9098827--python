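# Methods

This note documents the model underlying `genmod`, the conventions and
numerical choices the implementation makes where several were possible,
and the limits of what the shipped tests demonstrate.

## The generalized model and its normalization

A generalized model is the class of ODE systems sharing a declared
structure: variables $X_i$, processes $P(X_{d_1},\dots)$ contributing
with a fixed sign to one or more equations, and declared dependency
sets.  Two standing assumptions make the normalization well-defined:

1. all variables and process rates are strictly positive (a process
   that can run backwards must be declared as two antagonistic one-way
   processes — the schema enforces this);
2. every variable has at least one gain and one loss process, so
   positive steady states exist within the class.

Normalizing $x = X/X^*$ and $p = P/P^*$ moves every steady state under
study to the all-ones point, where every normalized process runs at
rate 1.  The prefactors become scale parameters:

* **turnover** `alpha_v` (units 1/time): the per-unit total gain rate of
  variable $v$ at the steady state.  Stationarity (total gain = total
  loss) is enforced *by construction* — gain and loss groups share one
  turnover symbol — so parameterizations describing impossible steady
  states are unrepresentable rather than filtered after the fact.
* **branching weights** (dimensionless, per (variable, sign) group): the
  share of the turnover carried by each process.  A $k$-way group keeps
  $k-1$ free symbols in process-declaration order; the last weight is
  $1-\sum$ of the others, so the sum-to-one constraint holds identically
  in every downstream expression.  Gain weights are named `beta_<proc>`,
  loss weights `sigma_<proc>` (a variable suffix is added only when a
  shared process needs distinct weights in different equations).

The unknown derivatives become **elasticities** `p_v` = $\partial\ln
P/\partial\ln X_v|_*$, one symbol per *declared* (process, variable)
pair; undeclared pairs are structural zeros of the Jacobian.  Entry
$(i,j)$ of the generalized Jacobian is
$\alpha_i\sum_P \mathrm{sign}(P,i)\,w_{P,i}\,\theta_{P,j}$, linear in
every elasticity.

**Timescale normalization.** One turnover can always be removed by
measuring time in units of a reference variable's turnover time; the
remaining `alpha_v` symbols are then turnover *ratios* (e.g. predator
metabolic rate relative to prey).  The operation is idempotent for a
fixed reference.

## Constraints

Constraints are applied in a fixed order: explicit inner forms first,
then function compositions innermost-to-outermost (cycles rejected),
then derivative conditions.  This mirrors how the pieces feed each
other: closed forms supply numbers, compositions consume them.

* **Explicit inner forms** (e.g. per-capita consumption $C = F/Y$) are
  log-differentiated symbolically and evaluated at the normalized point
  (all referenced quantities equal 1).  For a power-law form $aX^p$ the
  result is exactly $p$, independent of $a$ and of the steady state.  A
  form whose elasticity does not reduce to a number there is rejected.
* **Function compositions** $G = H(A_1, A_2, \dots)$ replace the outer
  process's elasticities via the chain rule,
  $g_v = \sum_k h_{a_k}\,\partial\ln A_k/\partial\ln x_v$, introducing
  outer elasticities such as $h_f$, $h_c$ that can be fixed to numbers
  (e.g. $h_f=1$ for constant conversion efficiency).  An elasticity
  symbol like $c_y$ denotes only the explicit-argument derivative;
  indirect paths appear as separate chain-rule terms ($c_f f_y$).  For
  the conversion-efficiency example ($H(F, C)$, $C = F/Y$, $h_f = 1$)
  this yields $g_x = (1+h_c)f_x$ and $g_y = f_y + h_c(f_y-1)$.  If the
  chain rule produces a nonzero elasticity for a variable the outer
  process does not declare, the declaration is inconsistent and the
  constraint is rejected — constraints can never create entries outside
  the declared sparsity pattern.
* **Derivative conditions** ($\partial P/\partial X|_*=0$, e.g.
  evolutionary or allocation optimality) pin the corresponding
  elasticity to zero.
* **Conservation laws** keep the Jacobian at full size — the stricter
  notion of stability, in which perturbations violating the law are
  admissible — and record flux-matching relations on the scale
  parameters: for a shared process moving conserved quantity from $i$
  to $j$, $c_i w_{P,i}\alpha_i X_i^* = c_j w_{P,j}\alpha_j X_j^*$.  The
  unknown abundance ratio $X_j^*/X_i^*$ is represented by a symbol
  `chi_<j>_<i>`; this bookkeeping is an extension of the toolkit (the
  relations are recorded, not substituted), adequate for single
  conservation laws but not a full flux-mode treatment of many
  simultaneous conservation constraints in large metabolic systems.

## Ensemble stability analysis

Scalar parameters are sampled uniformly on user ranges; branching
groups uniformly on the simplex (flat Dirichlet), which weights all
admissible branchings equally — componentwise-uniform-then-renormalize
would not.  Stability is the strict sign of the leading eigenvalue's
real part; the boundary counts as unstable.  Ties on the real part are
broken by larger imaginary modulus, and of a conjugate pair the member
with $\mathrm{Im}\ge 0$ is reported.  The eigenvalue backend is dense
up to 200 variables, iterative (largest real part, with dense fallback)
above; for the shipped fixtures everything is dense.

The parameter–stability score is the **Pearson correlation** between a
parameter column and the 0/1 stability indicator, so a parameter that
fully explains stability scores $\pm 1$; the raw covariance is
available behind `normalized=False`.  When every sample has the same
label the score is undefined and NaN is returned with a warning.

PSW sweeps clamp 1–2 parameters to grid values and randomize the rest;
each cell draws from an independent child seed of the global seed, so
cells are reproducible and order-independent.  Identical (ranges, M,
seed) give bitwise-identical ensembles.

Default illustrative ranges: elasticities $[0,2]$ (constant through
quadratic response, the span a Holling type-III response can produce),
turnover ratios $[0.1, 10]$ (allometric spread), outer conversion
elasticities $[-1, 1]$.  All overridable; correlations are
sampling-dependent, so ranges should encode actual prior knowledge.

## Press response and importance scores

The steady-state shift under a sustained (press) perturbation with
direct impact vector $p$ (units of normalized turnover) is
$\delta=-J^{-1}p$; an element $0.05$ is a 5% increase.  A *loss* of a
fraction $\epsilon$ of a variable's turnover enters as $-\epsilon$ in
$p$ (the classic harvesting example prints the resulting components
with this sign convention).  The solve is guarded by condition number:
warning above $10^8$, error above $10^{12}$, since the linearization
presumes distance from any bifurcation.

Sensitivity and influence are $\mathrm{Se}_i=\log\sum_n
|v_{n,i}|/|\lambda_n|$ and $\mathrm{In}_i=\log\sum_n
|w_{n,i}|/|\lambda_n|$ with right eigenvectors $w_n$ normalized to unit
length and left eigenvectors $v_n$ scaled to $v_n\cdot w_n=1$ (rows of
the inverse eigenvector matrix).  Using $|\lambda_n|$ and component
moduli keeps the scores real for complex pairs and reduces to
$-\lambda_n$ for real stable spectra; the bi-orthogonal normalization
makes the scores invariant under eigenvector rescaling.  Dynamical
importance is the product $\mathrm{Se}_i\cdot\mathrm{In}_i$.  Unstable
states yield formal scores with a warning; defective Jacobians are
rejected.

## Bifurcation detection

Zero-eigenvalue (saddle-node-type) points: det $J$ is evaluated on an
initial bracketing grid along the path (default 200 points — cheap
relative to eigensolves and adequate for the fixture systems; any hit
is also validated against the eigenvalue view) and sign changes are
refined by Brent's method to the requested tolerance.

Hopf points: the largest real part among genuinely non-real eigenvalues
is tracked along the path and its sign changes bisected; a hit must
have a non-real pair ($|\mathrm{Im}|>$ tol) *and* $|\det J|>$ tol,
excluding zero-eigenvalue crossings.  Eigenvalue tracking was chosen as
the primary detector because it is robust at any system size; the
algebraic alternative — the determinant of the bialternate product
$2J\odot I$, which vanishes when two eigenvalues sum to zero — is
provided as a cross-check for small systems (its expressions degrade
beyond roughly ten variables).

Diagram grids classify each cell as `stable`, `unstable_oscillatory`
(non-real leading pair — the Hopf side) or `unstable_real` (the
saddle-node side), with the non-axis parameters either fixed
(deterministic diagrams) or randomized PSW-style behind an option.
Three-parameter grids are emitted as stacked 2-D tables; no 3-D
rendering, no continuation of bifurcation curves, no normal forms, no
codimension-2 classification.

## Realizations

Any numeric generalized parameter set is realized by giving every
process the form $w\prod_v x_v^{\theta_{P,v}}$: the value at the
all-ones point equals the turnover share (so the steady state sits at
all-ones by construction, residual checked below $10^{-10}$) and the
elasticities are the exponents, exactly.  Processes constrained by
compositions realize their *effective* elasticities.  For saturating
kinetics the template $(1+K)x/(K+x)$ has elasticity $K/(K+1)$ at 1,
giving $K=p/(1-p)$ for target $p\in[0,1)$ ($p=0$ degenerates to the
constant response; $p\ge1$ is unachievable and rejected); custom
one-shape-constant templates are solved by bracketed root finding on
$[10^{-6},10^6]$.

The round trip re-measures turnovers (gain totals at all-ones),
branching weights (term shares) and elasticities (central-difference
log-derivatives, relative step $10^{-6}$) and reports the maximum
deviation from the requested set.  This same comparison — symbolic
Jacobian vs. central-difference Jacobian of the realization — is the
toolkit's master oracle, enforced at $10^{-6}$ relative tolerance.

Pure power-law realizations carry a `degenerate_bifurcations` flag:
with every process a power law certain bifurcations of the realized
model become degenerate, which is harmless for simulation but can
distort bifurcation studies; mixing in a saturating template clears the
flag.  Only local steady-state properties are matched — global dynamics
of a realization are not constrained.

## Problem sizes and what the tests show

The shipped fixtures are deliberately small (1–4 variables): the
one-variable gain/loss system, the predator–prey pair with and without
the conversion constraint, a three-variable branching example, and food
chains of configurable length.  Test ensembles use $10^3$–$10^5$
samples — enough to pin Monte-Carlo estimates to a few standard errors
of their closed-form values.  Passing tests therefore demonstrate the
*machinery* (normalization calculus, constraint propagation, sampling
conventions, detector correctness) on structures whose answers are
known in closed form; they do not certify conclusions about any
particular empirical network, which inherit all the usual caveats of
range choice and structural completeness.  Ensembles here are synthetic
by design — generalized modeling samples hypothetical steady states,
not data — so there is no data-generating process to mis-emulate, but
results remain conditional on the declared structure and ranges.

## Known limitations

* Conventional steady-state *locations* and trajectories cannot be
  computed from a generalized model; realizations exist precisely to
  hand off to conventional tooling.
* Stability analysis covers steady states only (no Floquet analysis of
  limit cycles; model the Poincaré map instead).
* Conservation-law support records scale constraints but does not
  provide flux-mode machinery for many simultaneous laws.
* No quasi-Monte-Carlo/Latin-hypercube sampling; no arclength
  continuation of bifurcation curves.
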