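# Methods

## Model

Let P be a finite joint pmf of a target T and sources X, Y, Z.  The
maximum-entropy trivariate PID is defined on the polytope

Δ_P = { Q ≥ 0 : Q(T,X) = P(T,X), Q(T,Y) = P(T,Y), Q(T,Z) = P(T,Z) }

through the four minima m_XYZ = min MI_Q(T;X,Y,Z) and
m_ij = min MI_Q(T;X_i,X_j).  Because the three pairwise constraints fix the
target marginal, H_Q(T) = H_P(T) on all of Δ_P, and each minimization is
equivalent to maximizing the concave conditional entropy H_Q(T | scope):
a convex program with linear equality constraints and nonnegativity.

The eight decomposition parts are linear in the minima (see README); the
linear map is the inverse of the classical identity system — conservation
of MI(T;X,Y,Z) and, per source, MI(T;X_i) = SI + UI_i + UI_ij + UI_ik —
combined with the context-invariance relations that tie the trivariate
atoms to bivariate quantities (SI2(T;X_i,X_j) = SI + UI_ij and
UI2(T;X_i∖X_j) = UI_i + UI_ik).  Consequently the assembled parts satisfy
both identity families *exactly* for any input vector of minima; the
quality of the decomposition is entirely the quality of the four minima,
which is what the optimality certificates measure.

All information quantities are in bits.  Natural logarithms are used inside
the optimizer; conversion to bits happens once at reporting.  0·log 0 = 0
by continuity; zero-mass terms are skipped, never evaluated.

## Solving the minimizations

The optimization variable is indexed only over the *admissible cells*
{(t,x,y,z) : P(t,x)>0, P(t,y)>0, P(t,z)>0} — cells forced to zero by a zero
pairwise-marginal entry are excluded up front, which both matches the
feasibility structure of Δ_P and avoids log(0).  The solve is staged:

1. **Constraint propagation.**  Constraint rows touching a single
   undetermined cell pin it; iterated to a fixed point.  Highly structured
   inputs — point masses and every Copy gate, whose pairwise marginals
   determine all cells — are solved exactly here, with a zero duality gap
   by construction (the feasible set is a single point).
2. **Sequential quadratic programming** (`scipy.optimize.minimize`,
   SLSQP) on the reduced cells from a strictly feasible start.  When the
   observed pmf has boundary zeros, an interior start is found by a
   max-min-slack linear program, and cells that are zero in *every*
   feasible point are detected by auxiliary LPs and removed.
3. **Active-set Newton polish.**  Equality-constrained Newton steps on the
   currently free cells (KKT systems with a 1e-12-scaled Tikhonov term for
   the entropy-neutral directions that have zero curvature), with
   fraction-to-boundary damping and Armijo backtracking.  Cells driven to
   the boundary are fixed; fixed cells whose reduced gradient is strictly
   negative are re-seeded in a batch and the move is kept only if the
   objective actually improves.  Near the optimum this converges
   quadratically, which is what produces gate decompositions at ~1e-14
   bits.
4. **Fallbacks**, entered only when the certified duality gap exceeds
   1e-8 bits: deterministically perturbed SQP restarts along the feasible
   null space, then scipy's trust-region interior-point method
   (`trust-constr`).  The best feasible iterate is kept throughout; at
   worst the observed pmf itself (always feasible) is returned with its
   honest, large gap.

### Optimality certificates

The violation record of a solution Q is

- *primal residual*: max of |A q − b|∞ over the marginal equalities and of
  the nonnegativity violation;
- *dual residual*: the dual-feasibility violation of fitted multipliers
  (below), in nats;
- *duality gap*: a rigorous upper bound on f(Q) − min f, in bits.

The dual has a closed form worth recording.  With objective
f(q) = Σ m_j ln(m_j / g_s(j)) (m the (T,scope)-marginal of q, g its
source-configuration groups) and multipliers λ for the equality rows, the
Lagrangian dual value is λᵀb provided every group s satisfies
log Σ_t exp(c*_{t,s}) ≤ 0, where c = Aᵀλ and c* is the per-marginal-cell
maximum of c over its fiber; otherwise the inner minimization is unbounded
(f is positively homogeneous).  Because one marginal family partitions the
cells, any λ can be shifted into dual feasibility at a cost equal to the
worst group violation, so *any* multiplier estimate yields a valid lower
bound.  Multipliers are fitted by least squares to the stationarity
condition ∇f = Aᵀλ restricted to cells with positive mass (stationarity
does not hold on zero cells, which carry free bound multipliers).  The fit
resolves gaps down to roughly 1e-8 bits on degenerate problems and to
machine precision on clean ones.

A solution is reported `optimal` when the residuals meet feastol and the
gap meets abstol/reltol, `inaccurate` under the relaxed `*_inacc`
thresholds, and `failed` otherwise.  Solver tolerances (feastol 1e-7,
abstol/reltol 1e-6, relaxed 1e-3/1e-4/1e-4, max_iter 100) follow the
conventional exponential-cone solver parameter set and surface verbatim in
the configuration object and the CLI.

## Repair of errant minima

A problem is errant when any certificate component exceeds the repair
threshold (default 1e-6, matching abstol) or its status is `failed`.
Errant minima are then moved as little as possible in the least-squares
sense subject to every bound an exact vector of minima must satisfy:

- m_scope ≤ MI_P(T; scope) (the observed pmf is feasible),
- m_ij ≥ max(MI(T;X_i), MI(T;X_j)) and m_XYZ ≥ max_i MI(T;X_i)
  (monotonicity under the preserved marginals),
- m_XYZ ≥ m_ij (nested scopes),

with non-errant values held fixed.  These constraints force CI ≥ 0 and
UI_i ≥ 0 in the assembled result.  The projection is solved by SLSQP on at
most four variables.  Identity-based repair can only correct values that
violate the constraint system: a corrupted minimum that is still feasible
for the identities (e.g. m_XYZ inflated but below MI(T;X,Y,Z)) is
unchanged by any identity-respecting projection.  If the fixed values
already contradict the constraints the repair is reported infeasible and
the raw values are returned with a warning — the package always returns a
result.

For numerically challenging pmfs (many almost-null masses), masses below a
user-chosen floor can be dropped and the pmf renormalized
(`prune_small_masses`, off by default); the objective's continuity on Δ_P
makes the pruned decomposition a controlled approximation of the original.

## Bivariate hierarchy and finer synergy parts

The bivariate solver minimizes MI_Q(T;A,B) preserving (T,A) and (T,B) —
the two-source instance of the same program — and returns SI2, CI2, UI2_A,
UI2_B, which are nonnegative in the bivariate case.  Context invariance of
redundancy links the levels: SI2 computed on a source pair must equal
SI + UI_ij of the trivariate result; the package checks this on every
finer-parts run (tolerance 2e-6 bits) and reports deviations instead of
absorbing them.

The finer split of CI uses the three agglomerated runs
CI2(T; X_k, (X_i,X_j)) — the synergy that still needs X_k as a separate
partner when the complementary pair acts as one coalition source,
lexicographically encoded as a product symbol.  The in-context coalition
synergy w_ij = CI − CI2(T;X_k,(X_i,X_j)), clipped to [0, CI], measures how
much of the synergy the pair (X_i,X_j) already provides.  Sorting
w(1) ≥ w(2) ≥ w(3) gives the additive atoms

- `syn_only_<pair>` = w(1) − w(2) for the strongest pair (zero for the rest),
- `syn_shared_pairs` = w(2) (available from at least two coalitions),
- `syn_triple` = CI − w(1) (requires all three sources),

which sum to CI exactly.  This bookkeeping is this package's own
construction from the six bivariate runs; it reproduces the expected
allocations on the benchmark gates (e.g. the XOR gate with a duplicated
source attributes its full bit of synergy to `syn_shared_pairs`).  When
CI ≈ 0 the split is identically zero rather than the solution of a
singular system; when an agglomerated solve fails its atoms are reported
as unidentifiable (NaN) and the unassigned share stays in the residual.

## Synthetic benchmark families

- *Paradigmatic gates* (XOR/AND variants with duplicated or
  coalition-structured sources), uniform over their input patterns, with
  closed-form decompositions used as ground truth.
- *Copy gates*: t = (x,y,z) over independent uniform sources — a purely
  unique-information system (UI_i = log2 of the alphabet size).  Their
  marginals pin every admissible cell, so these exercise the propagation
  path and the large-system bookkeeping (up to 125 000 outcomes at
  dimension 50³), not the iterative optimizer.
- *Flat-Dirichlet random joints*: "uniformly at random over the
  probability space" is implemented as the symmetric unit-parameter
  Dirichlet over the full outcome simplex, the uniform measure on the
  simplex; one integer seed fully determines a draw.

These families cover exact ground truths, scale, and genericity, but none
of them exhibits estimation noise: the package consumes a pmf and does not
address sampling bias, so passing tests say nothing about plug-in
estimation from finite data.

## Test and benchmark problem sizes

The suite validates the gates at 1e-9 bits against analytic references
(confirmed independently by a multi-restart brute-force minimizer over the
full outcome grid), the Copy sweep in-suite over sizes {10,20,30} and in
the acceptance script over the full {10,…,50} grid, oracle equivalence on
50 random all-binary joints at 1e-5 bits, and the qualitative trend that
growing |Z| (2→14 with 100 draws per size) drains the unique information
of the binary sources toward Z.  These sizes keep the default suite in the
minutes range on one CPU while covering every code path; they are choices
of this package, not limits of the method.

## Known limitations

- Optimal *solutions* (not values) can be non-unique along
  entropy-neutral directions; only the optimal value and its certificates
  are contractual.
- The dual-fit certificate saturates around 1e-8 bits on problems with
  degenerate fibers; reported gaps below that level should be read as
  "at certificate resolution".
- Very large unstructured joints (alphabets ≳ 20 per variable) leave the
  dense polish path and rely on the interior-point fallback alone;
  convergence there is slower and statuses should be inspected.
- Negative SI or UI_ij values are a documented property of the measure
  under deterministic dependencies, not a numerical defect; they are
  returned as computed.
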