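# Methods

## Model

Every branch of a dendritic tree is a uniform passive cylinder obeying

    dV/dt = D d2V/dx2 - V/tau,    D = lambda^2/tau,    lambda = sqrt(a R / 4 Ra),

with continuity of potential and conservation of axial current
(`1/r = pi a^2 / 4 Ra` per unit length) at branch points, and sealed
("closed", zero axial current) or grounded ("open", zero potential)
terminals.  The membrane time constant `tau = R C` must be uniform over the
tree; per-branch overrides of `R` are accepted only with a compensating `C`.
Diameters may jump discontinuously at nodes; a branch is always a uniform
cylinder.

The Green's function — the voltage at `x` on branch `i` for a delta-current
of unit charge at `y` on branch `j` — is the walk expansion

    G_ij(x, y, t) = 1/(pi a_j C) * sum over trips of A_trip Ginf(L_trip, t)

where a trip is any node walk from `x` to `y` (reflections and
pass-throughs in arbitrary number), `L_trip` is its electrotonic length
(every traversed segment divided by its branch's lambda), `Ginf` is the
free-space heat kernel with leak, and `A_trip` multiplies one factor per
node visit: `2 p_k` (pass onto branch k), `2 p_k - 1` (reflect at an
internal node), `+1`/`-1` (closed/open terminal), with
`p_k = a_k^{3/2} / sum a_m^{3/2}` for uniform membrane and
`p_k ∝ (lambda_k r_k)^{-1}` otherwise.  Node factors sum to one at every
node, which makes the summed trip coefficients O(1) at every truncation
depth (checked exactly via the matrix method's column sums).

Reciprocity: the bare kernel sums satisfy
`H_ji(y,x) = (D_j r_j)/(D_i r_i) H_ij(x,y)`; including the `1/(pi a C)`
prefactors the voltage Green's function is exactly symmetric under endpoint
exchange for uniform membrane, as the reciprocity theorem for passive
networks requires.  `reciprocal()` implements the full identity (with the
`a C` ratio), and the test suite verifies symmetry against exhaustive
enumeration on trees with heterogeneous diameters.

## Units

Internally: lengths in micrometres, times in milliseconds, `C` in uF cm^-2,
`R` in Ohm cm^2, `Ra` in Ohm cm, with the conversions applied once when a
branch's electrotonic quantities are derived.  The resulting series value,
multiplied by `MV_PER_NA_MS = 1e5`, is the response in millivolts to an
impulse of 1 nA ms.  A `dimensionless` mode applies the defining formulas
verbatim for non-dimensionalised model trees.  `Ginf(L, 0) := 0` for
`L > 0`; the `1/sqrt(t)` singularity of the self-kernel at `L = 0, t -> 0`
is never evaluated by the series route (coincident `x = y` is served by the
matrix method after local refinement, or by the finite-difference solver).

## Trip generators

*Four classes.*  The four shortest trips are distinguished by the departure
direction from `x` and the arrival direction at `y`; they seed the grammar.
When `x` and `y` share a branch, the seeds are the direct segment, the two
single-reflection walks and the double reflection.

*Grammar enumeration.*  Longer trips are derived by inserting two-node
"excursions" (`...n... -> ...n m n...`).  Two restrictions make the
derivation unambiguous: excursions may not be inserted before the most
recently inserted one (a leftmost derivation), and an excursion at node `n`
towards `m` is allowed only when the branch `nm` is directed `n -> m`,
where every branch is directed away from `x` and `x`'s own branch away from
`y`.  Equivalence with exhaustive walk enumeration (set equality, zero
duplicates) is asserted up to 10-11 node visits on three geometries.  For
the degenerate same-branch case the seeds cannot derive every
departure/arrival combination, and the generator falls back to exhaustive
prefix expansion, which is still duplicate-free and ordered.  Cyclic
structures are rejected: "away from a point" is undefined on them.

*Length-priority enumeration.*  Trips are emitted in non-decreasing
electrotonic length by a best-first search over walk prefixes (priority
queue keyed by exact accumulated length; completed trips re-enter the queue
keyed by their final length; ties broken lexicographically on the node
sequence).  This realises the k-shortest-walks ordering that Eppstein's
implicit-representation algorithm computes; the search keeps explicit
prefixes, trading Eppstein's O(1)-per-trip bound for simplicity, which
matches the O(kn)-per-trip coefficient evaluation that dominates anyway.
The first 500 emissions coincide with the sorted brute-force enumeration on
a depth-4 tree.

*Brute force.*  Breadth-first expansion of all walks, intended as the
oracle at small node budgets (the walk count grows like 3^k on degree-3
trees).

## Monte-Carlo estimator

A walk starts at either node adjacent to `x`'s branch (probability 1/2
each) and hops with transition probability `p_k` of the branch stepped
onto.  Every prefix whose final step crosses `y`'s branch is a trip; its
kernel value, weighted by the running product of importance ratios
(coefficient/probability: 2 for a pass, `(2p-1)/p` for a reflection, 1 at a
closed terminal), contributes to the estimate, and the leading factor 2
compensates the first-step probability.  The second step needs care: a
return along `x`'s own branch is a reflection, so its weight is
`(2p-1)/p`, not 1 — with that convention the exact expectation over the
enumerable walk space reproduces the node-count-truncated trip series to
machine precision, which the suite asserts for several truncation depths.
Open terminals substitute -1 in the terminal clause (experimental: only the
closed case has a published weight).  `kmax` defaults to the hop count
covering the diffusion range `6 sqrt(4T/tau)` (electrotonic) at the
shortest branch.  The estimator reports a per-time-point standard error and
is bit-reproducible from its seed.

The per-walk estimate is heavy-tailed (the weight product is typically
`2^hops`), so the k^-1/2 error decay is visible only in the
variance-dominated regime.  On the depth-4 benchmark tree the fitted
log-log slope over 125-8000 walks is about -0.49; the deep-tree condition
is scaled down to depth 5 (slope about -0.46 over 250-16000 walks), since
at depth 6 and beyond the regime is not reached at feasible walk counts.

## Matrix method

The tree is discretised into edges of one electrotonic length `dx`
(`round(el/dx) >= 1` per branch, maximum relative distortion reported; the
electrotonic-step interpretation lets diameters vary per branch).  The
modified directed-edge adjacency matrix Q holds the step coefficient from
edge to edge (`Q[i, j]`: from `e_j` to `e_i`); with equal radii and degree
<= 3 its entries are `2/3`, `-1/3`, `1`, every row and column sums to one,
and the worked 6x6 example on the Y structure is reproduced entry for entry
(exactly, in rational arithmetic, via `build_q(..., exact=True)`).
Iterating the sparse product `c_{k+1} = Q c_k` (never a dense power) costs
O(|E|) per step; trips are grouped into the four classes, and all trips of
a class travelling `k` edges share the length

    L1 = dx (k - 2 + x + y),  L2 = dx (k - 1 - x + y),
    L3 = dx (k - 1 + x - y),  L4 = dx (k - x - y),

i.e. `k dx` minus the untravelled stubs of the first and last edges, with
`x dx` the distance from `x` to `s2` and `y dx` from `g1` to `y`.  Classes
only receive coefficient mass at edge counts of the right parity, so the
pairing with the recursion is exact; the grouped sums are validated against
exhaustive enumeration on the Y structure and on a random 8-branch tree
with mixed diameters.  When `x` and `y` fall on one edge the whole tree is
re-discretised at `dx/2, dx/4, ...` until they separate (one common `dx` is
required throughout).  A whole-tree sweep reuses one iteration of the two
start vectors for every goal edge simultaneously.  Self-convergence reaches
relative L1 1e-15 between `kmax` and `2 kmax` once the diffusion range is
covered.

## Reference solver and metrics

The Crank-Nicolson solver integrates the branched cable in electrotonic
coordinates with a finite-volume assembly: junction flux weights
`1/(r lambda) ∝ a^{3/2}` reproduce the node factors, charge is conserved
exactly (total charge decays as `e^{-t/tau}` on sealed trees, asserted to
1e-4), and open terminals are Dirichlet rows.  The unit-charge impulse at
`y` becomes an initial condition deposited with linear weights into the two
bracketing cells; the first step is replaced by four backward-Euler
substeps (Rannacher smoothing) to damp the ringing a delta excites in
Crank-Nicolson.  The observed spatial order over an 8-fold refinement is
about 2.1, and against closed-form kernels the default resolution
(`dx_el = 0.005-0.01`, `dt = tau/1000`) is accurate to a few 1e-6 relative
L1 on the benchmark trees.

The convergence error is the normalised L1 distance
`eps = int |G - V*| dt / int V* dt` over `(0, T]` by composite trapezoid.
Both the first crossing of a threshold and the sustained stay-below
statistic are exposed; the benchmark trip counts quote first crossings
because the error oscillates around thresholds for long stretches on these
trees (see below).

Centroid delay `P_xy = t^_x - t^_y` and log-attenuation
`L_xy = log(int G_y dt / int G_x dt)` integrate the traces with an
exponential tail correction fitted on the last decade of samples.  The
`t = 0` sample is excluded: at the injection site the finite-difference
trace carries the deposited discrete delta, which is an artifact (its
inclusion biased attenuation ratios by ~15%; after exclusion the residual
against the closed-form steady-state ratio on a sealed cable is ~3%,
dominated by the unresolved `1/sqrt(t)` mass below the first time step).
Additivity of `P` and `L` along a chain holds to a few percent at the
default quadrature, and `A_xy >= 1` when `y` is the injection site.

## Benchmark conditions

The convergence benchmark uses a depth-4 full binary tree (a root branch
plus three bifurcation levels; depth d has 2^d nodes, matching the deep
tree's 65,536 nodes at depth 16).  Three parameter sets: A (dimensionless:
L = 0.3, a = 0.05, D = 1, tau = 1, C = 1) and B/C (physical: L = 50/100 um,
a = 1 um, D = 2.5e4 um^2/ms, tau = 3.3 ms, C = 1 uF/cm^2).  `x` sits at the
midpoint of a first-bifurcation branch and `y` at the midpoint of a
terminal branch of the opposite subtree; the error horizon is T = 5 tau
with dt = tau/1000.  These placements and grids are this package's
documented defaults — the trip counts to reach a threshold are sensitive to
all of them, so cross-study comparisons should be made in order of
magnitude only.  Under these conditions: set C first reaches eps < 0.1
after ~15 trips and sets A and B after ~1e3 and ~6e3 trips; the eps curve
then oscillates around the threshold for hundreds of trips before settling,
exactly the irregular convergence that makes trip-count prediction
unreliable on real morphologies.  At the 1e-3 threshold the in-range trip
population on this tree is combinatorially too large for the series route
(no crossing within 2e5 trips; the error plateaus near 3e-3), while the
matrix method reaches 1e-15 in milliseconds — the motivation for preferring
it on anything but the smallest problems.

## What the synthetic data does and does not cover

The generators produce ideal trees: uniform or randomly drawn cylinder
diameters, exact binary topology, noiseless geometry.  Real
reconstructions add features the benchmarks do not probe: hundreds of
branches with orders-of-magnitude length variation (which drives the
pathological trip orderings seen on real cells), radius jitter encoded at
sample points (handled by the SWC reader's averaging/collapsing rules, and
optionally by splitting at radius changes), somatic compartments (the soma
is collapsed to a point here), and active conductances (out of scope:
passive membrane only, uniform tau).  Passing tests therefore demonstrate
the correctness of the machinery and its convergence behaviour on model
trees, not convergence-rate guarantees on arbitrary morphologies.

## Known limitations

- Time-domain series require uniform tau; quasi-active membranes and
  frequency-dependent somatic shunts would need a Laplace-domain treatment.
- The Monte-Carlo route needs `x` and `y` on different branches and suffers
  heavy-tailed variance on electrotonically compact trees.
- The matrix method assumes one electrotonic step; multi-step
  generalisations are not implemented.
- Centroid/attenuation integrals truncate at T with an exponential tail
  correction; traces that have not decayed by T trigger a warning.
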