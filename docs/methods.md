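# Methods

`lactonet` simulates networks of identical pituitary lactotroph model
cells coupled by gap junctions, infers functional (synchrony) networks
from burst overlap, and relates them to the structural (coupling) graph
through centrality statistics.

## The cell model

Each cell has four state variables: membrane potential `V` (mV), free
cytosolic Ca²⁺ `c` (µM), delayed-rectifier K⁺ activation `n`, and BK
channel activation `b`:

    C_m dV/dt = −(I_Kdr + I_Ca + I_BK + I_SK + I_L + I_c)
    τ_n dn/dt = n∞(V) − n
      dc/dt   = −f_c (α I_Ca + k_c c)
    τ_b db/dt = b∞(V) − b

with ohmic currents `I_Kdr = g_Kdr n (V − V_K)`,
`I_Ca = g_Ca m∞(V) (V − V_Ca)`, `I_BK = g_BK b (V − V_K)`,
`I_SK = g_SK s∞(c) (V − V_K)`, `I_L = g_L (V − V_L)`, Boltzmann
activation `x∞(V) = 1/(1 + exp((ν_x − V)/l_x))` for x ∈ {n, m, b}, and
Ca²⁺-gated SK activation `s∞(c) = c²/(c² + k_SK²)`.  The fast variables
m and s are algebraic (quasi-equilibrium), never integrated.  The
gap-junction current of cell i is `I_c,i = Σ_{j∈N_i} g_c (V_i − V_j)`
over its structural neighbors; coupling is symmetric and conserves
charge exactly.

Units are pF / mV / ms / nS / pA / µM throughout, under which every
term of dV/dt is pA/pF = mV/ms.  With the default parameters
(`lactonet.CellParams`) an uncoupled cell produces pseudo-plateau
bursting: depolarized plateaus near −20 mV carrying small decaying
spikes, separated by silent phases near −65 mV.

Two entries of the reference parameter table required interpretation.
The printed rows "l_n | 1 mV" and "l_m | 12 0mV" are read as
l_n = 10 mV and l_m = 12 mV — a single displaced zero between two
adjacent rows.  These are the standard slope factors for n∞ and m∞ in
this lactotroph model family, and the package's validation experiments
(two-cell coupling sweep, center/satellite outcomes, multi-arm census)
reproduce the published network behavior only under this reading; with
l_n = 1 mV the two-cell system retains a large antiphase basin up to
~100 pS and the multi-arm network never synchronizes completely, both
contradicting the reported results.  Likewise "k_c | 0.12 µM" is a pump
*rate* (1/ms): it multiplies `c` in dc/dt.

## Integration protocol

Classical fixed-step 4th-order Runge–Kutta at Δt = 0.5 ms, no adaptive
stepping.  A bank of K initial conditions for the same network is
integrated as one (4n, K) array by a compiled (numba) kernel; column k
is bit-identical to a separate run of the same initial state.  The
coupling term is accumulated edge-wise over voltage *differences*, so
identical cells experience exactly zero coupling current and the
synchronous manifold is invariant to machine precision.  Halving Δt
leaves burst counts and active-phase durations unchanged within one
sample.

Each trial integrates `t_total = 400 s` and analyzes the final
`t_analysis = 10 s`.  The long transient is deliberate: with coupling
conductances of a few pS, the relative phase of two cells drifts on an
O(100 s), Ca²⁺-mediated timescale, and after shorter transients (e.g.
50 s) roughly half of random-IC pair trials are still in transit
between the synchronous and antiphase attractors (similarity between
0.2 and 0.99).  By 400 s pair trials classify cleanly at every coupling
studied.  For larger networks (the 16-cell multi-arm tree) cluster
states keep coarsening on even longer timescales — between 400 s and
800 s part of the within-ring-subset states merge into whole-ring and
fully synchronized states — so the multi-arm class counts depend on the
chosen transient; the package reports the 400 s protocol and exposes
`t_total` in `SimulationConfig`.

Initial conditions are sampled per cell as V ~ U(−75, −10) mV,
c ~ U(0, 1) µM, n, b ~ U(0, 1): the V box spans the K⁺ reversal to
above the plateau, the c box spans the oscillation range, and the box
demonstrably reaches both attractors of the coupled pair.  An "IC bank"
drawn once is reused across an entire coupling sweep so that every g_c
value sees bit-identical initial states.

## Synchrony and functional networks

A cell is *active* while V > −40 mV (midway between silent and plateau
levels; the plateau's small spikes stay above threshold, so no
debouncing is needed).  Active phases are maximal runs of
above-threshold samples, as intervals [t_first, t_last + Δt); durations
are sample counts × Δt.  For cells i, j with total active durations
T_i, T_j overlapping for T_ij, the similarity is

    S_ij = T_ij / √(T_i T_j)

computed by exact interval intersection (a per-sample boolean AND is
the test oracle; on a shared grid the two agree exactly).  S = 0 by
convention if either cell never bursts.  A *functional network* joins
pairs with S_ij > θ; θ = 0.99 demands near-perfect synchrony, θ = 0.85
is the relaxed criterion.  Two-cell runs are classified synchronized
(S > 0.99) or antiphase — the pair's only other attractor.  Multi-arm
trials are classified from the functional graph's synchrony clusters
(connected components among non-isolated nodes): `complete` (all
pairs), `ring` (clusters exactly the concentric rings), `subgraph`
(every cluster strictly inside one ring), else `other`.  The strict
cluster==ring criterion is conservative: states with one near-miss pair
(S marginally below θ) fall into `subgraph`/`other` rather than `ring`.

## Structural networks and centralities

Generators produce the coupled pair, center/satellite stars, multi-arm
trees (ring r of the default 5×3 tree holds nodes 5(r−1)+1 … 5r, so the
published edge labels (2,7), (5,7), (7,10) are reproducible), and
100-node configuration-model graphs with degree law p(k) ∝ k^−2.8
truncated to [1, n−1], realized by stub matching and simplified by
dropping self-loops and collapsing multi-edges.  Connectedness is not
forced.  The Erdős–Rényi baseline of a functional network redraws its
exact edge count uniformly over distinct pairs (G(n, M)).

Centralities of the structural graph: degree; closeness in the
component-corrected normalized (Wasserman–Faust) form, which remains
defined when an edge removal disconnects the graph; betweenness
normalized by pair count excluding endpoints; eigenvector centrality by
power iteration (tolerance 1e−10) on A + I per connected component
(the identity shift guarantees convergence on bipartite components),
max-normalized to 1.  All four match brute-force oracles (BFS distance
sums, exhaustive shortest-path enumeration, dense eigendecomposition)
on every ≤20-node graph in the test suite.

For a per-node centrality value v and a functional edge set ℰ, the
centrality-difference metric is `M = Σ_{(i,j)∈ℰ} |v_i − v_j| / |ℰ|`
(undefined, and an error, for edgeless networks).  Each functional
network is paired with its own rewired baseline and the two M samples
are compared with a two-sided Wilcoxon signed-rank test.  "Centrality
density" is a Gaussian KDE (Silverman bandwidth) of the node values
evaluated at each node's own value; functional degree vs density is
summarized by Pearson correlation (Spearman available).

## Problem sizes and determinism

The experiment drivers default to the study's trial counts (100 trials
for the pair sweep and multi-arm census, 1000 for the star sweep, 100
IC sets for the scale-free analysis); every driver takes a single
master seed and derives per-purpose streams via `SeedSequence`, so all
outputs are bit-reproducible.  The scale-free analysis holds one fixed
structural realization (`network_seed`, default 0) while initial
conditions vary with the master seed, mirroring the study design of one
network probed by many initial-condition sets; density-correlation
statistics in particular vary appreciably between realizations, so
conflating the two seeds would mix realization variance into
quantities the design treats as IC-ensemble statistics.  The reproduction script
(`scripts/acceptance.py`) runs the star sweep at 200 trials per degree
and the scale-free analysis at 32 IC sets, with tolerances widened
accordingly (binomial sampling error); counts over IC sets are scaled
proportionally when compared against per-100 figures.

## Known limitations

- Identical cells only: no conductance heterogeneity and no channel
  noise, so synchrony is exact on the synchronous manifold in a way real
  lactotroph networks never are; thresholded similarity on real Ca²⁺
  imaging data would need the θ = 0.85-style relaxed criterion.
- The multi-arm census (and any cluster-state statistic) depends on the
  transient length because cluster coarsening never truly stops; only
  the two-cell classification is demonstrably asymptotic.
- The configuration-model degree bounds [k_min, k_max] and the
  multi-edge policy are package choices; the degree sequence is only
  approximately power-law after simplification.
- Fixed-step explicit RK4 is the study's method; no error control is
  attempted beyond the Δt-halving robustness check.
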