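# Methods

## Model

The simulator implements a self-organizing recurrent network (SORN) of
binary threshold neurons in discrete time: `N^E` excitatory units and
`N^I = round(0.2 N^E)` inhibitory units.  `W^EE` (excitatory-to-excitatory)
and `W^EI` (inhibitory-to-excitatory) start as sparse random matrices with
connection probabilities 0.1 and 0.2; `W^IE` (excitatory-to-inhibitory) is
all-to-all, row-normalized, and fixed.  Inhibitory-to-inhibitory
connections and self-connections do not exist.  Entry `W_ij` is the
strength of the synapse from neuron `j` onto neuron `i`.

State update (Heaviside Θ with the convention Θ(0) = 0):

    x_i(t+1) = Θ( Σ_j W^EE_ij x_j(t) − Σ_k W^EI_ik y_k(t) − T^E_i + ξ^E_i )
    y_i(t+1) = Θ( Σ_j W^IE_ij x_j(t) − T^I_i + ξ^I_i )

with independent Gaussian membrane noise ξ ~ N(0, σ²_ξ) drawn per neuron
per step.  One time step corresponds roughly to one STDP window (~20 ms).

Five plasticity rules act on every step:

1. **STDP** (excitatory): ΔW^EE_ij = η_STDP (x_i(t) x_j(t−1) −
   x_i(t−1) x_j(t)).  Weights driven to ≤ 0 are removed from the topology
   (eliminated, not clamped).
2. **Inhibitory STDP**: ΔW^EI_ij = −η_inhib y_j(t−1) (1 − x_i(t)(1 +
   1/μ_iSTDP)); weights clamp at 0, the EI topology never changes.  The
   rule balances at P(x_i = 1 | y_j(t−1) = 1) = μ_iSTDP/(1 + μ_iSTDP).
3. **Structural plasticity**: with probability p_c = 0.2 per step, one new
   synapse of strength 0.001 appears between a uniformly chosen
   unconnected ordered excitatory pair.
4. **Synaptic scaling**: every nonempty row of W^EE is divided by its sum,
   so each excitatory neuron's summed excitatory input is exactly 1 at the
   end of every step.
5. **Intrinsic plasticity**: T^E_i ← T^E_i + η_IP (x_i(t) − H^IP_i), with
   per-neuron target rates H^IP_i ~ U[μ_IP − σ_HIP, μ_IP + σ_HIP].
   Thresholds are unbounded after initialization; clamping would bias the
   homeostatic fixed point.

### Default parameters

| parameter | default | meaning |
|---|---|---|
| μ_IP | 0.1 | target firing rate (spikes/step) |
| σ_HIP | 0 | half-width of the target-rate interval |
| η_IP | 0.01 | threshold adaptation rate |
| η_inhib | 0.001 | inhibitory STDP rate |
| μ_iSTDP | 0.1 | inhibitory STDP balance constant |
| η_STDP | 0.004 / 0.002 / 0.001 | for N^E ≤ 400 / 600–800 / ≥ 1000 (sizes between bands use the band below) |
| p_c | 0.2 | structural-plasticity rate (synapses/step) |
| T^E_max, T^I_max | 1, 0.5 | initial threshold ranges |
| σ²_ξ | 0.01 | membrane noise variance (accepted range [0.01, 0.05]) |

Initial `W^EE` values are drawn from a uniform, folded-normal ("gaussian"),
delta (all equal) or exponential distribution and each nonempty row is
normalized immediately, so the scaling invariant holds from step 0.
Initial `W^EI` values are uniform and deliberately *not* row-normalized
(the inhibitory STDP rule rescales them dynamically; nothing in the model
constrains their initial sum).

### Step composition and determinism

One canonical step applies, in order: draw noise → activity update →
history shift → STDP → inhibitory STDP → structural plasticity →
synaptic scaling → intrinsic plasticity.  Scaling runs after all weight
changes so the row-sum invariant is exact at the end of every step;
intrinsic plasticity runs last so it sees the just-computed activity.

All randomness flows through one seeded `numpy.random.Generator` with a
fixed draw protocol per step (excitatory noise vector, inhibitory noise
vector, structural coin, rejection-sampled pair — at most 64 tries, then a
uniform draw over the enumerated free pairs).  Floating-point summations
are defined to be sequential in ascending index order.  Together these
choices make the simulation reproducible bit for bit, and the test suite
verifies the compiled engine against an independently written
straight-line Python implementation at that level.

The compiled kernels store `W^EE` densely (zero = absent synapse; existing
synapses are strictly positive) next to explicit row/column adjacency
lists, which keeps the per-step cost proportional to the number of
existing synapses and active neurons rather than N².

## Analyses

**Motif census.**  The weight matrix is binarized (edge j→i iff
`W^EE_ij > 0.01`, strictly) and weakly-connected induced 3- or 4-node
subgraphs are counted by directed isomorphism class.  Classes are named by
a canonical code: the minimum over node permutations of the bit-packed
off-diagonal adjacency (exact for k ≤ 4).  The 3-node census enumerates
all connected triples in a compiled kernel; the 4-node census uses an ESU
(exhaustive subgraph enumeration) recursion and is intended for graphs up
to a few hundred edges.  Significance is assessed against random digraphs
with identical node and edge counts placed uniformly (edge-count matching
removes one variance source relative to matching the probability only).
The empirical p-value of a class is the fraction of null graphs containing
it *strictly* more often than the observed graph, so p ∈ [0, 1] and small
p means over-representation; ties favor the observed network.

**Pools.**  Pools (synfire layers) are connected components, of size ≥ 2,
of the graph linking neuron pairs whose Pearson activity correlation
exceeds a threshold; singletons are reported as unassigned.  The default
threshold is 0.2: in stabilized networks a neuron participates only
partially in its pool's activations (the target rate 0.1 is below
1/ring-length), which bounds within-pool pairwise correlations of the
binary trains well below 1 — empirically they concentrate around 0.25–0.55
while cross-pool correlations stay below ~0.05 (pools alternate, so
cross-pool correlations are weakly negative).  Any threshold inside that
gap recovers identical partitions; 0.2 sits in its middle.  Correlations
are estimated from a trailing raster of 5000 steps (`corr_window`): with
several rings alternating on a slow homeostatic timescale, a 500-step
window can miss a suppressed ring entirely.

**Rings.**  The pool-level edge strength A→B is the average over neurons
of B of the fraction of their surviving excitatory input mass contributed
by members of A.  Because synaptic scaling fixes each neuron's total input
at 1, this measure is size-invariant; a binarized connection-density
measure is not, since homeostasis bounds each neuron's number of strong
synapses so block densities shrink as pools grow (at N^E = 400 the
densest pool-to-pool blocks fall below 30% while still carrying ~100% of
the input mass).  An edge exists when A supplies at least half of B's
input (threshold 0.5); each pool follows its strongest outgoing edge, and
the cycles of this successor map are the rings — pool graphs are tiny, so
the greedy successor construction finds exactly the visually evident
block-cycles.  Maximal non-cyclic successor paths are reported as chains.

**Weight distribution.**  Summary statistics of log10 surviving weights
(deciles, skewness, max/min dynamic range) plus a unimodality check: the
30-bin log-histogram is smoothed with a 3-bin moving average and modes are
peaks with prominence ≥ 10% of the maximum.

## Experiments

*Perturbation insertions* plant `count` strong synapses (default 0.1, i.e.
stronger than ~70% of existing weights), one every `period` = 500 steps,
within one layer or from a layer to the layer two steps ahead, and track
each weight until elimination or a 10,000-step horizon.  *Structural-fate
tracking* follows every synapse created by structural plasticity during
the stable phase, classifying it as on-route (connecting a pool to its
ring successor) or off-route.  *Ablations* disable chosen mechanisms
(their updates become no-ops) and report ring formation plus a "healthy
regime" flag: trailing mean rate within μ_IP ± 0.05 and no step with more
than half of the excitatory units simultaneously active.  *Sweeps* run
replicated simulations along μ_IP ∈ [0.025, 0.125], σ_HIP ∈ [0, 0.08] or
N^E ∈ [200, 800] with seeds derived deterministically from (base seed,
setting, replicate).

**Planted fixtures.**  The generator builds block-cyclic (or terminating
chain) weight matrices — consecutive-pool synapses present with
probability 1 − ε, spurious synapses elsewhere with probability ε, rows
normalized — and matching rasters that activate pools in sequence with
per-neuron flip probability ε.  These fixtures emulate the *structure* of
a developed synfire ring, not the dynamics that produce it: there is no
partial pool participation, no slow alternation between rings and no
homeostatic drift, so analysis tests passing on fixtures demonstrate
correctness of the detection pipeline, not emergence of the structure
(the long-run acceptance tests cover that).

## Problem sizes and study battery

Emergence results are verified on a desk-scale battery chosen to keep a
full verification run practical on one CPU: two 200-neuron networks
(10^6 steps; the connection count typically plateaus at ~4–6 × 10^5) and
five 400-neuron networks (8 × 10^5 steps), instead of the hundredfold
larger batteries (and up to 4 × 10^6 steps) a cluster-scale replication
would use.  Consequences of this choice:

* The feed-forward motif check uses the *intersection* semantics of the
  original claim — classes over-represented in **every** network of the
  battery — with a 3-network battery.  A single network whose ring happens
  to have exactly 3 pools legitimately over-represents the directed
  3-cycle (one neuron per pool); such run-specific classes vanish from the
  intersection, while the feed-forward fan-in/fan-out/chain classes remain.
* Multi-ring formation is checked as "≥ 1 of 5 networks at N^E = 400
  develops ≥ 2 disjoint rings".  At 400 neurons the STDP rate is still
  0.004, so structure forms within ~6 × 10^5 steps; at 800 neurons
  (η_STDP = 0.002) formation needs several million steps, which is out of
  desk-scale reach.  The multi-ring probability rises with network size,
  so this is the conservative end of the claim.

## Known limitations

* Binary neurons, synchronous updates, one-step delays: no conduction-
  delay heterogeneity and no refractoriness beyond the homeostatic rules.
* The 4-node census is exponential in practice for dense stable-phase
  graphs (millions of connected tetrads); it is meant for fixtures and
  binarized graphs at higher thresholds.
* Ring extraction assumes scaling has normalized inputs; for matrices from
  other sources the input-mass fractions are computed after an internal
  row normalization.
* Pool detection by thresholded correlations cannot separate pools that
  never alternate within the recorded raster; the `corr_window` default
  (5000 steps) covers the alternation timescales seen at these sizes.
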