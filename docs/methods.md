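# Methods

This note documents the models, estimators, default parameters, and
numerical choices in `specgen`, including where a design was genuinely
open and what the package chose. Nothing here reports an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## 1. Synthetic recordings (`specgen.synth`)

### Stimulus design

`make_stimulus_design` enumerates a categories × exemplars × views
passive-viewing design. Defaults: 6 categories (animal, vehicle, face,
vegetable, house, tool), exemplar counts (9, 8, 10, 8, 5, 11) — each
within 4–11, 51 in total, the animal category at 9 — and 24 views per
exemplar, i.e. 1224 conditions. Eleven exemplars carry the binary
"spiky" feature flag by default; the flag is constant within an exemplar.

### Response model

The response of neuron *n* to condition *s* is

    r_ns = max(0, baseline + (1 − w)·(signal_ns + noise_ns) + w·(a_n · z_s))

with private tuning `signal_ns = gain_n · 1[cat(s) = pref(n)] · (1 +
eps_exemplar + eps_view)`, `gain_n = baseline·(gain_ratio − 1)` (so the
noiseless unmixed preferred/non-preferred mean ratio is exactly
`gain_ratio`), Gaussian exemplar/view modulations with user-set SDs, and
i.i.d. Gaussian noise. `w = shared_factor_weight ∈ [0, 1]` is the
interconnectivity proxy.

The shared latent is a **convex pooling** term, not a purely additive
one: lateral interconnectivity is modeled as each neuron mixing its
private tuning with a population-shared signal, which also averages out
private noise (hence the `(1 − w)` factor on signal *and* noise). The
latent `z_s` stacks

* a **categorical block** (rank 5): half-normal factors per category with
  nonnegative loadings, scale 2.0 — a shared nonnegative activation
  profile per category. Nonnegativity matters: pooled excitatory input is
  a rate-like, nonnegative quantity, and it guarantees that pooling grows
  every category centroid away from the origin. (With signed categorical
  factors, categories drawn negative are rectified toward zero rate,
  which erases their centroid and can invert the radius contrast on
  particular seeds.)
* a **conditional block** (rank 3): signed white factors per condition,
  scale 0.15. Because the private signal shrinks as `(1 − w)`, even this
  small block dominates the *shape* of within-category variability at
  high `w`, compressing the within-manifold dimension, while the total
  within-category spread still shrinks.

Consequences the test suite verifies: higher `w` lowers the participation
ratio and the anchor-geometry dimension and radius, and raises
within-category representational similarity — the direction of the
recorded contrast between a densely and a sparsely interconnected
region. A deliberate side effect: at `w = 0.8` pooling flattens all
category tuning ratios below 2, so *no* neuron passes the strict 2×
selection criterion; pipeline stages fall back to population-level scores
in that case.

### Lattice patterns and stimulus encodings

`generate_lattice_patterns` builds four rectangular category clusters.
The default layout tiles the lattice into quadrants, which makes the four
±1 patterns exactly orthogonal and hence genuine Hopfield attractors.
`corner_cluster_layout` instead leaves background sites (−1 in every
pattern); with the literal Hebbian sum such sites couple *positively* to
each other (+4/N) and to every cluster (+2/N), and cross-cluster weights
are exactly 0 in both layouts — the "inhibitory cross-cluster
connections" reading of the anti-Hebbian rule is not realizable with
four exhaustive ±1 patterns, only weight *absence* or background-mediated
positive coupling. The corner layout also makes the stored patterns
strongly correlated (background overlap), so they are not stable
attractors; it is provided for studying exactly that effect.

`encode_stimulus` sets an exact `floor(overlap·|cluster|)` count of +1
sites per cluster. Three spatial arrangements:

* `scatter` — uniform random subset (spatially white);
* `block` — one contiguous region grown from a seeded corner;
* `field` — the top-k cells of a multi-scale Gaussian random field
  (per-stimulus `field_scales`, default σ ∈ {0.5, 1, 2, 4, 8}).

The arrangement matters because the lattice dynamics coarse-grain the
stimulus at the wiring length scale: white scatter is destroyed
identically by *any* coupling range (all-or-none threshold at fill 0.5),
whereas multi-scale structure lets each wiring length preserve a
different amount of stimulus detail. The model batteries therefore use
`field` encodings.

## 2. Tuning metrics (`specgen.tuning`)

Conventions where the procedure was underdetermined:

* selection requires the preferred-category mean to be **≥** threshold ×
  the max other-category mean (boundary counts as selected), and a
  category is retained only if **strictly more than** `min_neurons`
  (default 5) neurons qualify;
* the per-repeat exemplar subsample size defaults to the smallest
  category size; 20 repeats; all subsampling is seeded;
* means are arithmetic means of raw rates, no baseline subtraction;
* view-level generalization is the per-exemplar min/max ratio across that
  exemplar's views, averaged over exemplars (not pooled across views);
* the SD-based generalization index uses the population SD (divisor n);
* `rsm` computes Pearson correlations between condition vectors on raw
  rates; constant conditions are reported as NaN rows/columns. Note that
  only a *global* affine rescaling leaves these correlations unchanged —
  per-neuron rescaling reweights neurons and genuinely changes the RSM;
* zero denominators in a specificity/generalization repeat are excluded
  with a warning; ties in the "maximum non-preferred mean" are resolved
  by `max` (first category in enumeration order wins), deterministically;
* the balance score min-max normalizes specificity and generalization
  across the compared conditions and sums them (range [0, 2]); it is
  undefined (error) when either array is constant.

## 3. Manifold geometry (`specgen.geometry`)

Representations (conditions in neuron space) are segmented with Louvain
modularity maximization on a symmetrized k-NN graph (k = 15, Euclidean
distances, Gaussian edge weights with bandwidth equal to the largest
retained neighbor distance — near-uniform weights inside a homogeneous
cloud so that cluster separation comes from graph topology, not the
kernel). Louvain is `networkx.algorithms.community.louvain_communities`,
seeded.

`anchor_geometry` implements the anchor-point estimator as a margin-κ
support problem per Gaussian probe (κ = 0 default, 500 probes): the cloud
is centered on its centroid and scaled by the centroid norm; at κ = 0 the
anchor for probe `t` is the extremal vertex `argmax ⟨t, s⟩` (exact
solution of the linear support problem); for κ > 0 a projected-gradient
ascent on the simplex (tolerance 1e-8) solves `max ⟨t, Sα⟩ − κ‖Sα‖`.
`D_M` is the mean squared alignment of probes with unit anchors, `R_M`
the root-mean-square anchor norm. Everything is computed in the row space
of the centered cloud via the Gram matrix, with probes drawn in that
basis — this makes `D_M`/`R_M` *exactly* invariant to global rotations of
the ambient space and caps `D_M` at the cloud rank.

Per-neuron z-scoring before geometry is exposed but **off by default**:
centering puts the grand-mean state at the origin, and any manifold whose
centroid passes near the origin makes the centroid-normalized radius
ill-conditioned. Raw nonnegative rates keep the centroid norm of order
`baseline·√n_neurons`.

The region protocol subsamples 100 neurons × 20 repeats (30 × 30 for
small per-animal pools), segments, and averages `D_M`/`R_M` over
manifolds with ≥ 5 points.

## 4. The attractor lattice (`specgen.lattice`)

Conventions:

* the EDR adjacency is sampled once per unordered pair (symmetric), no
  self-connections; both choices are needed for the energy to be a
  Lyapunov function under deterministic updates;
* distances are Euclidean in lattice units (unit spacing); λ is quoted at
  the 200 × 200 reference scale and rescaled by `200/L` on an `L × L`
  lattice so `exp(−λd)` is preserved at the cluster length scale;
* one "iteration" is one single-unit update; the external field enters
  through the weighted neighbor sum, `b_i = Σ_j w_ij (s_j + H_j)`, as
  printed — a `field_mode="direct"` variant adds `H_i` to `b_i` instead;
* resting-state noise is an independent Rademacher (±1) input per weight
  per iteration (resampled every use);
* at `β = ∞` updates become the deterministic sign rule with ties keeping
  the current state (required for monotone energy descent);
* stimulus runs use the encoded state both as the initial condition and
  as a sustained bottom-up field of amplitude 1; top-down perturbations
  add ±2 (twice the predefined ±1 state values).

### Reduced-scale protocol sizes

Full-scale runs (200 × 200, 150 000 iterations) correspond to only ~3.75
updates per site, so the scored states are mid-relaxation, not the
infinite-time consensus. All desk-scale protocols therefore match
**updates per site**, not raw step counts, on the default 40 × 40
lattice:

* λ-sweep: 10 000 steps (6.25 updates/site), 10 paired repeats with
  common random numbers across λ (same adjacency draws, encodings, and
  update noise per repeat index — a variance reduction for ordering
  comparisons);
* perturbation: epochs 3200/3200/10000 (2/2/6.25 updates per site,
  matching the 80k/80k/250k schedule). The per-site match is
  load-bearing: a deeper top-down epoch suppresses the face cluster
  below its basin of reattraction and the miss condition then fails to
  recover;
* resting state: three independent 16 000-step runs (10 updates/site)
  from random states, snapshots every 100 steps, Hamiltonians averaged.

The sweep grid is (0.0, 0.05, 0.075, 0.1). On a 40 × 40 lattice, nominal
λ below ≈ 0.04 has a mean interaction distance `2/λ_scaled` larger than a
cluster, making it dynamically indistinguishable from λ = 0; the grid
spans only the resolvable regime.

### Stimulus batteries

Face-specificity battery (face-cluster fills): human face 0.9;
shape-sharing and configuration-sharing objects 0.55/0.52 with *coarse*
activation blobs (scales 2–4), expressing that look-alike objects share
coarse configural structure with faces; familiar object 0.05.
Face-generalization battery: face views and cross-species faces with
fills 0.9 down to 0.6 at *intermediate-fine* scales (1–2). Fills are
chosen weakly face-correlated (> 0.5) because a fill below 0.5 is
*anti*-correlated with the face pattern in ±1 coding and is simply
extinguished under global wiring. Scores average the face-cluster
activation fraction over the last third of recorded samples; specificity
is face/max-other, generalization min/max over the face family; manifold
D/R are anchor-geometry estimates over the stabilized face-family states.

## 5. Energy landscape and path lengths (`specgen.landscape`)

The parametric embedding is UMAP (15 neighbors, min-dist 0.1, fixed seed)
on states restricted to 1000 uniformly sampled lattice sites, reproduced
by an MLP regressor with hidden layers (1000, 100), ReLU, and a 2-unit
output; the energy surface is a Delaunay-based linear interpolation of
state energies over the embedded plane.

Path lengths along relaxation trajectories are reported two ways:

* `path_length` — the literal summed Euclidean hop length of embedded
  waypoints (the 2-D parametric embedding; a 3-D variant including the
  energy axis is a matter of stacking the energy column);
* `excess_path_length` / `path_length_sweep` — the hop lengths in the
  *native* state space minus each trajectory's own stationary noise floor
  (median hop length over the second half of the recording), summed over
  the positive part.

The excess measure is what the λ-ordering analysis uses. Rationale: a
stochastic trajectory mixes directed basin-settling with stationary
boundary flicker and domain-wall diffusion, whose per-hop magnitude
*grows* with λ (sparser wiring → smaller, more granular local fields →
more zero-field boundary sites). Summed over the 15 waypoints this noise
floor dominates the raw path at desk scale and inverts the ordering; at
desk scale the 2-D embedding (trained on ~10× fewer states than the full
protocol) additionally distorts metric structure by more than the path
differences. Subtracting the stationary floor isolates the directed
component, which orders cleanly: global wiring pulls diverse inputs far
into deep attractors (long paths), local wiring leaves states near their
inputs (short paths). The protocol drives the network with diverse
random-fill, contiguous-block stimuli (an analog of a large random image
battery).

## 6. Ising reference (`specgen.ising`)

`H = −J Σ_⟨ij⟩ s_i s_j`, each neighboring pair counted once;
"first-ring" adjacency is read as the 4-neighbor von Neumann ring
(8-neighbor Moore available); open boundaries by default (comparable to
the model's sheet), periodic for the exact-result check. Metropolis
single-spin-flip from the ordered start, with running-energy tracking;
`n_equil` attempts discarded, `n_sample` accumulated; optionally
`n_replicates` independent chains averaged per temperature.

Numerical choices in `temperature_sweep`: the specific heat is the
central finite difference of H(T) after a light Savitzky–Golay smoothing
(window 7, order 3; differencing amplifies per-temperature Monte Carlo
noise), and the critical point is the *centroid of the top quarter of the
specific-heat peak* rather than the bare argmax, which jumps between
grid points when the finite-size peak is broad. `H_c` is interpolated at
that temperature. A fluctuation-dissipation estimate `Var(H)/T²` is
returned as a cross-check; near criticality it needs long chains
(~10⁷ attempts at L = 32) to agree with the finite-difference value.
The desk-scale matched sweep uses 40 temperatures in [0.5, 6] at
200k/100k steps × 3 replicates.

`criticality_report` classifies a resting Hamiltonian as near-critical
when `|H_rest − H_c| ≤ 0.2·|H_c|`, ordered below, chaotic above; 0.2 is
the default band and is configurable.

## 7. Pipeline and seeds (`specgen.pipeline`, CLI)

A single master seed derives independent per-stage sub-seeds through
`numpy.random.SeedSequence` spawn keys (all below 2³¹); identical configs
reproduce byte-identical CSV outputs. Scale presets: `test` (smoke),
`desk` (every qualitative comparison on one CPU), `full` (published
protocol sizes; the 200 × 200 / 500-temperature settings are expensive
and not exercised by the test suite).

## 8. Limitations

* The synthetic recording generator reproduces the *statistical
  structure* the metrics need (category gain, exemplar/view variability,
  pooling-induced correlation); it does not emulate spike-count
  statistics, temporal dynamics, or realistic tuning-curve shapes.
  Passing tests demonstrate internal consistency and parameter recovery,
  not properties of any real dataset.
* Stimulus encodings are abstract overlap codes; there is no image
  front end, and the per-stimulus fills and blob scales are modeling
  choices that define the study conditions, not measured quantities.
* The literal Hebbian sum over four exhaustive ±1 patterns cannot produce
  negative cross-cluster weights (see §1); cluster competition in this
  model is mediated by the sustained stimulus field and, with background
  layouts, by background units.
* Desk-scale λ grids resolve only wiring lengths whose interaction range
  is smaller than a cluster; conclusions about denser grids (e.g.
  distinguishing 0.01 from 0.023) require the full 200 × 200 lattice.
* The 2-D parametric embedding at desk scale is a visualization aid; the
  quantitative path-length ordering uses the native state space (§5).
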