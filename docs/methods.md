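# Methods

`fcnet` analyzes weighted functional-connectivity graphs built from per-ROI
resting-state timeseries, the way rodent fMRI cohort studies do: per-subject
Pearson correlation with Fisher's variance-stabilizing transform, proportional
density thresholding over a sweep, weighted graph metrics referenced to
strength/degree-preserving null networks, consensus Louvain community
detection, and threshold-free AUC summaries feeding group statistics.  A
synthetic cohort generator with planted modular covariance stands in for
in-vivo data, so every stage is testable end to end.

## Synthetic cohort generator

Each subject's node × time matrix is drawn from a zero-mean multivariate
normal with a block correlation matrix: unit diagonal, `rho_within` for pairs
in the same planted module, `rho_between` otherwise, plus independent
Gaussian sensor noise of standard deviation `noise_sd`, after which each node
series is L2-normalized (Pearson correlation is invariant to that
rescaling, so normalization is cosmetic but mirrors how ROI signals are
exported).  Defaults encode the emulated study design:

| parameter       | default                  | rationale |
|-----------------|--------------------------|-----------|
| groups          | 10wo / 30wo / 60wo       | three adult age groups |
| n_per_group     | 10                       | emulated cohort size (N = 30) |
| n_nodes         | 60                       | ICA-derived ROI count |
| n_timepoints    | 600                      | timeseries length per ROI |
| module_sizes    | 4 × 15                   | simplest balanced modular layout |
| rho_within      | 0.5 (all groups)         | strong but realistic intra-network coupling |
| rho_between     | 0.05 / 0.10 / 0.15       | group effect: lower coupling = more modular (young) |
| noise_sd        | 0.5                      | attenuates correlations by 1/(1+σ²) = 0.8, typical of fMRI SNR |
| seed            | required                 | master seed; per-subject streams spawned deterministically |

The additive-Gaussian noise model is the simplest one consistent with
Pearson-correlation analysis.  Validity of a spec is checked up front,
including positive semi-definiteness of the implied block covariance
(smallest eigenvalue ≥ −1e−10).

What the generator does *not* emulate: BOLD hemodynamics and autocorrelation,
anesthesia effects, scanner noise spectra, motion artifacts, hub/rich-club
degree structure, or spatial embedding.  Consequently, passing tests show
that the analysis chain recovers *planted covariance structure* from
realistic sample sizes and noise — not that it reproduces any in-vivo
finding.  In particular, group effects that arise from real brain topology
rather than from modular coupling (e.g. assortativity differences) are only
weakly induced by this design; see "Known limitations".

Toy behavior tables draw per-group Gaussian measures (open-field margin
distance, daily freezing counts, sucrose/water volumes), truncated at zero on
physical grounds; group labels without their own effect profile fall back to
the reference (30wo) means.

## Connectivity and thresholding

Pairwise Pearson r over node timeseries; z = atanh(r) with |r| clipped at
1 − 1e−7 to keep z finite; diagonal exactly zero.  For independent series the
sampling SD of z is 1/√(T−3) ≈ 0.0409 at T = 600, which the tests verify by
simulation.

Proportional thresholding retains the top `round(δ · N(N−1)/2)` edges ranked
by **signed** z (strongest positive first): downstream metric formulas
(clustering, rich club) assume nonnegative weights, and at the densities of
the sweep the retained edges are positive in practice.  Rounding is
half-away-from-zero; ties at the cutoff break by lexicographic (i, j) node
order, so edge sets are deterministic and nested across the density sweep.
The default sweep is 6–32% in 2% steps (14 levels) with nodal metrics at 16%
(283 of 1,770 edges at N = 60, mean degree 2E/N ≈ 9.43).

An optional bootstrap edge-significance operation resamples subjects,
forms percentile CIs of each edge's mean z, and reports the smallest
significant |r| and the implied density; on global-null cohorts the implied
density calibrates to the nominal α (percentile CIs are mildly
anticonservative at small subject counts).

## Graph metrics (conventions held fixed)

- **Clustering / transitivity**: Onnela geometric-mean triangle intensity on
  weights normalized by the network maximum; transitivity is the global
  analogue Σ2tᵢ / Σkᵢ(kᵢ−1).  Nodes with degree < 2 get CC = 0.
- **Paths**: length = 1/weight, Dijkstra; CPL averages finite pairwise
  distances (undefined and flagged when no pair connects); global efficiency
  averages 1/d with disconnected pairs contributing 0.
- **Local efficiency**: global efficiency of each node's neighbor-induced
  subgraph on max-normalized weights (in [0, 1]); < 2 neighbors gives 0.
- **Assortativity**: Pearson correlation of endpoint degree (or strength)
  over the symmetrized edge list.  Zero endpoint variance (regular graphs)
  yields NaN — deliberately distinct from an assortativity of 0.
- **Participation coefficient**: P = 1 − Σₘ (d_im/d_i)², degree-based, with
  P = 0 for isolated nodes; a strength-weighted variant is available but is
  not the primary definition.
- **Small world**: γ = T/⟨T_rand⟩, λ = CPL/⟨CPL_rand⟩, SWC = γ/λ against a
  randomized ensemble.  The lattice-referenced measure is the ω-style
  SWM = ⟨CPL_rand⟩/CPL − T/T_latt.  No canonical equation exists for the
  "small-world measure" in the source literature trail; this convention is
  documented rather than asserted to match any published table, and both the
  ensemble size (default m = 100, configurable; smaller in the bundled
  analyses) and the lattice construction are explicit parameters.
- **Rich club**: for each k, the club is the subgraph of nodes with degree
  strictly greater than k; Φ_w(k) = (club weight) / (sum of the E_club
  largest weights network-wide); Φ_norm divides by the ensemble mean curve.
  Levels with fewer than 2 club nodes, no club edges, or a zero/undefined
  ensemble mean are NaN, never silently zero.

## Null models

Signed matrices are randomized by sign-aware pair exchanges: entries of
(a,b),(c,d) swap with (a,d),(c,b) only when the first two carry one sign
class and the targets another (absent edges count as a class).  Every
accepted swap preserves each node's positive and negative degree exactly and
works on full signed matrices, where the two signs jointly occupy all pairs.
"~5 swaps" is interpreted as 5 swap passes over each sign's edge list
(candidates drawn per class so acceptance stays usable when one sign is
rare); the feasible amount of rewiring is bounded by the room the opposite
class leaves, which is a property of the ensemble, not a failure.  Networks
with a single sign class take a fast path of ordinary degree-preserving
double-edge swaps.

Weights are then re-assigned per sign by greedy re-sorting: the largest
remaining weight goes to the edge with the largest product of residual node
strengths, updating residuals at each step.  This preserves the weight
multiset exactly and tracks the original strength sequence closely (the
defining fidelity property of this null model; measured by the acceptance
script).  A random-rank assignment variant was evaluated and discarded: it
degrades strength fidelity substantially, which defeats the null model's
purpose.

The lattice reference uses the same swap machinery but accepts only swaps
that reduce total |i−j| node-index distance, then places the largest weights
on the most band-central edges — an "artificial non-ring lattice" with the
original degree sequence and weight multiset.

## Community detection

Q is Newman–Girvan weighted modularity; single runs use seeded Louvain
(networkx) on the positive-weight thresholded network (resolution fixed at
1).  Because a "median of node assignments" over label vectors is
ill-defined, stability over n_iter = 100 restarts is obtained by consensus
clustering: the co-assignment matrix is thresholded at τ = 0.5 and
re-clustered until every restart agrees; the median of the per-run Q values
is reported alongside the consensus partition's own Q (recomputed on the
original network).  Module labels are canonicalized by descending size.  If
no node pair is stable at τ (not observed on any tested graph), the
highest-Q run is used as a fallback rather than failing.

## Group statistics

Metric profiles over the sweep are reduced by trapezoidal AUC on the raw
density axis in fraction units (the 6–32% sweep spans 0.26; axis scaling is
a constant factor and cancels in group comparisons).  Nodal contrasts across
the 60 ROIs use Benjamini–Hochberg FDR (statsmodels).  The multivariate step
is correlation-matrix PCA (variables standardized — the 9-variable table
mixes units); the observed percent inertia of the first two dimensions is
judged against the 95th percentile of the same quantity over ≥ 2000 simulated
standard-normal tables of identical shape, a parallel-analysis-style
reference.  Group-level ANOVAs on AUCs are delegated to standard routines
(scipy) in the analysis scripts; the library guarantees tidy inputs for
them.  Global assortativity is reported in degree mode; on this synthetic
design the strength-mode variant carries no group signal.

## Behavioral indices

Sucrose preference S_I = (s − w)/(s + w), defined only when s + w > 0.  The
fear-conditioning session is a 180 s baseline then four 20 s tones each
followed by a 190 s interval (17 min total); each trial contributes one 60 s
quantification epoch anchored at tone onset (20 s pre-shock + 40 s
post-shock).  Bouts must last ≥ 30 frames at 30 fps (1 s); a bout is counted
in the epoch containing its *start* (the counting rule is otherwise
unspecified in the source protocol), while percent-time freezing uses
overlap durations — both are emitted since their interconversion is not
fixed.  Motion-index samples are averaged within the same epochs; empty
epochs are NaN, not zero.

## Problem sizes in the bundled checks

The tests and acceptance script choose sizes that keep the whole suite
desk-scale while leaving the study conditions intact where they matter:
planted-partition recovery uses 50 subjects at full 100-restart consensus;
direction recovery uses 20 independent two-group cohorts of n = 10 at the
full 14-level sweep with Q as the median of 5 restarts per density;
null-model ensembles in unit tests use m = 5–10.  The PCA reference uses
2000 simulated tables.

## Known limitations

- The generator's group effect lives entirely in between-module coupling.
  Modularity-based contrasts are recovered robustly; assortativity contrasts
  are only weakly induced (via shared-node sampling covariance of
  correlation estimates) and their direction is not reliable at n = 10 —
  an inherent property of the block design, reflected honestly by the
  direction-recovery check.
- Percentile bootstrap CIs for edge significance are anticonservative for
  small cohorts.
- Consensus clustering guarantees agreement, not global Q optimality;
  Louvain is exact only on the tiny graphs where the test suite enumerates
  all partitions.
- The SWM lattice reference and the rich-club boundary convention
  (strictly-greater-than-k club) are fixed choices among several defensible
  ones; changing them changes absolute values but not group contrasts.
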