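# Methods

This note documents the models, numerical choices and known limitations of
the package, in the order the pipeline runs.

## Network construction

Pearson correlation matrices are computed per subject from regions × time
matrices; any zero-variance region is an error naming the region. Fisher
z-transformation (`atanh`, with |r| clipped at 1 − 1e−7 to stay finite) is
available for group-level averaging of correlations, but **binarization
thresholds raw r, not z**: the conventional 0.3 cutoff is quoted on the
correlation scale, and the two operations are otherwise independent. The
threshold is strict (`r > 0.3`; r exactly at the threshold gives no edge)
and negative correlations never form edges. Construction-rule checks
(density within 10–50%, mean degree > 2 ln N, no isolated nodes,
connectedness) are report-only at the function level; the synthetic
generator enforces them on the healthy-control group-mean network and
refuses to emit a cohort that violates them.

Group-mean networks are element-wise means of subject adjacencies, so their
weights are edge frequencies. Density and mean degree of a mean network are
computed on the weights, which makes them subject-averaged quantities.

## Eigenvector centrality

Scores are the Perron eigenvector of the binary adjacency matrix, computed
by power iteration from the uniform positive start vector with L2
normalization each step; convergence is declared when successive iterates
differ by < 1e−10 in max-norm (max 1000 iterations; non-convergence is
logged and flagged, never raised). The iteration actually multiplies by
A + I: the shift leaves all eigenvectors unchanged while making the matrix
primitive on connected graphs, so bipartite ±λ pairs (for example a path
graph) cannot make the iteration oscillate. The reported eigenvalue is the
Rayleigh quotient of A itself. Hub ranking takes the top ⌈0.10·N⌉ scores
(9 of 90), descending, ties broken by label order; the attack target is the
arg-max. By default centrality is computed on the healthy-control
group-mean network binarized at the same 0.3 threshold — the analysis
reports a single group-level hub — but the function applies unchanged to
any per-subject network.

## CLM load-capacity cascade

The efficiency graph starts at e_ij(0) = 1 on edges (unit link lengths), 0
elsewhere. Node load L_i(t) is operationalised as the **number of
shortest paths between ordered pairs (s, u), s ≠ u ≠ i, that pass through i
as an intermediate node**, with link lengths d = 1/e, unreachable where
e = 0, and *all* co-optimal paths counted (an unnormalized betweenness path
count). Path-length ties are declared at relative tolerance 1e−9. This
reading — paths through i — follows the load-capacity cascade literature
and is verified against an exhaustive path-enumeration oracle on small
graphs.

Capacities are C_i = a·L_i(0) with the loads of the *intact* network;
a ≥ 1 is the capacity tolerance (default 1.2; the analysis' downstream
comparisons do not depend on it, see below). The attack zeroes the hub's
incident efficiencies permanently — attacked edges are exempt from the
restoration branch of the update, otherwise the attack would self-heal.
Each round rebuilds every edge from its initial value:
e_ij(t+1) = e_ij(0)·C_i/L_i(t) where i is overloaded, e_ij(0) otherwise;
when both endpoints are overloaded the smaller prescription wins
(conservative, symmetric, deterministic). A node whose initial load was
zero has zero capacity, so any acquired load drives its edges to zero —
a consequence of the capacity definition worth knowing when choosing toy
networks. The run stops when no node is overloaded and the efficiency
matrix changed by < 1e−12 in max-norm, or after 100 rounds (uniform
degradation leaves shortest-path counts unchanged, so a permanently
overloaded configuration is a fixed point that terminates at max_iter;
this is reported, not raised).

Downstream group statistics use the **isolation fault matrix** — hub row
and column zeroed, all other edges untouched — which equals the cascade's
final network in the a → ∞ limit whenever no initially idle node acquires
load. The `cascade_final` mode (additionally dropping edges whose
efficiency reached 0) is provided as an extension.

## Graph indicators

Clustering c_i = 2e_i/(k_i(k_i−1)) with c_i = 0 for degree < 2, included
in the N-node mean so the mean stays defined on attacked networks; global
efficiency is the mean inverse hop distance over ordered pairs with
disconnected pairs contributing 0. Both delegate to networkx and are
checked exactly against triangle-enumeration and Floyd–Warshall oracles.

## Rich club

φ(k) keeps nodes of full-network degree strictly greater than k and takes
the edge density of the surviving subgraph; it is undefined (NaN) when
fewer than two nodes survive. The curve runs k = 1..N−1 (1..89 for
N = 90). The null model is Maslov–Sneppen degree-preserving double-edge
swap (networkx), 10 swaps per edge, one seeded rewiring per replicate
(seeds base+0..base+n−1), 100 replicates by default; φ_random(k) averages
ensemble members where φ is defined, and φ_norm = φ/φ_random where the
denominator is positive (mean-then-ratio). Degree preservation is
essential: against density-only nulls φ_norm is meaningless.

Rich nodes are the top ⌈0.10·N⌉ regions by *strength* (weighted degree) of
the healthy-control group-mean network, ties by label order, and the same
set is applied to both groups so the decomposition is comparable; a
per-group selection mode exists behind a config flag. Edge weights then
split into rich / feeder / local sums over the upper triangle; the three
sums conserve total weight exactly, by construction and by test.

## Group statistics

Two-sided independent-samples t-tests (pooled variance; Welch by flag) on
each of the three connection classes, for four contrasts: HC-vs-JME
pre-attack, HC pre-vs-post, JME pre-vs-post, HC-vs-JME post-attack, plus
matching one-way ANOVAs (F = t² for two groups, asserted in tests).
Benjamini–Hochberg FDR is applied within each contrast's family of three
classes (a single global family of 12 is available); significance is
q < 0.05, with q < 0.01 annotated separately. The pre/post comparisons are
unpaired by design choice — the protocol applies two-sample tests
throughout — though the post networks derive from the same subjects.
If a class is constant in both cells with unequal means (possible in very
small cohorts), the battery reports the smallest achievable two-sided
permutation p, 2/C(n₁+n₂, n₁), instead of an undefined t. The
duration–rich-connection association is a Pearson correlation over
patients. The one-sample t of φ_norm > 1 across subjects per degree
threshold is available (`subject_level_rich_club` pipeline flag, off by
default purely because per-subject null ensembles dominate runtime:
74 subjects × 100 rewirings ≈ minutes).

## Synthetic cohort

The generator emulates a two-group resting-state cohort: 37 + 37 subjects,
90 regions, 190 timepoints (200 acquired minus 10 discarded for scanner
equilibration), patient illness durations uniform on 12–84 months (mean
≈ 48, matching the emulated cohort's reported mean; only a mean ± SD is
known, so the distribution is a modelling choice).

The ground-truth correlation matrix is a **factor model**, positive
semidefinite by construction:

* all rich nodes load on a shared club factor → pairwise
  `base_correlation` (default 0.42) inside the rich block;
* the non-rich regions are partitioned into one community module per rich
  node, loading on a module factor → within-module
  `background_correlation` (default 0.42); each rich node also loads on
  "its" module with its residual variance budget, producing feeder
  correlations ≈ 0.46 and making rich nodes the highest-strength nodes;
* the first rich node — the hub — owns a module ~1.45× larger, so it is
  the unique top-EC region;
* in patients, the hub's club loading is reduced so hub–rich correlations
  equal `base − deficit − duration_effect·duration` (defaults 0.10 and
  0.002/month), floored at 0. The lesion is **hub-incident**: it sits
  exactly at the region the attack later removes, which is what makes the
  post-attack group difference vanish while the pre-attack difference is
  large — the mechanism the analysis is designed to detect.

A naive alternative — assigning a strong correlation to each edge of a
sparse random graph — is geometrically infeasible: a region cannot be
0.5-correlated with a dozen mutually uncorrelated regions (the PSD
constraint bounds the sum of squared correlations), and eigenvalue-clipping
repair of such a matrix shrinks the correlations below the edge threshold.
Community structure is the standard, PSD-respecting way real functional
connectivity carries many supra-threshold edges per node. A `nearest_psd`
repair (eigenvalue clipping + unit-diagonal restoration) remains as a
defensive numeric guard.

Observation noise (`noise_sd`, default 0.25) is folded into the model: the
signal covariance is inflated by 1 + σ² before independent N(0, σ²) noise
is added, so the configured correlations are exactly what sample
correlations estimate, at any noise level. This requires every region to
keep idiosyncratic variance of at least σ²/(1+σ²) + 0.01, which bounds the
admissible correlation parameters (validated with named errors).

Correlation defaults sit moderately above the 0.3 threshold on purpose: at
190 timepoints, edges then appear with probability ~0.98 rather than ~1,
giving subject networks realistic variability — with near-certain edges the
post-attack connection sums become group-constant and the comparison
degenerates. Defaults were fixed once, at design time, to satisfy the
construction rules (observed HC mean-network density ≈ 0.11, mean degree
≈ 9.9 > 2 ln 90 ≈ 9.0, no isolated nodes) and to make the planted deficit
detectable at n = 37.

What the generator does **not** emulate: hemodynamics, autocorrelated
noise, motion artifacts, spatial smoothness, inter-subject anatomical
variability, or negative correlations. Passing tests therefore show the
pipeline recovers planted structure of the assumed form at realistic n and
T — not that the clinical findings themselves are reproduced.

Two scale caveats. First, identifiability of the planted club (rich set
recovered by strength ranking, hub by EC) holds by design at the default
90-region geometry; in strongly scaled-down cohorts (e.g. 30 regions,
3 rich nodes) the hub-module members' degree approaches the other rich
nodes' and selection can miss the planted set, so recovery tests run at
the 90-region geometry with fewer subjects, while null-calibration
experiments (where identifiability is irrelevant) use the small geometry.
Second, in generated patients the hub keeps partial rich connectivity, so
the JME pre-vs-post rich contrast often reaches significance at n = 37 (a
detectable residual); the replicated
headline pattern deliberately comprises the pre-attack deficit, the null
feeder/local contrasts, the post-attack equalisation, and the HC
pre-vs-post change.

## Determinism and problem sizes

Every stochastic component (cohort sampling, structure placement, null
rewirings, replicate experiments) is driven by explicit integer seeds;
identical config + seed gives bit-identical outputs, and the pipeline
manifest records per-stage SHA-256 hashes to verify it. Test and
acceptance problem sizes — 50 random graphs for the centrality oracle,
graphs up to 7 nodes for exact enumeration oracles, 25/50 replicate
cohorts for pattern/sign rates, 500 scaled-down cohorts for null
calibration — were chosen so the whole suite completes in well under a
minute per experiment while keeping binomial Monte-Carlo error small
relative to the margins being asserted.
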