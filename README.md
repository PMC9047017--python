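# hubfail

Targeted hub-attack analysis of functional brain networks: build binary
connectomes from regional time series, find the network hub by eigenvector
centrality, damage it with the Crucitti–Latora–Marchiori (CLM) load-capacity
cascade, and measure how the rich-club organisation of the network
reconfigures, group against group.

The package is aimed at researchers studying how focal dysfunction of a
highly central brain region (for example in juvenile myoclonic epilepsy,
JME) reshapes whole-network topology, and at anyone who needs a clean,
tested implementation of the underlying graph machinery: load-capacity
cascades, normalized rich-club curves, and the rich/feeder/local connection
decomposition. Because clinical resting-state data of this kind are rarely
shareable, the package ships a seeded synthetic-cohort generator that
reproduces the statistical structure the analysis assumes, so the whole
pipeline is runnable and testable end to end with no external data.

## The model

**Network construction.** For each subject, regional time series
`x_1 … x_N` (N = 90 regions by default) are correlated pairwise (Pearson
r), Fisher z-transformed for group averaging, and binarized: an edge
`A_ij = 1` iff `r_ij > 0.3` (strict). At this threshold the network density
falls in 10–50%, the mean degree exceeds `2 ln N`, and no node is isolated.

**Hub selection.** Eigenvector centrality solves `λ x = A x` for the
Perron eigenvector by power iteration; node i's importance `x_i` is high
when its neighbours are important. The top-EC region of the
healthy-control group-mean network is the attack target.

**CLM cascade.** Each edge carries efficiency `e_ij(0) = 1`; node load
`L_i(t)` is the number of shortest paths (lengths `d_ij = 1/e_ij`, all
co-optimal paths counted) through i; capacities are fixed at
`C_i = a·L_i(0)`, `a ≥ 1`. The attack zeroes the hub's incident edge
efficiencies permanently; load redistributes, and any overloaded node
(`L_i(t) > C_i`) degrades its incident edges to `e_ij(0)·C_i/L_i(t)`,
possibly overloading further nodes — a sequential failure. Group
comparisons use the isolation fault matrix (hub row/column zeroed), the
`a → ∞` limit of the cascade.

**Topology readouts.** Clustering coefficient
`c_i = 2e_i / (k_i(k_i−1))`; global efficiency
`E_glob = ⟨1/l_ij⟩` over all pairs; rich-club coefficient
`φ(k) = 2E_{>k} / (N_{>k}(N_{>k}−1))` normalized by 100 degree-preserving
rewirings, `φ_norm(k) = φ(k)/φ_random(k)`. The top 10% of regions by
strength of the HC mean network are "rich nodes"; edges split into rich
(rich–rich), feeder (rich–non-rich) and local (non-rich–non-rich)
connections whose weights are compared across groups and attack conditions
with two-sample t-tests, one-way ANOVAs and Benjamini–Hochberg FDR
correction (q < 0.05), plus the Pearson correlation between patients'
illness duration and their rich-connection weight.

## Worked example

```python
import numpy as np
from hubfail import (CohortConfig, generate_cohort, pearson_matrix, binarize,
                     group_mean_network, network_checks, eigenvector_centrality,
                     select_attack_target, select_rich_nodes, post_attack_network,
                     decompose_connections, run_contrast_battery,
                     headline_pattern, duration_correlation)

panel = generate_cohort(CohortConfig(seed=42))          # 37 HC + 37 JME
nets = {s.subject_id: binarize(pearson_matrix(s.series, panel.region_labels))
        for s in panel.subjects}
hc_mean = group_mean_network([nets[s.subject_id] for s in panel.group("HC")])
print(network_checks(hc_mean).density)                   # QC

cv = eigenvector_centrality(hc_mean.binarize(0.3))
target = select_attack_target(cv)
rich = select_rich_nodes(hc_mean)                        # top 10% by strength

cells = {}
for s in panel.subjects:
    pre = nets[s.subject_id]
    post = post_attack_network(pre, target, mode="isolation")
    for cond, net in (("pre", pre), ("post", post)):
        cells.setdefault((s.group, cond), []).append(decompose_connections(net, rich))

results = run_contrast_battery(cells)
print(headline_pattern(results)["pattern_holds"])
```

Output of the full version of this script (see `hubfail run` below for the
file-based equivalent):

```
HC mean network: density=0.111, mean degree=9.87 (> 2 ln N = 9.00)
attack target: ROI072 (EC=0.2789, lambda=14.10)
rich nodes (9): ROI072 ROI003 ROI056 ROI090 ROI005 ROI077 ROI053 ROI028 ROI085
HC mean rich connections (pre-attack): 34.8
JME mean rich connections (pre-attack): 29.4
HCpre_vs_JMEpre      rich: t=  11.68  q=8.40e-18  significant=True
HCpre_vs_HCpost      rich: t=  22.33  q=6.43e-34  significant=True
JMEpre_vs_JMEpost    rich: t=   4.79  q=1.32e-05  significant=True
HCpost_vs_JMEpost    rich: t=  -1.21  q=6.39e-01  significant=False
headline pattern holds: True
duration vs rich connections: r=-0.533, p=0.0007
```

Reading the numbers: the generated patient group carries significantly
fewer rich connections than controls before the attack (t = 11.68,
q < 0.05 FDR) while feeder/local classes do not differ; isolating the
top-EC hub in both groups erases the group difference (post contrast
q = 0.64); the attack itself significantly reconfigures the controls'
rich club; and patients' rich-connection weight decreases with illness
duration (r = −0.53).

## Command line

```bash
hubfail run -c config.yaml            # full pipeline into an output directory
hubfail generate -o cohort --seed 1   # synthetic cohort as TSV files
hubfail build SUBJECT.tsv -o adj.tsv  # correlate + binarize one subject
hubfail centrality adj.tsv -o ec.tsv
hubfail attack adj.tsv --target ROI072 --mode isolation -o fault.tsv
hubfail richclub adj.tsv -o curve.tsv --n-random 100
hubfail stats decomposition.tsv -o contrasts.tsv
```

All tables are tab-separated text; `hubfail run` writes a JSON run
manifest with per-stage output hashes so a run can be reproduced
bit-identically from its config and seed.

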