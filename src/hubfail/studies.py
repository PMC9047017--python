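"""Replicate-level experiments built on the pipeline stages.

These helpers run the core analysis — generate a cohort, build networks,
select the hub, apply the isolation attack, decompose connections, test —
many times over independent seeds, without any file I/O, to measure how
reliably the planted effects are recovered:

* ``headline_replicate``: one full analysis, reduced to the headline
  pattern, the duration-rich-connection correlation, and whether the
  selected attack target is the planted hub;
* ``pattern_replication_rate`` / ``duration_sign_rate``: replication
  frequencies over seeds;
* ``null_rich_fpr``: the rich-contrast false-positive rate when no effect
  is planted, on a scaled-down cohort so hundreds of replicates are cheap.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import cascade, centrality, netbuild, richclub, stats
from .synthetic import GROUP_HC, GROUP_JME, CohortConfig, generate_cohort

#: scaled-down cohort for replicate-hungry null calibration experiments
SCALED_NULL_CONFIG = CohortConfig(
    n_regions=30,
    rich_set_size=3,
    n_subjects_per_group=10,
    n_timepoints=60,
    patient_rich_deficit=0.0,
    duration_effect=0.0,
)


def _subject_networks(panel, threshold):
    return {
        s.subject_id: netbuild.binarize(
            netbuild.pearson_matrix(s.series, panel.region_labels), threshold
        )
        for s in panel.subjects
    }


def _decomposition_cells(panel, nets, target, rich):
    cells: dict[tuple[str, str], list[richclub.ConnectionDecomposition]] = {}
    for s in panel.subjects:
        pre = nets[s.subject_id]
        post = cascade.post_attack_network(pre, target, mode="isolation")
        for cond, net in (("pre", pre), ("post", post)):
            cells.setdefault((s.group, cond), []).append(
                richclub.decompose_connections(net, rich)
            )
    return cells


def headline_replicate(
    seed: int,
    config: CohortConfig | None = None,
    threshold: float = netbuild.DEFAULT_THRESHOLD,
    top_fraction: float = richclub.RICH_FRACTION,
    fdr_family: str = "per_contrast",
) -> dict:
    """One end-to-end analysis of a fresh seeded cohort, summarised.

    Returns the headline-pattern booleans, the duration-rich correlation
    among patients (pre-attack), the attack target, and whether that target
    and the selected rich set coincide with the planted ground truth.
    """
    cfg = replace(config or CohortConfig(), seed=seed)
    panel = generate_cohort(cfg, validate_network=False)
    nets = _subject_networks(panel, threshold)
    hc_mean = netbuild.group_mean_network(
        [nets[s.subject_id] for s in panel.group(GROUP_HC)]
    )
    cv = centrality.eigenvector_centrality(hc_mean.binarize(threshold))
    target = centrality.select_attack_target(cv)
    rich = richclub.select_rich_nodes(hc_mean, top_fraction)
    cells = _decomposition_cells(panel, nets, target, rich)
    results = stats.run_contrast_battery(cells, fdr_family=fdr_family)
    pattern = stats.headline_pattern(results)

    jme = panel.group(GROUP_JME)
    durations = [s.duration_months for s in jme]
    rich_pre = [d.rich_sum for d in cells[(GROUP_JME, "pre")]]
    try:
        r_dur, p_dur = stats.duration_correlation(durations, rich_pre)
    except Exception:
        r_dur, p_dur = float("nan"), float("nan")

    planted_hub = panel.region_labels[panel.structure.hub_index]
    planted_rich = {panel.region_labels[i] for i in panel.structure.rich_indices}
    return {
        "pattern": pattern,
        "duration_r": r_dur,
        "duration_p": p_dur,
        "target": target,
        "target_is_planted_hub": target == planted_hub,
        "rich_set_is_planted": set(rich.rich) == planted_rich,
        "results": results,
        "cells": cells,
    }


def pattern_replication_rate(
    n_replicates: int,
    base_seed: int = 0,
    config: CohortConfig | None = None,
) -> float:
    """Fraction of seeds on which the full headline pattern holds."""
    hits = sum(
        headline_replicate(base_seed + rep, config)["pattern"]["pattern_holds"]
        for rep in range(n_replicates)
    )
    return hits / n_replicates


def duration_sign_rate(
    n_replicates: int,
    base_seed: int = 0,
    config: CohortConfig | None = None,
) -> float:
    """Fraction of seeds with a negative duration-rich-sum correlation."""
    hits = 0
    for rep in range(n_replicates):
        r = headline_replicate(base_seed + rep, config)["duration_r"]
        hits += bool(np.isfinite(r) and r < 0)
    return hits / n_replicates


def null_rich_fpr(
    n_replicates: int,
    base_seed: int = 0,
    config: CohortConfig | None = None,
    threshold: float = netbuild.DEFAULT_THRESHOLD,
    top_fraction: float = richclub.RICH_FRACTION,
) -> float:
    """Rich-contrast false-positive rate (q < 0.05) with no planted effect.

    Per replicate only the pre-attack group contrast is run: rich / feeder /
    local two-sample tests with BH correction within the family of three,
    counting replicates where the rich contrast is (spuriously) significant.
    """
    cfg = config or SCALED_NULL_CONFIG
    if cfg.patient_rich_deficit != 0 or cfg.duration_effect != 0:
        raise ValueError("null_rich_fpr requires a config with no planted effects")
    hits = 0
    for rep in range(n_replicates):
        panel = generate_cohort(replace(cfg, seed=base_seed + rep), validate_network=False)
        nets = _subject_networks(panel, threshold)
        hc_mean = netbuild.group_mean_network(
            [nets[s.subject_id] for s in panel.group(GROUP_HC)]
        )
        rich = richclub.select_rich_nodes(hc_mean, top_fraction)
        cells: dict[str, list[richclub.ConnectionDecomposition]] = {GROUP_HC: [], GROUP_JME: []}
        for s in panel.subjects:
            cells[s.group].append(
                richclub.decompose_connections(nets[s.subject_id], rich)
            )
        ps = []
        for cls in stats.CONNECTION_CLASSES:
            attr = f"{cls}_sum"
            x = [getattr(d, attr) for d in cells[GROUP_HC]]
            y = [getattr(d, attr) for d in cells[GROUP_JME]]
            try:
                _, p = stats.two_sample_t(x, y)
            except stats.DegenerateDataError:
                p = 1.0  # constant equal-looking sums cannot reject
            ps.append(p)
        q = stats.fdr_adjust(ps)
        hits += bool(q[0] < stats.ALPHA)
    return hits / n_replicates
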