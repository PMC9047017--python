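"""Group-level inference: t-tests, one-way ANOVA, Benjamini-Hochberg FDR,
the duration-rich-connection correlation, and the four-contrast battery.

The battery compares rich / feeder / local connection sums across the four
group x condition contrasts (HC vs patients before the attack, each group
before vs after, HC vs patients after), with two-sided independent-samples
t-tests (pooled variance by default), matching one-way ANOVAs, and FDR
correction applied within each contrast's family of three connection
classes (optionally one global family).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, DegenerateDataError
from .richclub import ConnectionDecomposition

ALPHA = 0.05
ALPHA_STRICT = 0.01

CONNECTION_CLASSES = ("rich", "feeder", "local")
#: (name, (group, condition) numerator, (group, condition) denominator)
CONTRASTS = (
    ("HCpre_vs_JMEpre", ("HC", "pre"), ("JME", "pre")),
    ("HCpre_vs_HCpost", ("HC", "pre"), ("HC", "post")),
    ("JMEpre_vs_JMEpost", ("JME", "pre"), ("JME", "post")),
    ("HCpost_vs_JMEpost", ("HC", "post"), ("JME", "post")),
)


@dataclass(frozen=True)
class ComparisonResult:
    """One contrast x connection-class test with its FDR-adjusted p."""

    contrast: str
    connection_class: str
    statistic: float  # t value
    f_statistic: float
    p_value: float
    q_value: float
    significant: bool  # q < 0.05
    significant_strict: bool  # q < 0.01


def _as_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size < 2:
        raise ConfigurationError(f"{name} needs at least 2 observations, got {arr.size}")
    if not np.isfinite(arr).all():
        raise ConfigurationError(f"{name} contains non-finite values")
    return arr


def two_sample_t(x, y, welch: bool = False) -> tuple[float, float]:
    """Two-sided independent-samples t-test (pooled variance unless welch).

    Two identical constant samples compare as t = 0, p = 1; a zero-variance
    comparison with unequal means is undefined and raises.
    """
    x = _as_array(x, "x")
    y = _as_array(y, "y")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        raise DegenerateDataError("zero variance in both samples with unequal means")
    res = sps.ttest_ind(x, y, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def one_sample_t(x, mu0: float, alternative: str = "two-sided") -> tuple[float, float]:
    """One-sample t-test of mean(x) against mu0 (``greater`` for phi_norm > 1)."""
    x = _as_array(x, "x")
    if x.std(ddof=1) == 0:
        if x.mean() == mu0:
            return 0.0, 1.0
        raise DegenerateDataError("zero-variance sample with mean != mu0")
    res = sps.ttest_1samp(x, mu0, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def anova_oneway(groups) -> tuple[float, float]:
    """One-way ANOVA; for two groups F equals the pooled two-sample t squared."""
    if len(groups) < 2:
        raise ConfigurationError("ANOVA needs at least 2 groups")
    arrs = [_as_array(g, f"group {i}") for i, g in enumerate(groups)]
    pooled = np.concatenate(arrs)
    if pooled.std(ddof=1) == 0:
        return 0.0, 1.0
    if all(a.std(ddof=1) == 0 for a in arrs):
        raise DegenerateDataError("no within-group variance in any group")
    res = sps.f_oneway(*arrs)
    return float(res.statistic), float(res.pvalue)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ConfigurationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def duration_correlation(durations, rich_sums) -> tuple[float, float]:
    """Pearson r (and two-sided p) between illness duration and rich weight."""
    d = np.asarray(durations, dtype=float).ravel()
    r = np.asarray(rich_sums, dtype=float).ravel()
    if d.size != r.size:
        raise ConfigurationError("durations and rich_sums must have equal length")
    if d.size < 3:
        raise ConfigurationError("correlation needs at least 3 patients")
    if d.std() == 0 or r.std() == 0:
        raise DegenerateDataError("degenerate (constant) variable in correlation")
    res = sps.pearsonr(d, r)
    return float(res.statistic), float(res.pvalue)


def run_contrast_battery(
    decompositions: dict[tuple[str, str], list[ConnectionDecomposition]],
    fdr_family: str = "per_contrast",
    welch: bool = False,
) -> list[ComparisonResult]:
    """All four contrasts x three connection classes (12 t-tests + ANOVAs).

    ``decompositions`` maps (group, condition) with group in {"HC", "JME"}
    and condition in {"pre", "post"} to that cell's per-subject
    decompositions.  FDR families: ``per_contrast`` (three classes per
    contrast, the default) or ``global`` (one family of 12).
    """
    if fdr_family not in ("per_contrast", "global"):
        raise ConfigurationError(f"unknown fdr_family {fdr_family!r}")
    cells = {(g, c) for _, a, b in CONTRASTS for g, c in (a, b)}
    missing = sorted(cells - set(decompositions))
    if missing:
        raise ConfigurationError(f"missing design cells: {missing}")

    raw: list[tuple[str, str, float, float, float]] = []
    for name, cell_a, cell_b in CONTRASTS:
        da, db = decompositions[cell_a], decompositions[cell_b]
        for cls in CONNECTION_CLASSES:
            attr = f"{cls}_sum"
            x = [getattr(d, attr) for d in da]
            y = [getattr(d, attr) for d in db]
            try:
                t, p = two_sample_t(x, y, welch=welch)
                f, _ = anova_oneway([x, y])
            except DegenerateDataError:
                # complete separation: two constant samples at different
                # levels.  The t statistic is unbounded; report the smallest
                # achievable two-sided permutation p rather than aborting.
                t = math.copysign(math.inf, float(np.mean(x) - np.mean(y)))
                f = math.inf
                p = min(1.0, 2.0 / math.comb(len(x) + len(y), len(x)))
            raw.append((name, cls, t, f, p))

    ps = np.array([row[4] for row in raw])
    q = np.empty_like(ps)
    if fdr_family == "global":
        q[:] = fdr_adjust(ps)
    else:
        for start in range(0, len(raw), len(CONNECTION_CLASSES)):
            sl = slice(start, start + len(CONNECTION_CLASSES))
            q[sl] = fdr_adjust(ps[sl])

    return [
        ComparisonResult(
            contrast=name,
            connection_class=cls,
            statistic=t,
            f_statistic=f,
            p_value=p,
            q_value=float(qv),
            significant=bool(qv < ALPHA),
            significant_strict=bool(qv < ALPHA_STRICT),
        )
        for (name, cls, t, f, p), qv in zip(raw, q)
    ]


#: the qualitative finding the analysis is designed to detect
PATTERN_KEYS = (
    "pre_rich_significant",
    "pre_feeder_null",
    "pre_local_null",
    "post_rich_null",
    "hc_prepost_rich_significant",
)


def headline_pattern(results: list[ComparisonResult]) -> dict[str, bool]:
    """Reduce a contrast battery to the headline reconfiguration pattern.

    Before the attack the patient group shows fewer rich connections
    (significant rich contrast, feeder/local null); attacking the hub in
    both groups erases the group difference (post rich contrast null) while
    reconfiguring the controls (HC pre-vs-post rich contrast significant).
    """
    by_key = {(r.contrast, r.connection_class): r for r in results}

    def sig(contrast: str, cls: str) -> bool:
        return by_key[(contrast, cls)].significant

    out = {
        "pre_rich_significant": sig("HCpre_vs_JMEpre", "rich"),
        "pre_feeder_null": not sig("HCpre_vs_JMEpre", "feeder"),
        "pre_local_null": not sig("HCpre_vs_JMEpre", "local"),
        "post_rich_null": not sig("HCpost_vs_JMEpost", "rich"),
        "hc_prepost_rich_significant": sig("HCpre_vs_HCpost", "rich"),
    }
    out["pattern_holds"] = all(out[k] for k in PATTERN_KEYS)
    return out
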