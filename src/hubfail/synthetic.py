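"""Synthetic two-group cohort of regional time series with a planted rich club.

The generator emulates the statistical structure the downstream analysis
assumes: two groups (healthy controls, HC, and patients, JME) of subjects,
each a regions x time matrix, whose group-level binary networks (Pearson
r > 0.3) carry

* a planted rich club: a designated set of regions (default 9 of 90) that
  are mutually correlated at ``base_correlation`` through a shared factor,
* community structure: the remaining regions are partitioned into one
  module per rich node, correlated within module at
  ``background_correlation``; each rich node additionally loads on "its"
  module, producing feeder edges that make the rich nodes the
  highest-strength (and highest-eigenvector-centrality) nodes.  The first
  rich node — the designated hub — owns a larger module, so it is the
  unique top-centrality region,
* a patient deficit: in the JME group the correlations between the hub and
  the other rich nodes are reduced by ``patient_rich_deficit`` plus
  ``duration_effect`` per month of (uniformly drawn) illness duration.
  The deficit is hub-incident: the patients' lesion is planted exactly at
  the region the attack simulation will later target.

The ground-truth matrix is a correlation matrix of the *observed* series:
the signal covariance is inflated by 1 + noise_sd^2 before independent
observation noise is added, so configured correlations are what the sample
correlations estimate.  The factor construction is positive semidefinite by
design; a nearest-PSD repair (eigenvalue clipping + unit-diagonal
restoration) is applied defensively if numerics ever push it below zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import netbuild
from .errors import ConfigurationError, GenerationError

#: extra idiosyncratic variance floor beyond what the noise inflation needs
_IDIO_MARGIN = 0.01
#: hub module is this factor larger than the other modules
_HUB_MODULE_SCALE = 1.45

GROUP_HC = "HC"
GROUP_JME = "JME"


@dataclass(frozen=True)
class CohortConfig:
    """Cohort dimensions and planted effect sizes.

    Defaults mirror the emulated study: 37 subjects per group, 90 regions,
    190 retained timepoints (200 acquired minus 10 discarded), a 9-node rich
    club (top 10% of 90), and illness durations drawn uniformly from 12-84
    months (mean ~48).  Correlation defaults sit moderately above the 0.3
    edge threshold so subject networks vary realistically from sample to
    sample, with the deficit sized to be detectable at n = 37.
    """

    n_regions: int = 90
    n_subjects_per_group: int = 37
    n_timepoints: int = 190
    rich_set_size: int = 9
    base_correlation: float = 0.42
    background_correlation: float = 0.42
    patient_rich_deficit: float = 0.10
    duration_effect: float = 0.002  # correlation lost per month of illness
    duration_range_months: tuple[float, float] = (12.0, 84.0)
    noise_sd: float = 0.25
    seed: int = 0

    @property
    def idio_floor(self) -> float:
        """Minimum idiosyncratic variance every region must keep so the
        noise-inflated signal covariance stays positive semidefinite."""
        ns2 = self.noise_sd**2
        return ns2 / (1.0 + ns2) + _IDIO_MARGIN

    def validate(self) -> None:
        if self.n_regions < 2:
            raise ConfigurationError("n_regions must be >= 2")
        if not 1 <= self.rich_set_size <= self.n_regions:
            raise ConfigurationError(
                f"rich_set_size={self.rich_set_size} outside 1..n_regions={self.n_regions}"
            )
        if self.n_subjects_per_group < 1:
            raise ConfigurationError("n_subjects_per_group must be >= 1")
        if self.n_timepoints < 3:
            raise ConfigurationError("n_timepoints must be >= 3")
        for name in ("base_correlation", "background_correlation"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if not 0 <= self.patient_rich_deficit <= 1:
            raise ConfigurationError("patient_rich_deficit outside [0, 1]")
        if self.duration_effect < 0:
            raise ConfigurationError("duration_effect must be >= 0")
        lo, hi = self.duration_range_months
        if lo < 0 or hi < lo:
            raise ConfigurationError(f"bad duration_range_months ({lo}, {hi})")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        has_modules = self.rich_set_size < self.n_regions
        if has_modules and self.background_correlation > 1 - self.idio_floor:
            raise ConfigurationError(
                f"background_correlation={self.background_correlation} leaves no "
                f"idiosyncratic variance (needs <= {1 - self.idio_floor:.3f} at "
                f"noise_sd={self.noise_sd}); lower it or noise_sd"
            )
        if has_modules and self.base_correlation > 1 - self.idio_floor:
            raise ConfigurationError(
                f"base_correlation={self.base_correlation} leaves no feeder/"
                f"idiosyncratic variance (needs <= {1 - self.idio_floor:.3f} at "
                f"noise_sd={self.noise_sd}); lower it or noise_sd"
            )


@dataclass(frozen=True)
class CohortStructure:
    """Planted ground truth: which regions are rich, hub, and module members."""

    rich_indices: tuple[int, ...]  # first entry is the hub
    modules: tuple[tuple[int, ...], ...]  # modules[m] belongs to rich node m

    @property
    def hub_index(self) -> int:
        return self.rich_indices[0]


@dataclass(frozen=True)
class Subject:
    subject_id: str
    group: str  # GROUP_HC | GROUP_JME
    duration_months: float
    series: np.ndarray  # regions x time


@dataclass(frozen=True)
class TimeSeriesPanel:
    """A cohort of per-subject series plus the planted ground truth."""

    subjects: tuple[Subject, ...]
    region_labels: tuple[str, ...]
    config: CohortConfig
    structure: CohortStructure

    def group(self, label: str) -> list[Subject]:
        return [s for s in self.subjects if s.group == label]


def default_region_labels(n: int) -> tuple[str, ...]:
    return tuple(f"ROI{i + 1:03d}" for i in range(n))


def plant_structure(config: CohortConfig) -> CohortStructure:
    """Deterministically place the rich set, hub, and modules from the seed."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    n, r = config.n_regions, config.rich_set_size
    perm = rng.permutation(n)
    rich = tuple(int(i) for i in perm[:r])
    nonrich = perm[r:]
    n_nonrich = nonrich.size
    if n_nonrich == 0 or r == 1:
        modules = tuple(
            (tuple(int(i) for i in nonrich),) if n_nonrich else ()
        )
        return CohortStructure(rich_indices=rich, modules=modules)
    hub_sz = min(int(np.ceil(_HUB_MODULE_SCALE * n_nonrich / r)), n_nonrich)
    rest = n_nonrich - hub_sz
    sizes = [hub_sz] + [
        rest // (r - 1) + (1 if i < rest % (r - 1) else 0) for i in range(r - 1)
    ]
    modules, pos = [], 0
    for s in sizes:
        modules.append(tuple(int(i) for i in nonrich[pos : pos + s]))
        pos += s
    return CohortStructure(rich_indices=rich, modules=tuple(modules))


def nearest_psd(matrix: np.ndarray) -> np.ndarray:
    """Nearest PSD correlation matrix: clip eigenvalues at 0, restore unit diag."""
    w, v = np.linalg.eigh(matrix)
    if w[0] >= 0:
        return matrix
    s = (v * np.clip(w, 0, None)) @ v.T
    d = np.sqrt(np.clip(np.diag(s), 1e-12, None))
    s = s / np.outer(d, d)
    np.fill_diagonal(s, 1.0)
    return s


def _hub_rich_correlation(config: CohortConfig, group: str, duration: float) -> float:
    if group == GROUP_HC:
        return config.base_correlation
    rho = (
        config.base_correlation
        - config.patient_rich_deficit
        - config.duration_effect * duration
    )
    return max(rho, 0.0)


def build_ground_truth_covariance(
    config: CohortConfig,
    group: str,
    duration: float = 0.0,
    structure: CohortStructure | None = None,
) -> np.ndarray:
    """Target correlation matrix of one subject's observed series.

    Factor construction: rich nodes share a club factor (pairwise
    ``base_correlation``); each rich node and its module share a module
    factor (within-module ``background_correlation``, feeder correlations
    from the rich node's residual variance budget).  For patients the hub's
    club loading is reduced so hub-rich entries equal
    ``base - deficit - duration_effect * duration`` (floored at 0); for
    controls duration is ignored.
    """
    config.validate()
    if group not in (GROUP_HC, GROUP_JME):
        raise ConfigurationError(f"unknown group {group!r}")
    if group == GROUP_HC:
        duration = 0.0
    elif duration < 0:
        raise ConfigurationError("duration must be non-negative")
    st = structure if structure is not None else plant_structure(config)
    n, r = config.n_regions, config.rich_set_size
    base, bg = config.base_correlation, config.background_correlation
    rho_hub = _hub_rich_correlation(config, group, duration)

    has_modules = any(len(m) for m in st.modules)
    # feeder loading: what remains of a rich node's variance after the club
    # factor and the idiosyncratic floor
    lam_feed = np.sqrt(max(1.0 - base - config.idio_floor, 0.0)) if has_modules else 0.0

    loadings = np.zeros((n, 1 + max(len(st.modules), 1)))
    sqrt_base = np.sqrt(base)
    for m, idx in enumerate(st.rich_indices):
        if idx == st.hub_index:
            loadings[idx, 0] = rho_hub / sqrt_base if base > 0 else 0.0
        else:
            loadings[idx, 0] = sqrt_base
        if m < len(st.modules):
            loadings[idx, 1 + m] = lam_feed
    for m, members in enumerate(st.modules):
        loadings[list(members), 1 + m] = np.sqrt(bg)

    sigma = loadings @ loadings.T
    np.fill_diagonal(sigma, 1.0)
    if np.linalg.eigvalsh(sigma)[0] < -1e-10:  # defensive: construction is PSD
        sigma = nearest_psd(sigma)
    return sigma


def _sample_series(
    sigma: np.ndarray, config: CohortConfig, rng: np.random.Generator
) -> np.ndarray:
    """Draw a regions x time matrix whose correlations estimate ``sigma``."""
    n = sigma.shape[0]
    ns2 = config.noise_sd**2
    signal_cov = (1.0 + ns2) * sigma - ns2 * np.eye(n)
    w, v = np.linalg.eigh(signal_cov)
    if w[0] < -1e-8:
        raise ConfigurationError(
            "noise-inflated signal covariance is not PSD; "
            "raise the idiosyncratic margin (lower correlations or noise_sd)"
        )
    scale = np.sqrt(np.clip(w, 0.0, None))
    z = rng.standard_normal((config.n_timepoints, n))
    x = z * scale @ v.T
    if config.noise_sd > 0:
        x = x + config.noise_sd * rng.standard_normal(x.shape)
    return x.T


def generate_cohort(
    config: CohortConfig,
    region_labels: tuple[str, ...] | None = None,
    validate_network: bool = True,
) -> TimeSeriesPanel:
    """Generate the full two-group panel; bit-identical given config.seed.

    HC subjects have duration 0; patient durations are uniform over
    ``duration_range_months``.  With ``validate_network`` the HC group-mean
    binary network (threshold 0.3) is checked against the construction
    rules — density in 10-50%, mean degree > 2 ln N, no isolated nodes —
    and a violation raises ``GenerationError`` asking for re-parameterisation.
    """
    config.validate()
    labels = (
        tuple(region_labels)
        if region_labels is not None
        else default_region_labels(config.n_regions)
    )
    if len(labels) != config.n_regions:
        raise ConfigurationError("region_labels length != n_regions")
    st = plant_structure(config)
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))

    subjects: list[Subject] = []
    sigma_hc = build_ground_truth_covariance(config, GROUP_HC, structure=st)
    for i in range(config.n_subjects_per_group):
        subjects.append(
            Subject(
                subject_id=f"HC{i + 1:02d}",
                group=GROUP_HC,
                duration_months=0.0,
                series=_sample_series(sigma_hc, config, rng),
            )
        )
    lo, hi = config.duration_range_months
    for i in range(config.n_subjects_per_group):
        duration = float(rng.uniform(lo, hi))
        sigma = build_ground_truth_covariance(config, GROUP_JME, duration, structure=st)
        subjects.append(
            Subject(
                subject_id=f"JME{i + 1:02d}",
                group=GROUP_JME,
                duration_months=duration,
                series=_sample_series(sigma, config, rng),
            )
        )
    panel = TimeSeriesPanel(
        subjects=tuple(subjects), region_labels=labels, config=config, structure=st
    )
    if validate_network:
        report = hc_network_report(panel)
        if not report.passed:
            raise GenerationError(
                "HC group-mean network violates the construction rules "
                f"(density={report.density:.3f} in [0.10, 0.50]: {report.density_ok}; "
                f"mean degree={report.mean_degree:.2f} > {report.degree_bound:.2f}: "
                f"{report.degree_ok}; isolated nodes: {list(report.isolated_nodes)}) — "
                "adjust correlations, noise_sd, or n_timepoints"
            )
    return panel


def hc_network_report(
    panel: TimeSeriesPanel, threshold: float = netbuild.DEFAULT_THRESHOLD
) -> netbuild.NetworkQCReport:
    """QC report of the HC group-mean binary network at the given threshold."""
    nets = [
        netbuild.binarize(
            netbuild.pearson_matrix(s.series, panel.region_labels), threshold
        )
        for s in panel.group(GROUP_HC)
    ]
    return netbuild.network_checks(netbuild.group_mean_network(nets))


def null_config(config: CohortConfig) -> CohortConfig:
    """The same cohort with every planted group effect switched off."""
    return replace(config, patient_rich_deficit=0.0, duration_effect=0.0)
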