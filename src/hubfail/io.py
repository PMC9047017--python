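"""Delimited-text readers/writers for every artifact the pipeline touches.

One dialect throughout: tab separation, a header row, a leading label
column for matrices.  Real-valued matrices round-trip to full double
precision (17 significant digits); binary adjacencies round-trip
bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .errors import ParseError
from .netbuild import BinaryNetwork, CorrelationMatrix, MeanNetwork
from .richclub import RichClubCurve
from .synthetic import CohortConfig, TimeSeriesPanel

#: asymmetry below this is symmetrized silently; above it is an error
SYMMETRY_TOL = 1e-8


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


# -- subject series (regions x time) ----------------------------------------

def write_subject_matrix(path, series: np.ndarray, region_labels) -> None:
    """Write one subject's regions x time matrix; rows are labelled regions."""
    series = np.asarray(series, dtype=float)
    t = series.shape[1]
    lines = ["region\t" + "\t".join(f"t{j + 1}" for j in range(t))]
    for lab, row in zip(region_labels, series):
        lines.append(lab + "\t" + "\t".join(_fmt(v) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_table(path) -> tuple[list[str], list[str], np.ndarray]:
    """Common parse: header labels, row labels, float matrix with cell errors."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split("\t")[1:]
    row_labels: list[str] = []
    rows: list[list[float]] = []
    width = len(header)
    for r, line in enumerate(lines[1:], start=1):
        parts = line.split("\t")
        if len(parts) != width + 1:
            raise ParseError(
                f"{path}: ragged row {r} ({len(parts) - 1} cells, expected {width})"
            )
        row_labels.append(parts[0])
        vals = []
        for c, cell in enumerate(parts[1:], start=1):
            try:
                vals.append(float(cell))
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric cell at (row {r}, col {c}): {cell!r}"
                ) from None
        rows.append(vals)
    return header, row_labels, np.array(rows, dtype=float)


def read_subject_matrix(path) -> tuple[np.ndarray, tuple[str, ...]]:
    """Read a regions x time matrix; returns (series, region_labels)."""
    _, labels, mat = _parse_table(path)
    return mat, tuple(labels)


# -- square matrices (correlation / adjacency / mean weights) ---------------

def write_square_matrix(path, matrix: np.ndarray, labels, binary: bool = False) -> None:
    matrix = np.asarray(matrix)
    lines = ["region\t" + "\t".join(labels)]
    for lab, row in zip(labels, matrix):
        cells = (str(int(v)) for v in row) if binary else (_fmt(v) for v in row)
        lines.append(lab + "\t" + "\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


def _read_square(path) -> tuple[np.ndarray, tuple[str, ...]]:
    header, row_labels, mat = _parse_table(path)
    if header != row_labels:
        raise ParseError(f"{path}: header and row labels disagree")
    if mat.shape[0] != mat.shape[1]:
        raise ParseError(f"{path}: matrix is not square ({mat.shape})")
    asym = np.abs(mat - mat.T).max() if mat.size else 0.0
    if asym > SYMMETRY_TOL:
        raise ParseError(f"{path}: matrix asymmetric by {asym:g} (> {SYMMETRY_TOL:g})")
    mat = (mat + mat.T) / 2.0
    return mat, tuple(row_labels)


def write_adjacency(net: BinaryNetwork, path) -> None:
    write_square_matrix(path, net.adjacency, net.region_labels, binary=True)


def read_adjacency(path, threshold_used: float | None = None) -> BinaryNetwork:
    mat, labels = _read_square(path)
    if not np.isin(mat, (0.0, 1.0)).all():
        bad = np.argwhere(~np.isin(mat, (0.0, 1.0)))[0]
        raise ParseError(
            f"{path}: non-binary adjacency entry at (row {bad[0] + 1}, col {bad[1] + 1})"
        )
    return BinaryNetwork(mat.astype(np.int8), labels, threshold_used=threshold_used)


def write_correlation(corr: CorrelationMatrix, path) -> None:
    write_square_matrix(path, corr.values, corr.region_labels)


def read_correlation(path) -> CorrelationMatrix:
    mat, labels = _read_square(path)
    np.fill_diagonal(mat, 1.0)
    return CorrelationMatrix(mat, labels)


def write_mean_network(mean: MeanNetwork, path) -> None:
    write_square_matrix(path, mean.weights, mean.region_labels)


def read_mean_network(path, n_subjects: int = 0) -> MeanNetwork:
    mat, labels = _read_square(path)
    return MeanNetwork(mat, labels, n_subjects=n_subjects)


# -- cohort -----------------------------------------------------------------

def write_cohort(panel: TimeSeriesPanel, directory) -> Path:
    """One series file per subject plus a manifest and the config (YAML)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = ["subject_id\tgroup\tduration_months\tseries_file"]
    for s in panel.subjects:
        fname = f"{s.subject_id}_series.tsv"
        write_subject_matrix(directory / fname, s.series, panel.region_labels)
        rows.append(f"{s.subject_id}\t{s.group}\t{_fmt(s.duration_months)}\t{fname}")
    (directory / "cohort_manifest.tsv").write_text("\n".join(rows) + "\n")
    (directory / "cohort_config.yaml").write_text(
        yaml.safe_dump(config_to_dict(panel.config), sort_keys=True)
    )
    return directory


def read_cohort_manifest(directory) -> list[dict]:
    """Rows of subject_id / group / duration_months / series_file."""
    lines = (Path(directory) / "cohort_manifest.tsv").read_text().splitlines()
    header = lines[0].split("\t")
    out = []
    for line in lines[1:]:
        row = dict(zip(header, line.split("\t")))
        row["duration_months"] = float(row["duration_months"])
        out.append(row)
    return out


def config_to_dict(config: CohortConfig) -> dict:
    d = dict(config.__dict__)
    d["duration_range_months"] = list(config.duration_range_months)
    return d


def config_from_dict(d: dict) -> CohortConfig:
    d = dict(d)
    if "duration_range_months" in d:
        d["duration_range_months"] = tuple(d["duration_range_months"])
    return CohortConfig(**d)


# -- result tables ----------------------------------------------------------

def write_centrality_table(cv, path) -> None:
    """Region / EC-score table sorted descending (ties by label order)."""
    order = np.argsort(-cv.scores, kind="stable")
    lines = ["region\tec_score"]
    for i in order:
        lines.append(f"{cv.region_labels[i]}\t{cv.scores[i]:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_richclub_curve(curve: RichClubCurve, path) -> None:
    lines = ["k\tphi\tphi_random_mean\tphi_norm"]
    for i, k in enumerate(curve.k_values):
        cells = [
            str(int(k)),
            *("" if np.isnan(v) else _fmt(v)
              for v in (curve.phi[i], curve.phi_random_mean[i], curve.phi_norm[i])),
        ]
        lines.append("\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


def write_decomposition_table(rows, path) -> None:
    """rows: iterable of (subject_id, group, condition, ConnectionDecomposition)."""
    lines = ["subject_id\tgroup\tcondition\trich_sum\tfeeder_sum\tlocal_sum"]
    for sid, group, cond, dec in rows:
        lines.append(
            f"{sid}\t{group}\t{cond}\t{_fmt(dec.rich_sum)}\t"
            f"{_fmt(dec.feeder_sum)}\t{_fmt(dec.local_sum)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_metric_table(rows, path) -> None:
    """rows: iterable of (subject_id, group, condition, mean_clustering, E_glob)."""
    lines = ["subject_id\tgroup\tcondition\tmean_clustering\tglobal_efficiency"]
    for sid, group, cond, c, e in rows:
        lines.append(f"{sid}\t{group}\t{cond}\t{_fmt(c)}\t{_fmt(e)}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_contrast_table(results, path) -> None:
    lines = ["contrast\tconnection_class\tt\tF\tp\tq\tsignificant\tsignificant_q01"]
    for r in results:
        lines.append(
            f"{r.contrast}\t{r.connection_class}\t{_fmt(r.statistic)}\t"
            f"{_fmt(r.f_statistic)}\t{_fmt(r.p_value)}\t{_fmt(r.q_value)}\t"
            f"{int(r.significant)}\t{int(r.significant_strict)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_cascade_trace(trace, path) -> None:
    """Long table: iteration, node, load, capacity, overloaded flag, plus the
    per-iteration weighted global efficiency."""
    lines = ["iteration\tregion\tload\tcapacity\toverloaded\tglobal_efficiency"]
    for state in trace.states:
        eff = state.global_efficiency()
        labels = state.graph.region_labels
        over = set(state.overloaded)
        for i, lab in enumerate(labels):
            lines.append(
                f"{state.t}\t{lab}\t{_fmt(state.loads[i])}\t"
                f"{_fmt(state.capacities[i])}\t{int(i in over)}\t{_fmt(eff)}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
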