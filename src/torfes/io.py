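"""Readers and writers for the plain-text formats the workflow touches.

COLVAR and HILLS follow the de facto PLUMED conventions: whitespace
separated columns with ``#! FIELDS ...`` header lines; other ``#`` lines
are ignored.  Conformer tables and consistency reports are CSV.
"""

from __future__ import annotations

import logging
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .conformers import DISCARDED, ClusterSet
from .consistency import ConsistencyReport
from .geometry import ConfigurationSet, wrap_angles
from .metad_setup import HillWidthSuggestion
from .reweight import BiasTable, HillRecord

__all__ = [
    "read_colvar",
    "write_colvar",
    "read_hills",
    "write_hills",
    "write_conformer_table",
    "read_conformer_table",
    "write_assignments",
    "write_consistency_report",
    "write_hill_width_table",
]

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Malformed input file."""


def _parse_fields_table(path: str) -> Tuple[List[str], np.ndarray, List[int]]:
    """Parse a '#! FIELDS'-headed whitespace table.

    Returns (field names, data matrix, source line numbers per row).
    """
    fields: Optional[List[str]] = None
    rows: List[List[float]] = []
    line_numbers: List[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#!"):
                tokens = stripped[2:].split()
                if tokens and tokens[0] == "FIELDS":
                    fields = tokens[1:]
                continue
            if stripped.startswith("#"):
                continue
            if fields is None:
                raise FormatError(f"{path}:{lineno}: data before '#! FIELDS' header")
            parts = stripped.split()
            if len(parts) != len(fields):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(fields)} columns, got {len(parts)}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: unparseable value ({exc})") from None
            line_numbers.append(lineno)
    if fields is None:
        raise FormatError(f"{path}: no '#! FIELDS' header found")
    data = np.asarray(rows, dtype=float) if rows else np.empty((0, len(fields)))
    return fields, data, line_numbers


def read_colvar(
    path: str,
    torsion_fields: Sequence[str],
    bias_fields: Optional[Sequence[str]] = None,
    degrees: bool = False,
) -> Tuple[ConfigurationSet, Optional[BiasTable]]:
    """Read a COLVAR-style table into a configuration set.

    Angles are wrapped to ``(-pi, pi]``.  Repeated timestamps (restart
    artifacts) are deduplicated keeping the last occurrence.
    """
    fields, data, _ = _parse_fields_table(path)
    if data.shape[0] == 0:
        raise FormatError(f"{path}: no data rows")
    col = {name: i for i, name in enumerate(fields)}
    for name in list(torsion_fields) + list(bias_fields or []):
        if name not in col:
            raise FormatError(f"{path}: field '{name}' absent from header {fields}")
    if "time" not in col:
        raise FormatError(f"{path}: mandatory field 'time' absent from header")
    times = data[:, col["time"]]
    # keep the last occurrence of each timestamp, preserving time order
    _, last_idx = np.unique(times[::-1], return_index=True)
    keep = np.sort(data.shape[0] - 1 - last_idx)
    if keep.shape[0] < data.shape[0]:
        logger.info(
            "%s: deduplicated %d restart rows", path, data.shape[0] - keep.shape[0]
        )
    data = data[keep]
    times = times[keep]
    angles = data[:, [col[f] for f in torsion_fields]]
    if degrees:
        angles = np.deg2rad(angles)
    cs = ConfigurationSet(wrap_angles(angles), times)
    bias = None
    if bias_fields:
        bias = BiasTable(data[:, [col[f] for f in bias_fields]])
    return cs, bias


def write_colvar(
    path: str,
    cs: ConfigurationSet,
    torsion_fields: Sequence[str],
    bias: Optional[BiasTable] = None,
    bias_fields: Optional[Sequence[str]] = None,
    header_comments: Optional[Sequence[str]] = None,
) -> None:
    """Write a configuration set (and optional per-torsion bias) as COLVAR."""
    if len(torsion_fields) != cs.d:
        raise ValueError("one torsion field name per dimension required")
    if bias is not None:
        if bias_fields is None:
            bias_fields = [f"bias_{name}" for name in torsion_fields]
        if len(bias_fields) != bias.values.shape[1]:
            raise ValueError("one bias field name per bias column required")
    names = ["time"] + list(torsion_fields) + (list(bias_fields) if bias is not None else [])
    times = cs.times if cs.times is not None else np.arange(1.0, cs.n + 1.0)
    columns = [times, *cs.angles.T]
    if bias is not None:
        columns.extend(bias.values.T)
    matrix = np.column_stack(columns)
    with open(path, "w") as fh:
        for comment in header_comments or []:
            fh.write(f"# {comment}\n")
        fh.write("#! FIELDS " + " ".join(names) + "\n")
        np.savetxt(fh, matrix, fmt="%.10g")


def read_hills(path: str) -> List[HillRecord]:
    """Read a HILLS-style table into hill records (centers wrapped).

    Expected fields: time, a center column, sigma, height, and optionally
    a bias factor; an empty file is a valid zero bias.
    """
    try:
        fields, data, line_numbers = _parse_fields_table(path)
    except FormatError as exc:
        if "no '#! FIELDS' header" in str(exc) and _is_empty(path):
            return []
        raise
    if data.shape[0] == 0:
        return []
    col = {name: i for i, name in enumerate(fields)}
    if "time" not in col:
        raise FormatError(f"{path}: mandatory field 'time' absent")
    sigma_keys = [f for f in fields if f.startswith("sigma")]
    if not sigma_keys:
        raise FormatError(f"{path}: no sigma field in header {fields}")
    if "height" not in col:
        raise FormatError(f"{path}: mandatory field 'height' absent")
    reserved = {"time", "height", "biasf"} | set(sigma_keys)
    center_keys = [f for f in fields if f not in reserved]
    if len(center_keys) != 1 or len(sigma_keys) != 1:
        raise FormatError(
            f"{path}: expected exactly one center and one sigma column, header {fields}"
        )
    records = []
    for row, lineno in zip(data, line_numbers):
        sigma = row[col[sigma_keys[0]]]
        if sigma <= 0:
            raise FormatError(f"{path}:{lineno}: nonpositive sigma {sigma}")
        height = row[col["height"]]
        if height < 0:
            raise FormatError(f"{path}:{lineno}: negative height {height}")
        records.append(
            HillRecord(
                time=row[col["time"]],
                center=row[col[center_keys[0]]],
                sigma=sigma,
                height=height,
                bias_factor=row[col["biasf"]] if "biasf" in col else None,
            )
        )
    return records


def _is_empty(path: str) -> bool:
    with open(path) as fh:
        return all(not line.strip() or line.lstrip().startswith("#") for line in fh)


def write_hills(path: str, hills: Sequence[HillRecord], center_name: str = "cv") -> None:
    """Write hill records in the HILLS dialect (for fixtures and round-trips)."""
    has_biasf = any(h.bias_factor is not None for h in hills)
    names = ["time", center_name, f"sigma_{center_name}", "height"]
    if has_biasf:
        names.append("biasf")
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(names) + "\n")
        for h in hills:
            row = [h.time, h.center, h.sigma, h.height]
            if has_biasf:
                row.append(h.bias_factor if h.bias_factor is not None else 1.0)
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def write_conformer_table(
    clusters: ClusterSet, path: str, header_comments: Optional[Sequence[str]] = None
) -> None:
    """CSV of conformer labels, free energies, and torsion coordinates.

    Exactly one row carries free energy 0.00 (the global minimum
    conformer); labels are ordinals sorted by free energy.
    """
    if clusters.n_clusters == 0:
        raise ValueError("empty cluster set")
    d = clusters.d
    columns = ["conformer", "free_energy_kJ_mol"] + [f"gamma_{i+1}" for i in range(d)]
    rows = []
    for c in range(clusters.n_clusters):
        rows.append(
            [c, round(float(clusters.center_F[c]), 2)]
            + [round(float(v), 2) for v in clusters.center_coords[c]]
        )
    frame = pd.DataFrame(rows, columns=columns)
    with open(path, "w") as fh:
        for comment in header_comments or []:
            fh.write(f"# {comment}\n")
        frame.to_csv(fh, index=False, float_format="%.2f")


def read_conformer_table(path: str) -> pd.DataFrame:
    """Read back a conformer table CSV (comment lines skipped)."""
    return pd.read_csv(path, comment="#")


def write_assignments(
    clusters: ClusterSet, path: str, header_comments: Optional[Sequence[str]] = None
) -> None:
    """CSV mapping each configuration index to a conformer or 'discarded'."""
    labels = [
        str(a) if a != DISCARDED else "discarded" for a in clusters.assignment
    ]
    frame = pd.DataFrame(
        {"configuration": np.arange(len(labels)), "conformer": labels}
    )
    with open(path, "w") as fh:
        for comment in header_comments or []:
            fh.write(f"# {comment}\n")
        frame.to_csv(fh, index=False)


def write_consistency_report(
    report: ConsistencyReport, path: str, header_comments: Optional[Sequence[str]] = None
) -> None:
    """CSV of cluster counts and matching deviations per subsample size."""
    frame = pd.DataFrame(
        {
            "size": report.sizes,
            "n_clusters": report.n_clusters,
            "delta_d_bar_rad": report.delta_d_bar,
            "delta_F_bar_kJ_mol": report.delta_F_bar,
        }
    )
    with open(path, "w") as fh:
        for comment in header_comments or []:
            fh.write(f"# {comment}\n")
        fh.write(f"# reference_size: {report.reference_size}\n")
        frame.to_csv(fh, index=False)


def write_delta_F_curves(
    curves: dict, path: str, header_comments: Optional[Sequence[str]] = None
) -> None:
    """CSV of marginal-FES convergence curves, one row per (torsion, t)."""
    rows = [
        {"torsion": torsion, "t": t, "delta_F_M": v}
        for torsion, curve in curves.items()
        for t, v in curve
    ]
    frame = pd.DataFrame(rows, columns=["torsion", "t", "delta_F_M"])
    with open(path, "w") as fh:
        for comment in header_comments or []:
            fh.write(f"# {comment}\n")
        frame.to_csv(fh, index=False)


def write_hill_width_table(
    suggestions: Sequence[HillWidthSuggestion],
    path: str,
    header_comments: Optional[Sequence[str]] = None,
) -> None:
    """CSV of per-torsion minimum reference widths and suggested hill widths."""
    frame = pd.DataFrame(
        {
            "torsion": [s.torsion for s in suggestions],
            "min_reference_width_rad": [s.min_reference_width for s in suggestions],
            "suggested_width_rad": [s.suggested_width for s in suggestions],
            "n_components": [s.n_components for s in suggestions],
        }
    )
    with open(path, "w") as fh:
        for comment in header_comments or []:
            fh.write(f"# {comment}\n")
        frame.to_csv(fh, index=False)
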