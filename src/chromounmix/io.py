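"""CSV and manifest readers/writers.

File conventions: comma separator, dot decimal, UTF-8, ``#``-prefixed
metadata comment lines before the header, floats written to 6 significant
digits.  Spectrum files are two-column ``wavelength_nm,value``; measurement
files are three-column ``wavelength_nm,Tt,Rt``.  A library manifest is a
YAML file mapping component names to spectrum CSVs plus per-component
normalization and zero-cutoff settings.  Output files embed a config hash
and the package version (never timestamps, for byte-stable reruns).
"""

from __future__ import annotations

import csv
import hashlib
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .concentrations import ConcentrationTable
from .direct_mua import AbsorptionEnsemble, SampleMeasurement
from .spectral_library import (
    ComponentSpectrum,
    SpectralLibrary,
    WavelengthGrid,
    apply_zero_convention,
    normalize_unit_range,
    resample_to_grid,
)
from .unmixing import WeightVector

__all__ = [
    "read_spectrum_csv",
    "read_measurement_csv",
    "read_weights_csv",
    "read_concentrations_csv",
    "load_library",
    "write_spectrum_csv",
    "write_measurement_csv",
    "write_ensemble_csv",
    "write_weights_csv",
    "write_reconstruction_csv",
    "write_concentrations_csv",
    "write_comparison_csv",
    "write_library_manifest",
    "config_hash",
]

FLOAT_FMT = "%.6g"


def _fmt(x: float) -> str:
    return FLOAT_FMT % x


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping, for output headers."""
    canon = repr(sorted((str(k), repr(v)) for k, v in config.items()))
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _read_numeric_rows(path, n_cols: int, header: tuple[str, ...]):
    """Parse a comment-tolerant numeric CSV, reporting bad rows by line."""
    path = Path(path)
    rows = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        saw_header = False
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].lstrip().startswith("#"):
                continue
            if not saw_header:
                got = tuple(c.strip() for c in row)
                if got != header:
                    raise ValueError(
                        f"{path}: line {lineno}: expected header "
                        f"{','.join(header)}, got {','.join(got)}"
                    )
                saw_header = True
                continue
            if len(row) != n_cols:
                raise ValueError(
                    f"{path}: line {lineno}: expected {n_cols} columns, "
                    f"got {len(row)}"
                )
            try:
                rows.append([float(c) for c in row])
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric value in {row!r}"
                ) from None
    if not saw_header:
        raise ValueError(f"{path}: missing header line {','.join(header)}")
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return np.asarray(rows, dtype=float)


def _sort_and_check_unique(path, data: np.ndarray) -> np.ndarray:
    order = np.argsort(data[:, 0], kind="stable")
    data = data[order]
    dup = np.flatnonzero(np.diff(data[:, 0]) == 0)
    if dup.size:
        raise ValueError(
            f"{path}: duplicated wavelength {data[dup[0], 0]:g} nm"
        )
    return data


def read_spectrum_csv(path) -> tuple[WavelengthGrid, np.ndarray]:
    """Read a two-column spectrum file; rows are wavelength-sorted."""
    data = _read_numeric_rows(path, 2, ("wavelength_nm", "value"))
    data = _sort_and_check_unique(path, data)
    return WavelengthGrid(data[:, 0]), data[:, 1]


def read_measurement_csv(
    path, thickness_cm: float, sample_id: str, condition: str
) -> SampleMeasurement:
    """Read a three-column Tt/Rt measurement file."""
    data = _read_numeric_rows(path, 3, ("wavelength_nm", "Tt", "Rt"))
    data = _sort_and_check_unique(path, data)
    return SampleMeasurement(
        sample_id=sample_id,
        condition=condition,
        grid=WavelengthGrid(data[:, 0]),
        Tt=data[:, 1],
        Rt=data[:, 2],
        thickness_cm=thickness_cm,
    )


def read_weights_csv(path) -> WeightVector:
    """Read a ``component,weight`` file into a weight vector."""
    path = Path(path)
    names, values = [], []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        saw_header = False
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].lstrip().startswith("#"):
                continue
            if not saw_header:
                got = tuple(c.strip() for c in row[:2])
                if got != ("component", "weight"):
                    raise ValueError(
                        f"{path}: line {lineno}: expected header component,weight"
                    )
                saw_header = True
                continue
            try:
                names.append(row[0].strip())
                values.append(float(row[1]))
            except (IndexError, ValueError):
                raise ValueError(
                    f"{path}: line {lineno}: malformed row {row!r}"
                ) from None
    if not names:
        raise ValueError(f"{path}: no weight rows")
    return WeightVector(component_names=tuple(names), weights=values)


def read_concentrations_csv(path, condition: str = "") -> ConcentrationTable:
    """Read a concentrations export back into a table (for compare)."""
    path = Path(path)
    entries: dict[str, float] = {}
    water_pct = None
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        saw_header = False
        for row in reader:
            if not row or row[0].lstrip().startswith("#"):
                continue
            if not saw_header:
                saw_header = True
                continue
            name = row[0].strip()
            entries[name] = float(row[-1])
            if name.lower() == "water":
                water_pct = entries[name]
    if water_pct is None:
        raise ValueError(f"{path}: no water row")
    return ConcentrationTable(
        condition=condition, entries=entries, water_fraction_pct=water_pct
    )


def load_library(
    manifest_path, grid: WavelengthGrid | None = None
) -> SpectralLibrary:
    """Build a library from a YAML manifest.

    Manifest schema::

        components:
          - name: water
            path: water.csv          # relative to the manifest
            normalize: true          # default true
            zero_cutoff_nm: null     # e.g. 620 for lipids

    Each spectrum is resampled to ``grid`` (default: the manifest order's
    first spectrum grid), zero-conventioned, then 0-1 normalized.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path, encoding="utf-8") as fh:
        manifest = yaml.safe_load(fh)
    if not isinstance(manifest, dict) or "components" not in manifest:
        raise ValueError(f"{manifest_path}: manifest must map 'components'")
    components = []
    for entry in manifest["components"]:
        name = entry["name"]
        src_grid, values = read_spectrum_csv(manifest_path.parent / entry["path"])
        spec = ComponentSpectrum(
            name=name, grid=src_grid, values=values, provenance=str(entry["path"])
        )
        if grid is None:
            grid = src_grid
        if not spec.grid.matches(grid):
            spec = resample_to_grid(spec, grid)
        cutoff = entry.get("zero_cutoff_nm")
        if cutoff is not None:
            spec = apply_zero_convention(spec, float(cutoff))
        if entry.get("normalize", True):
            spec = normalize_unit_range(spec)
        components.append(spec)
    return SpectralLibrary(components=components)


def _write_csv(path, header: list[str], rows, meta: dict | None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write(f"# chromounmix {__version__}\n")
        if meta:
            fh.write(f"# config_hash: {config_hash(meta)}\n")
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(header)
        writer.writerows(rows)


def write_spectrum_csv(path, grid: WavelengthGrid, values, meta=None) -> None:
    rows = [(_fmt(wl), _fmt(v)) for wl, v in zip(grid.values, values)]
    _write_csv(path, ["wavelength_nm", "value"], rows, meta)


def write_measurement_csv(path, measurement: SampleMeasurement, meta=None) -> None:
    rows = [
        (_fmt(wl), _fmt(t), _fmt(r))
        for wl, t, r in zip(
            measurement.grid.values, measurement.Tt, measurement.Rt
        )
    ]
    _write_csv(path, ["wavelength_nm", "Tt", "Rt"], rows, meta)


def write_ensemble_csv(path, ensemble: AbsorptionEnsemble, meta=None) -> None:
    rows = [
        (_fmt(wl), _fmt(m), _fmt(s))
        for wl, m, s in zip(
            ensemble.grid.values, ensemble.mean.mua, ensemble.sd
        )
    ]
    _write_csv(path, ["wavelength_nm", "mean_mua_percm", "sd_mua_percm"], rows, meta)


def write_weights_csv(path, weights: WeightVector, meta=None) -> None:
    rows = [(name, _fmt(w)) for name, w in weights.items()]
    _write_csv(path, ["component", "weight"], rows, meta)


def write_reconstruction_csv(
    path, grid: WavelengthGrid, observed, reconstructed, residuals, meta=None
) -> None:
    rows = [
        (_fmt(wl), _fmt(o), _fmt(r), _fmt(e))
        for wl, o, r, e in zip(grid.values, observed, reconstructed, residuals)
    ]
    _write_csv(
        path,
        ["wavelength_nm", "observed_mua_percm", "reconstructed_mua_percm", "residual_percm"],
        rows,
        meta,
    )


def write_concentrations_csv(
    path, table: ConcentrationTable, weights: WeightVector | None = None, meta=None
) -> None:
    """Per-condition ``component,weight,concentration_pct`` export."""
    rows = []
    for name, conc in table.entries.items():
        w = _fmt(weights[name]) if weights is not None else ""
        rows.append((name, w, _fmt(round(conc, table.rounding))))
    _write_csv(path, ["component", "weight", "concentration_pct"], rows, meta)


def write_comparison_csv(path, comparison, meta=None) -> None:
    rows = [
        (
            r.component,
            _fmt(r.concentration_a),
            _fmt(r.concentration_b),
            _fmt(r.delta),
            r.direction,
        )
        for r in comparison.itertuples(index=False)
    ]
    _write_csv(
        path,
        ["component", "concentration_a", "concentration_b", "delta", "direction"],
        rows,
        meta,
    )


def write_library_manifest(path, library: SpectralLibrary, meta=None) -> None:
    """Write a library's spectra as CSVs plus a manifest next to them."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    entries = []
    for comp in library.components:
        csv_name = f"{comp.name}.csv"
        write_spectrum_csv(path.parent / csv_name, comp.grid, comp.values, meta)
        entries.append(
            {"name": comp.name, "path": csv_name, "normalize": bool(comp.normalized)}
        )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# chromounmix {__version__}\n")
        yaml.safe_dump({"components": entries}, fh, sort_keys=False)
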