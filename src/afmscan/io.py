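"""Tabular and config I/O.

All tables are TSV with a header line; lines starting with '#' carry
metadata and are skipped on read.  Traces: fragment_id, point_index, x_nm,
y_nm.  Complexes/measurements: one row per complex.  Spectra: two-column
wavelength_nm / intensity_cps with a condition header.  Configs are YAML
mirroring :class:`afmscan.simulate.SimulationConfig`.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidInputError
from .fluor import Spectrum
from .geometry import ComplexRecord, PolylineTrace, records_to_frame
from .simulate import SimulationConfig


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_traces(path, traces: list[PolylineTrace], comment: str = "") -> None:
    rows = []
    for t in traces:
        for i, (x, y) in enumerate(t.points):
            rows.append((t.fragment_id, i, x, y))
    df = pd.DataFrame(rows, columns=["fragment_id", "point_index", "x_nm", "y_nm"])
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_traces(path) -> list[PolylineTrace]:
    df = _read_tsv(path)
    need = {"fragment_id", "point_index", "x_nm", "y_nm"}
    if not need.issubset(df.columns):
        raise InvalidInputError(f"trace table must have columns {sorted(need)}")
    traces = []
    for fid, grp in df.groupby("fragment_id", sort=True):
        grp = grp.sort_values("point_index")
        traces.append(PolylineTrace(int(fid), grp[["x_nm", "y_nm"]].to_numpy()))
    return traces


def write_complexes(path, records: list[ComplexRecord], comment: str = "") -> None:
    df = records_to_frame(records)
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_complexes(path) -> pd.DataFrame:
    df = _read_tsv(path)
    if "fragment_id" not in df.columns:
        raise InvalidInputError("complex table must have a fragment_id column")
    return df


def write_table(path, df: pd.DataFrame, comment: str = "") -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def write_heightmap_txt(path, heightmap) -> None:
    """Plain-text grid of heights with the pixel size in a '#' header."""
    with open(path, "w") as fh:
        fh.write(f"# pixel_size_nm={heightmap.pixel_size}\n")
        np.savetxt(fh, heightmap.heights, fmt="%.5g")


def read_heightmap_txt(path):
    from .render import HeightMap
    pixel_size = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#") and "pixel_size_nm=" in first:
            pixel_size = float(first.split("pixel_size_nm=")[1])
    if pixel_size is None:
        raise InvalidInputError("height map header must state pixel_size_nm")
    heights = np.loadtxt(path, comments="#")
    return HeightMap(heights, pixel_size)


def write_spectrum(path, spectrum: Spectrum) -> None:
    with open(path, "w") as fh:
        fh.write(f"# condition={spectrum.label}\treplicate={spectrum.replicate}\n")
        fh.write("wavelength_nm\tintensity_cps\n")
        for w, i in zip(spectrum.wavelength_nm, spectrum.intensity_cps):
            fh.write(f"{w:g}\t{i:.6g}\n")


def read_spectrum(path) -> Spectrum:
    label, replicate = "", 0
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for part in first[1:].strip().split("\t"):
            if part.startswith("condition="):
                label = part.split("=", 1)[1]
            elif part.startswith("replicate="):
                replicate = int(part.split("=", 1)[1])
    df = _read_tsv(path)
    return Spectrum(df["wavelength_nm"].to_numpy(),
                    df["intensity_cps"].to_numpy(),
                    label=label, replicate=replicate)


def load_config(path) -> SimulationConfig:
    """Load a SimulationConfig from a YAML key-value file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    valid = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise InvalidInputError(f"unknown config keys: {sorted(unknown)}")
    for key in ("bend_states", "intrinsic_site_states"):
        if key in raw:
            raw[key] = [tuple(map(float, pair)) for pair in raw[key]]
    return SimulationConfig(**raw)


def dump_config(path, config: SimulationConfig) -> None:
    d = dataclasses.asdict(config)
    for key in ("bend_states", "intrinsic_site_states"):
        d[key] = [list(pair) for pair in d[key]]
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
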