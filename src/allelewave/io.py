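"""File formats, run configuration and result serialisation.

Formats:

* sample table — TSV/CSV with header ``id lat lon age_bp kind`` plus a
  kind-specific payload (``gl0 gl1 gl2`` / ``genotype`` / ``allele``);
* beagle genotype likelihoods — ``marker allele1 allele2`` then one triplet
  of columns per individual;
* topography — ESRI ASCII grid (elevation in metres, negative = water);
* surface export — NetCDF gridded time series (time coordinate in
  generations since origin, water as NaN);
* fit results — JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .landscape import Raster
from .likelihood import Dataset, Observation
from .pde import FrequencySurface

log = logging.getLogger("allelewave")

__all__ = [
    "RunConfig",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_samples",
    "write_samples",
    "read_beagle",
    "write_fit",
    "read_fit",
    "export_surface",
    "import_surface",
]

_REQUIRED_COLUMNS = ("id", "lat", "lon", "age_bp", "kind")
_PAYLOAD_COLUMNS = {
    "genotype_likelihood": ("gl0", "gl1", "gl2"),
    "diploid_genotype": ("genotype",),
    "pseudohaploid": ("allele",),
}

# default land bridges (row, col) on the 1-degree 30-75N/10W-80E grid:
# Great Britain <-> France and Sardinia <-> the Italian mainland
DEFAULT_LAND_BRIDGES = [[20, 9], [10, 19]]


@dataclasses.dataclass
class RunConfig:
    """Parsed run configuration (see ``RunConfig.from_yaml``)."""

    map: dict
    model: dict
    bounds: dict = dataclasses.field(default_factory=dict)
    optimizer: dict = dataclasses.field(default_factory=dict)
    params: list = dataclasses.field(default_factory=list)
    design: dict = dataclasses.field(default_factory=dict)
    forward: dict = dataclasses.field(default_factory=dict)
    output: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        cfg = cls(**{k: raw.get(k, {}) for k in known})
        cfg.validate(base=path.parent)
        return cfg

    def validate(self, base: Path | None = None) -> None:
        if "bbox" not in self.map:
            raise ValueError("config map section requires a bbox")
        topo = self.map.get("topography")
        if topo is not None:
            p = Path(topo)
            if base is not None and not p.is_absolute():
                p = base / p
                self.map["topography"] = str(p)
            if not p.exists():
                raise FileNotFoundError(f"topography raster not found: {p}")
        for name, lohi in (self.bounds or {}).items():
            if not (isinstance(lohi, (list, tuple)) and len(lohi) == 2
                    and lohi[0] < lohi[1]):
                raise ValueError(f"bounds for {name} are not well-ordered: {lohi}")


def read_ascii_grid(path: str | Path) -> Raster:
    """Read an ESRI ASCII elevation grid into a south-up :class:`Raster`."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            parts = fh.readline().split()
            if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value",
            ):
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        data = np.loadtxt(fh)
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing ESRI ASCII header field {key}")
    data = np.atleast_2d(data)
    if data.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(
            f"{path}: data shape {data.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    return Raster(
        data=data[::-1].copy(),  # ESRI rows run north to south
        lat_min=header["yllcorner"],
        lon_min=header["xllcorner"],
        cellsize=header["cellsize"],
        nodata=header.get("nodata_value"),
    )


def write_ascii_grid(path: str | Path, raster: Raster) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.data.shape[1]}\n")
        fh.write(f"nrows {raster.data.shape[0]}\n")
        fh.write(f"xllcorner {raster.lon_min}\n")
        fh.write(f"yllcorner {raster.lat_min}\n")
        fh.write(f"cellsize {raster.cellsize}\n")
        if raster.nodata is not None:
            fh.write(f"NODATA_value {raster.nodata}\n")
        np.savetxt(fh, raster.data[::-1], fmt="%.6g")


def _table_error(path, line, message):
    return ValueError(f"{path}:{line}: {message}")


def read_samples(path: str | Path) -> Dataset:
    """Parse a TSV/CSV sample table into a :class:`Dataset`.

    Errors cite 1-based line numbers of the offending row (header = line 1).
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype={"id": str})
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    observations = []
    for i, row in df.iterrows():
        line = i + 2
        kind = row["kind"]
        if kind not in _PAYLOAD_COLUMNS:
            raise _table_error(path, line, f"unknown kind {kind!r}")
        for col in ("lat", "lon", "age_bp") + _PAYLOAD_COLUMNS[kind]:
            if col not in df.columns:
                raise _table_error(path, line, f"kind {kind} requires column {col}")
            if pd.isna(row[col]) or not isinstance(row[col], (int, float, np.number)):
                raise _table_error(path, line, f"non-numeric or missing {col}")
        lat, lon, age = float(row["lat"]), float(row["lon"]), float(row["age_bp"])
        if not -90 <= lat <= 90 or not -180 <= lon <= 360:
            raise _table_error(path, line, f"lat/lon out of range: ({lat}, {lon})")
        if age < 0:
            raise _table_error(path, line, f"negative age {age}")
        kwargs = {}
        if kind == "genotype_likelihood":
            gl = (float(row["gl0"]), float(row["gl1"]), float(row["gl2"]))
            if min(gl) < 0 or max(gl) <= 0:
                raise _table_error(path, line, "degenerate likelihood triplet")
            kwargs["gl"] = gl
        elif kind == "diploid_genotype":
            kwargs["genotype"] = int(row["genotype"])
        else:
            kwargs["allele"] = int(row["allele"])
        try:
            observations.append(Observation(
                id=str(row["id"]), lat=lat, lon=lon, age_years_bp=age,
                kind=kind, **kwargs,
            ))
        except ValueError as exc:
            raise _table_error(path, line, str(exc)) from exc
    return Dataset(observations, locus=path.stem)


def write_samples(path: str | Path, data: Dataset) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    rows = []
    for obs in data:
        row = {
            "id": obs.id, "lat": obs.lat, "lon": obs.lon,
            "age_bp": obs.age_years_bp, "kind": obs.kind,
            "gl0": "", "gl1": "", "gl2": "", "genotype": "", "allele": "",
        }
        if obs.kind == "genotype_likelihood":
            row["gl0"], row["gl1"], row["gl2"] = obs.gl
        elif obs.kind == "diploid_genotype":
            row["genotype"] = obs.genotype
        else:
            row["allele"] = obs.allele
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def read_beagle(path: str | Path, target_site: str) -> pd.DataFrame:
    """Extract one site's genotype-likelihood triplets from a beagle file.

    Returns a frame with columns (individual, gl0, gl1, gl2); triplets are in
    ascending derived-allele-count order and may be unnormalised.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=r"\s+")
    if df.shape[1] < 6 or (df.shape[1] - 3) % 3 != 0:
        raise ValueError(
            f"{path}: expected 3 site columns plus triplets per individual, "
            f"got {df.shape[1]} columns"
        )
    hit = df[df.iloc[:, 0].astype(str) == target_site]
    if hit.empty:
        raise ValueError(f"{path}: site {target_site!r} not found")
    vals = hit.iloc[0, 3:].to_numpy(dtype=float)
    n_ind = len(vals) // 3
    names = list(df.columns[3:])
    out = pd.DataFrame({
        "individual": [names[3 * i] for i in range(n_ind)],
        "gl0": vals[0::3],
        "gl1": vals[1::3],
        "gl2": vals[2::3],
    })
    sums = out[["gl0", "gl1", "gl2"]].sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-6):
        log.info("beagle triplets for %s are unnormalised (accepted)", target_site)
    return out


def write_fit(path: str | Path, result) -> None:
    """Serialise a FitResult (or plain dict) to JSON."""
    payload = result.to_dict() if hasattr(result, "to_dict") else result

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_default, allow_nan=True)


def read_fit(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def export_surface(path: str | Path, surface: FrequencySurface) -> None:
    """Write a surface as a NetCDF time series (water = NaN)."""
    ls = surface.landscape
    ds = xr.Dataset(
        {"p": (("time", "lat", "lon"), surface.p)},
        coords={
            "time": surface.times,
            "lat": ls.cell_center_lats,
            "lon": ls.cell_center_lons,
        },
        attrs={
            "allele_age_years_bp": surface.allele_age_years_bp,
            "generation_time": surface.generation_time,
            "resolution": ls.resolution,
            "lat_min": ls.lat_min,
            "lon_min": ls.lon_min,
            "time_units": "generations since allele origin",
        },
    )
    ds.to_netcdf(path, engine="scipy")


def import_surface(path: str | Path) -> FrequencySurface:
    from .landscape import Landscape

    with xr.open_dataset(path, engine="scipy") as ds:
        p = ds["p"].values.copy()
        times = ds["time"].values.copy()
        attrs = dict(ds.attrs)
    mask = np.isfinite(p).all(axis=0)
    landscape = Landscape.from_mask(
        mask,
        lat_min=float(attrs["lat_min"]),
        lon_min=float(attrs["lon_min"]),
        resolution=float(attrs["resolution"]),
    )
    return FrequencySurface(
        landscape=landscape,
        times=times,
        p=p,
        allele_age_years_bp=float(attrs["allele_age_years_bp"]),
        generation_time=float(attrs["generation_time"]),
    )
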