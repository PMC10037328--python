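"""File formats: spectra (two-column text, HDF5) and georeferenced tables
(CSV, GeoJSON points).

The text spectrum format is a plain two-column table (ppm, intensity) with
``# key = value`` header lines carrying the acquisition parameters and
calibration state — portable and diffable. The HDF5 container mirrors it
with datasets ``/axis`` and ``/intensity`` and the metadata as attributes
of ``/meta``.

Georeferenced sample tables hold one row per field position: WGS84
latitude/longitude in decimal degrees, projected UTM easting/northing in
meters, and one column per metabolite concentration. GeoJSON output uses
Point features in WGS84 with the concentrations as properties.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .nmr import AcquisitionParams, Spectrum
from .projection import project_wgs84_to_utm

__all__ = [
    "write_spectrum_text",
    "read_spectrum_text",
    "write_spectrum_hdf5",
    "read_spectrum_hdf5",
    "GeoDataset",
]

_ACQ_KEYS = ("spectrometer_freq_mhz", "sweep_width_hz", "n_points",
             "center_ppm", "line_broadening_hz")


def write_spectrum_text(spec: Spectrum, path: str | Path) -> None:
    """Write the real (absorption) channel as a two-column text spectrum."""
    lines = ["# geometab spectrum v1"]
    if spec.acq is not None:
        for key in _ACQ_KEYS:
            lines.append(f"# {key} = {getattr(spec.acq, key)!r}")
    lines.append(f"# calibrated = {str(spec.calibrated).lower()}")
    lines.append(f"# reference_shift_ppm = {spec.reference_shift_ppm!r}")
    body = "\n".join(f"{p:.9f}\t{y:.9e}"
                     for p, y in zip(spec.ppm, spec.intensity))
    Path(path).write_text("\n".join(lines) + "\n" + body + "\n")


def _parse_header(lines: list[str]) -> dict:
    meta = {}
    for line in lines:
        if not line.startswith("#") or "=" not in line:
            continue
        key, _, val = line[1:].partition("=")
        meta[key.strip()] = val.strip().strip("'\"")
    return meta


def read_spectrum_text(path: str | Path) -> Spectrum:
    raw = Path(path).read_text().splitlines()
    header = [ln for ln in raw if ln.startswith("#")]
    meta = _parse_header(header)
    data = np.loadtxt([ln for ln in raw if ln and not ln.startswith("#")])
    acq = None
    if all(k in meta for k in _ACQ_KEYS):
        acq = AcquisitionParams(
            spectrometer_freq_mhz=float(meta["spectrometer_freq_mhz"]),
            sweep_width_hz=float(meta["sweep_width_hz"]),
            n_points=int(meta["n_points"]),
            center_ppm=float(meta["center_ppm"]),
            line_broadening_hz=float(meta["line_broadening_hz"]),
        )
    return Spectrum(
        data[:, 0], data[:, 1].astype(complex), acq=acq,
        calibrated=meta.get("calibrated", "false") == "true",
        reference_shift_ppm=float(meta.get("reference_shift_ppm", 0.015)),
    )


def write_spectrum_hdf5(spec: Spectrum, path: str | Path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("axis", data=spec.ppm)
        fh.create_dataset("intensity", data=spec.intensity)
        meta = fh.create_group("meta")
        meta.attrs["calibrated"] = spec.calibrated
        meta.attrs["reference_shift_ppm"] = spec.reference_shift_ppm
        if spec.acq is not None:
            for key in _ACQ_KEYS:
                meta.attrs[key] = getattr(spec.acq, key)


def read_spectrum_hdf5(path: str | Path) -> Spectrum:
    with h5py.File(path, "r") as fh:
        ppm = fh["axis"][:]
        intensity = fh["intensity"][:]
        attrs = dict(fh["meta"].attrs)
    acq = None
    if all(k in attrs for k in _ACQ_KEYS):
        acq = AcquisitionParams(
            spectrometer_freq_mhz=float(attrs["spectrometer_freq_mhz"]),
            sweep_width_hz=float(attrs["sweep_width_hz"]),
            n_points=int(attrs["n_points"]),
            center_ppm=float(attrs["center_ppm"]),
            line_broadening_hz=float(attrs["line_broadening_hz"]),
        )
    return Spectrum(ppm, intensity.astype(complex), acq=acq,
                    calibrated=bool(attrs.get("calibrated", False)),
                    reference_shift_ppm=float(attrs.get("reference_shift_ppm", 0.015)))


@dataclass
class GeoDataset:
    """Georeferenced site table with per-metabolite concentrations.

    ``table`` has index = site id and columns lat_deg, lon_deg, easting_m,
    northing_m followed by one column per variable.
    """

    table: pd.DataFrame
    utm_zone: int = 34
    hemisphere: str = "N"

    _COORD_COLS = ["lat_deg", "lon_deg", "easting_m", "northing_m"]

    def __post_init__(self):
        missing = [c for c in self._COORD_COLS if c not in self.table.columns]
        if missing:
            raise ValueError(f"GeoDataset table missing columns {missing}")
        coords = self.coords
        from scipy.spatial.distance import pdist
        if len(coords) >= 2 and pdist(coords).min() == 0.0:
            raise ValueError("duplicate site coordinates in GeoDataset")

    @classmethod
    def from_latlon(cls, lat_deg, lon_deg, variables: pd.DataFrame,
                    site_ids=None, utm_zone: int = 34,
                    hemisphere: str = "N") -> "GeoDataset":
        """Build from geographic coordinates; projects to UTM meters."""
        lat = np.asarray(lat_deg, dtype=float)
        lon = np.asarray(lon_deg, dtype=float)
        e, n = project_wgs84_to_utm(lat, lon, zone=utm_zone, hemisphere=hemisphere)
        if site_ids is None:
            site_ids = (variables.index if isinstance(variables, pd.DataFrame)
                        else [f"site_{i:03d}" for i in range(len(lat))])
        frame = pd.DataFrame(
            {"lat_deg": lat, "lon_deg": lon, "easting_m": e, "northing_m": n},
            index=pd.Index(site_ids, name="site_id"))
        var = pd.DataFrame(variables)
        var.index = frame.index
        return cls(pd.concat([frame, var], axis=1), utm_zone, hemisphere)

    @property
    def coords(self) -> np.ndarray:
        """Projected (easting, northing) in meters, shape (n, 2)."""
        return self.table[["easting_m", "northing_m"]].to_numpy()

    @property
    def variables(self) -> pd.DataFrame:
        cols = [c for c in self.table.columns if c not in self._COORD_COLS]
        return self.table[cols]

    def __len__(self) -> int:
        return len(self.table)

    # -- CSV ----------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, float_format="%.10g")

    @classmethod
    def from_csv(cls, path: str | Path, utm_zone: int = 34,
                 hemisphere: str = "N") -> "GeoDataset":
        """Read a CSV with lat/lon (+ optional projected) columns.

        If easting/northing are absent they are computed by projection.
        """
        frame = pd.read_csv(path, index_col=0)
        frame.columns = [c.strip() for c in frame.columns]
        rename = {"lat": "lat_deg", "lon": "lon_deg"}
        frame = frame.rename(columns=rename)
        if "easting_m" not in frame.columns:
            e, n = project_wgs84_to_utm(frame["lat_deg"].to_numpy(),
                                        frame["lon_deg"].to_numpy(),
                                        zone=utm_zone, hemisphere=hemisphere)
            frame.insert(2, "easting_m", e)
            frame.insert(3, "northing_m", n)
        return cls(frame, utm_zone, hemisphere)

    # -- GeoJSON ------------------------------------------------------------
    def to_geojson(self, path: str | Path) -> None:
        features = []
        for site_id, row in self.table.iterrows():
            props = {"site_id": str(site_id)}
            props.update({c: float(row[c]) for c in self.variables.columns})
            features.append({
                "type": "Feature",
                "geometry": {"type": "Point",
                             "coordinates": [float(row["lon_deg"]),
                                             float(row["lat_deg"])]},
                "properties": props,
            })
        doc = {"type": "FeatureCollection",
               "crs": {"type": "name",
                       "properties": {"name": "urn:ogc:def:crs:OGC:1.3:CRS84"}},
               "features": features}
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_geojson(cls, path: str | Path, utm_zone: int = 34,
                     hemisphere: str = "N") -> "GeoDataset":
        doc = json.loads(Path(path).read_text())
        ids, lats, lons, rows = [], [], [], []
        for k, feat in enumerate(doc["features"]):
            lon, lat = feat["geometry"]["coordinates"][:2]
            props = dict(feat.get("properties", {}))
            ids.append(props.pop("site_id", f"site_{k:03d}"))
            lats.append(float(lat))
            lons.append(float(lon))
            rows.append(props)
        variables = pd.DataFrame(rows, index=ids).astype(float)
        return cls.from_latlon(lats, lons, variables, site_ids=ids,
                               utm_zone=utm_zone, hemisphere=hemisphere)
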