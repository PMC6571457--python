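"""Gridded environmental layers and their plain-text on-disk format.

An :class:`EnvRasterStack` holds the six co-registered environmental layers used
to score heterogeneity around a colony: bathymetry, potential tidal
stratification, sea-surface temperature, and ocean-front strength, distance and
persistence.  Layers live on a regular longitude/latitude grid (cell-centre
registration).

Layers are stored on disk one file per layer in a small self-describing text
format (header lines followed by a latitude-major data block, ``nan`` for
missing cells).  The format is deliberately plain text so fixtures and outputs
remain human-readable and diff-able.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

#: canonical layer order used everywhere downstream
LAYER_NAMES = (
    "bathymetry",
    "tidal_stratification",
    "sst",
    "front_strength",
    "front_distance",
    "front_persistence",
)


@dataclass
class EnvRasterStack:
    """Six co-registered environmental layers on a regular lon/lat grid.

    Parameters
    ----------
    lat, lon
        1-D arrays of cell-centre coordinates in degrees (lat ascending).
    layers
        Mapping from layer name to a ``(len(lat), len(lon))`` array.
    """

    lat: np.ndarray
    lon: np.ndarray
    layers: dict

    def __post_init__(self):
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        for name, arr in self.layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (self.lat.size, self.lon.size):
                raise ValueError(f"layer {name!r} shape {arr.shape} does not match grid")
            self.layers[name] = arr

    @property
    def shape(self):
        return (self.lat.size, self.lon.size)

    def cell_centers(self):
        """Return broadcast ``(lat2d, lon2d)`` arrays of all cell centres."""
        lat2d, lon2d = np.meshgrid(self.lat, self.lon, indexing="ij")
        return lat2d, lon2d


def write_stack(stack: EnvRasterStack, directory, prefix: str = "layer") -> list:
    """Write one text file per layer; returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    nlat, nlon = stack.shape
    dlat = stack.lat[1] - stack.lat[0] if nlat > 1 else 0.0
    dlon = stack.lon[1] - stack.lon[0] if nlon > 1 else 0.0
    for name, arr in stack.layers.items():
        path = directory / f"{prefix}_{name}.grd"
        with open(path, "w") as fh:
            fh.write("# colonyforage gridded layer, cell-centre registration\n")
            fh.write(f"layer {name}\n")
            fh.write(f"nlon {nlon} nlat {nlat}\n")
            fh.write(f"lon0 {stack.lon[0]:.10f} dlon {dlon:.10f}\n")
            fh.write(f"lat0 {stack.lat[0]:.10f} dlat {dlat:.10f}\n")
            np.savetxt(fh, arr, fmt="%.10g")
        paths.append(path)
    return paths


def read_stack(directory, prefix: str = "layer") -> EnvRasterStack:
    """Read a stack previously written by :func:`write_stack`."""
    directory = Path(directory)
    layers = {}
    lat = lon = None
    for path in sorted(directory.glob(f"{prefix}_*.grd")):
        with open(path) as fh:
            fh.readline()  # comment
            name = fh.readline().split()[1]
            _, nlon, _, nlat = fh.readline().split()
            _, lon0, _, dlon = fh.readline().split()
            _, lat0, _, dlat = fh.readline().split()
            arr = np.loadtxt(fh, ndmin=2)
        nlon, nlat = int(nlon), int(nlat)
        lon = float(lon0) + float(dlon) * np.arange(nlon)
        lat = float(lat0) + float(dlat) * np.arange(nlat)
        layers[name] = arr.reshape(nlat, nlon)
    if not layers:
        raise FileNotFoundError(f"no {prefix}_*.grd files in {directory}")
    return EnvRasterStack(lat=lat, lon=lon, layers=layers)
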