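"""Raster grid primitives: grid geometry, masked surfaces and text-raster I/O.

Everything is WGS84 decimal degrees.  Rasters are stored row 0 = southernmost
row internally and serialised as ESRI ASCII grid (``.asc``), a plain-text
format readable by GDAL/QGIS.  Distances are great-circle kilometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

# mean length of one degree of latitude (and of longitude at the equator), km
KM_PER_DEGREE = 111.195

EARTH_RADIUS_KM = 6371.0

NODATA = -9999.0


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km between coordinate arrays (broadcasting)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def pairwise_distances_km(lon, lat, lon2=None, lat2=None) -> np.ndarray:
    """Dense great-circle distance matrix between two coordinate sets (km)."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if lon2 is None:
        lon2, lat2 = lon, lat
    lon2 = np.asarray(lon2, dtype=float)
    lat2 = np.asarray(lat2, dtype=float)
    return haversine_km(lon[:, None], lat[:, None], lon2[None, :], lat2[None, :])


@dataclass(frozen=True)
class GridSpec:
    """Regular lon/lat grid.

    ``origin_lon``/``origin_lat`` are the *outer edges* of the south-west
    corner cell; ``mask`` is True for cells inside the study region (e.g. the
    target-country boundary).
    """

    origin_lon: float
    origin_lat: float
    cell_size: float
    n_rows: int
    n_cols: int
    mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.mask is not None:
            m = np.asarray(self.mask, dtype=bool)
            if m.shape != (self.n_rows, self.n_cols):
                raise ValueError(
                    f"mask shape {m.shape} does not match grid ({self.n_rows}, {self.n_cols})"
                )
            object.__setattr__(self, "mask", m)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def mask_array(self) -> np.ndarray:
        if self.mask is None:
            return np.ones(self.shape, dtype=bool)
        return self.mask

    @property
    def n_unmasked(self) -> int:
        return int(self.mask_array().sum())

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) 2D arrays of cell centres, row 0 = southernmost."""
        lon = self.origin_lon + (np.arange(self.n_cols) + 0.5) * self.cell_size
        lat = self.origin_lat + (np.arange(self.n_rows) + 0.5) * self.cell_size
        return np.meshgrid(lon, lat)

    def unmasked_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """1D (lon, lat) of unmasked cell centres, row-major from the south."""
        lon, lat = self.cell_centers()
        m = self.mask_array()
        return lon[m], lat[m]

    def cell_index(self, lon: float, lat: float) -> tuple[int, int]:
        """(row, col) of the cell containing a point; raises if outside."""
        col = int(np.floor((lon - self.origin_lon) / self.cell_size))
        row = int(np.floor((lat - self.origin_lat) / self.cell_size))
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"point ({lon}, {lat}) outside grid")
        return row, col

    def same_geometry(self, other: "GridSpec") -> bool:
        return (
            np.isclose(self.origin_lon, other.origin_lon)
            and np.isclose(self.origin_lat, other.origin_lat)
            and np.isclose(self.cell_size, other.cell_size)
            and self.shape == other.shape
        )


@dataclass
class Surface:
    """A single raster layer on a :class:`GridSpec`.

    ``values`` is a full ``(n_rows, n_cols)`` float array with ``nan`` in
    masked cells (the sentinel is NaN, never 0, so "no data" is distinct from
    an observed zero).  ``scale`` is ``"probability"``, ``"logit"`` or a
    free-form unit label (e.g. ``"persons"``, ``"births"``).
    """

    grid: GridSpec
    values: np.ndarray
    form: str = ""
    scale: str = "probability"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        mask = self.grid.mask_array()
        self.values = np.where(mask, self.values, np.nan)
        if self.scale == "probability":
            v = self.values[mask]
            v = v[np.isfinite(v)]
            if v.size and (v.min() < -1e-12 or v.max() > 1 + 1e-12):
                raise ValueError(
                    f"probability-scale surface outside [0,1]: range ({v.min()}, {v.max()})"
                )

    def unmasked(self) -> np.ndarray:
        """Values at unmasked cells, row-major from the south."""
        return self.values[self.grid.mask_array()]

    def with_values(self, flat: np.ndarray, scale: str | None = None) -> "Surface":
        """New surface on the same grid from a flat unmasked-cell vector."""
        out = np.full(self.grid.shape, np.nan)
        out[self.grid.mask_array()] = flat
        return Surface(self.grid, out, form=self.form, scale=scale or self.scale)

    def total(self) -> float:
        return float(np.nansum(self.values))

    def plot(self, ax=None, **kwargs):
        """Quick-look map (pcolormesh); returns the matplotlib axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        lon = self.grid.origin_lon + np.arange(self.grid.n_cols + 1) * self.grid.cell_size
        lat = self.grid.origin_lat + np.arange(self.grid.n_rows + 1) * self.grid.cell_size
        pm = ax.pcolormesh(lon, lat, self.values, **kwargs)
        ax.set_xlabel("longitude")
        ax.set_ylabel("latitude")
        title = self.form or self.scale
        ax.set_title(title)
        plt.colorbar(pm, ax=ax)
        return ax


def surface_from_flat(grid: GridSpec, flat: np.ndarray, form: str = "", scale: str = "probability") -> Surface:
    values = np.full(grid.shape, np.nan)
    values[grid.mask_array()] = np.asarray(flat, dtype=float)
    return Surface(grid, values, form=form, scale=scale)


def write_ascii_grid(surface: Surface, path: str | Path) -> None:
    """Serialise a surface as ESRI ASCII grid; NaN cells become NODATA."""
    g = surface.grid
    vals = np.where(np.isfinite(surface.values), surface.values, NODATA)
    header = (
        f"ncols {g.n_cols}\n"
        f"nrows {g.n_rows}\n"
        f"xllcorner {g.origin_lon!r}\n"
        f"yllcorner {g.origin_lat!r}\n"
        f"cellsize {g.cell_size!r}\n"
        f"NODATA_value {NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        # .asc rows run north -> south
        np.savetxt(fh, vals[::-1], fmt="%.10g")


def read_ascii_grid(path: str | Path, form: str = "", scale: str = "probability") -> Surface:
    """Load an ESRI ASCII grid; NODATA cells define the mask."""
    with open(path) as fh:
        header = {}
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        data = np.loadtxt(fh)
    n_rows = int(header["nrows"])
    n_cols = int(header["ncols"])
    data = data.reshape(n_rows, n_cols)[::-1]
    nodata = header.get("nodata_value", NODATA)
    mask = data != nodata
    values = np.where(mask, data, np.nan)
    grid = GridSpec(
        origin_lon=header["xllcorner"],
        origin_lat=header["yllcorner"],
        cell_size=header["cellsize"],
        n_rows=n_rows,
        n_cols=n_cols,
        mask=mask,
    )
    return Surface(grid, values, form=form, scale=scale)


def rectangular_grid(
    west: float, south: float, cell_size: float, n_rows: int, n_cols: int
) -> GridSpec:
    """Convenience constructor for a fully unmasked rectangular grid."""
    return GridSpec(west, south, cell_size, n_rows, n_cols)
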