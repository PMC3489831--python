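"""Minimal projected-grid raster container and plain-text (ESRI ASCII grid) I/O.

All layers in an analysis share one grid: a projected CRS in meters, square
cells, row 0 at the north edge.  Point-in-cell assignment uses half-open
intervals [x0, x0 + cell_size) so every point inside the extent maps to
exactly one cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["Raster", "LandscapeStack", "read_ascii_grid", "read_landscape_stack"]


@dataclass
class Raster:
    """A single-band raster on a projected grid.

    Parameters
    ----------
    data : ndarray, shape (nrows, ncols)
        Cell values; row 0 is the northernmost row.
    cell_size : float
        Cell edge length in meters.
    x0, y0 : float
        Coordinates of the *outer corner* of cell (0, 0): x0 is the west
        edge, y0 the north edge.  Cell centers are offset by half a cell.
    nodata : float
        Sentinel for missing cells (compared with ==; NaN also honoured).
    crs : str
        Free-text CRS tag carried through I/O.
    """

    data: np.ndarray
    cell_size: float
    x0: float = 0.0
    y0: float = 0.0
    nodata: float = -9999.0
    crs: str = "local-meters"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")

    @property
    def nrows(self) -> int:
        return self.data.shape[0]

    @property
    def ncols(self) -> int:
        return self.data.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the outer extent."""
        return (
            self.x0,
            self.y0 - self.nrows * self.cell_size,
            self.x0 + self.ncols * self.cell_size,
            self.y0,
        )

    def same_grid(self, other: "Raster") -> bool:
        return (
            self.shape == other.shape
            and self.cell_size == other.cell_size
            and self.x0 == other.x0
            and self.y0 == other.y0
        )

    # -- coordinate mapping -------------------------------------------------

    def xy_to_rowcol(self, x, y):
        """Map point coordinates to (row, col); half-open cell intervals."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.cell_size).astype(int)
        row = np.floor((self.y0 - y) / self.cell_size).astype(int)
        return row, col

    def rowcol_to_xy(self, row, col):
        """Cell-center coordinates of (row, col)."""
        row = np.asarray(row)
        col = np.asarray(col)
        x = self.x0 + (col + 0.5) * self.cell_size
        y = self.y0 - (row + 0.5) * self.cell_size
        return x, y

    def in_bounds(self, x, y):
        row, col = self.xy_to_rowcol(x, y)
        return (row >= 0) & (row < self.nrows) & (col >= 0) & (col < self.ncols)

    def sample(self, x, y):
        """Values at point locations; out-of-extent points raise."""
        row, col = self.xy_to_rowcol(x, y)
        ok = (row >= 0) & (row < self.nrows) & (col >= 0) & (col < self.ncols)
        if not np.all(ok):
            raise ValueError(f"{int((~ok).sum())} point(s) outside raster extent")
        return self.data[row, col]

    def is_nodata(self, values=None) -> np.ndarray:
        v = self.data if values is None else np.asarray(values)
        with np.errstate(invalid="ignore"):
            return (v == self.nodata) | np.isnan(v.astype(float))

    def copy_with(self, data: np.ndarray) -> "Raster":
        if data.shape != self.shape:
            raise ValueError("replacement data shape mismatch")
        return replace(self, data=data)

    # -- I/O ----------------------------------------------------------------

    def write_ascii(self, path: str | Path) -> None:
        """Write as ESRI ASCII grid (plain text)."""
        path = Path(path)
        header = (
            f"ncols {self.ncols}\n"
            f"nrows {self.nrows}\n"
            f"xllcorner {self.x0!r}\n"
            f"yllcorner {self.y0 - self.nrows * self.cell_size!r}\n"
            f"cellsize {self.cell_size!r}\n"
            f"NODATA_value {self.nodata!r}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, np.nan_to_num(self.data.astype(float), nan=self.nodata), fmt="%.8g")


def read_ascii_grid(path: str | Path, crs: str = "local-meters") -> Raster:
    """Read an ESRI ASCII grid written by :meth:`Raster.write_ascii`."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, val = line.split()
            header[key.lower()] = float(val)
            pos = fh.tell()
        fh.seek(pos)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)
    nrows = int(header["nrows"])
    ncols = int(header["ncols"])
    if data.shape != (nrows, ncols):
        data = data.reshape(nrows, ncols)
    cs = header["cellsize"]
    return Raster(
        data=data,
        cell_size=cs,
        x0=header["xllcorner"],
        y0=header["yllcorner"] + nrows * cs,
        nodata=header.get("nodata_value", -9999.0),
        crs=crs,
    )


@dataclass
class LandscapeStack:
    """Co-registered raster layers for one study landscape.

    ``veg_class`` holds integer category codes (index into ``class_names``);
    ``water_mask`` is boolean (True = water, excluded from all selection
    layers); ``coast_mask`` marks coastline cells; ``ndvi`` is a dict of
    day-of-year -> composite raster; phenology/density layers are attached
    by the covariates module as they are computed.
    """

    veg_class: Raster
    dem: Raster
    water_mask: Raster
    coast_mask: Raster
    class_names: tuple[str, ...]
    ndvi: dict[int, Raster] = field(default_factory=dict)
    precip: Raster | None = None
    layers: dict[str, Raster] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, r in self._iter_layers():
            if not r.same_grid(self.veg_class):
                raise ValueError(f"layer {name!r} is not on the shared grid")

    def _iter_layers(self):
        yield "dem", self.dem
        yield "water_mask", self.water_mask
        yield "coast_mask", self.coast_mask
        for doy, r in self.ndvi.items():
            yield f"ndvi_{doy}", r
        if self.precip is not None:
            yield "precip", self.precip
        for name, r in self.layers.items():
            yield name, r

    @property
    def grid(self) -> Raster:
        return self.veg_class

    @property
    def cell_size(self) -> float:
        return self.veg_class.cell_size

    def add_layer(self, name: str, raster: Raster) -> None:
        if not raster.same_grid(self.veg_class):
            raise ValueError(f"layer {name!r} is not on the shared grid")
        self.layers[name] = raster

    def layer(self, name: str) -> Raster:
        """Look up a layer by name, including the fixed members."""
        fixed = {
            "veg_class": self.veg_class,
            "dem": self.dem,
            "water_mask": self.water_mask,
            "coast_mask": self.coast_mask,
            "precip": self.precip,
        }
        if name in fixed and fixed[name] is not None:
            return fixed[name]
        if name in self.layers:
            return self.layers[name]
        raise KeyError(f"no layer named {name!r} in stack")

    @property
    def land(self) -> np.ndarray:
        """Boolean mask of analysable (non-water) cells."""
        return ~self.water_mask.data.astype(bool)

    def write(self, outdir: str | Path) -> None:
        """Write every layer as an ASCII grid plus a class-name legend."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.veg_class.write_ascii(outdir / "veg_class.asc")
        for name, r in self._iter_layers():
            mask_int = r.copy_with(r.data.astype(float)) if r.data.dtype == bool else r
            mask_int.write_ascii(outdir / f"{name}.asc")
        (outdir / "class_names.txt").write_text("\n".join(self.class_names) + "\n")


def read_landscape_stack(indir: str | Path) -> LandscapeStack:
    """Read a stack written by :meth:`LandscapeStack.write`."""
    indir = Path(indir)
    class_names = tuple((indir / "class_names.txt").read_text().split())

    def rd(name: str, as_bool: bool = False) -> Raster:
        r = read_ascii_grid(indir / f"{name}.asc")
        if as_bool:
            r = r.copy_with(r.data.astype(bool))
        return r

    veg = rd("veg_class")
    veg = veg.copy_with(veg.data.astype(int))
    ndvi = {}
    for f in sorted(indir.glob("ndvi_*.asc")):
        doy = int(f.stem.split("_")[1])
        ndvi[doy] = read_ascii_grid(f)
    precip_path = indir / "precip.asc"
    extra_names = [
        f.stem for f in indir.glob("*.asc")
        if f.stem not in {"veg_class", "dem", "water_mask", "coast_mask", "precip"}
        and not f.stem.startswith("ndvi_")
    ]
    stack = LandscapeStack(
        veg_class=veg,
        dem=rd("dem"),
        water_mask=rd("water_mask", as_bool=True),
        coast_mask=rd("coast_mask", as_bool=True),
        class_names=class_names,
        ndvi=ndvi,
        precip=read_ascii_grid(precip_path) if precip_path.exists() else None,
    )
    for name in sorted(extra_names):
        stack.add_layer(name, rd(name))
    return stack
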