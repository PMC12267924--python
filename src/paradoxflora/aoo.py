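"""Gridded area-of-occupancy (AOO) computation.

Occurrence records are snapped onto a global longitude/latitude grid whose
cells measure ~6000 km^2 at the equator (0.7 degree default), with cell
areas shrinking poleward by cos(latitude of cell center). Each species'
occupied cells are partitioned into native-threatened, native-non-threatened
and naturalized components according to the occurrence's establishment role
and the national Red List status of its country, yielding per-partition AOO
and the percentage of native AOO classified as threatened.

A cell reached by native occurrences from both threatened and non-threatened
countries contributes its area to both native partitions (occurrence-level
routing, cell-level union per partition); the overlap is reported so users
can quantify it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .config import GridSpec
from .errors import InputError
from .threat import IUCNCategory, is_threatened

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("scientificName", "decimalLongitude", "decimalLatitude",
                    "countryCode", "establishmentMeans")

#: partitions an occurrence can be routed to
NATIVE_THREATENED, NATIVE_OK, NATURALIZED, UNRESOLVED = (
    "native_threatened", "native_ok", "naturalized", "unresolved")


@dataclass
class OccupancyPartition:
    """Per-species occupied cells and AOO in each partition."""

    accepted_name: str
    cells_native_threatened: set = field(default_factory=set)
    cells_native_ok: set = field(default_factory=set)
    cells_naturalized: set = field(default_factory=set)
    aoo_native_threatened: float = 0.0
    aoo_native_ok: float = 0.0
    aoo_naturalized: float = 0.0
    pct_native_threatened: Optional[float] = None
    n_unresolved: int = 0


def clean_occurrences(rows: pd.DataFrame, countries: pd.DataFrame,
                      tolerance_deg: float = 0.1):
    """Filter an occurrence table; returns (clean table, per-rule drop counts).

    Rules, applied in order: missing required columns is an input error;
    non-finite or missing coordinates; out-of-range coordinates; exact
    (0, 0) points; unknown country code; coordinates farther than
    ``tolerance_deg`` outside the stated country's polygon; exact
    duplicate (species, lon, lat) rows.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in rows.columns]
    if missing:
        raise InputError(f"occurrence table missing columns: {', '.join(missing)}")
    from shapely import contains_xy
    from shapely.geometry import box

    df = rows.copy()
    drops = {}

    lon = pd.to_numeric(df["decimalLongitude"], errors="coerce")
    lat = pd.to_numeric(df["decimalLatitude"], errors="coerce")
    ok = np.isfinite(lon) & np.isfinite(lat)
    drops["missing_coordinates"] = int((~ok).sum())
    df, lon, lat = df[ok], lon[ok], lat[ok]

    ok = (lon.abs() <= 180) & (lat.abs() <= 90)
    drops["coordinate_range"] = int((~ok).sum())
    df, lon, lat = df[ok], lon[ok], lat[ok]

    ok = ~((lon == 0.0) & (lat == 0.0))
    drops["zero_zero"] = int((~ok).sum())
    df, lon, lat = df[ok], lon[ok], lat[ok]
    df = df.assign(decimalLongitude=lon, decimalLatitude=lat)

    polys = {r.code: box(r.lon_min - tolerance_deg, r.lat_min - tolerance_deg,
                         r.lon_max + tolerance_deg, r.lat_max + tolerance_deg)
             for r in countries.itertuples()}
    known = df["countryCode"].isin(polys)
    drops["unknown_country"] = int((~known).sum())
    df = df[known]

    in_country = np.ones(len(df), bool)
    for code, grp in df.groupby("countryCode", sort=False):
        inside = contains_xy(polys[code], grp["decimalLongitude"].to_numpy(),
                             grp["decimalLatitude"].to_numpy())
        in_country[df.index.get_indexer(grp.index)] = inside
    drops["outside_country"] = int((~in_country).sum())
    df = df[in_country]

    n0 = len(df)
    df = df.drop_duplicates(subset=["scientificName", "decimalLongitude",
                                    "decimalLatitude"])
    drops["duplicate"] = n0 - len(df)
    for rule, n in drops.items():
        if n:
            log.info("clean_occurrences: dropped %d rows (%s)", n, rule)
    return df.reset_index(drop=True), drops


def occupied_cells(rows: pd.DataFrame, grid: GridSpec | None = None) -> set:
    """Set of (column, row) grid cell indices covered by the occurrences."""
    grid = grid or GridSpec()
    if len(rows) == 0:
        return set()
    ix, iy = cell_indices(rows["decimalLongitude"].to_numpy(float),
                          rows["decimalLatitude"].to_numpy(float), grid)
    return set(zip(ix.tolist(), iy.tolist()))


def cell_indices(lon: np.ndarray, lat: np.ndarray, grid: GridSpec):
    """Vectorized (column, row) assignment; the lon=180/lat=90 edges fold
    into the last cell so the grid tiles the globe without overlap."""
    cs = grid.cell_size_deg
    ix = np.floor((lon - grid.origin[0]) / cs).astype(np.int64)
    iy = np.floor((lat - grid.origin[1]) / cs).astype(np.int64)
    ix = np.minimum(ix, int(np.floor((180.0 - grid.origin[0]) / cs - 1e-9)))
    iy = np.minimum(iy, int(np.floor((90.0 - grid.origin[1]) / cs - 1e-9)))
    return ix, iy


def cellset_aoo(cells: set, grid: GridSpec) -> float:
    """Total km^2 of a set of (column, row) cells."""
    if not cells:
        return 0.0
    rows = np.array([c[1] for c in cells])
    return float(np.sum(grid.cell_area_km2(rows)))


def route_occurrences(occurrences: pd.DataFrame, statuses: pd.DataFrame,
                      naturalizations: pd.DataFrame, include_nt: bool = False
                      ) -> pd.DataFrame:
    """Label each occurrence row with its partition.

    native + a national status row -> native_threatened / native_ok by the
    threatened predicate; introduced + a naturalization row -> naturalized;
    anything else (no role registered for that species in that country, or
    a flag contradicting the tables) -> unresolved.
    """
    df = occurrences.copy()
    thr_codes = {c.value for c in IUCNCategory
                 if is_threatened(c, include_nt)}
    st = statuses.drop_duplicates(["speciesName", "countryCode"]).copy()
    st["__thr"] = st["category"].astype(str).isin(thr_codes)
    merged = df.merge(
        st[["speciesName", "countryCode", "__thr"]],
        left_on=["scientificName", "countryCode"],
        right_on=["speciesName", "countryCode"], how="left")
    nat = naturalizations.drop_duplicates(["speciesName", "countryCode"]).copy()
    nat["__nat"] = True
    merged = merged.merge(
        nat[["speciesName", "countryCode", "__nat"]],
        left_on=["scientificName", "countryCode"],
        right_on=["speciesName", "countryCode"], how="left")
    means = merged["establishmentMeans"].to_numpy()
    has_status = merged["__thr"].notna().to_numpy()
    thr = merged["__thr"].to_numpy() == True  # noqa: E712 (object col with NaN)
    is_nat = merged["__nat"].to_numpy() == True  # noqa: E712
    labels = np.full(len(df), UNRESOLVED, dtype=object)
    native = (means == "native") & has_status
    labels[native & thr] = NATIVE_THREATENED
    labels[native & ~thr] = NATIVE_OK
    labels[(means == "introduced") & is_nat] = NATURALIZED
    df["partition"] = labels
    n_unres = int((labels == UNRESOLVED).sum())
    if n_unres:
        log.warning("routing: %d occurrences had no registered role and were "
                    "excluded from all partitions", n_unres)
    return df


def partition_aoo(species: str, occurrences: pd.DataFrame, statuses: pd.DataFrame,
                  naturalizations: pd.DataFrame, grid: GridSpec | None = None,
                  include_nt: bool = False) -> OccupancyPartition:
    """AOO partition for one species from its cleaned occurrences."""
    grid = grid or GridSpec()
    occ = occurrences[occurrences["scientificName"] == species]
    routed = route_occurrences(occ, statuses, naturalizations, include_nt)
    part = OccupancyPartition(accepted_name=species)
    for label, attr in ((NATIVE_THREATENED, "cells_native_threatened"),
                        (NATIVE_OK, "cells_native_ok"),
                        (NATURALIZED, "cells_naturalized")):
        cells = occupied_cells(routed[routed["partition"] == label], grid)
        setattr(part, attr, cells)
    part.n_unresolved = int((routed["partition"] == UNRESOLVED).sum())
    part.aoo_native_threatened = cellset_aoo(part.cells_native_threatened, grid)
    part.aoo_native_ok = cellset_aoo(part.cells_native_ok, grid)
    part.aoo_naturalized = cellset_aoo(part.cells_naturalized, grid)
    denom = part.aoo_native_threatened + part.aoo_native_ok
    part.pct_native_threatened = (
        100.0 * part.aoo_native_threatened / denom if denom > 0 else None)
    return part


def partition_aoo_all(occurrences: pd.DataFrame, statuses: pd.DataFrame,
                      naturalizations: pd.DataFrame, grid: GridSpec | None = None,
                      include_nt: bool = False) -> pd.DataFrame:
    """Vectorized per-species AOO partition table.

    Returns one row per species with cell counts, per-partition AOO (km^2),
    the native-partition overlap (cells counted in both native partitions),
    pctNativeThreatened (NaN when the species has no native AOO) and the
    count of unresolved occurrences.
    """
    grid = grid or GridSpec()
    routed = route_occurrences(occurrences, statuses, naturalizations, include_nt)
    unresolved = (routed[routed["partition"] == UNRESOLVED]
                  .groupby("scientificName").size())
    routed = routed[routed["partition"] != UNRESOLVED].copy()
    species = sorted(set(occurrences["scientificName"]))
    out = pd.DataFrame({"acceptedName": species}).set_index("acceptedName")
    tags = {NATIVE_THREATENED: "NativeThreatened", NATIVE_OK: "NativeOk",
            NATURALIZED: "Naturalized"}
    if len(routed):
        ix, iy = cell_indices(routed["decimalLongitude"].to_numpy(float),
                              routed["decimalLatitude"].to_numpy(float), grid)
        routed["cell_x"], routed["cell_y"] = ix, iy
        cells = routed.drop_duplicates(["scientificName", "partition", "cell_x", "cell_y"])
        cells = cells.assign(area=np.asarray(grid.cell_area_km2(cells["cell_y"].to_numpy())))
        agg = (cells.groupby(["scientificName", "partition"])
               .agg(n_cells=("area", "size"), aoo=("area", "sum")).reset_index())
        for label, tag in tags.items():
            sub = agg[agg["partition"] == label].set_index("scientificName")
            out[f"aoo{tag}"] = sub["aoo"]
            out[f"nCells{tag}"] = sub["n_cells"]
        native = cells[cells["partition"].isin([NATIVE_THREATENED, NATIVE_OK])]
        overlap = (native.groupby(["scientificName", "cell_x", "cell_y"]).size() > 1)
        out["nCellsNativeOverlap"] = overlap.groupby("scientificName").sum()
    else:
        for tag in tags.values():
            out[f"aoo{tag}"] = np.nan
            out[f"nCells{tag}"] = np.nan
        out["nCellsNativeOverlap"] = np.nan
    for tag in tags.values():
        out[f"aoo{tag}"] = out[f"aoo{tag}"].fillna(0.0)
        out[f"nCells{tag}"] = out[f"nCells{tag}"].fillna(0).astype(int)
    out["nCellsNativeOverlap"] = out["nCellsNativeOverlap"].fillna(0).astype(int)
    denom = out["aooNativeThreatened"] + out["aooNativeOk"]
    out["pctNativeThreatened"] = np.where(
        denom > 0, 100.0 * out["aooNativeThreatened"] / denom, np.nan)
    out["nUnresolved"] = out.index.map(unresolved).fillna(0).astype(int)
    return out.reset_index()
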