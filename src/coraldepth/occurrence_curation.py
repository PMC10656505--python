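"""Curation of coral occurrence records and species depth/latitude ranges.

Implements the record-level filters applied before any phylogenetic
modelling:

* a bathymetry consistency check — a record whose depth deviates from the
  gridded seafloor depth of its cell by more than a wide tolerance
  (default 500 m) is treated as a wrong depth record;
* a photic-zone plausibility rule for zooxanthellate species — records below
  the deepest documented zooxanthellate register (default 165 m) are kept
  only while consecutive sorted depths are no more than 50 m apart, because
  isolated deep records of symbiotic corals are likely identification or
  sampling errors;
* a hard depth cap for azooxanthellate species (default 5740 m).

Filtered occurrences are then summarized per species into min/median/max
depth (the median rather than the mean, because sampling effort decreases
with depth) and latitude extremes, with depths below 1 m clamped to 1 m
before log10 and the minimum latitude set to zero for ranges crossing the
equator.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

RULE_BATHYMETRY = "bathymetry_mismatch"
RULE_PHOTIC_GAP = "photic_gap"
RULE_AZ_CAP = "az_depth_cap"


class BathymetryGrid:
    """Regular lon/lat grid of seafloor depths (m, positive down).

    Plain-text format: a five-line header (ncols, nrows, xllcorner,
    yllcorner, cellsize) followed by ``nrows`` rows of depths, northernmost
    row first (ESRI ASCII grid layout).  Lookup is nearest-cell.
    """

    def __init__(self, depth: np.ndarray, xll: float, yll: float, cellsize: float):
        self.depth = np.asarray(depth, dtype=float)  # (nrows, ncols), row 0 = north
        self.xll = float(xll)
        self.yll = float(yll)
        self.cellsize = float(cellsize)

    @property
    def nrows(self) -> int:
        return self.depth.shape[0]

    @property
    def ncols(self) -> int:
        return self.depth.shape[1]

    def cell_of(self, lon, lat):
        col = np.clip(((np.asarray(lon) - self.xll) / self.cellsize).astype(int),
                      0, self.ncols - 1)
        row_from_s = np.clip(((np.asarray(lat) - self.yll) / self.cellsize).astype(int),
                             0, self.nrows - 1)
        return self.nrows - 1 - row_from_s, col

    def depth_at(self, lon, lat):
        row, col = self.cell_of(lon, lat)
        return self.depth[row, col]

    def dumps(self) -> str:
        out = io.StringIO()
        out.write(f"ncols {self.ncols}\nnrows {self.nrows}\n")
        out.write(f"xllcorner {self.xll}\nyllcorner {self.yll}\ncellsize {self.cellsize}\n")
        for row in self.depth:
            out.write(" ".join(f"{v:g}" for v in row) + "\n")
        return out.getvalue()

    @classmethod
    def loads(cls, text: str) -> "BathymetryGrid":
        lines = text.strip().splitlines()
        hdr = {}
        for ln in lines[:5]:
            k, v = ln.split()
            hdr[k.lower()] = float(v)
        depth = np.loadtxt(io.StringIO("\n".join(lines[5:])))
        depth = depth.reshape(int(hdr["nrows"]), int(hdr["ncols"]))
        return cls(depth, hdr["xllcorner"], hdr["yllcorner"], hdr["cellsize"])

    def write(self, path: str):
        with open(path, "w") as fh:
            fh.write(self.dumps())

    @classmethod
    def read(cls, path: str) -> "BathymetryGrid":
        with open(path) as fh:
            return cls.loads(fh.read())


@dataclass
class CurationResult:
    kept: pd.DataFrame
    removal_log: pd.DataFrame  # columns: record_id, species, depth_m, rule


def apply_depth_filters(
    occurrences: pd.DataFrame,
    raster: BathymetryGrid,
    traits: pd.DataFrame,
    tol: float = 500.0,
    photic_cutoff: float = 165.0,
    gap: float = 50.0,
    az_cap: float = 5740.0,
) -> CurationResult:
    """Apply the three depth-plausibility filters to an occurrence table.

    Parameters
    ----------
    occurrences
        Columns ``species, lon, lat, depth_m`` (depth positive down, m).
    raster
        Gridded bathymetry used for the consistency check.
    traits
        Indexed by (or containing a column) ``species`` with a boolean
        ``symbiotic`` column; every species in ``occurrences`` must appear.
    tol, photic_cutoff, gap, az_cap
        Rule thresholds in metres (defaults are the study values).

    Rules fire in a fixed order per record: bathymetry mismatch first, then
    the zooxanthellate gap rule, then the azooxanthellate cap.  The gap rule
    walks the per-species depths in sorted order starting from the deepest
    record at or above the cutoff (records exactly at the cutoff count as
    above it) and drops everything beyond the first consecutive gap > ``gap``.
    Filtering is therefore order-independent with respect to input row order.
    """
    occ = occurrences.reset_index(drop=True).copy()
    occ["record_id"] = occ.index
    tr = traits.set_index("species") if "species" in traits.columns else traits
    missing = sorted(set(occ["species"]) - set(tr.index))
    if missing:
        raise ValueError(f"species missing trait flags: {missing}")
    symbiotic = occ["species"].map(tr["symbiotic"]).to_numpy(dtype=bool)

    drops: list[tuple[int, str, float, str]] = []

    # rule 1: bathymetry consistency
    grid_depth = raster.depth_at(occ["lon"].to_numpy(), occ["lat"].to_numpy())
    bathy_bad = np.abs(occ["depth_m"].to_numpy() - grid_depth) > tol
    for rid in occ.index[bathy_bad]:
        drops.append((rid, occ.at[rid, "species"], occ.at[rid, "depth_m"], RULE_BATHYMETRY))
    alive = ~bathy_bad

    # rule 2: zooxanthellate consecutive-gap rule below the photic cutoff
    for sp, sub in occ[alive & symbiotic].groupby("species"):
        sub = sub.sort_values("depth_m")
        depths = sub["depth_m"].to_numpy()
        below = depths > photic_cutoff  # records at the cutoff count as above it
        if not below.any():
            continue
        shallow = depths[~below]
        prev = shallow.max() if shallow.size else photic_cutoff
        broken = False
        for rid, d in zip(sub["record_id"].to_numpy()[below], depths[below]):
            if broken or d - prev > gap:
                broken = True
                drops.append((rid, sp, d, RULE_PHOTIC_GAP))
            else:
                prev = d
    dropped_ids = {d[0] for d in drops}
    alive = ~occ["record_id"].isin(dropped_ids).to_numpy()

    # rule 3: azooxanthellate depth cap
    cap_bad = alive & ~symbiotic & (occ["depth_m"].to_numpy() > az_cap)
    for rid in occ.index[cap_bad]:
        drops.append((rid, occ.at[rid, "species"], occ.at[rid, "depth_m"], RULE_AZ_CAP))

    log = pd.DataFrame(drops, columns=["record_id", "species", "depth_m", "rule"])
    kept = occ[~occ["record_id"].isin(log["record_id"])].drop(columns="record_id")
    return CurationResult(kept=kept.reset_index(drop=True), removal_log=log)


def summarize_species_ranges(
    occurrences: pd.DataFrame, traits: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-species min/median/max depth (m and log10) and latitude extremes.

    Depths below 1 m are clamped to 1 m before log10 so the log-scale range
    is non-negative.  For species whose latitudinal range crosses the
    equator, the minimum (absolute) latitude is set to zero.  Species with no
    records are simply absent; an empty input yields an empty table with a
    warning.
    """
    if len(occurrences) == 0:
        warnings.warn("no occurrence records to summarize")
    rows = []
    for sp, sub in occurrences.groupby("species"):
        d = sub["depth_m"].to_numpy(dtype=float)
        lat = sub["lat"].to_numpy(dtype=float)
        dmin, dmed, dmax = d.min(), float(np.median(d)), d.max()
        crosses = lat.min() < 0 < lat.max()
        lat_min = 0.0 if crosses else np.abs(lat).min()
        row = {
            "species": sp,
            "depth_min_m": dmin,
            "depth_median_m": dmed,
            "depth_max_m": dmax,
            "log_depth_min": np.log10(max(dmin, 1.0)),
            "log_depth_median": np.log10(max(dmed, 1.0)),
            "log_depth_max": np.log10(max(dmax, 1.0)),
            "lat_min": lat_min,
            "lat_max": np.abs(lat).max(),
            "n_records": len(sub),
        }
        rows.append(row)
    out = pd.DataFrame(rows)
    if traits is not None and len(out):
        tr = traits.set_index("species") if "species" in traits.columns else traits
        for col in ("symbiotic", "colonial", "facultative"):
            if col in tr.columns:
                out[col] = out["species"].map(tr[col]).to_numpy()
    return out


def dataset_agreement(
    ranges_a: pd.DataFrame,
    ranges_b: pd.DataFrame,
    metrics: tuple[str, ...] = ("log_depth_min", "log_depth_median", "log_depth_max"),
) -> pd.DataFrame:
    """Spearman rank agreement between two range tables, per depth metric.

    Used to decide whether two alternative curations of the same occurrence
    data (for instance a maximal and a more conservative depth set) imply
    the same ranking of species and can stand in for each other.
    """
    a = ranges_a.set_index("species")
    b = ranges_b.set_index("species")
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared species, got {len(shared)}")
    rows = []
    for m in metrics:
        rho, p = stats.spearmanr(a.loc[shared, m], b.loc[shared, m])
        rows.append({"metric": m, "rho": rho, "p_value": p, "n": len(shared)})
    return pd.DataFrame(rows)


def trait_composition(group_counts: dict[str, int], n_total: int) -> pd.DataFrame:
    """Composition of a species trait table with four fixed-trait groups.

    ``group_counts`` maps group label (AS/AC/ZS/ZC) to species count;
    species not in any fixed group are facultative for one of the traits.
    Percentages are of ``n_total``, rounded to two decimals.
    """
    rows = [
        {"group": g, "n": n, "percent": round(100.0 * n / n_total, 2)}
        for g, n in group_counts.items()
    ]
    n_fac = n_total - sum(group_counts.values())
    if n_fac < 0:
        raise ValueError("group counts exceed the total")
    rows.append({"group": "facultative", "n": n_fac,
                 "percent": round(100.0 * n_fac / n_total, 2)})
    return pd.DataFrame(rows)
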