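"""Species elevational ranges, band schemes, and richness profiles.

The sampling unit throughout the package is the fixed-width elevational band
(500 m by default).  A species' elevational range is interpolated: the species
is assumed present at every elevation between its minimum and maximum records,
so a range contributes to every band its interval touches.

Band-edge convention
--------------------
Bands are half-open intervals ``[low, high)``; species intervals are closed
``[elev_min, elev_max]``.  A species whose maximum sits exactly on a band edge
therefore still touches the band above that edge (point overlap with the
band's included lower edge), and a point range exactly on an interior edge
belongs to the upper band only.  This avoids both double counting and zero
counting at edges.  Presence below the scheme base (the gradient floor, 500 m
for tropical montane work) is clipped and ignored.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("elevdiv")

__all__ = [
    "SpeciesRange",
    "BandScheme",
    "RichnessProfile",
    "RangeTableError",
    "load_range_table",
    "write_range_table",
    "inflate_point_ranges",
    "interpolate_presence",
    "richness_per_band",
]


class RangeTableError(ValueError):
    """Raised when a range table is malformed (missing columns, bad rows)."""


@dataclass(frozen=True)
class SpeciesRange:
    """One species' elevational extent.

    Parameters
    ----------
    species_id
        Unique species identifier (e.g. a binomial).
    elev_min, elev_max
        Lowest and highest elevational records, metres a.s.l.
    regions
        Identifiers of the regions (mountain ranges, domains) the species
        occurs in; may be empty when analysing a single gradient.
    """

    species_id: str
    elev_min: float
    elev_max: float
    regions: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not (math.isfinite(self.elev_min) and math.isfinite(self.elev_max)):
            raise ValueError(f"{self.species_id}: non-finite elevation")
        if self.elev_min < 0:
            raise ValueError(f"{self.species_id}: elev_min {self.elev_min} < 0")
        if self.elev_min > self.elev_max:
            raise ValueError(
                f"{self.species_id}: elev_min {self.elev_min} > elev_max {self.elev_max}"
            )
        if not isinstance(self.regions, frozenset):
            object.__setattr__(self, "regions", frozenset(self.regions))

    @property
    def midpoint(self) -> float:
        """Range midpoint, (min + max) / 2.  Always recomputed, never stored."""
        return 0.5 * (self.elev_min + self.elev_max)

    @property
    def size(self) -> float:
        """Elevational range size, max - min."""
        return self.elev_max - self.elev_min


@dataclass(frozen=True)
class BandScheme:
    """A grid of contiguous half-open elevational bands ``[base+i*w, base+(i+1)*w)``."""

    base: float = 500.0
    width: float = 500.0
    n_bands: int = 9

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be positive")
        if self.n_bands < 1:
            raise ValueError("need at least one band")

    @property
    def top(self) -> float:
        return self.base + self.n_bands * self.width

    @property
    def edges(self) -> np.ndarray:
        """The ``n_bands + 1`` band edges."""
        return self.base + self.width * np.arange(self.n_bands + 1)

    @property
    def midpoints(self) -> np.ndarray:
        return self.base + self.width * (np.arange(self.n_bands) + 0.5)

    def band_of(self, elevation: float | np.ndarray) -> np.ndarray:
        """Band index of an elevation (half-open rule); -1 outside the scheme."""
        idx = np.floor((np.asarray(elevation, dtype=float) - self.base) / self.width)
        out = idx.astype(int)
        out[(idx < 0) | (idx >= self.n_bands)] = -1
        return out


@dataclass(frozen=True)
class RichnessProfile:
    """Per-band species counts (gamma diversity) on a band scheme."""

    scheme: BandScheme
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (self.scheme.n_bands,):
            raise ValueError("counts length must equal n_bands")
        if (counts < 0).any():
            raise ValueError("negative band count")
        object.__setattr__(self, "counts", counts)

    @property
    def band_midpoints(self) -> np.ndarray:
        return self.scheme.midpoints

    def to_frame(self) -> pd.DataFrame:
        edges = self.scheme.edges
        return pd.DataFrame(
            {
                "band_low": edges[:-1],
                "band_high": edges[1:],
                "band_mid": self.scheme.midpoints,
                "richness": self.counts,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_frame().to_dict(orient="list"), indent=1))


# Default column mapping for range tables; override any entry via the
# ``dialect`` argument of load_range_table.
DEFAULT_DIALECT: Mapping[str, str] = {
    "species": "species",
    "elev_min": "elev_min",
    "elev_max": "elev_max",
    "regions": "regions",  # optional, semicolon-separated
}


def load_range_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> list[SpeciesRange]:
    """Read a species elevational range table from CSV.

    The table needs at least a species-id column and min/max elevation
    columns; an optional regions column holds semicolon-separated region
    identifiers.  Column names are configurable through ``dialect``.
    Midpoint or range-size columns, if present, are ignored — derived
    quantities are always recomputed.

    Raises
    ------
    RangeTableError
        If a required column is missing, a species id is duplicated, or a
        row has min > max (the offending row is named).
    """
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    df = pd.read_csv(path, float_precision="round_trip")
    for key in ("species", "elev_min", "elev_max"):
        if cols[key] not in df.columns:
            raise RangeTableError(
                f"{path}: required column {cols[key]!r} (for {key}) not found; "
                f"available: {list(df.columns)}"
            )
    has_regions = cols["regions"] in df.columns

    out: list[SpeciesRange] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        sid = str(row[cols["species"]])
        if sid in seen:
            raise RangeTableError(f"{path}: duplicated species id {sid!r} at row {i}")
        seen.add(sid)
        lo, hi = float(row[cols["elev_min"]]), float(row[cols["elev_max"]])
        if lo > hi:
            raise RangeTableError(
                f"{path}: row {i} ({sid}): elev_min {lo} > elev_max {hi}"
            )
        regions: frozenset[str] = frozenset()
        if has_regions and not pd.isna(row[cols["regions"]]):
            regions = frozenset(
                r.strip() for r in str(row[cols["regions"]]).split(";") if r.strip()
            )
        try:
            out.append(SpeciesRange(sid, lo, hi, regions))
        except ValueError as e:
            raise RangeTableError(f"{path}: row {i}: {e}") from e
    logger.info("loaded %d species ranges from %s", len(out), path)
    return out


def write_range_table(ranges: Sequence[SpeciesRange], path: str | Path) -> None:
    """Write ranges as CSV in the default dialect (round-trips with the loader)."""
    pd.DataFrame(
        {
            "species": [r.species_id for r in ranges],
            "elev_min": [r.elev_min for r in ranges],
            "elev_max": [r.elev_max for r in ranges],
            "regions": [";".join(sorted(r.regions)) for r in ranges],
        }
    ).to_csv(path, index=False, float_format="%.17g")  # exact float round-trip


def inflate_point_ranges(
    ranges: Iterable[SpeciesRange], delta: float = 5.0
) -> list[SpeciesRange]:
    """Give point ranges (single-locality species) a nonzero size.

    Every range with ``elev_min == elev_max`` becomes
    ``[min - delta, max + delta]``, floored at 0 m; other ranges are
    unchanged.  Null-model range shuffling needs nonzero sizes, hence the
    conventional +/-5 m inflation.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    out = []
    for r in ranges:
        if r.elev_min == r.elev_max:
            out.append(
                replace(r, elev_min=max(0.0, r.elev_min - delta), elev_max=r.elev_max + delta)
            )
        else:
            out.append(r)
    return out


def interpolate_presence(rng: SpeciesRange, scheme: BandScheme) -> set[int]:
    """Band indices a species' interpolated range touches.

    A band is included iff the closed species interval intersects the
    half-open band interval (positive-length or point overlap).  A range
    entirely outside the scheme yields an empty set.
    """
    lo, hi = rng.elev_min, rng.elev_max
    if hi < scheme.base or lo >= scheme.top:
        return set()
    # lowest band whose [low, high) the closed interval meets: floor((lo-base)/w);
    # a lo exactly on an edge is excluded from the band below (half-open).
    i_min = max(0, math.floor((lo - scheme.base) / scheme.width))
    # highest band: hi touching a band's lower edge counts (closed interval).
    i_max = min(scheme.n_bands - 1, math.floor((hi - scheme.base) / scheme.width))
    if i_max < i_min:
        return set()
    return set(range(i_min, i_max + 1))


def richness_per_band(
    ranges: Iterable[SpeciesRange],
    scheme: BandScheme,
    region: str | None = None,
) -> RichnessProfile:
    """Tally per-band species richness from interpolated ranges.

    When ``region`` is given only species whose region set contains it are
    counted (region membership comes from the input table, not coordinates).
    """
    counts = np.zeros(scheme.n_bands, dtype=int)
    for r in ranges:
        if region is not None and region not in r.regions:
            continue
        for i in interpolate_presence(r, scheme):
            counts[i] += 1
    return RichnessProfile(scheme, counts)
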