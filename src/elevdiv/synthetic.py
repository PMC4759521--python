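"""Synthetic species-range tables and DEMs with known structure.

Every pipeline stage is testable without downloads: this module emulates
the two external inputs — a compiled elevational range database and a
coarse global DEM — at the scale of a tropical montane study system
(hundreds of species, a 500–5000 m gradient, DEM tiles of up to a few
hundred cells per side).

Two midpoint laws are provided.  ``mde_uniform`` places each range's
midpoint uniformly in its feasible interval, so the mid-domain null model
is true by construction — data generated this way must fit the null
closely, which is the generator's main diagnostic role.  ``niche_normal``
clusters midpoints around an elevational optimum, producing the
hump-shaped profiles typical of real montane clades without the geometry
being the cause.

Range sizes default to a lognormal law (right-skewed, as empirical
elevational range-size distributions are).  DEMs are cross-sectional
ridges with a convex flank profile (band area decreasing with elevation,
as in the northern tropical Andes) and an optional high-elevation plateau
(an interior band-area maximum, as the central Andean altiplano produces),
plus Gaussian roughness that sets the topographic ruggedness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .mde_null import Domain
from .ranges import SpeciesRange, write_range_table
from .terrain import DemGrid, write_ascii_grid

logger = logging.getLogger("elevdiv")

__all__ = [
    "SyntheticSpec",
    "make_species",
    "make_dem",
    "make_study_standin",
    "make_mountain_system",
    "MountainSystem",
    "write_fixtures",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic species set.

    ``range_size_law`` is ``("uniform", a, b)``, ``("lognormal", mu, sigma)``
    (of the underlying normal, metres) or ``("empirical", sizes)``;
    ``midpoint_law`` is ``("mde_uniform",)`` or ``("niche_normal", center, sd)``.
    Sizes are clipped to the domain span and midpoints to feasibility, so
    generated ranges always respect the domain.
    """

    n_species: int
    domain: Domain = field(default_factory=lambda: Domain(500.0, 5000.0))
    range_size_law: tuple = ("lognormal", 6.55, 0.8)
    midpoint_law: tuple = ("mde_uniform",)
    seed: int = 0
    prefix: str = "sp"
    regions: frozenset[str] = field(default_factory=frozenset)


def _draw_sizes(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    law = spec.range_size_law
    n = spec.n_species
    if law[0] == "uniform":
        _, a, b = law
        if not (0 < a <= b):
            raise ValueError(f"uniform size law needs 0 < a <= b, got {law}")
        sizes = rng.uniform(a, b, n)
    elif law[0] == "lognormal":
        _, mu, sigma = law
        if sigma < 0:
            raise ValueError(f"lognormal sigma must be >= 0, got {sigma}")
        sizes = rng.lognormal(mu, sigma, n)
    elif law[0] == "empirical":
        sizes = rng.choice(np.asarray(law[1], dtype=float), size=n, replace=True)
    else:
        raise ValueError(f"unknown range-size law {law[0]!r}")
    sizes = np.clip(sizes, 1.0, spec.domain.span)
    return sizes


def _draw_midpoints(
    spec: SyntheticSpec, sizes: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    f_lo = spec.domain.low + sizes / 2
    f_hi = spec.domain.high - sizes / 2
    law = spec.midpoint_law
    if law[0] == "mde_uniform":
        return f_lo + rng.random(len(sizes)) * (f_hi - f_lo)
    if law[0] == "niche_normal":
        _, center, sd = law
        if sd <= 0:
            raise ValueError(f"niche_normal sd must be positive, got {sd}")
        return np.clip(rng.normal(center, sd, len(sizes)), f_lo, f_hi)
    raise ValueError(f"unknown midpoint law {law[0]!r}")


def make_species(spec: SyntheticSpec) -> list[SpeciesRange]:
    """Generate a seeded species-range set under the spec's laws."""
    if spec.n_species < 0:
        raise ValueError("n_species must be >= 0")
    rng = np.random.default_rng(spec.seed)
    sizes = _draw_sizes(spec, rng)
    mids = _draw_midpoints(spec, sizes, rng)
    width = len(str(max(spec.n_species, 1)))
    return [
        SpeciesRange(
            f"{spec.prefix}{i:0{width}d}",
            float(m - s / 2),
            float(m + s / 2),
            spec.regions,
        )
        for i, (m, s) in enumerate(zip(mids, sizes))
    ]


def make_study_standin(seed: int = 0) -> list[SpeciesRange]:
    """A synthetic stand-in for a tropical-Andes rain-frog range database.

    378 species on a 500–4538 m gradient: lognormal range sizes (median
    about 700 m) and niche-clustered midpoints (optimum 2400 m, sd 900 m),
    which yields a hump-shaped richness profile peaking at mid elevations.
    The recorded extremes are pinned: the lowest species reaches the 500 m
    gradient floor and the highest reaches 4538 m.  This is synthetic data
    at the scale and shape of the real database, not a reconstruction of it.
    """
    spec = SyntheticSpec(
        n_species=378,
        domain=Domain(500.0, 4538.0),
        range_size_law=("lognormal", float(np.log(700.0)), 0.8),
        midpoint_law=("niche_normal", 2400.0, 900.0),
        seed=seed,
    )
    ranges = make_species(spec)
    lo_i = int(np.argmin([r.elev_min for r in ranges]))
    hi_i = int(np.argmax([r.elev_max for r in ranges]))
    lo = ranges[lo_i]
    ranges[lo_i] = SpeciesRange(lo.species_id, 500.0, lo.elev_max, lo.regions)
    hi = ranges[hi_i]
    ranges[hi_i] = SpeciesRange(hi.species_id, hi.elev_min, 4538.0, hi.regions)
    return ranges


def make_dem(
    ridge_height: float,
    ruggedness: float,
    extent: float = 1.0,
    latitude: float = 0.0,
    seed: int = 0,
    n_cells: int = 120,
    plateau_elev: float | None = None,
    profile_exponent: float = 2.0,
    lon: float = -75.0,
) -> DemGrid:
    """Generate a ridge-shaped DEM tile.

    The tile is an ``n_cells x n_cells`` grid spanning ``extent`` degrees,
    centred at ``latitude``.  Elevation follows a cross-sectional ridge:
    each cell's height is a convex function (exponent ``profile_exponent``)
    of its normalized distance from the east/west edges to the central
    ridge line, topping out at ``ridge_height``, so band area decreases
    monotonically with elevation.  With ``plateau_elev`` set, the flank
    profile gains a long near-flat bench at that elevation, creating an
    interior maximum in the band-area curve.  Independent Gaussian noise
    of standard deviation ``ruggedness`` (metres) is added per cell.
    """
    if extent <= 0:
        raise ValueError("extent must be positive")
    rng = np.random.default_rng(seed)
    c = (n_cells - 1) / 2
    j = np.arange(n_cells)[None, :]
    i = np.arange(n_cells)[:, None]
    # shear the ridge axis by one cell from north to south: rows sample the
    # flank profile at staggered offsets, so band hypsometry is smooth rather
    # than quantized to whole columns
    x = j + (i / n_cells - 0.5)
    d = np.clip(1.0 - np.abs(x - c) / c, 0.0, 1.0)  # 0 at edges, 1 at the ridge
    if plateau_elev is None:
        profile = ridge_height * d**profile_exponent
    else:
        if not 0 < plateau_elev < ridge_height:
            raise ValueError("plateau_elev must lie between 0 and ridge_height")
        # long near-flat bench around the plateau elevation
        e = plateau_elev
        d_nodes = np.array([0.0, 0.45, 0.9, 1.0])
        e_nodes = np.array([0.0, e - 0.02 * ridge_height, e + 0.02 * ridge_height, ridge_height])
        profile = np.interp(d, d_nodes, e_nodes)
    values = profile
    if ruggedness > 0:
        values = values + rng.normal(0.0, ruggedness, values.shape)
    values = np.maximum(values, 0.0)
    cellsize = extent / n_cells
    return DemGrid(values, xll=lon, yll=latitude - extent / 2, cellsize=cellsize)


@dataclass(frozen=True)
class MountainSystem:
    """A toy multi-cordillera system: per-region DEMs plus a pooled species table."""

    species: list[SpeciesRange]
    dems: dict[str, DemGrid]
    latitudes: dict[str, float]


def make_mountain_system(
    seed: int = 0,
    n_regions: int = 6,
    species_per_region: int = 80,
    domain: Domain = Domain(500.0, 5000.0),
    n_cells: int = 80,
    latitude_slope: float = -4.55,
    noise_sd: float = 3.0,
) -> MountainSystem:
    """Generate a complete toy mountain system.

    Regions sit at distinct latitudes spanning roughly 8°N to 15°S.
    Regional species totals decline with absolute latitude at
    ``latitude_slope`` species per degree (plus Gaussian noise of
    ``noise_sd``), emulating a latitudinal diversity gradient; midpoints
    are niche-clustered at mid elevations.  Region DEMs are ridges of
    varying height and ruggedness; southern regions get a high-elevation
    plateau, as in central-Andean hypsometry.
    """
    rng = np.random.default_rng(seed)
    lats = np.linspace(8.0, -15.0, n_regions)
    species: list[SpeciesRange] = []
    dems: dict[str, DemGrid] = {}
    latitudes: dict[str, float] = {}
    for i, lat in enumerate(lats):
        name = f"cordillera_{i + 1}"
        n_sp = int(
            round(
                species_per_region
                + latitude_slope * abs(lat)
                + rng.normal(0.0, noise_sd)
            )
        )
        n_sp = max(n_sp, 5)
        sub = SyntheticSpec(
            n_species=n_sp,
            domain=domain,
            range_size_law=("lognormal", float(np.log(700.0)), 0.8),
            midpoint_law=("niche_normal", 2500.0, 900.0),
            seed=int(rng.integers(2**31 - 1)),
            prefix=f"r{i + 1}_sp",
            regions=frozenset({name}),
        )
        species.extend(make_species(sub))
        plateau = 3700.0 if lat < -5 else None
        dems[name] = make_dem(
            ridge_height=float(rng.uniform(4200, 5200)),
            ruggedness=float(rng.uniform(20, 80)),
            extent=1.0,
            latitude=float(lat),
            seed=int(rng.integers(2**31 - 1)),
            n_cells=n_cells,
            plateau_elev=plateau,
            lon=-78.0 + 0.8 * i,
        )
        latitudes[name] = float(lat)
    return MountainSystem(species, dems, latitudes)


def write_fixtures(
    out_dir: str | Path,
    seed: int = 0,
    n_regions: int = 6,
    n_sims: int = 5000,
    **kwargs,
) -> Path:
    """Materialize a toy mountain system on disk, ready for a full run.

    Writes ``ranges.csv``, one ASCII-grid DEM per region under ``dems/``,
    and a ``config.yaml`` the pipeline can consume directly.  Returns the
    config path.
    """
    out = Path(out_dir)
    (out / "dems").mkdir(parents=True, exist_ok=True)
    system = make_mountain_system(seed=seed, n_regions=n_regions, **kwargs)
    write_range_table(system.species, out / "ranges.csv")
    for name, dem in system.dems.items():
        write_ascii_grid(dem, out / "dems" / f"{name}.asc")
    config = {
        "range_table": "ranges.csv",
        "dems": {name: f"dems/{name}.asc" for name in system.dems},
        "scheme": {"base": 500.0, "width": 500.0, "n_bands": 9},
        "n_sims": n_sims,
        "seed": seed,
    }
    cfg_path = out / "config.yaml"
    cfg_path.write_text(yaml.safe_dump(config, sort_keys=False))
    logger.info("wrote fixture system (%d regions) to %s", n_regions, out)
    return cfg_path
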