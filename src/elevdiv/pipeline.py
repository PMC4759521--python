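"""Config-driven orchestration of the full gradient analysis.

A run reproduces the standard layout of a montane diversity study: the
system as a whole, then each configured region (mountain range), each
analysed as one elevational gradient — richness profile, band area and
ruggedness, species-area model set, mid-domain null model with empirical
(and, where a significant SAR exists, area-corrected) fits, and
topographic-heterogeneity models — followed by cross-region stages: the
global SAR exponent z and the latitudinal model set with model-averaged
coefficients.

Every stage failure is caught and recorded per gradient; partial outputs
are retained.  Outputs are tidy CSV/JSON plus a run log with the seed,
package versions, chosen domain tops and per-fit exclusions, because those
choices change the statistics.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import gradient_stats as gs
from . import ranges as rg
from . import terrain as tr
from .mde_null import Domain, MdeResult, fit_corrected_to_mde, fit_empirical_to_mde, simulate_mde

logger = logging.getLogger("elevdiv")

__all__ = ["RunConfig", "GradientReport", "RunReport", "run_all", "classify_shape"]


@dataclass(frozen=True)
class RunConfig:
    """Everything a full run needs; loadable from a YAML file."""

    range_table: Path
    dems: dict[str, Path]  # region name -> DEM path
    scheme: rg.BandScheme = field(default_factory=rg.BandScheme)
    domains: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_sims: int = 50_000
    seed: int = 0
    delta: float = 5.0  # point-range inflation, metres
    alpha: float = 0.05
    replacement: bool = False
    signed_latitude: bool = False
    jacobian: bool = False
    dialect: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        base = path.parent
        scheme_raw = raw.get("scheme", {})
        scheme = rg.BandScheme(
            base=float(scheme_raw.get("base", 500.0)),
            width=float(scheme_raw.get("width", 500.0)),
            n_bands=int(scheme_raw.get("n_bands", 9)),
        )
        dems = {name: base / p for name, p in raw["dems"].items()}
        domains = {
            name: (float(v[0]), float(v[1])) for name, v in raw.get("domains", {}).items()
        }
        cfg = cls(
            range_table=base / raw["range_table"],
            dems=dems,
            scheme=scheme,
            domains=domains,
            n_sims=int(raw.get("n_sims", 50_000)),
            seed=int(raw.get("seed", 0)),
            delta=float(raw.get("delta", 5.0)),
            alpha=float(raw.get("alpha", 0.05)),
            replacement=bool(raw.get("replacement", False)),
            signed_latitude=bool(raw.get("signed_latitude", False)),
            jacobian=bool(raw.get("jacobian", False)),
            dialect=dict(raw.get("dialect", {})),
        )
        if not cfg.range_table.exists():
            raise FileNotFoundError(cfg.range_table)
        for name, p in cfg.dems.items():
            if not p.exists():
                raise FileNotFoundError(f"DEM for region {name!r}: {p}")
        return cfg


def classify_shape(counts: np.ndarray, tol: float = 0.05) -> str:
    """Label a richness curve: ``decreasing``, ``low-plateau`` or ``mid-peak``.

    Bands within ``tol`` (fraction of the peak) of the maximum form the peak
    set.  If the peak set lies entirely in the lowest third of the gradient,
    the curve is ``decreasing`` when it is a single band at the bottom of a
    monotonically non-increasing curve, else ``low-plateau``; otherwise
    ``mid-peak``.
    """
    counts = np.asarray(counts, dtype=float)
    n = len(counts)
    peak = counts.max()
    if peak <= 0:
        return "empty"
    peak_set = np.flatnonzero(counts >= (1 - tol) * peak)
    lowest_third = (n + 2) // 3
    if peak_set.max() < lowest_third:
        if len(peak_set) == 1 and peak_set[0] == 0 and np.all(np.diff(counts) <= 0):
            return "decreasing"
        return "low-plateau"
    return "mid-peak"


def default_domain(
    scheme: rg.BandScheme, counts: np.ndarray, area: np.ndarray | None
) -> Domain:
    """Null-model domain: scheme base up to the top edge of the highest band
    with land or species (the mountain-top constraint)."""
    occupied = counts > 0
    if area is not None:
        occupied = occupied | (area > 0)
    if not occupied.any():
        raise ValueError("no occupied bands; cannot infer a domain")
    top_band = int(np.flatnonzero(occupied).max())
    return Domain(scheme.base, float(scheme.edges[top_band + 1]))


@dataclass
class GradientReport:
    """All per-gradient results for one analysis level."""

    name: str
    domain: Domain
    profile: rg.RichnessProfile
    area: np.ndarray
    mean_tri: np.ndarray
    region_mean_tri: float
    mid_latitude: float
    sar: gs.ModelSet | None = None
    mde: MdeResult | None = None
    mde_fit: gs.ModelSet | None = None
    tri_raw: gs.ModelSet | None = None
    tri_adjusted: gs.ModelSet | None = None
    shape: str = ""
    corrected: np.ndarray | None = None
    corrected_fit: gs.ModelSet | None = None


@dataclass
class RunReport:
    """Bundle of all gradient reports plus the cross-gradient stages."""

    config: RunConfig
    gradients: dict[str, GradientReport]
    global_z: gs.GlobalZ | None
    latitude: gs.ModelSet | None
    averaged: gs.AveragedEstimates | None
    failures: dict[str, str]

    def fits_frame(self) -> pd.DataFrame:
        """Every fitted model in one tidy table."""
        rows = []
        for name, g in self.gradients.items():
            for response, mset in (
                ("sar", g.sar),
                ("mde_fit", g.mde_fit),
                ("mde_fit_corrected", g.corrected_fit),
                ("tri", g.tri_raw),
                ("tri_area_adjusted", g.tri_adjusted),
            ):
                if mset is None:
                    continue
                df = mset.to_frame()
                df.insert(0, "region", name)
                df.insert(1, "response", response)
                rows.append(df)
        if self.latitude is not None:
            df = self.latitude.to_frame()
            df.insert(0, "region", "__across__")
            df.insert(1, "response", "latitude")
            rows.append(df)
        return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, g in self.gradients.items():
            g.profile.to_csv(out / f"richness_{name}.csv")
            edges = g.profile.scheme.edges
            pd.DataFrame(
                {
                    "band_low": edges[:-1],
                    "band_high": edges[1:],
                    "area_km2": g.area,
                    "mean_tri": g.mean_tri,
                }
            ).to_csv(out / f"band_metrics_{name}.csv", index=False)
            if g.mde is not None:
                g.mde.to_csv(out / f"mde_{name}.csv")
            if g.corrected is not None:
                pd.DataFrame(
                    {"band_mid": g.profile.scheme.midpoints, "corrected": g.corrected}
                ).to_csv(out / f"corrected_richness_{name}.csv", index=False)
        self.fits_frame().to_csv(out / "fits.csv", index=False)
        summary: dict[str, Any] = {
            "seed": self.config.seed,
            "n_sims": self.config.n_sims,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "shapes": {n: g.shape for n, g in self.gradients.items()},
            "domains": {
                n: [g.domain.low, g.domain.high] for n, g in self.gradients.items()
            },
            "mid_latitude": {n: g.mid_latitude for n, g in self.gradients.items()},
            "failures": self.failures,
        }
        if self.global_z is not None:
            summary["global_z"] = {
                "z": self.global_z.z,
                "ci": [self.global_z.ci_low, self.global_z.ci_high],
                "contributing": list(self.global_z.contributing),
            }
        if self.averaged is not None:
            summary["averaged_estimates"] = self.averaged.estimates
            summary["model_weights"] = self.averaged.weights
        (out / "run_log.json").write_text(json.dumps(summary, indent=1))


def _analyze_gradient(
    name: str,
    species: list[rg.SpeciesRange],
    profile: rg.RichnessProfile,
    area: np.ndarray,
    mean_tri: np.ndarray,
    region_mean_tri: float,
    mid_latitude: float,
    cfg: RunConfig,
    seed: int,
    failures: dict[str, str],
) -> GradientReport:
    if name in cfg.domains:
        domain = Domain(*cfg.domains[name])
    else:
        domain = default_domain(cfg.scheme, profile.counts, area)
    g = GradientReport(
        name=name,
        domain=domain,
        profile=profile,
        area=area,
        mean_tri=mean_tri,
        region_mean_tri=region_mean_tri,
        mid_latitude=mid_latitude,
        shape=classify_shape(profile.counts),
    )
    for stage, fn in (
        ("sar", lambda: gs.sar_models(profile, area, jacobian=cfg.jacobian)),
        (
            "mde",
            lambda: simulate_mde(
                species, domain, cfg.scheme, cfg.n_sims, seed, cfg.replacement
            ),
        ),
        ("tri", lambda: gs.tri_models(profile, mean_tri, jacobian=cfg.jacobian)),
        (
            "tri_adjusted",
            lambda: gs.tri_models(profile, mean_tri, area, jacobian=cfg.jacobian),
        ),
    ):
        try:
            result = fn()
            if stage == "sar":
                g.sar = result
            elif stage == "mde":
                g.mde = result
            elif stage == "tri":
                g.tri_raw = result
            else:
                g.tri_adjusted = result
        except Exception as e:  # noqa: BLE001 — stage isolation is the contract
            failures[f"{name}/{stage}"] = str(e)
            logger.warning("%s: stage %s failed: %s", name, stage, e)
    if g.mde is not None:
        try:
            g.mde_fit = fit_empirical_to_mde(profile, g.mde)
        except Exception as e:  # noqa: BLE001
            failures[f"{name}/mde_fit"] = str(e)
    return g


def run_all(cfg: RunConfig, out_dir: str | Path | None = None) -> RunReport:
    """Run the full analysis described by ``cfg``; optionally write outputs."""
    failures: dict[str, str] = {}
    all_species = rg.inflate_point_ranges(
        rg.load_range_table(cfg.range_table, cfg.dialect or None), cfg.delta
    )
    region_names = list(cfg.dems)
    dems = {name: tr.read_dem(p) for name, p in cfg.dems.items()}
    metrics = {name: tr.compute_band_metrics(dem, cfg.scheme) for name, dem in dems.items()}

    # seeds: one per gradient, derived reproducibly from the run seed
    seed_seq = np.random.SeedSequence(cfg.seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in seed_seq.spawn(len(region_names) + 1)]

    gradients: dict[str, GradientReport] = {}

    # whole-system level: pooled species, metrics aggregated across regions
    sys_area = np.sum([m.area for m in metrics.values()], axis=0)
    sys_tri = np.nanmean(np.array([m.mean_tri for m in metrics.values()]), axis=0)
    sys_lat = float(np.mean([m.mid_latitude for m in metrics.values()]))
    sys_tri_mean = float(np.mean([m.region_mean_tri for m in metrics.values()]))
    profile = rg.richness_per_band(all_species, cfg.scheme)
    gradients["system"] = _analyze_gradient(
        "system",
        all_species,
        profile,
        sys_area,
        sys_tri,
        sys_tri_mean,
        sys_lat,
        cfg,
        child_seeds[0],
        failures,
    )

    for i, name in enumerate(region_names):
        sub = [s for s in all_species if name in s.regions]
        if not sub:
            failures[name] = "no species assigned to region"
            continue
        m = metrics[name]
        prof = rg.richness_per_band(sub, cfg.scheme, region=name)
        gradients[name] = _analyze_gradient(
            name,
            sub,
            prof,
            m.area,
            m.mean_tri,
            m.region_mean_tri,
            m.mid_latitude,
            cfg,
            child_seeds[i + 1],
            failures,
        )

    # global z from region-level gradients with significant power-law SARs
    zres: gs.GlobalZ | None = None
    curvi = {
        n: g.sar["curvilinear"]
        for n, g in gradients.items()
        if n != "system" and g.sar is not None
    }
    try:
        zres = gs.global_z(curvi, cfg.alpha)
    except ValueError as e:
        failures["global_z"] = str(e)

    # area-corrected curves + corrected MDE fits where the SAR is significant
    if zres is not None:
        for name, g in gradients.items():
            sar = g.sar
            if sar is None or g.mde is None:
                continue
            if not (np.isfinite(sar["curvilinear"].p_value) and sar["curvilinear"].p_value < cfg.alpha):
                continue
            try:
                g.corrected = gs.area_correct(g.profile, g.area, zres.z)
                g.corrected_fit = fit_corrected_to_mde(g.corrected, g.mde)
            except Exception as e:  # noqa: BLE001
                failures[f"{name}/area_correct"] = str(e)

    # latitudinal stage across regions
    lat_set: gs.ModelSet | None = None
    averaged: gs.AveragedEstimates | None = None
    rows = []
    for name in region_names:
        g = gradients.get(name)
        if g is None:
            continue
        sub = [s for s in all_species if name in s.regions]
        lo = min(s.elev_min for s in sub)
        hi = max(s.elev_max for s in sub)
        rows.append(
            {
                "region": name,
                "richness": len(sub),
                "mid_latitude": g.mid_latitude,
                "mean_tri": g.region_mean_tri,
                "mid_elevation": 0.5 * (lo + hi),
            }
        )
    try:
        lat_set, averaged = gs.latitude_models(
            pd.DataFrame(rows), signed_latitude=cfg.signed_latitude
        )
    except ValueError as e:
        failures["latitude"] = str(e)

    report = RunReport(cfg, gradients, zres, lat_set, averaged, failures)
    if out_dir is not None:
        report.write(out_dir)
    return report
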