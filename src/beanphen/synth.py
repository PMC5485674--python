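"""Synthetic weather, RI-family marker matrices, and noisy phenotypes.

The generators emulate the structure the model assumes so the whole
pipeline is testable without field data:

* weather -- daily mean temperature as site mean + seasonal sinusoid +
  AR(1) noise, TMAX/TMIN placed symmetrically around TMEAN with a fixed
  diurnal range, solar radiation as positive AR(1) around the site mean,
  and day length from solar geometry shifted to match the stated site
  mean.  The five default site templates carry the latitudes and seasonal
  mean TMEAN / SRAD / DL of the original five field sites (Citra FL,
  Palmira and Popayan Colombia, Isabela PR, Prosper ND).
* markers -- i.i.d. +1/-1 calls per locus for a bi-parental RI family,
  with the chromosome-1 region markers (TF2, MSN2, NAR2, JC28) optionally
  tied, plus two fixed parental rows (Calima all +1, Jamapa all -1).
* observations -- the simulator is run with a chosen "true" parameter set
  and Gaussian noise is added to flowering day, weekly node counts, and
  the final node number.

Everything is reproducible under an integer seed.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import solar
from .engine import simulate_genotype_site
from .errors import SchemaError
from .io_formats import MarkerTable, ParameterSet, SiteConfig, WeatherSeries
from .qtl_effects import ALL_MARKERS, TIED_REGION_MARKERS


@dataclass
class SyntheticSiteSpec:
    """Recipe for one synthetic site's daily weather."""

    site_id: str
    latitude: float
    season_days: int = 110
    mean_tmean: float = 22.0  # deg C, season mean
    mean_srad: float = 18.0  # MJ m-2 d-1
    mean_dl: float | None = None  # h; None = raw geometric day length
    tmean_amplitude: float = 2.0  # deg C, seasonal sinusoid
    ar1_rho: float = 0.6
    noise_sd: float = 1.5  # deg C, stationary AR(1) SD of TMEAN
    srad_rel_sd: float = 0.10  # SRAD AR(1) SD as a fraction of the mean
    diurnal_range: float = 10.0  # TMAX - TMIN, deg C
    planting_date: _dt.date = _dt.date(2012, 3, 15)
    emergence_dap: int = 7
    end_dap: int = 90
    seed: int | None = None

    def __post_init__(self):
        if isinstance(self.planting_date, str):
            self.planting_date = _dt.date.fromisoformat(self.planting_date)
        if self.season_days <= self.end_dap:
            raise SchemaError(
                f"{self.site_id}: season_days must exceed end_dap "
                f"({self.season_days} <= {self.end_dap})"
            )
        if not 0.0 <= self.ar1_rho < 1.0:
            raise SchemaError(f"{self.site_id}: ar1_rho must be in [0, 1)")

    def site_config(self) -> SiteConfig:
        return SiteConfig(
            site_id=self.site_id,
            planting_date=self.planting_date,
            emergence_dap=self.emergence_dap,
            end_dap=self.end_dap,
            latitude=self.latitude,
        )


@dataclass
class SyntheticPopulationSpec:
    """Recipe for a bi-parental RI marker matrix."""

    n_genotypes: int = 187
    markers: tuple = ALL_MARKERS
    allele_prob: float = 0.5  # P(+1 Calima allele) per marker
    tie_region: bool = True
    include_parents: bool = True
    seed: int | None = None

    def __post_init__(self):
        if self.n_genotypes < 1:
            raise SchemaError("n_genotypes must be >= 1")
        if not 0.0 < self.allele_prob < 1.0:
            raise SchemaError("allele_prob must be in (0, 1)")


#: Latitudes and seasonal mean TMEAN / SRAD / DL of the five field sites
#: used as synthetic templates (Citra FL; Palmira, CO; Isabela, PR;
#: Popayan, CO; Prosper, ND).
FIVE_SITE_TEMPLATE = (
    ("CT", 29.65, 24.61, 20.41, 13.36, "2011-03-15"),
    ("PA", 3.48, 23.94, 14.67, 11.82, "2011-11-15"),
    ("PR", 18.47, 24.36, 15.78, 12.90, "2012-02-15"),
    ("PO", 2.42, 18.08, 22.58, 12.21, "2012-03-15"),
    ("ND", 47.00, 20.39, 15.01, 14.96, "2012-05-20"),
)


def five_site_specs(
    season_days: int = 110, end_dap: int = 90, seed: int | None = None, **overrides
) -> list[SyntheticSiteSpec]:
    """Site specs templated on the five original field sites."""
    specs = []
    for i, (sid, lat, tmean, srad, dl, planting) in enumerate(FIVE_SITE_TEMPLATE):
        specs.append(
            SyntheticSiteSpec(
                site_id=sid,
                latitude=lat,
                season_days=season_days,
                mean_tmean=tmean,
                mean_srad=srad,
                mean_dl=dl,
                planting_date=planting,
                end_dap=end_dap,
                seed=None if seed is None else seed + i,
                **overrides,
            )
        )
    return specs


def _ar1(rng, n, rho, sd):
    """Stationary AR(1) series with marginal SD ``sd``, centered so the
    sample mean is exactly 0 (keeps generated season means on template)."""
    if sd == 0.0:
        return np.zeros(n)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    innov_sd = sd * np.sqrt(1.0 - rho**2)
    for t in range(1, n):
        x[t] = rho * x[t - 1] + rng.normal(0.0, innov_sd)
    return x - x.mean()


def gen_weather(spec: SyntheticSiteSpec, seed: int | None = None) -> WeatherSeries:
    """Generate one site's daily weather series starting at planting."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.season_days
    k = np.arange(n)
    sinusoid = spec.tmean_amplitude * np.sin(2.0 * np.pi * k / n)
    tmean = spec.mean_tmean + sinusoid + _ar1(rng, n, spec.ar1_rho, spec.noise_sd)
    tmax = tmean + spec.diurnal_range / 2.0
    tmin = tmean - spec.diurnal_range / 2.0
    srad_sd = spec.srad_rel_sd * spec.mean_srad
    srad = np.maximum(spec.mean_srad + _ar1(rng, n, spec.ar1_rho, srad_sd), 0.1)

    dates = [spec.planting_date + _dt.timedelta(days=int(d)) for d in k]
    doy = np.array([d.timetuple().tm_yday for d in dates])
    dl = solar.daylength(spec.latitude, doy, solar.GEOMETRIC_HORIZON)
    if spec.mean_dl is not None:
        dl = dl + (spec.mean_dl - dl.mean())  # keep the shape, match the mean
    frame = pd.DataFrame(
        {
            "date": dates,
            "srad": srad,
            "tmax": tmax,
            "tmin": tmin,
            "tmean": tmean,
            "daylength": dl,
        }
    )
    series = WeatherSeries(spec.site_id, spec.latitude, frame)
    series.validate()
    return series


def gen_sites(
    specs: list[SyntheticSiteSpec], seed: int | None = None
) -> list[tuple[SiteConfig, WeatherSeries]]:
    """Generate (SiteConfig, WeatherSeries) pairs for a list of site specs."""
    out = []
    for i, spec in enumerate(specs):
        s = None if seed is None else seed + i
        out.append((spec.site_config(), gen_weather(spec, seed=s)))
    return out


def gen_ril_markers(
    spec: SyntheticPopulationSpec, seed: int | None = None
) -> MarkerTable:
    """Generate an RI-family +1/-1 marker matrix (plus parental rows)."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    markers = list(spec.markers)
    n = spec.n_genotypes
    values = rng.choice(
        [1.0, -1.0], size=(n, len(markers)), p=[spec.allele_prob, 1 - spec.allele_prob]
    )
    frame = pd.DataFrame(
        values,
        index=[f"RIL{i + 1:03d}" for i in range(n)],
        columns=markers,
    )
    if spec.tie_region:
        tied = [m for m in TIED_REGION_MARKERS if m in frame.columns]
        if "JC28" in frame.columns:
            for m in tied:
                frame[m] = frame["JC28"]
    if spec.include_parents:
        parents = pd.DataFrame(
            [[1.0] * len(markers), [-1.0] * len(markers)],
            index=["Calima", "Jamapa"],
            columns=markers,
        )
        frame = pd.concat([parents, frame])
    frame.index.name = "genotype_id"
    return MarkerTable(frame)


@dataclass
class ObservationNoise:
    """Gaussian noise SDs for the three observation kinds."""

    flowering_sd: float = 0.0  # days
    node_sd: float = 0.0  # nodes
    final_sd: float = 0.0  # nodes


def gen_observations(
    population: MarkerTable,
    sites: list[tuple[SiteConfig, WeatherSeries]],
    params: ParameterSet,
    noise: ObservationNoise | None = None,
    seed: int | None = None,
    node_cadence_days: int = 7,
    scouting_cadence_days: int | None = None,
    linear_phase_only: bool = True,
    tie_region: bool = True,
) -> pd.DataFrame:
    """Simulate every genotype x site pair and emit noisy phenotypes.

    Flowering day (days after emergence, fractional), main-stem node counts
    every ``node_cadence_days`` starting one cadence after emergence, and
    the final node number (the module's node ceiling, observed on the day
    it is frozen).  ``scouting_cadence_days`` optionally rounds flowering
    days to a 2-3 day scouting grid.  With ``linear_phase_only`` node
    counts stop once the trajectory reaches its final value.  Negative
    noisy values are floored at 0.
    """
    noise = noise or ObservationNoise()
    rng = np.random.default_rng(seed)
    rows = []
    for gid in population.genotype_ids:
        genotype = population.genotype(gid)
        for cfg, weather in sites:
            res = simulate_genotype_site(genotype, cfg, weather, params, tie_region)
            if not res.never_flowered:
                fl = res.anthesis_dae_frac + rng.normal(0.0, noise.flowering_sd)
                if scouting_cadence_days:
                    fl = scouting_cadence_days * round(fl / scouting_cadence_days)
                rows.append(
                    (gid, cfg.site_id, "flowering_day_after_emergence",
                     np.nan, max(fl, 0.0))
                )
            day = cfg.emergence_dap + node_cadence_days
            while day <= cfg.end_dap:
                value = res.nodes_at(day)
                rows.append(
                    (gid, cfg.site_id, "node_count", day,
                     max(value + rng.normal(0.0, noise.node_sd), 0.0))
                )
                reached_final = (
                    not res.n_final_censored and value >= res.n_final - 1e-9
                )
                if linear_phase_only and reached_final:
                    break
                day += node_cadence_days
            # final node number: the frozen ceiling, observed on the freeze day
            freeze_day = (
                res.anthesis_dap if res.anthesis_dap is not None else cfg.end_dap
            )
            ceiling = float(res.msnodmax[freeze_day - cfg.emergence_dap])
            rows.append(
                (gid, cfg.site_id, "final_node_count", freeze_day,
                 max(ceiling + rng.normal(0.0, noise.final_sd), 0.0))
            )
    return pd.DataFrame(
        rows, columns=["genotype_id", "site_id", "obs_kind", "obs_day", "value"]
    )
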