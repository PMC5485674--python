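"""File formats: weather, markers, parameters, sites, observations, results.

All formats are plain delimited text or YAML:

* Weather: CSV with columns ``DATE`` (ISO-8601), ``SRAD``, ``TMAX``,
  ``TMIN``, optional ``TMEAN`` and ``DL``; one row per day, no gaps.
* Markers: CSV, first column the genotype id, remaining columns marker ids;
  values -1 / +1, empty or NA for a missing call.
* Parameters: YAML with a ``traits`` mapping (see the packaged default,
  ``beanphen/data/default_parameters.yaml``).
* Sites: YAML list of site configs, each naming its weather file.
* Observations: long CSV ``genotype_id, site_id, obs_kind, obs_day, value``.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd
import yaml

from . import solar
from .errors import ContinuityError, FormatError, RangeError, SchemaError
from .qtl_effects import (
    ALL_MARKERS,
    COVARIATES,
    GenotypeVector,
    TraitParameters,
    TRAITS,
)

logger = logging.getLogger(__name__)

OBS_KINDS = ("flowering_day_after_emergence", "node_count", "final_node_count")


class WeatherRecord(NamedTuple):
    """One day of weather; ``tmean`` and ``daylength`` are filled on read."""

    date: _dt.date
    srad: float
    tmax: float
    tmin: float
    daylength: float
    tmean: float


def derive_tmean(tmax: float, tmin: float, tmean: float | None = None) -> float:
    """Daily mean temperature: an explicit TMEAN value wins, else (max+min)/2."""
    if tmean is not None and not (isinstance(tmean, float) and np.isnan(tmean)):
        return float(tmean)
    return (float(tmax) + float(tmin)) / 2.0


def derive_daylength(
    latitude: float, day_of_year: int, sun_angle_deg: float = solar.DEFAULT_SUN_ANGLE
) -> float:
    """Day length in hours from solar geometry (see :mod:`beanphen.solar`)."""
    return solar.daylength(latitude, day_of_year, sun_angle_deg)


@dataclass
class WeatherSeries:
    """Gap-free, date-ordered daily weather for one site.

    ``frame`` has columns date, srad, tmax, tmin, tmean, daylength with one
    row per day.  Row 0 is taken as days-after-planting 0 by the simulation
    engine when the series starts on the planting date.
    """

    site_id: str
    latitude: float
    frame: pd.DataFrame

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def records(self) -> Iterator[WeatherRecord]:
        for row in self.frame.itertuples(index=False):
            yield WeatherRecord(
                date=row.date,
                srad=row.srad,
                tmax=row.tmax,
                tmin=row.tmin,
                daylength=row.daylength,
                tmean=row.tmean,
            )

    def validate(self) -> None:
        f = self.frame
        dates = pd.to_datetime(f["date"])
        if dates.duplicated().any():
            raise ContinuityError(f"{self.site_id}: duplicate dates in weather")
        deltas = dates.diff().dropna().dt.days
        if (deltas != 1).any():
            raise ContinuityError(
                f"{self.site_id}: weather dates are not consecutive days"
            )
        if (f["tmax"] < f["tmin"]).any():
            raise FormatError(f"{self.site_id}: TMAX < TMIN in weather")
        if (f["srad"] < 0).any():
            raise FormatError(f"{self.site_id}: negative SRAD in weather")
        if ((f["daylength"] <= 0) | (f["daylength"] > 24)).any():
            raise FormatError(f"{self.site_id}: day length outside (0, 24] h")

    def index_of(self, date: _dt.date) -> int:
        """Row index of a calendar date (raises RangeError if absent)."""
        first = self.frame["date"].iloc[0]
        offset = (date - first).days
        if offset < 0 or offset >= len(self.frame):
            raise RangeError(
                f"{self.site_id}: date {date} outside weather coverage "
                f"{first}..{self.frame['date'].iloc[-1]}"
            )
        return offset

    def aligned(self, planting_date: _dt.date, end_dap: int) -> "WeatherSeries":
        """Sub-series starting at the planting date and covering end_dap days."""
        start = self.index_of(planting_date)
        stop = start + end_dap + 1
        if stop > len(self.frame):
            raise RangeError(
                f"{self.site_id}: weather ends before day {end_dap} after "
                f"planting {planting_date}"
            )
        return WeatherSeries(
            self.site_id,
            self.latitude,
            self.frame.iloc[start:stop].reset_index(drop=True),
        )

    def covariate_arrays(self) -> dict[str, np.ndarray]:
        return {
            "TMEAN": self.frame["tmean"].to_numpy(float),
            "SRAD": self.frame["srad"].to_numpy(float),
            "DL": self.frame["daylength"].to_numpy(float),
        }


def read_weather(
    path,
    latitude: float,
    site_id: str | None = None,
    sun_angle_deg: float = solar.DEFAULT_SUN_ANGLE,
) -> WeatherSeries:
    """Read a daily weather CSV; derive TMEAN and day length where absent."""
    path = Path(path)
    raw = pd.read_csv(path)
    raw.columns = [c.strip().upper() for c in raw.columns]
    required = {"DATE", "SRAD", "TMAX", "TMIN"}
    missing = required - set(raw.columns)
    if missing:
        raise FormatError(f"{path}: missing weather columns {sorted(missing)}")
    try:
        dates = pd.to_datetime(raw["DATE"], format="ISO8601").dt.date
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: unparseable DATE column: {exc}") from exc
    frame = pd.DataFrame(
        {
            "date": dates,
            "srad": raw["SRAD"].astype(float),
            "tmax": raw["TMAX"].astype(float),
            "tmin": raw["TMIN"].astype(float),
        }
    )
    if "TMEAN" in raw.columns:
        frame["tmean"] = [
            derive_tmean(a, b, t)
            for a, b, t in zip(frame["tmax"], frame["tmin"], raw["TMEAN"].astype(float))
        ]
    else:
        frame["tmean"] = (frame["tmax"] + frame["tmin"]) / 2.0
    if "DL" in raw.columns:
        frame["daylength"] = raw["DL"].astype(float)
    else:
        doy = pd.to_datetime(raw["DATE"], format="ISO8601").dt.dayofyear.to_numpy()
        frame["daylength"] = solar.daylength(latitude, doy, sun_angle_deg)
    series = WeatherSeries(site_id or path.stem, latitude, frame)
    series.validate()
    return series


def write_weather(series: WeatherSeries, path) -> None:
    """Write the CSV dialect read back by :func:`read_weather` (full precision)."""
    out = pd.DataFrame(
        {
            "DATE": [d.isoformat() for d in series.frame["date"]],
            "SRAD": series.frame["srad"],
            "TMAX": series.frame["tmax"],
            "TMIN": series.frame["tmin"],
            "TMEAN": series.frame["tmean"],
            "DL": series.frame["daylength"],
        }
    )
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Site configuration


@dataclass
class SiteConfig:
    """Planting calendar and simulation window for one site."""

    site_id: str
    planting_date: _dt.date
    emergence_dap: int
    end_dap: int
    latitude: float | None = None

    def __post_init__(self):
        if isinstance(self.planting_date, str):
            self.planting_date = _dt.date.fromisoformat(self.planting_date)
        if isinstance(self.planting_date, _dt.datetime):
            self.planting_date = self.planting_date.date()
        if self.emergence_dap < 0 or self.emergence_dap >= self.end_dap:
            raise SchemaError(
                f"{self.site_id}: need 0 <= emergence_dap < end_dap, got "
                f"{self.emergence_dap} / {self.end_dap}"
            )


def read_sites(path) -> list[tuple[SiteConfig, WeatherSeries]]:
    """Read a sites YAML; weather paths are resolved relative to the YAML."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    entries = doc.get("sites") if isinstance(doc, dict) else doc
    if not entries:
        raise SchemaError(f"{path}: no sites defined")
    out = []
    for entry in entries:
        entry = dict(entry)
        weather_path = entry.pop("weather")
        sun_angle = entry.pop("sun_angle_deg", solar.DEFAULT_SUN_ANGLE)
        cfg = SiteConfig(**entry)
        series = read_weather(
            path.parent / weather_path,
            latitude=cfg.latitude if cfg.latitude is not None else 0.0,
            site_id=cfg.site_id,
            sun_angle_deg=sun_angle,
        )
        out.append((cfg, series))
    return out


def write_sites(sites, weather_names: dict[str, str], path) -> None:
    """Write a sites YAML referencing already-written weather CSVs."""
    doc = {
        "sites": [
            {
                "site_id": cfg.site_id,
                "latitude": cfg.latitude,
                "planting_date": cfg.planting_date.isoformat(),
                "emergence_dap": cfg.emergence_dap,
                "end_dap": cfg.end_dap,
                "weather": weather_names[cfg.site_id],
            }
            for cfg, _ in sites
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Marker tables


@dataclass
class MarkerTable:
    """Genotype x marker matrix with entries in {-1, +1} (NaN = missing)."""

    frame: pd.DataFrame  # index: genotype ids; columns: marker ids
    missing: list[tuple[str, str]] = field(default_factory=list)

    @property
    def genotype_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.frame.columns)

    def genotype(self, genotype_id: str) -> GenotypeVector:
        """Extract one genotype; missing calls are substituted with 0."""
        if genotype_id not in self.frame.index:
            raise SchemaError(f"unknown genotype {genotype_id!r}")
        row = self.frame.loc[genotype_id]
        values = {}
        for marker, v in row.items():
            if pd.isna(v):
                logger.info(
                    "genotype %s marker %s missing; substituted 0", genotype_id, marker
                )
                values[marker] = 0.0
            else:
                values[marker] = float(v)
        return GenotypeVector(genotype_id, values)

    def genotypes(self) -> list[GenotypeVector]:
        return [self.genotype(g) for g in self.genotype_ids]

    def allele_frequencies(self) -> pd.Series:
        """Per-marker frequency of the +1 (Calima) allele among called values."""
        def freq(col):
            called = col.notna().sum()
            return (col == 1).sum() / called if called else float("nan")

        return self.frame.apply(freq)


_NA_TOKENS = {"", "NA", "NAN", "N/A", "."}


def read_markers(path) -> MarkerTable:
    """Read a genotype x marker CSV and validate the +1/-1 coding."""
    path = Path(path)
    raw = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    if raw.index.duplicated().any():
        raise FormatError(f"{path}: duplicate genotype ids")
    values = pd.DataFrame(index=raw.index.astype(str), dtype=float)
    missing: list[tuple[str, str]] = []
    for col in raw.columns:
        parsed = []
        for gid, token in zip(raw.index, raw[col]):
            token = token.strip()
            if token.upper() in _NA_TOKENS:
                parsed.append(np.nan)
                missing.append((str(gid), col))
                continue
            try:
                v = float(token)
            except ValueError:
                raise FormatError(
                    f"{path}: marker {col} genotype {gid}: "
                    f"unparseable value {token!r}"
                ) from None
            if v not in (-1.0, 1.0):
                raise FormatError(
                    f"{path}: marker {col} genotype {gid}: value {token!r} "
                    f"outside {{-1, +1}}"
                )
            parsed.append(v)
        values[col] = parsed
    table = MarkerTable(values, missing=missing)
    if missing:
        logger.warning("%s: %d missing marker calls (substituted 0 on use)",
                       path, len(missing))
    freq = table.allele_frequencies()
    logger.info("%s: +1 allele frequency per marker:\n%s", path, freq.to_string())
    return table


def write_markers(table: MarkerTable, path) -> None:
    out = table.frame.copy()
    out.index.name = "genotype_id"
    # integers where called, empty where missing
    out = out.map(lambda v: "" if pd.isna(v) else str(int(v)))
    out.to_csv(path)


# ---------------------------------------------------------------------------
# Trait parameters


def _params_from_dict(trait_name: str, doc: dict) -> TraitParameters:
    known = {"mean", "env", "qtl", "qtl_env", "env_env", "env_means", "se"}
    extra = set(doc) - known
    if extra:
        raise SchemaError(f"{trait_name}: unknown config keys {sorted(extra)}")
    qtl = {str(k): float(v) for k, v in (doc.get("qtl") or {}).items()}
    for marker in qtl:
        if marker not in ALL_MARKERS:
            raise SchemaError(f"{trait_name}: unknown marker {marker!r}")
    qtl_env = {}
    for item in doc.get("qtl_env") or []:
        marker, cov = str(item["marker"]), str(item["covariate"])
        if marker not in ALL_MARKERS:
            raise SchemaError(f"{trait_name}: unknown marker {marker!r}")
        if cov not in COVARIATES:
            raise SchemaError(f"{trait_name}: unknown covariate {cov!r}")
        qtl_env[(marker, cov)] = float(item["value"])
    env_env = {}
    for item in doc.get("env_env") or []:
        c1, c2 = (str(c) for c in item["covariates"])
        env_env[(c1, c2)] = float(item["value"])
    se = doc.get("se")
    return TraitParameters(
        trait_name=trait_name,
        mu=float(doc["mean"]),
        env_terms={str(k): float(v) for k, v in (doc.get("env") or {}).items()},
        qtl_terms=qtl,
        qtl_env_terms=qtl_env,
        env_env_terms=env_env,
        env_means={str(k): float(v) for k, v in (doc.get("env_means") or {}).items()},
        standard_errors={str(k): float(v) for k, v in se.items()} if se else None,
    )


def _params_to_dict(p: TraitParameters) -> dict:
    doc: dict = {"mean": p.mu}
    if p.env_terms:
        doc["env"] = dict(p.env_terms)
    if p.qtl_terms:
        doc["qtl"] = dict(p.qtl_terms)
    if p.qtl_env_terms:
        doc["qtl_env"] = [
            {"marker": m, "covariate": c, "value": v}
            for (m, c), v in p.qtl_env_terms.items()
        ]
    if p.env_env_terms:
        doc["env_env"] = [
            {"covariates": list(k), "value": v} for k, v in p.env_env_terms.items()
        ]
    doc["env_means"] = dict(p.env_means)
    if p.standard_errors:
        doc["se"] = dict(p.standard_errors)
    return doc


@dataclass
class ParameterSet:
    """One TraitParameters per trait module."""

    rf: TraitParameters
    nar: TraitParameters
    msnodmax: TraitParameters

    def for_trait(self, trait: str) -> TraitParameters:
        try:
            return {"RF": self.rf, "NAR": self.nar, "MSNODMAX": self.msnodmax}[trait]
        except KeyError:
            raise SchemaError(f"unknown trait {trait!r}") from None

    def replacing(self, params: TraitParameters) -> "ParameterSet":
        parts = {"RF": self.rf, "NAR": self.nar, "MSNODMAX": self.msnodmax}
        parts[params.trait_name] = params
        return ParameterSet(parts["RF"], parts["NAR"], parts["MSNODMAX"])


def _parameter_set_from_doc(doc: dict, source: str) -> ParameterSet:
    traits = doc.get("traits")
    if not isinstance(traits, dict):
        raise SchemaError(f"{source}: expected a top-level 'traits' mapping")
    unknown = set(traits) - set(TRAITS)
    if unknown:
        raise SchemaError(f"{source}: unknown traits {sorted(unknown)}")
    missing = set(TRAITS) - set(traits)
    if missing:
        raise SchemaError(f"{source}: missing traits {sorted(missing)}")
    return ParameterSet(
        rf=_params_from_dict("RF", traits["RF"]),
        nar=_params_from_dict("NAR", traits["NAR"]),
        msnodmax=_params_from_dict("MSNODMAX", traits["MSNODMAX"]),
    )


def read_parameters(path) -> ParameterSet:
    """Read a trait-parameter YAML (schema of the packaged default)."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return _parameter_set_from_doc(doc, str(path))


def write_parameters(params: ParameterSet, path) -> None:
    doc = {
        "traits": {
            "RF": _params_to_dict(params.rf),
            "MSNODMAX": _params_to_dict(params.msnodmax),
            "NAR": _params_to_dict(params.nar),
        }
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_default_parameters() -> ParameterSet:
    """The packaged published coefficient tables for all three modules."""
    ref = resources.files("beanphen").joinpath("data/default_parameters.yaml")
    doc = yaml.safe_load(ref.read_text())
    return _parameter_set_from_doc(doc, "default_parameters.yaml")


# ---------------------------------------------------------------------------
# Observations


def read_observations(path) -> pd.DataFrame:
    """Read a long-format observation CSV and validate kinds and values."""
    path = Path(path)
    obs = pd.read_csv(path)
    required = {"genotype_id", "site_id", "obs_kind", "obs_day", "value"}
    missing = required - set(obs.columns)
    if missing:
        raise FormatError(f"{path}: missing observation columns {sorted(missing)}")
    bad = set(obs["obs_kind"]) - set(OBS_KINDS)
    if bad:
        raise FormatError(f"{path}: unknown obs_kind values {sorted(bad)}")
    if (obs["value"] < 0).any():
        raise FormatError(f"{path}: negative observation values")
    obs["genotype_id"] = obs["genotype_id"].astype(str)
    obs["site_id"] = obs["site_id"].astype(str)
    return obs


def write_observations(obs: pd.DataFrame, path) -> None:
    obs.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Simulation results


def write_trajectories(results, path) -> None:
    """Tidy per-day CSV: genotype_id, site_id, dap, tf_cum, nodes, msnodmax."""
    frames = [r.trajectory_frame() for r in results]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_summary(results, path) -> None:
    """Per genotype x site summary CSV (anthesis, final nodes, flags)."""
    rows = []
    for r in results:
        rows.append(
            {
                "genotype_id": r.genotype_id,
                "site_id": r.site_id,
                "anthesis_dap": r.anthesis_dap if r.anthesis_dap is not None else "",
                "anthesis_dae": r.anthesis_dae if r.anthesis_dae is not None else "",
                "n_final": r.n_final,
                "never_flowered": r.never_flowered,
                "n_final_censored": r.n_final_censored,
                "clamp_events": r.clamp_events,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_summary(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["genotype_id"] = df["genotype_id"].astype(str)
    df["site_id"] = df["site_id"].astype(str)
    return df


def read_trajectories(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["genotype_id"] = df["genotype_id"].astype(str)
    df["site_id"] = df["site_id"].astype(str)
    return df
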