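import dataclasses
import datetime as dt

import pandas as pd
import pytest

import beanphen as bp

PLANTING = dt.date(2012, 3, 15)


@pytest.fixture(scope="session")
def params() -> bp.ParameterSet:
    return bp.load_default_parameters()


def make_constant_weather(
    tmean: float,
    srad: float,
    daylength: float,
    n_days: int = 91,
    site_id: str = "CONST",
    latitude: float = 10.0,
    start: dt.date = PLANTING,
) -> bp.WeatherSeries:
    frame = pd.DataFrame(
        {
            "date": [start + dt.timedelta(days=i) for i in range(n_days)],
            "srad": srad,
            "tmax": tmean + 5.0,
            "tmin": tmean - 5.0,
            "tmean": tmean,
            "daylength": daylength,
        }
    )
    series = bp.WeatherSeries(site_id, latitude, frame)
    series.validate()
    return series


def centered_params(params: bp.ParameterSet, tmean, srad, dl) -> bp.ParameterSet:
    """Re-center every module on the same covariate point, so that a constant
    environment at that point makes each module return exactly its mean --
    the closed-form constant-environment oracle setup."""
    means = {"TMEAN": tmean, "SRAD": srad, "DL": dl}
    return bp.ParameterSet(
        rf=dataclasses.replace(params.rf, env_means=means),
        nar=dataclasses.replace(params.nar, env_means=means),
        msnodmax=dataclasses.replace(params.msnodmax, env_means=means),
    )


def genotype_with(markers: dict[str, float], genotype_id: str = "g") -> bp.GenotypeVector:
    values = {m: 0.0 for m in bp.qtl_effects.ALL_MARKERS}
    values.update(markers)
    return bp.GenotypeVector(genotype_id, values)


@pytest.fixture
def indeterminate_genotype() -> bp.GenotypeVector:
    return genotype_with({"JC28": -1.0}, "indet")


@pytest.fixture
def determinate_genotype() -> bp.GenotypeVector:
    return genotype_with({"JC28": 1.0}, "det")
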