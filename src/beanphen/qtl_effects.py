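"""Dynamic QTL-effect linear models for common bean development traits.

Three trait modules share one linear predictor: a daily trait value is

    y(t) = mu
         + sum_i  b1_i  * (E_i(t) - Ebar_i)                 (environment)
         + sum_j  b2_j  * QTL_j                             (QTL main effects)
         + sum_ij b3_ij * QTL_j * (E_i(t) - Ebar_i)         (QTL x E)
         + sum_ik c_ik  * (E_i(t) - Ebar_i)(E_k(t) - Ebar_k)  (E x E)

where the environmental covariates E_i are daily mean temperature TMEAN
(deg C), solar radiation SRAD (MJ m-2 d-1) and day length DL (h), each
centered on its across-site mean Ebar_i, and QTL_j are bi-parental marker
values coded +1 (Calima allele) / -1 (Jamapa allele), 0 for a missing call.

The three instantiations are

* RF -- rate of progress from emergence toward first anthesis (d-1); the
  only module with an E x E term (TMEAN x DL).
* NAR -- main-stem node addition rate (nodes d-1); its reciprocal is the
  phyllochron in days per node.
* MSNODmax -- maximum (final) main-stem node number (nodes), evaluated on
  covariates averaged from planting to the current simulation day rather
  than on single-day values.

Predicted rates are clamped at zero (development does not run backwards);
the predicted node ceiling is floored at zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .errors import ModelError, RangeError, SchemaError

logger = logging.getLogger(__name__)

#: Environmental covariates recognized by the trait models.
COVARIATES = ("TMEAN", "SRAD", "DL")

#: Canonical trait names.
TRAITS = ("RF", "NAR", "MSNODMAX")

#: Marker panels per module, plus the determinacy locus.
RF_MARKERS = tuple(f"TF{i}" for i in range(1, 13))
MSN_MARKERS = tuple(f"MSN{i}" for i in range(1, 7))
NAR_MARKERS = tuple(f"NAR{i}" for i in range(1, 5))
DETERMINACY_MARKER = "JC28"
#: Markers that sit in the same (recombination-suppressed) region of
#: chromosome 1 as the FIN/TFL1Y determinacy gene.
TIED_REGION_MARKERS = ("TF2", "MSN2", "NAR2", DETERMINACY_MARKER)
ALL_MARKERS = RF_MARKERS + MSN_MARKERS + NAR_MARKERS + (DETERMINACY_MARKER,)


@dataclass(frozen=True)
class DailyEnvironment:
    """One day's environmental covariates (or running means thereof)."""

    tmean: float
    srad: float
    daylength: float

    def __post_init__(self):
        for name in ("tmean", "srad", "daylength"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ModelError(f"non-finite covariate {name}={v!r}")
        if not 0.0 < self.daylength <= 24.0:
            raise ModelError(f"day length {self.daylength!r} outside (0, 24] h")

    def get(self, covariate_id: str) -> float:
        try:
            return {"TMEAN": self.tmean, "SRAD": self.srad, "DL": self.daylength}[
                covariate_id
            ]
        except KeyError:
            raise ModelError(f"unknown covariate {covariate_id!r}") from None


@dataclass(frozen=True)
class GenotypeVector:
    """Marker values for one genotype.

    Values are +1 (Calima allele), -1 (Jamapa allele) or 0 for a
    missing-substituted call.
    """

    genotype_id: str
    marker_values: Mapping[str, float]

    def marker(self, marker_id: str) -> float:
        try:
            return self.marker_values[marker_id]
        except KeyError:
            raise ModelError(
                f"genotype {self.genotype_id!r} has no value for marker "
                f"{marker_id!r} required by the active trait model"
            ) from None


def zero_genotype(genotype_id: str = "null") -> GenotypeVector:
    """A genotype with every marker at 0 (all allelic effects switched off)."""
    return GenotypeVector(genotype_id, {m: 0.0 for m in ALL_MARKERS})


@dataclass(frozen=True)
class TraitParameters:
    """Coefficients and centering means for one trait module.

    ``env_terms`` maps covariate id to b1; ``qtl_terms`` maps marker id to
    b2; ``qtl_env_terms`` maps (marker, covariate) to b3; ``env_env_terms``
    maps a (covariate, covariate) pair to its coefficient (only the RF
    module carries one, TMEAN x DL).  ``env_means`` holds the across-site
    centering mean of every covariate used anywhere in the model.
    ``standard_errors`` (optional) is keyed by the same flat parameter
    names as :meth:`param_names`.
    """

    trait_name: str
    mu: float
    env_terms: Mapping[str, float] = field(default_factory=dict)
    qtl_terms: Mapping[str, float] = field(default_factory=dict)
    qtl_env_terms: Mapping[tuple, float] = field(default_factory=dict)
    env_env_terms: Mapping[tuple, float] = field(default_factory=dict)
    env_means: Mapping[str, float] = field(default_factory=dict)
    standard_errors: Mapping[str, float] | None = None

    def __post_init__(self):
        if self.trait_name not in TRAITS:
            raise SchemaError(
                f"unknown trait {self.trait_name!r}; expected one of {TRAITS}"
            )
        used = set(self.env_terms)
        used.update(cov for _, cov in self.qtl_env_terms)
        for c1, c2 in self.env_env_terms:
            used.update((c1, c2))
        for cov in used:
            if cov not in COVARIATES:
                raise SchemaError(f"unknown covariate {cov!r} in {self.trait_name}")
            if cov not in self.env_means:
                raise SchemaError(
                    f"covariate {cov!r} used in {self.trait_name} has no "
                    f"centering mean"
                )
        for values in (
            [self.mu],
            self.env_terms.values(),
            self.qtl_terms.values(),
            self.qtl_env_terms.values(),
            self.env_env_terms.values(),
        ):
            for v in values:
                if not np.isfinite(v):
                    raise SchemaError(f"non-finite coefficient in {self.trait_name}")

    # -- flat parameter naming (used by calibration and the config format) --

    def param_names(self) -> list[str]:
        """Ordered flat names: mu, env:*, qtl:*, qtl_env:*, env_env:*."""
        names = ["mu"]
        names += [f"env:{c}" for c in self.env_terms]
        names += [f"qtl:{m}" for m in self.qtl_terms]
        names += [f"qtl_env:{m}:{c}" for m, c in self.qtl_env_terms]
        names += [f"env_env:{c1}:{c2}" for c1, c2 in self.env_env_terms]
        return names

    def get_param(self, name: str) -> float:
        kind, _, rest = name.partition(":")
        if kind == "mu":
            return self.mu
        if kind == "env":
            return self.env_terms[rest]
        if kind == "qtl":
            return self.qtl_terms[rest]
        if kind == "qtl_env":
            m, _, c = rest.partition(":")
            return self.qtl_env_terms[(m, c)]
        if kind == "env_env":
            c1, _, c2 = rest.partition(":")
            return self.env_env_terms[(c1, c2)]
        raise SchemaError(f"unknown parameter name {name!r}")

    def with_params(self, updates: Mapping[str, float]) -> "TraitParameters":
        """Return a copy with the named flat parameters replaced."""
        mu = self.mu
        env = dict(self.env_terms)
        qtl = dict(self.qtl_terms)
        qtl_env = dict(self.qtl_env_terms)
        env_env = dict(self.env_env_terms)
        for name, value in updates.items():
            kind, _, rest = name.partition(":")
            if kind == "mu":
                mu = value
            elif kind == "env" and rest in env:
                env[rest] = value
            elif kind == "qtl" and rest in qtl:
                qtl[rest] = value
            elif kind == "qtl_env":
                m, _, c = rest.partition(":")
                if (m, c) not in qtl_env:
                    raise SchemaError(f"unknown parameter {name!r}")
                qtl_env[(m, c)] = value
            elif kind == "env_env":
                c1, _, c2 = rest.partition(":")
                if (c1, c2) not in env_env:
                    raise SchemaError(f"unknown parameter {name!r}")
                env_env[(c1, c2)] = value
            else:
                raise SchemaError(f"unknown parameter {name!r}")
        return replace(
            self,
            mu=mu,
            env_terms=env,
            qtl_terms=qtl,
            qtl_env_terms=qtl_env,
            env_env_terms=env_env,
        )

    def mean_environment(self) -> DailyEnvironment:
        """The environment at which every centered term vanishes."""
        return DailyEnvironment(
            tmean=self.env_means.get("TMEAN", 0.0),
            srad=self.env_means.get("SRAD", 0.0),
            daylength=self.env_means.get("DL", 12.0),
        )


def evaluate_trait(
    params: TraitParameters, env: DailyEnvironment, genotype: GenotypeVector
) -> float:
    """Evaluate the linear predictor; deterministic (no residual term)."""
    value = params.mu
    centered = {}
    for cov in params.env_means:
        centered[cov] = env.get(cov) - params.env_means[cov]
    for cov, b1 in params.env_terms.items():
        value += b1 * centered[cov]
    for marker, b2 in params.qtl_terms.items():
        value += b2 * genotype.marker(marker)
    for (marker, cov), b3 in params.qtl_env_terms.items():
        value += b3 * genotype.marker(marker) * centered[cov]
    for (c1, c2), b in params.env_env_terms.items():
        value += b * centered[c1] * centered[c2]
    return value


def _clamped_rate(params, env, genotype, trait):
    if params.trait_name != trait:
        raise ModelError(
            f"expected {trait} parameters, got {params.trait_name!r}"
        )
    value = evaluate_trait(params, env, genotype)
    if value < 0.0:
        logger.warning(
            "%s rate %.3g < 0 for genotype %s; clamped to 0",
            trait,
            value,
            genotype.genotype_id,
        )
        return 0.0, True
    return value, False


def rf_rate(
    env: DailyEnvironment, genotype: GenotypeVector, params: TraitParameters
) -> float:
    """Daily rate of progress toward flowering (d-1), clamped at 0."""
    return _clamped_rate(params, env, genotype, "RF")[0]


def nar_rate(
    env: DailyEnvironment, genotype: GenotypeVector, params: TraitParameters
) -> float:
    """Daily main-stem node addition rate (nodes d-1), clamped at 0."""
    return _clamped_rate(params, env, genotype, "NAR")[0]


def msnodmax_value(
    running_env: DailyEnvironment,
    genotype: GenotypeVector,
    params: TraitParameters,
) -> float:
    """Maximum main-stem node number from running-mean covariates, >= 0.

    ``running_env`` must hold covariates averaged from planting (day 0)
    through the current simulation day, inclusive.
    """
    if params.trait_name != "MSNODMAX":
        raise ModelError(f"expected MSNODMAX parameters, got {params.trait_name!r}")
    return max(0.0, evaluate_trait(params, running_env, genotype))


def running_environment_mean(series, from_dap: int, to_dap: int) -> DailyEnvironment:
    """Arithmetic mean of TMEAN, SRAD, DL over days ``from_dap..to_dap``.

    ``series`` is a :class:`beanphen.io_formats.WeatherSeries` whose first
    record is the planting day (day-after-planting 0).
    """
    if to_dap < from_dap:
        raise RangeError(f"empty window [{from_dap}, {to_dap}]")
    if from_dap < 0 or to_dap >= len(series.frame):
        raise RangeError(
            f"window [{from_dap}, {to_dap}] outside weather series of length "
            f"{len(series.frame)}"
        )
    sub = series.frame.iloc[from_dap : to_dap + 1]
    return DailyEnvironment(
        tmean=float(sub["tmean"].mean()),
        srad=float(sub["srad"].mean()),
        daylength=float(sub["daylength"].mean()),
    )
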