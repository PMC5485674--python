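"""Simulate-and-compare nonlinear least squares for the trait modules.

Each trait has its own sum-of-squares objective:

* flowering: squared differences between simulated and observed day of
  first flower (days after emergence), summed over genotype x site pairs;
  pairs whose simulation never flowers by the end of the experiment
  contribute the end-of-experiment day instead (and are logged), so the
  objective has no flat "missing" regions;
* node counts: squared differences between simulated and observed
  main-stem node number on each observation date (days after planting);
* final node number: the node-ceiling model is evaluated directly on
  covariates averaged from planting to the day the final node number was
  first observed, and compared with the observed value.

Within the flowering objective the simulated day of first flower is the
fractional (linearly interpolated) crossing of cumulative development
through 1.0, which makes the objective piecewise smooth in the parameters
and lets a derivative-based optimizer converge; whole-day output is
unaffected.

Minimization is Levenberg-Marquardt on the residual vector with a
finite-difference Jacobian; standard errors come from the Gauss-Newton
approximation s^2 (J'J)^-1 at the optimum.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .engine import simulate_site_batch
from .errors import ObjectiveError, SchemaError
from .io_formats import (
    MarkerTable,
    ParameterSet,
    SiteConfig,
    WeatherSeries,
    load_default_parameters,
)
from .qtl_effects import (
    DailyEnvironment,
    GenotypeVector,
    TraitParameters,
    evaluate_trait,
)

logger = logging.getLogger(__name__)


@dataclass
class FitSpec:
    """What to fit and how.

    ``free_parameters`` uses the flat names of
    :meth:`~beanphen.qtl_effects.TraitParameters.param_names`; ``None``
    frees every coefficient of the module.  ``initial`` supplies starting
    values (defaults to the shipped published estimates).
    """

    trait: str
    free_parameters: list[str] | None = None
    initial: TraitParameters | None = None
    bounds: dict[str, tuple[float, float]] | None = None
    max_iterations: int = 200
    tolerance: float = 1e-8
    diff_step: float = 1e-6


@dataclass
class FitResult:
    trait: str
    estimates: dict[str, float]
    standard_errors: dict[str, float]
    ssq: float
    n_obs: int
    converged: bool
    iterations: int
    message: str = ""
    parameters: TraitParameters | None = None

    def diagnostics_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": list(self.estimates),
                "estimate": list(self.estimates.values()),
                "se": [self.standard_errors.get(k, np.nan) for k in self.estimates],
            }
        )


def _as_genotypes(population) -> list[GenotypeVector]:
    if isinstance(population, MarkerTable):
        return population.genotypes()
    return list(population)


def _obs_of_kind(observations: pd.DataFrame, kind: str) -> pd.DataFrame:
    return observations[observations["obs_kind"] == kind]


class _TraitObjective:
    """Residual vector for one trait, over all sites with observations."""

    def __init__(
        self,
        trait: str,
        observations: pd.DataFrame,
        population,
        sites: list[tuple[SiteConfig, WeatherSeries]],
        base_params: ParameterSet,
        tie_region: bool = True,
    ):
        self.trait = trait
        self.base = base_params
        self.tie_region = tie_region
        genotypes = _as_genotypes(population)
        by_id = {g.genotype_id: g for g in genotypes}
        kind = {
            "RF": "flowering_day_after_emergence",
            "NAR": "node_count",
            "MSNODMAX": "final_node_count",
        }[trait]
        obs = _obs_of_kind(observations, kind)
        self.site_ctx = []
        self._msn_rows = []  # (env, genotype, value) for the final-node objective
        n_used = 0
        for cfg, weather in sites:
            sobs = obs[obs["site_id"] == cfg.site_id]
            if sobs.empty:
                continue
            gids = [g for g in sobs["genotype_id"].unique() if g in by_id]
            dropped = set(sobs["genotype_id"].unique()) - set(gids)
            if dropped:
                logger.warning(
                    "%s: observations for unknown genotypes %s skipped",
                    cfg.site_id,
                    sorted(dropped),
                )
            if not gids:
                continue
            gindex = {g: i for i, g in enumerate(gids)}
            site_genos = [by_id[g] for g in gids]
            if trait == "RF":
                rows = sobs[sobs["genotype_id"].isin(gindex)]
                g_idx = rows["genotype_id"].map(gindex).to_numpy(int)
                values = rows["value"].to_numpy(float)
                self.site_ctx.append(
                    dict(cfg=cfg, weather=weather, genotypes=site_genos,
                         g_idx=g_idx, values=values)
                )
                n_used += len(values)
            elif trait == "NAR":
                rows = sobs[sobs["genotype_id"].isin(gindex)].copy()
                days = rows["obs_day"].to_numpy(float)
                ok = (days >= cfg.emergence_dap) & (days <= cfg.end_dap)
                if (~ok).any():
                    logger.warning(
                        "%s: %d node observations outside the emergence..end "
                        "window excluded",
                        cfg.site_id,
                        int((~ok).sum()),
                    )
                rows = rows[ok]
                if rows.empty:
                    continue
                g_idx = rows["genotype_id"].map(gindex).to_numpy(int)
                day_idx = rows["obs_day"].to_numpy(int) - cfg.emergence_dap
                values = rows["value"].to_numpy(float)
                self.site_ctx.append(
                    dict(cfg=cfg, weather=weather, genotypes=site_genos,
                         g_idx=g_idx, day_idx=day_idx, values=values)
                )
                n_used += len(values)
            else:  # MSNODMAX: direct evaluation, window planting..obs_day
                aligned = weather.aligned(cfg.planting_date, cfg.end_dap)
                cov = aligned.covariate_arrays()
                for row in sobs.itertuples(index=False):
                    if row.genotype_id not in by_id:
                        continue
                    if pd.isna(row.obs_day):
                        logger.warning(
                            "%s/%s: final-node record without obs_day skipped",
                            row.genotype_id,
                            cfg.site_id,
                        )
                        continue
                    d = int(row.obs_day)
                    d = min(max(d, 0), cfg.end_dap)
                    env = DailyEnvironment(
                        float(cov["TMEAN"][: d + 1].mean()),
                        float(cov["SRAD"][: d + 1].mean()),
                        float(cov["DL"][: d + 1].mean()),
                    )
                    self._msn_rows.append((env, by_id[row.genotype_id],
                                           float(row.value)))
                    n_used += 1
        if n_used == 0:
            raise ObjectiveError(
                f"no usable {kind!r} observations match the population and sites"
            )
        self.n_obs = n_used

    def residuals(self, trait_params: TraitParameters) -> np.ndarray:
        params = self.base.replacing(trait_params)
        out = []
        if self.trait == "MSNODMAX":
            for env, genotype, value in self._msn_rows:
                pred = max(0.0, evaluate_trait(trait_params, env, genotype))
                out.append(pred - value)
            return np.asarray(out)
        for ctx in self.site_ctx:
            cfg = ctx["cfg"]
            batch = simulate_site_batch(
                ctx["genotypes"], cfg, ctx["weather"], params,
                tie_region=self.tie_region,
                compute_nodes=(self.trait == "NAR"),
            )
            if self.trait == "RF":
                end_dae = float(cfg.end_dap - cfg.emergence_dap)
                sim = np.where(
                    np.isnan(batch.anthesis_dae_frac),
                    end_dae,
                    batch.anthesis_dae_frac,
                )
                n_never = int(np.isnan(batch.anthesis_dae_frac).sum())
                if n_never:
                    logger.info(
                        "%s: %d genotypes never flowered; penalized at day %.0f",
                        cfg.site_id, n_never, end_dae,
                    )
                out.append(sim[ctx["g_idx"]] - ctx["values"])
            else:
                sim = batch.nodes[ctx["g_idx"], ctx["day_idx"]]
                out.append(sim - ctx["values"])
        return np.concatenate(out)


def ssq_flowering(
    params_rf, observations, population, sites, base_params=None, tie_region=True
) -> float:
    """Sum of squared flowering-day errors (days^2) at the given RF parameters."""
    base = base_params or load_default_parameters()
    obj = _TraitObjective("RF", observations, population, sites, base, tie_region)
    return float(np.sum(obj.residuals(params_rf) ** 2))


def ssq_nodes(
    params_nar, observations, population, sites, base_params=None, tie_region=True
) -> float:
    """Sum of squared node-count errors (nodes^2) at the given NAR parameters."""
    base = base_params or load_default_parameters()
    obj = _TraitObjective("NAR", observations, population, sites, base, tie_region)
    return float(np.sum(obj.residuals(params_nar) ** 2))


def ssq_final_nodes(
    params_msn, observations, population, sites, base_params=None, tie_region=True
) -> float:
    """Sum of squared final-node errors (nodes^2) at the given parameters."""
    base = base_params or load_default_parameters()
    obj = _TraitObjective(
        "MSNODMAX", observations, population, sites, base, tie_region
    )
    return float(np.sum(obj.residuals(params_msn) ** 2))


def fit_module(
    spec: FitSpec,
    observations: pd.DataFrame,
    population,
    sites: list[tuple[SiteConfig, WeatherSeries]],
    base_params: ParameterSet | None = None,
    tie_region: bool = True,
) -> FitResult:
    """Estimate the free coefficients of one trait module.

    Deterministic given the spec (no stochastic restarts).  Non-convergence
    is reported via ``converged=False``, not raised.
    """
    base = base_params or load_default_parameters()
    initial = spec.initial or base.for_trait(spec.trait)
    if initial.trait_name != spec.trait:
        raise SchemaError(
            f"initial parameters are for {initial.trait_name}, spec wants "
            f"{spec.trait}"
        )
    free = (
        initial.param_names()
        if spec.free_parameters is None
        else list(spec.free_parameters)
    )
    for name in free:
        initial.get_param(name)  # raises SchemaError on unknown names
    obj = _TraitObjective(
        spec.trait, observations, population, sites, base, tie_region
    )

    if not free:
        ssq = float(np.sum(obj.residuals(initial) ** 2))
        return FitResult(
            trait=spec.trait,
            estimates={},
            standard_errors={},
            ssq=ssq,
            n_obs=obj.n_obs,
            converged=True,
            iterations=0,
            message="no free parameters; objective evaluated at initial values",
            parameters=initial,
        )

    x0 = np.array([initial.get_param(n) for n in free], float)

    def fun(x):
        return obj.residuals(initial.with_params(dict(zip(free, x))))

    kwargs: dict = dict(
        xtol=spec.tolerance,
        ftol=spec.tolerance,
        gtol=spec.tolerance,
        diff_step=spec.diff_step,
        max_nfev=spec.max_iterations * (len(free) + 1),
    )
    if spec.bounds:
        lo = np.array([spec.bounds.get(n, (-np.inf, np.inf))[0] for n in free])
        hi = np.array([spec.bounds.get(n, (-np.inf, np.inf))[1] for n in free])
        res = least_squares(fun, x0, bounds=(lo, hi), method="trf", **kwargs)
    else:
        res = least_squares(fun, x0, method="lm", **kwargs)

    estimates = dict(zip(free, (float(v) for v in res.x)))
    ssq = float(np.sum(res.fun**2))
    n, p = len(res.fun), len(free)
    ses: dict[str, float] = {}
    if n > p:
        s2 = ssq / (n - p)
        jtj = res.jac.T @ res.jac
        cov = s2 * np.linalg.pinv(jtj)
        diag = np.clip(np.diag(cov), 0.0, None)
        ses = dict(zip(free, (float(v) for v in np.sqrt(diag))))
    fitted = dataclasses.replace(
        initial.with_params(estimates), standard_errors=ses or None
    )
    converged = bool(res.status > 0)
    if not converged:
        logger.warning("fit for %s did not converge: %s", spec.trait, res.message)
    return FitResult(
        trait=spec.trait,
        estimates=estimates,
        standard_errors=ses,
        ssq=ssq,
        n_obs=obj.n_obs,
        converged=converged,
        iterations=int(res.nfev),
        message=str(res.message),
        parameters=fitted,
    )
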