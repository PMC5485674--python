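"""Daily-time-step integration of the three trait modules.

For each genotype at a site the engine integrates, from emergence to the
end of the experiment (both in days after planting, DAP):

* cumulative development TF(t) = TF(t-1) + RF(t) * dt, with dt = 1 d;
  anthesis is the first day on which TF >= 1 (a fractional crossing day is
  also recorded for calibration, by linear interpolation within that day);
* the node ceiling MSNODmax(t), evaluated on covariates averaged from
  planting (day 0) through day t inclusive, re-evaluated daily until the
  day of anthesis and frozen thereafter;
* node number N(t) = N(t-1) + NAR(t) * dt, starting at 0.0 on the
  emergence day.  Node addition requires (i) the genotype has not finished
  (final node number not yet set), (ii) for determinate genotypes,
  flowering had not occurred before today, and (iii) yesterday's node
  number was below yesterday's ceiling.  The increment is truncated so the
  node count never exceeds today's ceiling.

The final node number is set at anthesis for determinate genotypes, or
when the node count reaches the ceiling (either habit); node addition
stops permanently once it is set.

Determinacy is read from the JC28 marker (+1 Calima = determinate,
-1 Jamapa = indeterminate); when JC28 is absent or missing, the tied
chromosome-1 region markers TF2/MSN2/NAR2 are consulted as a fallback.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import DeterminacyError, RangeError
from .io_formats import MarkerTable, ParameterSet, SiteConfig, WeatherSeries
from .qtl_effects import (
    DETERMINACY_MARKER,
    DailyEnvironment,
    GenotypeVector,
    TIED_REGION_MARKERS,
    TraitParameters,
    evaluate_trait,
    msnodmax_value,
    nar_rate,
    rf_rate,
)

logger = logging.getLogger(__name__)

_CEILING_EPS = 1e-12


def determinacy_of(genotype: GenotypeVector, tie_region: bool = True) -> str:
    """Growth habit: ``"determinate"`` (+1 at JC28) or ``"indeterminate"`` (-1).

    With ``tie_region`` (default), a missing JC28 call falls back to the
    consensus of the tied chromosome-1 markers TF2, MSN2, NAR2.
    """
    value = genotype.marker_values.get(DETERMINACY_MARKER, 0.0)
    if value == 0.0 and tie_region:
        tied = [
            genotype.marker_values.get(m, 0.0)
            for m in TIED_REGION_MARKERS
            if m != DETERMINACY_MARKER
        ]
        nonzero = {v for v in tied if v != 0.0}
        if len(nonzero) == 1:
            value = nonzero.pop()
    if value > 0:
        return "determinate"
    if value < 0:
        return "indeterminate"
    raise DeterminacyError(
        f"genotype {genotype.genotype_id!r}: determinacy marker "
        f"{DETERMINACY_MARKER} missing and tied-region markers do not resolve it"
    )


@dataclass(frozen=True)
class SimulationState:
    """Engine state at the end of day ``dap`` (days after planting)."""

    dap: int
    tf_cum: float = 0.0
    nodes: float = 0.0
    msnodmax_t: float = 0.0
    flowered: bool = False
    anthesis_dae: int | None = None
    anthesis_dae_frac: float | None = None
    n_final: float | None = None
    clamp_events: int = 0


@dataclass
class SimulationResult:
    """Daily trajectory and summary for one genotype at one site."""

    genotype_id: str
    site_id: str
    emergence_dap: int
    end_dap: int
    dap: np.ndarray
    tf_cum: np.ndarray
    nodes: np.ndarray
    msnodmax: np.ndarray
    anthesis_dae: int | None
    anthesis_dap: int | None
    anthesis_dae_frac: float | None
    n_final: float
    never_flowered: bool
    n_final_censored: bool
    clamp_events: int

    def trajectory_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "genotype_id": self.genotype_id,
                "site_id": self.site_id,
                "dap": self.dap,
                "tf_cum": self.tf_cum,
                "nodes": self.nodes,
                "msnodmax": self.msnodmax,
            }
        )

    def nodes_at(self, dap: int) -> float:
        """Node count on a given day after planting (0 before emergence)."""
        if dap < self.emergence_dap:
            return 0.0
        idx = dap - self.emergence_dap
        if idx >= len(self.nodes):
            raise RangeError(f"day {dap} beyond simulation end {self.end_dap}")
        return float(self.nodes[idx])


def _rate_clamped(params, env, genotype, kind):
    raw = evaluate_trait(params, env, genotype)
    if raw < 0.0:
        return 0.0, True
    return raw, False


def step(
    state: SimulationState,
    env: DailyEnvironment,
    running_env: DailyEnvironment,
    genotype: GenotypeVector,
    params_rf: TraitParameters,
    params_nar: TraitParameters,
    params_msn: TraitParameters,
    emergence_dap: int,
    tie_region: bool = True,
) -> SimulationState:
    """Advance one day: returns the state at the end of day ``state.dap + 1``.

    ``env`` holds that day's covariates; ``running_env`` their means from
    planting through that day inclusive.
    """
    determinate = determinacy_of(genotype, tie_region) == "determinate"
    day = state.dap + 1
    prev_flowered = state.flowered
    prev_nodes = state.nodes
    prev_ceiling = state.msnodmax_t
    clamps = state.clamp_events

    # (i) development toward flowering
    tf = state.tf_cum
    flowered = prev_flowered
    anthesis_dae = state.anthesis_dae
    anthesis_frac = state.anthesis_dae_frac
    if not prev_flowered:
        rf, clamped = _rate_clamped(params_rf, env, genotype, "RF")
        clamps += int(clamped)
        tf = tf + rf
        if tf >= 1.0:
            flowered = True
            anthesis_dae = day - emergence_dap
            # linear interpolation within the crossing day
            anthesis_frac = (day - emergence_dap - 1) + (1.0 - state.tf_cum) / rf

    # (ii) node ceiling: re-evaluated until (and including) the anthesis day
    if not prev_flowered:
        ceiling = msnodmax_value(running_env, genotype, params_msn)
    else:
        ceiling = prev_ceiling

    # (iii) node addition
    nodes = prev_nodes
    n_final = state.n_final
    may_add = (
        n_final is None
        and ((not determinate) or (not prev_flowered))
        and prev_nodes < prev_ceiling
    )
    if may_add:
        nar, clamped = _rate_clamped(params_nar, env, genotype, "NAR")
        clamps += int(clamped)
        nodes = min(prev_nodes + nar, ceiling)

    # (iv) final node number
    if n_final is None:
        if nodes >= ceiling - _CEILING_EPS:
            n_final = nodes
        elif determinate and flowered:
            n_final = nodes

    return replace(
        state,
        dap=day,
        tf_cum=tf,
        nodes=nodes,
        msnodmax_t=ceiling,
        flowered=flowered,
        anthesis_dae=anthesis_dae,
        anthesis_dae_frac=anthesis_frac,
        n_final=n_final,
        clamp_events=clamps,
    )


def simulate_genotype_site(
    genotype: GenotypeVector,
    site: SiteConfig,
    weather: WeatherSeries,
    params: ParameterSet,
    tie_region: bool = True,
) -> SimulationResult:
    """Run the daily state machine from emergence to the end of experiment."""
    aligned = weather.aligned(site.planting_date, site.end_dap)
    cov = aligned.covariate_arrays()
    run = {k: np.cumsum(v) / np.arange(1, len(v) + 1) for k, v in cov.items()}

    def env_at(d):
        return DailyEnvironment(cov["TMEAN"][d], cov["SRAD"][d], cov["DL"][d])

    def run_at(d):
        return DailyEnvironment(run["TMEAN"][d], run["SRAD"][d], run["DL"][d])

    e = site.emergence_dap
    state = SimulationState(
        dap=e,
        msnodmax_t=msnodmax_value(run_at(e), genotype, params.msnodmax),
    )
    daps = [e]
    tf_traj = [0.0]
    node_traj = [0.0]
    ceil_traj = [state.msnodmax_t]
    for day in range(e + 1, site.end_dap + 1):
        state = step(
            state,
            env_at(day),
            run_at(day),
            genotype,
            params.rf,
            params.nar,
            params.msnodmax,
            emergence_dap=e,
            tie_region=tie_region,
        )
        daps.append(day)
        tf_traj.append(state.tf_cum)
        node_traj.append(state.nodes)
        ceil_traj.append(state.msnodmax_t)

    never_flowered = not state.flowered
    if never_flowered:
        logger.warning(
            "genotype %s at %s never flowered by day %d",
            genotype.genotype_id,
            site.site_id,
            site.end_dap,
        )
    censored = state.n_final is None
    return SimulationResult(
        genotype_id=genotype.genotype_id,
        site_id=site.site_id,
        emergence_dap=e,
        end_dap=site.end_dap,
        dap=np.asarray(daps),
        tf_cum=np.asarray(tf_traj),
        nodes=np.asarray(node_traj),
        msnodmax=np.asarray(ceil_traj),
        anthesis_dae=state.anthesis_dae,
        anthesis_dap=(
            state.anthesis_dae + e if state.anthesis_dae is not None else None
        ),
        anthesis_dae_frac=state.anthesis_dae_frac,
        n_final=float(state.nodes) if censored else float(state.n_final),
        never_flowered=never_flowered,
        n_final_censored=censored,
        clamp_events=state.clamp_events,
    )


def simulate_population(
    marker_table: MarkerTable,
    sites: list[tuple[SiteConfig, WeatherSeries]],
    params: ParameterSet,
    tie_region: bool = True,
) -> list[SimulationResult]:
    """One result per genotype x site; per-genotype failures are logged
    and skipped so the rest of the population still runs."""
    results = []
    failures = []
    for gid in marker_table.genotype_ids:
        genotype = marker_table.genotype(gid)
        for cfg, weather in sites:
            try:
                results.append(
                    simulate_genotype_site(genotype, cfg, weather, params, tie_region)
                )
            except Exception as exc:  # aggregated, run continues
                failures.append((gid, cfg.site_id, exc))
                logger.error("genotype %s at %s failed: %s", gid, cfg.site_id, exc)
    if failures and not results:
        raise failures[0][2]
    return results


# ---------------------------------------------------------------------------
# Vectorized batch path (same semantics as `step`, all genotypes at once).
# Used by the calibration objectives, where the engine is re-run hundreds of
# times; equivalence with the scalar path is covered by the test suite.


def _marker_matrix(genotypes, order):
    return np.array(
        [[g.marker_values.get(m, 0.0) for m in order] for g in genotypes], float
    )


def _batch_rates(params: TraitParameters, E: dict, genotypes) -> np.ndarray:
    """Raw (unclamped) rate matrix, genotypes x days."""
    n_days = len(E["TMEAN"])
    centered = {c: E[c] - params.env_means[c] for c in params.env_means}
    base = np.full(n_days, params.mu)
    for cov, b1 in params.env_terms.items():
        base = base + b1 * centered[cov]
    for (c1, c2), b in params.env_env_terms.items():
        base = base + b * centered[c1] * centered[c2]
    qtl_order = list(params.qtl_terms)
    Q = _marker_matrix(genotypes, qtl_order)
    b2 = np.array([params.qtl_terms[m] for m in qtl_order])
    rates = np.tile(base, (len(genotypes), 1))
    if len(qtl_order):
        rates += (Q @ b2)[:, None]
    for (marker, cov), b3 in params.qtl_env_terms.items():
        q = np.array([g.marker_values.get(marker, 0.0) for g in genotypes])
        rates += b3 * q[:, None] * centered[cov][None, :]
    return rates


@dataclass
class BatchResult:
    """Arrays over genotypes (axis 0) and days emergence..end (axis 1)."""

    genotype_ids: list[str]
    site_id: str
    emergence_dap: int
    end_dap: int
    tf_cum: np.ndarray
    nodes: np.ndarray
    msnodmax: np.ndarray
    anthesis_dae: np.ndarray  # int, -1 if never flowered
    anthesis_dae_frac: np.ndarray  # nan if never flowered
    n_final: np.ndarray
    clamp_events: int


def simulate_site_batch(
    genotypes: list[GenotypeVector],
    site: SiteConfig,
    weather: WeatherSeries,
    params: ParameterSet,
    tie_region: bool = True,
    compute_nodes: bool = True,
) -> BatchResult:
    """Vectorized equivalent of per-genotype `simulate_genotype_site`."""
    aligned = weather.aligned(site.planting_date, site.end_dap)
    cov = aligned.covariate_arrays()
    run = {k: np.cumsum(v) / np.arange(1, len(v) + 1) for k, v in cov.items()}
    e, end = site.emergence_dap, site.end_dap
    steps = np.arange(e + 1, end + 1)  # days driving increments
    G, T = len(genotypes), len(steps)

    E_steps = {k: v[steps] for k, v in cov.items()}
    run_days = {k: v[e : end + 1] for k, v in run.items()}  # days e..end

    det = np.array(
        [determinacy_of(g, tie_region) == "determinate" for g in genotypes]
    )

    rf_raw = _batch_rates(params.rf, E_steps, genotypes)
    nar_raw = _batch_rates(params.nar, E_steps, genotypes)
    clamps = int((rf_raw < 0).sum() + (nar_raw < 0).sum())
    rf = np.maximum(rf_raw, 0.0)
    nar = np.maximum(nar_raw, 0.0)

    # ceiling over days e..end (pre-freeze), floored at 0
    ceil_all = np.maximum(_batch_rates(params.msnodmax, run_days, genotypes), 0.0)

    # flowering
    tf = np.cumsum(rf, axis=1)  # tf[:, k] is TF at day steps[k]
    crossed = tf >= 1.0
    any_cross = crossed.any(axis=1)
    cross_idx = np.where(any_cross, crossed.argmax(axis=1), -1)
    anthesis_dae = np.where(any_cross, cross_idx + 1, -1)
    tf_prev = np.where(
        cross_idx > 0, np.take_along_axis(
            tf, np.maximum(cross_idx - 1, 0)[:, None], axis=1
        )[:, 0], 0.0
    )
    rf_cross = np.take_along_axis(rf, np.maximum(cross_idx, 0)[:, None], axis=1)[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = cross_idx + (1.0 - tf_prev) / rf_cross
    anthesis_frac = np.where(any_cross, frac, np.nan)

    # scalar engine stops accumulating TF once flowered: freeze at crossing
    step_idx = np.arange(T)[None, :]
    tf_at_cross = np.take_along_axis(tf, np.maximum(cross_idx, 0)[:, None], axis=1)
    tf = np.where(
        any_cross[:, None] & (step_idx > cross_idx[:, None]), tf_at_cross, tf
    )

    # freeze ceiling at the anthesis day (day index anthesis_dae within e..end)
    ceil = ceil_all.copy()
    day_idx = np.arange(end - e + 1)[None, :]
    freeze_at = np.where(any_cross, anthesis_dae, end - e)[:, None]
    frozen_vals = np.take_along_axis(ceil_all, np.minimum(freeze_at, end - e), axis=1)
    ceil = np.where(day_idx > freeze_at, frozen_vals, ceil_all)

    # node integration (loop over days, vectorized over genotypes)
    nodes = np.zeros((G, T + 1))
    n_final = np.full(G, np.nan)
    flowered_before = np.zeros(G, bool)
    for k in range(T if compute_nodes else 0):
        prev_nodes = nodes[:, k]
        prev_ceil = ceil[:, k]
        today_ceil = ceil[:, k + 1]
        flowered_today = any_cross & (anthesis_dae == k + 1)
        may_add = (
            np.isnan(n_final)
            & (~det | ~flowered_before)
            & (prev_nodes < prev_ceil)
        )
        new_nodes = np.where(
            may_add, np.minimum(prev_nodes + nar[:, k], today_ceil), prev_nodes
        )
        nodes[:, k + 1] = new_nodes
        hit = np.isnan(n_final) & (new_nodes >= today_ceil - _CEILING_EPS)
        n_final = np.where(hit, new_nodes, n_final)
        det_done = np.isnan(n_final) & det & (flowered_before | flowered_today)
        n_final = np.where(det_done, new_nodes, n_final)
        flowered_before = flowered_before | flowered_today

    n_final = np.where(np.isnan(n_final), nodes[:, -1], n_final)
    tf_full = np.concatenate([np.zeros((G, 1)), tf], axis=1)
    return BatchResult(
        genotype_ids=[g.genotype_id for g in genotypes],
        site_id=site.site_id,
        emergence_dap=e,
        end_dap=end,
        tf_cum=tf_full,
        nodes=nodes,
        msnodmax=ceil,
        anthesis_dae=anthesis_dae,
        anthesis_dae_frac=anthesis_frac,
        n_final=n_final,
        clamp_events=clamps,
    )
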