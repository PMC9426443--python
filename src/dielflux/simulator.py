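"""Diel dynamic-FBA marching loop with decoupled biomass and PI control.

Each timestep of length dt (default 0.1 h, i.e. 6 min):

1. every GPR-bearing reaction is re-bounded from the transcript curves
   (E-Flux rule: upper bound u_max * min(1, v_rule(t)));
2. the PI controllers update production/consumption errors from the
   current component mass fractions versus the diel setpoints;
3. the cell first secures maintenance ATP (NGAM): from the medium if it
   can, otherwise by opening component degradation in consumption-priority
   order — failure with every store open is cell death;
4. production maximizes the error-weighted sum of component synthesis
   fluxes and then expands the production window: achieved fluxes are
   fixed as floors and the remaining (nonlimiting) components re-maximized
   until no further gain; a final pass minimizes degradation at the
   achieved production so stores are only consumed as far as needed;
5. masses advance by forward Euler, Δm_k = (v_syn,k − v_deg,k)·M·dt, with
   the non-catabolizable share of degraded mass dumped from the cell and
   tracked in a ledger that closes exactly:
   Δtotal = production − consumption − dumped.

Synthesis and degradation pseudo-reaction fluxes are in grams of component
per gram dry weight per hour by construction, so no stoichiometric
conversion appears in the mass update.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .biomass import (BiomassComponent, ControllerState, SetpointTable,
                      consumption_priority, objective_weights)
from .errors import ConfigError, ValidationError
from .gpr import BoundSchedule, CurveSet, calibrate_umax, parse_gpr

log = logging.getLogger(__name__)

_BIG = 1000.0


@dataclass
class Environment:
    """Light schedule, medium composition and maintenance demand.

    ``light_availability`` is the photon supply (mmol photons/gDW/h)
    during the photoperiod of a 12:12 square-wave schedule; ``medium``
    maps exchange-reaction ids to maximum uptake rates (positive numbers,
    mmol/gDW/h); ``ngam`` is the non-growth-associated maintenance ATP
    demand (mmol ATP/gDW/h) enforced at every timestep.
    """

    light_availability: float
    medium: Dict[str, float] = field(default_factory=dict)
    ngam: float = 1.0
    day_length: float = 12.0
    photon_exchange: str = "EX_photon"
    #: exchanges counted as energy inputs (closed when testing production
    #: fueled by a biomass component); nutrient exchanges stay open
    energy_exchanges: Tuple[str, ...] = ("EX_photon", "EX_ac")
    light_reaction: str | None = None  # GPR-bearing light-uptake reaction
    ngam_reaction: str = "ATPM"

    def __post_init__(self):
        if self.light_availability < 0:
            raise ConfigError("light availability must be >= 0")
        if self.ngam <= 0:
            raise ConfigError("NGAM must be positive")

    def light_at(self, t: float) -> float:
        return self.light_availability if (t % 24.0) < self.day_length else 0.0


@dataclass
class SimulationConfig:
    hours: float = 24.0
    dt: float = 0.1
    production_grid_h: float = 1.0  # producibility precompute spacing
    expansion_tol: float = 1e-6
    max_expansion_rounds: int = 4
    mass_tol: float = 1e-6
    seed: int = 0


@dataclass
class DielState:
    """Simulation clock, per-component masses and the dumped-mass ledger."""

    t: float
    component_masses: Dict[str, float]
    dumped_mass: float
    status: str = "alive"  # alive | died

    @property
    def total_mass(self) -> float:
        return sum(self.component_masses.values())


@dataclass
class FluxSolution:
    t: float
    fluxes: Dict[str, float]
    objective: float
    synthesis: Dict[str, float]  # g component / gDW / h
    degradation: Dict[str, float]
    status: str


@dataclass
class StepLedger:
    """Per-step mass bookkeeping (grams)."""

    produced: float
    consumed: float
    dumped: float
    delta_total: float


@dataclass
class SimulationResult:
    states: List[DielState]
    solutions: List[FluxSolution]
    ledgers: List[StepLedger]
    initial_mass: float
    status: str  # completed | died

    @property
    def final_state(self) -> DielState:
        return self.states[-1]

    @property
    def final_normalized_mass(self) -> float:
        return self.final_state.total_mass / self.initial_mass

    def normalized_mass_series(self) -> np.ndarray:
        return np.array([s.total_mass / self.initial_mass for s in self.states])

    def to_frame(self):
        import pandas as pd
        rows = []
        for s in self.states:
            row = {"t": s.t, "total_mass": s.total_mass,
                   "normalized_mass": s.total_mass / self.initial_mass,
                   "dumped_mass": s.dumped_mass, "status": s.status}
            row.update({f"mass_{k}": v for k, v in s.component_masses.items()})
            rows.append(row)
        return pd.DataFrame(rows)


def advance(state: DielState, synthesis: Mapping[str, float],
            degradation: Mapping[str, float],
            components: Mapping[str, BiomassComponent], dt: float,
            mass_tol: float = 1e-6) -> Tuple[DielState, StepLedger]:
    """Forward-Euler mass update with exact ledger bookkeeping.

    Rates are per gram dry weight, so each is multiplied by the current
    total mass and the timestep.  Masses are clamped at zero; an overshoot
    beyond ``mass_tol`` grams raises, smaller overshoots log a warning.
    """
    if dt <= 0:
        raise ValidationError("dt must be positive")
    M = state.total_mass
    masses = dict(state.component_masses)
    produced = consumed = dumped = 0.0
    for k in masses:
        syn = synthesis.get(k, 0.0)
        deg = degradation.get(k, 0.0)
        dm = (syn - deg) * M * dt
        produced += syn * M * dt
        catab = components[k].catabolizable_fraction if k in components else 0.0
        consumed += deg * catab * M * dt
        dumped += deg * (1.0 - catab) * M * dt
        new_mass = masses[k] + dm
        if new_mass < -mass_tol:
            raise ValidationError(
                f"component {k} mass driven to {new_mass:.3e} g; "
                "degradation exceeded availability beyond tolerance")
        if new_mass < 0:
            log.warning("component %s clamped at 0 (overshoot %.2e g)",
                        k, -new_mass)
            dumped += new_mass  # keep the ledger exact under clamping
            new_mass = 0.0
        masses[k] = new_mass
    new_state = DielState(state.t + dt, masses,
                          state.dumped_mass + dumped, state.status)
    ledger = StepLedger(produced, consumed, dumped,
                        new_state.total_mass - state.total_mass)
    return new_state, ledger


class DielSimulation:
    """Owns the decoupled COBRA model and marches it through the cycle."""

    def __init__(self, model, components: Mapping[str, BiomassComponent],
                 curves: CurveSet, environment: Environment,
                 setpoints: SetpointTable,
                 controller: Optional[ControllerState] = None,
                 config: Optional[SimulationConfig] = None):
        self.model = model
        self.components = dict(components)
        self.curves = curves
        self.env = environment
        self.setpoints = setpoints
        self.controller = controller or ControllerState()
        self.config = config or SimulationConfig()
        self.model.solver = "glpk"

        # E-Flux ceiling: anchor the light-uptake rule to light availability
        u_max = environment.light_availability
        if environment.light_reaction is not None:
            rxn = self.model.reactions.get_by_id(environment.light_reaction)
            rule = parse_gpr(rxn.gene_reaction_rule, rxn.id)
            if rule.root is not None:
                u_max = calibrate_umax(rule, curves,
                                       environment.light_availability)
        self.u_max = u_max
        self.schedule = BoundSchedule.from_model(self.model, curves, u_max)

        self._syn = {k: self.model.reactions.get_by_id(c.synthesis_id)
                     for k, c in self.components.items()}
        self._deg = {k: self.model.reactions.get_by_id(c.degradation_id)
                     for k, c in self.components.items()
                     if c.degradation_id is not None}
        self._ngam = self.model.reactions.get_by_id(environment.ngam_reaction)
        self._photon = (self.model.reactions.get_by_id(environment.photon_exchange)
                        if environment.photon_exchange in
                        {r.id for r in self.model.reactions} else None)
        self._sched_rxns = {rid: self.model.reactions.get_by_id(rid)
                            for rid in self.schedule.rules}
        self._obj_vars: Set = set()
        self._apply_medium()
        self._possibilities: Dict[Tuple[float, str], Set[str]] | None = None

    # -- plumbing ---------------------------------------------------------

    def _apply_medium(self):
        for rxn in self.model.boundary:
            if rxn is self._photon:
                continue
            uptake = self.env.medium.get(rxn.id, 0.0)
            rxn.lower_bound = -abs(uptake)
            if rxn.upper_bound <= 0:
                rxn.upper_bound = _BIG
        self._ngam.lower_bound = self.env.ngam
        self._ngam.upper_bound = _BIG

    def _apply_time_bounds(self, t: float):
        for rid, (lb, ub) in self.schedule.bounds_at(t).items():
            self._sched_rxns[rid].bounds = (lb, ub)
        if self._photon is not None:
            self._photon.lower_bound = -self.env.light_at(t)

    def _set_objective(self, coeffs: Mapping, direction: str = "max"):
        # incremental objective editing; far cheaper than rebuilding
        obj = self.model.solver.objective
        if obj.direction != direction:
            obj.direction = direction
        reset = {v: 0.0 for v in self._obj_vars}
        reset.update(coeffs)
        obj.set_linear_coefficients(reset)
        self._obj_vars = set(coeffs)

    def _slim(self) -> float:
        self.model.solver.update()
        status = self.model.solver.optimize()
        if status != "optimal":
            return math.nan
        return float(self.model.solver.objective.value)

    def _deg_cap(self, comp: str, masses: Mapping[str, float],
                 total: float, dt: float) -> float:
        return max(masses.get(comp, 0.0), 0.0) / max(total * dt, 1e-12)

    def _close_all_degs(self):
        for rxn in self._deg.values():
            rxn.upper_bound = 0.0

    def _open_degs(self, comps: Iterable[str], masses: Mapping[str, float],
                   total: float, dt: float):
        for k in comps:
            if k in self._deg:
                self._deg[k].upper_bound = self._deg_cap(k, masses, total, dt)

    # -- production possibilities ----------------------------------------

    def precompute_production_possibilities(
            self, grid_step: float | None = None) -> Dict[Tuple[float, str], Set[str]]:
        """Feasible-synthesis table per (grid time, energy source).

        Source ``medium`` opens the environment's exchanges (and light per
        the schedule); source = component k closes every uptake and opens
        only k's degradation.  A component is producible from a source at
        a grid time when its synthesis flux can be driven positive.
        """
        grid_step = grid_step or self.config.production_grid_h
        grid = np.arange(0.0, 24.0, grid_step)
        sources = ["medium"] + [k for k, c in self.components.items()
                                if c.degradation_id is not None
                                and c.catabolizable_fraction > 0]
        ngam_lb = self._ngam.lower_bound
        self._ngam.lower_bound = 0.0  # pure production capability
        table: Dict[Tuple[float, str], Set[str]] = {}
        saved_medium = {r.id: r.lower_bound for r in self.model.boundary}
        try:
            for tg in grid:
                self._apply_time_bounds(float(tg))
                for source in sources:
                    if source == "medium":
                        for r in self.model.boundary:
                            r.lower_bound = saved_medium[r.id]
                        if self._photon is not None:
                            self._photon.lower_bound = -self.env.light_at(float(tg))
                        self._close_all_degs()
                    else:
                        # energy inputs closed; nutrient exchanges stay open
                        for r in self.model.boundary:
                            r.lower_bound = (0.0 if r.id in
                                             self.env.energy_exchanges
                                             else saved_medium[r.id])
                        self._close_all_degs()
                        self._deg[source].upper_bound = _BIG
                    feasible = set()
                    for comp, syn in self._syn.items():
                        self._set_objective({syn.forward_variable: 1.0})
                        val = self._slim()
                        if math.isfinite(val) and val > 1e-8:
                            feasible.add(comp)
                    table[(float(tg), source)] = feasible
        finally:
            for r in self.model.boundary:
                r.lower_bound = saved_medium[r.id]
            self._close_all_degs()
            self._ngam.lower_bound = ngam_lb
        self._possibilities = table
        self._grid_step = grid_step
        return table

    def _producible_now(self, t: float, open_sources: Sequence[str]) -> Set[str]:
        if self._possibilities is None:
            self.precompute_production_possibilities()
        tg = math.floor((t % 24.0) / self._grid_step) * self._grid_step
        out: Set[str] = set(self._possibilities.get((tg, "medium"), set()))
        for k in open_sources:
            out |= self._possibilities.get((tg, k), set())
        return out

    # -- step phases ------------------------------------------------------

    def satisfy_ngam(self, state: DielState, t: float,
                     apply_bounds: bool = True) -> Tuple[bool, List[str]]:
        """Secure maintenance ATP; returns (alive, opened components).

        Degradations open strictly in consumption-priority order, one
        store at a time; the subsequent production pass minimizes the
        opened fluxes so each store is only drawn down as far as needed.
        Death (False) means NGAM is unreachable with every store open.
        """
        if apply_bounds:
            self._apply_time_bounds(t)
        masses, total = state.component_masses, state.total_mass
        dt = self.config.dt
        self._close_all_degs()
        self._set_objective({}, "max")  # pure feasibility probe
        if math.isfinite(self._slim()):
            return True, []
        priority = consumption_priority(self.controller.e_cons)
        opened: List[str] = []
        for ranked in (priority,
                       consumption_priority(self.controller.e_cons,
                                            emergency=True)):
            for comp in ranked:
                if comp in opened or comp not in self._deg:
                    continue
                if masses.get(comp, 0.0) <= 0:
                    continue
                opened.append(comp)
                self._open_degs([comp], masses, total, dt)
                if math.isfinite(self._slim()):
                    return True, opened
        return False, opened

    def produce_step(self, weights: Mapping[str, float], state: DielState,
                     t: float, open_degs: Sequence[str],
                     apply_bounds: bool = False) -> FluxSolution:
        """Iterative production-window expansion at one timestep.

        First the error-weighted synthesis sum is maximized; achieved
        fluxes are then fixed as floors and the total synthesis of the
        desired set re-maximized, repeating while the window still grows.
        Limiting components are exactly those whose floors bind.  A final
        pass minimizes degradation at the achieved production.

        Open stores degrade at most at their maintenance-required rate
        plus their positive consumption error: catabolism in excess of
        survival is paced by the PI controller, not by availability.
        """
        if apply_bounds:
            self._apply_time_bounds(t)
        masses, total = state.component_masses, state.total_mass
        self._close_all_degs()
        self._open_degs(open_degs, masses, total, self.config.dt)
        deg_vars = {k: self._deg[k] for k in open_degs if k in self._deg}
        if deg_vars:
            # minimal degradation that still meets maintenance ATP
            self._set_objective({r.forward_variable: -1.0
                                 for r in deg_vars.values()})
            if math.isnan(self._slim()):
                return self._record(t, math.nan, "infeasible")
            for k, rxn in deg_vars.items():
                need = max(rxn.flux, 0.0)
                err = max(self.controller.e_cons.get(k, 0.0), 0.0)
                rxn.upper_bound = min(rxn.upper_bound, need + err + 1e-9)
        tol = self.config.expansion_tol
        active = [k for k, w in weights.items() if w > 0]
        floors: Dict[str, float] = {}
        saved_lb = {k: self._syn[k].lower_bound for k in self._syn}
        objective = 0.0
        try:
            if active:
                self._set_objective({self._syn[k].forward_variable: weights[k]
                                     for k in active})
                objective = self._slim()
                if math.isnan(objective):
                    return self._record(t, math.nan, "infeasible")
                floors = {k: max(self._syn[k].flux, 0.0) for k in active}
                last_total = sum(floors.values())
                for _ in range(self.config.max_expansion_rounds):
                    for k, v in floors.items():
                        self._syn[k].lower_bound = max(v - 1e-9, 0.0)
                    self._set_objective({self._syn[k].forward_variable: 1.0
                                         for k in active})
                    val = self._slim()
                    if math.isnan(val):  # relax the last fixing and stop
                        for k in active:
                            self._syn[k].lower_bound = saved_lb[k]
                        log.warning("expansion fixing infeasible at t=%.2f; "
                                    "backed off", t)
                        break
                    new_floors = {k: max(self._syn[k].flux, 0.0) for k in active}
                    gain = sum(new_floors.values()) - last_total
                    floors = new_floors
                    if gain <= tol * max(1.0, last_total):
                        break
                    last_total = sum(floors.values())
                for k, v in floors.items():
                    self._syn[k].lower_bound = max(v - 1e-9, 0.0)
            # final pass: meet NGAM and the fixed production with the least
            # component consumption; a small synthesis penalty pins
            # production at its floors so the vertex is deterministic
            coeffs = {self._deg[k].forward_variable: -1.0
                      for k in open_degs if k in self._deg}
            for k, rxn in self._syn.items():
                coeffs[rxn.forward_variable] = -1e-3
            self._set_objective(coeffs, "max")
            val = self._slim()
            if math.isnan(val):
                return self._record(t, math.nan, "infeasible")
            return self._record(t, objective if active else 0.0, "optimal")
        finally:
            for k, lb in saved_lb.items():
                self._syn[k].lower_bound = lb

    def _record(self, t: float, objective: float, status: str) -> FluxSolution:
        if status != "optimal":
            return FluxSolution(t, {}, objective, {}, {}, status)
        primal = self.model.solver.primal_values
        fluxes = {}
        for rxn in self.model.reactions:
            fwd = primal.get(rxn.forward_variable.name, 0.0)
            rev = primal.get(rxn.reverse_variable.name, 0.0)
            fluxes[rxn.id] = fwd - rev
        syn = {k: fluxes.get(c.synthesis_id, 0.0)
               for k, c in self.components.items()}
        deg = {k: (fluxes.get(c.degradation_id, 0.0)
                   if c.degradation_id else 0.0)
               for k, c in self.components.items()}
        return FluxSolution(t, fluxes, objective, syn, deg, status)

    # -- the loop ---------------------------------------------------------

    def initial_state(self, total_mass: float = 1.0) -> DielState:
        sp = self.setpoints.at(0.0)
        weights = {k: sp.get(k, 0.0) for k in self.components}
        total = sum(weights.values())
        if total <= 0:
            raise ConfigError("setpoints at t=0 sum to zero")
        masses = {k: total_mass * w / total for k, w in weights.items()}
        return DielState(0.0, masses, 0.0)

    def simulate(self, hours: float | None = None,
                 state: DielState | None = None) -> SimulationResult:
        hours = hours if hours is not None else self.config.hours
        dt = self.config.dt
        n_steps = int(round(hours / dt))
        if self._possibilities is None:
            self.precompute_production_possibilities()
        state = state or self.initial_state()
        states = [state]
        solutions: List[FluxSolution] = []
        ledgers: List[StepLedger] = []
        status = "completed"
        for step in range(n_steps):
            t = state.t
            self._apply_time_bounds(t)
            total = state.total_mass
            fractions = {k: state.component_masses.get(k, 0.0) / total
                         for k in self.components}
            self.controller.update(fractions, self.setpoints.at(t), dt)
            alive, opened = self.satisfy_ngam(state, t, apply_bounds=False)
            if not alive:
                state = replace(state, status="died")
                states[-1] = state
                status = "died"
                log.info("cell death at t=%.2f h (NGAM unmet)", t)
                break
            producible = self._producible_now(t, opened)
            weights = objective_weights(self.controller.e_prod, producible)
            sol = self.produce_step(weights, state, t, opened)
            if sol.status != "optimal":
                state = replace(state, status="died")
                states[-1] = state
                status = "died"
                break
            state, ledger = advance(state, sol.synthesis, sol.degradation,
                                    self.components, dt, self.config.mass_tol)
            solutions.append(sol)
            ledgers.append(ledger)
            states.append(state)
        return SimulationResult(states, solutions, ledgers,
                                states[0].total_mass
                                if states[0].total_mass else 1.0,
                                status)


def simulate(model, components, curves, environment, setpoints,
             config: Optional[SimulationConfig] = None,
             controller: Optional[ControllerState] = None) -> SimulationResult:
    """One-call wrapper: build a :class:`DielSimulation` and run it."""
    sim = DielSimulation(model, components, curves, environment, setpoints,
                         controller=controller, config=config)
    return sim.simulate()
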