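"""Decoupled biomass: component pseudo-reactions, setpoints, PI control.

The model's single biomass formation equation is split into 10 independent
component pools — carotenoid, chlorophyll a, chlorophyll b, protein, lipid,
lipid droplet, carbohydrate, nucleotide, redox, and starch — so that the
cell can synthesize whichever components are currently feasible instead of
requiring every biomass precursor in fixed ratios at every instant.  Each
component k gets a synthesis pseudo-reaction (its share of the original
biomass metabolites, rescaled so one flux unit produces exactly one gram
of component per gram dry weight per hour) and, where catabolism is
possible, a degradation pseudo-reaction returning the catabolizable
metabolites to the network.  Metabolites nothing downstream can consume
are dumped — mass leaves the cell and is tracked in a ledger.

Production and consumption targets come from a pair of PI controllers per
component tracking a diel mass-fraction setpoint x_sp(t):

    I_k   <- clamp(I_k + (sp_k - x_k) dt, +/- windup)
    e_prod,k = Kp (sp_k - x_k) + Ki I_k
    e_cons,k = Kp (x_k - sp_k) - Ki I_k

Positive production errors become normalized objective weights; positive
consumption errors order the catabolism priority list.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np

from .errors import ConfigError, ValidationError

log = logging.getLogger(__name__)

#: The canonical 10-component decomposition, in fixed tie-break order.
COMPONENTS: Tuple[str, ...] = (
    "carotenoid", "chlorophyll_a", "chlorophyll_b", "protein", "lipid",
    "lipid_droplet", "carbohydrate", "nucleotide", "redox", "starch",
)

#: Components with no catabolic route by default (producible-only).
PRODUCIBLE_ONLY: Tuple[str, ...] = ("redox", "nucleotide")

SYN_PREFIX = "SYN_"
DEG_PREFIX = "DEG_"


@dataclass
class BiomassComponent:
    """One decoupled biomass pool.

    ``stoichiometry`` maps metabolite id -> mmol consumed per gram of
    component (negative = consumed, matching the original biomass signs);
    ``mass_fraction`` is the component's share of one gram dry weight in
    the original equation; ``catabolizable_fraction`` is the mass share of
    its metabolites that a degradation flux can return to the network (the
    remainder is dumped).
    """

    name: str
    stoichiometry: Dict[str, float]
    mass_fraction: float
    synthesis_id: str
    degradation_id: str | None
    catabolizable_fraction: float = 0.0


def split_lipids(lipid_metabolites: Iterable[str],
                 measured_tag_list: Iterable[str]) -> Dict[str, str]:
    """Partition lipid species: measured TAGs -> lipid_droplet, rest -> lipid."""
    tags = list(dict.fromkeys(measured_tag_list))  # dedupe, keep order
    mapping = {}
    for met in dict.fromkeys(lipid_metabolites):
        mapping[met] = "lipid_droplet" if met in tags else "lipid"
    if not any(v == "lipid_droplet" for v in mapping.values()):
        log.warning("no measured TAG species found; lipid_droplet pool empty")
    return mapping


def _find_biomass_reaction(model, biomass_id: str | None):
    if biomass_id is not None:
        return model.reactions.get_by_id(biomass_id)
    objs = [r for r in model.reactions
            if r.objective_coefficient not in (0, 0.0)]
    if len(objs) == 1:
        return objs[0]
    cands = [r for r in model.reactions if "biomass" in r.id.lower()]
    if len(cands) == 1:
        return cands[0]
    raise ValidationError(
        "could not identify a unique biomass reaction; pass biomass_id")


def _metabolite_weight_g_per_mmol(met) -> float:
    w = met.formula_weight
    if w is None or not w:
        raise ValidationError(
            f"metabolite {met.id} has no usable formula weight")
    return float(w) / 1000.0


def split_biomass(model, component_map: Mapping[str, str],
                  biomass_id: str | None = None,
                  producible_only: Sequence[str] = PRODUCIBLE_ONLY,
                  ) -> Tuple[object, Dict[str, BiomassComponent]]:
    """Replace the biomass equation with per-component pseudo-reactions.

    Every biomass metabolite must be assigned to exactly one component by
    ``component_map``; unassigned metabolites raise with their names.  The
    original biomass reaction is disabled (bounds 0) but kept for
    reference.  Summing component synthesis stoichiometries times their
    mass fractions reproduces the original biomass demands exactly.

    Returns the modified model copy and the component table.
    """
    from cobra import Reaction

    model = model.copy()
    biomass = _find_biomass_reaction(model, biomass_id)
    unknown = [m for m in component_map
               if m not in {met.id for met in biomass.metabolites}]
    if unknown:
        raise ValidationError(
            f"component_map names metabolites absent from the biomass "
            f"equation: {sorted(unknown)}")
    missing = [met.id for met in biomass.metabolites
               if met.id not in component_map]
    if missing:
        raise ValidationError(
            f"biomass metabolites not assigned to any component: "
            f"{sorted(missing)}")
    bad = sorted(set(component_map.values()) - set(COMPONENTS))
    if bad:
        raise ConfigError(f"unknown component names: {bad}")

    # group biomass coefficients by component
    groups: Dict[str, Dict[str, float]] = {name: {} for name in COMPONENTS}
    for met, coeff in biomass.metabolites.items():
        groups[component_map[met.id]][met.id] = float(coeff)

    # pseudo-reaction ids count as internal plumbing when deciding whether
    # a returned metabolite has a genuine consumer
    pseudo_ids = {biomass.id}
    consumers: Dict[str, int] = {}
    for rxn in model.reactions:
        for met, coeff in rxn.metabolites.items():
            consumes = (coeff < 0 and rxn.upper_bound > 0) or \
                       (coeff > 0 and rxn.lower_bound < 0)
            if consumes and rxn.id not in pseudo_ids and not rxn.boundary:
                consumers[met.id] = consumers.get(met.id, 0) + 1

    components: Dict[str, BiomassComponent] = {}
    new_reactions = []
    for name in COMPONENTS:
        stoich = groups[name]
        if not stoich:
            log.warning("component %s has no assigned metabolites", name)
        mass = sum(abs(c) * _metabolite_weight_g_per_mmol(
            model.metabolites.get_by_id(m)) for m, c in stoich.items()
            if c < 0)
        if stoich and mass <= 0:
            raise ValidationError(f"component {name} has zero mass")
        scale = 1.0 / mass if mass > 0 else 0.0
        per_g = {m: c * scale for m, c in stoich.items()}

        syn = Reaction(SYN_PREFIX + name)
        syn.name = f"{name} synthesis (1 g per flux unit)"
        syn.lower_bound, syn.upper_bound = 0.0, 1000.0
        syn.add_metabolites({model.metabolites.get_by_id(m): c
                             for m, c in per_g.items()})
        new_reactions.append(syn)

        deg_id, catab_frac = None, 0.0
        if stoich and name not in producible_only:
            returnable = {m: -c for m, c in per_g.items()
                          if c < 0 and consumers.get(m, 0) > 0}
            catab_mass = sum(c * _metabolite_weight_g_per_mmol(
                model.metabolites.get_by_id(m))
                for m, c in returnable.items())
            catab_frac = min(catab_mass, 1.0)  # per-g stoich: already a mass share
            deg = Reaction(DEG_PREFIX + name)
            deg.name = f"{name} degradation (1 g per flux unit)"
            deg.lower_bound, deg.upper_bound = 0.0, 0.0  # opened by simulator
            if returnable:
                deg.add_metabolites({model.metabolites.get_by_id(m): c
                                     for m, c in returnable.items()})
            new_reactions.append(deg)
            deg_id = deg.id
        elif stoich:
            log.info("component %s is producible-only (no degradation)", name)

        components[name] = BiomassComponent(
            name=name, stoichiometry=per_g, mass_fraction=mass,
            synthesis_id=syn.id, degradation_id=deg_id,
            catabolizable_fraction=catab_frac)

    model.add_reactions(new_reactions)
    biomass.lower_bound = biomass.upper_bound = 0.0
    total = sum(c.mass_fraction for c in components.values())
    if not math.isclose(total, 1.0, rel_tol=0.05):
        log.warning("biomass equation is not mass-consistent "
                    "(components sum to %.3f g/gDW)", total)
    return model, components


# ---------------------------------------------------------------------------
# setpoints
# ---------------------------------------------------------------------------


class SetpointTable:
    """Diel mass-fraction setpoints, piecewise-linear and 24-periodic."""

    def __init__(self, times: Sequence[float],
                 fractions: Mapping[str, Sequence[float]]):
        self.times = np.asarray(times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ConfigError("setpoint times must be strictly increasing")
        self.fractions = {k: np.asarray(v, dtype=float)
                          for k, v in fractions.items()}
        for k, v in self.fractions.items():
            if len(v) != len(self.times):
                raise ConfigError(f"setpoint column {k} length mismatch")
            if np.any(v < 0):
                raise ConfigError(f"setpoint column {k} has negative entries")
        sums = np.sum(list(self.fractions.values()), axis=0)
        if np.any(sums > 1.0 + 1e-9):
            raise ConfigError("setpoint fractions exceed 1 at some time")

    def at(self, t: float) -> Dict[str, float]:
        tt = float(t) % 24.0
        # periodic linear interpolation
        times = np.concatenate([self.times, [self.times[0] + 24.0]])
        out = {}
        for k, v in self.fractions.items():
            vals = np.concatenate([v, [v[0]]])
            out[k] = float(np.interp(tt, times, vals))
        return out

    @classmethod
    def from_frame(cls, df) -> "SetpointTable":
        cols = [c for c in df.columns if c != "time_h"]
        return cls(df["time_h"].to_numpy(), {c: df[c].to_numpy() for c in cols})

    @classmethod
    def read_tsv(cls, path) -> "SetpointTable":
        import pandas as pd
        return cls.from_frame(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# PI controllers
# ---------------------------------------------------------------------------


@dataclass
class ControllerState:
    """Dual PI control per component: production and consumption errors.

    Gains default to Kp = 1.0 /h-scaled proportional response and
    Ki = 0.1 /h^2 integral response with anti-windup at +/- 10x the mean
    setpoint; all three are configuration, since cellular regulation is
    abstracted rather than measured.
    """

    components: Tuple[str, ...] = COMPONENTS
    kp: float = 1.0
    ki: float = 0.1
    windup: Dict[str, float] = field(default_factory=dict)
    integral: Dict[str, float] = field(default_factory=dict)
    e_prod: Dict[str, float] = field(default_factory=dict)
    e_cons: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for k in self.components:
            self.integral.setdefault(k, 0.0)
            self.e_prod.setdefault(k, 0.0)
            self.e_cons.setdefault(k, 0.0)

    def update(self, actual_fractions: Mapping[str, float],
               setpoints: Mapping[str, float], dt: float) -> None:
        if dt <= 0:
            raise ValidationError("dt must be positive")
        for k in self.components:
            sp = setpoints.get(k, 0.0)
            x = actual_fractions.get(k, 0.0)
            err = sp - x
            lim = self.windup.get(k, 10.0 * max(sp, 1e-3))
            self.integral[k] = float(np.clip(self.integral[k] + err * dt,
                                             -lim, lim))
            self.e_prod[k] = self.kp * err + self.ki * self.integral[k]
            self.e_cons[k] = -self.kp * err - self.ki * self.integral[k]


def update_controllers(state: ControllerState,
                       actual_fractions: Mapping[str, float],
                       setpoints: Mapping[str, float], dt: float) -> ControllerState:
    """Functional wrapper over :meth:`ControllerState.update`."""
    state.update(actual_fractions, setpoints, dt)
    return state


def objective_weights(e_prod: Mapping[str, float],
                      producible: Iterable[str]) -> Dict[str, float]:
    """Normalized production weights over the currently producible set.

    Weights are proportional to the positive part of the production error;
    if no producible component has positive error the weights fall back to
    uniform over the producible set (growth never stalls merely because
    every pool is at setpoint).
    """
    prod = [k for k in producible]
    if not prod:
        return {}
    pos = {k: max(e_prod.get(k, 0.0), 0.0) for k in prod}
    total = sum(pos.values())
    if total <= 0:
        return {k: 1.0 / len(prod) for k in prod}
    return {k: v / total for k, v in pos.items()}


def consumption_priority(e_cons: Mapping[str, float],
                         emergency: bool = False,
                         components: Sequence[str] = COMPONENTS,
                         ) -> List[str]:
    """Catabolism order: positive consumption errors, largest first.

    Ties break by starch-first, then the fixed component order.  In an
    emergency (maintenance ATP still unmet), components with nonpositive
    error are appended in the same descending-error order.
    """
    def key(name):
        return (-e_cons.get(name, 0.0),
                0 if name == "starch" else 1,
                components.index(name))

    positive = sorted((k for k in components if e_cons.get(k, 0.0) > 0), key=key)
    if not emergency:
        return positive
    rest = sorted((k for k in components if e_cons.get(k, 0.0) <= 0), key=key)
    return positive + rest
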