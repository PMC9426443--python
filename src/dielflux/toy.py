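"""Synthetic toy photoautotroph: model, transcriptome, setpoints, scenarios.

A miniature constraint-based model of a green alga growing on light + CO2
(optionally acetate): photon capture charges ATP/NADPH, a carbon-fixation
lump converts CO2 into a generic sugar unit, and ten biomass macromolecule
pools (carotenoid, chlorophylls a/b, protein, lipid, lipid droplet,
carbohydrate, nucleotide, redox cofactor, starch) are synthesized through
GPR-governed routes over a ~30-gene synthetic genome.  Starch is the only
respirable store with night-peaking catabolic genes, so a cell that cannot
build starch by day starves in the dark — the starchless-mutant phenotype
the scenarios probe.  Every reaction balances carbon and nitrogen by
construction; the ATP/ADP and NADPH/NADP pairs share formulas so the
energy cycle is element-neutral, and the photon carries no mass.

All quantitative choices (pool mass fractions, ATP yields, gene expression
phases) are plausible round numbers, not measurements: the fixture is a
test harness, not a biological claim.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np

from .biomass import BiomassComponent, SetpointTable, split_biomass
from .curves import CurveFitEnsemble, ensemble_from_params
from .errors import ConfigError
from .gpr import CurveSet
from .simulator import Environment, SimulationConfig

#: Gene whose knockout removes starch synthesis (the sta6-like lesion).
STA6_LIKE_GENE = "gSTA6"

#: Target mass fractions (g/gDW) of the toy biomass equation.
BIOMASS_FRACTIONS: Dict[str, float] = {
    "protein": 0.45, "carbohydrate": 0.12, "starch": 0.20, "lipid": 0.10,
    "lipid_droplet": 0.04, "chlorophyll_a": 0.03, "chlorophyll_b": 0.015,
    "carotenoid": 0.01, "nucleotide": 0.03, "redox": 0.005,
}

#: macromolecule metabolite per component and its elemental formula
_MACROS: Dict[str, Tuple[str, str]] = {
    "carotenoid": ("caro_m", "C40"),
    "chlorophyll_a": ("chla_m", "C55N4"),
    "chlorophyll_b": ("chlb_m", "C55N4"),
    "protein": ("prot_m", "C5N"),
    "lipid": ("lip_m", "C50N"),
    "lipid_droplet": ("tag_m", "C55"),
    "carbohydrate": ("carb_m", "C6"),
    "nucleotide": ("nuc_m", "C10N5"),
    "redox": ("redox_m", "C27N9"),
    "starch": ("starch_m", "C6"),
}


@dataclass
class ToyModelSpec:
    include_acetate: bool = True
    seed: int = 7
    light_availability: float = 30.0
    ngam: float = 2.5
    nh4_uptake: float = 5.0
    acetate_uptake: float = 2.0


@dataclass
class ScenarioBundle:
    name: str
    model: object  # decoupled cobra model
    components: Dict[str, BiomassComponent]
    curves: CurveSet
    environment: Environment
    setpoints: SetpointTable
    config: SimulationConfig
    knocked_genes: Tuple[str, ...] = ()


def _toy_transcriptome() -> Dict[str, CurveFitEnsemble]:
    """Known diel curves for the synthetic genome (no fitting involved).

    Light harvesting and carbon fixation peak midday; starch synthesis
    peaks late-day; starch catabolism peaks at night; respiratory and
    housekeeping genes are constant.
    """
    cos = "one_term_cosine"
    const = "constant"
    specs = {
        "gLHC1": (cos, (100, 80, 6)), "gLHC2": (cos, (100, 80, 6)),
        "gFNR1": (const, (100,)),
        "gRBC1": (cos, (120, 90, 5)), "gRBC2": (cos, (100, 70, 6)),
        "gRBC3": (cos, (80, 60, 5.5)),
        "gMDH1": (const, (150,)), "gCOX1": (const, (150,)),
        "gACK1": (const, (100,)), "gICL1": (const, (120,)),
        "gSTA6": (cos, (100, 80, 8)), "gSTA1": (cos, (110, 80, 8)),
        "gAMY1": (cos, (100, 80, 18)), "gPHO1": (cos, (90, 70, 19)),
        "gCARB1": (cos, (100, 60, 7)),
        "gAA1": (cos, (120, 70, 6)), "gRIB1": (cos, (120, 70, 7)),
        "gFAS1": (cos, (100, 60, 8)), "gFAS2": (cos, (100, 60, 8)),
        "gDGAT1": (cos, (80, 50, 10)), "gPDAT1": (cos, (70, 40, 12)),
        "gCRT1": (cos, (90, 50, 6)),
        "gCHL1": (cos, (100, 60, 5)), "gCHLA1": (cos, (100, 60, 5)),
        "gCHLB1": (cos, (90, 50, 5)),
        "gNUC1": (const, (100,)), "gFAD1": (cos, (100, 50, 6)),
        "gPPP1": (const, (100,)),
    }
    return {g: ensemble_from_params(g, fam, params)
            for g, (fam, params) in specs.items()}


def _build_raw_model(spec: ToyModelSpec):
    from cobra import Metabolite, Model, Reaction

    model = Model("toy_photoautotroph")
    mets = {}

    def met(mid, formula):
        m = Metabolite(mid, formula=formula, compartment="c")
        mets[mid] = m
        return m

    met("photon", "")
    met("co2", "C")
    met("ac", "C2")
    met("nh4", "N")
    met("atp", "C10N5")
    met("adp", "C10N5")
    met("nadph", "C21N7")
    met("nadp", "C21N7")
    met("ch2o", "C")
    for name, (mid, formula) in _MACROS.items():
        met(mid, formula)

    reactions = []

    def rxn(rid, stoich, gpr="", lb=0.0, ub=1000.0, name=""):
        r = Reaction(rid, name=name or rid, lower_bound=lb, upper_bound=ub)
        r.add_metabolites({mets[m]: c for m, c in stoich.items()})
        if gpr:
            r.gene_reaction_rule = gpr
        reactions.append(r)
        return r

    # exchanges (uptake bounds set by the environment at run time)
    for mid in ("photon", "co2", "ac", "nh4"):
        rxn(f"EX_{mid}", {mid: -1}, lb=0.0, ub=1000.0)

    # photosynthetic energy capture (plastid) and electron rebalancing
    rxn("PHOT", {"photon": -1, "adp": -1, "nadp": -1, "atp": 1, "nadph": 1},
        gpr="gLHC1 and gLHC2", name="light capture")
    rxn("FNR", {"nadph": -1, "adp": -1, "nadp": 1, "atp": 1}, gpr="gFNR1")
    # oxidative pentose-phosphate lump: dark NADPH from sugar units
    rxn("OPP", {"ch2o": -1, "nadp": -2, "co2": 1, "nadph": 2}, gpr="gPPP1")
    # carbon fixation lump
    rxn("CBB", {"co2": -1, "atp": -3, "nadph": -2,
                "ch2o": 1, "adp": 3, "nadp": 2},
        gpr="gRBC1 and (gRBC2 or gRBC3)", name="carbon fixation")
    # mitochondrial respiration of sugar units
    rxn("RESP", {"ch2o": -1, "adp": -5, "co2": 1, "atp": 5},
        gpr="gMDH1 and gCOX1", name="respiration")
    # acetate assimilation and respiration
    rxn("ACUP", {"ac": -1, "atp": -1, "ch2o": 2, "adp": 1}, gpr="gACK1")
    rxn("ACRESP", {"ac": -1, "adp": -10, "co2": 2, "atp": 10},
        gpr="gICL1 and gCOX1")
    # starch: the respirable day store
    rxn("STARCH_SYN", {"ch2o": -6, "atp": -1, "starch_m": 1, "adp": 1},
        gpr=f"{STA6_LIKE_GENE} and gSTA1")
    rxn("STARCH_CAT", {"starch_m": -1, "adp": -25, "co2": 6, "atp": 25},
        gpr="gAMY1 or gPHO1")
    rxn("STARCH_MOB", {"starch_m": -1, "ch2o": 6}, gpr="gAMY1 or gPHO1",
        name="starch remobilization")
    # structural carbohydrate (not respirable)
    rxn("CARB_SYN", {"ch2o": -6, "atp": -1, "carb_m": 1, "adp": 1},
        gpr="gCARB1")
    # protein, lipids, pigments, nucleotides, redox cofactor
    rxn("PROT_SYN", {"ch2o": -5, "nh4": -1, "atp": -2, "prot_m": 1, "adp": 2},
        gpr="gAA1 and gRIB1")
    rxn("LIP_SYN", {"ch2o": -50, "nh4": -1, "atp": -10, "nadph": -10,
                    "lip_m": 1, "adp": 10, "nadp": 10},
        gpr="gFAS1 and gFAS2")
    rxn("TAG_SYN", {"ch2o": -55, "atp": -12, "nadph": -12,
                    "tag_m": 1, "adp": 12, "nadp": 12},
        gpr="gDGAT1 or gPDAT1")
    rxn("CARO_SYN", {"ch2o": -40, "atp": -8, "nadph": -8,
                     "caro_m": 1, "adp": 8, "nadp": 8}, gpr="gCRT1")
    rxn("CHLA_SYN", {"ch2o": -55, "nh4": -4, "atp": -10, "nadph": -5,
                     "chla_m": 1, "adp": 10, "nadp": 5},
        gpr="gCHL1 and gCHLA1")
    rxn("CHLB_SYN", {"ch2o": -55, "nh4": -4, "atp": -10, "nadph": -5,
                     "chlb_m": 1, "adp": 10, "nadp": 5},
        gpr="gCHL1 and gCHLB1")
    rxn("NUC_SYN", {"ch2o": -10, "nh4": -5, "atp": -4, "nuc_m": 1, "adp": 4},
        gpr="gNUC1")
    rxn("REDOX_SYN", {"ch2o": -27, "nh4": -9, "atp": -10,
                      "redox_m": 1, "adp": 10}, gpr="gFAD1")
    # maintenance ATP demand (lower bound set by the environment)
    rxn("ATPM", {"atp": -1, "adp": 1}, name="non-growth maintenance ATP")

    # single biomass equation; coefficients chosen mass-consistently
    biomass = Reaction("BIOMASS", name="biomass formation")
    stoich = {}
    for comp, frac in BIOMASS_FRACTIONS.items():
        mid, _ = _MACROS[comp]
        coeff = frac * 1000.0 / mets[mid].formula_weight
        stoich[mets[mid]] = -coeff
    biomass.add_metabolites(stoich)
    biomass.lower_bound, biomass.upper_bound = 0.0, 1000.0
    reactions.append(biomass)

    model.add_reactions(reactions)
    model.objective = "BIOMASS"
    return model


def component_map() -> Dict[str, str]:
    """Biomass metabolite id -> component name."""
    return {mid: comp for comp, (mid, _) in _MACROS.items()}


def default_setpoints() -> SetpointTable:
    """Plausible diel composition: starch builds by day, burns at night."""
    times = [0.0, 6.0, 12.0, 18.0]
    return SetpointTable(times, {
        "starch": [0.12, 0.22, 0.28, 0.18],
        "carbohydrate": [0.12, 0.11, 0.10, 0.11],
        "protein": [0.45, 0.43, 0.39, 0.44],
        "lipid": [0.10, 0.10, 0.10, 0.10],
        "lipid_droplet": [0.04, 0.04, 0.04, 0.04],
        "chlorophyll_a": [0.03, 0.03, 0.03, 0.03],
        "chlorophyll_b": [0.015, 0.015, 0.015, 0.015],
        "carotenoid": [0.01, 0.01, 0.01, 0.01],
        "nucleotide": [0.03, 0.03, 0.03, 0.03],
        "redox": [0.005, 0.005, 0.005, 0.005],
    })


def build_toy_model(spec: ToyModelSpec | None = None):
    """Raw toy model + transcriptome + setpoints + biomass component map.

    Returns ``(model, curves, setpoints, component_map)`` where the model
    still carries its single biomass equation (decouple it with
    :func:`dielflux.biomass.split_biomass`).
    """
    spec = spec or ToyModelSpec()
    model = _build_raw_model(spec)
    curves = CurveSet(_toy_transcriptome())
    return model, curves, default_setpoints(), component_map()


def default_environment(spec: ToyModelSpec | None = None,
                        acetate: bool = False) -> Environment:
    spec = spec or ToyModelSpec()
    medium = {"EX_co2": 1000.0, "EX_nh4": spec.nh4_uptake}
    if acetate:
        medium["EX_ac"] = spec.acetate_uptake
    return Environment(light_availability=spec.light_availability,
                       medium=medium, ngam=spec.ngam,
                       photon_exchange="EX_photon", light_reaction="PHOT",
                       ngam_reaction="ATPM")


_SCENARIOS = ("wt_minimal", "wt_acetate", "sta6_minimal", "sta6_acetate",
              "n_limited_series")


def scenario(name: str, spec: ToyModelSpec | None = None,
             hours: float = 48.0, dt: float = 0.1):
    """Reproducible input bundle(s) for a named diel growth scenario.

    ``wt``/``sta6`` x ``minimal`` (CO2-only) / ``acetate`` under 12:12
    light; ``n_limited_series`` returns a list of bundles with
    monotonically decreasing nitrogen uptake.
    """
    if name not in _SCENARIOS:
        raise ConfigError(f"unknown scenario '{name}' (choose from {_SCENARIOS})")
    spec = spec or ToyModelSpec()
    raw, curves, setpoints, cmap = build_toy_model(spec)
    model, components = split_biomass(raw, cmap, biomass_id="BIOMASS")
    config = SimulationConfig(hours=hours, dt=dt, seed=spec.seed)

    def bundle(nm, acetate, knocked, env=None):
        cs = curves.knockout(knocked) if knocked else curves
        return ScenarioBundle(nm, model.copy(), components, cs,
                              env or default_environment(spec, acetate),
                              setpoints, config, tuple(knocked))

    if name == "n_limited_series":
        out = []
        for n_up in (5.0, 1.0, 0.2, 0.05):
            env = default_environment(spec, acetate=False)
            env.medium["EX_nh4"] = n_up
            out.append(bundle(f"n_limited_{n_up:g}", False, (), env))
        return out
    knocked = (STA6_LIKE_GENE,) if name.startswith("sta6") else ()
    return bundle(name, name.endswith("acetate"), knocked)


def run_scenario(bundle: ScenarioBundle, hours: float | None = None):
    """Simulate one scenario bundle end to end."""
    from .biomass import ControllerState
    from .simulator import DielSimulation
    sim = DielSimulation(bundle.model, bundle.components, bundle.curves,
                         bundle.environment, bundle.setpoints,
                         controller=ControllerState(), config=bundle.config)
    return sim.simulate(hours=hours)


def calibrate_light_for_doubling(target: float = 2.0, hours: float = 24.0,
                                 lo: float = 2.0, hi: float = 80.0,
                                 max_iter: int = 18, rel_tol: float = 0.005,
                                 spec: ToyModelSpec | None = None,
                                 dt: float = 0.1):
    """Bisect light availability until the wild type hits a target
    normalized mass over ``hours`` on minimal medium.

    Growth responds monotonically to light supply on this fixture, so a
    plain bisection suffices.  Returns ``(light_availability, result)``
    with ``result`` the run at the calibrated value.
    """
    from dataclasses import replace as _replace

    base = spec or ToyModelSpec()

    def run(light):
        b = scenario("wt_minimal",
                     spec=_replace(base, light_availability=light),
                     hours=hours, dt=dt)
        return run_scenario(b)

    res_lo, res_hi = run(lo), run(hi)
    if res_lo.final_normalized_mass > target or \
            res_hi.final_normalized_mass < target:
        raise ConfigError(
            f"target {target} outside bracket "
            f"[{res_lo.final_normalized_mass:.3f}, "
            f"{res_hi.final_normalized_mass:.3f}]")
    best = None
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        res = run(mid)
        best = (mid, res)
        err = res.final_normalized_mass - target
        if abs(err) <= rel_tol * target:
            break
        if err > 0:
            hi = mid
        else:
            lo = mid
    return best


def save_fixture(directory, spec: ToyModelSpec | None = None):
    """Emit the fixture as COBRA-JSON + TSVs (doubles as a format test)."""
    import json
    import os
    from cobra.io import save_json_model
    import pandas as pd

    os.makedirs(directory, exist_ok=True)
    model, curves, setpoints, cmap = build_toy_model(spec)
    save_json_model(model, os.path.join(directory, "toy_model.json"))
    rows = [(comp, mid) for mid, comp in cmap.items()]
    pd.DataFrame(rows, columns=["component", "metabolite"]).to_csv(
        os.path.join(directory, "component_map.tsv"), sep="\t", index=False)
    sp = pd.DataFrame({"time_h": setpoints.times,
                       **{k: v for k, v in setpoints.fractions.items()}})
    sp.to_csv(os.path.join(directory, "setpoints.tsv"), sep="\t", index=False)
    grid = np.arange(0.0, 24.0, 2.0)
    rows = [(g, t, float(curves._curves[g].query(t)))
            for g in sorted(curves.genes()) for t in grid]
    pd.DataFrame(rows, columns=["gene_id", "time_h", "fpkm"]).to_csv(
        os.path.join(directory, "transcriptome.tsv"), sep="\t", index=False)
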