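"""Genome-wide single-knockout phenotype scan under a fixed diel scenario.

Each knockout zeroes one gene's transcript curve everywhere, so every GPR
containing the gene degrades by the AND=min / OR=sum semantics, and the
full diel simulation is re-run.  Results are compared against a wild-type
baseline simulated under identical conditions: underperformers show a
growth defect of 25% or more (normalized-mass ratio <= 0.75), while
overperformers gain 10% or more biomass (ratio >= 1.10); both thresholds
are configurable and boundary-inclusive.

Per-gene runs are a pure function of (model, curves, scenario), so the
scan parallelizes as a plain map and is independent of worker count and
gene order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

from .biomass import ControllerState, SetpointTable
from .gpr import CurveSet
from .simulator import (DielSimulation, Environment, SimulationConfig,
                        SimulationResult)

log = logging.getLogger(__name__)

UNDERPERFORM_THRESHOLD = 0.75  # growth defect of 25% or more
OVERPERFORM_THRESHOLD = 1.10   # biomass increase of 10% or more


@dataclass
class KnockoutResult:
    gene_id: str
    status: str  # grew | impaired | died | error
    normalized_mass: float
    component_fractions: Dict[str, float]
    relative_to_wt: float


def _run_scenario(model, components, curves: CurveSet, environment: Environment,
                  setpoints: SetpointTable, config: SimulationConfig,
                  ) -> SimulationResult:
    sim = DielSimulation(model, components, curves, environment, setpoints,
                         controller=ControllerState(), config=config)
    return sim.simulate()


def _result_from_run(gene: str, run: SimulationResult,
                     wt_mass: float) -> KnockoutResult:
    final = run.final_state
    total = final.total_mass or 1.0
    fractions = {k: v / total for k, v in final.component_masses.items()}
    ratio = run.final_normalized_mass / wt_mass
    if run.status == "died":
        status = "died"
    elif ratio <= UNDERPERFORM_THRESHOLD:
        status = "impaired"
    else:
        status = "grew"
    return KnockoutResult(gene, status, run.final_normalized_mass,
                          fractions, ratio)


def scan_knockouts(model, components, curves: CurveSet,
                   environment: Environment, setpoints: SetpointTable,
                   config: Optional[SimulationConfig] = None,
                   gene_list: Optional[Sequence[str]] = None,
                   workers: int = 1) -> List[KnockoutResult]:
    """Simulate the wild type, then every single-gene knockout.

    ``gene_list`` defaults to every gene in the curve set that appears in
    at least one model GPR (others are phenotype-neutral by construction).
    Per-gene failures are recorded as ``error`` entries and never abort
    the scan.  The wild type is included as gene id ``WT`` with relative
    mass exactly 1.
    """
    config = config or SimulationConfig()
    model_genes = {g.id for g in model.genes}
    if gene_list is None:
        gene_list = sorted(set(curves.genes()) & model_genes)
    wt_run = _run_scenario(model, components, curves, environment,
                           setpoints, config)
    wt_mass = wt_run.final_normalized_mass
    results = [_result_from_run("WT", wt_run, wt_mass)]
    results[0].relative_to_wt = 1.0

    def one(gene: str) -> KnockoutResult:
        try:
            ko = curves.knockout([gene])
            run = _run_scenario(model, components, ko, environment,
                                setpoints, config)
            return _result_from_run(gene, run, wt_mass)
        except Exception as exc:  # recorded, never aborts the scan
            log.warning("knockout %s failed: %s", gene, exc)
            return KnockoutResult(gene, "error", float("nan"), {}, float("nan"))

    if workers > 1:
        from joblib import Parallel, delayed
        results += Parallel(n_jobs=workers)(delayed(one)(g) for g in gene_list)
    else:
        results += [one(g) for g in gene_list]
    return results


@dataclass
class RankedTables:
    underperformers: List[KnockoutResult]
    overperformers: List[KnockoutResult]
    all_results: List[KnockoutResult]


def classify_and_rank(results: Sequence[KnockoutResult],
                      underperform_threshold: float = UNDERPERFORM_THRESHOLD,
                      overperform_threshold: float = OVERPERFORM_THRESHOLD,
                      ) -> RankedTables:
    """Split knockouts into under-/overperformers (inclusive thresholds)."""
    scored = [r for r in results if r.gene_id != "WT"]
    under = sorted((r for r in scored
                    if r.status == "died" or r.relative_to_wt <= underperform_threshold),
                   key=lambda r: (r.relative_to_wt if r.relative_to_wt ==
                                  r.relative_to_wt else -1.0))
    over = sorted((r for r in scored if r.relative_to_wt >= overperform_threshold),
                  key=lambda r: -r.relative_to_wt)
    return RankedTables(under, over, list(results))


def results_to_frame(results: Sequence[KnockoutResult]):
    import pandas as pd
    rows = []
    for r in results:
        row = {"gene": r.gene_id, "status": r.status,
               "normalized_mass": r.normalized_mass,
               "relative_to_wt": r.relative_to_wt}
        row.update({f"frac_{k}": v for k, v in r.component_fractions.items()})
        rows.append(row)
    return pd.DataFrame(rows)
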