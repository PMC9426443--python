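"""Gene-protein-reaction rules and transcript-derived flux bounds.

A GPR rule is a Boolean AND/OR tree over gene identifiers: AND encodes a
multimeric enzyme (every subunit required), OR encodes isozymes (any one
suffices).  Transcript curves translate into a dimensionless flux fraction
per gene,

    v_a(t) = a(t) / max{a(t) : t in [0, 24)}

and rules combine fractions recursively: AND takes the minimum of its
children, OR their sum (isozyme capacities add; the sum may exceed one and
is only capped at the bound stage).  A reaction's diel upper bound is then

    u_A(t) = u_max * min(1, v_rule(t))

with the lower bound at -u_A(t) for reversible reactions and 0 otherwise.
The global flux ceiling u_max is calibrated so that the transcript-bounded
light-uptake reaction peaks exactly at the environment's light
availability.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple, Union

import numpy as np

from .curves import CurveFitEnsemble, PERIOD
from .errors import CalibrationError, GPRParseError, ValidationError

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# rule AST
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneLeaf:
    gene: str


@dataclass(frozen=True)
class AndNode:
    children: Tuple["Node", ...]


@dataclass(frozen=True)
class OrNode:
    children: Tuple["Node", ...]


Node = Union[GeneLeaf, AndNode, OrNode]


@dataclass(frozen=True)
class GPRRule:
    """Parsed Boolean rule for one reaction; ``root is None`` = unmapped."""

    root: Node | None
    reaction_id: str = ""

    def genes(self) -> Set[str]:
        out: Set[str] = set()

        def walk(node):
            if isinstance(node, GeneLeaf):
                out.add(node.gene)
            elif node is not None:
                for ch in node.children:
                    walk(ch)

        walk(self.root)
        return out

    def to_string(self) -> str:
        """Canonical text: OR joined by ' or ', AND by ' and ', OR children
        of an AND parenthesized (AND binds tighter than OR)."""

        def render(node, parent_is_and=False):
            if isinstance(node, GeneLeaf):
                return node.gene
            if isinstance(node, AndNode):
                return " and ".join(render(c, True) for c in node.children)
            text = " or ".join(render(c, False) for c in node.children)
            return f"({text})" if parent_is_and else text

        return "" if self.root is None else render(self.root)


_TOKEN_RE = re.compile(r"\s*(\(|\)|[A-Za-z0-9_.\-]+)")


def _tokenize(text: str) -> List[Tuple[str, int]]:
    tokens, pos = [], 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            if text[pos:].strip():
                raise GPRParseError(
                    f"unexpected character {text[pos]!r}", pos)
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


def parse_gpr(rule_string: str, reaction_id: str = "") -> GPRRule:
    """Parse ``a and (b or c)``-style text with AND binding tighter than OR.

    The empty string denotes an unmapped reaction.  Unbalanced parentheses
    raise :class:`GPRParseError` with the character position.
    """
    tokens = _tokenize(rule_string or "")
    if not tokens:
        return GPRRule(None, reaction_id)
    idx = 0

    def peek():
        return tokens[idx][0].lower() if idx < len(tokens) else None

    def expr() -> Node:
        nonlocal idx
        terms = [term()]
        while peek() == "or":
            idx += 1
            terms.append(term())
        return terms[0] if len(terms) == 1 else OrNode(tuple(terms))

    def term() -> Node:
        nonlocal idx
        factors = [factor()]
        while peek() == "and":
            idx += 1
            factors.append(factor())
        return factors[0] if len(factors) == 1 else AndNode(tuple(factors))

    def factor() -> Node:
        nonlocal idx
        if idx >= len(tokens):
            pos = tokens[-1][1] + len(tokens[-1][0])
            raise GPRParseError("unexpected end of rule", pos)
        tok, pos = tokens[idx]
        if tok == "(":
            idx += 1
            node = expr()
            if peek() != ")":
                raise GPRParseError("unbalanced parenthesis", pos)
            idx += 1
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GPRParseError(f"unexpected token {tok!r}", pos)
        idx += 1
        return GeneLeaf(tok)

    root = expr()
    if idx < len(tokens):
        raise GPRParseError(f"unexpected token {tokens[idx][0]!r}", tokens[idx][1])
    return GPRRule(root, reaction_id)


# ---------------------------------------------------------------------------
# curve sets (with knockouts) and fractions
# ---------------------------------------------------------------------------


class CurveSet:
    """Gene -> fitted-curve lookup with optional knocked-out genes.

    Knocked genes return an expression of exactly zero at every time, so
    every rule containing them degrades per the AND/OR semantics.  Genes in
    GPRs that are absent from the transcriptome are treated as
    unconstrained (fraction 1) with a logged warning — penalizing
    unmeasured genes would fabricate constraints.
    """

    def __init__(self, ensembles: Union[Mapping[str, CurveFitEnsemble],
                                        Iterable[CurveFitEnsemble]],
                 knocked: Iterable[str] = ()):
        if isinstance(ensembles, Mapping):
            self._curves = dict(ensembles)
        else:
            self._curves = {e.gene_id: e for e in ensembles}
        self.knocked = frozenset(knocked)
        self._warned: Set[str] = set()

    def __contains__(self, gene):
        return gene in self._curves

    def genes(self):
        return self._curves.keys()

    def knockout(self, gene_ids: Iterable[str]) -> "CurveSet":
        ids = set(gene_ids)
        unknown = sorted(ids - set(self._curves))
        if unknown:
            raise ValidationError(f"unknown genes for knockout: {unknown}")
        return CurveSet(self._curves, self.knocked | ids)

    def fraction(self, gene: str, t: float) -> float:
        """Single-gene normalized fraction v_a(t) in [0, 1]."""
        if gene in self.knocked:
            return 0.0
        ens = self._curves.get(gene)
        if ens is None:
            if gene not in self._warned:
                log.warning("gene %s absent from transcriptome; unconstrained",
                            gene)
                self._warned.add(gene)
            return 1.0
        peak = ens.diel_max()
        if peak <= 0:
            if gene not in self._warned:
                log.warning("gene %s: all-zero curve; fraction 0", gene)
                self._warned.add(gene)
            return 0.0
        return float(ens.query(t)) / peak


def normalized_fraction(ensemble: CurveFitEnsemble, t: float) -> float:
    """v_a(t) = a(t) / max_t a(t); 0 (flagged) for an all-zero curve."""
    peak = ensemble.diel_max()
    if peak <= 0:
        log.warning("gene %s: all-zero curve; fraction 0", ensemble.gene_id)
        return 0.0
    return float(ensemble.query(t)) / peak


def rule_fraction(rule: GPRRule, curves: CurveSet, t: float) -> float:
    """Recursive AND=min / OR=sum evaluation of the rule at time t.

    OR sums are deliberately not capped inside the tree; capping happens
    once at the bound stage.
    """
    if rule.root is None:
        raise ValidationError(
            f"reaction {rule.reaction_id or '<anonymous>'} has no GPR")

    def ev(node) -> float:
        if isinstance(node, GeneLeaf):
            return curves.fraction(node.gene, t)
        if isinstance(node, AndNode):
            return min(ev(c) for c in node.children)
        return sum(ev(c) for c in node.children)

    return ev(rule.root)


def bound_at(fraction: float, u_max: float, reversible: bool) -> Tuple[float, float]:
    """(lower, upper) bounds: upper = u_max*min(1, v); lower mirrors if
    reversible, else 0."""
    if u_max <= 0:
        raise ValidationError("u_max must be positive")
    upper = u_max * min(1.0, max(fraction, 0.0))
    return (-upper if reversible else 0.0, upper)


def calibrate_umax(light_rule: GPRRule, curves: CurveSet,
                   light_availability: float, grid_step: float = 0.05) -> float:
    """Flux ceiling such that the transcript-bounded light uptake peaks at
    the environment's light availability.

    With the Eq-style cap, max_t u_max*min(1, v_light(t)) equals
    ``light_availability`` exactly.
    """
    if light_availability <= 0:
        raise CalibrationError(
            "light availability must be positive for calibration")
    grid = np.arange(0.0, PERIOD, grid_step)
    peak = max(min(1.0, rule_fraction(light_rule, curves, float(t)))
               for t in grid)
    if peak <= 0:
        raise CalibrationError("light-reaction rule has zero peak fraction")
    return light_availability / peak


def knockout_curves(curves: CurveSet, gene_ids: Iterable[str]) -> CurveSet:
    """Curve set in which the named genes express zero at all times."""
    return curves.knockout(gene_ids)


# ---------------------------------------------------------------------------
# bound schedules over a metabolic model
# ---------------------------------------------------------------------------


class BoundSchedule:
    """Time-varying transcript bounds for every GPR-bearing reaction.

    Bounds are evaluated lazily at arbitrary times (the simulation
    timestep is adjustable); reactions without a GPR keep their model
    defaults.  The schedule is 24-periodic because every curve is.
    """

    def __init__(self, rules: Mapping[str, GPRRule], curves: CurveSet,
                 u_max: float, reversible: Mapping[str, bool]):
        self.rules = {rid: r for rid, r in rules.items() if r.root is not None}
        self.curves = curves
        self.u_max = float(u_max)
        self.reversible = dict(reversible)

    @classmethod
    def from_model(cls, model, curves: CurveSet, u_max: float) -> "BoundSchedule":
        """Extract GPR rules and reversibility from a COBRA model."""
        rules, rev = {}, {}
        for rxn in model.reactions:
            rule = parse_gpr(rxn.gene_reaction_rule, rxn.id)
            if rule.root is not None:
                rules[rxn.id] = rule
                rev[rxn.id] = rxn.lower_bound < 0
        return cls(rules, curves, u_max, rev)

    def fraction_at(self, reaction_id: str, t: float) -> float:
        return rule_fraction(self.rules[reaction_id], self.curves, t)

    def bounds_at(self, t: float) -> Dict[str, Tuple[float, float]]:
        """Map reaction id -> (lb, ub) at time t (hours, taken modulo 24)."""
        return {
            rid: bound_at(rule_fraction(rule, self.curves, t), self.u_max,
                          self.reversible.get(rid, False))
            for rid, rule in self.rules.items()
        }

    def with_curves(self, curves: CurveSet) -> "BoundSchedule":
        return BoundSchedule(self.rules, curves, self.u_max, self.reversible)

    def to_frame(self, times: Sequence[float]):
        """Long-form table (reaction, t, lb, ub) for export."""
        import pandas as pd
        rows = []
        for t in times:
            for rid, (lb, ub) in self.bounds_at(float(t)).items():
                rows.append((rid, float(t), lb, ub))
        return pd.DataFrame(rows, columns=["reaction", "t", "lb", "ub"])
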