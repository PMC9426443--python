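"""Transcript time-series I/O and synthetic diel transcriptome generation.

Tables are long-form delimited files with columns ``gene_id``, ``time_h``
(hours since light onset, within one 24-h cycle) and ``fpkm`` (nonnegative
abundance).  Fitted-curve databases round-trip through JSON.  The synthetic
generator emulates a 2-h-resolution diel RNA-seq experiment: each gene is
drawn from one of the eight parametric expression families with recorded
ground truth, and multiplicative lognormal noise of a chosen coefficient of
variation is applied (FPKM are positive and heteroscedastic, so additive
Gaussian noise would be unrealistic).
"""

from __future__ import annotations

import gzip
import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .curves import CurveFitEnsemble, FAMILIES, FAMILY_ORDER, ModelFit, PERIOD
from .errors import ConfigError, FormatError, ValidationError

_COLUMN_ALIASES = {
    "gene_id": ("gene_id", "gene"),
    "time_h": ("time_h", "time", "t"),
    "fpkm": ("fpkm", "value", "expression"),
}

#: 2-h sampling across one diel cycle, endpoints included (13 points).
DEFAULT_SAMPLING_TIMES: Tuple[float, ...] = tuple(float(t) for t in range(0, 25, 2))


@dataclass
class ExpressionSeries:
    """One gene's diel abundance series (hours since light onset, FPKM)."""

    gene_id: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValidationError(
                f"gene {self.gene_id}: times and values differ in length")
        if len(self.times) < 4:
            raise ValidationError(
                f"gene {self.gene_id}: need at least 4 timepoints, got {len(self.times)}")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError(
                f"gene {self.gene_id}: times must be strictly increasing")
        if self.times[0] < 0 or self.times[-1] > PERIOD:
            raise ValidationError(
                f"gene {self.gene_id}: times must lie within [0, {PERIOD}]")
        neg = np.flatnonzero(self.values < 0)
        if neg.size:
            raise ValidationError(
                f"gene {self.gene_id}: negative FPKM at row {int(neg[0])} "
                f"(value {self.values[neg[0]]:g})")


def _resolve_columns(df: pd.DataFrame) -> Dict[str, str]:
    lower = {c.lower(): c for c in df.columns}
    resolved = {}
    for canon, aliases in _COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in lower:
                resolved[canon] = lower[alias]
                break
        else:
            raise FormatError(
                f"missing required column '{canon}' (accepted names: {aliases}); "
                f"found columns {list(df.columns)}")
    return resolved


def read_expression_table(path, sep: str | None = None) -> List[ExpressionSeries]:
    """Read a long-form expression table (TSV/CSV, optionally gzipped).

    Duplicate (gene, time) rows are averaged with a warning.  Negative
    abundances raise :class:`ValidationError` naming the gene and row.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    cols = _resolve_columns(df)
    df = df.rename(columns={v: k for k, v in cols.items()})
    neg = df[df["fpkm"] < 0]
    if len(neg):
        row = neg.iloc[0]
        raise ValidationError(
            f"negative FPKM for gene {row['gene_id']} at table row "
            f"{int(neg.index[0])} (value {row['fpkm']:g})")
    dup = df.duplicated(subset=["gene_id", "time_h"])
    if dup.any():
        warnings.warn(
            f"{int(dup.sum())} duplicate (gene, time) rows averaged",
            stacklevel=2)
        df = df.groupby(["gene_id", "time_h"], as_index=False)["fpkm"].mean()
    out = []
    for gene, grp in df.groupby("gene_id", sort=True):
        grp = grp.sort_values("time_h")
        out.append(ExpressionSeries(str(gene), grp["time_h"].to_numpy(),
                                    grp["fpkm"].to_numpy()))
    return out


def write_expression_table(series: Sequence[ExpressionSeries], path,
                           sep: str = "\t") -> None:
    rows = [(s.gene_id, t, v) for s in series
            for t, v in zip(s.times, s.values)]
    pd.DataFrame(rows, columns=["gene_id", "time_h", "fpkm"]).to_csv(
        path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# synthetic transcriptomes
# ---------------------------------------------------------------------------


@dataclass
class SyntheticTranscriptomeSpec:
    """Recipe for a synthetic diel transcriptome with known ground truth."""

    n_genes: int = 100
    shape_mix: Dict[str, float] = field(
        default_factory=lambda: {name: 1 / len(FAMILY_ORDER)
                                 for name in FAMILY_ORDER})
    noise_cv: float = 0.05
    sampling_times: Tuple[float, ...] = DEFAULT_SAMPLING_TIMES
    seed: int = 0

    def __post_init__(self):
        if not self.shape_mix:
            raise ConfigError("shape_mix must not be empty")
        unknown = set(self.shape_mix) - set(FAMILY_ORDER)
        if unknown:
            raise ConfigError(f"unknown families in shape_mix: {sorted(unknown)}")
        total = sum(self.shape_mix.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ConfigError(f"shape_mix proportions must sum to 1, got {total}")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")


@dataclass
class GroundTruth:
    gene_id: str
    family: str
    params: Tuple[float, ...]


def _draw_params(family: str, t_grid: np.ndarray,
                 rng: np.random.Generator) -> Tuple[float, ...]:
    """Draw realistic, mutually distinguishable diel-shape parameters.

    Ranges keep the families identifiable at modest noise: amplitudes are a
    sizable fraction of the mesor, hat plateaus span at least a quarter of
    the day, variable-decay time constants avoid the fixed-decay value, and
    the multiplicative growth rate is bounded away from zero.
    """
    c = rng.uniform(20.0, 200.0)
    if family == "constant":
        return (c,)
    if family == "one_term_cosine":
        return (c, c * rng.uniform(0.5, 0.9), rng.uniform(0, PERIOD))
    if family == "two_term_cosine":
        a1 = c * rng.uniform(0.4, 0.7)
        return (c, a1, rng.uniform(0, PERIOD),
                a1 * rng.uniform(0.5, 0.9), rng.uniform(0, PERIOD / 2))
    if family == "hat":
        t_on = rng.uniform(0, PERIOD)
        width = rng.uniform(6.0, 12.0)
        return (c, c * rng.uniform(1.0, 2.0), t_on, (t_on + width) % PERIOD)
    if family == "fixed_decay":
        return (c, c * rng.uniform(1.5, 3.0))
    if family == "variable_decay":
        tau = rng.uniform(1.0, 2.0) if rng.random() < 0.5 else rng.uniform(9.0, 16.0)
        return (c, c * rng.uniform(1.5, 3.0), tau)
    if family == "kronecker_delta":
        interior = t_grid[(t_grid > 0) & (t_grid < t_grid[-1])]
        t0 = float(rng.choice(interior))
        return (c, c * rng.uniform(2.0, 4.0), t0)
    if family == "cosine_multiplicative":
        sign = 1.0 if rng.random() < 0.5 else -1.0
        return (c, c * rng.uniform(0.5, 0.9), rng.uniform(0, PERIOD),
                sign * rng.uniform(0.05, 0.09))
    raise ConfigError(f"unknown family '{family}'")


def generate_synthetic_transcriptome(
        spec: SyntheticTranscriptomeSpec,
) -> Tuple[List[ExpressionSeries], List[GroundTruth]]:
    """Sample a transcriptome from the parametric families.

    Deterministic under the spec seed; with ``noise_cv = 0`` the sampled
    values equal the analytic family curves exactly (clamped at zero).
    """
    rng = np.random.default_rng(spec.seed)
    t = np.asarray(spec.sampling_times, dtype=float)
    names = sorted(spec.shape_mix)
    probs = np.array([spec.shape_mix[n] for n in names])
    probs = probs / probs.sum()
    assignments = rng.choice(len(names), size=spec.n_genes, p=probs)
    if spec.noise_cv > 0:
        sigma = math.sqrt(math.log(1 + spec.noise_cv ** 2))
    else:
        sigma = 0.0
    series, truths = [], []
    for i, fam_idx in enumerate(assignments):
        family = names[fam_idx]
        gene = f"g{i:04d}"
        params = _draw_params(family, t, rng)
        y = np.maximum(FAMILIES[family].evaluate(params, t), 0.0)
        if sigma > 0:
            y = y * np.exp(rng.normal(0.0, sigma, size=len(t)))
        series.append(ExpressionSeries(gene, t, np.maximum(y, 0.0)))
        truths.append(GroundTruth(gene, family, params))
    return series, truths


# ---------------------------------------------------------------------------
# fitted-curve databases (JSON)
# ---------------------------------------------------------------------------

_DB_VERSION = 1


def _open_text(path, mode):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def write_curve_database(ensembles: Sequence[CurveFitEnsemble], path) -> None:
    """Serialize fitted ensembles (families, params, AICc, weights) to JSON."""
    def enc(x):
        return None if (isinstance(x, float) and not math.isfinite(x)) else x

    genes = {}
    for ens in ensembles:
        genes[ens.gene_id] = {
            "best_family": ens.best_family,
            "weights": {k: enc(v) for k, v in ens.weights.items()},
            "fits": {
                name: {"params": list(f.params), "rss": enc(f.rss),
                       "aicc": enc(f.aicc), "n_obs": f.n_obs}
                for name, f in ens.fits.items()
            },
        }
    with _open_text(path, "w") as fh:
        json.dump({"version": _DB_VERSION, "period": PERIOD, "genes": genes},
                  fh, indent=1)


def read_curve_database(path) -> List[CurveFitEnsemble]:
    """Read back a curve database; unknown family tags raise FormatError."""
    with _open_text(path, "r") as fh:
        doc = json.load(fh)
    if "genes" not in doc:
        raise FormatError("curve database missing 'genes' section")

    def dec(x, default):
        return default if x is None else float(x)

    out = []
    for gene_id, rec in doc["genes"].items():
        fits = {}
        for name, f in rec["fits"].items():
            if name not in FAMILIES:
                raise FormatError(
                    f"unknown family tag '{name}' for gene {gene_id}")
            fits[name] = ModelFit(name, tuple(f["params"]),
                                  dec(f.get("rss"), math.inf),
                                  dec(f.get("aicc"), math.inf),
                                  int(f.get("n_obs", 0)))
        if rec["best_family"] not in FAMILIES:
            raise FormatError(
                f"unknown family tag '{rec['best_family']}' for gene {gene_id}")
        weights = {k: dec(v, math.nan) for k, v in rec["weights"].items()}
        out.append(CurveFitEnsemble(gene_id, fits, weights, rec["best_family"]))
    return out
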