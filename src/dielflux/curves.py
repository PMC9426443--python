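"""Parametric diel expression families, AICc model selection, Akaike weights.

Every transcript time-series is fitted against eight candidate curve shapes
defined on a 24-h period: constant, one-term cosine, two-term cosine, hat
(boxcar plateau), fixed-rate exponential decay, variable-rate exponential
decay, Kronecker delta (single-interval spike), and a multiplicatively
growing/damped cosine.  Model selection uses the small-sample corrected
Akaike information criterion

    AICc = n ln(RSS/n) + 2k + 2k(k+1)/(n - k - 1)

and per-gene Akaike weights

    w_i = exp(-Delta_i/2) / sum_r exp(-Delta_r/2),   Delta_i = AICc_i - min AICc

which sum to one and act as relative model probabilities.  The winning
family yields a continuous, 24-periodic expression curve a(t) that can be
queried at arbitrary time and is clamped at zero (FPKM are nonnegative).

Families that are linear in their coefficients once the nonlinear shape
parameter is fixed (cosines given phase via a sin/cos basis, decays given
the time constant, the multiplicative cosine given its growth rate) are
solved by exact linear least squares; the random restarts then perturb only
the remaining nonlinear parameter.  The two discontinuous families (hat,
Kronecker delta) are fitted by exhaustive enumeration of breakpoints over
the sampling grid with closed-form conditional means, which is the global
least-squares optimum for those shapes.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np

from .errors import UnfittableGeneError, ValidationError

PERIOD = 24.0

#: Canonical family ordering used for tie-breaks and vector layouts.
FAMILY_ORDER: Tuple[str, ...] = (
    "constant",
    "one_term_cosine",
    "two_term_cosine",
    "hat",
    "fixed_decay",
    "variable_decay",
    "kronecker_delta",
    "cosine_multiplicative",
)

#: Default time constant (h) of the fixed-decay family; configurable.
FIXED_DECAY_TAU = 4.0

#: Default spike width (h) of the Kronecker-delta family — one sampling
#: interval of a 2-h diel series.
DEFAULT_SPIKE_WIDTH = 2.0


def _wrap(t):
    return np.asarray(t, dtype=float) % PERIOD


# ---------------------------------------------------------------------------
# family definitions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionFamily:
    """One candidate parametric expression shape on the 24-h diel frame."""

    name: str
    n_params: int
    param_names: Tuple[str, ...]
    _evaluate: Callable[[Sequence[float], np.ndarray], np.ndarray]
    _fit: Callable[["ExpressionFamily", np.ndarray, np.ndarray, int, np.random.Generator], Tuple[Tuple[float, ...], float]]
    spike_width: float = DEFAULT_SPIKE_WIDTH

    def evaluate(self, params: Sequence[float], t) -> np.ndarray:
        """Evaluate the raw (unclamped) curve at time ``t`` (hours)."""
        if len(params) != self.n_params:
            raise ValidationError(
                f"family '{self.name}' expects {self.n_params} parameters, got {len(params)}"
            )
        scalar = np.isscalar(t)
        out = self._evaluate(params, _wrap(t))
        return float(out) if scalar else out

    def fit(self, times: np.ndarray, values: np.ndarray, n_restarts: int,
            rng: np.random.Generator) -> Tuple[Tuple[float, ...], float]:
        """Least-squares fit; returns (params, rss)."""
        return self._fit(self, times, values, n_restarts, rng)


def _eval_constant(p, t):
    return np.full_like(t, p[0])


def _eval_one_cos(p, t):
    c, A, phi = p
    return c + A * np.cos(2 * np.pi * (t - phi) / PERIOD)


def _eval_two_cos(p, t):
    c, a1, p1, a2, p2 = p
    return (c + a1 * np.cos(2 * np.pi * (t - p1) / PERIOD)
            + a2 * np.cos(4 * np.pi * (t - p2) / PERIOD))


def _in_window(t, t_on, t_off):
    t_on, t_off = t_on % PERIOD, t_off % PERIOD
    if t_on <= t_off:
        return (t >= t_on) & (t < t_off)
    return (t >= t_on) | (t < t_off)  # wrap-around plateau


def _eval_hat(p, t):
    c, A, t_on, t_off = p
    return c + A * _in_window(t, t_on, t_off)


def _eval_fixed_decay(p, t):
    c, A = p
    return c + A * np.exp(-t / FIXED_DECAY_TAU)


def _eval_variable_decay(p, t):
    c, A, tau = p
    return c + A * np.exp(-t / tau)


def _eval_cos_mult(p, t):
    c, A, phi, g = p
    return (c + A * np.cos(2 * np.pi * (t - phi) / PERIOD)) * np.exp(g * t)


def _make_eval_kron(width):
    def _eval(p, t):
        c, A, t0 = p
        return c + A * _in_window(t, t0, t0 + width)
    return _eval


def _rss(y, yhat):
    r = y - yhat
    return float(r @ r)


def _lin_lsq(design: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, float]:
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return coef, _rss(y, design @ coef)


def _fit_constant(fam, t, y, n_restarts, rng):
    c = float(np.mean(y))
    return (c,), _rss(y, np.full_like(y, c))


def _harmonic_to_polar(a_cos: float, b_sin: float, harmonic: int) -> Tuple[float, float]:
    """(a cos wt + b sin wt) -> amplitude A >= 0 and peak phase in [0, 24)."""
    A = math.hypot(a_cos, b_sin)
    omega = 2 * np.pi * harmonic / PERIOD
    phi = (math.atan2(b_sin, a_cos) / omega) % (PERIOD / harmonic)
    return A, phi


def _fit_one_cos(fam, t, y, n_restarts, rng):
    w = 2 * np.pi * t / PERIOD
    X = np.column_stack([np.ones_like(t), np.cos(w), np.sin(w)])
    coef, rss = _lin_lsq(X, y)
    A, phi = _harmonic_to_polar(coef[1], coef[2], 1)
    return (float(coef[0]), A, phi), rss


def _fit_two_cos(fam, t, y, n_restarts, rng):
    w = 2 * np.pi * t / PERIOD
    X = np.column_stack([np.ones_like(t), np.cos(w), np.sin(w),
                         np.cos(2 * w), np.sin(2 * w)])
    coef, rss = _lin_lsq(X, y)
    A1, p1 = _harmonic_to_polar(coef[1], coef[2], 1)
    A2, p2 = _harmonic_to_polar(coef[3], coef[4], 2)
    return (float(coef[0]), A1, p1, A2, p2), rss


def _fit_hat(fam, t, y, n_restarts, rng):
    # Exact LS over all (on, off) breakpoint pairs drawn from the sample grid.
    best = None
    n = len(t)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            mask = _in_window(t, t[i], t[j])
            if mask.all() or not mask.any():
                continue
            c = float(np.mean(y[~mask]))
            A = float(np.mean(y[mask]) - c)
            rss = _rss(y, c + A * mask)
            if best is None or rss < best[1]:
                best = ((c, A, float(t[i] % PERIOD), float(t[j] % PERIOD)), rss)
    if best is None:  # fewer than 2 distinct times — degenerate
        c = float(np.mean(y))
        return (c, 0.0, 0.0, PERIOD / 2), _rss(y, np.full_like(y, c))
    return best


def _fit_kron(fam, t, y, n_restarts, rng):
    best = None
    for i in range(len(t)):
        mask = _in_window(t, t[i], t[i] + fam.spike_width)
        if mask.all() or not mask.any():
            continue
        c = float(np.mean(y[~mask]))
        A = float(np.mean(y[mask]) - c)
        rss = _rss(y, c + A * mask)
        if best is None or rss < best[1]:
            best = ((c, A, float(t[i] % PERIOD)), rss)
    if best is None:
        c = float(np.mean(y))
        return (c, 0.0, 0.0), _rss(y, np.full_like(y, c))
    return best


def _fit_fixed_decay(fam, t, y, n_restarts, rng):
    X = np.column_stack([np.ones_like(t), np.exp(-t / FIXED_DECAY_TAU)])
    coef, rss = _lin_lsq(X, y)
    return (float(coef[0]), float(coef[1])), rss


def _profile_fit_1d(t, y, basis_of, candidates, bounds):
    """Profile LS over one nonlinear parameter with a linear inner solve."""
    from scipy.optimize import minimize_scalar

    def inner(theta):
        return _lin_lsq(basis_of(theta), y)

    best_theta, (best_coef, best_rss) = None, (None, np.inf)
    for theta in candidates:
        coef, rss = inner(theta)
        if rss < best_rss:
            best_theta, best_coef, best_rss = theta, coef, rss
    # local polish in a bracket around the best candidate
    lo, hi = bounds
    span = (hi - lo) * 0.15
    res = minimize_scalar(lambda th: inner(th)[1],
                          bounds=(max(lo, best_theta - span), min(hi, best_theta + span)),
                          method="bounded")
    if res.fun < best_rss:
        best_theta = float(res.x)
        best_coef, best_rss = inner(best_theta)
    return best_theta, best_coef, best_rss


def _fit_variable_decay(fam, t, y, n_restarts, rng):
    lo, hi = 0.3, PERIOD
    # deterministic log-spaced ladder plus the random restarts
    cands = list(np.geomspace(lo, hi, 16)) + \
        list(rng.uniform(lo, hi, size=max(1, n_restarts)))
    tau, coef, rss = _profile_fit_1d(
        t, y, lambda tau: np.column_stack([np.ones_like(t), np.exp(-t / tau)]),
        cands, (lo, hi))
    return (float(coef[0]), float(coef[1]), float(tau)), rss


def _fit_cos_mult(fam, t, y, n_restarts, rng):
    lo, hi = -0.2, 0.2
    w = 2 * np.pi * t / PERIOD

    def basis(g):
        e = np.exp(g * t)
        return np.column_stack([e, e * np.cos(w), e * np.sin(w)])

    cands = list(np.linspace(lo, hi, 21)) + \
        list(rng.uniform(lo, hi, size=max(1, n_restarts)))
    g, coef, rss = _profile_fit_1d(t, y, basis, cands, (lo, hi))
    A, phi = _harmonic_to_polar(coef[1], coef[2], 1)
    return (float(coef[0]), A, phi, float(g)), rss


def make_families(spike_width: float = DEFAULT_SPIKE_WIDTH) -> Dict[str, ExpressionFamily]:
    """Instantiate the eight candidate families (keyed, canonical order)."""
    fams = [
        ExpressionFamily("constant", 1, ("c",), _eval_constant, _fit_constant),
        ExpressionFamily("one_term_cosine", 3, ("c", "amplitude", "phase"),
                         _eval_one_cos, _fit_one_cos),
        ExpressionFamily("two_term_cosine", 5,
                         ("c", "a1", "phase1", "a2", "phase2"),
                         _eval_two_cos, _fit_two_cos),
        ExpressionFamily("hat", 4, ("c", "height", "t_on", "t_off"),
                         _eval_hat, _fit_hat),
        ExpressionFamily("fixed_decay", 2, ("c", "amplitude"),
                         _eval_fixed_decay, _fit_fixed_decay),
        ExpressionFamily("variable_decay", 3, ("c", "amplitude", "tau"),
                         _eval_variable_decay, _fit_variable_decay),
        ExpressionFamily("kronecker_delta", 3, ("c", "height", "t0"),
                         _make_eval_kron(spike_width), _fit_kron,
                         spike_width=spike_width),
        ExpressionFamily("cosine_multiplicative", 4,
                         ("c", "amplitude", "phase", "growth"),
                         _eval_cos_mult, _fit_cos_mult),
    ]
    return {f.name: f for f in fams}


FAMILIES: Dict[str, ExpressionFamily] = make_families()


# ---------------------------------------------------------------------------
# information criteria
# ---------------------------------------------------------------------------


def aicc(rss: float, n_obs: int, k_params: int) -> float:
    """Small-sample corrected AIC for a Gaussian least-squares fit.

    ``n ln(RSS/n) + 2k + 2k(k+1)/(n-k-1)``; returns ``+inf`` when the
    correction denominator is nonpositive (too few observations).  RSS is
    floored at a scale-free epsilon so interpolating fits stay finite.
    """
    if rss < 0:
        raise ValidationError(f"rss must be nonnegative, got {rss}")
    if n_obs - k_params - 1 <= 0:
        return math.inf
    rss = max(rss, 1e-12 * n_obs)
    return (n_obs * math.log(rss / n_obs) + 2 * k_params
            + 2 * k_params * (k_params + 1) / (n_obs - k_params - 1))


def akaike_weights(aiccs: Mapping[str, float]) -> Dict[str, float]:
    """Akaike weights from per-family AICc values.

    Infinite entries receive weight zero; raises if every family is
    infinite (the gene is unfittable).
    """
    finite = {k: v for k, v in aiccs.items() if math.isfinite(v)}
    if not finite:
        raise UnfittableGeneError("all candidate families have infinite AICc")
    best = min(finite.values())
    raw = {k: (math.exp(-0.5 * (v - best)) if math.isfinite(v) else 0.0)
           for k, v in aiccs.items()}
    total = sum(raw.values())
    return {k: v / total for k, v in raw.items()}


# ---------------------------------------------------------------------------
# fit containers
# ---------------------------------------------------------------------------


@dataclass
class ModelFit:
    """A single family's least-squares fit to one gene."""

    family: str
    params: Tuple[float, ...]
    rss: float
    aicc: float
    n_obs: int


@dataclass
class CurveFitEnsemble:
    """All candidate fits for one gene plus Akaike weights.

    The ensemble is the continuous stand-in for the discrete series: the
    best family's curve (clamped at zero, evaluated modulo 24) is the
    queryable expression function a(t).
    """

    gene_id: str
    fits: Dict[str, ModelFit]
    weights: Dict[str, float]
    best_family: str
    _diel_max: float | None = field(default=None, repr=False, compare=False)

    def query(self, t, families: Mapping[str, ExpressionFamily] | None = None):
        """Best-family expression value at time ``t`` (h), clamped >= 0."""
        fams = families or FAMILIES
        fit = self.fits[self.best_family]
        val = fams[self.best_family].evaluate(fit.params, t)
        return np.maximum(val, 0.0) if isinstance(val, np.ndarray) else max(val, 0.0)

    def diel_max(self, grid_step: float = 0.05) -> float:
        """Maximum of the clamped best-family curve over one 24-h cycle."""
        if self._diel_max is None:
            grid = np.arange(0.0, PERIOD, grid_step)
            self._diel_max = float(np.max(self.query(grid)))
        return self._diel_max


def query_curve(ensemble: CurveFitEnsemble, t):
    """Module-level alias for :meth:`CurveFitEnsemble.query`."""
    return ensemble.query(t)


def ensemble_from_params(gene_id: str, family: str, params: Sequence[float],
                         families: Mapping[str, ExpressionFamily] | None = None,
                         ) -> CurveFitEnsemble:
    """Build a degenerate ensemble with all weight on one known family.

    Used for scenario fixtures where the generating curve is known exactly
    and fitting would be redundant.
    """
    fams = families or FAMILIES
    if family not in fams:
        raise ValidationError(f"unknown family '{family}'")
    fit = ModelFit(family, tuple(float(p) for p in params), 0.0, -math.inf, 0)
    weights = {name: (1.0 if name == family else 0.0) for name in fams}
    fits = {family: fit}
    return CurveFitEnsemble(gene_id, fits, weights, family)


# ---------------------------------------------------------------------------
# fitting driver
# ---------------------------------------------------------------------------


def _gene_rng(seed: int, gene_id: str, family: str) -> np.random.Generator:
    # Stable per-(gene, family) stream so batch order and parallelism are moot.
    key = zlib.crc32(f"{gene_id}|{family}".encode())
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, key]))


def fit_family(series, family: ExpressionFamily, n_restarts: int = 100,
               seed: int = 0) -> ModelFit:
    """Fit one family to one series, keeping the best of all restarts."""
    if n_restarts < 1:
        raise ValidationError("n_restarts must be >= 1")
    # fit in the wrapped diel frame: evaluation is always modulo 24, so a
    # sample at t=24 is the t=0 phase point for every family
    t = np.asarray(series.times, dtype=float) % PERIOD
    y = np.asarray(series.values, dtype=float)
    rng = _gene_rng(seed, series.gene_id, family.name)
    try:
        params, rss = family.fit(t, y, n_restarts, rng)
    except Exception:
        return ModelFit(family.name, (math.nan,) * family.n_params,
                        math.inf, math.inf, len(y))
    return ModelFit(family.name, params, rss,
                    aicc(rss, len(y), family.n_params), len(y))


def _tie_break_best(fits: Dict[str, ModelFit]) -> str:
    # lowest AICc; exact ties -> fewest parameters, then canonical order
    order = {name: i for i, name in enumerate(FAMILY_ORDER)}
    return min(
        fits,
        key=lambda name: (fits[name].aicc, len(fits[name].params), order.get(name, 99)),
    )


def fit_gene(series, n_restarts: int = 100, seed: int = 0,
             families: Mapping[str, ExpressionFamily] | None = None,
             ) -> CurveFitEnsemble:
    """Fit all candidate families to one gene and compute Akaike weights."""
    fams = families or FAMILIES
    fits = {name: fit_family(series, fam, n_restarts, seed)
            for name, fam in fams.items()}
    weights = akaike_weights({name: f.aicc for name, f in fits.items()})
    return CurveFitEnsemble(series.gene_id, fits, weights, _tie_break_best(fits))


def fit_transcriptome(series_collection: Iterable, n_restarts: int = 100,
                      seed: int = 0, workers: int = 1,
                      families: Mapping[str, ExpressionFamily] | None = None,
                      ) -> List[CurveFitEnsemble]:
    """Fit every gene independently; per-gene failures become flagged records.

    Results are a pure, order-independent function of each series and the
    seed, so any parallel map produces identical output.
    """
    series_list = list(series_collection)
    if not series_list:
        raise ValidationError("empty series collection")

    def one(series):
        try:
            return fit_gene(series, n_restarts, seed, families)
        except UnfittableGeneError:
            fams = families or FAMILIES
            fits = {name: ModelFit(name, (math.nan,) * fam.n_params,
                                   math.inf, math.inf, len(series.values))
                    for name, fam in fams.items()}
            return CurveFitEnsemble(series.gene_id, fits,
                                    {n: math.nan for n in fits}, "constant")

    if workers > 1:
        from joblib import Parallel, delayed
        return Parallel(n_jobs=workers)(delayed(one)(s) for s in series_list)
    return [one(s) for s in series_list]
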