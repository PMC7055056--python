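"""Two-input lognormal richness prediction.

The model treats the species curve in log-abundance space, ``y = ln(x)``, as
a Gaussian truncated to the span of observed abundances:

    S(y) = S0 * exp(-a^2 (y - y0)^2),   y in [ln(Nmin), ln(Nmax)]

with three anchoring conventions:

* the distribution spans ``[Nmin, Nmax]`` with its mode at the geometric
  midpoint, ``x0 = sqrt(Nmin * Nmax)`` (symmetric lognormal);
* the species curve equals one at the most abundant species,
  ``S(ln Nmax) = 1``, which fixes ``S0 = exp(a^2 (D/2)^2)`` for span
  ``D = ln(Nmax/Nmin)``;
* the inverse width ``a`` is solved so the individuals integral
  ``int x S(y) dy`` equals the supplied total ``N``.

Total richness is then ``S_total = int S(y) dy``. Both integrals have
closed forms via the Gaussian error function; the scalar solve for ``a``
uses bracketing plus Brent's method. Because the two inputs (N, Nmax) are
quantities at the scale of interest, the prediction is at that same scale —
there is no extrapolation step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import erf, log_ndtr

from microcensus.dar_scaling import ScalingFit, predict_nmax

__all__ = [
    "LognormalInfeasibleError",
    "LognormalSolution",
    "GlobalPredictionReport",
    "PathwayPrediction",
    "solve_lognormal",
    "predict_global_richness",
    "sample_lognormal_sad",
]

_SQRT_PI = math.sqrt(math.pi)
_SQRT2 = math.sqrt(2.0)


class LognormalInfeasibleError(ValueError):
    """The (N, Nmax, Nmin) inputs admit no lognormal spanning [Nmin, Nmax]."""


@dataclass(frozen=True)
class LognormalSolution:
    """Solved lognormal species curve and its predicted richness."""

    S_total: float
    N_input: float
    Nmax_input: float
    Nmin: float
    shape_a: float            # inverse width; inf in the degenerate limit
    sigma_ln: float           # equivalent log-space std dev, 1 / (a sqrt(2))
    modal_abundance: float    # x0 = sqrt(Nmin * Nmax)
    residual: float           # relative mismatch of the individuals constraint

    def __post_init__(self) -> None:
        if self.S_total < 1.0 - 1e-9:
            raise ValueError("S_total must be >= 1")


def _log_erfc(x: float) -> float:
    # erfc(x) = 2 * Phi(-x * sqrt(2))
    return math.log(2.0) + float(log_ndtr(-x * _SQRT2))


def _log_erf_sum(A: float, B: float) -> float:
    """ln(erf(A - B) + erf(A + B)) for A, B > 0, robust to cancellation."""
    if A - B > -5.0:
        val = erf(A - B) + erf(A + B)
        if val > 0.0:
            return math.log(val)
    # erf(A-B) + erf(A+B) = erfc(B-A) - erfc(A+B); both tails tiny, work in logs
    l1 = _log_erfc(B - A)
    l2 = _log_erfc(A + B)
    return l1 + math.log1p(-math.exp(min(l2 - l1, 0.0)))


def _ln_individuals(a: float, y0: float, half_span: float) -> float:
    """ln of int_{y0-h}^{y0+h} exp(y) * S0 * exp(-a^2 (y-y0)^2) dy with S(ymax)=1."""
    A = a * half_span
    B = 1.0 / (2.0 * a)
    return (
        math.log(_SQRT_PI / (2.0 * a))
        + A * A          # ln S0 = a^2 * half_span^2
        + y0
        + B * B          # 1 / (4 a^2)
        + _log_erf_sum(A, B)
    )


def _ln_richness(a: float, half_span: float) -> float:
    A = a * half_span
    return math.log(_SQRT_PI / a) + A * A + math.log(erf(A))


def solve_lognormal(
    N: float, Nmax: float, Nmin: float = 1.0, tol: float = 1e-10
) -> LognormalSolution:
    """Solve the two-input lognormal model for total richness.

    Parameters
    ----------
    N, Nmax, Nmin:
        Total abundance, abundance of the most abundant species, and the
        assumed abundance of the rarest species (default 1). Must satisfy
        ``Nmin <= Nmax <= N``.
    tol:
        Accepted relative mismatch of the individuals constraint.

    Raises
    ------
    LognormalInfeasibleError
        If no positive width reproduces ``N`` (the bracket on the inverse
        width shows no sign change).
    """
    if not (Nmin > 0 and Nmax > 0 and N > 0):
        raise ValueError("N, Nmax and Nmin must be positive")
    if Nmax > N:
        raise ValueError(f"Nmax ({Nmax}) cannot exceed N ({N})")
    if Nmin > Nmax:
        raise ValueError(f"Nmin ({Nmin}) cannot exceed Nmax ({Nmax})")
    if Nmax == Nmin:
        # Zero span: all species share abundance Nmax; N = Nmax gives S = 1.
        return LognormalSolution(
            S_total=float(N / Nmax),
            N_input=float(N),
            Nmax_input=float(Nmax),
            Nmin=float(Nmin),
            shape_a=math.inf,
            sigma_ln=0.0,
            modal_abundance=float(Nmax),
            residual=0.0,
        )

    y_min, y_max = math.log(Nmin), math.log(Nmax)
    y0 = 0.5 * (y_min + y_max)
    half_span = 0.5 * (y_max - y_min)
    target = math.log(N)

    def g(a: float) -> float:
        return _ln_individuals(a, y0, half_span) - target

    a_lo = 1e-6
    while g(a_lo) > 0.0 and a_lo > 1e-13:
        a_lo /= 10.0
    if g(a_lo) > 0.0:
        raise LognormalInfeasibleError(
            f"no lognormal spanning [{Nmin:g}, {Nmax:g}] holds as few as "
            f"N={N:g} individuals (no sign change down to a={a_lo:g})"
        )
    a_hi = 1.0
    while g(a_hi) < 0.0:
        a_hi *= 2.0
        if a_hi > 1e9:
            raise LognormalInfeasibleError(
                f"no lognormal spanning [{Nmin:g}, {Nmax:g}] holds as many as "
                f"N={N:g} individuals (no sign change up to a={a_hi:g})"
            )
    a = brentq(g, a_lo, a_hi, xtol=1e-300, rtol=8.9e-16, maxiter=200)
    residual = abs(math.expm1(g(a)))
    if residual > tol:
        raise RuntimeError(
            f"lognormal solve did not reach tolerance: residual={residual:g}"
        )
    s_total = math.exp(_ln_richness(a, half_span))
    return LognormalSolution(
        S_total=s_total,
        N_input=float(N),
        Nmax_input=float(Nmax),
        Nmin=float(Nmin),
        shape_a=float(a),
        sigma_ln=1.0 / (a * _SQRT2),
        modal_abundance=math.sqrt(Nmin * Nmax),
        residual=float(residual),
    )


@dataclass(frozen=True)
class PathwayPrediction:
    pathway: str              # "empirical_nmax" | "dar_predicted_nmax"
    Nmax_used: float
    solution: LognormalSolution


@dataclass(frozen=True)
class GlobalPredictionReport:
    """Richness predictions with provenance of the Nmax input."""

    N_input: float
    Nmin: float
    predictions: tuple[PathwayPrediction, ...]
    notes: str = ""

    @property
    def S_total(self) -> float:
        """Richness from the first (primary) pathway."""
        return self.predictions[0].solution.S_total

    def by_pathway(self, pathway: str) -> PathwayPrediction:
        for p in self.predictions:
            if p.pathway == pathway:
                return p
        raise KeyError(pathway)


def predict_global_richness(
    N: float,
    Nmax: float | None = None,
    dominance_fit: ScalingFit | None = None,
    Nmin: float = 1.0,
    notes: str = "",
) -> GlobalPredictionReport:
    """Predict richness at the scale of N, resolving Nmax empirically and/or
    from a fitted dominance DAR.

    Supplying both sources reports both pathways side by side (empirical
    first).
    """
    if Nmax is None and dominance_fit is None:
        raise ValueError("supply an explicit Nmax, a dominance fit, or both")
    preds: list[PathwayPrediction] = []
    if Nmax is not None:
        preds.append(
            PathwayPrediction(
                "empirical_nmax", float(Nmax), solve_lognormal(N, Nmax, Nmin)
            )
        )
    if dominance_fit is not None:
        nmax_hat = predict_nmax(dominance_fit, N)
        preds.append(
            PathwayPrediction(
                "dar_predicted_nmax",
                float(nmax_hat),
                solve_lognormal(N, nmax_hat, Nmin),
            )
        )
    return GlobalPredictionReport(
        N_input=float(N), Nmin=float(Nmin), predictions=tuple(preds), notes=notes
    )


def sample_lognormal_sad(
    solution: LognormalSolution,
    seed: int | None = None,
    method: str = "iid",
) -> np.ndarray:
    """Realize an integer abundance vector from a solved species curve.

    ``ceil(S_total)`` log-abundances are taken from the fitted truncated
    Gaussian (normalized as a density), exponentiated, and rounded to
    integers >= Nmin. Returned sorted descending.

    ``method="iid"`` draws independently (seeded). ``method="quantile"``
    places species deterministically at the density quantiles i/S with the
    top species pinned to the span edge Nmax; use it for self-consistency
    round trips — the iid maximum fluctuates by a large factor (Gumbel
    scale sigma_ln / sqrt(2 ln S)), which dominates re-solved richness.
    """
    s_draw = int(math.ceil(solution.S_total))
    floor_abund = max(1, int(round(solution.Nmin)))
    if not math.isfinite(solution.shape_a):
        return np.full(s_draw, floor_abund, dtype=np.int64)
    y_min = math.log(solution.Nmin)
    y_max = math.log(solution.Nmax_input)
    y0 = math.log(solution.modal_abundance)
    sigma = solution.sigma_ln
    from scipy.stats import truncnorm

    a_std = (y_min - y0) / sigma
    b_std = (y_max - y0) / sigma
    if method == "iid":
        rng = np.random.default_rng(seed)
        y = truncnorm.rvs(
            a_std, b_std, loc=y0, scale=sigma, size=s_draw, random_state=rng
        )
    elif method == "quantile":
        q = np.arange(1, s_draw + 1) / s_draw
        y = truncnorm.ppf(q, a_std, b_std, loc=y0, scale=sigma)
    else:
        raise ValueError(f"unknown method {method!r}; expected 'iid' or 'quantile'")
    abund = np.maximum(np.rint(np.exp(y)), floor_abund).astype(np.int64)
    return np.sort(abund)[::-1]
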