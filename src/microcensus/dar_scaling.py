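"""Diversity-abundance relationship (DAR) fits.

Each DAR is a power law ``response = c * N^z`` fit as an ordinary least
squares regression in log10-log10 space. The fit is repeated over many
bootstrap draws: each draw selects ``n_per_boot`` assemblages with
replacement, allocated as evenly as possible across strata (1-decade bins
of log10 N by default) so that the heavily sampled middle decades do not
dominate. Reported coefficients are means over bootstrap replicates with
95% percentile intervals.

Response transforms: richness, dominance (Nmax) and evenness are fit as
log10(response); rarity (a skewness, possibly <= 0) is fit untransformed
against log10(N).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from microcensus.metrics import SADSummary

logger = logging.getLogger(__name__)

__all__ = ["ScalingFit", "fit_dar", "predict_nmax", "prediction_interval", "RESPONSES"]

# response -> (attribute, log-transform?)
RESPONSES = {
    "richness": ("S", True),
    "dominance": ("Nmax", True),
    "evenness": ("evenness", True),
    "rarity": ("rarity", False),
}


@dataclass
class ScalingFit:
    """Bootstrapped log-log regression result.

    Per-bootstrap coefficient arrays are retained so prediction intervals
    can be reconstructed without refitting.
    """

    response: str
    log_response: bool
    exponent_mean: float
    intercept_mean: float
    r2_mean: float
    exponent_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    n_boot: int
    n_per_boot: int
    strata_width: float | None
    seed: int | None
    # per-bootstrap internals
    slopes: np.ndarray
    intercepts: np.ndarray
    r2: np.ndarray
    resid_var: np.ndarray
    x_mean: np.ndarray
    x_ssx: np.ndarray

    def __post_init__(self) -> None:
        lo, hi = self.exponent_ci
        if not (lo - 1e-12 <= self.exponent_mean <= hi + 1e-12):
            raise ValueError("exponent CI must contain the exponent mean")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")


def _response_xy(
    summaries: Sequence[SADSummary], response: str
) -> tuple[np.ndarray, np.ndarray, bool]:
    if response not in RESPONSES:
        raise ValueError(
            f"unknown response {response!r}; expected one of {sorted(RESPONSES)}"
        )
    attr, log_y = RESPONSES[response]
    x = np.log10(np.asarray([s.N for s in summaries], dtype=float))
    y = np.asarray([getattr(s, attr) for s in summaries], dtype=float)
    if log_y:
        if np.any(y <= 0):
            raise ValueError(
                f"response {response!r} must be positive for the log transform"
            )
        y = np.log10(y)
    return x, y, log_y


def _strata_indices(
    x: np.ndarray, strata_width: float | None
) -> list[np.ndarray]:
    if strata_width is None:
        return [np.arange(x.size)]
    codes = np.floor(x / strata_width).astype(int)
    return [np.flatnonzero(codes == c) for c in np.unique(codes)]


def _allocate(n: int, strata: list[np.ndarray]) -> list[int]:
    """Split n draws as evenly as possible; remainder goes to largest strata."""
    k = len(strata)
    base, rem = divmod(n, k)
    alloc = [base] * k
    order = sorted(range(k), key=lambda i: (-strata[i].size, i))
    for i in order[:rem]:
        alloc[i] += 1
    return alloc


def fit_dar(
    summaries: Sequence[SADSummary],
    response: str,
    n_boot: int = 10_000,
    n_per_boot: int = 500,
    strata_width: float | None = 1.0,
    seed: int | None = None,
) -> ScalingFit:
    """Fit a DAR by stratified bootstrapped OLS in log-log space.

    Parameters
    ----------
    summaries:
        Per-assemblage SAD summaries (needs >= 2 distinct N).
    response:
        One of ``richness``, ``dominance``, ``evenness``, ``rarity``.
    n_boot, n_per_boot:
        Bootstrap replicates and assemblages per regression. The reference
        configuration is 10,000 x 500.
    strata_width:
        Width (in decades of log10 N) of the allocation strata; ``None``
        disables stratification.
    """
    if n_per_boot < 3:
        raise ValueError("n_per_boot must be >= 3 for a regression with df > 0")
    x_all, y_all, log_y = _response_xy(summaries, response)
    if np.unique(x_all).size < 2:
        raise ValueError("all N identical: slope is undefined")
    if len(summaries) < n_per_boot:
        logger.info(
            "corpus has %d summaries < n_per_boot=%d; drawing with replacement "
            "from what exists",
            len(summaries),
            n_per_boot,
        )
    strata = _strata_indices(x_all, strata_width)
    alloc = _allocate(n_per_boot, strata)
    rng = np.random.default_rng(seed)

    idx = np.empty((n_boot, n_per_boot), dtype=np.int64)
    pos = 0
    for members, k in zip(strata, alloc):
        if k == 0:
            continue
        idx[:, pos : pos + k] = members[
            rng.integers(0, members.size, size=(n_boot, k))
        ]
        pos += k

    slopes, intercepts, r2, resid_var, x_mean, x_ssx = _ols_rows(
        x_all[idx], y_all[idx]
    )
    # Redraw degenerate replicates (all-x-equal draws); vanishingly rare
    # unless a single stratum holds a single N value.
    for _ in range(100):
        bad = np.flatnonzero(x_ssx <= 0)
        if bad.size == 0:
            break
        redraw = np.empty((bad.size, n_per_boot), dtype=np.int64)
        pos = 0
        for members, k in zip(strata, alloc):
            if k == 0:
                continue
            redraw[:, pos : pos + k] = members[
                rng.integers(0, members.size, size=(bad.size, k))
            ]
            pos += k
        (
            slopes[bad],
            intercepts[bad],
            r2[bad],
            resid_var[bad],
            x_mean[bad],
            x_ssx[bad],
        ) = _ols_rows(x_all[redraw], y_all[redraw])
    else:
        raise RuntimeError("could not draw non-degenerate bootstrap replicates")

    exp_ci = tuple(np.percentile(slopes, [2.5, 97.5]))
    int_ci = tuple(np.percentile(intercepts, [2.5, 97.5]))
    return ScalingFit(
        response=response,
        log_response=log_y,
        exponent_mean=float(slopes.mean()),
        intercept_mean=float(intercepts.mean()),
        r2_mean=float(r2.mean()),
        exponent_ci=(float(exp_ci[0]), float(exp_ci[1])),
        intercept_ci=(float(int_ci[0]), float(int_ci[1])),
        n_boot=n_boot,
        n_per_boot=n_per_boot,
        strata_width=strata_width,
        seed=seed,
        slopes=slopes,
        intercepts=intercepts,
        r2=r2,
        resid_var=resid_var,
        x_mean=x_mean,
        x_ssx=x_ssx,
    )


def _ols_rows(X: np.ndarray, Y: np.ndarray):
    """Row-wise simple OLS for (n_rows, n_points) design/response arrays."""
    n = X.shape[1]
    xm = X.mean(axis=1)
    ym = Y.mean(axis=1)
    dx = X - xm[:, None]
    dy = Y - ym[:, None]
    sxx = np.einsum("ij,ij->i", dx, dx)
    sxy = np.einsum("ij,ij->i", dx, dy)
    syy = np.einsum("ij,ij->i", dy, dy)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), np.nan)
    intercept = ym - slope * xm
    sse = np.maximum(syy - slope * sxy, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(syy > 0, 1.0 - sse / np.where(syy > 0, syy, 1.0), 1.0)
    resid_var = sse / (n - 2)
    return slope, intercept, r2, resid_var, xm, sxx


def predict_nmax(fit: ScalingFit, N) -> float | np.ndarray:
    """Predict dominance from a fitted dominance DAR: 10^b * N^z, capped at N."""
    if fit.response != "dominance":
        raise ValueError(
            f"predict_nmax needs a dominance fit, got response={fit.response!r}"
        )
    N = np.asarray(N, dtype=float)
    if np.any(N <= 0):
        raise ValueError("N must be positive")
    pred = np.minimum(10.0 ** fit.intercept_mean * N ** fit.exponent_mean, N)
    return float(pred) if pred.ndim == 0 else pred


def prediction_interval(
    fit: ScalingFit, N: float, level: float = 0.95
) -> tuple[float, float]:
    """95% (by default) prediction interval for the response at abundance N.

    The standard OLS prediction interval is formed in the fit's transformed
    space for each bootstrap replicate, averaged over replicates, and
    back-transformed if the response was log10-transformed.
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    if N <= 0:
        raise ValueError("N must be positive")
    x = np.log10(N)
    yhat = fit.intercepts + fit.slopes * x
    df = fit.n_per_boot - 2
    tcrit = stats.t.ppf(0.5 + level / 2.0, df)
    se = np.sqrt(
        fit.resid_var
        * (1.0 + 1.0 / fit.n_per_boot + (x - fit.x_mean) ** 2 / fit.x_ssx)
    )
    lo = float(np.mean(yhat - tcrit * se))
    hi = float(np.mean(yhat + tcrit * se))
    if fit.log_response:
        return 10.0 ** lo, 10.0 ** hi
    return lo, hi
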