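"""The internal background model N(n) = p^n * A + B and the excess ratio.

Under the assumption that background tags land uniformly and independently,
the number of regions covered by at least one tag is N(1) = p*A, with A the
effective mappable length and p the per-position tag probability, and the
number of regions where at least n tags overlap a single base decays
geometrically: p^n * A.  Real binding adds an (approximately depth-
independent) offset B of true peaks, so the observed cumulative table is
modelled as N(n) = p^n * A + B over n = 1..4 — deep enough to see the
geometric decay, shallow enough that real peaks contribute only through B.

Peak significance is the excess ratio ER(n) = N_obs(n) / (p^n * A): how many
times more regions of depth >= n were seen than uniform background alone
would produce.  The denominator deliberately excludes B.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .coverage_regions import CountTable, Region

_FIT_DEPTHS = np.arange(1, 5)  # the model is fitted to N(1)..N(4)


class InsufficientBackgroundError(ValueError):
    """The count table cannot support a background fit (N(4)=0 or flat)."""


class FitConvergenceError(RuntimeError):
    """The constrained least-squares fit failed to converge."""


@dataclass
class BackgroundFit:
    """Fitted background parameters.

    p
        Per-position background tag probability, 0 < p < 1.
    A
        Effective mappable length (bp).  Fitted, not fixed to the genome
        size: unmappable and unsequenced stretches shrink it.
    B
        Offset representing the number of real peaks (regions).
    residuals
        log10(model) - log10(observed) at n = 1..4.
    """

    p: float
    A: float
    B: float
    residuals: np.ndarray

    def log10_expected(self, n: int) -> float:
        """log10 of the background-only expectation p^n * A."""
        return n * np.log10(self.p) + np.log10(self.A)

    def expected_background(self, n: int) -> float:
        return float(10.0 ** self.log10_expected(n))


def _model_log10(theta: np.ndarray, n: np.ndarray) -> np.ndarray:
    p, log10_a, b = theta
    background = 10.0 ** (n * np.log10(p) + log10_a)
    return np.log10(background + b)


def _initial_guesses(obs: np.ndarray) -> list[np.ndarray]:
    """Deterministic starting points for (p, log10 A, B).

    The first start inverts the model exactly through successive differences
    (N(n) - N(n+1) = p^n * A * (1-p), so B cancels); it lands on the truth for
    any noiseless admissible table.  The second assumes B = 0 (p = N2/N1),
    which is robust when the differences are noise-dominated.
    """
    guesses = []
    d = -np.diff(obs)
    if np.all(d > 0):
        p0 = d[1] / d[0]
        if 0 < p0 < 1:
            a0 = d[0] / (p0 * (1 - p0))
            b0 = max(obs[0] - p0 * a0, 0.0)
            guesses.append(np.array([p0, np.log10(a0), b0]))
    p1 = obs[1] / obs[0]
    if 0 < p1 < 1:
        guesses.append(np.array([p1, np.log10(obs[0] ** 2 / obs[1]), 0.0]))
    return guesses


def fit_background(counts: CountTable, label: str = "") -> BackgroundFit:
    """Fit (p, A, B) to N(1)..N(4) by least squares on log10 counts.

    The loss is on the log scale because the four counts span orders of
    magnitude; a linear-scale loss would fit N(1) only.  Box constraints
    0 < p < 1, A > 0, B >= 0 are enforced; the optimizer is started from the
    deterministic guesses of :func:`_initial_guesses` (no random restarts)
    and the lowest-objective solution is kept, so fitting is reproducible.

    Raises
    ------
    InsufficientBackgroundError
        If N(1)..N(4) are not all positive and strictly decreasing.
    FitConvergenceError
        If no optimizer start converges.
    """
    where = f" in {label}" if label else ""
    if counts.n_max < 4:
        raise InsufficientBackgroundError(
            f"insufficient background depth{where}: no region reaches depth 4"
        )
    obs = counts.counts[:4].astype(float)
    if np.any(obs <= 0) or np.any(np.diff(obs) >= 0):
        raise InsufficientBackgroundError(
            f"insufficient background depth{where}: N(1..4)={obs.tolist()} "
            "must be positive and strictly decreasing"
        )
    log_obs = np.log10(obs)

    def residual(theta: np.ndarray) -> np.ndarray:
        return _model_log10(theta, _FIT_DEPTHS) - log_obs

    eps = 1e-12
    lower = np.array([eps, -12.0, 0.0])
    upper = np.array([1.0 - eps, 18.0, np.inf])

    best_theta: Optional[np.ndarray] = None
    best_cost = np.inf
    for guess in _initial_guesses(obs):
        theta0 = np.clip(guess, lower, upper)
        # the algebraic start may already be the exact solution
        start_cost = float(np.sum(residual(theta0) ** 2))
        if start_cost < best_cost:
            best_cost, best_theta = start_cost, theta0
        try:
            result = least_squares(
                residual,
                theta0,
                bounds=(lower, upper),
                method="trf",
                xtol=1e-15,
                ftol=1e-15,
                gtol=1e-15,
                max_nfev=2000,
            )
        except Exception:  # noqa: BLE001 - one start failing is not fatal
            continue
        if result.success and result.cost * 2 < best_cost:
            best_cost, best_theta = result.cost * 2, result.x

    if best_theta is None:
        raise FitConvergenceError(
            f"background fit did not converge{where}; observed N(1..4)={obs.tolist()}"
        )
    p, log10_a, b = best_theta
    return BackgroundFit(
        p=float(p),
        A=float(10.0 ** log10_a),
        B=float(b),
        residuals=residual(best_theta),
    )


def log10_excess_ratio(n_obs: float, fit: BackgroundFit, n: int) -> float:
    """log10 ER(n) = log10 N_obs(n) - log10(p^n * A).

    Computed in log space so that deep peaks (where p^n * A underflows) keep
    a finite, meaningful significance.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n_obs < 0:
        raise ValueError("observed count must be >= 0")
    if n_obs == 0:
        return -np.inf
    return float(np.log10(n_obs) - fit.log10_expected(n))


def excess_ratio(n_obs: float, fit: BackgroundFit, n: int) -> float:
    """ER(n) = N_obs(n) / (p^n * A); 0 when nothing was observed."""
    if n_obs == 0:
        if n < 1:
            raise ValueError("n must be >= 1")
        return 0.0
    log_er = log10_excess_ratio(n_obs, fit, n)
    if log_er > 300:
        return np.inf
    return float(10.0 ** log_er)


def assign_significance(
    regions: Sequence[Region],
    counts: CountTable,
    fit: BackgroundFit,
    statistic: str = "depth",
) -> list[Region]:
    """Fill ``log_er`` on every region from its depth class.

    All regions of equal depth n receive the same significance
    log10(N_obs(n) / (p^n * A)): the excess ratio depends only on the read
    density of the peak and the global noise level, not on the peak's
    location.  Modifies the regions in place and returns them.
    """
    for region in regions:
        n = region.max_depth if statistic == "depth" else region.tag_count
        n_obs = counts.n(n)
        if n_obs <= 0:
            raise ValueError(
                f"count table does not cover depth {n} "
                f"(region {region.chrom}:{region.start}-{region.end})"
            )
        region.log_er = log10_excess_ratio(n_obs, fit, n)
    return list(regions)
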