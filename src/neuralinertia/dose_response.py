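"""Population concentration-response tables, constrained Hill fits, and the
chamber washin helper.

Per-fly endpoint calls are aggregated into one cumulative table per limb:

- ascending limb: the fraction anesthetized at step concentration ``c`` is the
  fraction of flies whose induction concentration is <= ``c``;
- descending limb: the fraction anesthetized at ``c`` is the fraction of flies
  whose emergence concentration is strictly below ``c``, plus all flies that
  never emerged (never-emergers stay anesthetized at every descending step).

Curves are fit to the Hill equation with the bottom plateau constrained to
zero while the top plateau, EC50 and Hill coefficient are free::

    increasing:  F(c) = top * c**n / (c**n + EC50**n)
    decreasing:  F(c) = top * EC50**n / (c**n + EC50**n)

The ascending limb is fit directly as fraction anesthetized (increasing).
The descending limb is fit in the fraction-*emerged* parameterization
(decreasing): its bottom is genuinely zero at high concentration, and its
fitted ``top`` is the fraction of the cohort that ever emerges, so
never-emergers surface as a top below one rather than a nonzero bottom.  Use
:meth:`HillResults.anesthetized_fraction` to evaluate either fit on the common
fraction-anesthetized scale.

``EC_p`` is defined relative to the fitted top plateau (p% of top), which
keeps EC_99 finite when the top is below one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .endpoints import EndpointCall
from .io_monitor import ConcentrationProtocol

__all__ = [
    "DoseResponseTable",
    "HillModel",
    "HillResults",
    "HillFitError",
    "WashinParams",
    "aggregate",
    "fit_hill",
    "ec_p",
    "washin_time",
]


class HillFitError(RuntimeError):
    """Raised when a Hill fit cannot be performed or does not converge.

    Carries the best attempt (if any) on the ``best`` attribute.
    """

    def __init__(self, message: str, best: "HillResults | None" = None):
        super().__init__(message)
        self.best = best


@dataclass
class DoseResponseTable:
    """Cumulative population response per protocol step for one limb.

    ``fraction`` is the fraction *anesthetized* at each concentration for both
    limbs.
    """

    limb: str
    concentration: np.ndarray
    n_total: np.ndarray
    n_responding: np.ndarray

    def __post_init__(self) -> None:
        self.concentration = np.asarray(self.concentration, dtype=float)
        self.n_total = np.asarray(self.n_total, dtype=np.int64)
        self.n_responding = np.asarray(self.n_responding, dtype=np.int64)
        if not (
            self.concentration.shape == self.n_total.shape == self.n_responding.shape
        ):
            raise ValueError("table columns must have equal length")
        if np.any(self.n_responding < 0) or np.any(self.n_responding > self.n_total):
            raise ValueError("need 0 <= n_responding <= n_total")

    @property
    def fraction(self) -> np.ndarray:
        return self.n_responding / self.n_total

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "limb": self.limb,
                "concentration": self.concentration,
                "n_total": self.n_total,
                "n_responding": self.n_responding,
                "fraction": self.fraction,
            }
        )


def aggregate(
    calls: Iterable[EndpointCall],
    protocol: ConcentrationProtocol,
    limb: str,
) -> DoseResponseTable:
    """Aggregate endpoint calls into a cumulative dose-response table.

    Excluded calls are dropped, with one exception: flies excluded for 24-h
    non-recovery are genuine never-emergers and are retained in the
    descending-limb denominator (they contribute to the emergence top
    constant but have no induction data usable on the ascending limb).
    """
    if limb not in ("ascending", "descending"):
        raise ValueError("limb must be 'ascending' or 'descending'")
    calls = list(calls)
    concs = np.unique(
        [s.concentration for s in protocol.steps if s.limb == limb]
    )
    if limb == "ascending":
        usable = [c for c in calls if not c.excluded]
        if not usable:
            raise ValueError("no usable (non-excluded) flies on the ascending limb")
        n = len(usable)
        resp = np.array(
            [
                sum(
                    1
                    for c in usable
                    if c.inducted and c.induction_conc is not None
                    and c.induction_conc <= conc + 1e-12
                )
                for conc in concs
            ]
        )
    else:
        usable = [
            c
            for c in calls
            if (not c.excluded or c.exclusion_reason == "no_24h_recovery")
            and (c.inducted or c.exclusion_reason == "no_24h_recovery")
        ]
        if not usable:
            raise ValueError("no usable flies on the descending limb")
        n = len(usable)
        resp = np.array(
            [
                sum(
                    1
                    for c in usable
                    if (not c.emerged)
                    or (c.emergence_conc is not None and c.emergence_conc < conc - 1e-12)
                )
                for conc in concs
            ]
        )
    return DoseResponseTable(
        limb=limb,
        concentration=concs,
        n_total=np.full(concs.shape, n, dtype=np.int64),
        n_responding=resp,
    )


# ---------------------------------------------------------------------------
# Hill model


def _hill(c, ec50, n, top, direction):
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        ratio = np.where(c > 0, (c / ec50) ** n, 0.0)
    if direction == "increasing":
        return top * ratio / (1.0 + ratio)
    return top / (1.0 + ratio)


class HillModel:
    """Three-parameter Hill curve (bottom constrained to zero) for binned
    population response fractions.

    Parameters
    ----------
    concentration, response : array-like
        Observed concentrations (vol% atm) and response fractions in [0, 1].
    direction : {"increasing", "decreasing"}
        Whether the response rises or falls with concentration.
    binomial_weights : bool
        Optional inverse-variance weighting by ``n_total`` (off by default;
        the default fit is unweighted least squares).
    n_total : array-like, optional
        Flies per concentration, required for binomial weighting.
    """

    def __init__(
        self,
        concentration: Sequence[float],
        response: Sequence[float],
        *,
        direction: str = "increasing",
        binomial_weights: bool = False,
        n_total: Sequence[int] | None = None,
    ):
        self.concentration = np.asarray(concentration, dtype=float)
        self.response = np.asarray(response, dtype=float)
        if direction not in ("increasing", "decreasing"):
            raise ValueError("direction must be 'increasing' or 'decreasing'")
        self.direction = direction
        if self.concentration.shape != self.response.shape:
            raise ValueError("concentration and response must have equal length")
        if np.unique(self.concentration).size < 4:
            raise HillFitError("need >= 4 distinct concentrations to fit a Hill curve")
        if np.any(self.response < -1e-9) or np.any(self.response > 1 + 1e-9):
            raise ValueError("response fractions must lie in [0, 1]")
        self.weights = None
        if binomial_weights:
            if n_total is None:
                raise ValueError("binomial weighting requires n_total")
            p = np.clip(self.response, 0.02, 0.98)
            self.weights = np.sqrt(np.asarray(n_total, float) / (p * (1 - p)))

    @classmethod
    def from_table(
        cls, table: DoseResponseTable, *, binomial_weights: bool = False
    ) -> "HillModel":
        """Build the conventional model for a limb table.

        Ascending tables are fit as fraction anesthetized (increasing);
        descending tables are fit as fraction emerged = 1 - fraction
        anesthetized (decreasing, bottom genuinely zero).
        """
        if table.limb == "ascending":
            return cls(
                table.concentration,
                table.fraction,
                direction="increasing",
                binomial_weights=binomial_weights,
                n_total=table.n_total,
            )
        return cls(
            table.concentration,
            1.0 - table.fraction,
            direction="decreasing",
            binomial_weights=binomial_weights,
            n_total=table.n_total,
        )

    def fit(
        self,
        *,
        n_ec50_starts: int = 20,
        hill_starts: Sequence[float] = (1.0, 2.0, 4.0, 8.0),
    ) -> "HillResults":
        """Multistart bounded least squares.

        EC50 starting values are log-spaced over the observed (positive)
        concentration range; the top starts at the maximum observed response.
        Raises :class:`HillFitError` on degenerate data or if no start
        converges.
        """
        y = self.response
        if np.ptp(y) < 1e-9 or np.all(y < 1e-9) or np.all(y > 1 - 1e-9):
            raise HillFitError("no transition observed (responses are flat)")
        pos = self.concentration[self.concentration > 0]
        lo, hi = pos.min(), pos.max()
        if hi <= lo:
            ec50_grid = np.array([lo])
        else:
            ec50_grid = np.geomspace(lo, hi, n_ec50_starts)
        top0 = float(np.clip(y.max(), 0.05, 1.0))

        w = self.weights

        def residuals(theta):
            ec50, n, top = theta
            r = _hill(self.concentration, ec50, n, top, self.direction) - y
            return r * w if w is not None else r

        bounds = ([1e-9, 1e-3, 1e-6], [1e6, 60.0, 1.0])
        attempts = []
        for ec50_0 in ec50_grid:
            for n0 in hill_starts:
                try:
                    attempts.append(
                        optimize.least_squares(
                            residuals,
                            x0=[ec50_0, n0, top0],
                            bounds=bounds,
                            method="trf",
                            xtol=1e-12,
                            ftol=1e-12,
                            gtol=1e-10,
                        )
                    )
                except Exception:
                    continue
        if not attempts:
            raise HillFitError("Hill fit failed from every starting point")
        best_cost = min(r.cost for r in attempts)
        # Convergence: a clean termination in the best basin, or several
        # independent starts agreeing on the same minimum (steep transitions
        # leave the slope weakly identified, so starts may stop on the
        # iteration cap at the minimum without satisfying gtol).
        basin = [r for r in attempts if r.cost <= best_cost * (1 + 1e-6) + 1e-15]
        winners = [r for r in basin if r.success]
        # A near-interpolating fit (RSS ~ 0) is converged even if the
        # optimizer never trips its relative criteria while sliding along the
        # slope bound.
        any_success = bool(winners) or len(basin) >= 2 or best_cost < 1e-10
        best = min(winners or basin, key=lambda r: r.cost)

        ec50, n, top = best.x
        rss = float(2 * best.cost)
        dof = max(y.size - 3, 1)
        jtj = best.jac.T @ best.jac
        try:
            cov = np.linalg.pinv(jtj) * (rss / dof)
        except np.linalg.LinAlgError:
            cov = np.full((3, 3), np.nan)
        results = HillResults(
            ec50=float(ec50),
            hill_n=float(n),
            top=float(top),
            direction=self.direction,
            residual_ss=rss,
            converged=bool(any_success),
            param_cov=cov,
            nobs=int(y.size),
            model=self,
        )
        if not any_success:
            raise HillFitError(
                "Hill fit did not converge after multistart", best=results
            )
        return results


@dataclass
class HillResults:
    """Fitted constrained Hill curve.

    ``top`` is the upper plateau of the fitted response (for descending fits
    the response is the fraction emerged, so ``top`` estimates the fraction of
    the cohort that ever emerges).  ``param_cov`` is ordered
    (EC50, hill_n, top).
    """

    ec50: float
    hill_n: float
    top: float
    direction: str
    residual_ss: float
    converged: bool
    param_cov: np.ndarray
    nobs: int = 0
    model: HillModel | None = None
    bottom: float = 0.0  # constrained, kept for the record

    @property
    def bse(self) -> np.ndarray:
        """Asymptotic standard errors of (EC50, hill_n, top)."""
        with np.errstate(invalid="ignore"):
            return np.sqrt(np.diag(self.param_cov))

    def predict(self, concentration) -> np.ndarray:
        """Fitted response at the given concentration(s)."""
        return _hill(concentration, self.ec50, self.hill_n, self.top, self.direction)

    def anesthetized_fraction(self, concentration) -> np.ndarray:
        """Fitted fraction anesthetized, regardless of fit orientation."""
        f = self.predict(concentration)
        return f if self.direction == "increasing" else 1.0 - f

    def ec_p(self, p: float) -> float:
        return ec_p(self, p)

    def summary(self) -> str:
        se = self.bse
        lines = [
            "Hill fit (bottom constrained to 0)",
            "-" * 46,
            f"direction      {self.direction}",
            f"n obs          {self.nobs}",
            f"EC50           {self.ec50:10.4f}  (se {se[0]:.4f})",
            f"Hill n         {self.hill_n:10.4f}  (se {se[1]:.4f})",
            f"top            {self.top:10.4f}  (se {se[2]:.4f})",
            f"residual SS    {self.residual_ss:10.3e}",
            f"converged      {self.converged}",
        ]
        return "\n".join(lines)


def fit_hill(
    table: DoseResponseTable,
    *,
    binomial_weights: bool = False,
    n_ec50_starts: int = 20,
    hill_starts: Sequence[float] = (1.0, 2.0, 4.0, 8.0),
) -> HillResults:
    """Fit the conventional Hill curve for a limb table (see HillModel)."""
    model = HillModel.from_table(table, binomial_weights=binomial_weights)
    return model.fit(n_ec50_starts=n_ec50_starts, hill_starts=hill_starts)


def ec_p(fit: HillResults, p: float) -> float:
    """Concentration at which the fitted response reaches p% of its top.

    ``EC_p = EC50 * (p / (100 - p)) ** (1 / n)`` for increasing fits, with the
    reciprocal exponent for decreasing fits.  ``ec_p(50)`` is exactly EC50.
    """
    if not 0 < p < 100:
        raise ValueError("p must lie strictly between 0 and 100")
    expo = 1.0 / fit.hill_n
    if fit.direction == "decreasing":
        expo = -expo
    return float(fit.ec50 * (p / (100.0 - p)) ** expo)


# ---------------------------------------------------------------------------
# Washin


@dataclass(frozen=True)
class WashinParams:
    """Single-compartment gas exchange: tube volume (ml), flow (ml/min), and
    the tolerated fractional distance from the inflow concentration."""

    volume: float = 0.75
    flow: float = 15.0
    tolerance_fraction: float = 0.0025

    def __post_init__(self) -> None:
        if not (self.volume > 0 and self.flow > 0):
            raise ValueError("volume and flow must be positive")
        if not 0 < self.tolerance_fraction < 1:
            raise ValueError("tolerance_fraction must lie in (0, 1)")


def washin_time(params: WashinParams = WashinParams()) -> float:
    """Seconds for a well-mixed tube to reach (1 - tolerance) of the inflow.

    The chamber obeys c(t) = c_in (1 - exp(-Q t / V)), so
    t = (V / Q) ln(1 / tolerance).  With the default 0.75 ml tube at
    15 ml/min, 99.75% equilibration takes just under 18 s.
    """
    minutes = (params.volume / params.flow) * math.log(1.0 / params.tolerance_fraction)
    return minutes * 60.0
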