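"""Neural inertia: the area between induction and emergence curves.

Neural inertia quantifies the barrier separating wakefulness from
anesthetic-induced immobility.  Operationally it is the area between the
population induction and emergence concentration-response curves (both on the
fraction-anesthetized scale), integrated from the induction curve's EC_1 up
to the emergence curve's EC_99, in units of vol% atm x probability.

Conventions for degenerate hysteresis: when the integration bounds invert
(emergence at concentrations at or above induction, as in na/unc79-like
collapse) the reported value is floored at zero, but the raw signed area is
always computed and reported alongside as a diagnostic.

Standard errors come from a nonparametric fly-level bootstrap: flies are
resampled with replacement, both limbs are re-aggregated and re-fit, and the
area is recomputed per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import integrate, stats

from .dose_response import (
    DoseResponseTable,
    HillFitError,
    HillResults,
    aggregate,
    ec_p,
    fit_hill,
)
from .endpoints import EndpointCall, apply_exclusions, call_endpoints
from .io_monitor import ActivityTrace, AlignedTrace, ConcentrationProtocol, align_to_protocol

__all__ = [
    "InertiaResult",
    "GroupComparison",
    "neural_inertia",
    "bootstrap_inertia",
    "compare_groups",
    "NeuralInertiaModel",
    "NeuralInertiaResults",
]


@dataclass
class InertiaResult:
    """Area between the induction and emergence curves.

    ``value`` is floored at zero when bounds invert; ``signed_value`` is the
    raw signed integral over [min(bounds), max(bounds)].  ``se`` is the
    bootstrap standard error when available.
    """

    value: float
    signed_value: float
    lower_bound: float  # induction EC_1 (vol% atm)
    upper_bound: float  # emergence EC_99 (vol% atm)
    bounds_inverted: bool = False
    se: float | None = None
    boot_mean: float | None = None
    n_boot: int = 0
    n_failed: int = 0
    seed: int | None = None


def _anesthetized_ec(fit: HillResults, p: float) -> float:
    """EC_p measured on the fraction-anesthetized orientation of a fit."""
    if fit.direction == "increasing":
        return ec_p(fit, p)
    return ec_p(fit, 100.0 - p)


def neural_inertia(
    fit_induction: HillResults, fit_emergence: HillResults
) -> InertiaResult:
    """Integrate the gap between the emergence and induction curves.

    Both fits are evaluated on the fraction-anesthetized scale; the integrand
    is ``F_emergence(c) - F_induction(c)`` over [induction EC_1, emergence
    EC_99], computed by adaptive quadrature (absolute tolerance <= 1e-8).
    """
    for name, fit in (("induction", fit_induction), ("emergence", fit_emergence)):
        if not fit.converged:
            raise ValueError(f"{name} fit did not converge; refusing to integrate")
    lower = _anesthetized_ec(fit_induction, 1.0)
    upper = _anesthetized_ec(fit_emergence, 99.0)

    def integrand(c):
        return fit_emergence.anesthetized_fraction(c) - fit_induction.anesthetized_fraction(c)

    lo, hi = min(lower, upper), max(lower, upper)
    if hi - lo < 1e-15:
        signed = 0.0
    else:
        signed, _ = integrate.quad(integrand, lo, hi, epsabs=1e-10, limit=500)
        signed = float(signed)
    inverted = lower >= upper
    value = 0.0 if (inverted or signed < 0) else signed
    if inverted:
        # Report the (typically negative) area with the sign it would carry
        # when traversed from the inverted bounds.
        signed = -abs(signed) if signed != 0 else 0.0
    return InertiaResult(
        value=value,
        signed_value=signed,
        lower_bound=lower,
        upper_bound=upper,
        bounds_inverted=inverted,
    )


def _fit_both_limbs(
    calls: Sequence[EndpointCall],
    protocol: ConcentrationProtocol,
    *,
    n_ec50_starts: int,
    hill_starts: Sequence[float],
) -> tuple[HillResults, HillResults]:
    t_asc = aggregate(calls, protocol, "ascending")
    t_desc = aggregate(calls, protocol, "descending")
    kw = dict(n_ec50_starts=n_ec50_starts, hill_starts=hill_starts)
    return fit_hill(t_asc, **kw), fit_hill(t_desc, **kw)


def bootstrap_inertia(
    calls: Sequence[EndpointCall],
    protocol: ConcentrationProtocol,
    *,
    n_boot: int = 1000,
    seed: int | None = None,
    n_ec50_starts: int = 5,
    hill_starts: Sequence[float] = (2.0, 6.0),
    max_failure_fraction: float = 0.2,
) -> InertiaResult:
    """Fly-level bootstrap of the neural-inertia area.

    The point estimate comes from the full cohort; ``se`` is the standard
    deviation of the replicate areas.  Replicates whose Hill fits fail (for
    example a resample with no observed transition) are dropped and counted;
    more than ``max_failure_fraction`` failures raises.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100 for a stable standard error")
    calls = list(calls)
    fit_i, fit_e = _fit_both_limbs(
        calls, protocol, n_ec50_starts=20, hill_starts=(1.0, 2.0, 4.0, 8.0)
    )
    point = neural_inertia(fit_i, fit_e)

    rng = np.random.default_rng(seed)
    values = []
    failed = 0
    n = len(calls)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sample = [calls[i] for i in idx]
        try:
            bi, be = _fit_both_limbs(
                sample, protocol, n_ec50_starts=n_ec50_starts, hill_starts=hill_starts
            )
            values.append(neural_inertia(bi, be).value)
        except (HillFitError, ValueError):
            failed += 1
    if failed > max_failure_fraction * n_boot:
        raise RuntimeError(
            f"{failed}/{n_boot} bootstrap replicates failed to fit; the cohort "
            "is too small or too degenerate for a bootstrap standard error"
        )
    se = float(np.std(values, ddof=1)) if len(values) > 1 else None
    return InertiaResult(
        value=point.value,
        signed_value=point.signed_value,
        lower_bound=point.lower_bound,
        upper_bound=point.upper_bound,
        bounds_inverted=point.bounds_inverted,
        se=se,
        boot_mean=float(np.mean(values)) if values else None,
        n_boot=len(values),
        n_failed=failed,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Group comparisons


@dataclass
class GroupComparison:
    groups: tuple[str, ...]
    statistic_name: str
    statistic: float
    p_value: float
    adjusted: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p_value must lie in [0, 1]")


def compare_groups(
    values_by_group: Mapping[str, Sequence[float]],
    method: str = "anova_bonferroni",
) -> list[GroupComparison]:
    """Run the standard group comparisons used for inertia and log(EC50).

    ``anova_bonferroni``: one-way ANOVA across all groups followed by all
    pairwise unpaired t-tests with Bonferroni-adjusted p-values.
    ``t_test``: pairwise unpaired two-tailed t-tests, unadjusted.
    ``mann_whitney``: pairwise two-sided Mann-Whitney U tests, unadjusted.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for name, vals in groups.items():
        if vals.size < 2:
            raise ValueError(f"group {name!r} needs >= 2 values")
    names = list(groups)
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    out: list[GroupComparison] = []
    if method == "anova_bonferroni":
        f, p = stats.f_oneway(*groups.values())
        out.append(GroupComparison(tuple(names), "anova_F", float(f), float(p)))
        m = len(pairs)
        for a, b in pairs:
            t, p = stats.ttest_ind(groups[a], groups[b])
            out.append(
                GroupComparison(
                    (a, b), "t", float(t), float(min(1.0, m * p)), adjusted=True
                )
            )
    elif method == "t_test":
        for a, b in pairs:
            t, p = stats.ttest_ind(groups[a], groups[b])
            out.append(GroupComparison((a, b), "t", float(t), float(p)))
    elif method == "mann_whitney":
        for a, b in pairs:
            u, p = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
            out.append(GroupComparison((a, b), "U", float(u), float(p)))
    else:
        raise ValueError(
            "method must be one of 'anova_bonferroni', 't_test', 'mann_whitney'"
        )
    return out


# ---------------------------------------------------------------------------
# Top-level model object


class NeuralInertiaModel:
    """End-to-end cohort analysis: endpoint calls -> Hill fits -> inertia.

    Build from already-called endpoints, or from raw traces with
    :meth:`from_traces` (which aligns, calls endpoints and applies the
    exclusion filters).  ``fit`` returns a :class:`NeuralInertiaResults`.
    """

    def __init__(
        self,
        calls: Sequence[EndpointCall],
        protocol: ConcentrationProtocol,
        *,
        group: str = "",
    ):
        self.calls = list(calls)
        if not self.calls:
            raise ValueError("empty cohort")
        self.protocol = protocol
        self.group = group

    @classmethod
    def from_traces(
        cls,
        traces: Iterable[ActivityTrace],
        protocol: ConcentrationProtocol,
        *,
        persistence: bool = True,
        missing_as_inactive: bool = False,
        group: str = "",
    ) -> "NeuralInertiaModel":
        calls = []
        for trace in traces:
            aligned = align_to_protocol(trace, protocol)
            call = call_endpoints(
                aligned, persistence=persistence, missing_as_inactive=missing_as_inactive
            )
            calls.append(
                apply_exclusions(aligned, call, missing_as_inactive=missing_as_inactive)
            )
        return cls(calls, protocol, group=group)

    def fit(
        self,
        *,
        n_boot: int = 0,
        seed: int | None = None,
        binomial_weights: bool = False,
    ) -> "NeuralInertiaResults":
        t_asc = aggregate(self.calls, self.protocol, "ascending")
        t_desc = aggregate(self.calls, self.protocol, "descending")
        fit_i = fit_hill(t_asc, binomial_weights=binomial_weights)
        fit_e = fit_hill(t_desc, binomial_weights=binomial_weights)
        if n_boot:
            inertia = bootstrap_inertia(
                self.calls, self.protocol, n_boot=n_boot, seed=seed
            )
        else:
            inertia = neural_inertia(fit_i, fit_e)
        excl = {}
        for c in self.calls:
            if c.excluded:
                excl[c.exclusion_reason] = excl.get(c.exclusion_reason, 0) + 1
        return NeuralInertiaResults(
            model=self,
            induction=fit_i,
            emergence=fit_e,
            inertia=inertia,
            table_ascending=t_asc,
            table_descending=t_desc,
            n_flies=len(self.calls),
            exclusions=excl,
        )


@dataclass
class NeuralInertiaResults:
    model: NeuralInertiaModel
    induction: HillResults
    emergence: HillResults
    inertia: InertiaResult
    table_ascending: DoseResponseTable
    table_descending: DoseResponseTable
    n_flies: int
    exclusions: dict = field(default_factory=dict)

    def summary(self) -> str:
        g = self.model.group or "(unlabeled cohort)"
        i, e, a = self.induction, self.emergence, self.inertia
        se = f"{a.se:.4f}" if a.se is not None else "n/a"
        n_excl = sum(self.exclusions.values())
        lines = [
            f"Neural inertia analysis: {g}",
            "=" * 54,
            f"flies                {self.n_flies} ({n_excl} excluded: {self.exclusions or 'none'})",
            f"induction EC50       {i.ec50:8.4f} vol%  (Hill n {i.hill_n:.2f}, top {i.top:.3f})",
            f"emergence EC50       {e.ec50:8.4f} vol%  (Hill n {e.hill_n:.2f}, top {e.top:.3f})",
            f"integration bounds   [{a.lower_bound:.4f}, {a.upper_bound:.4f}] vol%",
            f"neural inertia       {a.value:8.4f} vol% x prob  (se {se}, "
            f"signed {a.signed_value:.4f})",
        ]
        if a.bounds_inverted:
            lines.append("NOTE: bounds inverted (collapsed/inverted hysteresis); value floored at 0")
        return "\n".join(lines)

    def to_row(self) -> dict:
        """One results-table row: group, per-limb log(EC50) and top constants
        with standard errors, inertia with SE, and cohort size."""
        i, e, a = self.induction, self.emergence, self.inertia
        return {
            "group": self.model.group,
            "log_ec50_induction": float(np.log10(i.ec50)),
            "log_ec50_induction_se": float(i.bse[0] / (i.ec50 * np.log(10))),
            "top_induction": i.top,
            "log_ec50_emergence": float(np.log10(e.ec50)),
            "log_ec50_emergence_se": float(e.bse[0] / (e.ec50 * np.log(10))),
            "top_emergence": e.top,
            "inertia": a.value,
            "inertia_se": a.se,
            "n": self.n_flies,
        }

    def curve_dataframe(self, n_points: int = 200):
        """Fitted curves on a concentration grid, for plotting or export."""
        import pandas as pd

        concs = np.concatenate(
            [self.table_ascending.concentration, self.table_descending.concentration]
        )
        pos = concs[concs > 0]
        grid = np.linspace(0, float(pos.max()) * 1.1, n_points)
        return pd.DataFrame(
            {
                "concentration": grid,
                "induction_anesthetized": self.induction.anesthetized_fraction(grid),
                "emergence_anesthetized": self.emergence.anesthetized_fraction(grid),
            }
        )

    def plot(self, ax=None):
        """Induction/emergence curves with the inertia area shaded."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3.5))
        df = self.curve_dataframe()
        ax.plot(df.concentration, df.induction_anesthetized, "-", color="k",
                label="induction")
        ax.plot(df.concentration, df.emergence_anesthetized, "--", color="k",
                label="emergence")
        a = self.inertia
        if not a.bounds_inverted:
            sel = (df.concentration >= a.lower_bound) & (df.concentration <= a.upper_bound)
            ax.fill_between(
                df.concentration[sel],
                df.induction_anesthetized[sel],
                df.emergence_anesthetized[sel],
                alpha=0.25,
                color="tab:blue",
                label=f"inertia = {a.value:.3f}",
            )
        ax.plot(
            self.table_ascending.concentration, self.table_ascending.fraction,
            "o", color="k", ms=4,
        )
        ax.plot(
            self.table_descending.concentration, self.table_descending.fraction,
            "o", mfc="white", color="k", ms=4,
        )
        ax.set_xlabel("concentration (vol% atm)")
        ax.set_ylabel("fraction anesthetized")
        ax.legend(frameon=False, fontsize=8)
        return ax
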