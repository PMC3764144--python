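"""Firing-rate model of a 3-cell flip-flop arousal circuit.

Two wake-promoting cells (W1, W2) excite each other and inhibit a
wake-suppressing cell (A); A inhibits both W cells.  The anesthetic enters as
an additive input scaled by a per-cell signed coupling: negative on the W
cells (the drug suppresses arousal-promoting activity) and non-negative on A.
In the shipped defaults W1 - the cell that expresses both anesthetic
sensitivity genes - carries most of the drug coupling, W2 only a weak one,
and A none: W1 acts as the drug sensor that trips the W/A flip-flop, while
W2 retains residual, bias-sensitive activity during anesthesia whose
inhibition of A sets how easily the anesthetized state destabilizes.  Each
cell's activity x_i in (0, 1) relaxes toward a logistic function of its
total input:

    tau dx_i/dt = -x_i + sigma(gain * (sum_j w_ji x_j + b_i + d_i c))

with inhibitory weights entering negatively.  Mutual excitation within W and
mutual inhibition between W and A create bistability over a window of
concentrations: sweeping the concentration up and then down traverses
different branches, so the circuit becomes immobile (mean W activity below
``mobility_threshold``) at a higher concentration than the one at which it
recovers - hysteresis, the circuit-level analogue of neural inertia.

Mutation operators perturb intrinsic biases: ``sss`` (alias ``Sh``) excites
both W cells, which right-shifts induction and, because W2's residual
activity then suppresses A even during anesthesia, destabilizes the
anesthetized state and shrinks the hysteresis gap; ``na`` (alias ``unc79``)
suppresses W1 and A, which left-shifts induction and, by weakening A,
likewise shrinks the gap.

All numeric defaults are invented: the published content of the circuit is
its topology and sign structure, which the direction and collapse properties
pin down.  Defaults are chosen so that the bistable window lies inside the
standard 0-2 vol% titration range and the descending flip stays above zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .endpoints import EndpointCall
from .io_monitor import ConcentrationProtocol

__all__ = [
    "CircuitParams",
    "SweepResult",
    "relax",
    "sweep",
    "apply_mutation",
    "population_curves",
    "WAKE_STATE",
    "ANESTHESIA_STATE",
]

#: Canonical initial conditions for the two behavioral states.
WAKE_STATE = np.array([1.0, 1.0, 0.0])
ANESTHESIA_STATE = np.array([0.0, 0.0, 1.0])


@dataclass(frozen=True)
class CircuitParams:
    """Weights, biases, drug couplings and dynamics constants.

    State order is (W1, W2, A).  ``w_excite`` is the W1<->W2 mutual
    excitation, ``w_WA`` the strength of W->A inhibition (applied per W
    cell), ``w_AW`` the strength of A->W inhibition.  ``drug_coupling`` is
    the signed per-cell concentration coupling (negative for W, >= 0 for A).
    """

    w_excite: float = 0.45
    w_WA: float = 0.9
    w_AW: float = 0.6
    bias: tuple[float, float, float] = (1.1, 0.6, 0.8)
    drug_coupling: tuple[float, float, float] = (-1.0, -0.3, 0.0)
    gain: float = 6.0
    tau: float = 1.0
    mobility_threshold: float = 0.5

    def __post_init__(self) -> None:
        if min(self.w_excite, self.w_WA, self.w_AW) < 0:
            raise ValueError("weights must be >= 0")
        if not (self.gain > 0 and self.tau > 0):
            raise ValueError("gain and tau must be positive")
        if not 0 < self.mobility_threshold < 1:
            raise ValueError("mobility_threshold must lie in (0, 1)")

    def weight_matrix(self) -> np.ndarray:
        """Signed connection matrix W with W[i, j] the weight from j to i."""
        we, wa, aw = self.w_excite, self.w_WA, self.w_AW
        return np.array(
            [
                [0.0, we, -aw],
                [we, 0.0, -aw],
                [-wa, -wa, 0.0],
            ]
        )


def _sigma(u: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-u))


def relax(
    params: CircuitParams,
    c: float,
    initial_state: Sequence[float],
    *,
    tol: float = 1e-10,
    max_time: float = 5000.0,
    dt_factor: float = 0.2,
) -> np.ndarray:
    """Integrate the rate equations from ``initial_state`` to a fixed point.

    Forward-Euler relaxation with step ``dt_factor * tau``; converged when
    ``||dx/dt|| < tol``.  Raises on non-convergence (e.g. oscillation),
    reporting the residual trajectory norm.
    """
    x = np.asarray(initial_state, dtype=float).copy()
    if x.shape != (3,) or not np.all(np.isfinite(x)):
        raise ValueError("initial_state must be 3 finite activities")
    W = params.weight_matrix()
    b = np.asarray(params.bias, float)
    d = np.asarray(params.drug_coupling, float)
    g, tau = params.gain, params.tau
    dt = dt_factor * tau
    n_steps = int(max_time / dt)
    for _ in range(n_steps):
        target = _sigma(g * (W @ x + b + d * c))
        dxdt = (target - x) / tau
        norm = float(np.linalg.norm(dxdt))
        if norm < tol:
            return x
        x = x + dt * dxdt
    raise RuntimeError(
        f"relaxation did not converge within t={max_time}: ||dx/dt|| = {norm:.3e}"
    )


@dataclass
class SweepResult:
    """Adiabatic concentration sweep of the circuit."""

    direction: str  # "ascending" | "descending"
    concentration: np.ndarray
    activities: np.ndarray  # shape (n, 3): x_W1, x_W2, x_A
    mobile: np.ndarray  # bool per grid point
    transition_conc: float | None  # concentration at the mobility flip

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "concentration": self.concentration,
                "x_W1": self.activities[:, 0],
                "x_W2": self.activities[:, 1],
                "x_A": self.activities[:, 2],
                "mobile": self.mobile,
            }
        )


def sweep(
    params: CircuitParams,
    c_grid: Sequence[float],
    direction: str,
    *,
    initial_state: Sequence[float] | None = None,
) -> SweepResult:
    """Quasi-static titration: the steady state at each concentration seeds
    the next (adiabatic continuation), mirroring the stepwise assay.

    ``c_grid`` must be monotone in the stated direction.  The transition
    concentration is the first grid point at which the mobility flag flips
    from its initial value; if no flip occurs it is ``None``.
    """
    c_grid = np.asarray(c_grid, dtype=float)
    if direction == "ascending":
        if np.any(np.diff(c_grid) < 0):
            raise ValueError("ascending sweep needs a non-decreasing grid")
        x = WAKE_STATE.copy() if initial_state is None else np.asarray(initial_state, float)
    elif direction == "descending":
        if np.any(np.diff(c_grid) > 0):
            raise ValueError("descending sweep needs a non-increasing grid")
        x = ANESTHESIA_STATE.copy() if initial_state is None else np.asarray(initial_state, float)
    else:
        raise ValueError("direction must be 'ascending' or 'descending'")

    acts = np.empty((c_grid.size, 3))
    for i, c in enumerate(c_grid):
        x = relax(params, float(c), x)
        acts[i] = x
    mobile = acts[:, :2].mean(axis=1) >= params.mobility_threshold
    transition = None
    if mobile.size and np.any(mobile != mobile[0]):
        flip = int(np.argmax(mobile != mobile[0]))
        transition = float(c_grid[flip])
    return SweepResult(
        direction=direction,
        concentration=c_grid,
        activities=acts,
        mobile=mobile,
        transition_conc=transition,
    )


def circuit_to_yaml(params: CircuitParams, path) -> None:
    """Write the model configuration (weights, biases, couplings, dynamics)."""
    import yaml

    doc = {
        "circuit": {
            "w_excite": params.w_excite,
            "w_WA": params.w_WA,
            "w_AW": params.w_AW,
            "bias": list(params.bias),
            "drug_coupling": list(params.drug_coupling),
            "gain": params.gain,
            "tau": params.tau,
            "mobility_threshold": params.mobility_threshold,
        }
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def circuit_from_yaml(path) -> CircuitParams:
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    spec = doc["circuit"] if "circuit" in doc else doc
    spec = {
        **spec,
        "bias": tuple(spec["bias"]),
        "drug_coupling": tuple(spec["drug_coupling"]),
    }
    return CircuitParams(**spec)


_MUTATION_ALIASES = {"sss": "sss", "Sh": "sss", "na": "na", "unc79": "na"}


def apply_mutation(
    params: CircuitParams, gene: str, *, increment: float = 0.25
) -> CircuitParams:
    """Return the circuit perturbed by a loss-of-function mutation.

    ``sss`` (or its pathway partner ``Sh``) excites both W cells: biases of
    W1 and W2 rise by ``increment``.  ``na`` (or ``unc79``) suppresses the
    cells that express it, W1 and A: their biases fall by ``increment``.
    """
    key = _MUTATION_ALIASES.get(gene)
    if key is None:
        raise ValueError(
            f"unknown gene {gene!r}; valid: {', '.join(sorted(_MUTATION_ALIASES))}"
        )
    b1, b2, b3 = params.bias
    if key == "sss":
        bias = (b1 + increment, b2 + increment, b3)
    else:
        bias = (b1 - increment, b2, b3 - increment)
    return replace(params, bias=bias)


def population_curves(
    params: CircuitParams,
    *,
    jitter_sd: float = 0.15,
    n_flies: int = 100,
    protocol: ConcentrationProtocol,
    seed: int | None = None,
    genotype: str = "",
) -> list[EndpointCall]:
    """Per-fly circuit sweeps over the protocol's concentration steps.

    Each simulated fly receives a common Normal(0, jitter_sd^2) perturbation
    of both W biases (individual variability in arousal drive), is swept up
    the ascending and down the descending limb, and yields an EndpointCall:
    induction at the ascending mobility flip, emergence at the descending
    flip.  Flies whose sweep lacks a flip are flagged non-inducted or
    non-emerged.  The calls feed directly into aggregate/fit_hill/inertia.
    """
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    rng = np.random.default_rng(seed)
    asc = protocol.limb_concentrations("ascending")
    desc = protocol.limb_concentrations("descending")
    calls = []
    for i in range(n_flies):
        delta = rng.normal(0.0, jitter_sd) if jitter_sd else 0.0
        b1, b2, b3 = params.bias
        fly_params = replace(params, bias=(b1 + delta, b2 + delta, b3))
        up = sweep(fly_params, asc, "ascending")
        inducted = up.transition_conc is not None and up.mobile[0]
        induction_conc = up.transition_conc if inducted else None
        emerged = False
        emergence_conc = None
        if inducted:
            down = sweep(fly_params, desc, "descending")
            if down.mobile[0]:
                # already mobile at the highest descending step
                emerged = True
                emergence_conc = float(desc[0])
            elif down.transition_conc is not None:
                emerged = True
                emergence_conc = down.transition_conc
        calls.append(
            EndpointCall(
                fly_id=f"sim_{i:04d}",
                genotype=genotype,
                induction_conc=induction_conc,
                emergence_conc=emergence_conc,
                inducted=bool(inducted),
                emerged=emerged,
            )
        )
    return calls
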