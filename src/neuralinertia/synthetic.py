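"""Synthetic fly populations with the statistical structure the analysis
assumes.

Each fly carries a latent induction threshold and a latent emergence
threshold (vol% atm).  Induction log-thresholds are normal around
``log(induction_median)`` with spread ``induction_log_sd`` (thresholds are
positive and population dose-response curves are sigmoidal on a log axis, so
log-normal per-fly variability is the natural latent model).  The emergence
log-threshold sits ``hysteresis_log_shift`` below the induction log-threshold
on average - the hysteresis gap - with correlated per-fly noise
(``threshold_corr``) and the same marginal spread.  A ``p_never_emerge``
fraction of flies never resumes movement during the descending titration,
which surfaces as an emergence-curve top below one.

Forward model of the assay: while awake a fly alternates between wake and
sleep via a two-state Markov chain (per-bin transition probabilities
``sleep_transition``); in a wake bin it registers counts with probability
``p_active_bin``.  The fly becomes immobile from the first ascending bin
whose step concentration reaches its induction threshold and (unless it is a
never-emerger) resumes the wake chain from the first descending bin whose
concentration drops below its emergence threshold.  Anesthetized flies emit
exactly zero counts by default; set ``twitch_prob`` > 0 to add rare movement
artifacts.

Scenario presets reproduce the qualitative genotype shifts studied with this
assay: Sh/sss-like loss of function raises the induction median and collapses
the hysteresis gap; na-like lowers the induction median and collapses or
inverts the gap (with fragmented sleep/wake bouts); sleep deprivation leaves
induction untouched but widens the gap by lowering emergence thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io_monitor import ActivityTrace, ConcentrationProtocol, default_protocol

__all__ = [
    "PopulationParams",
    "FlyGroundTruth",
    "sample_population",
    "generate_traces",
    "scenario",
    "SCENARIOS",
]


@dataclass(frozen=True)
class PopulationParams:
    """Ground-truth population and assay-noise parameters.

    All concentrations in vol% atm, probabilities per 5-min bin.
    """

    n_flies: int = 100
    induction_median: float = 1.0
    induction_log_sd: float = 0.4
    hysteresis_log_shift: float = 0.5
    threshold_corr: float = 0.6
    p_never_emerge: float = 0.1
    p_active_bin: float = 0.9
    sleep_transition: tuple[float, float] = (0.03, 0.4)  # (wake->sleep, sleep->wake)
    twitch_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_flies < 1:
            raise ValueError("n_flies must be positive")
        vals = [
            self.induction_median,
            self.induction_log_sd,
            self.hysteresis_log_shift,
            self.threshold_corr,
            self.p_never_emerge,
            self.p_active_bin,
            *self.sleep_transition,
            self.twitch_prob,
        ]
        if not all(np.isfinite(vals)):
            raise ValueError("population parameters must be finite")
        if self.induction_median <= 0:
            raise ValueError("induction_median must be positive")
        if self.induction_log_sd < 0:
            raise ValueError("induction_log_sd must be >= 0")
        if not 0 <= self.threshold_corr <= 1:
            raise ValueError("threshold_corr must lie in [0, 1]")
        if not 0 <= self.p_never_emerge <= 1:
            raise ValueError("p_never_emerge must lie in [0, 1]")
        if not 0 < self.p_active_bin <= 1:
            raise ValueError("p_active_bin must lie in (0, 1]")
        pws, psw = self.sleep_transition
        if not (0 <= pws <= 1 and 0 <= psw <= 1):
            raise ValueError("sleep_transition probabilities must lie in [0, 1]")

    def noiseless(self) -> "PopulationParams":
        """Variant with deterministic waking activity: every awake bin
        registers movement and no naps occur.  Under these conditions the
        endpoint caller recovers each fly's threshold step exactly."""
        return replace(self, p_active_bin=1.0, sleep_transition=(0.0, 1.0))


@dataclass(frozen=True)
class FlyGroundTruth:
    fly_id: str
    induction_threshold: float
    emergence_threshold: float
    never_emerges: bool
    genotype: str = ""

    def __post_init__(self) -> None:
        if self.induction_threshold <= 0 or self.emergence_threshold <= 0:
            raise ValueError("thresholds must be positive")


def sample_population(params: PopulationParams) -> list[FlyGroundTruth]:
    """Draw per-fly latent thresholds.

    Induction: ``log T_ind ~ Normal(log median, sd)``.  Emergence:
    ``log T_em = log median - shift + sd * (rho * z_ind + sqrt(1 - rho^2) * z')``,
    i.e. same marginal spread, correlation ``rho`` with the induction
    log-threshold, and a median log-ratio T_ind/T_em equal to the shift.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_flies
    z_ind = rng.standard_normal(n)
    z_extra = rng.standard_normal(n)
    rho = params.threshold_corr
    log_med = np.log(params.induction_median)
    sd = params.induction_log_sd
    log_ind = log_med + sd * z_ind
    log_em = (
        log_med
        - params.hysteresis_log_shift
        + sd * (rho * z_ind + np.sqrt(1 - rho**2) * z_extra)
    )
    never = rng.random(n) < params.p_never_emerge
    return [
        FlyGroundTruth(
            fly_id=f"fly_{i:04d}",
            induction_threshold=float(np.exp(log_ind[i])),
            emergence_threshold=float(np.exp(log_em[i])),
            never_emerges=bool(never[i]),
        )
        for i in range(n)
    ]


def population_to_dataframe(population: Sequence[FlyGroundTruth]) -> pd.DataFrame:
    """Ground-truth export for test audits."""
    return pd.DataFrame(
        [
            {
                "fly_id": f.fly_id,
                "induction_threshold": f.induction_threshold,
                "emergence_threshold": f.emergence_threshold,
                "never_emerges": f.never_emerges,
            }
            for f in population
        ]
    )


def _expand_concentrations(
    protocol: ConcentrationProtocol, bin_minutes: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-bin concentration and limb code (0 pre, 1 asc, 2 desc, 3 post)."""
    per_step = protocol.bins_per_step(bin_minutes)
    n_pre = int(round(protocol.pre_window_minutes / bin_minutes))
    n_post = int(round(protocol.post_window_minutes / bin_minutes))
    conc = [0.0] * n_pre
    limb = [0] * n_pre
    for s, nb in zip(protocol.steps, per_step):
        conc += [s.concentration] * nb
        limb += [1 if s.limb == "ascending" else 2] * nb
    conc += [0.0] * n_post
    limb += [3] * n_post
    return np.array(conc), np.array(limb), np.array(per_step)


def generate_traces(
    population: Sequence[FlyGroundTruth],
    protocol: ConcentrationProtocol,
    params: PopulationParams,
    *,
    bin_minutes: float = 5.0,
    genotype: str = "",
) -> list[ActivityTrace]:
    """Simulate one activity trace per fly under the titration protocol.

    Traces cover pre-window + all dwells + post-window.  Flies start the
    pre-window awake (the assay is run at an activity peak), so with default
    parameters almost all traces pass the exclusion filters.
    """
    if not population:
        raise ValueError("empty population")
    conc, limb, _ = _expand_concentrations(protocol, bin_minutes)
    n_bins = conc.size
    p_ws, p_sw = params.sleep_transition
    traces = []
    for i, fly in enumerate(population):
        rng = np.random.default_rng([params.seed, 1000 + i])
        counts = np.zeros(n_bins, dtype=np.int64)
        awake = True  # wake/sleep chain state while not anesthetized
        anesthetized = False
        for b in range(n_bins):
            if limb[b] == 1 and conc[b] >= fly.induction_threshold:
                anesthetized = True
            if anesthetized and limb[b] == 2 and conc[b] < fly.emergence_threshold:
                if not fly.never_emerges:
                    anesthetized = False
                    awake = True
            if anesthetized or (fly.never_emerges and limb[b] == 3):
                if params.twitch_prob and rng.random() < params.twitch_prob:
                    counts[b] = 1
                continue
            if awake:
                if rng.random() < params.p_active_bin:
                    counts[b] = 1 + rng.poisson(2.0)
                if rng.random() < p_ws:
                    awake = False
            else:
                if rng.random() < p_sw:
                    awake = True
        traces.append(
            ActivityTrace(
                fly_id=fly.fly_id,
                counts=counts,
                genotype=genotype or fly.genotype,
                bin_minutes=bin_minutes,
                start_time=0.0,
            )
        )
    return traces


#: Scenario presets.  Values are chosen to reproduce the qualitative
#: direction of each manipulation, not any particular measured cohort.
SCENARIOS: dict[str, dict] = {
    "control": {},
    "Sh_like": {
        "induction_median": 1.45,
        "hysteresis_log_shift": 0.05,
        "p_never_emerge": 0.05,
    },
    "sss_like": {
        "induction_median": 1.4,
        "hysteresis_log_shift": 0.05,
        "p_never_emerge": 0.05,
    },
    "na_like": {
        "induction_median": 0.5,
        "hysteresis_log_shift": -0.1,
        "p_never_emerge": 0.05,
        "sleep_transition": (0.2, 0.6),
    },
    "sleep_deprived": {
        "induction_median": 1.0,
        "hysteresis_log_shift": 0.8,
    },
}


def params_to_yaml(params: PopulationParams, path) -> None:
    """Write population parameters in the same config namespace as protocols."""
    import yaml
    from dataclasses import asdict

    doc = {"population": {k: (list(v) if isinstance(v, tuple) else v)
                          for k, v in asdict(params).items()}}
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def params_from_yaml(path) -> PopulationParams:
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    spec = doc["population"] if "population" in doc else doc
    if "sleep_transition" in spec:
        spec = {**spec, "sleep_transition": tuple(spec["sleep_transition"])}
    return PopulationParams(**spec)


def scenario(name: str, **overrides) -> PopulationParams:
    """Preset population parameters for a named genotype/condition scenario.

    ``control``: baseline hysteresis.  ``Sh_like``/``sss_like``: raised
    induction median, collapsed hysteresis gap.  ``na_like``: lowered
    induction median, collapsed/inverted gap, fragmented sleep/wake.
    ``sleep_deprived``: induction unchanged, widened gap.  Keyword overrides
    (e.g. ``n_flies``, ``seed``) are applied on top of the preset.
    """
    if name not in SCENARIOS:
        raise ValueError(
            f"unknown scenario {name!r}; valid names: {', '.join(sorted(SCENARIOS))}"
        )
    kwargs = dict(SCENARIOS[name])
    kwargs.update(overrides)
    return PopulationParams(**kwargs)
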