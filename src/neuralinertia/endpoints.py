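"""Per-fly anesthesia endpoint calling, exclusion rules, and sleep scoring.

The behavioral endpoint is immobility in 5-minute binned locomotor data.
Counts are binarized (1 = any movement in the bin, 0 = none).  Induction is
the lowest ascending-limb concentration at which movement ceased for five or
more minutes; emergence is the highest descending-limb concentration at which
movement resumed.

Because a sleeping fly is also immobile, a transient >= 5-min zero run at a
low dose followed by renewed activity later in the ascending limb is, by
default, NOT called as induction: the default caller requires the immobility
run to persist for the remainder of the ascending limb (``persistence=True``).
The literal first->=5-min-run reading is available with ``persistence=False``.

Exclusion rules mirror the standard assay hygiene filters: flies inactive for
the final 15 minutes of the pre-window, inactive during the first 5 minutes at
the lowest dose, or failing to recover any activity in the 24 h post-window
are excluded from curve fitting.  A fly excluded for non-recovery is still a
genuine never-emerger and is counted as such when the descending-limb
population curve is aggregated (see :mod:`neuralinertia.dose_response`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .io_monitor import ActivityTrace, AlignedTrace

__all__ = [
    "EndpointCall",
    "SleepSummary",
    "binarize",
    "call_endpoints",
    "apply_exclusions",
    "score_sleep",
    "EXCLUSION_REASONS",
]

EXCLUSION_REASONS = ("none", "inactive_pre", "inactive_first_dose", "no_24h_recovery")


@dataclass
class EndpointCall:
    """Induction/emergence call for one fly.

    ``induction_conc`` / ``emergence_conc`` are in vol% atm, or ``None`` when
    undefined (non-inducted, non-emerged, or excluded).  ``emerged`` is False
    for never-emergers; ``inducted`` is False for flies that stayed mobile
    through the whole ascending limb.
    """

    fly_id: str
    induction_conc: float | None = None
    emergence_conc: float | None = None
    inducted: bool = False
    emerged: bool = False
    excluded: bool = False
    exclusion_reason: str = "none"
    genotype: str = ""

    def __post_init__(self) -> None:
        if self.exclusion_reason not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion reason {self.exclusion_reason!r}")
        if self.excluded and (
            self.induction_conc is not None or self.emergence_conc is not None
        ):
            raise ValueError("excluded calls must carry no endpoint concentrations")
        if not self.emerged and self.emergence_conc is not None:
            raise ValueError("non-emerged calls must carry no emergence concentration")


@dataclass
class SleepSummary:
    """Sleep/wake bout statistics for one fly over a scoring window.

    Sleep is any maximal run of inactive 5-min bins (every bout is therefore
    >= 5 min); wake bouts are maximal runs of active bins.
    """

    fly_id: str
    total_sleep_min: float
    bout_count: int
    mean_bout_min: float
    wake_bout_count: int
    mean_wake_bout_min: float


def binarize(trace: ActivityTrace, *, missing_as_inactive: bool = False) -> np.ndarray:
    """Convert counts to a 0/1 activity sequence (1 iff count > 0).

    Missing bins have no defined activity; pass ``missing_as_inactive=True``
    to score them as no-movement, otherwise a trace with missing bins raises.
    """
    act = (trace.counts > 0).astype(np.int8)
    if trace.has_missing():
        if not missing_as_inactive:
            raise ValueError(
                f"trace {trace.fly_id!r} has missing bins; pass "
                "missing_as_inactive=True to score them as immobile"
            )
        act[trace.missing] = 0
    return act


def _run_starts(values: np.ndarray, target: int) -> np.ndarray:
    """Indices where a maximal run of `target` begins."""
    isin = values == target
    prev = np.concatenate(([False], isin[:-1]))
    return np.flatnonzero(isin & ~prev)


def call_endpoints(
    aligned: AlignedTrace,
    *,
    persistence: bool = True,
    missing_as_inactive: bool = False,
) -> EndpointCall:
    """Call per-fly induction and emergence concentrations.

    Induction: concentration of the earliest ascending step containing a run
    of >= 5 min (>= 1 bin) of inactivity that, when ``persistence`` is True,
    persists for the remainder of the ascending limb.  Emergence:
    concentration of the earliest descending step (i.e. the highest
    descending concentration) containing an active bin; ``emerged=False`` if
    the descending limb shows no activity at all.
    """
    trace = aligned.trace
    act = binarize(trace, missing_as_inactive=missing_as_inactive)
    steps = aligned.protocol.steps
    labels = aligned.step_index_per_bin

    asc_bins = aligned.limb_bins("ascending")
    asc_act = act[asc_bins]

    induction_conc: float | None = None
    inducted = False
    if np.all(asc_act == 1):
        inducted = False  # never immobile during the ascending limb
    else:
        if persistence:
            active_idx = np.flatnonzero(asc_act)
            first_zero_after = active_idx[-1] + 1 if active_idx.size else 0
            if first_zero_after >= asc_act.size:
                inducted = False  # active through the very last ascending bin
            else:
                inducted = True
                bin_idx = asc_bins[first_zero_after]
                induction_conc = steps[labels[bin_idx]].concentration
        else:
            first_zero = int(np.flatnonzero(asc_act == 0)[0])
            inducted = True
            bin_idx = asc_bins[first_zero]
            induction_conc = steps[labels[bin_idx]].concentration

    desc_bins = aligned.limb_bins("descending")
    desc_act = act[desc_bins]
    emerged = bool(np.any(desc_act == 1))
    emergence_conc: float | None = None
    if emerged:
        first_active = int(np.flatnonzero(desc_act)[0])
        bin_idx = desc_bins[first_active]
        emergence_conc = steps[labels[bin_idx]].concentration

    return EndpointCall(
        fly_id=trace.fly_id,
        genotype=trace.genotype,
        induction_conc=induction_conc,
        emergence_conc=emergence_conc,
        inducted=inducted,
        emerged=emerged,
    )


def apply_exclusions(
    aligned: AlignedTrace,
    call: EndpointCall,
    *,
    missing_as_inactive: bool = False,
) -> EndpointCall:
    """Apply the assay exclusion filters to an endpoint call.

    Rules, in precedence order:

    - ``inactive_pre``: no movement during the final 15 min of the pre-window;
    - ``inactive_first_dose``: no movement during the first 5-min bin of the
      first ascending step;
    - ``no_24h_recovery``: the fly never emerged and shows no movement in the
      24 h post-window.

    An excluded call carries no endpoint concentrations; ``emerged`` is
    preserved so never-emergers can still inform the emergence curve's top.
    """
    trace = aligned.trace
    act = binarize(trace, missing_as_inactive=missing_as_inactive)
    bw = trace.bin_minutes

    reason = "none"
    pre = aligned.pre_bins
    n_last = max(int(np.ceil(15.0 / bw)), 1)
    last_pre = pre[-n_last:]
    if last_pre.size and np.all(act[last_pre] == 0):
        reason = "inactive_pre"
    else:
        first_step_bins = aligned.bins_of_step(0)
        if first_step_bins.size and act[first_step_bins[0]] == 0:
            reason = "inactive_first_dose"
        elif not call.emerged:
            post = aligned.post_bins
            needed = int(np.ceil(1440.0 / bw))
            if post.size < needed:
                warnings.warn(
                    f"fly {trace.fly_id!r}: non-emerged but the post-window is "
                    f"shorter than 24 h; recovery exclusion undecidable",
                    stacklevel=2,
                )
            elif np.all(act[post] == 0):
                reason = "no_24h_recovery"

    if reason == "none":
        return replace(call, excluded=False, exclusion_reason="none")
    return replace(
        call,
        induction_conc=None,
        emergence_conc=None,
        excluded=True,
        exclusion_reason=reason,
    )


def score_sleep(
    trace: ActivityTrace,
    *,
    window: tuple[float, float] | None = None,
    missing_as_inactive: bool = False,
) -> SleepSummary:
    """Score sleep as maximal runs of inactive bins (>= 5 min each).

    ``window`` restricts scoring to bins whose start time lies in
    ``[start, stop)`` zeitgeber minutes; by default the whole trace is scored.
    """
    act = binarize(trace, missing_as_inactive=missing_as_inactive)
    if window is not None:
        starts = trace.bin_starts
        sel = (starts >= window[0]) & (starts < window[1])
        act = act[sel]
    if act.size == 0:
        return SleepSummary(trace.fly_id, 0.0, 0, 0.0, 0, 0.0)

    bw = trace.bin_minutes
    sleep_starts = _run_starts(act, 0)
    wake_starts = _run_starts(act, 1)
    # A run starting at s ends at the next state change (or end of window).
    boundaries = np.concatenate(
        (np.flatnonzero(np.diff(act) != 0) + 1, [act.size])
    )

    def _run_lengths(starts: np.ndarray) -> np.ndarray:
        ends = np.searchsorted(boundaries, starts, side="right")
        return boundaries[ends] - starts

    sleep_lens = _run_lengths(sleep_starts) if sleep_starts.size else np.array([])
    wake_lens = _run_lengths(wake_starts) if wake_starts.size else np.array([])

    total_sleep = float(sleep_lens.sum() * bw) if sleep_lens.size else 0.0
    return SleepSummary(
        fly_id=trace.fly_id,
        total_sleep_min=total_sleep,
        bout_count=int(sleep_lens.size),
        mean_bout_min=float(sleep_lens.mean() * bw) if sleep_lens.size else 0.0,
        wake_bout_count=int(wake_lens.size),
        mean_wake_bout_min=float(wake_lens.mean() * bw) if wake_lens.size else 0.0,
    )


def sleep_to_dataframe(summaries: Iterable[SleepSummary]) -> pd.DataFrame:
    """Tabulate sleep summaries for CSV export."""
    return pd.DataFrame(
        [
            {
                "fly_id": s.fly_id,
                "total_sleep_min": s.total_sleep_min,
                "bout_count": s.bout_count,
                "mean_bout_min": s.mean_bout_min,
                "wake_bout_count": s.wake_bout_count,
                "mean_wake_bout_min": s.mean_wake_bout_min,
            }
            for s in summaries
        ]
    )


def calls_to_dataframe(calls: Iterable[EndpointCall]) -> pd.DataFrame:
    """Tabulate endpoint calls for CSV export / auditing."""
    return pd.DataFrame(
        [
            {
                "fly_id": c.fly_id,
                "genotype": c.genotype,
                "induction_conc": c.induction_conc,
                "emergence_conc": c.emergence_conc,
                "inducted": c.inducted,
                "emerged": c.emerged,
                "excluded": c.excluded,
                "exclusion_reason": c.exclusion_reason,
            }
            for c in calls
        ]
    )
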