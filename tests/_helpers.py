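"""Shared test helpers."""

import numpy as np

from neuralinertia.dose_response import HillResults


def make_fit(ec50, hill_n, top=1.0, direction="increasing"):
    """Construct a synthetic converged Hill fit with the given parameters."""
    return HillResults(
        ec50=ec50,
        hill_n=hill_n,
        top=top,
        direction=direction,
        residual_ss=0.0,
        converged=True,
        param_cov=np.zeros((3, 3)),
    )
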