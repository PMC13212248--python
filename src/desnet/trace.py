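"""Time-sampled propagation output shared by the open-system and classical engines."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import require

__all__ = ["PropagationTrace", "absorption_readout"]


@dataclass
class PropagationTrace:
    """Populations and cumulative sink absorption on a fixed output grid.

    ``target_absorption[k]`` is P_T(t_k), the total mass absorbed by target
    sinks up to time ``times[k]``; likewise ``distractor_absorption`` for
    P_D(t).  Both start at 0 and are nondecreasing.  ``site_populations``
    holds the diagonal of the graph block (shape ``n_times x n_nodes``).
    """

    times: np.ndarray
    site_populations: np.ndarray
    sink_populations: np.ndarray  # per-sink cumulative absorption, n_times x n_sinks
    target_absorption: np.ndarray
    distractor_absorption: np.ndarray
    engine: str = "gksl"
    states: np.ndarray | None = None  # optional full density matrices / vectors

    @property
    def n_times(self) -> int:
        return len(self.times)


def absorption_readout(trace: PropagationTrace) -> tuple[float, float]:
    """Final cumulative target and distractor absorption (P_T, P_D) at T_end."""
    require(trace.n_times > 0, "empty trace")
    p_t = float(trace.target_absorption[-1])
    p_d = float(trace.distractor_absorption[-1])
    require(-1e-9 <= p_t <= 1 + 1e-6 and -1e-9 <= p_d <= 1 + 1e-6, "absorption out of [0, 1]")
    return max(p_t, 0.0), max(p_d, 0.0)
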