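"""Reference in-silico experiments built from the generator + pipeline.

These reproduce, at desk scale, the study designs the package is meant to
analyze — e.g. periodic short-pulse entrainment — and are used by the test
suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np

from .io import StimulusProtocol
from .synthetic import WaveParams, build_geometry, program_traces, schedule_waves
from .waves import detect_waves, wave_intervals, WaveEvent, WaveTable


def pulse_train_protocol(
    n_pulses: int = 10,
    period_s: float = 240.0,
    pulse_s: float = 60.0,
    duration_s: float | None = None,
) -> StimulusProtocol:
    """A train of short stimulus pulses: default ten 1 min pulses every 4 min."""
    if duration_s is None:
        duration_s = n_pulses * period_s + period_s
    pulses = [(i * period_s, i * period_s + pulse_s) for i in range(n_pulses)]
    return StimulusProtocol(pulses=pulses, recording_duration_s=duration_s)


def entrainment_experiment(
    seed: int = 0,
    n_seeds: int = 5,
    n_filaments: int = 12,
    cells_per_filament: int = 4,
    branch_prob: float = 0.25,
    protocol: StimulusProtocol | None = None,
    params: WaveParams | None = None,
) -> dict:
    """Drive synthetic colonies with a periodic pulse train and measure how
    tightly the recovered inter-wave intervals lock to the stimulation period.

    For each replicate colony (>= 50 ROI regions by default) the ground-truth
    dF/F0 traces are evaluated, waves are detected, and peak-to-peak intervals
    are pooled across ROIs.  Returns the replicate-averaged median interval,
    its percent deviation from the stimulation period, and the pooled
    interval count.
    """
    if protocol is None:
        protocol = pulse_train_protocol(n_pulses=10, period_s=240.0, pulse_s=60.0,
                                        duration_s=2640.0)
    period = protocol.onsets[1] - protocol.onsets[0] if protocol.n_pulses > 1 else np.nan

    medians, n_total = [], 0
    for rep in range(n_seeds):
        s = int(seed) * 1000 + rep
        geometry = build_geometry(s, n_filaments, cells_per_filament, branch_prob)
        program = schedule_waves(geometry, protocol, params, seed=s + 500)
        _, _, dff = program_traces(program, frame_interval_s=1.0)
        pooled: list[float] = []
        for r in range(dff.shape[0]):
            events = detect_waves(dff[r], frame_interval_s=1.0)
            pooled.extend(wave_intervals(events)["intervals_s"])
        if pooled:
            medians.append(float(np.median(pooled)))
            n_total += len(pooled)
    median_iv = float(np.mean(medians))
    return {
        "median_interval_s": median_iv,
        "period_s": float(period),
        "deviation_pct": 100.0 * abs(median_iv - period) / period,
        "n_intervals": int(n_total),
        "n_replicates": len(medians),
    }
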