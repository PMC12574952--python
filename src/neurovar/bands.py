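"""Band-limited re-analysis: oscillatory profiles of ΔSD and ΔAmplitude.

Single-trial epochs are band-pass filtered into the canonical delta
(1-4 Hz), theta (4-8 Hz), alpha (8-12 Hz) and beta (12-30 Hz) bands with
the same zero-phase Butterworth used for broadband preprocessing, and the
mutual partial-correlation analyses are repeated per band: ΔSD with
discriminability controlling ΔAmplitude, and ΔAmplitude with
discriminability controlling ΔSD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import cohort_tracksets, delta_tracks
from .io import EpochSet, bandpass
from .stats import AssociationTrack, track_association
from .variability import MetricTrack

__all__ = [
    "BandDefinition",
    "CANONICAL_BANDS",
    "band_profile",
    "band_amplitude_latencies",
]


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ValueError(f"invalid band edges ({self.lo}, {self.hi})")


CANONICAL_BANDS = {
    "delta": BandDefinition("delta", 1.0, 4.0),
    "theta": BandDefinition("theta", 4.0, 8.0),
    "alpha": BandDefinition("alpha", 8.0, 12.0),
    "beta": BandDefinition("beta", 12.0, 30.0),
}


def band_profile(
    cohort: list[EpochSet],
    scores,
    band: BandDefinition,
    window_ms: float = 100.0,
    step_ms: float = 1.0,
    alpha: float = 0.05,
    compute_bf: bool = True,
) -> tuple[AssociationTrack, AssociationTrack]:
    """Both partial-correlation directions on band-limited data.

    Returns ``(var_given_amp, amp_given_var)``: the ΔSD-discriminability
    partial track controlling ΔAmplitude, and the converse.
    """
    if band.hi >= cohort[0].sfreq / 2:
        raise ValueError(f"band {band.name} exceeds the Nyquist frequency")
    filtered = [bandpass(e, band.lo, band.hi) for e in cohort]
    var_d = delta_tracks(cohort_tracksets(filtered, "tempSD", window_ms, step_ms))
    amp_d = delta_tracks(cohort_tracksets(filtered, "amplitude", window_ms, step_ms))
    var_given_amp = track_association(
        var_d, scores, covariate_tracks=amp_d, alpha=alpha,
        compute_bf=compute_bf, covariate_name=f"{band.name}_delta_amplitude",
    )
    amp_given_var = track_association(
        amp_d, scores, covariate_tracks=var_d, alpha=alpha,
        compute_bf=compute_bf, covariate_name=f"{band.name}_delta_sd",
    )
    return var_given_amp, amp_given_var


def band_amplitude_latencies(
    track: MetricTrack, band_name: str, flat_tol: float = 0.0
) -> tuple[float, float]:
    """(negative-peak, positive-peak) latencies of a band-limited waveform.

    For the slow bands (delta, theta) the N2-like minimum and P2-like
    maximum of the trial-averaged waveform are located over the whole
    post-stimulus window; for alpha and beta, where no stable deflection
    exists, the search is restricted to 100-500 ms.
    """
    if band_name in ("delta", "theta"):
        lo_ms, hi_ms = 0.0, np.inf
    elif band_name in ("alpha", "beta"):
        lo_ms, hi_ms = 100.0, 500.0
    else:
        raise ValueError(f"unknown band {band_name!r}")
    mask = (track.times >= lo_ms) & (track.times <= hi_ms)
    if not mask.any():
        raise ValueError("track has no window centers in the search interval")
    v = track.values[mask]
    t = track.times[mask]
    if np.ptp(v) <= flat_tol:
        raise ValueError("flat track: peak latencies undefined")
    return float(t[np.argmin(v)]), float(t[np.argmax(v)])
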