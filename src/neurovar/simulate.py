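"""Synthetic multi-subject EEG cohorts with planted effects.

The generator emulates the structure the analyses are built to detect:

* an evoked (phase-locked) biphasic ERP with an N2-like negative deflection
  near 200 ms and a P2-like positive deflection near 400 ms whose amplitude
  scales with stimulus intensity,
* an induced (phase-random, average-cancelling) band-limited component whose
  within-window SD is larger for high- than low-intensity stimuli by a
  per-subject amount Δσ_i,
* band-limited background noise present throughout the epoch, and
* per-trial 0-10 NRS ratings from a per-subject psychometric offset μ_i
  plus a per-subject high-low rating difference D_i and trial noise.

Per-subject (D_i, Δσ_i, amplitude gain) are drawn from correlated Gaussians
so the cohort carries a known ground-truth association between neural
variability differences and rating discriminability (``rho_var_discrim``)
and between amplitude gain and discriminability (``rho_amp_discrim``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .io import EpochSet, validate_ratings

__all__ = ["GeneratorConfig", "GroundTruth", "generate_cohort", "generate_multimodal_ratings"]

logger = logging.getLogger(__name__)


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    Amplitudes are in microvolts, times in milliseconds, rates in Hz,
    ratings in NRS units (0-10).
    """

    n_subjects: int = 30
    n_trials_per_condition: int = 15
    sfreq: float = 1000.0
    epoch_window: tuple[float, float] = (-500.0, 1000.0)
    conditions: tuple[str, ...] = ("low", "high")
    # evoked component
    erp_peak_latencies: tuple[float, float] = (200.0, 400.0)
    erp_peak_widths: tuple[float, float] = (50.0, 50.0)
    erp_peak_amps: tuple[float, float] = (-2.5, 4.0)
    amp_effect: float = 1.3          # mean high/low ERP gain ratio
    amp_effect_sd: float = 0.1       # between-subject SD of the high gain
    # induced component
    sigma_base: float = 0.8          # induced envelope SD in the low condition
    sigma_base_sd: float = 0.0       # between-subject SD of the base level
    var_effect_mean: float = 0.6     # mean of per-subject Δσ_i
    var_effect_sd: float = 0.6       # SD of per-subject Δσ_i
    osc_band: tuple[float, float] = (1.0, 30.0)
    envelope_center: float = 350.0
    envelope_width: float = 150.0
    # ratings
    discrim_mean: float = 2.0        # mean of per-subject D_i (high-low rating)
    discrim_sd: float = 1.0
    rating_low_mean: float = 3.0     # mean of per-subject low-condition rating μ_i
    rating_low_sd: float = 0.5
    rating_noise_sd: float = 0.8
    # planted correlations
    rho_var_discrim: float = 0.5
    rho_amp_discrim: float = 0.4
    rho_base_rating: float = 0.0     # couples per-subject base σ with the rating offset μ_i
    # background noise
    noise_band: tuple[float, float] = (1.0, 30.0)
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_trials_per_condition < 1:
            raise ValueError("subject and trial counts must be positive")
        if len(self.conditions) < 2:
            raise ValueError("need at least two intensity conditions")
        if not (self.epoch_window[0] < 0 < self.epoch_window[1]):
            raise ValueError("epoch window must contain stimulus onset t=0")
        for name in ("var_effect_sd", "discrim_sd", "rating_noise_sd",
                     "rating_low_sd", "amp_effect_sd", "noise_sd", "sigma_base",
                     "sigma_base_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("rho_var_discrim", "rho_amp_discrim", "rho_base_rating"):
            if abs(getattr(self, name)) > 1:
                raise ValueError(f"|{name}| must be <= 1")

    def times(self) -> np.ndarray:
        """Epoch time axis in ms: [t0, t1) at step 1000/sfreq (t1 exclusive)."""
        step = 1000.0 / self.sfreq
        return np.arange(self.epoch_window[0], self.epoch_window[1], step)


@dataclass
class GroundTruth:
    """Planted per-subject parameters and the correlations realized in the sample."""

    subject_ids: list[str]
    discrim: np.ndarray        # D_i, NRS units
    delta_sigma: np.ndarray    # Δσ_i, µV
    amp_gain: np.ndarray       # high-condition ERP gain a_i,high (low gain is 1)
    rho_var_discrim_realized: float = field(init=False)
    rho_amp_discrim_realized: float = field(init=False)

    def __post_init__(self) -> None:
        n = len(self.subject_ids)
        if not (len(self.discrim) == len(self.delta_sigma) == len(self.amp_gain) == n):
            raise ValueError("ground-truth columns must have one entry per subject")
        def _corr(a, b):
            if len(a) < 3 or np.std(a) == 0 or np.std(b) == 0:
                return math.nan
            return float(np.corrcoef(a, b)[0, 1])

        self.rho_var_discrim_realized = _corr(self.delta_sigma, self.discrim)
        self.rho_amp_discrim_realized = _corr(self.amp_gain, self.discrim)


def erp_template(config: GeneratorConfig) -> np.ndarray:
    """Fixed biphasic ERP template: Gaussian-windowed N2-like and P2-like peaks."""
    t = config.times()
    template = np.zeros_like(t)
    for lat, width, amp in zip(
        config.erp_peak_latencies, config.erp_peak_widths, config.erp_peak_amps
    ):
        template += amp * np.exp(-0.5 * ((t - lat) / width) ** 2)
    template[t < 0] = 0.0
    return template


def _post_stimulus_envelope(config: GeneratorConfig) -> np.ndarray:
    """Smooth envelope of the induced component; exactly zero pre-stimulus."""
    t = config.times()
    g = np.exp(-0.5 * ((t - config.envelope_center) / config.envelope_width) ** 2)
    g[t < 0] = 0.0
    return g


def _bandlimited_noise(
    rng: np.random.Generator, shape: tuple[int, ...], band: tuple[float, float],
    sfreq: float,
) -> np.ndarray:
    """Unit-SD Gaussian noise band-limited with a zero-phase Butterworth.

    Generated with 500-sample padding on each side so filter edge transients
    do not leak into the epoch.
    """
    pad = 500
    n = shape[-1]
    white = rng.standard_normal(shape[:-1] + (n + 2 * pad,))
    sos = signal.butter(4, band, btype="bandpass", fs=sfreq, output="sos")
    filt = signal.sosfiltfilt(sos, white, axis=-1)[..., pad:pad + n]
    sd = filt.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return filt / sd


def _draw_subject_params(config: GeneratorConfig, rng: np.random.Generator):
    """Correlated latent draws: D_i is the shared factor.

    z_V = ρ_v z_D + sqrt(1-ρ_v²) e1 and z_A = ρ_a z_D + sqrt(1-ρ_a²) e2,
    the Cholesky construction for a tri-variate normal in which Δσ and the
    amplitude gain each correlate with D at the configured level.
    """
    n = config.n_subjects
    z_d = rng.standard_normal(n)
    e1 = rng.standard_normal(n)
    e2 = rng.standard_normal(n)
    rv, ra = config.rho_var_discrim, config.rho_amp_discrim
    z_v = rv * z_d + math.sqrt(1 - rv**2) * e1
    z_a = ra * z_d + math.sqrt(1 - ra**2) * e2
    discrim = config.discrim_mean + config.discrim_sd * z_d
    delta_sigma = config.var_effect_mean + config.var_effect_sd * z_v
    # keep the high-condition induced SD non-negative
    delta_sigma = np.maximum(delta_sigma, -config.sigma_base)
    amp_gain = config.amp_effect + config.amp_effect_sd * z_a
    z_mu = rng.standard_normal(n)
    mu = config.rating_low_mean + config.rating_low_sd * z_mu
    rb = config.rho_base_rating
    z_b = rb * z_mu + math.sqrt(1 - rb**2) * rng.standard_normal(n)
    sigma_base_i = np.maximum(config.sigma_base + config.sigma_base_sd * z_b, 0.05)
    return discrim, delta_sigma, amp_gain, mu, sigma_base_i


def _condition_level(config: GeneratorConfig, cond: str) -> float:
    """Intensity level in [0, 1]: 0 for the lowest condition, 1 for the highest."""
    idx = list(config.conditions).index(cond)
    return idx / (len(config.conditions) - 1)


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[list[EpochSet], pd.DataFrame, GroundTruth]:
    """Generate epochs + ratings + ground truth for one synthetic cohort.

    Per subject i, condition c, trial k the single-trial signal is

        x(t) = a_{i,c} ERP(t) + (σ_base + level(c) Δσ_i) g(t) osc_k(t) + ε_k(t)

    with ERP the fixed biphasic template, g a post-stimulus envelope that is
    exactly zero before onset, osc_k independent band-limited unit-SD noise
    per trial (so the induced term cancels in the trial average), and ε_k
    band-limited background noise present throughout the epoch.  Ratings are
    μ_i + level(c) D_i + trial noise, clipped to [0, 10].  Identical config
    and seed give bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    t = config.times()
    template = erp_template(config)
    envelope = _post_stimulus_envelope(config)
    discrim, delta_sigma, amp_gain, mu, sigma_base_i = _draw_subject_params(config, rng)

    n_tr = config.n_trials_per_condition
    cohort: list[EpochSet] = []
    rating_rows = []
    n_clipped = 0
    for i in range(config.n_subjects):
        sid = f"S{i:03d}"
        blocks, cond_labels = [], []
        for cond in config.conditions:
            level = _condition_level(config, cond)
            a = 1.0 + level * (amp_gain[i] - 1.0)
            sigma = sigma_base_i[i] + level * delta_sigma[i]
            osc = _bandlimited_noise(rng, (n_tr, t.size), config.osc_band, config.sfreq)
            eps = config.noise_sd * _bandlimited_noise(
                rng, (n_tr, t.size), config.noise_band, config.sfreq
            )
            blocks.append(a * template + sigma * envelope * osc + eps)
            cond_labels += [cond] * n_tr
            raw = mu[i] + level * discrim[i] + config.rating_noise_sd * rng.standard_normal(n_tr)
            clipped = np.clip(raw, 0.0, 10.0)
            n_clipped += int(np.sum(clipped != raw))
            for k in range(n_tr):
                rating_rows.append((sid, "pain", cond, k, clipped[k]))
        cohort.append(
            EpochSet(
                subject_id=sid,
                sfreq=config.sfreq,
                times=t,
                data=np.vstack(blocks),
                condition=np.asarray(cond_labels, dtype=object),
            )
        )
    if n_clipped:
        logger.info(
            "clipped %d ratings to [0, 10]; clipping biases D_i recovery at scale ends",
            n_clipped,
        )
    ratings = validate_ratings(
        pd.DataFrame(
            rating_rows,
            columns=["subject_id", "modality", "condition", "trial_index", "rating"],
        )
    )
    truth = GroundTruth(
        subject_ids=[f"S{i:03d}" for i in range(config.n_subjects)],
        discrim=discrim,
        delta_sigma=delta_sigma,
        amp_gain=amp_gain,
    )
    return cohort, ratings, truth


def generate_multimodal_ratings(
    config: GeneratorConfig,
    modalities: list[str],
    offsets: dict[str, float] | list[float],
) -> pd.DataFrame:
    """Ratings for several modalities with modality-specific mean offsets.

    Each modality uses the same generative rating model (fresh per-subject
    μ and D draws) with its offset added to the subject baseline; used to
    exercise the cross-modality rating-matching procedure.
    """
    if not modalities:
        raise ValueError("modality list must not be empty")
    if not isinstance(offsets, dict):
        offsets = dict(zip(modalities, offsets))
    unknown = set(offsets) - set(modalities)
    if unknown:
        raise KeyError(f"offsets given for unknown modalities: {sorted(unknown)}")
    for m in modalities:
        off = offsets.get(m, 0.0)
        if not np.isfinite(off):
            raise ValueError(f"offset for {m!r} must be finite")
    rng = np.random.default_rng(config.seed)
    n_tr = config.n_trials_per_condition
    rows = []
    for m in modalities:
        off = float(offsets.get(m, 0.0))
        for i in range(config.n_subjects):
            sid = f"S{i:03d}"
            mu = off + config.rating_low_mean + config.rating_low_sd * rng.standard_normal()
            d = config.discrim_mean + config.discrim_sd * rng.standard_normal()
            for cond in config.conditions:
                level = _condition_level(config, cond)
                raw = mu + level * d + config.rating_noise_sd * rng.standard_normal(n_tr)
                for k, r in enumerate(np.clip(raw, 0.0, 10.0)):
                    rows.append((sid, m, cond, k, r))
    return validate_ratings(
        pd.DataFrame(
            rows, columns=["subject_id", "modality", "condition", "trial_index", "rating"]
        )
    )
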