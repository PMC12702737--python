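"""Synthetic cohort and raw-EEG generation with a known generative structure.

The cohort generator draws the three predictors (theta band-power change,
gamma band-power change, affective shift) independently from Gaussians whose
moments default to values back-derived from the study cohort's reported
bootstrap confidence intervals, then produces the two outcomes
(Delta_Positive, Delta_Negative) from the second-order response surface

    dE = b0 + b1*dTheta + b2*dGamma + b3*AS + b4*(dTheta*AS)
         + b5*dGamma^2 + b6*AS^2 + eps,    eps ~ N(0, noise_sd)

with one coefficient vector per outcome.  The default coefficient vectors are
the published fitted coefficients, so parameter-recovery experiments test the
estimator against a known truth on realistic scales (theta ~1e-11 power
units, gamma ~1e-12).

The raw-EEG generator emits matched pre/post 32-channel recordings built from
shared pink-noise background plus band-limited theta (4-8 Hz) and gamma
(30-50 Hz) components whose post-session band power is scaled by configurable
multipliers, so downstream band-power change scores have a known sign.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError, InputError

__all__ = [
    "COEFFICIENT_NAMES",
    "GenerativeConfig",
    "ParticipantRecord",
    "Cohort",
    "default_generative_config",
    "generate_cohort",
    "generate_eeg_pair",
    "response_surface",
    "CHANNELS_32",
]

#: Fixed term order of the response-surface coefficient vectors.
COEFFICIENT_NAMES = (
    "intercept",
    "theta_change",
    "gamma_change",
    "affective_shift",
    "theta_x_shift",
    "gamma_sq",
    "shift_sq",
)

#: 32-channel 10-20-style montage including the midline sites (Fz, FCz, Cz,
#: Pz) needed by the default frontal-midline / frontal-parietal aggregates.
CHANNELS_32 = (
    "Fp1", "Fp2", "AF3", "AF4", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FCz", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6", "P7", "P3", "Pz", "P4", "P8",
    "PO3", "PO4", "O1", "O2",
)


def _sd_from_bootstrap_ci(lo: float, hi: float, n: int) -> float:
    """Back out a sample SD from a 95% bootstrap CI of a mean of n cases."""
    se = (hi - lo) / (2.0 * 1.959963984540054)
    return se * math.sqrt(n)


@dataclass(frozen=True)
class GenerativeConfig:
    """Full specification of a synthetic cohort.

    Coefficient vectors are ordered as :data:`COEFFICIENT_NAMES`.  Predictor
    means/SDs are on the raw (unstandardized) scales: power units for theta
    (~1e-11) and gamma (~1e-12), PANAS points for the affective shift and for
    both outcome noise SDs.

    ``shift_mode``:

    * ``"latent"`` (default) -- the affective shift is drawn directly and
      used as the generative predictor; PANAS scores are back-filled to match
      the generated outcome deltas.
    * ``"derived"`` -- a latent shift drives the response surface, but the
      *recorded* affective shift is recomputed from the realized PANAS
      deltas, reproducing the instrument's circular construction
      (shift = dPA - dNA).
    """

    n_participants: int = 50
    coef_positive: tuple = (0.0,) * 7
    coef_negative: tuple = (0.0,) * 7
    theta_mean: float = 0.0
    theta_sd: float = 1.0
    gamma_mean: float = 0.0
    gamma_sd: float = 1.0
    shift_mean: float = 0.0
    shift_sd: float = 1.0
    noise_sd_positive: float = 0.0
    noise_sd_negative: float = 0.0
    shift_mode: str = "latent"
    emit_items: bool = False
    seed: int = 42

    def validate(self) -> None:
        if self.n_participants < 2:
            raise ConfigError("n_participants must be >= 2")
        for name in ("theta_sd", "gamma_sd", "shift_sd",
                     "noise_sd_positive", "noise_sd_negative"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("coef_positive", "coef_negative"):
            vec = getattr(self, name)
            if len(vec) != 7:
                raise ConfigError(
                    f"{name} must have exactly 7 entries "
                    f"({', '.join(COEFFICIENT_NAMES)}); got {len(vec)}"
                )
        if self.shift_mode not in ("latent", "derived"):
            raise ConfigError(f"shift_mode must be 'latent' or 'derived', got {self.shift_mode!r}")

    def with_(self, **kwargs) -> "GenerativeConfig":
        """Return a copy with fields replaced."""
        return replace(self, **kwargs)


@dataclass
class ParticipantRecord:
    """One participant's scores, band-power change scores, and derived deltas."""

    participant_id: str
    pa_pre: float
    na_pre: float
    pa_post: float
    na_post: float
    theta_change: float
    gamma_change: float
    affective_shift: float
    delta_positive: float
    delta_negative: float
    panas_pre_items: Optional[tuple] = None
    panas_post_items: Optional[tuple] = None


class Cohort(list):
    """A list of :class:`ParticipantRecord` with tabular conversion.

    ``clip_events`` counts PANAS scores clipped into [10, 50] during
    item-emitting generation.
    """

    clip_events: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self:
            row = {
                "participant_id": rec.participant_id,
                "pa_pre": rec.pa_pre,
                "na_pre": rec.na_pre,
                "pa_post": rec.pa_post,
                "na_post": rec.na_post,
                "theta_change": rec.theta_change,
                "gamma_change": rec.gamma_change,
                "affective_shift": rec.affective_shift,
                "delta_positive": rec.delta_positive,
                "delta_negative": rec.delta_negative,
            }
            if rec.panas_pre_items is not None:
                for j in range(10):
                    row[f"pa{j + 1:02d}_pre"] = rec.panas_pre_items[j]
                    row[f"na{j + 1:02d}_pre"] = rec.panas_pre_items[10 + j]
            if rec.panas_post_items is not None:
                for j in range(10):
                    row[f"pa{j + 1:02d}_post"] = rec.panas_post_items[j]
                    row[f"na{j + 1:02d}_post"] = rec.panas_post_items[10 + j]
            rows.append(row)
        return pd.DataFrame(rows)


def default_generative_config() -> GenerativeConfig:
    """The reference configuration.

    Coefficients are the published fitted response-surface coefficients, with
    the interaction assigned to the negative-affect equation and the
    quadratic gamma / shift terms to the positive-affect equation.  Predictor
    moments are back-derived from the reported bootstrap CIs of the cohort
    (n = 50): SE = (hi - lo) / (2 * 1.96), SD = SE * sqrt(50).
    """
    n_ref = 50
    theta_sd = _sd_from_bootstrap_ci(-3.09131e-12, 7.30581e-11, n_ref)
    gamma_sd = _sd_from_bootstrap_ci(5.51989e-13, 3.06104e-12, n_ref)
    # Affective shift = dPA - dNA; moments combine the two reported delta
    # rows assuming independence.
    dp_mean, dn_mean = 1.651578947, -3.925368421
    dp_sd = _sd_from_bootstrap_ci(-0.631578947, 4.052631579, n_ref)
    dn_sd = _sd_from_bootstrap_ci(-5.894736842, -2.052631579, n_ref)
    return GenerativeConfig(
        n_participants=50,
        coef_negative=(0.0, 2.68e-11, 0.0, -3.96, 1.77e-10, 0.0, 0.0),
        coef_positive=(0.0, 0.0, 1.70e-12, 1.69, 0.0, 1.03e-23, 79.43),
        theta_mean=2.67218e-11,
        theta_sd=theta_sd,
        gamma_mean=1.66029e-12,
        gamma_sd=gamma_sd,
        shift_mean=dp_mean - dn_mean,
        shift_sd=math.hypot(dp_sd, dn_sd),
        noise_sd_positive=4.0,
        noise_sd_negative=4.0,
        shift_mode="latent",
        emit_items=False,
        seed=42,
    )


def response_surface(coef: Sequence[float], theta: np.ndarray,
                     gamma: np.ndarray, shift: np.ndarray) -> np.ndarray:
    """Evaluate the second-order response surface at raw predictor values."""
    b = np.asarray(coef, dtype=float)
    return (b[0] + b[1] * theta + b[2] * gamma + b[3] * shift
            + b[4] * theta * shift + b[5] * gamma ** 2 + b[6] * shift ** 2)


def _backfill_items(score: int, rng_offset: int = 0) -> tuple:
    """Distribute an integer subscale score in [10, 50] over 10 items in [1, 5].

    Round-robin increments from all-ones; deterministic.
    """
    items = [1] * 10
    remaining = int(score) - 10
    idx = rng_offset % 10
    while remaining > 0:
        if items[idx] < 5:
            items[idx] += 1
            remaining -= 1
        idx = (idx + 1) % 10
    return tuple(items)


def generate_cohort(config: GenerativeConfig) -> Cohort:
    """Draw a cohort of participants from the generative model.

    Each participant uses an independent substream seeded by
    ``(config.seed, index)``, so extending the cohort never perturbs
    earlier participants and identical configs yield bit-identical cohorts.
    """
    config.validate()
    cohort = Cohort()
    clip_events = 0
    for i in range(config.n_participants):
        rng = np.random.default_rng([config.seed, i])
        theta = config.theta_mean + config.theta_sd * rng.standard_normal()
        gamma = config.gamma_mean + config.gamma_sd * rng.standard_normal()
        shift = config.shift_mean + config.shift_sd * rng.standard_normal()
        eps_p = config.noise_sd_positive * rng.standard_normal()
        eps_n = config.noise_sd_negative * rng.standard_normal()
        dp = float(response_surface(config.coef_positive, theta, gamma, shift) + eps_p)
        dn = float(response_surface(config.coef_negative, theta, gamma, shift) + eps_n)

        pa_pre = 30.0 + 5.0 * rng.standard_normal()
        na_pre = 25.0 + 5.0 * rng.standard_normal()
        pre_items = post_items = None
        if config.emit_items:
            pa_pre_i = int(np.clip(round(pa_pre), 10, 50))
            na_pre_i = int(np.clip(round(na_pre), 10, 50))
            pa_post_i = int(round(pa_pre_i + dp))
            na_post_i = int(round(na_pre_i + dn))
            pa_post_c = int(np.clip(pa_post_i, 10, 50))
            na_post_c = int(np.clip(na_post_i, 10, 50))
            clip_events += int(pa_post_c != pa_post_i) + int(na_post_c != na_post_i)
            pa_pre, na_pre = float(pa_pre_i), float(na_pre_i)
            pa_post, na_post = float(pa_post_c), float(na_post_c)
            dp = pa_post - pa_pre
            dn = na_post - na_pre
            pre_items = _backfill_items(pa_pre_i, i) + _backfill_items(na_pre_i, i)
            post_items = _backfill_items(pa_post_c, i) + _backfill_items(na_post_c, i)
        else:
            pa_post = pa_pre + dp
            na_post = na_pre + dn

        if config.shift_mode == "derived":
            recorded_shift = dp - dn
        else:
            recorded_shift = shift

        cohort.append(ParticipantRecord(
            participant_id=f"P{i + 1:05d}",
            pa_pre=pa_pre, na_pre=na_pre, pa_post=pa_post, na_post=na_post,
            theta_change=theta, gamma_change=gamma,
            affective_shift=float(recorded_shift),
            delta_positive=dp, delta_negative=dn,
            panas_pre_items=pre_items, panas_post_items=post_items,
        ))
    cohort.clip_events = clip_events
    return cohort


def _band_limited_noise(rng: np.ndarray, n_channels: int, n_samples: int,
                        fs: float, band: tuple) -> np.ndarray:
    """Unit-RMS noise confined to a frequency band (per channel)."""
    from scipy import signal

    white = rng.standard_normal((n_channels, n_samples))
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, white, axis=-1)
    rms = np.sqrt(np.mean(x ** 2, axis=-1, keepdims=True))
    return x / np.maximum(rms, 1e-30)


def _pink_noise(rng, n_channels: int, n_samples: int) -> np.ndarray:
    """Unit-RMS 1/f-power-weighted noise (per channel)."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples)
    weights = np.ones_like(freqs)
    weights[1:] = 1.0 / np.sqrt(freqs[1:])
    weights[0] = 0.0
    x = np.fft.irfft(spec * weights, n=n_samples, axis=-1)
    rms = np.sqrt(np.mean(x ** 2, axis=-1, keepdims=True))
    return x / np.maximum(rms, 1e-30)


def generate_eeg_pair(channels: int = 32, fs: float = 128.0,
                      duration: float = 10.0, theta_multiplier: float = 1.0,
                      gamma_multiplier: float = 1.0, seed: int = 0):
    """Generate a matched (pre, post) pair of synthetic EEG recordings.

    Both recordings share the same pink-noise background and oscillatory
    component waveforms; the post recording scales the theta and gamma
    component amplitudes by sqrt(multiplier), so the corresponding band
    POWER scales by the multiplier exactly (identity multipliers give an
    identical pair).

    Returns ``(pre, post)`` as :class:`~neuroaffect.eeg.EEGRecording`.
    """
    from .eeg import EEGRecording

    if fs < 128:
        raise InputError(f"fs must be >= 128 Hz, got {fs}")
    if duration < 4.0:
        raise InputError(f"duration must be >= 4 s (two 2-s epochs), got {duration}")
    if theta_multiplier <= 0 or gamma_multiplier <= 0:
        raise InputError("band-power multipliers must be > 0")
    if not 1 <= channels <= len(CHANNELS_32):
        raise InputError(f"channels must be in [1, {len(CHANNELS_32)}]")

    n = int(round(duration * fs))
    rng = np.random.default_rng([seed, 0])
    bg = 5.0 * _pink_noise(rng, channels, n)                       # microvolts RMS
    theta = 4.0 * _band_limited_noise(rng, channels, n, fs, (4.0, 8.0))
    gamma = 2.0 * _band_limited_noise(rng, channels, n, fs, (30.0, 50.0))

    labels = list(CHANNELS_32[:channels])
    pre = EEGRecording(channel_labels=labels, fs=fs,
                       samples=bg + theta + gamma, condition="pre")
    post = EEGRecording(
        channel_labels=labels, fs=fs,
        samples=bg + math.sqrt(theta_multiplier) * theta
        + math.sqrt(gamma_multiplier) * gamma,
        condition="post")
    return pre, post
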