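"""Virtual expert tasting panel: synthetic EEG epochs and sensory ratings.

The generator emulates the statistical structure the downstream analysis
assumes, so the whole pipeline is testable without access to human
recordings:

* a per-subject alpha rhythm at an individual alpha frequency (IAF) in
  the 7.5–12.5 Hz range over occipital channels, visible in the
  eyes-closed baseline;
* a 1/f-shaped broadband background with a white floor, band-limited to
  0.1–40 Hz (the generated data is "post-cleaning": no blinks, EMG or
  line noise);
* tasting (TL) epochs whose band powers in configured (region, band)
  targets are multiplied by ``1 + gain × latent_intensity``, so a
  monotone feature–target coupling exists by construction;
* noisy 0–10 ratings of four attributes (bitter, sweet, acid,
  astringent) over two phases: Be (reference solutions) and Co (coffee
  blends), four tasting trials each.

All randomness flows through explicit :class:`numpy.random.Generator`
instances; identical (config, seed) produce bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .features import Epoch, define_bands
from .montage import CHANNELS_38, region_channels

ATTRIBUTES: tuple[str, ...] = ("bitter", "sweet", "acid", "astringent")
PHASES: tuple[str, ...] = ("Be", "Co")
TASKS: tuple[str, ...] = ("BSL", "WR", "TL")
N_TRIALS: int = 4

_PHASE_CODE = {"Be": 1, "Co": 2}
_TASK_CODE = {"BSL": 0, "WR": 1, "TL": 2}


class ConfigurationError(ValueError):
    """A panel-configuration field is invalid."""


@dataclass(frozen=True)
class EffectSpec:
    """Coupling of one sensory attribute to a (scalp region, band) target.

    During a tasting epoch the band power of every channel in ``region``
    is multiplied by ``1 + gain × latent_intensity`` within ``band`` of
    the subject-specific band scheme.
    """

    region: str
    band: str
    gain: float


#: Default attribute → (region, band) couplings.  Distinct, non-overlapping
#: targets so each attribute is recoverable from its own feature block.
DEFAULT_EFFECT_MAP: dict[str, EffectSpec] = {
    "bitter": EffectSpec("frontal", "theta", 0.05),
    "sweet": EffectSpec("central", "alpha", 0.05),
    "acid": EffectSpec("parietal", "beta", 0.05),
    "astringent": EffectSpec("occipital", "gamma", 0.05),
}


@dataclass(frozen=True)
class PanelConfig:
    """Everything that defines a virtual tasting panel.

    Signal-model fields (µV²/Hz unless noted): ``pink_scale`` scales the
    1/f background, ``white_scale`` the flat floor, ``alpha_amplitude``
    (µV) the occipital alpha oscillation, ``alpha_mod_depth`` its slow
    amplitude modulation (0 ⇒ pure sinusoid).
    """

    n_subjects: int = 15
    seed: int = 1
    fs: float = 512.0
    n_channels: int = 38
    channel_names: tuple[str, ...] = CHANNELS_38
    baseline_duration: float = 60.0
    tl_duration: float = 10.0
    wr_duration: float = 10.0
    iaf_range: tuple[float, float] = (8.5, 11.5)
    effect_map: dict[str, EffectSpec] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_MAP)
    )
    rating_noise_sd: float = 1.0
    age_range: tuple[int, int] = (24, 59)
    group_proportions: tuple[float, float] = (0.5, 0.5)  # (T, E)
    latent_range: tuple[float, float] = (1.0, 9.0)
    pink_scale: float = 10.0
    white_scale: float = 0.2
    alpha_amplitude: float = 8.0
    alpha_mod_depth: float = 0.3
    alpha_mod_freq: float = 0.5  # Hz, envelope bandwidth
    band_limit: tuple[float, float] = (0.1, 40.0)

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ConfigurationError("n_subjects must be ≥ 2")
        if self.fs <= 2 * 40.0:
            raise ConfigurationError("fs must exceed twice the 40 Hz band limit")
        lo, hi = self.iaf_range
        if not (7.5 < lo <= hi < 12.5):
            raise ConfigurationError("iaf_range must lie strictly inside (7.5, 12.5)")
        if len(self.channel_names) != self.n_channels:
            raise ConfigurationError(
                f"channel_names has {len(self.channel_names)} entries for "
                f"n_channels={self.n_channels}"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ConfigurationError("channel_names must be unique")
        for dur_name in ("baseline_duration", "tl_duration", "wr_duration"):
            if getattr(self, dur_name) < 1.0:
                raise ConfigurationError(f"{dur_name} must be ≥ 1 s")
        if not (0 <= self.group_proportions[0] <= 1):
            raise ConfigurationError("group_proportions must be fractions")
        if self.rating_noise_sd < 0:
            raise ConfigurationError("rating_noise_sd must be ≥ 0")
        for attr, eff in self.effect_map.items():
            if attr not in ATTRIBUTES:
                raise ConfigurationError(f"effect_map key {attr!r} not an attribute")
            region_channels(eff.region)  # raises on unknown region
            if eff.gain < 0:
                raise ConfigurationError(f"effect_map[{attr!r}].gain must be ≥ 0")

    def with_(self, **kwargs) -> "PanelConfig":
        """A copy with some fields replaced."""
        return replace(self, **kwargs)


@dataclass
class VirtualSubject:
    """Ground truth for one panelist."""

    subject_id: str
    age: int
    group: str  # "T" (trained) or "E" (expert)
    true_iaf: float
    #: (phase, trial, attribute) → latent intensity on the 0–10 scale
    latent_intensity: dict[tuple[str, int, str], float]
    index: int = 0


@dataclass
class SessionRecording:
    """One subject's full recording session plus ratings."""

    subject_id: str
    baseline: Epoch
    wr_epochs: dict[tuple[str, int], Epoch]
    tl_epochs: dict[tuple[str, int], Epoch]
    ratings: dict[tuple[str, int, str], float]


def generate_panel(config: PanelConfig) -> list[VirtualSubject]:
    """Draw the panel's demographics, IAFs and latent intensities.

    Deterministic given ``config.seed``; two calls with the same config
    return identical panels.
    """
    rng = np.random.default_rng([0x9A4E1, config.seed])
    subjects = []
    for i in range(config.n_subjects):
        age = int(rng.integers(config.age_range[0], config.age_range[1] + 1))
        group = "T" if rng.random() < config.group_proportions[0] else "E"
        lo, hi = config.iaf_range
        iaf = float(lo + (hi - lo) * rng.random())
        latent = {
            (phase, trial, attr): float(
                config.latent_range[0]
                + (config.latent_range[1] - config.latent_range[0]) * rng.random()
            )
            for phase in PHASES
            for trial in range(1, N_TRIALS + 1)
            for attr in ATTRIBUTES
        }
        subjects.append(
            VirtualSubject(
                subject_id=f"S{i + 1:02d}",
                age=age,
                group=group,
                true_iaf=iaf,
                latent_intensity=latent,
                index=i,
            )
        )
    return subjects


def _background_psd(config: PanelConfig, freqs: np.ndarray) -> np.ndarray:
    """1/f + white background density (µV²/Hz), band-limited."""
    lo, hi = config.band_limit
    psd = np.zeros_like(freqs)
    mask = (freqs >= lo) & (freqs <= hi)
    psd[mask] = config.pink_scale / freqs[mask] + config.white_scale
    return psd


def _band_factors(
    config: PanelConfig,
    subject: VirtualSubject,
    phase: str,
    trial: int,
    freqs: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-(channel, freq) multiplicative gain for a TL epoch.

    Returns the factor matrix and the per-channel factor applying to the
    alpha oscillation (1 where the alpha band of an occipital channel is
    not targeted).
    """
    names = list(config.channel_names)
    bands = define_bands(subject.true_iaf)
    factors = np.ones((len(names), freqs.size))
    alpha_factor = np.ones(len(names))
    for attr, eff in config.effect_map.items():
        intensity = subject.latent_intensity[(phase, trial, attr)]
        gain = 1.0 + eff.gain * intensity
        lo, hi = bands.intervals[eff.band]
        fmask = (freqs >= lo) & (freqs < hi)
        for chan in region_channels(eff.region):
            if chan in names:
                ci = names.index(chan)
                factors[ci, fmask] *= gain
                if lo <= subject.true_iaf < hi:
                    alpha_factor[ci] *= gain
    return factors, alpha_factor


def synthesize_epoch(
    subject: VirtualSubject,
    task: str,
    phase: str | None,
    trial: int | None,
    rng: np.random.Generator,
    config: PanelConfig,
) -> Epoch:
    """Synthesize one multichannel epoch for a subject/task.

    The broadband background is frequency-domain shaped Gaussian noise;
    the alpha rhythm is an amplitude-modulated sinusoid at the subject's
    true IAF on occipital channels.  For TL epochs the configured
    (region, band) powers are scaled by ``1 + gain × latent_intensity``.
    """
    if rng is None:
        raise ValueError("an explicit numpy Generator is required (rng=None)")
    if task not in TASKS:
        raise ValueError(f"task must be one of {TASKS}, got {task!r}")
    if task != "BSL" and (phase not in PHASES or trial not in range(1, N_TRIALS + 1)):
        raise ValueError(f"invalid (phase={phase!r}, trial={trial!r}) for task {task}")

    duration = {
        "BSL": config.baseline_duration,
        "WR": config.wr_duration,
        "TL": config.tl_duration,
    }[task]
    n = int(round(duration * config.fs))
    n_ch = config.n_channels
    freqs = np.fft.rfftfreq(n, d=1.0 / config.fs)

    psd = np.broadcast_to(_background_psd(config, freqs), (n_ch, freqs.size)).copy()
    alpha_factor = np.ones(n_ch)
    if task == "TL":
        factors, alpha_factor = _band_factors(config, subject, phase, trial, freqs)
        psd *= factors

    # Shaped Gaussian noise: white → rfft → amplitude sqrt(P·fs/2) → irfft.
    white = rng.standard_normal((n_ch, n))
    spec = np.fft.rfft(white, axis=-1) * np.sqrt(psd * config.fs / 2.0)
    data = np.fft.irfft(spec, n=n, axis=-1)

    # Occipital alpha: amplitude-modulated sinusoid at the true IAF.
    names = list(config.channel_names)
    occ = [c for c in region_channels("occipital") if c in names]
    if occ and config.alpha_amplitude > 0:
        t = np.arange(n) / config.fs
        for chan in occ:
            ci = names.index(chan)
            phi = rng.uniform(0, 2 * np.pi)
            if config.alpha_mod_depth > 0:
                env_noise = rng.standard_normal(n)
                env_spec = np.fft.rfft(env_noise)
                env_spec[freqs > config.alpha_mod_freq] = 0.0
                slow = np.fft.irfft(env_spec, n=n)
                sd = slow.std()
                if sd > 0:
                    slow /= sd
                envelope = np.clip(1.0 + config.alpha_mod_depth * slow, 0.1, None)
            else:
                envelope = 1.0
            amp = config.alpha_amplitude * np.sqrt(alpha_factor[ci])
            data[ci] += amp * envelope * np.sin(2 * np.pi * subject.true_iaf * t + phi)

    return Epoch(data=data, fs=config.fs, channel_names=names, task=task)


def generate_ratings(
    subject: VirtualSubject,
    phase: str,
    trial: int,
    rng: np.random.Generator,
    noise_sd: float,
) -> dict[str, float]:
    """Noisy 0–10 ratings: clip(latent + N(0, noise_sd), 0, 10)."""
    if rng is None:
        raise ValueError("an explicit numpy Generator is required (rng=None)")
    out = {}
    for attr in ATTRIBUTES:
        latent = subject.latent_intensity[(phase, trial, attr)]
        noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
        out[attr] = float(np.clip(latent + noise, 0.0, 10.0))
    return out


def _epoch_rng(config: PanelConfig, subject: VirtualSubject, task: str,
               phase: str | None, trial: int | None) -> np.random.Generator:
    return np.random.default_rng(
        [config.seed, subject.index, _TASK_CODE[task],
         _PHASE_CODE.get(phase, 0), trial or 0]
    )


def simulate_session(subject: VirtualSubject, config: PanelConfig) -> SessionRecording:
    """Full recording for one subject: baseline, 2 phases × 4 trials of
    WR + TL epochs, and the attribute ratings."""
    baseline = synthesize_epoch(
        subject, "BSL", None, None, _epoch_rng(config, subject, "BSL", None, None), config
    )
    wr, tl, ratings = {}, {}, {}
    for phase in PHASES:
        for trial in range(1, N_TRIALS + 1):
            wr[(phase, trial)] = synthesize_epoch(
                subject, "WR", phase, trial,
                _epoch_rng(config, subject, "WR", phase, trial), config,
            )
            tl[(phase, trial)] = synthesize_epoch(
                subject, "TL", phase, trial,
                _epoch_rng(config, subject, "TL", phase, trial), config,
            )
            rating_rng = np.random.default_rng(
                [config.seed, subject.index, 9, _PHASE_CODE[phase], trial]
            )
            for attr, val in generate_ratings(
                subject, phase, trial, rating_rng, config.rating_noise_sd
            ).items():
                ratings[(phase, trial, attr)] = val
    return SessionRecording(
        subject_id=subject.subject_id,
        baseline=baseline,
        wr_epochs=wr,
        tl_epochs=tl,
        ratings=ratings,
    )


def simulate_panel(
    config: PanelConfig,
) -> tuple[list[VirtualSubject], list[SessionRecording]]:
    """Generate the whole panel and every subject's session."""
    subjects = generate_panel(config)
    sessions = [simulate_session(s, config) for s in subjects]
    return subjects, sessions
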