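"""Spectral and temporal EEG feature extraction.

Implements the per-epoch primitives of the analysis: Welch power spectral
densities, the individual alpha frequency (IAF) as the spectral center of
gravity in the extended 7.5–12.5 Hz alpha band over occipital channels,
IAF-anchored frequency bands, normalized band powers, and the Hjorth
time-domain parameters (activity, mobility, complexity).

Conventions
-----------
* PSDs are one-sided densities (µV²/Hz) so that the integral over
  [0, fs/2] approximates the signal variance (Parseval).
* Band integrals use the trapezoidal rule on the Welch grid, with band
  edges falling between bins handled by linear interpolation of the
  cumulative integral; band powers are therefore continuous in the IAF.
* Hjorth mobility is reported in rad/s: derivatives are first differences
  scaled by the sample rate, so a pure sinusoid at frequency f has
  mobility ≈ 2πf.  Divide by 2π for a Hz-scaled convention.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.integrate import cumulative_trapezoid

logger = logging.getLogger(__name__)

BAND_NAMES: tuple[str, ...] = ("delta", "theta", "alpha", "beta", "gamma")

#: Extended alpha band used for the IAF center of gravity (Hz).
ALPHA_SEARCH_BAND: tuple[float, float] = (7.5, 12.5)


@dataclass
class Epoch:
    """One task segment of multichannel EEG.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in µV.
    fs : float
        Sample rate in Hz.
    channel_names : list of str
        One label per row of ``data``.
    task : str
        Task label, e.g. ``"BSL"``, ``"WR"``, ``"TL"``.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    task: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("epoch data must be 2-D (channels × samples)")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("epoch data contains NaN or Inf")
        if self.data.shape[1] < self.fs:
            raise ValueError(
                "epoch shorter than 1 s; the 1 s Welch window needs "
                f"≥ {int(self.fs)} samples, got {self.data.shape[1]}"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs

    def channel_index(self, names: list[str] | tuple[str, ...]) -> np.ndarray:
        idx = []
        for name in names:
            try:
                idx.append(self.channel_names.index(name))
            except ValueError:
                raise KeyError(f"channel {name!r} not in epoch") from None
        return np.asarray(idx, dtype=int)


@dataclass
class PSDEstimate:
    """Per-channel one-sided Welch PSD on a common frequency grid."""

    freqs: np.ndarray
    power: np.ndarray  # (n_channels, n_freqs), µV²/Hz
    channel_names: list[str]
    window_len: float = 1.0
    overlap: float = 0.5

    def __post_init__(self) -> None:
        if np.any(self.power < 0):
            raise ValueError("PSD has negative entries")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")


@dataclass
class BandScheme:
    """The five IAF-anchored frequency intervals (Hz)."""

    iaf: float
    intervals: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lows = [self.intervals[b][0] for b in BAND_NAMES]
        highs = [self.intervals[b][1] for b in BAND_NAMES]
        if lows[0] != 0.0:
            raise ValueError("delta band must start at 0 Hz")
        for i in range(1, len(BAND_NAMES)):
            if lows[i] != highs[i - 1]:
                raise ValueError("bands must be contiguous")


@dataclass
class SpectralPowers:
    """Normalized band powers p[channel][band] ∈ [0, 1]."""

    p: dict[str, dict[str, float]]

    def as_vector(self, channel_order: list[str]) -> np.ndarray:
        """Flatten channels-major, bands in canonical δθαβγ order."""
        return np.array(
            [self.p[c][b] for c in channel_order for b in BAND_NAMES]
        )


@dataclass
class HjorthParams:
    """Per-channel Hjorth activity (µV²), mobility (rad/s), complexity."""

    activity: dict[str, float]
    mobility: dict[str, float]
    complexity: dict[str, float]

    def as_vector(self, channel_order: list[str]) -> np.ndarray:
        """Flatten channels-major, parameters in (A, M, C) order."""
        return np.array(
            [
                v
                for c in channel_order
                for v in (self.activity[c], self.mobility[c], self.complexity[c])
            ]
        )


def welch_psd(epoch: Epoch, window_len: float = 1.0, overlap: float = 0.5) -> PSDEstimate:
    """Welch PSD with a Hamming window of ``window_len`` seconds.

    Segments overlap by the fraction ``overlap`` (default 50 %).  The
    density normalization is such that the trapezoidal integral of the
    PSD over [0, fs/2] approximates the per-channel signal variance.
    """
    nperseg = int(round(window_len * epoch.fs))
    if epoch.n_samples < nperseg:
        raise ValueError(
            f"epoch ({epoch.n_samples} samples) shorter than the Welch "
            f"window ({nperseg} samples)"
        )
    noverlap = int(round(overlap * nperseg))
    freqs, power = sps.welch(
        epoch.data,
        fs=epoch.fs,
        window="hamming",
        nperseg=nperseg,
        noverlap=noverlap,
        detrend="constant",
        scaling="density",
        axis=-1,
    )
    return PSDEstimate(
        freqs=freqs,
        power=power,
        channel_names=list(epoch.channel_names),
        window_len=window_len,
        overlap=overlap,
    )


def estimate_iaf(
    baseline: Epoch,
    occipital_channels: list[str] | tuple[str, ...],
    band: tuple[float, float] = ALPHA_SEARCH_BAND,
) -> float:
    """Individual alpha frequency: PSD center of gravity in ``band``.

    The occipital-average Welch PSD of the (eyes-closed) baseline epoch is
    averaged over ``occipital_channels``; the IAF is
    Σ f·P̄(f) / Σ P̄(f) over the frequency bins inside ``band``.
    """
    idx = baseline.channel_index(occipital_channels)
    psd = welch_psd(baseline)
    mean_power = psd.power[idx].mean(axis=0)
    in_band = (psd.freqs >= band[0]) & (psd.freqs <= band[1])
    weights = mean_power[in_band]
    total = weights.sum()
    if total <= 0:
        raise ValueError(
            "occipital PSD is zero everywhere in the alpha search band; "
            "center of gravity undefined"
        )
    return float((psd.freqs[in_band] * weights).sum() / total)


def define_bands(iaf: float) -> BandScheme:
    """IAF-anchored band scheme.

    δ=[0, IAF−6], θ=[IAF−6, IAF−2], α=[IAF−2, IAF+2],
    β=[IAF+2, IAF+16], γ=[IAF+16, IAF+25].
    """
    if iaf <= 6:
        raise ValueError(
            f"iaf={iaf} Hz gives an empty delta band (upper edge IAF−6 ≤ 0)"
        )
    intervals = {
        "delta": (0.0, iaf - 6.0),
        "theta": (iaf - 6.0, iaf - 2.0),
        "alpha": (iaf - 2.0, iaf + 2.0),
        "beta": (iaf + 2.0, iaf + 16.0),
        "gamma": (iaf + 16.0, iaf + 25.0),
    }
    return BandScheme(iaf=float(iaf), intervals=intervals)


def band_powers(psd: PSDEstimate, bands: BandScheme) -> SpectralPowers:
    """Normalized band powers: band integral over the total [0, fs/2] integral.

    Integrals are trapezoidal on the Welch grid; a band edge between bins
    is handled by linear interpolation of the cumulative integral.  Bands
    extending past the grid (γ above Nyquist) are truncated with a warning.
    """
    nyq = psd.freqs[-1]
    cum = cumulative_trapezoid(psd.power, psd.freqs, axis=-1, initial=0.0)
    totals = cum[:, -1]
    if np.any(totals <= 0):
        bad = [psd.channel_names[i] for i in np.nonzero(totals <= 0)[0]]
        raise ValueError(f"zero total power on channels {bad}")

    p: dict[str, dict[str, float]] = {c: {} for c in psd.channel_names}
    for band_name in BAND_NAMES:
        lo, hi = bands.intervals[band_name]
        if hi > nyq:
            warnings.warn(
                f"{band_name} band upper edge {hi} Hz exceeds the PSD grid "
                f"({nyq} Hz); truncating",
                stacklevel=2,
            )
            hi = nyq
        lo = min(lo, nyq)
        for i, chan in enumerate(psd.channel_names):
            num = np.interp(hi, psd.freqs, cum[i]) - np.interp(lo, psd.freqs, cum[i])
            p[chan][band_name] = float(num / totals[i])
    return SpectralPowers(p=p)


def hjorth(epoch: Epoch) -> HjorthParams:
    """Hjorth activity, mobility and complexity per channel.

    Activity is the temporal variance; the derivative is the first
    difference scaled by fs, so mobility carries rad/s units and equals
    2πf for a pure sinusoid at f Hz.  Complexity is ≥ 1 (Cauchy–Schwarz)
    and equals 1 for a sinusoid.
    """
    x = epoch.data
    if x.shape[1] < 3:
        raise ValueError("need at least 3 samples for Hjorth parameters")
    var_x = x.var(axis=1)
    constant = (var_x <= 0) | (np.ptp(x, axis=1) == 0)
    if np.any(constant):
        bad = [epoch.channel_names[i] for i in np.nonzero(constant)[0]]
        raise ValueError(f"constant signal (zero variance) on channels {bad}")
    dx = np.diff(x, axis=1) * epoch.fs
    d2x = np.diff(dx, axis=1) * epoch.fs
    var_dx = dx.var(axis=1)
    var_d2x = d2x.var(axis=1)
    mob = np.sqrt(var_dx / var_x)
    mob_dx = np.sqrt(var_d2x / var_dx)
    comp = mob_dx / mob
    names = epoch.channel_names
    return HjorthParams(
        activity={c: float(var_x[i]) for i, c in enumerate(names)},
        mobility={c: float(mob[i]) for i, c in enumerate(names)},
        complexity={c: float(comp[i]) for i, c in enumerate(names)},
    )
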