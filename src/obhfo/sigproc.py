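"""Spectral and analytic-signal primitives shared by all pipeline stages.

Conventions: zero-phase (forward-backward) Butterworth filtering so phase
statistics are undistorted; Welch power spectra with a Hann window, 50%
overlap and one-sided density normalisation, default 60 s windows.
Canonical analysis bands are exposed as module-level :class:`BandSpec`
constants (delta 0.3–3, gamma 30–65, HFO 80–130, fast HFO 100–180 Hz, and
the >500 Hz multi-unit high-pass).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .containers import Recording

__all__ = [
    "BandSpec",
    "SpectralEstimate",
    "DELTA",
    "GAMMA",
    "HFO",
    "FAST_HFO",
    "MUA_HIGHPASS",
    "bandpass",
    "analytic_envelope_phase",
    "welch_psd",
    "dominant_frequency",
    "band_power_timecourse",
    "settle_samples",
]


@dataclass(frozen=True)
class BandSpec:
    """Named frequency band in Hz; ``hi=None`` denotes a high-pass band."""

    name: str
    lo: float
    hi: float | None

    def __post_init__(self) -> None:
        if self.lo <= 0:
            raise ValueError(f"band {self.name!r}: lo must be > 0, got {self.lo}")
        if self.hi is not None and self.hi <= self.lo:
            raise ValueError(
                f"band {self.name!r}: hi={self.hi} must exceed lo={self.lo}"
            )

    @property
    def center(self) -> float:
        if self.hi is None:
            raise ValueError(f"high-pass band {self.name!r} has no centre")
        return 0.5 * (self.lo + self.hi)

    def validate_for(self, fs: float) -> None:
        nyq = fs / 2
        if self.lo >= nyq:
            raise ValueError(
                f"band {self.name!r}: lower edge {self.lo} Hz >= Nyquist {nyq} Hz"
            )
        if self.hi is not None and self.hi >= nyq:
            raise ValueError(
                f"band {self.name!r}: upper edge {self.hi} Hz >= Nyquist {nyq} Hz"
            )


DELTA = BandSpec("delta", 0.3, 3.0)
GAMMA = BandSpec("gamma", 30.0, 65.0)
HFO = BandSpec("hfo", 80.0, 130.0)
FAST_HFO = BandSpec("fast_hfo", 100.0, 180.0)
MUA_HIGHPASS = BandSpec("mua", 500.0, None)


@dataclass
class SpectralEstimate:
    """One-sided Welch power spectral density (mV²/Hz)."""

    frequencies: np.ndarray
    power: np.ndarray
    window_length: float
    method: str = "welch"

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(self.power < 0):
            raise ValueError("spectral power must be nonnegative")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequency grid must be strictly increasing")


def _as_array(x) -> tuple[np.ndarray, float | None]:
    if isinstance(x, Recording):
        if x.n_channels != 1:
            raise ValueError(
                f"expected a 1-channel signal, got {x.n_channels} channels"
            )
        return x.samples[0], x.fs
    return np.asarray(x, dtype=float), None


def _design_sos(band: BandSpec, fs: float, order: int) -> np.ndarray:
    band.validate_for(fs)
    if band.hi is None:
        return sps.butter(order, band.lo, btype="highpass", fs=fs, output="sos")
    return sps.butter(
        order, [band.lo, band.hi], btype="bandpass", fs=fs, output="sos"
    )


def bandpass(rec: Recording, band: BandSpec, order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass (or high-pass) of every channel.

    Forward-backward application doubles the effective order and cancels
    the phase response, so in-band components keep their timing.
    """
    sos = _design_sos(band, rec.fs, order)
    out = sps.sosfiltfilt(sos, rec.samples, axis=1)
    return rec.copy_with(out)


def settle_samples(band: BandSpec, fs: float, n_widths: float = 3.0) -> int:
    """Filter-settling margin: ~3 impulse-response widths of the band edge.

    Statistics that depend on band-filtered signals should exclude this
    many samples from each end of the trace.
    """
    return int(round(n_widths * fs / band.lo))


def analytic_envelope_phase(
    signal: Recording | np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Hilbert envelope (mV, >= 0) and instantaneous phase in (-pi, pi].

    The caller is responsible for band-limiting the input first; the
    analytic signal of a broadband trace has no useful phase.
    """
    x, _ = _as_array(signal)
    if x.size < 8:
        raise ValueError(f"signal too short for Hilbert transform: {x.size} < 8")
    analytic = sps.hilbert(x)
    return np.abs(analytic), np.angle(analytic)


def welch_psd(
    signal: Recording | np.ndarray,
    fs: float | None = None,
    window_length: float = 60.0,
    allow_short: bool = False,
) -> SpectralEstimate:
    """Welch PSD: Hann window of ``window_length`` seconds, 50% overlap.

    Signals shorter than one window are rejected unless ``allow_short``
    is set, in which case a single full-length window is used.
    """
    x, fs_rec = _as_array(signal)
    fs = fs_rec if fs_rec is not None else fs
    if fs is None:
        raise ValueError("fs must be given for plain-array input")
    nperseg = int(round(window_length * fs))
    if x.size < nperseg:
        if not allow_short:
            raise ValueError(
                f"signal ({x.size / fs:.3g} s) shorter than the "
                f"{window_length:.3g} s Welch window; pass allow_short=True "
                "to use a single shorter window"
            )
        nperseg = x.size
        window_length = nperseg / fs
    f, p = sps.welch(
        x,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend="constant",
        scaling="density",
    )
    # drop the DC bin so the frequency grid starts at a usable value
    return SpectralEstimate(
        frequencies=f[1:], power=p[1:], window_length=window_length
    )


def dominant_frequency(
    psd: SpectralEstimate, band: BandSpec
) -> tuple[float, float]:
    """Frequency and power of the largest PSD bin inside ``band``.

    Ties break toward the lower frequency (first argmax on an ascending
    grid).  For a high-pass band the upper limit is the grid maximum.
    """
    hi = band.hi if band.hi is not None else np.inf
    mask = (psd.frequencies >= band.lo) & (psd.frequencies <= hi)
    if not np.any(mask):
        raise ValueError(
            f"band {band.name!r} [{band.lo}, {band.hi}] Hz does not intersect "
            "the PSD frequency grid"
        )
    f_band = psd.frequencies[mask]
    p_band = psd.power[mask]
    i = int(np.argmax(p_band))
    return float(f_band[i]), float(p_band[i])


def band_power_timecourse(
    rec: Recording | np.ndarray,
    band: BandSpec,
    window: float = 60.0,
    step: float = 10.0,
    fs: float | None = None,
    nperseg_fraction: float = 0.25,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sliding-window dominant-band power (and frequency) timecourse.

    Each window is analysed with a Welch PSD whose segment length is
    ``nperseg_fraction`` of the window (several averages per estimate),
    then reduced to the dominant frequency and its power inside ``band``.
    Returns (window-centre times, dominant power, dominant frequency).
    """
    x, fs_rec = _as_array(rec)
    fs = fs_rec if fs_rec is not None else fs
    if fs is None:
        raise ValueError("fs must be given for plain-array input")
    if step <= 0:
        raise ValueError(f"step must be > 0, got {step}")
    n = x.size
    w = int(round(window * fs))
    if w > n:
        raise ValueError(
            f"window ({window} s) longer than the signal ({n / fs:.3g} s)"
        )
    s = max(int(round(step * fs)), 1)
    centers, powers, freqs = [], [], []
    for start in range(0, n - w + 1, s):
        seg = x[start : start + w]
        psd = welch_psd(
            seg, fs=fs, window_length=window * nperseg_fraction, allow_short=True
        )
        fd, pd_ = dominant_frequency(psd, band)
        centers.append((start + w / 2) / fs)
        powers.append(pd_)
        freqs.append(fd)
    return np.asarray(centers), np.asarray(powers), np.asarray(freqs)
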