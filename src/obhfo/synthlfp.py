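"""Forward-model generator of laminar olfactory-bulb-like recordings.

The generator renders, with fully known ground truth, the statistical
structure that the analysis stages assume:

* a quasi-periodic respiration drive (phase oscillator with lognormal
  per-cycle period jitter) whose trough marks inhalation;
* a slow "delta" LFP component locked to the respiration phase, projected
  onto the probe through a sign-reversing dipole profile;
* high-frequency oscillation (HFO) bursts — Hann-windowed sinusoids in the
  80–130 Hz range — whose occurrence within each respiration cycle is gated
  by a von Mises distribution around a configurable lock phase, projected
  through a second dipole centred near the mitral layer;
* a weak continuous gamma-band component (for two-condition power
  contrasts);
* multi-unit spiking locked to the HFO carrier phase, injected into the
  wideband trace as brief biphasic transients;
* channel-wise white plus 1/f ("pink") noise with a 50% common-mode share.

All randomness flows from explicit integer seeds through
``numpy.random.SeedSequence``; identical parameters give bit-identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.special import i0

from .containers import ProbeGeometry, Recording

__all__ = [
    "GroundTruth",
    "SimulationResult",
    "generate_respiration",
    "generate_laminar_recording",
    "generate_mua",
    "generate_condition_pair",
    "dipole_profile",
]


@dataclass
class GroundTruth:
    """Full generative parameter set of a synthetic laminar recording.

    Units: frequencies in Hz, times in s, depths in μm, amplitudes and
    noise levels in mV, phases in radians.  Phase convention: the LFP
    delta component is ``cos(theta)`` of the respiration phase, so its
    peak is phase 0; the respiration (thermocouple-like) trace is
    ``-cos(theta)``, so its trough (inhalation) coincides with the LFP
    delta peak.  ``lock_phase`` is the respiration/delta phase at which
    HFO bursts preferentially occur (default π/4, early descending
    phase).  ``mua_lock_phase`` is the HFO carrier phase of maximal
    spiking with the carrier peak at 0, so the default π locks spikes to
    the oscillation trough.
    """

    seed: int = 0
    fs: float = 2000.0
    duration: float = 60.0
    f_resp: float = 1.5
    f_hfo: float = 105.0
    f_gamma: float = 50.0
    burst_rate: float = 1.0
    burst_duration: float = 0.1
    burst_freq_jitter: float = 5.0
    coupling_kappa: float = 4.0
    lock_phase: float = math.pi / 4
    resp_jitter_cv: float = 0.1
    hfo_dipole_depth: float = 1600.0
    hfo_dipole_halfwidth: float = 200.0
    delta_dipole_depth: float = 2000.0
    delta_dipole_halfwidth: float = 300.0
    mua_lock_phase: float = math.pi
    mua_lock_kappa: float = 4.0
    mua_rate: float = 100.0
    spike_amp_mv: float = 0.15
    delta_amp_mv: float = 0.5
    hfo_amp_mv: float = 0.2
    gamma_amp_mv: float = 0.05
    noise_white_sd: float = 0.01
    noise_pink_scale: float = 0.02
    condition_scalers: dict = field(
        default_factory=lambda: {"delta": 1.0, "gamma": 1.0, "hfo": 1.0}
    )

    def validate(self, geometry: ProbeGeometry | None = None) -> None:
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")
        if self.fs <= 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")
        if self.fs <= 2 * self.f_hfo:
            raise ValueError(
                f"fs={self.fs} must exceed 2*f_hfo={2 * self.f_hfo} (aliasing)"
            )
        if self.burst_duration * self.burst_rate >= 1:
            raise ValueError("burst_duration * burst_rate must be < 1")
        if self.coupling_kappa < 0:
            raise ValueError(f"coupling_kappa must be >= 0, got {self.coupling_kappa}")
        if self.mua_rate < 0:
            raise ValueError(f"mua_rate must be >= 0, got {self.mua_rate}")
        if not 0 <= self.resp_jitter_cv < 0.5:
            raise ValueError(
                f"resp_jitter_cv must be in [0, 0.5), got {self.resp_jitter_cv}"
            )
        for k, v in self.condition_scalers.items():
            if v <= 0:
                raise ValueError(f"condition scaler {k!r} must be > 0, got {v}")
        if geometry is not None:
            lo, hi = geometry.span_um
            for name in ("hfo_dipole_depth", "delta_dipole_depth"):
                d = getattr(self, name)
                if not lo <= d <= hi:
                    raise ValueError(
                        f"{name}={d} outside probe span [{lo}, {hi}] um"
                    )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(**d)


@dataclass
class SimulationResult:
    """Everything a simulated session produced, with ground truth attached.

    ``bursts`` is the true event table (columns onset_s, offset_s, peak_s,
    channel, kind, resp_phase, f_hz, amp_mv); ``spikes`` is a list of
    per-channel spike-time arrays (s).
    """

    lfp: Recording
    respiration: Recording
    bursts: pd.DataFrame
    spikes: list
    ground_truth: GroundTruth
    geometry: ProbeGeometry

    def __iter__(self):
        # allow (lfp, respiration, bursts) tuple unpacking
        return iter((self.lfp, self.respiration, self.bursts))


# ---------------------------------------------------------------------------
# respiration phase oscillator
# ---------------------------------------------------------------------------

def _respiration_phase(
    duration: float, fs: float, f_resp: float, cv: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous respiration phase (rad) and cycle-start times.

    Successive cycle periods are lognormal with mean 1/f_resp and
    coefficient of variation ``cv``; the phase advances linearly within
    each cycle, giving an exact ground-truth phase reference.
    """
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    mean_period = 1.0 / f_resp
    n_cycles = int(math.ceil(duration / mean_period * 2)) + 8
    if cv > 0:
        sig = math.sqrt(math.log1p(cv**2))
        mu = math.log(mean_period) - sig**2 / 2
        periods = rng.lognormal(mean=mu, sigma=sig, size=n_cycles)
    else:
        periods = np.full(n_cycles, mean_period)
    while periods.sum() < duration:  # vanishingly rare under cv < 0.5
        periods = np.concatenate([periods, rng.lognormal(mu, sig, size=8)])
    boundaries = np.concatenate(([0.0], np.cumsum(periods)))
    # piecewise-linear phase: 2*pi*k at each cycle boundary
    phase = np.interp(t, boundaries, 2 * np.pi * np.arange(len(boundaries)))
    return phase, boundaries


def _resp_waveform(phase: np.ndarray) -> np.ndarray:
    # trough at phase 0 (inhalation), mild second harmonic for a
    # thermocouple-like asymmetric shape
    return -np.cos(phase) - 0.15 * np.cos(2 * phase)


def generate_respiration(
    duration: float,
    fs: float,
    f_resp: float = 1.5,
    cycle_jitter_cv: float = 0.1,
    seed: int = 0,
) -> Recording:
    """Synthesize a thermocouple-like respiration trace.

    The trace is a quasi-periodic oscillation at ``f_resp`` whose cycle
    periods jitter with the given coefficient of variation.  The trough
    corresponds to inhalation by convention.  Deterministic per seed.
    """
    if duration <= 0:
        raise ValueError(f"duration must be > 0, got {duration}")
    if fs < 100:
        raise ValueError(f"fs must be >= 100 Hz for respiration, got {fs}")
    if not 0 <= cycle_jitter_cv < 0.5:
        raise ValueError(
            f"cycle_jitter_cv must be in [0, 0.5), got {cycle_jitter_cv}"
        )
    rng = np.random.default_rng(seed)
    phase, _ = _respiration_phase(duration, fs, f_resp, cycle_jitter_cv, rng)
    return Recording(
        samples=_resp_waveform(phase), fs=fs, channel_labels=["respiration"]
    )


# ---------------------------------------------------------------------------
# spatial profiles and noise
# ---------------------------------------------------------------------------

def dipole_profile(
    depths_um: np.ndarray, center_um: float, halfwidth_um: float
) -> np.ndarray:
    """Sign-reversing laminar dipole weight: difference of two Gaussians.

    Positive lobe dorsal to (above) the centre, negative lobe ventral;
    exact zero crossing at the centre depth.  Normalised to peak |w| = 1.
    """
    d = np.asarray(depths_um, dtype=float)
    s = halfwidth_um
    w = np.exp(-((d - (center_um - s)) ** 2) / (2 * s**2)) - np.exp(
        -((d - (center_um + s)) ** 2) / (2 * s**2)
    )
    peak = np.max(np.abs(w))
    return w / peak if peak > 0 else w


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-SD 1/f-shaped noise via spectral shaping of white noise."""
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0)
    # flatten below the first nonzero bin so DC is not singular
    scale = 1.0 / np.sqrt(np.maximum(f, f[1] if n > 1 else 1.0))
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _spike_kernel(fs: float, tau: float = 2e-4) -> np.ndarray:
    """Biphasic extracellular spike transient, negative-leading, peak |1|."""
    half = max(int(round(6 * tau * fs)), 2)
    tk = np.arange(-half, half + 1) / fs
    k = -np.exp(-(tk**2) / (2 * tau**2)) + 0.35 * np.exp(
        -((tk - 3 * tau) ** 2) / (2 * (1.5 * tau) ** 2)
    )
    return k / np.max(np.abs(k))


# ---------------------------------------------------------------------------
# laminar recording
# ---------------------------------------------------------------------------

def _draw_bursts(
    gt: GroundTruth,
    boundaries: np.ndarray,
    rng: np.random.Generator,
    scale_hfo: float,
) -> pd.DataFrame:
    """Draw burst events cycle by cycle, gated by the von Mises lock."""
    rows = []
    p_burst = min(gt.burst_rate / gt.f_resp, 1.0)
    half = gt.burst_duration / 2
    n_cycles = len(boundaries) - 1
    for k in range(n_cycles):
        t0, t1 = boundaries[k], boundaries[k + 1]
        if t0 > gt.duration:
            break
        if rng.random() >= p_burst:
            continue
        psi = rng.vonmises(gt.lock_phase, gt.coupling_kappa)
        frac = (psi % (2 * np.pi)) / (2 * np.pi)
        peak = t0 + frac * (t1 - t0)
        f_b = gt.f_hfo + rng.uniform(-gt.burst_freq_jitter, gt.burst_freq_jitter)
        if peak - half < 0 or peak + half > gt.duration:
            continue
        rows.append(
            {
                "onset_s": peak - half,
                "offset_s": peak + half,
                "peak_s": peak,
                "channel": -1,
                "kind": "hfo",
                "resp_phase": float(np.angle(np.exp(1j * psi))),
                "f_hz": f_b,
                "amp_mv": gt.hfo_amp_mv * scale_hfo,
            }
        )
    cols = [
        "onset_s", "offset_s", "peak_s", "channel", "kind",
        "resp_phase", "f_hz", "amp_mv",
    ]
    return pd.DataFrame(rows, columns=cols)


def _render_hfo_source(
    bursts: pd.DataFrame, n: int, fs: float
) -> np.ndarray:
    """Sum of unit-amplitude Hann-windowed sinusoids at each burst."""
    src = np.zeros(n)
    for row in bursts.itertuples(index=False):
        i0_ = int(round(row.onset_s * fs))
        i1 = int(round(row.offset_s * fs))
        i0_, i1 = max(i0_, 0), min(i1, n)
        if i1 <= i0_ + 2:
            continue
        tt = np.arange(i0_, i1) / fs
        win = np.hanning(i1 - i0_)
        src[i0_:i1] += win * np.cos(2 * np.pi * row.f_hz * (tt - row.peak_s))
    return src


def generate_laminar_recording(
    gt: GroundTruth,
    geometry: ProbeGeometry | None = None,
    scalers: dict | None = None,
    include_mua: bool = True,
) -> SimulationResult:
    """Render a full laminar session from the generative parameters.

    Each channel is the sum of the delta source and the HFO burst source,
    weighted by their respective sign-reversing dipole profiles, plus a
    spatially uniform gamma component, phase-locked spike transients, and
    white + pink noise.  Returns the recording, the paired respiration
    trace, the true burst table, and per-channel spike times.
    """
    geometry = geometry or ProbeGeometry()
    gt.validate(geometry)
    scalers = dict(scalers or {"delta": 1.0, "gamma": 1.0, "hfo": 1.0})
    for k, v in scalers.items():
        if v <= 0:
            raise ValueError(f"condition scaler {k!r} must be > 0, got {v}")
    sc_delta = math.sqrt(scalers.get("delta", 1.0))
    sc_gamma = math.sqrt(scalers.get("gamma", 1.0))
    sc_hfo = math.sqrt(scalers.get("hfo", 1.0))

    ss = np.random.SeedSequence(gt.seed)
    rng_resp, rng_burst, rng_noise, rng_mua, rng_gamma = (
        np.random.default_rng(c) for c in ss.spawn(5)
    )

    n = int(round(gt.duration * gt.fs))
    t = np.arange(n) / gt.fs
    phase, boundaries = _respiration_phase(
        gt.duration, gt.fs, gt.f_resp, gt.resp_jitter_cv, rng_resp
    )
    respiration = Recording(
        samples=_resp_waveform(phase), fs=gt.fs, channel_labels=["respiration"]
    )

    delta_src = gt.delta_amp_mv * sc_delta * np.cos(phase)
    bursts = _draw_bursts(gt, boundaries, rng_burst, sc_hfo)
    hfo_src = gt.hfo_amp_mv * sc_hfo * _render_hfo_source(bursts, n, gt.fs)
    # gamma: narrowband tone with a slow phase random walk (~1 Hz linewidth)
    walk = np.cumsum(rng_gamma.normal(0.0, math.sqrt(2 * np.pi / gt.fs), size=n))
    gamma_src = gt.gamma_amp_mv * sc_gamma * np.cos(2 * np.pi * gt.f_gamma * t + walk)

    depths = geometry.depths_um
    w_hfo = dipole_profile(depths, gt.hfo_dipole_depth, gt.hfo_dipole_halfwidth)
    w_delta = dipole_profile(
        depths, gt.delta_dipole_depth, gt.delta_dipole_halfwidth
    )

    samples = np.outer(w_delta, delta_src) + np.outer(w_hfo, hfo_src)
    samples += gamma_src[None, :]

    if gt.noise_white_sd > 0 or gt.noise_pink_scale > 0:
        common = _pink_noise(rng_noise, n)
        for c in range(geometry.n_channels):
            white = rng_noise.normal(0.0, gt.noise_white_sd, size=n)
            own = _pink_noise(rng_noise, n)
            pink = gt.noise_pink_scale * (
                math.sqrt(0.5) * own + math.sqrt(0.5) * common
            )
            samples[c] += white + pink

    spikes: list[np.ndarray] = [np.array([]) for _ in range(geometry.n_channels)]
    if include_mua and gt.mua_rate > 0 and len(bursts):
        mua = generate_mua(bursts, gt, gt.fs, geometry=geometry, rng=rng_mua)
        spikes = mua.spike_times
        samples += mua.waveform

    lfp = Recording(samples=samples, fs=gt.fs, depths_um=depths)
    return SimulationResult(
        lfp=lfp,
        respiration=respiration,
        bursts=bursts,
        spikes=spikes,
        ground_truth=gt,
        geometry=geometry,
    )


# ---------------------------------------------------------------------------
# multi-unit activity
# ---------------------------------------------------------------------------

@dataclass
class MUAResult:
    """Spike times per channel plus the injectable transient waveform."""

    spike_times: list
    waveform: np.ndarray


def generate_mua(
    true_bursts: pd.DataFrame,
    gt: GroundTruth,
    fs: float,
    geometry: ProbeGeometry | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> MUAResult:
    """Draw burst-locked spikes and render their wideband transients.

    Within each burst, spikes follow an inhomogeneous point process whose
    rate peaks at ``gt.mua_lock_phase`` of the HFO carrier (peak = 0), with
    von Mises sharpness ``gt.mua_lock_kappa``; the cycle-averaged rate is
    ``gt.mua_rate`` scaled per channel by the magnitude of the HFO dipole
    weight.  Each spike adds a brief biphasic (>500 Hz) transient to the
    waveform so threshold-based detectors can recover it.
    """
    if gt.mua_rate < 0:
        raise ValueError(f"mua_rate must be >= 0, got {gt.mua_rate}")
    n_channels = geometry.n_channels if geometry is not None else 1
    duration = gt.duration
    n = int(round(duration * fs))
    if rng is None:
        rng = np.random.default_rng(gt.seed + 1 if seed is None else seed)

    empty = MUAResult(
        spike_times=[np.array([]) for _ in range(n_channels)],
        waveform=np.zeros((n_channels, n)),
    )
    if gt.mua_rate == 0 or true_bursts is None or len(true_bursts) == 0:
        return empty

    # channel-independent modulation profile lambda(t)/rate over burst samples
    lam_norm = np.zeros(n)
    for row in true_bursts.itertuples(index=False):
        i0_ = max(int(round(row.onset_s * fs)), 0)
        i1 = min(int(round(row.offset_s * fs)), n)
        if i1 <= i0_:
            continue
        tt = np.arange(i0_, i1) / fs
        phi = 2 * np.pi * row.f_hz * (tt - row.peak_s)
        lam_norm[i0_:i1] = np.exp(
            gt.mua_lock_kappa * np.cos(phi - gt.mua_lock_phase)
        ) / i0(gt.mua_lock_kappa)

    if geometry is not None:
        w = np.abs(
            dipole_profile(
                geometry.depths_um, gt.hfo_dipole_depth, gt.hfo_dipole_halfwidth
            )
        )
    else:
        w = np.ones(1)

    kernel = _spike_kernel(fs)
    spike_times: list[np.ndarray] = []
    waveform = np.zeros((n_channels, n))
    active = lam_norm > 0
    idx_active = np.flatnonzero(active)
    for c in range(n_channels):
        p = gt.mua_rate * w[c] * lam_norm[idx_active] / fs
        hits = idx_active[rng.random(idx_active.size) < p]
        spike_times.append(hits / fs)
        if hits.size:
            train = np.zeros(n)
            train[hits] = gt.spike_amp_mv
            waveform[c] = sps.fftconvolve(train, kernel, mode="same")
    return MUAResult(spike_times=spike_times, waveform=waveform)


# ---------------------------------------------------------------------------
# condition contrasts
# ---------------------------------------------------------------------------

def generate_condition_pair(
    gt: GroundTruth,
    scalers: dict | None = None,
    geometry: ProbeGeometry | None = None,
) -> tuple[Recording, Recording]:
    """Render a matched pair of recordings for a two-condition contrast.

    Both recordings share the seed, hence identical respiration, burst
    times, noise and spikes; the second has each band's source amplitude
    multiplied by the square root of its power scaler (so measured band
    power scales by the scaler itself).  With all scalers at 1 the two
    recordings are bit-identical.
    """
    scalers = dict(scalers if scalers is not None else gt.condition_scalers)
    for k, v in scalers.items():
        if v <= 0:
            raise ValueError(f"condition scaler {k!r} must be > 0, got {v}")
    base = generate_laminar_recording(gt, geometry=geometry)
    scaled = generate_laminar_recording(gt, geometry=geometry, scalers=scalers)
    return base.lfp, scaled.lfp
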