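"""Burst detection and cross-signal / cross-frequency coupling statistics.

This module quantifies how high-frequency oscillation (HFO) bursts relate
to the respiration-locked delta rhythm:

* envelope-threshold burst detection (default 3 robust SDs);
* burst phase relative to the delta cycle, by time-rescaling between
  successive delta peaks (default) or by instantaneous Hilbert phase;
* intertrial phase clustering, ITPC = \\|n^-1 sum_r exp(i k_r)\\|;
* Pearson correlation between a slow waveform and a fast-band envelope;
* the Tort modulation index (normalised KL divergence of the phase-binned
  amplitude distribution from uniform) and comodulogram matrices over a
  (phase frequency x amplitude frequency) grid;
* a group-level resampling test comparing two sets of comodulograms cell
  by cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.stats import pearsonr

from .containers import Recording
from .sigproc import BandSpec, analytic_envelope_phase, bandpass, settle_samples

__all__ = [
    "BurstEvent",
    "PhaseSet",
    "Comodulogram",
    "detect_bursts",
    "burst_delta_phase",
    "itpc",
    "envelope_correlation",
    "tort_mi",
    "comodulogram",
    "mi_resampling_test",
]


@dataclass
class BurstEvent:
    """One detected oscillatory burst on one channel."""

    onset_s: float
    offset_s: float
    peak_s: float
    peak_envelope: float
    channel: int = 0
    band: BandSpec | None = None

    def __post_init__(self) -> None:
        if not (self.onset_s < self.peak_s <= self.offset_s):
            raise ValueError(
                f"burst times must satisfy onset < peak <= offset, got "
                f"({self.onset_s}, {self.peak_s}, {self.offset_s})"
            )
        if self.peak_envelope <= 0:
            raise ValueError(f"peak_envelope must be > 0, got {self.peak_envelope}")


@dataclass
class PhaseSet:
    """Phases (radians, one per burst) with their reference convention."""

    phases: np.ndarray
    convention: str = "delta_peak_zero"
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float)
        # wrap into (-pi, pi]
        self.phases = np.angle(np.exp(1j * self.phases))

    def __len__(self) -> int:
        return self.phases.size

    def circular_mean(self) -> float:
        if self.phases.size == 0:
            raise ValueError("empty phase set has no circular mean")
        return float(np.angle(np.mean(np.exp(1j * self.phases))))


@dataclass
class Comodulogram:
    """Modulation-index matrix over a phase x amplitude frequency grid.

    ``mi[i, j]`` is the Tort MI for phase frequency ``phase_freqs[i]`` and
    amplitude frequency ``amp_freqs[j]``; cells whose bands overlap are
    NaN (flagged invalid, never computed).
    """

    phase_freqs: np.ndarray
    amp_freqs: np.ndarray
    mi: np.ndarray
    n_phase_bins: int = 18
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.phase_freqs = np.asarray(self.phase_freqs, dtype=float)
        self.amp_freqs = np.asarray(self.amp_freqs, dtype=float)
        self.mi = np.asarray(self.mi, dtype=float)
        if self.mi.shape != (self.phase_freqs.size, self.amp_freqs.size):
            raise ValueError("mi matrix shape does not match the frequency grids")
        valid = self.mi[np.isfinite(self.mi)]
        if np.any(valid < 0) or np.any(valid > 1):
            raise ValueError("modulation index values must lie in [0, 1]")

    def argmax_cell(self) -> tuple[float, float]:
        """(phase frequency, amplitude frequency) of the largest MI cell."""
        m = np.where(np.isfinite(self.mi), self.mi, -np.inf)
        i, j = np.unravel_index(int(np.argmax(m)), m.shape)
        return float(self.phase_freqs[i]), float(self.amp_freqs[j])


# ---------------------------------------------------------------------------
# burst detection
# ---------------------------------------------------------------------------

def detect_bursts(
    env: np.ndarray,
    fs: float,
    threshold_sd: float = 3.0,
    baseline: str = "robust",
    quiet_segment: tuple[float, float] | None = None,
    band: BandSpec | None = None,
    min_duration_s: float | None = None,
    merge_gap_s: float | None = None,
    channel: int = 0,
) -> list[BurstEvent]:
    """Detect envelope bursts exceeding ``mean + threshold_sd * SD``.

    The baseline statistics default to a robust whole-trace estimate
    (median centre, 1.4826*MAD scale) since bursts inflate the plain SD;
    ``baseline='quiet'`` with a ``quiet_segment=(t0, t1)`` instead uses the
    plain mean/SD of a user-marked burst-free stretch.  Runs shorter than
    ``min_duration_s`` are dropped and gaps shorter than ``merge_gap_s``
    merged; the defaults are 3 and 1 cycles of the band centre.  A
    constant envelope yields zero bursts.
    """
    env = np.asarray(env, dtype=float)
    if threshold_sd < 0:
        raise ValueError(f"threshold_sd must be >= 0, got {threshold_sd}")
    if np.any(env < 0):
        raise ValueError("envelope must be nonnegative")
    if min_duration_s is None:
        min_duration_s = 3.0 / band.center if band is not None else 0.03
    if merge_gap_s is None:
        merge_gap_s = 1.0 / band.center if band is not None else 0.01

    if baseline == "robust":
        center = float(np.median(env))
        sd = 1.4826 * float(np.median(np.abs(env - center)))
    elif baseline == "quiet":
        if quiet_segment is None:
            raise ValueError("baseline='quiet' requires quiet_segment=(t0, t1)")
        i0 = int(round(quiet_segment[0] * fs))
        i1 = int(round(quiet_segment[1] * fs))
        seg = env[i0:i1]
        if seg.size < 2:
            raise ValueError("quiet segment too short")
        center = float(seg.mean())
        sd = float(seg.std())
    else:
        raise ValueError(f"unknown baseline policy {baseline!r}")

    if sd == 0:
        return []
    thr = center + threshold_sd * sd

    above = env > thr
    if not np.any(above):
        return []
    edges = np.diff(above.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)  # exclusive
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(env.size)

    # merge short gaps
    merged: list[list[int]] = []
    gap = int(round(merge_gap_s * fs))
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] < gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    min_len = max(int(round(min_duration_s * fs)), 1)
    events = []
    for s, e in merged:
        if e - s < min_len:
            continue
        peak_i = s + int(np.argmax(env[s:e]))
        events.append(
            BurstEvent(
                onset_s=(s - 0.5) / fs,
                offset_s=(e - 0.5) / fs,
                peak_s=peak_i / fs,
                peak_envelope=float(env[peak_i]),
                channel=channel,
                band=band,
            )
        )
    return events


# ---------------------------------------------------------------------------
# burst phase relative to delta
# ---------------------------------------------------------------------------

def burst_delta_phase(
    bursts,
    delta: np.ndarray,
    fs: float,
    hi_delta: float = 3.0,
    method: str = "rescale",
) -> PhaseSet:
    """Phase of each burst peak within the delta cycle (peak = 0).

    ``method='rescale'`` (default): delta peaks are found as local maxima
    separated by at least half the fastest delta period; each burst's
    phase is ``2*pi * (peak_s - preceding_peak) / cycle_period`` wrapped
    into (-pi, pi].  ``method='hilbert'`` instead samples the
    instantaneous Hilbert phase of the delta trace at the burst peak.
    Bursts falling before the first or after the last delta peak are
    skipped and counted in ``n_skipped``.
    """
    delta = np.asarray(delta, dtype=float)
    peak_times = _burst_peak_times(bursts)
    if method == "hilbert":
        _, phi = analytic_envelope_phase(delta)
        idx = np.round(np.asarray(peak_times) * fs).astype(int)
        ok = (idx >= 0) & (idx < delta.size)
        return PhaseSet(phases=phi[idx[ok]], convention="delta_peak_zero",
                        n_skipped=int(np.sum(~ok)))
    if method != "rescale":
        raise ValueError(f"unknown method {method!r}")

    min_sep = int(round(fs / (2 * hi_delta)))
    peaks, _ = sps.find_peaks(delta, distance=max(min_sep, 1))
    if peaks.size < 2:
        raise ValueError("need at least two delta peaks (one full cycle)")
    pt = peaks / fs
    phases = []
    skipped = 0
    for tb in peak_times:
        k = int(np.searchsorted(pt, tb, side="right")) - 1
        if k < 0 or k >= pt.size - 1:
            skipped += 1
            continue
        period = pt[k + 1] - pt[k]
        phases.append(2 * np.pi * (tb - pt[k]) / period)
    return PhaseSet(phases=np.asarray(phases), convention="delta_peak_zero",
                    n_skipped=skipped)


def _burst_peak_times(bursts) -> list[float]:
    if hasattr(bursts, "itertuples"):  # event-table DataFrame
        return [float(r.peak_s) for r in bursts.itertuples(index=False)]
    return [float(b.peak_s) for b in bursts]


# ---------------------------------------------------------------------------
# circular and correlation statistics
# ---------------------------------------------------------------------------

def itpc(ps) -> float:
    """Intertrial phase clustering: modulus of the mean unit phasor.

    Equals 1 iff all phases coincide, 0 for perfectly cancelling phase
    sets, and is invariant to a global phase rotation.
    """
    phases = ps.phases if isinstance(ps, PhaseSet) else np.asarray(ps, dtype=float)
    if phases.size == 0:
        raise ValueError("ITPC is undefined for an empty phase set")
    return float(np.abs(np.mean(np.exp(1j * phases))))


def envelope_correlation(
    x: np.ndarray,
    y: np.ndarray,
    fs_x: float | None = None,
    fs_y: float | None = None,
) -> float:
    """Pearson correlation between two series, resampled to a common rate.

    Typically a slow band-filtered waveform against a fast-band envelope,
    but any signal-signal pair works.  If sampling rates differ, the
    faster series is decimated to the slower rate with a polyphase
    anti-aliased resampler.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if fs_x is not None and fs_y is not None and fs_x != fs_y:
        if fs_x > fs_y:
            x = _decimate_to(x, fs_x, fs_y)
        else:
            y = _decimate_to(y, fs_y, fs_x)
    n = min(x.size, y.size)
    x, y = x[:n], y[:n]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined: zero-variance input")
    return float(pearsonr(x, y)[0])


def _decimate_to(x: np.ndarray, fs_from: float, fs_to: float) -> np.ndarray:
    frac = _as_fraction(fs_to / fs_from)
    return sps.resample_poly(x, frac[0], frac[1])


def _as_fraction(ratio: float, max_den: int = 10000) -> tuple[int, int]:
    from fractions import Fraction

    fr = Fraction(ratio).limit_denominator(max_den)
    return fr.numerator, fr.denominator


# ---------------------------------------------------------------------------
# Tort modulation index
# ---------------------------------------------------------------------------

def tort_mi(phase: np.ndarray, amplitude: np.ndarray, n_bins: int = 18) -> float:
    """Phase-amplitude modulation index (Tort method).

    Phases are binned into ``n_bins`` equal bins over (-pi, pi]; the mean
    amplitude per bin, normalised to sum 1, gives a distribution P whose
    deviation from uniform is measured as
    ``MI = (log N - H(P)) / log N`` with natural logs.  MI is 0 for
    amplitude independent of phase and 1 when all amplitude concentrates
    in a single bin.
    """
    phase = np.asarray(phase, dtype=float)
    amplitude = np.asarray(amplitude, dtype=float)
    if phase.shape != amplitude.shape:
        raise ValueError("phase and amplitude must have equal length")
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    # map phase into (-pi, pi] and assign bins; right edge inclusive
    ph = np.angle(np.exp(1j * phase))
    idx = np.clip(np.searchsorted(edges, ph, side="left") - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    if np.any(counts == 0):
        raise ValueError(
            f"{int(np.sum(counts == 0))} of {n_bins} phase bins are empty; "
            "use fewer bins or a longer signal"
        )
    sums = np.bincount(idx, weights=amplitude, minlength=n_bins)
    p = sums / counts
    total = p.sum()
    if total <= 0:
        return 0.0
    p = p / total
    nz = p[p > 0]
    entropy = -float(np.sum(nz * np.log(nz)))
    return float((math.log(n_bins) - entropy) / math.log(n_bins))


def comodulogram(
    rec: Recording | np.ndarray,
    phase_freqs,
    amp_freqs,
    fs: float | None = None,
    phase_halfwidth: float = 0.5,
    amp_halfwidth: float = 15.0,
    n_bins: int = 18,
    order: int = 4,
) -> Comodulogram:
    """Tort-MI matrix over a (phase frequency x amplitude frequency) grid.

    For each cell the signal is band-passed around both centre
    frequencies (phase band +-``phase_halfwidth`` Hz, amplitude band
    +-``amp_halfwidth`` Hz), the slow phase and fast envelope extracted by
    Hilbert transform, and the modulation index computed after trimming
    the filter-settling margins.  Cells whose two bands overlap are
    flagged invalid (NaN).
    """
    if isinstance(rec, Recording):
        x, fs = rec.samples[0] if rec.n_channels == 1 else None, rec.fs
        if x is None:
            raise ValueError("comodulogram expects a 1-channel recording")
    else:
        x = np.asarray(rec, dtype=float)
        if fs is None:
            raise ValueError("fs must be given for plain-array input")
    phase_freqs = np.asarray(phase_freqs, dtype=float)
    amp_freqs = np.asarray(amp_freqs, dtype=float)
    nyq = fs / 2
    if np.any(amp_freqs + amp_halfwidth >= nyq):
        raise ValueError("amplitude band grid exceeds the Nyquist frequency")
    slowest = phase_freqs.min()
    if x.size / fs < 10.0 / slowest:
        raise ValueError(
            "signal too short: need at least 10 cycles of the slowest "
            f"phase frequency ({slowest} Hz)"
        )

    mi = np.full((phase_freqs.size, amp_freqs.size), np.nan)
    for i, fp in enumerate(phase_freqs):
        p_lo = max(fp - phase_halfwidth, 0.1 * fp)
        p_hi = fp + phase_halfwidth
        pband = BandSpec(f"p{fp:g}", p_lo, p_hi)
        sos = sps.butter(order, [p_lo, p_hi], btype="bandpass", fs=fs, output="sos")
        slow = sps.sosfiltfilt(sos, x)
        _, phi = analytic_envelope_phase(slow)
        trim = min(settle_samples(pband, fs), x.size // 4)
        sl = slice(trim, x.size - trim if trim > 0 else x.size)
        for j, fa in enumerate(amp_freqs):
            a_lo, a_hi = fa - amp_halfwidth, fa + amp_halfwidth
            if a_lo <= p_hi:  # overlapping bands: cell invalid
                continue
            sos_a = sps.butter(
                order, [a_lo, a_hi], btype="bandpass", fs=fs, output="sos"
            )
            fast = sps.sosfiltfilt(sos_a, x)
            env, _ = analytic_envelope_phase(fast)
            mi[i, j] = tort_mi(phi[sl], env[sl], n_bins=n_bins)
    return Comodulogram(
        phase_freqs=phase_freqs,
        amp_freqs=amp_freqs,
        mi=mi,
        n_phase_bins=n_bins,
        meta={
            "phase_halfwidth_hz": phase_halfwidth,
            "amp_halfwidth_hz": amp_halfwidth,
            "fs_hz": fs,
        },
    )


# ---------------------------------------------------------------------------
# group-level resampling test
# ---------------------------------------------------------------------------

def mi_resampling_test(
    group_a: list,
    group_b: list,
    n_draws: int = 100_000,
    seed: int = 0,
) -> np.ndarray:
    """Cell-wise resampling test between two groups of comodulograms.

    The resampling unit is the per-subject matrix cell value.  For each
    cell, the observed statistic is the absolute difference of group
    means; the null pools both groups' values and redraws two
    pseudo-groups of the original sizes with replacement ``n_draws``
    times.  The p-value uses add-one smoothing,
    ``p = (1 + #{null >= observed}) / (1 + n_draws)``, and is bit-exact
    reproducible for a fixed seed.  Cells invalid in any subject are NaN.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 comodulograms per group")
    stack_a = _stack_group(group_a)
    stack_b = _stack_group(group_b)
    if stack_a.shape[1:] != stack_b.shape[1:]:
        raise ValueError("comodulogram grids are not congruent between groups")
    n_a, n_b = stack_a.shape[0], stack_b.shape[0]
    shape = stack_a.shape[1:]
    rng = np.random.default_rng(seed)
    p = np.full(shape, np.nan)
    for i in range(shape[0]):
        for j in range(shape[1]):
            va, vb = stack_a[:, i, j], stack_b[:, i, j]
            if not (np.all(np.isfinite(va)) and np.all(np.isfinite(vb))):
                continue
            obs = abs(va.mean() - vb.mean())
            pool = np.concatenate([va, vb])
            draw_a = pool[rng.integers(0, pool.size, size=(n_draws, n_a))]
            draw_b = pool[rng.integers(0, pool.size, size=(n_draws, n_b))]
            null = np.abs(draw_a.mean(axis=1) - draw_b.mean(axis=1))
            p[i, j] = (1 + int(np.sum(null >= obs))) / (1 + n_draws)
    return p


def _stack_group(group: list) -> np.ndarray:
    mats = []
    grid = None
    for cm in group:
        if isinstance(cm, Comodulogram):
            g = (tuple(cm.phase_freqs), tuple(cm.amp_freqs))
            m = cm.mi
        else:
            m = np.asarray(cm, dtype=float)
            g = m.shape
        if grid is None:
            grid = g
        elif g != grid:
            raise ValueError("comodulogram grids are not congruent within a group")
        mats.append(m)
    return np.stack(mats)
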