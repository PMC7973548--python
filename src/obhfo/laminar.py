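"""Depth-resolved analyses for laminar probe recordings.

Covers the spatial signature of a laminar oscillation generator:

* per-channel dominant-band power profiles;
* inter-channel phase shift relative to a reference channel, from the
  cross-correlation lag inside burst windows (a phase reversal across a
  dipole shows up as a ~180 degree step in this profile);
* 1D kernel current-source-density (kCSD) reconstruction: sources are
  modelled as a sum of Gaussian basis functions along the probe, mapped
  to electrode potentials by a quasi-1D line-source forward operator, and
  inverted with Tikhonov regularisation; the regularisation weight is
  chosen by leave-one-electrode-out cross-validation;
* band-filtering of reconstructed CSD maps (reconstruct first, filter
  second);
* multi-unit activity (MUA) extraction from the >500 Hz band by robust
  threshold crossing, and the correlation between the burst-aligned spike
  histogram and the average HFO waveform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.stats import pearsonr

from .containers import ProbeGeometry, Recording
from .sigproc import BandSpec, bandpass, dominant_frequency, welch_psd

__all__ = [
    "CSDMap",
    "DepthProfile",
    "MUADensity",
    "depth_power_profile",
    "interchannel_phase_shift",
    "kcsd_reconstruct",
    "band_filtered_csd",
    "detect_mua",
    "mua_hfo_correlation",
    "reversal_depth_from_profile",
    "reversal_depth_from_csd",
]


@dataclass
class CSDMap:
    """Space x time current-source-density estimate (arbitrary units).

    ``depths`` is a fine grid (denser than the electrodes), ``csd`` has
    shape ``(len(depths), len(times))``.  ``lam`` is the regularisation
    weight selected by cross-validation.
    """

    depths: np.ndarray
    times: np.ndarray
    csd: np.ndarray
    lam: float
    basis_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.csd = np.asarray(self.csd, dtype=float)
        if np.any(np.diff(self.depths) <= 0):
            raise ValueError("CSD depth grid must be strictly increasing")
        if not np.all(np.isfinite(self.csd)):
            raise ValueError("CSD map contains non-finite values")
        if self.lam < 0:
            raise ValueError(f"lambda must be >= 0, got {self.lam}")


@dataclass
class DepthProfile:
    """One value per channel along the probe (power, phase, or lag)."""

    depths_um: np.ndarray
    values: np.ndarray
    kind: str = "power"

    def __post_init__(self) -> None:
        self.depths_um = np.asarray(self.depths_um, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.depths_um.shape != self.values.shape:
            raise ValueError("depths and values must have equal length")


@dataclass
class MUADensity:
    """Burst-aligned aggregate spike histogram per channel."""

    time_grid: np.ndarray
    counts: np.ndarray  # (n_channels, n_bins)
    n_events: int

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ValueError("MUADensity requires at least one event")
        if np.any(self.counts < 0):
            raise ValueError("spike counts must be nonnegative")


# ---------------------------------------------------------------------------
# depth profiles
# ---------------------------------------------------------------------------

def depth_power_profile(
    rec: Recording, band: BandSpec, window_length: float | None = None
) -> DepthProfile:
    """Per-channel dominant-band power along the probe."""
    if rec.depths_um is None:
        raise ValueError("recording has no channel depths")
    if rec.n_channels < 2:
        raise ValueError("need at least 2 channels for a depth profile")
    wl = window_length if window_length is not None else min(60.0, rec.duration)
    powers = np.empty(rec.n_channels)
    for c in range(rec.n_channels):
        if np.all(rec.samples[c] == 0):
            powers[c] = 0.0
            continue
        psd = welch_psd(rec.samples[c], fs=rec.fs, window_length=wl,
                        allow_short=True)
        _, powers[c] = dominant_frequency(psd, band)
    return DepthProfile(depths_um=rec.depths_um, values=powers, kind="power")


def interchannel_phase_shift(
    rec: Recording,
    band: BandSpec,
    reference_channel: int,
    bursts,
    window_s: float = 0.1,
    order: int = 4,
    min_rel_amp: float = 0.1,
    min_resultant: float = 0.6,
    min_rel_power: float = 0.05,
) -> DepthProfile:
    """Phase shift (degrees) of each channel relative to a reference.

    For every burst window, the lag maximising the cross-correlation with
    the reference channel is found within +-half a band-centre cycle and
    converted to degrees via the band-centre period; per-channel shifts
    are the circular mean across bursts.  Channels whose in-band RMS in a
    window falls below ``min_rel_amp`` times the reference RMS carry no
    usable phase there and are skipped.  A channel is NaN (marked
    missing) when it is silent or below that floor in every window, when
    its circular resultant across bursts falls below ``min_resultant``
    (no consistent phase), or when its dominant in-band power is below
    ``min_rel_power`` of the strongest channel (volume-conducted noise
    only — common-mode noise carries a spuriously consistent phase).
    """
    if not 0 <= reference_channel < rec.n_channels:
        raise ValueError(
            f"reference channel {reference_channel} outside 0..{rec.n_channels - 1}"
        )
    peak_times = [float(b.peak_s) for b in _iter_bursts(bursts)]
    if not peak_times:
        raise ValueError("need at least one burst window")
    filt = bandpass(rec, band, order=order)
    fc = band.center
    max_lag = max(int(round(rec.fs / (2 * fc))), 1)
    half_w = int(round(window_s * rec.fs))
    phasors = np.zeros(rec.n_channels, dtype=complex)
    counts = np.zeros(rec.n_channels, dtype=int)
    for tp in peak_times:
        i = int(round(tp * rec.fs))
        lo, hi = i - half_w, i + half_w
        if lo - max_lag < 0 or hi + max_lag > rec.n_samples:
            continue
        ref = filt.samples[reference_channel, lo:hi]
        ref_rms = float(np.sqrt(np.mean(ref**2)))
        if ref_rms == 0:
            continue
        for c in range(rec.n_channels):
            seg0 = filt.samples[c, lo:hi]
            if np.sqrt(np.mean(seg0**2)) < min_rel_amp * ref_rms:
                continue
            best_val, best_lag = -np.inf, 0
            for lag in range(-max_lag, max_lag + 1):
                seg = filt.samples[c, lo + lag : hi + lag]
                v = float(np.dot(ref, seg))
                if v > best_val:
                    best_val, best_lag = v, lag
            deg = 360.0 * best_lag / rec.fs * fc
            phasors[c] += np.exp(1j * np.deg2rad(deg))
            counts[c] += 1
    values = np.full(rec.n_channels, np.nan)
    resultant = np.zeros(rec.n_channels)
    ok = counts > 0
    resultant[ok] = np.abs(phasors[ok]) / counts[ok]
    ok &= resultant >= min_resultant
    if min_rel_power > 0 and rec.depths_um is not None:
        power = depth_power_profile(rec, band).values
        ok &= power >= min_rel_power * power.max()
    values[ok] = np.rad2deg(np.angle(phasors[ok]))
    depths = rec.depths_um if rec.depths_um is not None else np.arange(
        rec.n_channels, dtype=float
    )
    return DepthProfile(depths_um=depths, values=values, kind="phase_deg")


def _iter_bursts(bursts):
    if hasattr(bursts, "itertuples"):
        return list(bursts.itertuples(index=False))
    return list(bursts)


def reversal_depth_from_profile(profile: DepthProfile) -> float:
    """Depth of the phase reversal: the largest jump between neighbours.

    The phase profile steps by ~180 degrees across the dipole; the
    estimate is the midpoint of the channel pair with the largest
    circular phase difference.
    """
    v = np.deg2rad(profile.values)
    ok = np.isfinite(v)
    d = profile.depths_um[ok]
    v = v[ok]
    if v.size < 2:
        raise ValueError("need at least two finite channels")
    dphi = np.abs(np.angle(np.exp(1j * np.diff(v))))
    i = int(np.argmax(dphi))
    return float(0.5 * (d[i] + d[i + 1]))


# ---------------------------------------------------------------------------
# kernel CSD
# ---------------------------------------------------------------------------

def _forward_potentials(
    z_elec: np.ndarray,
    z_basis: np.ndarray,
    basis_width: float,
    src_radius: float,
) -> np.ndarray:
    """Potentials at electrodes from unit Gaussian basis sources.

    Quasi-1D volume conductor: a planar source disk of radius ``r`` at
    depth z contributes ``(sqrt((x - z)^2 + r^2) - |x - z|) / 2`` to the
    potential at depth x (conductivity folded into the arbitrary units);
    the basis potential is this line-source integral over the Gaussian
    source profile.
    """
    # integration grid spanning the basis support
    step = basis_width / 10.0
    pots = np.empty((z_elec.size, z_basis.size))
    for j, zb in enumerate(z_basis):
        zz = np.arange(zb - 4 * basis_width, zb + 4 * basis_width + step, step)
        b = np.exp(-((zz - zb) ** 2) / (2 * basis_width**2))
        d = np.abs(z_elec[:, None] - zz[None, :])
        g = 0.5 * (np.sqrt(d**2 + src_radius**2) - d)
        pots[:, j] = np.trapezoid(b[None, :] * g, dx=step, axis=1)
    return pots


def kcsd_reconstruct(
    snapshot: Recording | np.ndarray,
    geometry: ProbeGeometry | np.ndarray | None = None,
    basis_count: int | None = None,
    basis_halfwidth: float | None = None,
    lambda_grid: np.ndarray | None = None,
    src_radius_um: float = 500.0,
    fine_step_um: float | None = None,
    fs: float | None = None,
) -> CSDMap:
    """1D kernel current-source-density reconstruction.

    The estimator is ``CSD = Kc (K + lambda I)^-1 V`` where ``K`` is the
    electrode-space kernel built from the forward-modelled potentials of
    Gaussian basis sources and ``Kc`` the cross-kernel evaluating the
    source space on a fine depth grid overshooting the probe by two basis
    widths.  ``lambda`` is chosen from ``lambda_grid`` by deterministic
    leave-one-electrode-out cross-validation of potential prediction.
    """
    if isinstance(snapshot, Recording):
        v = snapshot.samples
        depths = snapshot.depths_um
        fs = snapshot.fs
    else:
        v = np.atleast_2d(np.asarray(snapshot, dtype=float))
        depths = None
    if depths is None:
        if geometry is None:
            raise ValueError("electrode depths are required (geometry or recording)")
        depths = (
            geometry.depths_um
            if isinstance(geometry, ProbeGeometry)
            else np.asarray(geometry, dtype=float)
        )
    depths = np.asarray(depths, dtype=float)
    if depths.size < 4:
        raise ValueError(f"kCSD needs >= 4 channels, got {depths.size}")
    if np.any(np.diff(depths) <= 0):
        raise ValueError("electrode depths must be strictly increasing (no duplicates)")
    if v.shape[0] != depths.size:
        raise ValueError("potential matrix row count must equal channel count")

    spacing = float(np.median(np.diff(depths)))
    n_elec = depths.size
    m = basis_count if basis_count is not None else 2 * n_elec
    width = basis_halfwidth if basis_halfwidth is not None else spacing
    over = 2.0 * width
    z_basis = np.linspace(depths[0] - over, depths[-1] + over, m)
    if fine_step_um is None:
        fine_step_um = spacing / 4.0
    z_fine = np.arange(depths[0] - over, depths[-1] + over + fine_step_um / 2,
                       fine_step_um)

    f_mat = _forward_potentials(depths, z_basis, width, src_radius_um)
    b_mat = np.exp(
        -((z_fine[:, None] - z_basis[None, :]) ** 2) / (2 * width**2)
    )
    k = f_mat @ f_mat.T
    kc = b_mat @ f_mat.T
    # normalise the kernel scale so the lambda grid is dimensionless
    scale = np.trace(k) / n_elec
    k /= scale
    kc /= scale

    if lambda_grid is None:
        lambda_grid = np.logspace(-6, 0, 10)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    lam = _cv_lambda(k, v, lambda_grid)
    try:
        coef = np.linalg.solve(k + lam * np.eye(n_elec), v)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "kernel matrix is singular; include a nonzero lambda in the grid"
        ) from exc
    csd = kc @ coef
    times = (
        np.arange(v.shape[1]) / fs if fs is not None else np.arange(v.shape[1], dtype=float)
    )
    return CSDMap(
        depths=z_fine,
        times=times,
        csd=csd,
        lam=float(lam),
        basis_params={
            "basis_count": int(m),
            "basis_halfwidth_um": float(width),
            "src_radius_um": float(src_radius_um),
            "kernel_scale": float(scale),
        },
    )


def _cv_lambda(k: np.ndarray, v: np.ndarray, grid: np.ndarray) -> float:
    """Leave-one-electrode-out CV error of potential prediction per lambda."""
    n = k.shape[0]
    errs = np.empty(grid.size)
    for gi, lam in enumerate(grid):
        err = 0.0
        ok = True
        for i in range(n):
            keep = np.arange(n) != i
            kk = k[np.ix_(keep, keep)] + lam * np.eye(n - 1)
            try:
                coef = np.linalg.solve(kk, v[keep])
            except np.linalg.LinAlgError:
                ok = False
                break
            pred = k[i, keep] @ coef
            err += float(np.sum((v[i] - pred) ** 2))
        errs[gi] = err if ok else np.inf
    if not np.any(np.isfinite(errs)):
        raise ValueError(
            "kernel matrix is singular for every lambda; include a nonzero "
            "lambda in the grid"
        )
    return float(grid[int(np.argmin(errs))])


def band_filtered_csd(csd: CSDMap, band: BandSpec, fs: float, order: int = 4
                      ) -> CSDMap:
    """Band-pass each depth row of a CSD map (reconstruct-then-filter)."""
    band.validate_for(fs)
    if csd.csd.shape[1] < 3 * order * 3:
        raise ValueError("CSD time axis too short for band filtering")
    if band.hi is None:
        sos = sps.butter(order, band.lo, btype="highpass", fs=fs, output="sos")
    else:
        sos = sps.butter(order, [band.lo, band.hi], btype="bandpass", fs=fs,
                         output="sos")
    out = sps.sosfiltfilt(sos, csd.csd, axis=1)
    return CSDMap(
        depths=csd.depths.copy(),
        times=csd.times.copy(),
        csd=out,
        lam=csd.lam,
        basis_params=dict(csd.basis_params, filtered_band=band.name),
    )


def reversal_depth_from_csd(csd: CSDMap) -> float:
    """Depth of the dominant CSD sign change, from the time-RMS-weighted
    spatial profile at the moment of maximal CSD power."""
    j = int(np.argmax(np.sum(csd.csd**2, axis=0)))
    prof = csd.csd[:, j]
    # largest-amplitude zero crossing
    sign = np.sign(prof)
    crossings = np.flatnonzero(np.diff(sign) != 0)
    if crossings.size == 0:
        raise ValueError("CSD profile has no sign change")
    amp = np.abs(prof[crossings]) + np.abs(prof[crossings + 1])
    i = crossings[int(np.argmax(amp))]
    # linear interpolation of the zero crossing
    z0, z1 = csd.depths[i], csd.depths[i + 1]
    y0, y1 = prof[i], prof[i + 1]
    if y1 == y0:
        return float(0.5 * (z0 + z1))
    return float(z0 - y0 * (z1 - z0) / (y1 - y0))


# ---------------------------------------------------------------------------
# multi-unit activity
# ---------------------------------------------------------------------------

def detect_mua(
    rec: Recording,
    cutoff_hz: float = 500.0,
    threshold_sd: float = 3.0,
    dead_time_s: float = 1e-3,
    polarity: str = "neg",
    order: int = 4,
) -> list:
    """Threshold-crossing spike candidates from the >``cutoff_hz`` band.

    Each channel is high-passed, its noise scale estimated robustly
    (1.4826*MAD), and runs beyond ``threshold_sd`` times that scale in
    the chosen polarity (negative by extracellular convention) are
    reduced to their local extremum; a refractory dead time suppresses
    re-triggers.  Returns one spike-time array per channel.
    """
    if rec.fs < 2000:
        raise ValueError(
            f"fs={rec.fs} Hz too low for MUA extraction (need >= 2 kHz)"
        )
    if polarity not in ("neg", "pos"):
        raise ValueError(f"polarity must be 'neg' or 'pos', got {polarity!r}")
    sos = sps.butter(order, cutoff_hz, btype="highpass", fs=rec.fs, output="sos")
    dead = max(int(round(dead_time_s * rec.fs)), 1)
    out = []
    for c in range(rec.n_channels):
        x = sps.sosfiltfilt(sos, rec.samples[c])
        if polarity == "neg":
            x = -x
        sd = 1.4826 * float(np.median(np.abs(x - np.median(x))))
        if sd == 0:
            out.append(np.array([]))
            continue
        thr = threshold_sd * sd
        above = x > thr
        if not np.any(above):
            out.append(np.array([]))
            continue
        edges = np.diff(above.astype(int))
        starts = list(np.flatnonzero(edges == 1) + 1)
        ends = list(np.flatnonzero(edges == -1) + 1)
        if above[0]:
            starts.insert(0, 0)
        if above[-1]:
            ends.append(x.size)
        peaks = [s + int(np.argmax(x[s:e])) for s, e in zip(starts, ends)]
        kept = []
        last = -np.inf
        for p in peaks:
            if p - last >= dead:
                kept.append(p)
                last = p
        out.append(np.asarray(kept) / rec.fs)
    return out


def mua_hfo_correlation(
    spikes: list,
    bursts,
    hfo: Recording,
    window_s: float = 0.1,
    histogram_bin_s: float = 1e-3,
) -> tuple[np.ndarray, MUADensity]:
    """Correlate the burst-aligned spike histogram with the mean HFO wave.

    Spike times and the band-filtered HFO trace are aligned to each burst
    peak within +-``window_s``; spikes aggregate into a histogram, the
    waveform averages across events, and each channel's Pearson r between
    the two (on the common bin grid) is returned.  Channels without
    spikes are NaN.  Spikes locked to oscillation troughs give negative r
    for a peak-positive waveform.
    """
    burst_list = _iter_bursts(bursts)
    if len(burst_list) < 5:
        raise ValueError(f"need >= 5 bursts, got {len(burst_list)}")
    fs = hfo.fs
    edges = np.arange(-window_s, window_s + histogram_bin_s / 2, histogram_bin_s)
    centers = 0.5 * (edges[:-1] + edges[1:])
    n_ch = hfo.n_channels
    counts = np.zeros((n_ch, centers.size))
    wave = np.zeros((n_ch, centers.size))
    n_events = 0
    peak_times = [float(b.peak_s) for b in burst_list]
    t_all = np.arange(hfo.n_samples) / fs
    for tp in peak_times:
        if tp - window_s < 0 or tp + window_s > hfo.duration:
            continue
        n_events += 1
        for c in range(n_ch):
            st = np.asarray(spikes[c], dtype=float) if c < len(spikes) else np.array([])
            rel = st - tp
            sel = rel[(rel >= -window_s) & (rel < window_s)]
            if sel.size:
                counts[c] += np.histogram(sel, bins=edges)[0]
            wave[c] += np.interp(tp + centers, t_all, hfo.samples[c])
    if n_events == 0:
        raise ValueError("no burst window fits inside the recording")
    wave /= n_events
    rs = np.full(n_ch, np.nan)
    for c in range(n_ch):
        if counts[c].sum() == 0 or counts[c].std() == 0 or wave[c].std() == 0:
            continue
        rs[c] = float(pearsonr(counts[c], wave[c])[0])
    return rs, MUADensity(time_grid=centers, counts=counts, n_events=n_events)
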