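"""Laminar analyses: depth power profile around the dipole, phase-shift
reversal, kCSD forward/inverse self-consistency and invariances, MUA
detection, and spike-histogram/HFO-waveform correlation."""

import numpy as np
import pytest

from obhfo import coupling as cpl
from obhfo import laminar as lam
from obhfo.containers import ProbeGeometry, Recording
from obhfo.laminar import _forward_potentials
from obhfo.sigproc import DELTA, HFO, analytic_envelope_phase, bandpass
from obhfo.synthlfp import GroundTruth, generate_laminar_recording


@pytest.fixture(scope="module")
def detected_bursts(coupled_session, hfo_best_channel):
    filt = bandpass(coupled_session.lfp, HFO)
    env, _ = analytic_envelope_phase(filt.samples[hfo_best_channel])
    return cpl.detect_bursts(env, coupled_session.lfp.fs, band=HFO,
                             channel=hfo_best_channel), filt


class TestDepthPowerProfile:
    def test_generator_dipole_geometry(self, coupled_session):
        prof = lam.depth_power_profile(coupled_session.lfp, HFO)
        gt = coupled_session.ground_truth
        spacing = coupled_session.geometry.spacing_um
        peak_depth = prof.depths_um[int(np.argmax(prof.values))]
        lobe_depths = (gt.hfo_dipole_depth - gt.hfo_dipole_halfwidth,
                       gt.hfo_dipole_depth + gt.hfo_dipole_halfwidth)
        assert min(abs(peak_depth - d) for d in lobe_depths) <= 2 * spacing
        near = np.abs(prof.depths_um - gt.hfo_dipole_depth) <= 3 * spacing
        i_min = np.argmin(prof.values[near])
        min_depth = prof.depths_um[near][i_min]
        assert abs(min_depth - gt.hfo_dipole_depth) <= spacing

    def test_common_mode_signal_flat(self):
        t = np.arange(20000) / 1000.0
        x = np.cos(2 * np.pi * 100 * t)
        rec = Recording(np.tile(x, (8, 1)), fs=1000.0,
                        depths_um=np.arange(8) * 100.0)
        prof = lam.depth_power_profile(rec, HFO)
        assert prof.values.max() / prof.values.min() < 1.2

    def test_zero_signal_zero_profile(self):
        rec = Recording(np.zeros((4, 8000)), fs=1000.0,
                        depths_um=np.arange(4) * 100.0)
        assert not lam.depth_power_profile(rec, HFO).values.any()

    def test_missing_depths_rejected(self):
        rec = Recording(np.zeros((4, 8000)), fs=1000.0)
        with pytest.raises(ValueError, match="depths"):
            lam.depth_power_profile(rec, HFO)


class TestInterchannelPhaseShift:
    def test_reference_channel_zero(self, coupled_session, hfo_best_channel,
                                    detected_bursts):
        bursts, _ = detected_bursts
        prof = lam.interchannel_phase_shift(
            coupled_session.lfp, HFO, hfo_best_channel, bursts
        )
        assert prof.values[hfo_best_channel] == pytest.approx(0.0, abs=1e-9)

    def test_inverted_copy_is_180_degrees(self):
        fs = 10_000.0  # fine lag grid: 3.8 degrees per sample at 105 Hz
        t = np.arange(int(20 * fs)) / fs
        x = np.cos(2 * np.pi * 105 * t) * (1 + 0.3 * np.cos(2 * np.pi * t))
        rec = Recording(np.vstack([x, -x]), fs=fs,
                        depths_um=np.array([0.0, 100.0]))
        bursts = [cpl.BurstEvent(onset_s=tp - 0.05, offset_s=tp + 0.05,
                                 peak_s=tp, peak_envelope=1.0)
                  for tp in (5.0, 10.0, 15.0)]
        prof = lam.interchannel_phase_shift(rec, HFO, 0, bursts)
        assert abs(abs(prof.values[1]) - 180.0) < 5.0

    def test_reversal_at_dipole_center(self, coupled_session,
                                       hfo_best_channel, detected_bursts):
        bursts, _ = detected_bursts
        prof = lam.interchannel_phase_shift(
            coupled_session.lfp, HFO, hfo_best_channel, bursts
        )
        rev = lam.reversal_depth_from_profile(prof)
        gt = coupled_session.ground_truth
        assert abs(rev - gt.hfo_dipole_depth) <= (
            coupled_session.geometry.spacing_um
        )

    def test_bad_reference_rejected(self, coupled_session, detected_bursts):
        bursts, _ = detected_bursts
        with pytest.raises(ValueError, match="reference"):
            lam.interchannel_phase_shift(coupled_session.lfp, HFO, 99, bursts)


class TestKCSD:
    DEPTHS = np.arange(32) * 20.0 + 1000.0  # dense probe, 20 um pitch

    def forward(self, centers, amps, width=60.0):
        """Potentials from a sum of Gaussian sources via the same
        quasi-1D operator used by the reconstruction."""
        v = np.zeros((self.DEPTHS.size, 1))
        for c, a in zip(centers, amps):
            f = _forward_potentials(self.DEPTHS, np.array([c]), width, 500.0)
            v += a * f
        return v

    def test_zero_in_zero_out(self):
        m = lam.kcsd_reconstruct(np.zeros((32, 5)), geometry=self.DEPTHS)
        assert not m.csd.any()

    def test_single_source_recovery(self):
        v = self.forward([1300.0], [1.0])
        m = lam.kcsd_reconstruct(v, geometry=self.DEPTHS, basis_halfwidth=60.0)
        true = np.exp(-((m.depths - 1300.0) ** 2) / (2 * 60.0**2))
        r = np.corrcoef(m.csd[:, 0], true)[0, 1]
        assert r > 0.95
        peak = m.depths[int(np.argmax(m.csd[:, 0]))]
        assert abs(peak - 1300.0) <= 20.0

    def test_two_opposite_sources_one_sign_change(self):
        v = self.forward([1200.0, 1400.0], [1.0, -1.0])
        m = lam.kcsd_reconstruct(v, geometry=self.DEPTHS, basis_halfwidth=60.0)
        prof = m.csd[:, 0]
        inner = (m.depths > 1100.0) & (m.depths < 1500.0)
        signs = np.sign(prof[inner])
        changes = np.sum(np.diff(signs) != 0)
        assert changes == 1

    def test_linearity_at_fixed_lambda(self):
        v1 = self.forward([1250.0], [1.0])
        v2 = self.forward([1450.0], [1.0])
        grid = np.array([1e-3])
        m1 = lam.kcsd_reconstruct(v1, geometry=self.DEPTHS, lambda_grid=grid)
        m2 = lam.kcsd_reconstruct(v2, geometry=self.DEPTHS, lambda_grid=grid)
        m12 = lam.kcsd_reconstruct(2 * v1 - 3 * v2, geometry=self.DEPTHS,
                                   lambda_grid=grid)
        assert np.allclose(m12.csd, 2 * m1.csd - 3 * m2.csd, atol=1e-9)

    def test_second_difference_oracle_nulls_uniform_offset(self):
        """The classical second-difference CSD (the independent oracle for
        localisation checks) is exactly zero on a depth-uniform potential
        but not on a localised source profile."""
        offset = np.full(32, 1.0)
        assert not np.diff(offset, n=2).any()
        structured = self.forward([1300.0], [1.0])[:, 0]
        assert np.abs(np.diff(structured, n=2)).max() > 0

    def test_cv_lambda_deterministic(self):
        rng = np.random.default_rng(0)
        v = self.forward([1350.0], [1.0]) + 0.01 * rng.normal(size=(32, 1))
        lams = {lam.kcsd_reconstruct(v, geometry=self.DEPTHS).lam
                for _ in range(3)}
        assert len(lams) == 1

    def test_duplicate_depths_rejected(self):
        bad = self.DEPTHS.copy()
        bad[5] = bad[4]
        with pytest.raises(ValueError, match="increasing"):
            lam.kcsd_reconstruct(np.zeros((32, 1)), geometry=bad)

    def test_too_few_channels_rejected(self):
        with pytest.raises(ValueError, match="4 channels"):
            lam.kcsd_reconstruct(np.zeros((3, 1)),
                                 geometry=np.array([0.0, 20.0, 40.0]))


class TestBandFilteredCSD:
    def test_band_separated_dipoles(self, coupled_session, detected_bursts):
        """Delta-filtered CSD peaks at the delta dipole, HFO-filtered at
        the HFO dipole."""
        bursts, _ = detected_bursts
        gt = coupled_session.ground_truth
        fs = coupled_session.lfp.fs
        strongest = max(bursts, key=lambda b: b.peak_envelope)
        i0 = int((strongest.peak_s - 2.0) * fs)
        i1 = int((strongest.peak_s + 2.0) * fs)
        m = lam.kcsd_reconstruct(
            coupled_session.lfp.samples[:, i0:i1],
            geometry=coupled_session.geometry, fs=fs,
        )
        spacing = coupled_session.geometry.spacing_um
        m_hfo = lam.band_filtered_csd(m, HFO, fs=fs)
        rev_hfo = lam.reversal_depth_from_csd(m_hfo)
        assert abs(rev_hfo - gt.hfo_dipole_depth) <= spacing
        m_delta = lam.band_filtered_csd(m, DELTA, fs=fs)
        rms_hfo = np.sqrt((m_hfo.csd**2).mean(axis=1))
        rms_delta = np.sqrt((m_delta.csd**2).mean(axis=1))
        lobe = lambda center, hw: np.abs(
            np.abs(m.depths - center) - hw
        ).argmin()
        peak_hfo = m.depths[int(np.argmax(rms_hfo))]
        peak_delta = m.depths[int(np.argmax(rms_delta))]
        assert abs(peak_hfo - gt.hfo_dipole_depth) <= (
            gt.hfo_dipole_halfwidth + 2 * spacing
        )
        assert abs(peak_delta - gt.delta_dipole_depth) <= (
            gt.delta_dipole_halfwidth + 2 * spacing
        )

    def test_zero_map_stays_zero(self):
        m = lam.CSDMap(depths=np.arange(10.0), times=np.arange(500) / 1000.0,
                       csd=np.zeros((10, 500)), lam=0.1)
        out = lam.band_filtered_csd(m, HFO, fs=1000.0)
        assert not out.csd.any()


class TestDetectMUA:
    def test_fs_too_low_rejected(self):
        rec = Recording(np.zeros((1, 4000)), fs=1000.0)
        with pytest.raises(ValueError, match="2 kHz|2000|fs"):
            lam.detect_mua(rec)

    def test_zero_signal_no_spikes(self):
        rec = Recording(np.zeros((2, 8000)), fs=4000.0)
        spikes = lam.detect_mua(rec)
        assert all(len(s) == 0 for s in spikes)

    def test_lfp_band_only_signal_no_false_positives(self):
        # pure LFP-band content leaves only filter leakage above 500 Hz,
        # whose max/SD ratio stays below the 3 SD threshold
        t = np.arange(int(30 * 4000)) / 4000.0
        x = 0.5 * np.cos(2 * np.pi * 2 * t) + 0.2 * np.cos(2 * np.pi * 105 * t)
        rec = Recording(x, fs=4000.0)
        spikes = lam.detect_mua(rec)
        assert len(spikes[0]) / 30.0 < 0.5

    def test_gaussian_floor_crossing_rate_within_rice_bound(self):
        rng = np.random.default_rng(0)
        dur = 60.0
        rec = Recording(0.01 * rng.normal(size=int(dur * 4000)), fs=4000.0)
        spikes = lam.detect_mua(rec)
        # Rice rate for one-sided 3 SD crossings of 0.5-2 kHz Gaussian
        # noise: f0 * exp(-9/2), f0 = sqrt((f2^3 - f1^3) / (3 (f2 - f1)))
        f1, f2 = 500.0, 2000.0
        f0 = np.sqrt((f2**3 - f1**3) / (3 * (f2 - f1)))
        bound = f0 * np.exp(-4.5)
        assert len(spikes[0]) / dur <= 1.5 * bound

    def test_generator_spikes_recovered(self):
        gt = GroundTruth(seed=13, duration=30.0, fs=8000.0,
                         coupling_kappa=8.0, delta_dipole_depth=1700.0,
                         delta_dipole_halfwidth=200.0)
        geom = ProbeGeometry(n_channels=4, spacing_um=200.0,
                             depth_of_first_channel_um=1200.0)
        sim = generate_laminar_recording(gt, geom)
        ch = 1  # dorsal lobe of the HFO dipole at 1600 um
        spikes = lam.detect_mua(sim.lfp)
        true = np.sort(sim.spikes[ch])
        assert len(true) > 50
        # recall over temporally isolated spikes: transients closer than
        # ~2 ms overlap and cannot be resolved by any threshold detector
        gaps = np.diff(true, prepend=-np.inf, append=np.inf)
        isolated = true[(gaps[:-1] > 2e-3) & (gaps[1:] > 2e-3)]
        assert len(isolated) > 30
        det = spikes[ch]
        errs = np.array([np.min(np.abs(det - t)) for t in isolated])
        assert np.mean(errs < 1e-3) >= 0.9


class TestMUAHFOCorrelation:
    def test_trough_locked_spikes_negative_r(self, coupled_session,
                                             detected_bursts):
        bursts, filt = detected_bursts
        spikes = lam.detect_mua(coupled_session.lfp)
        rs, density = lam.mua_hfo_correlation(spikes, bursts, filt)
        gt = coupled_session.ground_truth
        # dorsal lobe channel: positive dipole weight, peak-positive wave
        ch = 14
        assert rs[ch] < 0
        assert abs(rs[ch]) > 0.5
        assert density.n_events >= 5

    def test_uniform_spikes_uncorrelated(self):
        rng = np.random.default_rng(2)
        fs = 2000.0
        t = np.arange(int(300 * fs)) / fs
        x = np.cos(2 * np.pi * 105 * t)
        rec = Recording(x, fs=fs)
        bursts = [
            cpl.BurstEvent(onset_s=tp - 0.05, offset_s=tp + 0.05, peak_s=tp,
                           peak_envelope=1.0)
            for tp in np.arange(1.0, 299.0, 1.0)
        ]
        spikes = [np.sort(rng.uniform(0, 300, size=3000))]
        rs, _ = lam.mua_hfo_correlation(spikes, bursts, rec)
        assert abs(rs[0]) < 0.1

    def test_spikes_at_cosine_minima_give_minus_one(self):
        # half-period bins alternate between trough-centred (all spikes)
        # and peak-centred (none), so r on the binned grid is exactly -1
        fs = 2000.0
        f = 100.0
        t = np.arange(int(60 * fs)) / fs
        rec = Recording(np.cos(2 * np.pi * f * t), fs=fs)
        peaks = np.arange(1.0, 59.0, 1.0) + 0.0025  # centre bins on extrema
        bursts = [
            cpl.BurstEvent(onset_s=tp - 0.05, offset_s=tp + 0.05, peak_s=tp,
                           peak_envelope=1.0)
            for tp in peaks
        ]
        minima = []
        for tp in peaks:
            m = np.arange(-10, 10)
            minima.append((m + 0.5) / f + np.round(tp))  # cos = -1 times
        rs, _ = lam.mua_hfo_correlation([np.concatenate(minima)], bursts, rec,
                                        histogram_bin_s=5e-3)
        assert rs[0] == pytest.approx(-1.0, abs=1e-6)

    def test_too_few_bursts_rejected(self):
        rec = Recording(np.zeros(10000), fs=2000.0)
        with pytest.raises(ValueError, match="5 bursts"):
            lam.mua_hfo_correlation([np.array([])], [], rec)
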