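"""End-to-end orchestration: simulate -> spectra -> bursts -> coupling ->
laminar -> statistics, driven by a single JSON config document.

The pipeline is the integration surface of the package: it renders a
synthetic laminar session with known ground truth, runs every analysis
stage on it, writes all intermediates (recordings, event tables, CSV
matrices) plus a run manifest (config hash, seed, versions, output
hashes), and returns a summary report.  Because the generator's
parameters are known, the report doubles as a parameter-recovery check:
dominant HFO frequency, burst lock phase, comodulogram peak cell and
dipole reversal depth are all directly comparable to the configured
truth.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import coupling as cpl
from . import io as obio
from . import laminar as lam
from . import stats as obstats
from .containers import ProbeGeometry
from .sigproc import (
    BandSpec,
    analytic_envelope_phase,
    bandpass,
    dominant_frequency,
    welch_psd,
)
from .synthlfp import GroundTruth, generate_condition_pair, generate_laminar_recording

__all__ = ["ConfigError", "default_config", "validate_config", "run_full_pipeline"]

log = logging.getLogger("obhfo")


class ConfigError(ValueError):
    """Raised when a run configuration fails schema validation."""


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {
        "duration": 150.0,
        "fs": 2500.0,
        "n_channels": 16,
        "spacing_um": 200.0,
        "depth_of_first_channel_um": 0.0,
        "f_resp": 1.5,
        "f_hfo": 105.0,
        "burst_rate": 1.0,
        "coupling_kappa": 8.0,
        "lock_phase": 0.7853981633974483,  # pi/4
        "hfo_dipole_depth": 1600.0,
        "hfo_dipole_halfwidth": 200.0,
        "delta_dipole_depth": 2000.0,
        "delta_dipole_halfwidth": 300.0,
    },
    "spectra": {
        "welch_window_s": 30.0,
        "bands": {"delta": [0.3, 3.0], "gamma": [30.0, 65.0], "hfo": [80.0, 130.0]},
    },
    "bursts": {"threshold_sd": 3.0, "band": [80.0, 130.0]},
    "coupling": {
        "phase_freqs": [0.5, 1.0, 1.5, 2.0, 2.5, 3.0],
        "amp_freqs": [65.0, 85.0, 105.0, 125.0, 145.0],
        "phase_halfwidth": 0.5,
        "amp_halfwidth": 15.0,
        "n_bins": 18,
    },
    "laminar": {
        "band": [80.0, 130.0],
        "csd_window_s": 0.5,
        "mua": True,
    },
    "stats": {
        "n_subjects": 8,
        "scalers": {"hfo": 4.0, "gamma": 0.25},
        "subject_duration_s": 8.0,
        "subject_fs": 1000.0,
        "epochs": ["baseline", "post"],
    },
}


def default_config() -> dict:
    """A deep copy of the packaged demo configuration."""
    return copy.deepcopy(DEFAULT_CONFIG)


def _deep_update(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v
    return out


def validate_config(config: dict) -> dict:
    """Merge with defaults and check cross-field consistency.

    Rejects (before any compute) sampling rates that would alias the HFO
    carrier, analysis bands at or above Nyquist, non-positive condition
    scalers, and malformed grids.
    """
    cfg = _deep_update(DEFAULT_CONFIG, config or {})
    sim = cfg["simulate"]
    fs = float(sim["fs"])
    if fs <= 2 * float(sim["f_hfo"]):
        raise ConfigError(
            f"simulate.fs={fs} must exceed twice f_hfo={sim['f_hfo']}"
        )
    nyq = fs / 2
    for name, (lo, hi) in cfg["spectra"]["bands"].items():
        if not 0 < lo < hi:
            raise ConfigError(f"band {name!r}: need 0 < lo < hi, got [{lo}, {hi}]")
        if hi >= nyq:
            raise ConfigError(
                f"band {name!r}: upper edge {hi} Hz >= Nyquist {nyq} Hz"
            )
    cc = cfg["coupling"]
    amax = max(cc["amp_freqs"]) + float(cc["amp_halfwidth"])
    if amax >= nyq:
        raise ConfigError(
            f"coupling amplitude grid reaches {amax} Hz >= Nyquist {nyq} Hz"
        )
    if min(cc["phase_freqs"]) <= 0:
        raise ConfigError("coupling phase frequencies must be positive")
    for k, v in cfg["stats"]["scalers"].items():
        if v <= 0:
            raise ConfigError(f"stats scaler {k!r} must be > 0, got {v}")
    if int(cfg["stats"]["n_subjects"]) < 2:
        raise ConfigError("stats.n_subjects must be >= 2")
    return cfg


def _ground_truth_from_config(cfg: dict, seed: int) -> tuple[GroundTruth, ProbeGeometry]:
    sim = cfg["simulate"]
    geom = ProbeGeometry(
        n_channels=int(sim["n_channels"]),
        spacing_um=float(sim["spacing_um"]),
        depth_of_first_channel_um=float(sim["depth_of_first_channel_um"]),
    )
    gt_fields = {
        k: sim[k]
        for k in (
            "duration",
            "fs",
            "f_resp",
            "f_hfo",
            "burst_rate",
            "coupling_kappa",
            "lock_phase",
            "hfo_dipole_depth",
            "hfo_dipole_halfwidth",
            "delta_dipole_depth",
            "delta_dipole_halfwidth",
        )
        if k in sim
    }
    gt = GroundTruth(seed=seed, **gt_fields)
    return gt, geom


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_full_pipeline(
    config: dict | None = None,
    out_dir: str | Path = "runs/demo",
    seed: int | None = None,
) -> dict:
    """Run the full simulate-to-report pipeline.

    Returns the report dict (also written to ``report.json`` in
    ``out_dir`` together with all intermediates and ``manifest.json``).
    Any stage failure aborts with the stage name in the exception.
    """
    t_start = time.time()
    cfg = validate_config(config or {})
    if seed is not None:
        cfg["seed"] = int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    report: dict = {"seed": cfg["seed"]}

    stage = "simulate"
    try:
        log.info("stage %s", stage)
        gt, geom = _ground_truth_from_config(cfg, cfg["seed"])
        sim = generate_laminar_recording(gt, geometry=geom)
        obio.save_recording(sim.lfp, out / "lfp")
        obio.save_recording(sim.respiration, out / "respiration")
        sim.bursts.to_csv(out / "true_bursts.csv", index=False)
        obio.save_ground_truth(gt, out / "ground_truth.json")

        stage = "spectra"
        log.info("stage %s", stage)
        bands = {
            n: BandSpec(n, lo, hi) for n, (lo, hi) in cfg["spectra"]["bands"].items()
        }
        hfo_band = bands["hfo"]
        wl = min(cfg["spectra"]["welch_window_s"], sim.lfp.duration)
        band_power = np.empty(sim.lfp.n_channels)
        for c in range(sim.lfp.n_channels):
            psd_c = welch_psd(sim.lfp.samples[c], fs=gt.fs, window_length=wl,
                              allow_short=True)
            _, band_power[c] = dominant_frequency(psd_c, hfo_band)
        best = int(np.argmax(band_power))
        psd = welch_psd(sim.lfp.samples[best], fs=gt.fs, window_length=wl,
                        allow_short=True)
        pd.DataFrame(
            {"freq_hz": psd.frequencies, "power_mv2": psd.power}
        ).to_csv(out / "psd_best_channel.csv", index=False)
        f_dom, p_dom = dominant_frequency(psd, hfo_band)
        report["hfo_channel"] = best
        report["hfo_dominant_freq_hz"] = f_dom
        report["hfo_dominant_power_mv2"] = p_dom

        stage = "bursts"
        log.info("stage %s", stage)
        hfo_filt = bandpass(sim.lfp, hfo_band)
        env, _ = analytic_envelope_phase(hfo_filt.samples[best])
        bursts = cpl.detect_bursts(
            env, gt.fs, threshold_sd=cfg["bursts"]["threshold_sd"],
            band=hfo_band, channel=best,
        )
        obio.save_events(bursts, out / "detected_bursts.csv")
        report["n_bursts"] = len(bursts)

        stage = "coupling"
        log.info("stage %s", stage)
        # pick the delta reference channel whose delta band is oriented
        # like inverted respiration (trough = inhalation = delta peak)
        delta_filt = bandpass(sim.lfp, bands["delta"])
        resp = sim.respiration.samples[0]
        corrs = [
            float(np.corrcoef(delta_filt.samples[c], -resp)[0, 1])
            for c in range(sim.lfp.n_channels)
        ]
        delta_ref = int(np.argmax(corrs))
        ps = cpl.burst_delta_phase(bursts, delta_filt.samples[delta_ref], gt.fs)
        report["delta_reference_channel"] = delta_ref
        report["itpc"] = cpl.itpc(ps)
        report["lock_phase_rad"] = ps.circular_mean()
        report["n_phases"] = len(ps)
        report["delta_hfo_envelope_r"] = cpl.envelope_correlation(
            delta_filt.samples[delta_ref], env
        )
        cm = cpl.comodulogram(
            sim.lfp.samples[best],
            cfg["coupling"]["phase_freqs"],
            cfg["coupling"]["amp_freqs"],
            fs=gt.fs,
            phase_halfwidth=cfg["coupling"]["phase_halfwidth"],
            amp_halfwidth=cfg["coupling"]["amp_halfwidth"],
            n_bins=cfg["coupling"]["n_bins"],
        )
        pd.DataFrame(
            cm.mi, index=cm.phase_freqs, columns=cm.amp_freqs
        ).to_csv(out / "comodulogram.csv")
        (out / "comodulogram_axes.json").write_text(
            json.dumps(
                {
                    "phase_freqs_hz": cm.phase_freqs.tolist(),
                    "amp_freqs_hz": cm.amp_freqs.tolist(),
                    "n_phase_bins": cm.n_phase_bins,
                    "meta": cm.meta,
                }
            )
        )
        fp_peak, fa_peak = cm.argmax_cell()
        report["comodulogram_peak_phase_hz"] = fp_peak
        report["comodulogram_peak_amp_hz"] = fa_peak

        stage = "laminar"
        log.info("stage %s", stage)
        lam_band = BandSpec("hfo", *cfg["laminar"]["band"])
        prof = lam.depth_power_profile(sim.lfp, lam_band)
        pd.DataFrame(
            {"depth_um": prof.depths_um, "power_mv2": prof.values}
        ).to_csv(out / "depth_power_profile.csv", index=False)
        shift = lam.interchannel_phase_shift(sim.lfp, lam_band, best, bursts)
        pd.DataFrame(
            {"depth_um": shift.depths_um, "phase_deg": shift.values}
        ).to_csv(out / "phase_shift_profile.csv", index=False)
        report["reversal_depth_profile_um"] = lam.reversal_depth_from_profile(shift)
        # kCSD around the strongest detected burst
        strongest = max(bursts, key=lambda b: b.peak_envelope)
        half_w = cfg["laminar"]["csd_window_s"]
        i0 = max(int((strongest.peak_s - half_w) * gt.fs), 0)
        i1 = min(int((strongest.peak_s + half_w) * gt.fs), sim.lfp.n_samples)
        csd = lam.kcsd_reconstruct(
            sim.lfp.samples[:, i0:i1], geometry=geom, fs=gt.fs
        )
        report["kcsd_lambda"] = csd.lam
        csd_hfo = lam.band_filtered_csd(csd, lam_band, fs=gt.fs)
        report["reversal_depth_csd_um"] = lam.reversal_depth_from_csd(csd_hfo)
        if cfg["laminar"]["mua"] and gt.fs >= 2000:
            spikes = lam.detect_mua(sim.lfp)
            rs, density = lam.mua_hfo_correlation(spikes, bursts, hfo_filt)
            pd.DataFrame(
                {"depth_um": geom.depths_um, "mua_hfo_r": rs}
            ).to_csv(out / "mua_hfo_correlation.csv", index=False)
            report["mua_hfo_r_best_channel"] = float(rs[best])
            report["mua_n_events"] = density.n_events

        stage = "stats"
        log.info("stage %s", stage)
        report["stats"] = _condition_stats(cfg, bands)

    except ConfigError:
        raise
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report["runtime_s"] = time.time() - t_start
    (out / "report.json").write_text(json.dumps(report, indent=1))
    manifest = {
        "seed": cfg["seed"],
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "versions": {
            "python": sys.version.split()[0],
            "numpy": np.__version__,
        },
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.suffix in (".csv", ".bin") and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    log.info("pipeline finished in %.1f s", report["runtime_s"])
    return report


def _condition_stats(cfg: dict, bands: dict) -> dict:
    """Paired baseline-vs-scaled contrast across simulated subjects."""
    s = cfg["stats"]
    n_subj = int(s["n_subjects"])
    geom = ProbeGeometry(n_channels=4, spacing_um=200.0,
                         depth_of_first_channel_um=1200.0)
    rows = []
    ss = np.random.SeedSequence([int(cfg["seed"]), 9137])
    child_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n_subj)]
    for subj, sd in enumerate(child_seeds):
        gt = GroundTruth(
            seed=sd,
            fs=float(s["subject_fs"]),
            duration=float(s["subject_duration_s"]),
            hfo_dipole_depth=1600.0,
            delta_dipole_depth=1700.0,
            delta_dipole_halfwidth=200.0,
        )
        rec_a, rec_b = generate_condition_pair(gt, scalers=s["scalers"],
                                               geometry=geom)
        for label, rec in (("baseline", rec_a), ("post", rec_b)):
            ch = int(np.argmax(np.abs(rec.samples).max(axis=1)))
            for metric in ("hfo", "gamma"):
                psd = welch_psd(
                    rec.samples[ch], fs=gt.fs,
                    window_length=min(4.0, rec.duration), allow_short=True,
                )
                _, p = dominant_frequency(psd, bands[metric])
                rows.append(
                    {"subject": subj, "epoch": label, "metric": metric, "value": p}
                )
    df = pd.DataFrame(rows)
    out = {}
    for metric in ("hfo", "gamma"):
        rep = obstats.compare_epochs(df, metric=metric, design="paired")
        out[metric] = rep.to_dict()
    return out


def _setup_logging(out: Path) -> None:
    if log.handlers:
        return
    log.setLevel(logging.INFO)
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    sh = logging.StreamHandler(sys.stderr)
    sh.setFormatter(fmt)
    log.addHandler(sh)
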