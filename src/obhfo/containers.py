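"""Core data containers shared by the whole package.

A :class:`Recording` is the universal in-memory representation of a
multichannel extracellular signal: a ``(n_channels, n_samples)`` array of
voltages in mV with a sampling rate, optional per-channel depth coordinates
(laminar probes), and channel labels.  Single-site signals (respiration
thermocouple, a single LFP electrode) are 1-channel recordings.

On disk a recording is a raw little-endian float32 flat binary file
(channel-major) next to a JSON sidecar holding the metadata; see
:mod:`obhfo.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ProbeGeometry", "Recording"]


@dataclass(frozen=True)
class ProbeGeometry:
    """Linear silicon-probe geometry.

    Depth increases ventrally; channel 0 is the most dorsal contact.

    Parameters
    ----------
    n_channels : int
        Number of contacts (default 32).
    spacing_um : float
        Inter-contact distance in micrometres (typically 100 for a long
        probe spanning the whole dorsoventral axis, or 20 for a short,
        dense probe).
    depth_of_first_channel_um : float
        Depth of channel 0 in micrometres.
    """

    n_channels: int = 32
    spacing_um: float = 100.0
    depth_of_first_channel_um: float = 0.0

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ValueError(f"n_channels must be >= 2, got {self.n_channels}")
        if self.spacing_um <= 0:
            raise ValueError(f"spacing_um must be > 0, got {self.spacing_um}")

    @property
    def depths_um(self) -> np.ndarray:
        """Strictly monotone channel depths in micrometres."""
        return (
            self.depth_of_first_channel_um
            + self.spacing_um * np.arange(self.n_channels, dtype=float)
        )

    @property
    def span_um(self) -> tuple[float, float]:
        d = self.depths_um
        return float(d[0]), float(d[-1])


@dataclass
class Recording:
    """Multichannel time series in mV with sampling metadata.

    ``samples`` has shape ``(n_channels, n_samples)``; 1-D input is
    promoted to a single channel.  All samples must be finite.
    """

    samples: np.ndarray
    fs: float
    depths_um: np.ndarray | None = None
    channel_labels: list[str] = field(default_factory=list)
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")
        if self.depths_um is not None:
            self.depths_um = np.asarray(self.depths_um, dtype=float)
            if self.depths_um.shape[0] != self.samples.shape[0]:
                raise ValueError(
                    "depths_um length does not match channel count: "
                    f"{self.depths_um.shape[0]} vs {self.samples.shape[0]}"
                )
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.samples.shape[0])]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def channel(self, index: int) -> np.ndarray:
        """Return the 1-D sample array of one channel."""
        return self.samples[index]

    def copy_with(self, samples: np.ndarray) -> "Recording":
        """New recording with the same metadata but different samples."""
        return Recording(
            samples=np.asarray(samples, dtype=float),
            fs=self.fs,
            depths_um=None if self.depths_um is None else self.depths_um.copy(),
            channel_labels=list(self.channel_labels),
            t0=self.t0,
        )
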