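"""Stimulation paradigms, electrode layout and EEG container types.

Fast periodic visual stimulation (FPVS) tags each stimulus stream with a
fixed presentation rate, so the neural response appears at that rate and its
integer harmonics in the amplitude spectrum.  Two paradigms are supported:

* ``oddball`` — a base stream at ``base_rate_hz`` (neutral scenes at 5 Hz)
  with a deviant (negative) scene every ``oddball_cycle``-th image, so the
  discrimination response is tagged at ``base_rate_hz / oddball_cycle``
  (1.25 Hz by default).
* ``multi_input`` — two simultaneous streams (negative vs neutral scenes)
  tagged at distinct rates (4.61 and 5 Hz by default), one per visual
  hemifield; relative spectral amplitude indexes the neural salience of
  each stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

#: Electrode sets over which responses are aggregated (10-20 labels).
ROI_CHANNELS: Mapping[str, tuple[str, ...]] = {
    "LOT": ("P7", "P9", "PO7"),          # left occipito-temporal
    "MO": ("Iz", "Oz", "O1", "O2"),      # medial occipital
    "ROT": ("P8", "P10", "PO8"),         # right occipito-temporal
}

#: Default channel layout: the union of all ROI channels.
DEFAULT_CHANNELS: tuple[str, ...] = tuple(
    ch for roi in ("LOT", "MO", "ROT") for ch in ROI_CHANNELS[roi]
)


@dataclass(frozen=True)
class StimulationParadigm:
    """Frequency structure of one FPVS condition.

    Parameters
    ----------
    kind:
        ``"oddball"`` or ``"multi_input"``.
    base_rate_hz:
        Base image presentation rate (oddball paradigm).
    oddball_cycle:
        Every n-th base image is a deviant; the oddball rate is
        ``base_rate_hz / oddball_cycle``.
    stream_rates_hz:
        The two tagging rates of the multi-input paradigm.
    content:
        ``"social"`` or ``"nonsocial"`` scene content.
    valence_assignment:
        Multi-input bookkeeping: maps each stream rate to a valence and a
        hemifield, e.g. ``{"negative": ("left", 5.0), "neutral":
        ("right", 4.61)}``.  Sides are nuisance factors pooled downstream.
    """

    kind: str = "oddball"
    base_rate_hz: float = 5.0
    oddball_cycle: int = 4
    stream_rates_hz: tuple[float, float] = (4.61, 5.0)
    content: str = "social"
    valence_assignment: Mapping[str, tuple[str, float]] = field(
        default_factory=lambda: {
            "negative": ("left", 5.0),
            "neutral": ("right", 4.61),
        }
    )

    def __post_init__(self) -> None:
        if self.kind not in ("oddball", "multi_input"):
            raise ValueError(f"unknown paradigm kind: {self.kind!r}")
        if self.oddball_cycle < 2:
            raise ValueError("oddball_cycle must be >= 2")
        if self.base_rate_hz <= 0:
            raise ValueError("base_rate_hz must be positive")
        if self.kind == "multi_input":
            r1, r2 = self.stream_rates_hz
            if r1 == r2:
                raise ValueError("multi-input stream rates must be distinct")

    @property
    def oddball_rate_hz(self) -> float:
        """Deviant-stimulus rate: base rate divided by the oddball cycle."""
        return self.base_rate_hz / self.oddball_cycle

    def tagged_rates(self) -> tuple[float, ...]:
        """Fundamental frequencies carrying a tagged response."""
        if self.kind == "oddball":
            return (self.oddball_rate_hz, self.base_rate_hz)
        return tuple(self.stream_rates_hz)


@dataclass
class EEGRecording:
    """Multichannel EEG time series (µV) with paradigm metadata."""

    channel_labels: tuple[str, ...]
    sampling_rate_hz: float
    samples: np.ndarray  # channels x time, µV
    paradigm: StimulationParadigm
    subject_id: str
    condition: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a channels x time matrix")
        if self.samples.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{len(self.channel_labels)} channel labels but "
                f"{self.samples.shape[0]} sample rows"
            )
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        missing = [ch for ch in DEFAULT_CHANNELS if ch not in self.channel_labels]
        if missing:
            raise ValueError(f"layout is missing required ROI channels: {missing}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)  # type: ignore[union-attr]
        except (ValueError, AttributeError):
            idx = list(self.channel_labels).index(label)
            return idx
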