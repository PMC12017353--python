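"""Amplitude spectra and per-bin statistics for frequency-tagged EEG.

The quantification is entirely frequency-domain: the (epoch-averaged) time
series is Fourier transformed and, at each tagged frequency bin, three
statistics are computed against the local noise floor estimated from the 20
surrounding bins (10 per side, skipping 1 bin immediately adjacent to the
target to guard against spectral leakage):

* ``snr`` — target amplitude divided by the mean of the surrounding bins;
* ``baseline_subtracted_uv`` — target amplitude minus that mean (µV);
* ``z`` — baseline-subtracted amplitude divided by the sample standard
  deviation (n-1 denominator) of the surrounding bins.

Amplitudes use single-sided 2/N normalisation so that a pure sinusoid of
amplitude *a* µV reads *a* µV at its bin.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .paradigm import EEGRecording

#: Default number of surrounding bins per side of the target.
N_PER_SIDE = 10
#: Default number of bins immediately flanking the target to skip.
EXCLUDE_ADJACENT = 1
#: Bin-alignment tolerance as a fraction of the frequency resolution.
BIN_TOLERANCE = 0.25


@dataclass
class AmplitudeSpectrum:
    """Single-sided amplitude spectrum, channels x frequency bins (µV)."""

    freq_resolution_hz: float
    amplitudes_uv: np.ndarray
    channel_labels: tuple[str, ...]
    subject_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.amplitudes_uv = np.asarray(self.amplitudes_uv, dtype=float)
        if self.amplitudes_uv.ndim == 1:
            self.amplitudes_uv = self.amplitudes_uv[None, :]
        if self.amplitudes_uv.shape[0] != len(self.channel_labels):
            raise ValueError("channel label count does not match amplitude rows")
        if self.freq_resolution_hz <= 0:
            raise ValueError("freq_resolution_hz must be positive")

    @property
    def n_bins(self) -> int:
        return self.amplitudes_uv.shape[1]

    @property
    def frequencies_hz(self) -> np.ndarray:
        return np.arange(self.n_bins) * self.freq_resolution_hz

    def channel_index(self, label: str) -> int:
        labels = list(self.channel_labels)
        if label not in labels:
            raise KeyError(f"channel {label!r} not in spectrum")
        return labels.index(label)

    def channel(self, label: str) -> np.ndarray:
        return self.amplitudes_uv[self.channel_index(label)]

    def roi_average(self, channels: tuple[str, ...]) -> np.ndarray:
        """Mean amplitude over a set of channels (used for group plots)."""
        idx = [self.channel_index(c) for c in channels]
        return self.amplitudes_uv[idx].mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        freqs = self.frequencies_hz
        rows = []
        for i, ch in enumerate(self.channel_labels):
            rows.append(
                pd.DataFrame(
                    {
                        "subject": self.subject_id,
                        "condition": self.condition,
                        "channel": ch,
                        "frequency_hz": freqs,
                        "amplitude_uv": self.amplitudes_uv[i],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class BinNeighborhood:
    """Indices of the surrounding bins used as the local noise estimate."""

    target_bin: int
    neighbor_bins: tuple[int, ...]
    excluded_adjacent: int

    def __post_init__(self) -> None:
        if self.target_bin in self.neighbor_bins:
            raise ValueError("target bin cannot be its own neighbor")


@dataclass(frozen=True)
class BinStats:
    """Noise-referenced statistics of one frequency bin."""

    frequency_hz: float
    amplitude_uv: float
    snr: float
    baseline_subtracted_uv: float
    z: float


def average_epochs(recordings: list[EEGRecording]) -> EEGRecording:
    """Coherently average time-domain epochs of equal length.

    Averaging before the FFT enhances phase-locked (stimulus-driven)
    activity relative to non-phase-locked noise.
    """
    if not recordings:
        raise ValueError("no epochs to average")
    first = recordings[0]
    shapes = {rec.samples.shape for rec in recordings}
    if len(shapes) != 1:
        raise ValueError(f"epochs have unequal shapes: {shapes}")
    mean = np.mean([rec.samples for rec in recordings], axis=0)
    return EEGRecording(
        channel_labels=first.channel_labels,
        sampling_rate_hz=first.sampling_rate_hz,
        samples=mean,
        paradigm=first.paradigm,
        subject_id=first.subject_id,
        condition=first.condition,
    )


def compute_spectrum(
    rec: EEGRecording,
    window: tuple[float, float] | None = None,
) -> AmplitudeSpectrum:
    """FFT the recording (optionally a time window of it) to µV amplitudes.

    The channel mean is removed before the transform; no other detrending
    is applied.  ``freq_resolution_hz`` equals 1 / window length.
    """
    fs = rec.sampling_rate_hz
    data = rec.samples
    if window is not None:
        t0, t1 = window
        if not (0 <= t0 < t1 <= rec.duration_s + 1e-12):
            raise ValueError(f"window {window} outside recording of {rec.duration_s} s")
        i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
        data = data[:, i0:i1]
    n = data.shape[1]
    if n == 0:
        raise ValueError("empty analysis window")
    data = data - data.mean(axis=1, keepdims=True)
    coef = np.fft.rfft(data, axis=1)
    amp = np.abs(coef) * (2.0 / n)
    amp[:, 0] /= 2.0  # DC has no conjugate pair
    if n % 2 == 0:
        amp[:, -1] /= 2.0  # neither does Nyquist
    return AmplitudeSpectrum(
        freq_resolution_hz=fs / n,
        amplitudes_uv=amp,
        channel_labels=tuple(rec.channel_labels),
        subject_id=rec.subject_id,
        condition=rec.condition,
    )


def target_bin(
    spectrum: AmplitudeSpectrum,
    frequency_hz: float,
    tolerance: float = BIN_TOLERANCE,
) -> int:
    """Bin index of a tagged frequency; errors if misaligned with the grid.

    ``tolerance`` is a fraction of the bin width.  Silent nearest-bin
    snapping can misattribute a response to a neighboring bin, so
    misalignment beyond the tolerance is a hard error.
    """
    res = spectrum.freq_resolution_hz
    k = frequency_hz / res
    idx = int(round(k))
    if abs(k - idx) > tolerance:
        raise ValueError(
            f"frequency {frequency_hz} Hz is {abs(k - idx):.3f} bins from the "
            f"grid (resolution {res} Hz); not bin-aligned"
        )
    if not (0 <= idx < spectrum.n_bins):
        raise ValueError(f"frequency {frequency_hz} Hz outside the spectrum")
    return idx


def neighborhood(
    spectrum: AmplitudeSpectrum,
    target: int,
    n_per_side: int = N_PER_SIDE,
    exclude_adjacent: int = EXCLUDE_ADJACENT,
) -> BinNeighborhood:
    """The surrounding bins of a target bin, skipping its immediate flanks."""
    lo = target - exclude_adjacent - n_per_side
    hi = target + exclude_adjacent + n_per_side
    if lo < 0 or hi >= spectrum.n_bins:
        raise ValueError(
            f"target bin {target} too close to the spectrum edge for "
            f"{n_per_side} neighbors per side"
        )
    left = range(lo, target - exclude_adjacent)
    right = range(target + exclude_adjacent + 1, hi + 1)
    return BinNeighborhood(
        target_bin=target,
        neighbor_bins=tuple(left) + tuple(right),
        excluded_adjacent=exclude_adjacent,
    )


def bin_stats_from_values(
    frequency_hz: float, target_amp: float, neighbor_amps: np.ndarray
) -> BinStats:
    """Compute SNR, baseline-subtracted amplitude and Z from raw amplitudes."""
    neighbor_amps = np.asarray(neighbor_amps, dtype=float)
    mean = float(neighbor_amps.mean())
    sd = float(neighbor_amps.std(ddof=1))
    diff = target_amp - mean
    if mean > 0:
        snr = target_amp / mean
    else:
        warnings.warn("zero neighborhood mean; SNR reported as +inf")
        snr = math.inf
    if sd > 0:
        z = diff / sd
    else:
        warnings.warn("zero neighborhood SD; Z reported as signed inf sentinel")
        z = math.copysign(math.inf, diff) if diff != 0 else 0.0
    return BinStats(
        frequency_hz=frequency_hz,
        amplitude_uv=float(target_amp),
        snr=snr,
        baseline_subtracted_uv=diff,
        z=z,
    )


def bin_stats(
    spectrum: AmplitudeSpectrum,
    channel: str,
    frequency_hz: float,
    n_per_side: int = N_PER_SIDE,
    exclude_adjacent: int = EXCLUDE_ADJACENT,
    tolerance: float = BIN_TOLERANCE,
) -> BinStats:
    """Noise-referenced statistics of one tagged bin on one channel."""
    tb = target_bin(spectrum, frequency_hz, tolerance)
    nb = neighborhood(spectrum, tb, n_per_side, exclude_adjacent)
    amps = spectrum.channel(channel)
    return bin_stats_from_values(
        frequency_hz=tb * spectrum.freq_resolution_hz,
        target_amp=float(amps[tb]),
        neighbor_amps=amps[list(nb.neighbor_bins)],
    )


def spectrum_table(spectra: list[AmplitudeSpectrum]) -> pd.DataFrame:
    """Long-format export of several spectra."""
    return pd.concat([s.to_frame() for s in spectra], ignore_index=True)
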