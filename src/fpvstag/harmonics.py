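"""Harmonic enumeration, significance selection and response summation.

A frequency-tagged response is spread over the tagging frequency and its
integer harmonics.  The total response is quantified as the sum of
baseline-subtracted amplitudes over a harmonic set:

* oddball paradigm — the first five oddball harmonics, excluding any
  harmonic that coincides with the base rate (5 Hz is simultaneously the
  4th oddball harmonic and the 1st base harmonic), i.e. 1.25, 2.5, 3.75,
  6.25 and 7.5 Hz;
* multi-input paradigm — the first four harmonics of each stream rate,
  i.e. up to 18.44 Hz for 4.61 Hz and 20 Hz for 5 Hz.

How many harmonics carry a genuine response is decided on group-average
spectra: harmonics are retained while their Z-score exceeds the one-sided
5% normal critical value (1.64) in every ROI x group x content cell,
stopping before the first run of two consecutive non-significant harmonics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from .paradigm import ROI_CHANNELS
from .spectral import (
    EXCLUDE_ADJACENT,
    N_PER_SIDE,
    AmplitudeSpectrum,
    BinStats,
    bin_stats,
)

#: One-sided standard normal critical value at p < 0.05.
Z_THRESHOLD = 1.64
#: Consecutive non-significant harmonics that terminate the retained prefix.
RUN_LENGTH = 2


@dataclass(frozen=True)
class ROIDefinition:
    name: str
    channels: tuple[str, ...]


ROIS: tuple[ROIDefinition, ...] = tuple(
    ROIDefinition(name, chans) for name, chans in ROI_CHANNELS.items()
)


def _as_fraction(x: float) -> Fraction:
    # recover the exact rational a float denotes (4.61 -> 461/100,
    # 4.61666... -> 277/60); stimulation rates are short decimals or bin
    # fractions, both well within this denominator bound
    return Fraction(float(x)).limit_denominator(1_000_000)


@dataclass(frozen=True)
class HarmonicSet:
    """A fundamental and the harmonics retained for summation."""

    fundamental_hz: float
    frequencies_hz: tuple[float, ...]
    excluded_hz: tuple[tuple[float, str], ...] = ()

    def __post_init__(self) -> None:
        fund = _as_fraction(self.fundamental_hz)
        for f in self.frequencies_hz:
            if (_as_fraction(f) / fund).denominator != 1:
                raise ValueError(
                    f"{f} Hz is not an integer multiple of {self.fundamental_hz} Hz"
                )
        overlap = set(self.frequencies_hz) & {f for f, _ in self.excluded_hz}
        if overlap:
            raise ValueError(f"harmonics both retained and excluded: {overlap}")


def enumerate_harmonics(
    fundamental_hz: float,
    n_keep: int,
    exclude_multiples_of_hz: float | None = None,
) -> HarmonicSet:
    """First ``n_keep`` harmonics of a fundamental, skipping base-rate overlaps.

    Overlap detection uses exact rational arithmetic on the frequencies, not
    floating-point equality: a harmonic is excluded when it is an integer
    multiple of ``exclude_multiples_of_hz``.
    """
    if n_keep < 1:
        raise ValueError("n_keep must be >= 1")
    fund = _as_fraction(fundamental_hz)
    excl = _as_fraction(exclude_multiples_of_hz) if exclude_multiples_of_hz else None
    kept: list[float] = []
    excluded: list[tuple[float, str]] = []
    k = 0
    while len(kept) < n_keep:
        k += 1
        freq = fund * k
        if excl is not None and (freq / excl).denominator == 1:
            excluded.append(
                (float(freq), f"coincides with {exclude_multiples_of_hz} Hz harmonic")
            )
            continue
        kept.append(float(freq))
    return HarmonicSet(
        fundamental_hz=float(fund),
        frequencies_hz=tuple(kept),
        excluded_hz=tuple(excluded),
    )


def oddball_harmonics(base_rate_hz: float = 5.0, cycle: int = 4, n_keep: int = 5) -> HarmonicSet:
    """Oddball summation set: first harmonics of base/cycle, base rate excluded."""
    return enumerate_harmonics(
        base_rate_hz / cycle, n_keep, exclude_multiples_of_hz=base_rate_hz
    )


def select_significant(
    z_table: pd.DataFrame,
    threshold: float = Z_THRESHOLD,
    run_length: int = RUN_LENGTH,
) -> int:
    """Number of leading harmonics retained by the consecutive-Z rule.

    ``z_table`` holds one row per candidate harmonic (ascending ``harmonic``
    order) per cell (any combination of ROI/group/content columns) with a
    ``z`` column computed on group-average spectra.  A harmonic counts as
    significant only if ``z > threshold`` in *every* cell.  Scanning in
    ascending order, the retained prefix ends just before the first run of
    ``run_length`` consecutive non-significant harmonics; a retained prefix
    never extends past that cut.
    """
    if z_table.empty:
        raise ValueError("empty z table")
    if "harmonic" not in z_table.columns or "z" not in z_table.columns:
        raise ValueError("z_table needs 'harmonic' and 'z' columns")
    sig = (
        z_table.assign(ok=z_table["z"] > threshold)
        .groupby("harmonic", sort=True)["ok"]
        .all()
    )
    flags = sig.to_numpy()
    run = 0
    for i, ok in enumerate(flags):
        if ok:
            run = 0
        else:
            run += 1
            if run == run_length:
                return i - run_length + 1
    return len(flags)


@dataclass
class HarmonicSummary:
    """Summed baseline-subtracted response for one subject x condition x ROI."""

    subject: str
    condition: str
    roi: str
    summed_baseline_subtracted_uv: float
    per_harmonic: dict[str, list[BinStats]] = field(default_factory=dict)


def summed_response(
    spectrum: AmplitudeSpectrum,
    harmonic_set: HarmonicSet,
    roi: ROIDefinition,
    n_per_side: int = N_PER_SIDE,
    exclude_adjacent: int = EXCLUDE_ADJACENT,
) -> HarmonicSummary:
    """Sum baseline-subtracted amplitudes over harmonics, average over ROI.

    Per channel, the baseline-subtracted amplitude is computed at each
    retained harmonic and summed; channel sums are then averaged across the
    ROI.  All three operations are linear, so the order is a reproducibility
    convention, not a modelling choice.
    """
    per_channel: dict[str, list[BinStats]] = {}
    channel_sums = []
    for ch in roi.channels:
        stats = [
            bin_stats(spectrum, ch, f, n_per_side, exclude_adjacent)
            for f in harmonic_set.frequencies_hz
        ]
        per_channel[ch] = stats
        channel_sums.append(sum(s.baseline_subtracted_uv for s in stats))
    return HarmonicSummary(
        subject=spectrum.subject_id,
        condition=spectrum.condition,
        roi=roi.name,
        summed_baseline_subtracted_uv=float(np.mean(channel_sums)),
        per_harmonic=per_channel,
    )


def summary_table(
    spectra: list[AmplitudeSpectrum],
    harmonic_set: HarmonicSet,
    rois: tuple[ROIDefinition, ...] = ROIS,
    **kwargs,
) -> pd.DataFrame:
    """HarmonicSummary rows for every spectrum x ROI as a tidy table."""
    rows = []
    for spec in spectra:
        for roi in rois:
            s = summed_response(spec, harmonic_set, roi, **kwargs)
            rows.append(
                {
                    "subject": s.subject,
                    "condition": s.condition,
                    "roi": s.roi,
                    "summed_uv": s.summed_baseline_subtracted_uv,
                }
            )
    return pd.DataFrame(rows)


def group_average_z_table(
    spectra_by_cell: dict[tuple, list[AmplitudeSpectrum]],
    candidate_harmonics: tuple[float, ...],
    rois: tuple[ROIDefinition, ...] = ROIS,
    cell_names: tuple[str, ...] = ("group", "content"),
    **kwargs,
) -> pd.DataFrame:
    """Z-scores per harmonic x ROI x cell on group-averaged, ROI-averaged spectra.

    Feeds :func:`select_significant`.  Spectra within a cell are averaged in
    the amplitude domain, then the ROI channels are averaged, and the Z is
    computed on that single average spectrum per cell x ROI.
    """
    from .spectral import bin_stats_from_values, neighborhood, target_bin

    rows = []
    for cell, spectra in spectra_by_cell.items():
        if not spectra:
            raise ValueError(f"no spectra for cell {cell}")
        mean_amp = np.mean([s.amplitudes_uv for s in spectra], axis=0)
        avg = AmplitudeSpectrum(
            freq_resolution_hz=spectra[0].freq_resolution_hz,
            amplitudes_uv=mean_amp,
            channel_labels=spectra[0].channel_labels,
        )
        for roi in rois:
            roi_amp = avg.roi_average(roi.channels)
            for i, f in enumerate(candidate_harmonics, start=1):
                tb = target_bin(avg, f)
                nb = neighborhood(avg, tb, **kwargs)
                st = bin_stats_from_values(f, roi_amp[tb], roi_amp[list(nb.neighbor_bins)])
                row = {"harmonic": i, "frequency_hz": f, "roi": roi.name, "z": st.z}
                row.update(dict(zip(cell_names, cell if isinstance(cell, tuple) else (cell,))))
                rows.append(row)
    return pd.DataFrame(rows)
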