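"""Synthetic EEG, fixation and cohort data with known ground truth.

Because no raw recordings accompany the study design this package analyses,
every downstream stage is validated against simulated data whose generative
parameters are known exactly:

* :func:`simulate_eeg` — stationary sinusoids at the tagged frequencies and
  their harmonics (amplitudes in µV, per-ROI topography gains, random but
  seed-fixed phases) superposed on a 1/f-amplitude plus white noise floor.
  FPVS responses are quantified purely in the frequency domain, so harmonic
  content is the only waveform property that matters.
* :func:`simulate_fixations` — fixation streams with configurable dwell
  probabilities per AOI and Gaussian position scatter with SD equal to the
  subject's calibration error.
* :func:`simulate_cohort` — subject-level covariates (age, sex, adversity /
  threat / neglect exposure, three symptom scores) and score-level outcome
  tables for both paradigms that embed configurable group x content,
  valence (x content), threat x content and adversity x valence effects,
  plus a shared latent factor linking gaze and neural valence preferences.

All draws derive from a single seed; identical config + seed reproduces
outputs bit for bit.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gaze import AOIRect, FixationRecord
from .harmonics import oddball_harmonics
from .paradigm import DEFAULT_CHANNELS, ROI_CHANNELS, EEGRecording, StimulationParadigm

_CHANNEL_ROI = {ch: roi for roi, chans in ROI_CHANNELS.items() for ch in chans}


def _stable_hash(text: str) -> int:
    """Process-independent 31-bit hash for seeding sub-streams."""
    return zlib.crc32(text.encode()) & 0x7FFFFFFF


@dataclass
class SimulationConfig:
    """All generator knobs; defaults reproduce the study conditions.

    Neural effect sizes are expressed in units of the within-subject
    residual SD; gaze effects in proportion units.
    """

    seed: int = 0

    # --- EEG signal ----------------------------------------------------
    sampling_rate_hz: float = 256.0
    duration_s: float = 60.0
    #: base-rate response amplitude per harmonic (µV), MO-dominant
    base_amplitudes_uv: tuple[float, ...] = (1.0, 0.6, 0.4, 0.3)
    #: oddball (deviant) response amplitude per retained harmonic (µV)
    oddball_amplitudes_uv: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)
    #: multi-input per-stream amplitude per harmonic (µV)
    stream_amplitudes_uv: tuple[float, ...] = (0.5, 0.35, 0.25, 0.15)
    n_oddball_harmonics: int = 5
    n_stream_harmonics: int = 4
    roi_gains_base: Mapping[str, float] = field(
        default_factory=lambda: {"LOT": 0.8, "MO": 1.2, "ROT": 0.8}
    )
    roi_gains_response: Mapping[str, float] = field(
        default_factory=lambda: {"LOT": 1.0, "MO": 1.0, "ROT": 1.0}
    )
    #: noise SDs are calibrated so the per-subject noise floor keeps the
    #: summed baseline-subtracted quantification bias under 10% (baseline
    #: subtraction removes the mean neighbour amplitude, which biases the
    #: recovered response low by roughly the noise-floor amplitude per
    #: harmonic)
    pink_sd_uv: float = 0.5
    pink_exponent: float = 1.0
    white_sd_uv: float = 0.25
    #: multiplicative per-subject response variability (SD of a unit-mean factor)
    subject_amp_sd: float = 0.1

    # --- cohort sizes ---------------------------------------------------
    n_control: int = 43
    n_adversity: int = 48
    n_control_gaze: int = 28
    n_adversity_gaze: int = 41
    female_ratio: float = 0.6
    age_range: tuple[float, float] = (16.0, 24.0)

    # --- outcome model (neural, µV scale) -------------------------------
    sigma_within: float = 0.4
    sigma_subject: float = 0.3
    oddball_grand_mean_uv: float = 1.0
    multiinput_grand_mean_uv: float = 0.8
    #: control-group social-minus-nonsocial discrimination gap (x sigma_within);
    #: the adversity group has no gap, which is the group x content interaction
    group_content_gap_sd: float = 1.0
    group_main_sd: float = 0.0
    #: change in the social-minus-nonsocial gap per SD of threat exposure
    threat_content_slope_sd: float = -1.0
    neglect_content_slope_sd: float = 0.5
    #: neutral-minus-negative salience (x sigma_within)
    valence_main_sd: float = 1.0
    #: extra neutral-minus-negative salience in the social context
    valence_content_sd: float = 1.0
    sex_main_sd: float = 0.5  # females > males, multi-input salience

    # --- gaze outcome (proportion scale) --------------------------------
    gaze_base_proportion: float = 0.41
    gaze_valence_main: float = 0.08  # neutral - negative looking proportion
    adversity_valence_gaze_slope: float = 0.03  # per SD of adversity, on negative
    gaze_sigma_within: float = 0.06
    gaze_sigma_subject: float = 0.04
    #: shared subject x content valence-preference factor and its gaze loading
    sigma_latent: float = 1.5
    gaze_latent_loading: float = 0.1

    # --- fixations -------------------------------------------------------
    screen_px: tuple[int, int] = (1920, 1080)
    calibration_error_px: float = 30.0
    fixations_per_trial: int = 120
    fixation_duration_mean_s: float = 0.3

    def __post_init__(self) -> None:
        for name in (
            "sampling_rate_hz", "duration_s", "pink_sd_uv", "white_sd_uv",
            "sigma_within", "sigma_subject", "gaze_sigma_within",
            "gaze_sigma_subject", "sigma_latent", "subject_amp_sd",
            "calibration_error_px",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for amps in (self.base_amplitudes_uv, self.oddball_amplitudes_uv,
                     self.stream_amplitudes_uv):
            if any(a < 0 for a in amps):
                raise ValueError("signal amplitudes must be non-negative")
        for n in (self.n_control, self.n_adversity):
            if n < 2:
                raise ValueError("group sizes must be >= 2")

    def rng(self, *stream: int) -> np.random.Generator:
        """Independent, reproducible generator for a named sub-stream."""
        return np.random.default_rng([self.seed, *stream])

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------

def snap_frequency(freq_hz: float, duration_s: float) -> float:
    """Nearest frequency lying exactly on the FFT bin grid of the duration."""
    return round(freq_hz * duration_s) / duration_s


def _pink_noise(rng, n_channels, n_samples, fs, exponent, sd) -> np.ndarray:
    """Noise with 1/f^exponent amplitude spectrum, scaled to a target SD."""
    if sd == 0:
        return np.zeros((n_channels, n_samples))
    n_freq = n_samples // 2 + 1
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    shape = np.zeros(n_freq)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    coef = (
        rng.standard_normal((n_channels, n_freq))
        + 1j * rng.standard_normal((n_channels, n_freq))
    ) * shape
    x = np.fft.irfft(coef, n=n_samples, axis=1)
    x_sd = x.std(axis=1, keepdims=True)
    x_sd[x_sd == 0] = 1.0
    return x / x_sd * sd


def stream_harmonic_frequencies(
    rate_hz: float, n_keep: int, duration_s: float
) -> tuple[float, ...]:
    """Harmonics of a stream rate after snapping the fundamental to the grid.

    The stimulus is periodic at the *snapped* rate, so its harmonics are
    integer multiples of the snapped fundamental (all exactly bin-aligned),
    not individually snapped multiples of the nominal rate.
    """
    snapped = snap_frequency(rate_hz, duration_s)
    return tuple(snapped * k for k in range(1, n_keep + 1))


def _signal_components(
    paradigm: StimulationParadigm,
    cfg: SimulationConfig,
    response_scale: float | Mapping[float, float],
) -> list[tuple[float, float, Mapping[str, float]]]:
    """(frequency, amplitude µV, roi gains) for every injected sinusoid.

    ``response_scale`` multiplies the deviant/stream response amplitudes
    (scalar, or a mapping from nominal stream rate to scale for multi-input).
    """

    def scale_for(fund: float) -> float:
        if isinstance(response_scale, Mapping):
            return float(response_scale.get(fund, 1.0))
        return float(response_scale)

    comps: list[tuple[float, float, Mapping[str, float]]] = []
    if paradigm.kind == "oddball":
        for k, amp in enumerate(cfg.base_amplitudes_uv, start=1):
            comps.append((paradigm.base_rate_hz * k, amp, cfg.roi_gains_base))
        hs = oddball_harmonics(
            paradigm.base_rate_hz, paradigm.oddball_cycle, cfg.n_oddball_harmonics
        )
        s = scale_for(paradigm.oddball_rate_hz)
        for f, amp in zip(hs.frequencies_hz, cfg.oddball_amplitudes_uv):
            comps.append((f, amp * s, cfg.roi_gains_response))
    else:
        for rate in paradigm.stream_rates_hz:
            freqs = stream_harmonic_frequencies(
                rate, cfg.n_stream_harmonics, cfg.duration_s
            )
            s = scale_for(rate)
            for f, amp in zip(freqs, cfg.stream_amplitudes_uv):
                comps.append((f, amp * s, cfg.roi_gains_response))
    return comps


def simulate_eeg(
    paradigm: StimulationParadigm,
    cfg: SimulationConfig,
    subject_id: str,
    condition: str = "",
    response_scale: float | Mapping[float, float] = 1.0,
    align: str = "snap",
    rng: np.random.Generator | None = None,
) -> EEGRecording:
    """Synthesize one recording for one subject x condition.

    Tagged frequencies that do not lie exactly on the FFT bin grid of the
    configured duration are snapped to the nearest bin (``align="snap"``,
    the default — e.g. 4.61 Hz at 60 s becomes 4.6167 Hz) or rejected
    (``align="strict"``).  The snapped values are what the analysis must
    target, so they are discoverable via :func:`snap_frequency`.
    """
    if rng is None:
        rng = cfg.rng(_stable_hash(subject_id), _stable_hash(condition))
    fs, dur = cfg.sampling_rate_hz, cfg.duration_s
    if align == "strict" and paradigm.kind == "multi_input":
        # stream harmonics are generated as multiples of the snapped
        # fundamental, so strictness must be enforced on the nominal rates
        for rate in paradigm.stream_rates_hz:
            if abs(snap_frequency(rate, dur) - rate) > 1e-9:
                raise ValueError(
                    f"{rate} Hz does not align with the {1 / dur:.6f} Hz bin "
                    f"grid of a {dur} s recording"
                )
    n = int(round(fs * dur))
    t = np.arange(n) / fs
    channels = DEFAULT_CHANNELS
    data = np.zeros((len(channels), n))
    for freq, amp, gains in _signal_components(paradigm, cfg, response_scale):
        f_exact = snap_frequency(freq, dur)
        if align == "strict" and abs(f_exact - freq) > 1e-9:
            raise ValueError(
                f"{freq} Hz does not align with the {1 / dur:.6f} Hz bin grid "
                f"of a {dur} s recording"
            )
        phase = rng.uniform(0, 2 * np.pi)
        wave = np.sin(2 * np.pi * f_exact * t + phase)
        for i, ch in enumerate(channels):
            data[i] += amp * gains.get(_CHANNEL_ROI[ch], 1.0) * wave
    data += _pink_noise(rng, len(channels), n, fs, cfg.pink_exponent, cfg.pink_sd_uv)
    if cfg.white_sd_uv > 0:
        data += rng.normal(0.0, cfg.white_sd_uv, size=data.shape)
    return EEGRecording(
        channel_labels=channels,
        sampling_rate_hz=fs,
        samples=data,
        paradigm=paradigm,
        subject_id=subject_id,
        condition=condition,
    )


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortTables:
    """Covariates plus score-level outcome tables for both paradigms."""

    covariates: pd.DataFrame
    oddball: pd.DataFrame            # subject x content x roi, y in µV
    multiinput_neural: pd.DataFrame  # subject x valence x content x rate, µV
    multiinput_gaze: pd.DataFrame    # subject x valence x content, proportion


def _covariates(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for group, n in (("control", cfg.n_control), ("adversity", cfg.n_adversity)):
        for i in range(n):
            if group == "adversity":
                threat = rng.gamma(2.0, 0.5)
                neglect = max(0.0, 0.5 * threat + rng.gamma(1.5, 0.4) - 0.3)
            else:
                threat = abs(rng.normal(0.0, 0.08))
                neglect = abs(rng.normal(0.0, 0.08))
            adversity = (5 * threat + 2 * neglect) / 7.0
            rows.append(
                {
                    "subject": f"{group[:3]}{i:03d}",
                    "group": group,
                    "age": rng.uniform(*cfg.age_range),
                    "sex": "female" if rng.random() < cfg.female_ratio else "male",
                    "threat": threat,
                    "neglect": neglect,
                    "adversity": adversity,
                    "depression": max(0.0, 6 * adversity + rng.normal(3, 2)),
                    "anxiety": max(0.0, 8 * adversity + rng.normal(30, 6)),
                    "psychosis": max(0.0, 2 * adversity + rng.normal(2, 1.5)),
                }
            )
    return pd.DataFrame(rows)


def _group_z(cov: pd.DataFrame, col: str) -> pd.Series:
    """Within-adversity-group z-score of a score, 0 for controls."""
    z = pd.Series(0.0, index=cov.index)
    mask = cov["group"] == "adversity"
    vals = cov.loc[mask, col]
    sd = vals.std(ddof=1)
    z.loc[mask] = (vals - vals.mean()) / sd if sd > 0 else 0.0
    return z


def simulate_cohort(cfg: SimulationConfig) -> CohortTables:
    """Draw covariates and score-level outcomes embedding the configured effects.

    Oddball discrimination (per subject x content x ROI): the control group
    gains ``group_content_gap_sd x sigma_within`` in the social context, the
    adversity group does not (the group x content interaction); within the
    adversity group threat and neglect exposure tilt the social-vs-nonsocial
    gap by their configured slopes.

    Multi-input salience (per subject x valence x content x rate): neutral
    exceeds negative by ``valence_main_sd x sigma_within``, more so in the
    social context, plus a latent subject x content valence preference shared
    with gaze, which makes gaze and neural difference scores correlate.
    """
    rng = cfg.rng(1)
    cov = _covariates(cfg, rng)
    sw, ss = cfg.sigma_within, cfg.sigma_subject
    threat_z = _group_z(cov, "threat")
    neglect_z = _group_z(cov, "neglect")
    adversity_z = _group_z(cov, "adversity")

    # ---- oddball ------------------------------------------------------
    roi_offsets = {"LOT": -0.1, "MO": 0.05, "ROT": 0.05}
    odd_rows = []
    u = rng.normal(0, ss, len(cov))
    for (i, subj), ui in zip(cov.iterrows(), u):
        for content in ("social", "nonsocial"):
            xc = 0.5 if content == "social" else -0.5
            mu = cfg.oddball_grand_mean_uv + ui
            mu += cfg.group_main_sd * sw * (0.5 if subj.group == "control" else -0.5)
            if subj.group == "control":
                # social-vs-nonsocial gap exists only in controls: a pure
                # group x content interaction plus the content main effect
                # it induces, with no group main effect
                mu += cfg.group_content_gap_sd * sw * xc
            else:
                mu += cfg.threat_content_slope_sd * sw * threat_z[i] * xc
                mu += cfg.neglect_content_slope_sd * sw * neglect_z[i] * xc
            for roi, off in roi_offsets.items():
                odd_rows.append(
                    {
                        "subject": subj.subject,
                        "content": content,
                        "roi": roi,
                        "y": mu + off + rng.normal(0, sw),
                    }
                )
    oddball = pd.DataFrame(odd_rows).merge(cov, on="subject")

    # ---- multi-input neural + gaze -------------------------------------
    neural_rows, gaze_rows = [], []
    u_n = rng.normal(0, ss, len(cov))
    u_g = rng.normal(0, cfg.gaze_sigma_subject, len(cov))
    gaze_subjects = set(
        cov[cov.group == "control"].subject.iloc[: cfg.n_control_gaze]
    ) | set(cov[cov.group == "adversity"].subject.iloc[: cfg.n_adversity_gaze])
    for (i, subj), ui, ugi in zip(cov.iterrows(), u_n, u_g):
        sex_c = 0.5 if subj.sex == "female" else -0.5
        for content in ("social", "nonsocial"):
            xc = 0.5 if content == "social" else -0.5
            latent = rng.normal(0, cfg.sigma_latent)
            for valence in ("neutral", "negative"):
                xv = 0.5 if valence == "neutral" else -0.5
                mu = (
                    cfg.multiinput_grand_mean_uv
                    + ui
                    + cfg.sex_main_sd * sw * sex_c
                    + cfg.valence_main_sd * sw * xv
                    + cfg.valence_content_sd * sw * xv * xc
                    + latent * xv
                )
                for rate in (4.61, 5.0):
                    neural_rows.append(
                        {
                            "subject": subj.subject,
                            "valence": valence,
                            "content": content,
                            "rate": rate,
                            "y": mu + rng.normal(0, sw),
                        }
                    )
                if subj.subject in gaze_subjects:
                    p = (
                        cfg.gaze_base_proportion
                        + ugi
                        + xv
                        * (
                            cfg.gaze_valence_main
                            - cfg.adversity_valence_gaze_slope * adversity_z[i]
                            + cfg.gaze_latent_loading * latent
                        )
                        + rng.normal(0, cfg.gaze_sigma_within)
                    )
                    gaze_rows.append(
                        {
                            "subject": subj.subject,
                            "valence": valence,
                            "content": content,
                            "y": float(np.clip(p, 0.0, 1.0)),
                        }
                    )
    neural = pd.DataFrame(neural_rows).merge(cov, on="subject")
    gaze = pd.DataFrame(gaze_rows).merge(cov, on="subject")
    return CohortTables(
        covariates=cov, oddball=oddball, multiinput_neural=neural,
        multiinput_gaze=gaze,
    )


# ---------------------------------------------------------------------------
# Fixations
# ---------------------------------------------------------------------------

def default_aois(screen_px: tuple[int, int] = (1920, 1080)) -> tuple[AOIRect, AOIRect]:
    """Two mirror-symmetric scene rectangles, one per hemifield."""
    w, h = screen_px
    rw, rh = int(w * 0.33), int(h * 0.48)
    y0 = (h - rh) // 2
    return (
        AOIRect("left", int(w * 0.06), int(w * 0.06) + rw, y0, y0 + rh),
        AOIRect("right", w - int(w * 0.06) - rw, w - int(w * 0.06), y0, y0 + rh),
    )


def simulate_fixations(
    aois: Sequence[AOIRect],
    probabilities: Mapping[str, float],
    n_fixations: int,
    cfg: SimulationConfig,
    subject_id: str = "",
    condition: str = "",
    rng: np.random.Generator | None = None,
) -> list[FixationRecord]:
    """Fixation stream with configured dwell probabilities per AOI.

    ``probabilities`` maps each AOI label plus ``"outside"`` to a dwell
    probability (must sum to 1).  True fixation targets are drawn uniformly
    inside the chosen AOI (with a 3-sigma margin from its borders so the
    probability-weighted recovery is unbiased); the reported position adds
    isotropic Gaussian scatter with SD ``calibration_error_px``.
    """
    labels = [a.label for a in aois] + ["outside"]
    missing = set(labels) - set(probabilities)
    if missing:
        raise ValueError(f"missing dwell probabilities for {sorted(missing)}")
    probs = np.array([probabilities[lab] for lab in labels], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(f"dwell probabilities sum to {probs.sum()}, not 1")
    for i, a in enumerate(aois):
        for b in aois[i + 1:]:
            if a.overlaps(b):
                raise ValueError("AOIs must be non-overlapping")
    if rng is None:
        rng = cfg.rng(2, _stable_hash(subject_id), _stable_hash(condition))
    err = cfg.calibration_error_px
    margin = 3.0 * err
    w, h = cfg.screen_px
    fixations = []
    onset = 0.0
    for _ in range(n_fixations):
        choice = labels[rng.choice(len(labels), p=probs)]
        if choice == "outside":
            # rejection-sample a point at least `margin` away from both rects
            for _ in range(1000):
                x = rng.uniform(0, w)
                y = rng.uniform(0, h)
                if all(
                    not (
                        a.x_min - margin <= x <= a.x_max + margin
                        and a.y_min - margin <= y <= a.y_max + margin
                    )
                    for a in aois
                ):
                    break
        else:
            a = next(r for r in aois if r.label == choice)
            lo_x, hi_x = a.x_min + margin, a.x_max - margin
            lo_y, hi_y = a.y_min + margin, a.y_max - margin
            if lo_x >= hi_x or lo_y >= hi_y:  # margin larger than the AOI
                lo_x, hi_x = a.x_min, a.x_max
                lo_y, hi_y = a.y_min, a.y_max
            x = rng.uniform(lo_x, hi_x)
            y = rng.uniform(lo_y, hi_y)
        x += rng.normal(0, err) if err > 0 else 0.0
        y += rng.normal(0, err) if err > 0 else 0.0
        duration = rng.gamma(4.0, cfg.fixation_duration_mean_s / 4.0)
        fixations.append(
            FixationRecord(
                x_px=float(x),
                y_px=float(y),
                onset_s=onset,
                duration_s=float(duration),
                subject_id=subject_id,
                condition=condition,
                calibration_error_px=err,
            )
        )
        onset += duration + 0.05
    return fixations


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def eeg_to_frame(rec: EEGRecording) -> pd.DataFrame:
    """Long-format CSV schema: subject, condition, channel, sample_index, µV."""
    n = rec.n_samples
    frames = []
    for i, ch in enumerate(rec.channel_labels):
        frames.append(
            pd.DataFrame(
                {
                    "subject": rec.subject_id,
                    "condition": rec.condition,
                    "channel": ch,
                    "sample_index": np.arange(n),
                    "uv": rec.samples[i],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def eeg_from_frame(
    df: pd.DataFrame, sampling_rate_hz: float, paradigm: StimulationParadigm
) -> EEGRecording:
    """Rebuild a recording from the long-format CSV schema."""
    channels = tuple(df["channel"].unique())
    pivot = df.pivot_table(
        index="channel", columns="sample_index", values="uv", sort=False
    ).loc[list(channels)]
    return EEGRecording(
        channel_labels=channels,
        sampling_rate_hz=sampling_rate_hz,
        samples=pivot.to_numpy(),
        paradigm=paradigm,
        subject_id=str(df["subject"].iloc[0]),
        condition=str(df["condition"].iloc[0]),
    )


def fixations_to_frame(fixations: list[FixationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject": [f.subject_id for f in fixations],
            "condition": [f.condition for f in fixations],
            "x_px": [f.x_px for f in fixations],
            "y_px": [f.y_px for f in fixations],
            "onset_s": [f.onset_s for f in fixations],
            "duration_s": [f.duration_s for f in fixations],
            "calibration_error_px": [f.calibration_error_px for f in fixations],
        }
    )
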