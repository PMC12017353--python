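"""Cohort-level statistical pipeline.

Outcome tables (summed neural responses or gaze proportions, one row per
subject x factor cell) are screened for outliers with the median absolute
deviation within each measurement cell, continuous adversity and symptom
scores are standardised, and three random-intercept linear mixed models are
fitted per outcome:

* Model 1 — group contrast: ``y ~ age + sex + Group * Content (* ROI, or
  * Valence for the multi-input paradigm) + (1 | subject)``;
* Model 2 — continuous childhood-adversity score within the adversity
  group, controlling for depression, anxiety and psychosis symptom scores;
* Model 3 — as Model 2 with adversity split into threat and neglect
  dimensions.

Two-level factors are coded +/- 0.5 (sum-to-zero), ROI with a sum contrast,
so the Type-III F tests of :mod:`fpvstag.lmm` are orthogonal on balanced
data.  Post-hoc cell-mean comparisons are Tukey-corrected.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .lmm import LMMFit, fit_random_intercept

logger = logging.getLogger(__name__)

#: Consistency constant making the MAD estimate Gaussian-sd-comparable.
MAD_SCALE = 1.4826
#: Robust-z threshold beyond which a value is flagged.
MAD_THRESHOLD = 3.0

#: +/-0.5 sum-to-zero codings for the two-level factors.
FACTOR_CODES = {
    "group": {"control": 0.5, "adversity": -0.5},
    "sex": {"female": 0.5, "male": -0.5},
    "content": {"social": 0.5, "nonsocial": -0.5},
    "valence": {"neutral": 0.5, "negative": -0.5},
}

CONTINUOUS_SCORES = (
    "adversity", "threat", "neglect", "depression", "anxiety", "psychosis",
)


def mad_outliers(
    values,
    scale_constant: float = MAD_SCALE,
    threshold: float = MAD_THRESHOLD,
) -> np.ndarray:
    """Flag values whose robust z-score exceeds ``threshold``.

    Robust z = |x - median| / (scale_constant * MAD) with MAD the raw median
    absolute deviation.  A zero MAD yields no flags (with a warning), since
    the scale is then uninformative.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values for MAD screening")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        warnings.warn("MAD is zero; no outliers flagged")
        return np.zeros(x.shape, dtype=bool)
    return np.abs(x - med) / (scale_constant * mad) > threshold


def standardize(values) -> np.ndarray:
    """Z-score to mean 0, SD 1 (n-1 denominator)."""
    x = np.asarray(values, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot standardize a constant vector")
    return (x - x.mean()) / sd


@dataclass(frozen=True)
class ModelSpec:
    """One of the three cohort model specifications for one outcome."""

    model_id: int
    outcome: str  # "oddball" | "multiinput_neural" | "multiinput_gaze"

    def __post_init__(self) -> None:
        if self.model_id not in (1, 2, 3):
            raise ValueError("model_id must be 1, 2 or 3")
        if self.outcome not in ("oddball", "multiinput_neural", "multiinput_gaze"):
            raise ValueError(f"unknown outcome {self.outcome!r}")

    @property
    def adversity_only(self) -> bool:
        return self.model_id in (2, 3)

    @property
    def outlier_cells(self) -> list[str]:
        if self.outcome == "oddball":
            return ["roi", "content"]
        if self.outcome == "multiinput_neural":
            return ["valence", "content", "rate"]
        return ["valence", "content"]


def model_formula(spec: ModelSpec) -> str:
    """patsy formula of the fixed part (random intercept handled separately)."""
    if spec.outcome == "oddball":
        within = "content_c * C(roi, Sum)"
        within_2 = "content_c"
    else:
        within = "valence_c * content_c"
        within_2 = "valence_c * content_c"
    if spec.model_id == 1:
        return f"y ~ age + sex_c + group_c * {within}"
    scores = (
        ["adversity_z"] if spec.model_id == 2 else ["threat_z", "neglect_z"]
    ) + ["depression_z", "anxiety_z", "psychosis_z"]
    terms = " + ".join(f"{s} * {within_2}" for s in scores)
    return f"y ~ age + sex_c + {terms}"


def code_factors(table: pd.DataFrame) -> pd.DataFrame:
    """Add +/-0.5 numeric codes for the two-level factors present."""
    out = table.copy()
    for col, mapping in FACTOR_CODES.items():
        if col in out.columns:
            bad = set(out[col].unique()) - set(mapping)
            if bad:
                raise ValueError(f"unknown {col} levels: {sorted(bad)}")
            out[f"{col}_c"] = out[col].map(mapping)
    return out


def standardize_scores(
    table: pd.DataFrame, scores=CONTINUOUS_SCORES
) -> pd.DataFrame:
    """Standardise subject-level scores (M=0, SD=1 across subjects).

    Scores repeat across a subject's rows, so the z-scoring is computed on
    one value per subject and broadcast back.
    """
    out = table.copy()
    per_subj = out.drop_duplicates("subject").set_index("subject")
    for s in scores:
        if s not in out.columns:
            continue
        z = pd.Series(standardize(per_subj[s]), index=per_subj.index)
        out[f"{s}_z"] = out["subject"].map(z)
    return out


def remove_outliers(
    table: pd.DataFrame,
    by: list[str],
    value_col: str = "y",
    scale_constant: float = MAD_SCALE,
    threshold: float = MAD_THRESHOLD,
) -> tuple[pd.DataFrame, int]:
    """Drop MAD-flagged rows within each measurement cell; log the count."""
    flags = np.zeros(len(table), dtype=bool)
    tbl = table.reset_index(drop=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _, idx in tbl.groupby(by).indices.items():
            flags[idx] = mad_outliers(
                tbl.loc[idx, value_col], scale_constant, threshold
            )
    n_removed = int(flags.sum())
    if n_removed:
        logger.info(
            "removed %d / %d data points as MAD outliers", n_removed, len(tbl)
        )
    return tbl.loc[~flags].reset_index(drop=True), n_removed


@dataclass
class ModelResult:
    """Fitted model with its ANOVA table and screening diagnostics."""

    spec: ModelSpec
    fit: LMMFit
    anova: pd.DataFrame
    n_outliers_removed: int
    n_obs: int

    def contrasts(self, factors: list[str], by: list[str] | None = None) -> pd.DataFrame:
        return self.fit.tukey_contrasts(factors, by)


def prepare_table(
    spec: ModelSpec,
    table: pd.DataFrame,
    mad_scale: float = MAD_SCALE,
    mad_threshold: float = MAD_THRESHOLD,
) -> tuple[pd.DataFrame, int]:
    """Subset, screen, code and standardise an outcome table for one model."""
    tbl = table.copy()
    if spec.adversity_only:
        tbl = tbl[tbl["group"] == "adversity"].reset_index(drop=True)
        if tbl.empty:
            raise ValueError("no adversity-group rows for Models 2/3")
    elif spec.model_id in (2, 3) and (tbl["group"] == "control").any():
        raise ValueError("Models 2 and 3 are fitted within the adversity group")
    cells = [c for c in spec.outlier_cells if c in tbl.columns]
    tbl, n_removed = remove_outliers(tbl, cells, "y", mad_scale, mad_threshold)
    tbl = code_factors(tbl)
    if spec.adversity_only:
        tbl = standardize_scores(tbl)
    return tbl, n_removed


def fit_model(
    spec: ModelSpec,
    table: pd.DataFrame,
    mad_scale: float = MAD_SCALE,
    mad_threshold: float = MAD_THRESHOLD,
) -> ModelResult:
    """Full pipeline for one model: screen, standardise, fit, test."""
    tbl, n_removed = prepare_table(spec, table, mad_scale, mad_threshold)
    fit = fit_random_intercept(model_formula(spec), tbl, groups="subject")
    return ModelResult(
        spec=spec,
        fit=fit,
        anova=fit.anova(),
        n_outliers_removed=n_removed,
        n_obs=fit.n_obs,
    )


def gaze_neural_correlation(
    gaze: pd.DataFrame, neural: pd.DataFrame
) -> pd.DataFrame:
    """Pearson r between preferential looking and neural salience per context.

    Both inputs are tidy tables with columns ``subject, content, valence, y``
    (multiple rows per cell, e.g. per tagging rate, are averaged).  For each
    subject and content the negative-minus-neutral difference is formed for
    both measures; the correlation is computed across subjects separately in
    the social and non-social context.
    """

    def diffs(df: pd.DataFrame) -> pd.DataFrame:
        cell = df.groupby(["subject", "content", "valence"])["y"].mean().unstack()
        return (cell["negative"] - cell["neutral"]).rename("d").reset_index()

    merged = diffs(gaze).merge(
        diffs(neural), on=["subject", "content"], suffixes=("_gaze", "_neural")
    )
    rows = []
    for content, sub in merged.groupby("content"):
        n = len(sub)
        if n < 3:
            raise ValueError(f"need >= 3 paired subjects per context, got {n}")
        r, p = sps.pearsonr(sub["d_gaze"], sub["d_neural"])
        rows.append({"content": content, "r": float(r), "df": n - 2, "p": float(p)})
    return pd.DataFrame(rows)
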