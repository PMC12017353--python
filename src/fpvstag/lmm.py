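"""Random-intercept linear mixed models with Type-III F tests.

The cohort models are all of the form ``y ~ fixed effects + (1 | subject)``:
a single random intercept per subject over a compound-symmetric residual
structure.  For that model the covariance is ``V_i = sigma^2 (I + theta J)``
per subject block (``theta = tau^2 / sigma^2``), so REML profiles down to a
one-dimensional optimisation in ``theta`` with closed-form GLS for the fixed
effects — solved here directly rather than through a general mixed-model
optimiser, which keeps boundary cases (``theta -> 0``) exact.

Inference conventions:

* fixed-effect terms are tested with Type-III Wald F statistics (factors
  must be coded sum-to-zero for these to be meaningful);
* denominator degrees of freedom follow the between-within (containment)
  rule: terms constant within subject are tested against
  ``n_subjects - p_between`` and within-subject terms against
  ``n_obs - n_subjects - p_within``;
* post-hoc pairwise comparisons of estimated marginal means use the
  studentized-range (Tukey) family correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import patsy
from scipy import linalg, optimize
from scipy import stats as sps

_BOUNDARY_TOL = 1e-10


class RankDeficientDesign(ValueError):
    """Raised when fixed-effect columns are aliased."""


class ConvergenceError(RuntimeError):
    """Raised when the REML profile optimisation fails."""


def _group_sums(X: np.ndarray, y: np.ndarray, codes: np.ndarray):
    """Per-group row sums of X and y, and group sizes."""
    n_groups = codes.max() + 1
    p = X.shape[1]
    Sx = np.zeros((n_groups, p))
    Sy = np.zeros(n_groups)
    np.add.at(Sx, codes, X)
    np.add.at(Sy, codes, y)
    sizes = np.bincount(codes)
    return Sx, Sy, sizes


def _gls_pieces(theta: float, XtX, Xty, yty, Sx, Sy, sizes):
    """X'V*X, X'V*y, y'V*y and log|V*| for V* = (I + theta J)^-1 blocks."""
    c = theta / (1.0 + theta * sizes)  # shrinkage per group
    XtVX = XtX - (Sx * c[:, None]).T @ Sx
    XtVy = Xty - Sx.T @ (c * Sy)
    yTVy = yty - float(np.dot(c * Sy, Sy))
    logdet_v = float(np.sum(np.log1p(theta * sizes)))
    return XtVX, XtVy, yTVy, logdet_v


def _neg2_reml(theta, XtX, Xty, yty, Sx, Sy, sizes, n, p):
    XtVX, XtVy, yTVy, logdet_v = _gls_pieces(theta, XtX, Xty, yty, Sx, Sy, sizes)
    try:
        cf = linalg.cho_factor(XtVX)
    except linalg.LinAlgError:
        return np.inf
    beta = linalg.cho_solve(cf, XtVy)
    rss = yTVy - float(XtVy @ beta)
    if rss <= 0:
        return np.inf
    sigma2 = rss / (n - p)
    logdet_xvx = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    return (n - p) * np.log(sigma2) + logdet_v + logdet_xvx


@dataclass
class LMMFit:
    """Fitted random-intercept model."""

    formula: str
    group_col: str
    params: pd.Series
    cov_params: np.ndarray
    sigma2: float          # residual variance
    tau2: float            # random-intercept variance
    n_obs: int
    n_groups: int
    df_between: int
    df_within: int
    between_cols: np.ndarray  # bool per design column
    design_info: patsy.DesignInfo
    data: pd.DataFrame
    neg2_reml: float

    @property
    def theta(self) -> float:
        return self.tau2 / self.sigma2 if self.sigma2 > 0 else 0.0

    # ------------------------------------------------------------------
    def _term_slices(self):
        return {
            name: self.design_info.term_name_slices[name]
            for name in self.design_info.term_names
        }

    def _df_den_for_cols(self, cols: np.ndarray) -> int:
        """Containment df: within-subject columns dominate."""
        return self.df_between if self.between_cols[cols].all() else self.df_within

    def anova(self) -> pd.DataFrame:
        """Type-III F test for every fixed-effect term (intercept excluded)."""
        rows = []
        beta = self.params.to_numpy()
        for name, sl in self._term_slices().items():
            if name == "Intercept":
                continue
            idx = np.arange(sl.start, sl.stop)
            b = beta[idx]
            C = self.cov_params[np.ix_(idx, idx)]
            q = len(idx)
            F = float(b @ linalg.solve(C, b, assume_a="pos")) / q
            df_den = self._df_den_for_cols(idx)
            p = float(sps.f.sf(F, q, df_den))
            rows.append(
                {"term": name, "F": F, "df_num": q, "df_den": df_den, "p": p}
            )
        return pd.DataFrame(rows)

    # ------------------------------------------------------------------
    def _reference_grid(self, factors: list[str], by: list[str]) -> pd.DataFrame:
        """Cartesian grid over requested factor levels, averaging the rest.

        Requested (and ``by``) columns take their unique observed values;
        other non-numeric model variables contribute every level to the grid
        (rows are later averaged over them); numeric covariates sit at their
        observed mean.
        """
        wanted = list(dict.fromkeys(factors + by))
        var_names = [
            v for v in self.design_info.describe().replace("+", " ").split()
            if v in self.data.columns
        ]
        # fall back: any data column used by the design
        var_names = [c for c in self.data.columns if c in set(var_names) or c in wanted]
        levels: dict[str, list] = {}
        for col in wanted:
            levels[col] = sorted(self.data[col].dropna().unique().tolist())
        others_cat = [
            c
            for c in self.data.columns
            if c not in wanted
            and c != self.group_col
            and self.data[c].dtype == object
            and c in self.design_info.describe()
        ]
        for col in others_cat:
            levels[col] = sorted(self.data[col].dropna().unique().tolist())
        grid = pd.DataFrame(
            [
                dict(zip(levels, combo))
                for combo in __import__("itertools").product(*levels.values())
            ]
        )
        for c in self.data.columns:
            if c in grid.columns or c == self.group_col:
                continue
            if np.issubdtype(self.data[c].dtype, np.number):
                grid[c] = self.data[c].mean()
        return grid

    def emmeans(self, factors: list[str], by: list[str] | None = None) -> pd.DataFrame:
        """Estimated marginal means over the cells of ``factors`` (x ``by``)."""
        by = by or []
        grid = self._reference_grid(factors, by)
        M = np.asarray(
            patsy.build_design_matrices([self.design_info], grid)[0]
        )
        keys = factors + by
        beta = self.params.to_numpy()
        rows = []
        for cell, sub in grid.groupby(keys, sort=True):
            L = M[sub.index.to_numpy()].mean(axis=0)
            est = float(L @ beta)
            se = float(np.sqrt(L @ self.cov_params @ L))
            cell = cell if isinstance(cell, tuple) else (cell,)
            rows.append({**dict(zip(keys, cell)), "emmean": est, "se": se, "_L": L})
        return pd.DataFrame(rows)

    def tukey_contrasts(
        self, factors: list[str], by: list[str] | None = None
    ) -> pd.DataFrame:
        """Pairwise Tukey-corrected contrasts of cell means.

        With ``by`` given, cells of ``factors`` are compared within each
        level combination of ``by``; the Tukey family size is the number of
        cells compared within one ``by`` stratum.
        """
        by = by or []
        em = self.emmeans(factors, by)
        beta = self.params.to_numpy()
        groups = [((), em)] if not by else list(em.groupby(by, sort=True))
        rows = []
        for by_cell, sub in groups:
            sub = sub.reset_index(drop=True)
            k = len(sub)
            for i in range(k):
                for j in range(i + 1, k):
                    L = sub["_L"][i] - sub["_L"][j]
                    est = float(L @ beta)
                    se = float(np.sqrt(L @ self.cov_params @ L))
                    touched = np.abs(L) > 1e-12
                    df = self._df_den_for_cols(np.where(touched)[0])
                    t = est / se
                    p = float(sps.studentized_range.sf(abs(t) * np.sqrt(2.0), k, df))
                    lab_i = ",".join(str(sub[f][i]) for f in factors)
                    lab_j = ",".join(str(sub[f][j]) for f in factors)
                    row = {
                        "contrast": f"{lab_i} - {lab_j}",
                        "estimate": est,
                        "se": se,
                        "t": t,
                        "df": df,
                        "p_tukey": min(1.0, p),
                    }
                    if by:
                        bc = by_cell if isinstance(by_cell, tuple) else (by_cell,)
                        row.update(dict(zip(by, bc)))
                    rows.append(row)
        return pd.DataFrame(rows)


def fit_random_intercept(
    formula: str, data: pd.DataFrame, groups: str
) -> LMMFit:
    """Fit ``formula`` with a random intercept per ``groups`` by REML.

    The variance ratio ``theta = tau^2 / sigma^2`` is profiled out and
    optimised on a log grid with an exact boundary check at ``theta = 0``;
    fixed effects are the GLS solution at the optimum.
    """
    data = data.reset_index(drop=True)
    y_mat, X_mat = patsy.dmatrices(formula, data, return_type="dataframe")
    X = np.asarray(X_mat)
    y = np.asarray(y_mat).ravel()
    n, p = X.shape
    design_info = X_mat.design_info

    # rank check with named aliased columns
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int(np.sum(diag > diag.max() * n * np.finfo(float).eps))
    if rank < p:
        aliased = [X_mat.columns[i] for i in piv[rank:]]
        raise RankDeficientDesign(f"aliased fixed-effect columns: {aliased}")

    codes, uniques = pd.factorize(data[groups])
    n_groups = len(uniques)
    if n_groups < 2:
        raise ValueError("need at least two grouping units")

    XtX, Xty, yty = X.T @ X, X.T @ y, float(y @ y)
    Sx, Sy, sizes = _group_sums(X, y, codes)

    def objective(log_theta: float) -> float:
        return _neg2_reml(np.exp(log_theta), XtX, Xty, yty, Sx, Sy, sizes, n, p)

    res = optimize.minimize_scalar(
        objective, bounds=(-14.0, 14.0), method="bounded",
        options={"xatol": 1e-10},
    )
    if not res.success:
        raise ConvergenceError(f"REML profile optimisation failed: {res.message}")
    theta = float(np.exp(res.x))
    crit_interior = float(res.fun)
    crit_boundary = _neg2_reml(0.0, XtX, Xty, yty, Sx, Sy, sizes, n, p)
    if crit_boundary <= crit_interior or theta < _BOUNDARY_TOL:
        theta, crit = 0.0, crit_boundary
    else:
        crit = crit_interior

    XtVX, XtVy, yTVy, _ = _gls_pieces(theta, XtX, Xty, yty, Sx, Sy, sizes)
    cf = linalg.cho_factor(XtVX)
    beta = linalg.cho_solve(cf, XtVy)
    sigma2 = (yTVy - float(XtVy @ beta)) / (n - p)
    cov = sigma2 * linalg.cho_solve(cf, np.eye(p))

    # between/within column classification: constant within every group?
    group_means = Sx / sizes[:, None]
    within_ss = XtX.diagonal() - np.einsum("gp,gp,g->p", group_means, group_means, sizes.astype(float))
    scale = np.maximum(XtX.diagonal(), 1.0)
    between_cols = within_ss / scale < 1e-10
    p_between = int(between_cols.sum())
    p_within = p - p_between

    return LMMFit(
        formula=formula,
        group_col=groups,
        params=pd.Series(beta, index=X_mat.columns),
        cov_params=cov,
        sigma2=float(sigma2),
        tau2=float(theta * sigma2),
        n_obs=n,
        n_groups=n_groups,
        df_between=n_groups - p_between,
        df_within=n - n_groups - p_within,
        between_cols=between_cols,
        design_info=design_info,
        data=data,
        neg2_reml=float(crit),
    )
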