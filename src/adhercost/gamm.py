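"""Gaussian additive mixed model for yearly health-care costs.

The estimator regresses patient-year costs on a parametric covariate block
plus smooth functions of the adherence covariates (per-class PDC mean and
yearly PDC deviation, entered separately for males and females), with a
random intercept per patient.  Each smooth is a penalized cubic regression
spline whose wiggly component is treated as a random-effect block with its
own variance (estimated by REML), while its unpenalized linear component is a
fixed effect; a smoothing variance of zero therefore collapses the smooth to
a straight line and the whole model to a linear mixed model.

The class follows the scikit-learn estimator protocol: hyper-parameters in
``__init__``, data only in :meth:`fit`, fitted attributes with a trailing
underscore.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .basis import SmoothBasis, build_smooth_basis
from .reml import ConvergenceError, MixedModelREML

__all__ = ["CostGAMM", "SmoothSpec", "Term", "GammSummary", "ConvergenceError"]


@dataclass(frozen=True)
class SmoothSpec:
    """One smooth term: a spline in ``col``, optionally restricted to rows
    where ``by_col == by_val`` (sex stratification)."""

    name: str
    col: str
    by_col: str | None = None
    by_val: object | None = None
    rank: int = 10


@dataclass(frozen=True)
class Term:
    """One parametric term: numeric as-is, categorical dummy-coded against
    the first level of ``levels`` (the fixed reference level)."""

    col: str
    kind: str = "numeric"                 # "numeric" | "categorical"
    levels: tuple = ()

    def labels(self) -> list[str]:
        if self.kind == "numeric":
            return [self.col]
        return [f"{self.col}[{lv}]" for lv in self.levels[1:]]


def _significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class GammSummary:
    """Machine-readable fit report: parametric block, smooth block, fit stats."""

    parametric: pd.DataFrame
    smooths: pd.DataFrame
    r2_adj: float
    n_obs: int
    sigma_patient: float
    sigma_resid: float

    def __str__(self) -> str:
        lines = [f"N = {self.n_obs}", "", "Parametric coefficients:"]
        par = self.parametric.copy()
        par["sig"] = [_significance_stars(p) for p in par["p_value"]]
        lines.append(par.to_string(float_format=lambda v: f"{v: .4f}"))
        lines += ["", "Approximate significance of smooth terms:"]
        sm = self.smooths.copy()
        sm["sig"] = [_significance_stars(p) for p in sm["p_value"]]
        lines.append(sm.to_string(float_format=lambda v: f"{v: .4f}"))
        lines += ["",
                  f"sigma (patient intercept) = {self.sigma_patient:.2f}",
                  f"sigma (residual)          = {self.sigma_resid:.2f}",
                  f"R-sq. (adj.) = {self.r2_adj:.3f}"]
        return "\n".join(lines)


class CostGAMM(BaseEstimator):
    """Additive mixed model: parametric terms + penalized-spline smooths +
    patient random intercepts, estimated by REML.

    Parameters
    ----------
    parametric : list of :class:`Term`
        Covariates entering linearly (categoricals dummy-coded against their
        first level).  An intercept is always included.
    smooths : list of :class:`SmoothSpec`
        Penalized spline terms, each with its own smoothing variance.
    group_col : str
        Column identifying the patient (random-intercept grouping).
    smooth_variances : "estimate" | "zero"
        ``"zero"`` pins every smoothing variance at zero, reducing the model
        to a linear mixed model with the smooths' linear parts as fixed
        effects (used for the linear-limit validation).
    max_iter, tol : optimizer controls for the REML criterion.
    """

    def __init__(self, parametric=(), smooths=(), group_col="patient_id",
                 smooth_variances="estimate", max_iter=200, tol=1e-10):
        self.parametric = list(parametric)
        self.smooths = list(smooths)
        self.group_col = group_col
        self.smooth_variances = smooth_variances
        self.max_iter = max_iter
        self.tol = tol

    # ------------------------------------------------------------ design
    def _build_parametric(self, frame: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
        cols = [np.ones(len(frame))]
        labels = ["(Intercept)"]
        for term in self.parametric:
            v = frame[term.col]
            if v.isna().any():
                raise ValueError(f"missing values in covariate {term.col!r}")
            if term.kind == "numeric":
                cols.append(v.to_numpy(dtype=float))
                labels.append(term.col)
            else:
                levels = term.levels or tuple(pd.unique(v))
                for lv in levels[1:]:
                    cols.append((v == lv).to_numpy(dtype=float))
                    labels.append(f"{term.col}[{lv}]")
        return np.column_stack(cols), labels

    def _build_smooth_columns(self, frame: pd.DataFrame, fit: bool):
        n = len(frame)
        fixed_cols, fixed_labels, blocks, infos = [], [], [], []
        for spec in self.smooths:
            mask = np.ones(n, dtype=bool) if spec.by_col is None else \
                (frame[spec.by_col] == spec.by_val).to_numpy()
            vals = frame.loc[mask, spec.col].to_numpy(dtype=float)
            if fit:
                basis = build_smooth_basis(vals, rank=spec.rank)
            else:
                basis = self._smooth_info_[spec.name]["basis"]
            xf = np.zeros((n, 1))
            zr = np.zeros((n, basis.n_random))
            if mask.any() and not basis.degenerate:
                xf[mask, :] = basis.fixed(vals)
                zr[mask, :] = basis.random(vals)
            if not basis.degenerate:
                fixed_cols.append(xf)
                fixed_labels.append(f"{spec.name}.linear")
                blocks.append(zr)
            infos.append({"spec": spec, "basis": basis, "mask": mask,
                          "values": vals, "degenerate": basis.degenerate})
        return fixed_cols, fixed_labels, blocks, infos

    # --------------------------------------------------------------- fit
    def fit(self, X: pd.DataFrame, y=None):
        """Fit the model.  ``X`` is the model frame; ``y`` the cost response."""
        frame = X.reset_index(drop=True)
        if y is None:
            raise ValueError("y (the cost response) is required")
        yv = np.asarray(y, dtype=float)
        if len(yv) != len(frame):
            raise ValueError("X and y have different lengths")
        # canonicalize the row order so the fit is an exact function of the
        # data as a set: cross-products, and hence the whole REML path, become
        # bit-identical under any input row permutation
        frame = frame.assign(_response=yv)
        frame = frame.sort_values(list(frame.columns), kind="mergesort")
        frame = frame.reset_index(drop=True)
        yv = frame.pop("_response").to_numpy()

        Xp, labels_p = self._build_parametric(frame)
        # drop aliased (zero-variance) columns, e.g. a rare flag absent from
        # this cohort; the intercept is always kept
        keep = [0] + [j for j in range(1, Xp.shape[1]) if Xp[:, j].std() > 0]
        self.dropped_terms_ = [labels_p[j] for j in range(Xp.shape[1]) if j not in keep]
        if self.dropped_terms_:
            import warnings
            warnings.warn("dropping constant design columns: "
                          f"{self.dropped_terms_}", UserWarning)
        Xp = Xp[:, keep]
        labels_p = [labels_p[j] for j in keep]
        self._kept_parametric_ = keep
        self._smooth_info_ = {}
        fixed_cols, fixed_labels, blocks, infos = self._build_smooth_columns(frame, fit=True)
        for info in infos:
            self._smooth_info_[info["spec"].name] = info
        Xfull = np.column_stack([Xp] + fixed_cols) if fixed_cols else Xp
        labels = labels_p + fixed_labels
        self.n_parametric_ = Xp.shape[1]

        groups, self.group_levels_ = pd.factorize(frame[self.group_col], sort=True)

        engine = MixedModelREML(Xfull, yv, groups, blocks)
        fixed_zero = list(range(len(blocks))) if self.smooth_variances == "zero" else None
        res = engine.fit(fixed_zero=fixed_zero, max_iter=self.max_iter, tol=self.tol)
        self.reml_ = res
        self.design_labels_ = labels
        self.coef_ = pd.Series(res.beta, index=labels)
        self.bse_ = pd.Series(res.se_beta, index=labels)
        self.tvalues_ = self.coef_ / self.bse_
        # large-sample Wald normal approximation
        self.pvalues_ = pd.Series(
            2 * stats.norm.sf(np.abs(self.tvalues_)), index=labels)

        self.sigma_resid_ = float(np.sqrt(res.sigma2))
        self.sigma_patient_ = float(np.sqrt(res.gamma[-1] * res.sigma2))
        self.smooth_sd_ = pd.Series(
            np.sqrt(res.gamma[:-1] * res.sigma2),
            index=[info["spec"].name for info in infos if not info["degenerate"]])

        self._attach_smooth_slices(infos, res, len(frame))
        self._fit_statistics(frame, yv, res)
        self.n_obs_ = len(frame)
        self.n_iter_ = res.n_iter
        return self

    def _attach_smooth_slices(self, infos, res, n_rows: int):
        """Per-smooth edf and the penalized-Wald F approximation.

        Design-coefficient layout: [parametric | one linear column per active
        smooth | concatenated wiggly blocks]; ``cov_theta``/``edf_coef`` span
        the first two groups plus the wiggly coefficients.
        """
        p0 = self.n_parametric_
        ncols = p0 + sum(1 for info in infos if not info["degenerate"])
        total_edf = float(res.edf_coef.sum() + res.edf_group)
        resid_df = max(4.0, n_rows - total_edf)
        j, rand_start = 0, 0
        for info in infos:
            if info["degenerate"]:
                info.update(edf=0.0, ref_df=0.0, F=np.nan, p_value=np.nan,
                            fixed_idx=None, rand_slice=slice(0, 0))
                continue
            nr = info["basis"].n_random
            rs = slice(rand_start, rand_start + nr)
            fixed_idx = p0 + j
            idxs = np.r_[fixed_idx, ncols + np.arange(rs.start, rs.stop)]
            coef = np.r_[res.beta[fixed_idx], res.b_smooth[rs]]
            edf = float(res.edf_coef[fixed_idx]
                        + res.edf_coef[ncols + rs.start: ncols + rs.stop].sum())
            cov = res.cov_theta[np.ix_(idxs, idxs)]
            T = float(coef @ np.linalg.pinv(cov, rcond=1e-10) @ coef)
            F = T / max(edf, 1e-8)
            p_val = float(stats.f.sf(F, max(edf, 1e-8), resid_df))
            info.update(edf=edf, ref_df=edf, F=F, p_value=p_val,
                        fixed_idx=fixed_idx, rand_slice=rs)
            j += 1
            rand_start += nr

    def _active_specs(self):
        return [s for s in self.smooths
                if not self._smooth_info_[s.name]["degenerate"]]

    def n_design_cols_(self) -> int:
        return self.n_parametric_ + len(self._active_specs())

    def _fit_statistics(self, frame, yv, res):
        eta = self.predict(frame)
        rss = float(((yv - eta) ** 2).sum())
        tss = float(((yv - yv.mean()) ** 2).sum())
        n = len(yv)
        edf_model = float(res.edf_coef.sum())
        self.edf_model_ = edf_model
        self.edf_total_ = edf_model + res.edf_group
        self.r2_adj_ = 1.0 - (rss / max(n - edf_model, 1)) / (tss / (n - 1))
        self.fitted_population_ = eta

    # ----------------------------------------------------------- predict
    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Population-level prediction (parametric + smooths, no patient
        intercept)."""
        frame = X.reset_index(drop=True)
        Xp, _ = self._build_parametric(frame)
        Xp = Xp[:, self._kept_parametric_]
        eta = Xp @ self.coef_.to_numpy()[: self.n_parametric_]
        res = self.reml_
        for spec in self._active_specs():
            info = self._smooth_info_[spec.name]
            basis: SmoothBasis = info["basis"]
            mask = np.ones(len(frame), dtype=bool) if spec.by_col is None else \
                (frame[spec.by_col] == spec.by_val).to_numpy()
            if not mask.any():
                continue
            vals = frame.loc[mask, spec.col].to_numpy(dtype=float)
            contrib = (basis.fixed(vals)[:, 0] * res.beta[info["fixed_idx"]]
                       + basis.random(vals) @ res.b_smooth[info["rand_slice"]])
            out = np.zeros(len(frame))
            out[mask] = contrib
            eta = eta + out
        return eta

    # ----------------------------------------------------- partial effect
    def partial_effect(self, name: str, grid=None, num: int = 100,
                       level: float = 0.95) -> pd.DataFrame:
        """Centred smooth evaluated on a grid with pointwise Bayesian bands."""
        if name not in self._smooth_info_:
            raise KeyError(f"unknown smooth {name!r}; have "
                           f"{sorted(self._smooth_info_)}")
        info = self._smooth_info_[name]
        if info["degenerate"]:
            raise ValueError(f"smooth {name!r} was degenerate (linear only)")
        basis: SmoothBasis = info["basis"]
        res = self.reml_
        if grid is None:
            v = info["values"]
            grid = np.linspace(v.min(), v.max(), num)
        grid = np.asarray(grid, dtype=float)
        Xg = np.column_stack([basis.fixed(grid), basis.random(grid)])
        coef = np.r_[res.beta[info["fixed_idx"]], res.b_smooth[info["rand_slice"]]]
        rs = info["rand_slice"]
        idxs = np.r_[info["fixed_idx"],
                     self.n_design_cols_() + np.arange(rs.start, rs.stop)]
        cov = res.cov_theta[np.ix_(idxs, idxs)]
        est = Xg @ coef
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xg, cov, Xg), 0.0))
        z = stats.norm.ppf(0.5 + level / 2)
        return pd.DataFrame({"x": grid, "estimate": est, "se": se,
                             "lo": est - z * se, "hi": est + z * se})

    # ------------------------------------------------------------ report
    def summary(self) -> GammSummary:
        par = pd.DataFrame({
            "estimate": self.coef_[: self.n_parametric_],
            "std_error": self.bse_[: self.n_parametric_],
            "t_value": self.tvalues_[: self.n_parametric_],
            "p_value": self.pvalues_[: self.n_parametric_],
        })
        rows = []
        for spec in self.smooths:
            info = self._smooth_info_[spec.name]
            rows.append({"smooth": spec.name, "edf": info["edf"],
                         "ref_df": info["ref_df"], "F": info["F"],
                         "p_value": info["p_value"]})
        sm = pd.DataFrame(rows).set_index("smooth") if rows else \
            pd.DataFrame(columns=["edf", "ref_df", "F", "p_value"])
        return GammSummary(parametric=par, smooths=sm, r2_adj=self.r2_adj_,
                           n_obs=self.n_obs_, sigma_patient=self.sigma_patient_,
                           sigma_resid=self.sigma_resid_)
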