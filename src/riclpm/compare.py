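"""Fit indices and nested model comparison.

The model chi-square is the FIML likelihood-ratio statistic against the
saturated (unstructured mean + covariance) model fitted on the same cases;
the independence baseline (free means and variances, zero covariances) feeds
the incremental indices CFI and TLI. Nested constraint schemes are compared
with central chi-square difference tests on the plain (unscaled) FIML
likelihood ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimation import FitResult, em_saturated, missingness_patterns
from .model import SCHEMES

__all__ = [
    "SaturatedFit",
    "BaselineFit",
    "FitIndices",
    "ComparisonReport",
    "saturated_fit",
    "baseline_fit",
    "fit_indices",
    "compare_nested",
    "selection_report",
]


@dataclass
class SaturatedFit:
    mu: np.ndarray
    Sigma: np.ndarray
    loglik: float
    n_params: int
    n: int


@dataclass
class BaselineFit:
    loglik: float
    df: int
    chi2: float
    n_params: int


@dataclass
class FitIndices:
    """Chi-square-based fit summary of one model."""

    chi2: float
    df: int
    cfi: float
    tli: float
    rmsea: float
    aic: float
    bic: float
    loglik: float
    n: int
    n_params: int
    baseline_chi2: float
    baseline_df: int

    def to_dict(self) -> dict:
        return {k: (None if v is None or (isinstance(v, float) and np.isnan(v)) else v)
                for k, v in self.__dict__.items()}


def saturated_fit(panel, variable_names=None, tol: float = 1e-8) -> SaturatedFit:
    """FIML fit of the unstructured MVN model on the panel's cases."""
    patterns, n_used, _ = missingness_patterns(panel, variable_names)
    p = len(patterns[0].mask)
    mu, Sigma, ll, _ = em_saturated(patterns, p, tol=tol)
    return SaturatedFit(mu=mu, Sigma=Sigma, loglik=ll, n_params=p + p * (p + 1) // 2, n=n_used)


def baseline_fit(panel, saturated: SaturatedFit, variable_names=None) -> BaselineFit:
    """Independence model: free means/variances, zero covariances.

    With a diagonal covariance the FIML likelihood factorizes per variable, so
    the fit is closed form: each variable's observed-case mean and ML variance.
    """
    patterns, _, _ = missingness_patterns(panel, variable_names)
    p = len(patterns[0].mask)
    cnt = np.zeros(p)
    s1 = np.zeros(p)
    s2 = np.zeros(p)
    for pat in patterns:
        idx = pat.indices
        cnt[idx] += pat.count
        s1[idx] += pat.count * pat.mean
        s2[idx] += np.diag(pat.scatter) + pat.count * pat.mean**2
    mean = s1 / np.maximum(cnt, 1)
    var = s2 / np.maximum(cnt, 1) - mean**2
    ll = float(np.sum(-0.5 * cnt * (np.log(2 * np.pi) + np.log(var) + 1.0)))
    chi2 = max(2.0 * (saturated.loglik - ll), 0.0)
    return BaselineFit(loglik=ll, df=p * (p - 1) // 2, chi2=chi2, n_params=2 * p)


def fit_indices(fitres: FitResult, saturated: SaturatedFit, baseline: BaselineFit) -> FitIndices:
    """Chi-square, CFI, TLI, RMSEA, AIC, BIC for a fitted model."""
    q = fitres.n_free
    df = saturated.n_params - q
    chi2 = max(2.0 * (saturated.loglik - fitres.loglik), 0.0)
    n = fitres.n_used
    excess = max(chi2 - df, 0.0)
    base_excess = max(baseline.chi2 - baseline.df, 0.0)
    cfi = 1.0 - excess / max(base_excess, excess, np.finfo(float).tiny)
    if df > 0 and baseline.df > 0 and baseline.chi2 / baseline.df != 1.0:
        tli = ((baseline.chi2 / baseline.df) - (chi2 / df)) / ((baseline.chi2 / baseline.df) - 1.0)
    else:
        tli = np.nan
    if df > 0:
        rmsea = np.sqrt(excess / (df * n))
    else:
        # a model with no testable restrictions: no misfit means RMSEA 0;
        # otherwise the index is undefined and flagged as NaN
        rmsea = 0.0 if excess == 0.0 else np.nan
    aic = -2.0 * fitres.loglik + 2.0 * q
    bic = -2.0 * fitres.loglik + q * np.log(n)
    return FitIndices(
        chi2=chi2,
        df=df,
        cfi=float(cfi),
        tli=float(tli),
        rmsea=float(rmsea),
        aic=float(aic),
        bic=float(bic),
        loglik=fitres.loglik,
        n=n,
        n_params=q,
        baseline_chi2=baseline.chi2,
        baseline_df=baseline.df,
    )


def _nesting_rank(cfg):
    scheme_rank = SCHEMES.index(cfg.scheme)
    means_rank = 0 if cfg.means == "equal_over_waves" else 1
    return scheme_rank, means_rank


def _is_nested(cfg_restricted, cfg_full) -> bool:
    same = (
        cfg_restricted.n_constructs == cfg_full.n_constructs
        and cfg_restricted.n_waves == cfg_full.n_waves
        and cfg_restricted.predictor == cfg_full.predictor
        and cfg_restricted.construct_labels == cfg_full.construct_labels
    )
    if not same:
        return False
    rs, rm = _nesting_rank(cfg_restricted)
    fs, fm = _nesting_rank(cfg_full)
    return rs <= fs and rm <= fm and (rs, rm) != (fs, fm)


def compare_nested(fit_restricted: FitResult, fit_full: FitResult):
    """Chi-square difference test of two nested fits on the same data.

    Returns ``(delta_chi2, delta_df, p)``. The same fit on both sides gives
    (0, 0, 1). Raises on non-nested configurations or mismatched samples.
    """
    if fit_restricted is fit_full or (
        fit_restricted.spec.config == fit_full.spec.config
        and np.array_equal(fit_restricted.theta, fit_full.theta)
    ):
        return 0.0, 0, 1.0
    if not _is_nested(fit_restricted.spec.config, fit_full.spec.config):
        raise ValueError("models are not nested")
    if fit_restricted.n_used != fit_full.n_used:
        raise ValueError("fits use different samples; comparison is invalid")
    delta_df = fit_full.n_free - fit_restricted.n_free
    delta_chi2 = 2.0 * (fit_full.loglik - fit_restricted.loglik)
    if delta_chi2 < -1e-6 * (1.0 + abs(fit_full.loglik)):
        raise ValueError(
            "restricted model has higher likelihood than the full model; "
            "one of the fits is not at its optimum"
        )
    delta_chi2 = max(delta_chi2, 0.0)
    p = float(stats.chi2.sf(delta_chi2, delta_df)) if delta_df > 0 else 1.0
    return float(delta_chi2), int(delta_df), p


@dataclass
class ComparisonReport:
    """Fit indices, nested tests and the selected model for a model grid."""

    names: list
    indices: dict
    tests: list = field(default_factory=list)  # dicts with restricted/full/dchi2/ddf/p
    flags: dict = field(default_factory=dict)
    selected: str = ""

    def to_frame(self) -> pd.DataFrame:
        """Table shaped like a published fit-comparison table."""
        rows = []
        for name in self.names:
            ix = self.indices[name]
            rows.append(
                {
                    "model": name,
                    "CFI": ix.cfi,
                    "TLI": ix.tli,
                    "AIC": ix.aic,
                    "BIC": ix.bic,
                    "LogLik": ix.loglik,
                    "RMSEA": ix.rmsea,
                    "chi2": ix.chi2,
                    "df": ix.df,
                    "n_params": ix.n_params,
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "models": {name: self.indices[name].to_dict() for name in self.names},
            "nested_tests": self.tests,
            "criteria_flags": self.flags,
            "selected": self.selected,
        }


def selection_report(
    models: dict,
    alpha: float = 0.05,
    cfi_tli_cut: float = 0.95,
    rmsea_cut: float = 0.08,
) -> ComparisonReport:
    """Compare a grid of fitted models sharing the same data.

    ``models`` maps name -> (FitResult, FitIndices). Every nested pair is
    tested; a restricted model rejected against any fuller model at ``alpha``
    is dropped from candidacy. Among the remaining candidates the model with
    the lowest BIC wins (then AIC, then fewer parameters). Each model is also
    flagged against the conventional CFI/TLI >= 0.95 and RMSEA <= 0.08 cuts.
    """
    names = list(models)
    indices = {name: ix for name, (_, ix) in models.items()}
    report = ComparisonReport(names=names, indices=indices)
    for name in names:
        ix = indices[name]
        report.flags[name] = {
            "cfi_ok": bool(ix.cfi >= cfi_tli_cut),
            "tli_ok": bool(np.isnan(ix.tli) or ix.tli >= cfi_tli_cut),
            "rmsea_ok": bool(np.isnan(ix.rmsea) or ix.rmsea <= rmsea_cut),
        }
    rejected = set()
    for i, rname in enumerate(names):
        for fname in names:
            if rname == fname:
                continue
            rfit, ffit = models[rname][0], models[fname][0]
            if not _is_nested(rfit.spec.config, ffit.spec.config):
                continue
            dchi2, ddf, p = compare_nested(rfit, ffit)
            report.tests.append(
                {"restricted": rname, "full": fname, "delta_chi2": dchi2, "delta_df": ddf, "p": p}
            )
            if p < alpha:
                rejected.add(rname)
    candidates = [n for n in names if n not in rejected] or names
    report.selected = min(
        candidates,
        key=lambda n: (indices[n].bic, indices[n].aic, indices[n].n_params, names.index(n)),
    )
    return report
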