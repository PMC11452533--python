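"""Questionnaire scoring and descriptive statistics.

Converts item-level responses of the four instruments — the Relationship
Satisfaction Scale (10 items at waves 1-3, 5 items at wave 4, 6-point), the
Differential Emotions Scale enjoyment subscale (3 items, 5-point), and the
SCL-8 depressive and anxiety subscales (4 items each, 4-point) — into
per-wave mean composites, and provides Cronbach's alpha, (partial)
correlations and the log transform applied before modelling.

Item columns follow the dialect ``<construct>_<item#>_t<wave>`` (e.g.
``relsat_03_t1``); composites are named ``<construct>_t<wave>``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ScaleDef",
    "SCALES",
    "CONSTRUCTS",
    "composite_score",
    "score_items",
    "cronbach_alpha",
    "log_transform",
    "correlation_matrix",
    "partial_correlation",
    "composite_columns",
    "item_columns",
    "descriptives",
]


@dataclass(frozen=True)
class ScaleDef:
    """Definition of one instrument: items per wave and response range."""

    name: str
    items_per_wave: dict[int, int]
    response_min: int
    response_max: int

    def n_items(self, wave: int) -> int:
        try:
            return self.items_per_wave[wave]
        except KeyError:
            raise KeyError(f"scale {self.name!r} not administered at wave {wave}") from None


#: Canonical construct order used everywhere downstream (construct-major,
#: wave-minor column ordering in the panel).
CONSTRUCTS = ("relsat", "posaff", "dep", "anx")

SCALES: dict[str, ScaleDef] = {
    "relsat": ScaleDef("relsat", {1: 10, 2: 10, 3: 10, 4: 5}, 1, 6),
    "posaff": ScaleDef("posaff", {1: 3, 2: 3, 3: 3, 4: 3}, 1, 5),
    "dep": ScaleDef("dep", {1: 4, 2: 4, 3: 4, 4: 4}, 1, 4),
    "anx": ScaleDef("anx", {1: 4, 2: 4, 3: 4, 4: 4}, 1, 4),
}


def composite_columns(constructs=CONSTRUCTS, waves=(1, 2, 3, 4)) -> list[str]:
    """Composite column names in construct-major, wave-minor order."""
    return [f"{c}_t{t}" for c in constructs for t in waves]


def item_columns(construct: str, wave: int) -> list[str]:
    scale = SCALES[construct]
    return [f"{construct}_{i:02d}_t{wave}" for i in range(1, scale.n_items(wave) + 1)]


def composite_score(items, min_fraction: float = 0.5) -> float:
    """Mean composite of one subject's items for one construct x wave.

    The composite is the mean of the non-missing items, defined only when the
    fraction of answered items is at least ``min_fraction`` (default: half the
    items); otherwise NaN.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    arr = np.asarray(items, dtype=float)
    if arr.size == 0:
        raise ValueError("no items defined for construct")
    observed = ~np.isnan(arr)
    if observed.sum() / arr.size < min_fraction or observed.sum() == 0:
        return float("nan")
    return float(arr[observed].mean())


def score_items(
    items: pd.DataFrame,
    min_fraction: float = 0.5,
    constructs=CONSTRUCTS,
    waves=(1, 2, 3, 4),
    validate: bool = True,
) -> pd.DataFrame:
    """Score an item-level table into the wide composite panel.

    Parameters
    ----------
    items
        One row per subject; item columns per the ``<construct>_<item#>_t<wave>``
        dialect. Extra columns (``pgi``, flags) are carried through untouched.
    min_fraction
        Minimum answered-item fraction for a composite to be defined.
    validate
        Check item values against the declared response range.
    """
    out = {}
    for c in constructs:
        scale = SCALES[c]
        for t in waves:
            cols = item_columns(c, t)
            missing_cols = [col for col in cols if col not in items.columns]
            if missing_cols:
                raise ValueError(f"missing item columns for {c} wave {t}: {missing_cols}")
            block = items[cols].to_numpy(dtype=float)
            if validate:
                bad = (block < scale.response_min) | (block > scale.response_max)
                if np.any(bad & ~np.isnan(block)):
                    raise ValueError(
                        f"item responses outside [{scale.response_min}, "
                        f"{scale.response_max}] for {c} wave {t}"
                    )
            n_items = block.shape[1]
            n_obs = np.sum(~np.isnan(block), axis=1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
                means = np.nanmean(block, axis=1)
            means[n_obs / n_items < min_fraction] = np.nan
            out[f"{c}_t{t}"] = means
    panel = pd.DataFrame(out, index=items.index)
    for extra in ("pgi", "stillbirth", "any_participation", "subject_id"):
        if extra in items.columns:
            panel[extra] = items[extra]
    return panel


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha of a subjects x items matrix (listwise complete rows).

    alpha = p/(p-1) * (1 - sum_i s2_i / s2_total).
    """
    X = np.asarray(item_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 items")
    X = X[~np.isnan(X).any(axis=1)]
    if X.shape[0] < 2:
        raise ValueError("need at least 2 complete rows")
    p = X.shape[1]
    item_vars = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("degenerate scale: zero total variance")
    return float(p / (p - 1) * (1.0 - item_vars.sum() / total_var))


def log_transform(x):
    """Natural log of composite scores; NaN passes through.

    All scales start at 1, so valid composites are >= 1 and the transform is
    nonnegative. Scalar in, scalar out; array-likes return arrays.
    """
    arr = np.asarray(x, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any(arr[~np.isnan(arr)] < 1):
            raise ValueError("score below scale minimum (composites must be >= 1)")
    result = np.log(arr, out=np.full_like(arr, np.nan), where=~np.isnan(arr))
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(result)
    return result


def correlation_matrix(
    panel: pd.DataFrame,
    method: str = "pairwise",
    min_overlap: int = 3,
    columns: list[str] | None = None,
) -> pd.DataFrame:
    """Correlation matrix of the panel's numeric columns.

    ``pairwise`` (default) uses all overlapping observations per pair, matching
    how descriptive correlations are reported under heavy wave-wise attrition;
    ``listwise`` restricts to complete cases. Pairs with fewer than
    ``min_overlap`` overlapping observations are set to NaN with a warning.
    """
    if method not in ("pairwise", "listwise"):
        raise ValueError("method must be 'pairwise' or 'listwise'")
    cols = columns if columns is not None else [c for c in panel.columns if pd.api.types.is_numeric_dtype(panel[c])]
    data = panel[cols]
    if method == "listwise":
        data = data.dropna()
    corr = data.corr(method="pearson", min_periods=min_overlap)
    counts = data.notna().astype(int).T @ data.notna().astype(int)
    thin = (counts < min_overlap) & ~np.eye(len(cols), dtype=bool)
    if thin.to_numpy().any():
        warnings.warn(
            f"{int(thin.to_numpy().sum() // 2)} variable pair(s) have fewer than "
            f"{min_overlap} overlapping observations; entries set to NaN",
            stacklevel=2,
        )
        corr = corr.mask(thin)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def partial_correlation(x, y, covariates=None) -> float:
    """Correlation of x and y after residualizing both on the covariates.

    With an empty covariate set this is the plain Pearson correlation. Uses
    complete cases across x, y and all covariates; raises on a rank-deficient
    covariate matrix.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        Z = np.empty((x.size, 0))
    else:
        Z = np.asarray(covariates, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
    keep = ~np.isnan(x) & ~np.isnan(y) & ~np.isnan(Z).any(axis=1)
    x, y, Z = x[keep], y[keep], Z[keep]
    if x.size < Z.shape[1] + 3:
        raise ValueError("too few complete cases for partial correlation")
    design = np.column_stack([np.ones(x.size), Z])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("singular covariate matrix")
    coef_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    coef_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ coef_x
    ry = y - design @ coef_y
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    if denom == 0:
        raise ValueError("zero residual variance")
    return float(np.clip((rx @ ry) / denom, -1.0, 1.0))


def descriptives(panel: pd.DataFrame, constructs=CONSTRUCTS, waves=(1, 2, 3, 4)) -> dict:
    """Per-construct, per-wave means/SDs/counts plus the correlation matrix."""
    table = {}
    for c in constructs:
        table[c] = {}
        for t in waves:
            col = panel[f"{c}_t{t}"]
            table[c][f"t{t}"] = {
                "mean": float(col.mean()),
                "sd": float(col.std(ddof=1)),
                "n": int(col.notna().sum()),
            }
    cols = composite_columns(constructs, waves)
    corr = correlation_matrix(panel, columns=cols + (["pgi"] if "pgi" in panel.columns else []))
    return {
        "means": table,
        "correlations": {
            "columns": list(corr.columns),
            "matrix": [[None if pd.isna(v) else round(float(v), 6) for v in row] for row in corr.to_numpy()],
        },
    }
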