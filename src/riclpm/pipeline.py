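"""End-to-end analysis orchestration.

Scores raw items into composites, applies the log transform, fits the model
grid (constraint schemes x mean structures x predictor targets), compares the
nested fits, and writes machine-readable reports plus a manifest that
suffices to reproduce every artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .compare import baseline_fit, fit_indices, saturated_fit, selection_report
from .estimation import FitOptions, FitResult, fit, icc, predictor_effects, ri_variance_explained
from .model import ModelConfig, build_model
from .scales import CONSTRUCTS, composite_columns, descriptives, log_transform, score_items

__all__ = ["RunConfig", "run_pipeline", "report_paths", "residual_correlation_report", "ri_report"]

log = logging.getLogger("riclpm")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    input_path: str
    output_dir: str
    input_kind: str = "items"  # items | composites
    constructs: tuple = CONSTRUCTS
    waves: tuple = (1, 2, 3, 4)
    log_transform_constructs: tuple | None = None  # None -> all constructs
    min_item_fraction: float = 0.5
    schemes: tuple = ("constrained", "first_free", "free")
    mean_structures: tuple = ("free",)
    predictor: str = "on_random_intercepts"
    significance: float = 0.01
    tolerance: float = 1e-6
    max_iter: int = 1000
    seed: int = 0
    na_token: str = ""

    def __post_init__(self):
        if not 0 < self.significance < 1:
            raise ValueError("significance threshold must be in (0, 1)")
        for s in self.schemes:
            if s not in ("constrained", "first_free", "free"):
                raise ValueError(f"unknown scheme {s!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("constructs", "waves", "schemes", "mean_structures"):
            d[key] = list(d[key])
        if d["log_transform_constructs"] is not None:
            d["log_transform_constructs"] = list(d["log_transform_constructs"])
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def prepare_panel(config: RunConfig, table: pd.DataFrame) -> pd.DataFrame:
    """Score (if item-level) and transform the input into the model panel."""
    if config.input_kind == "items":
        panel = score_items(
            table, min_fraction=config.min_item_fraction, constructs=config.constructs,
            waves=config.waves,
        )
    elif config.input_kind == "composites":
        panel = table.copy()
    else:
        raise ValueError("input_kind must be 'items' or 'composites'")
    targets = (
        config.constructs
        if config.log_transform_constructs is None
        else config.log_transform_constructs
    )
    for c in targets:
        for t in config.waves:
            panel[f"{c}_t{t}"] = log_transform(panel[f"{c}_t{t}"].to_numpy())
    return panel


def report_paths(fitres: FitResult, threshold: float = 0.01) -> pd.DataFrame:
    """Edge list of standardized within-person paths with significance flags.

    One row per transition entry (autoregressive or cross-lagged), carrying the
    standardized coefficient, the raw estimate and SE, the Wald p-value of the
    raw path, and a significance flag at ``threshold``. The flag is a display
    annotation; nothing is filtered.
    """
    spec = fitres.spec
    cfg = spec.config
    K, T = cfg.n_constructs, cfg.n_waves
    std = fitres.standardized["transitions_std"]
    rows = []
    for t in range(1, T):
        for i in range(K):
            for j in range(K):
                pj = spec.B_idx[t - 1, i, j]
                se = fitres.se[pj] if fitres.se is not None else np.nan
                est = fitres.theta[pj]
                from scipy.stats import norm

                p = 2 * norm.sf(abs(est / se)) if np.isfinite(se) and se > 0 else np.nan
                rows.append(
                    {
                        "from_construct": cfg.construct_labels[j],
                        "from_wave": t,
                        "to_construct": cfg.construct_labels[i],
                        "to_wave": t + 1,
                        "kind": "autoregressive" if i == j else "cross_lagged",
                        "beta_std": float(std[t - 1, i, j]),
                        "estimate": float(est),
                        "se": float(se),
                        "p": float(p) if np.isfinite(p) else np.nan,
                        "significant": bool(p < threshold) if np.isfinite(p) else False,
                        "parameter": spec.params["label"][pj],
                    }
                )
    return pd.DataFrame(rows)


def residual_correlation_report(fitres: FitResult) -> pd.DataFrame:
    """Within-wave residual (co-development) correlations, waves 2..T."""
    cfg = fitres.spec.config
    K, T = cfg.n_constructs, cfg.n_waves
    corr = fitres.standardized["residual_corr"]
    rows = []
    for t in range(1, T):
        for i in range(K):
            for j in range(i + 1, K):
                rows.append(
                    {
                        "wave": t + 1,
                        "construct_a": cfg.construct_labels[i],
                        "construct_b": cfg.construct_labels[j],
                        "correlation": float(corr[t - 1, i, j]),
                    }
                )
    return pd.DataFrame(rows)


def ri_report(fitres: FitResult) -> dict:
    """Between-person summary: ICCs, RI loadings/correlations, predictor betas."""
    cfg = fitres.spec.config
    std = fitres.standardized
    out = {
        "constructs": list(cfg.construct_labels),
        "icc": icc(fitres).tolist(),
        "ri_variance_explained": ri_variance_explained(fitres).tolist(),
        "ri_loading_std": std["ri_loading_std"].tolist(),
        "ri_correlations": std["ri_corr"].tolist(),
    }
    if cfg.predictor == "on_random_intercepts":
        eff = predictor_effects(fitres)
        out["predictor_beta_std"] = eff["beta_std"].tolist()
        out["predictor_variance_share"] = eff["variance_share"].tolist()
    return out


def paths_to_dot(paths: pd.DataFrame, threshold: float = 1.0) -> str:
    """DOT export of the within-person path diagram (edges below threshold kept)."""
    lines = ["digraph riclpm {", "  rankdir=LR;"]
    for _, r in paths.iterrows():
        if np.isfinite(r["p"]) and r["p"] >= threshold:
            continue
        style = "solid" if r["kind"] == "autoregressive" else "dashed"
        lines.append(
            f'  "{r.from_construct}_t{r.from_wave}" -> "{r.to_construct}_t{r.to_wave}"'
            f' [label="{r.beta_std:.2f}", style={style}];'
        )
    lines.append("}")
    return "\n".join(lines)


def _write_json(path: Path, obj):
    path.write_text(json.dumps(obj, indent=2, allow_nan=False, default=_jsonable) + "\n")


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")


def run_pipeline(config: RunConfig, table: pd.DataFrame | None = None) -> Path:
    """Run the full analysis and write artifacts to the output directory.

    ``table`` may be passed directly (e.g. a simulated cohort's item table);
    otherwise ``config.input_path`` is read as CSV. Returns the run directory.
    Stage failures abort with the stage name; artifacts produced so far are
    kept.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = []
    t_start = time.time()

    def stage(name):
        log.info("stage %s", name)
        stages.append({"stage": name, "t": round(time.time() - t_start, 3)})

    try:
        stage("load")
        if table is None:
            table = pd.read_csv(
                config.input_path, na_values=[config.na_token, "NA"], keep_default_na=True
            )

        stage("score")
        panel = prepare_panel(config, table)
        cols = composite_columns(config.constructs, config.waves)
        model_cols = cols + (["pgi"] if config.predictor != "none" else [])

        stage("descriptives")
        _write_json(out / "descriptives.json", descriptives(panel, config.constructs, config.waves))
        panel[[c for c in panel.columns if c in set(model_cols) | {"subject_id"}]].to_csv(
            out / "composites.csv", index=False
        )

        stage("saturated")
        sat = saturated_fit(panel, model_cols)
        base = baseline_fit(panel, sat, model_cols)

        fits = {}
        options = FitOptions(
            tolerance=config.tolerance, max_iter=config.max_iter, seed=config.seed
        )
        for means in config.mean_structures:
            for scheme in config.schemes:
                name = f"{scheme}" + ("" if means == "free" else f"_{means}")
                stage(f"fit:{name}")
                spec = build_model(
                    ModelConfig(
                        n_constructs=len(config.constructs),
                        n_waves=len(config.waves),
                        scheme=scheme,
                        means=means,
                        predictor=config.predictor,
                        construct_labels=tuple(config.constructs),
                    )
                )
                res = fit(spec, panel[model_cols], options=options)
                ix = fit_indices(res, sat, base)
                fits[name] = (res, ix)
                _write_json(out / f"fit_{name}.json", res.to_dict(config.significance))
                log.info(
                    "fitted %s: ll=%.3f q=%d iters=%d n=%d",
                    name, res.loglik, res.n_free, res.n_iter, res.n_used,
                )

        stage("compare")
        report = selection_report(fits)
        _write_json(out / "comparison.json", report.to_dict())
        report.to_frame().to_csv(out / "comparison.csv", index=False)

        stage("report")
        best = fits[report.selected][0] if len(fits) > 1 else next(iter(fits.values()))[0]
        paths = report_paths(best, config.significance)
        paths.to_csv(out / "paths.csv", index=False)
        (out / "paths.dot").write_text(paths_to_dot(paths, config.significance) + "\n")
        residual_correlation_report(best).to_csv(out / "residual_correlations.csv", index=False)
        _write_json(out / "ri_report.json", ri_report(best))

        stage("manifest")
        _write_json(
            out / "manifest.json",
            {
                "config": config.to_dict(),
                "config_digest": config.digest(),
                "selected_model": report.selected,
                "package_version": __version__,
                "numpy_version": np.__version__,
                "pandas_version": pd.__version__,
                "stages": stages,
            },
        )
    except Exception as exc:
        failed_at = stages[-1]["stage"] if stages else "init"
        raise RuntimeError(f"pipeline failed at stage {failed_at!r}: {exc}") from exc
    return out
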