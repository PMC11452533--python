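"""RI-CLPM specification: parameter tables, constraint schemes, implied moments.

The structural model for K constructs observed at T waves is

    x_{k,t} = mu_{k,t} + RI_k + w_{k,t}
    RI_k    = b_k (g - mu_g) + u_k,     u ~ MVN(0, Psi)
    w_{.,1} ~ MVN(0, Sigma_w1)
    w_{.,t} = B_t w_{.,t-1} + eps_t,    eps_t ~ MVN(0, Theta_t)

with g an observed exogenous covariate (the polygenic index) with free mean
and variance, entering the joint likelihood so subjects missing g are kept
under FIML. Centering g in the RI regression leaves the grand means mu_{k,t}
interpretable; the fit is identical to the uncentered parameterization.

Three nested constraint schemes tie the transition matrices B_t (the
autoregressive and cross-lagged paths) over time:

* ``constrained``  — one shared B for all transitions (model 1)
* ``first_free``   — B_2 free, B_3..B_T shared (model 2)
* ``free``         — every B_t free (model 3)

Within-wave residual covariances Theta_t stay free per wave in every scheme;
only the regression paths are constrained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ModelConfig",
    "ModelSpec",
    "build_model",
    "count_free_parameters",
    "implied_moments",
    "standardize",
    "SCHEMES",
]

SCHEMES = ("constrained", "first_free", "free")
MEANS = ("free", "equal_over_waves")
PREDICTORS = ("none", "on_random_intercepts", "on_observed")


@dataclass(frozen=True)
class ModelConfig:
    """Configuration of an RI-CLPM: dimensions, constraint scheme, predictor."""

    n_constructs: int = 4
    n_waves: int = 4
    scheme: str = "free"
    means: str = "free"
    predictor: str = "none"
    construct_labels: tuple = ()

    def __post_init__(self):
        if self.n_constructs < 1:
            raise ValueError("need at least one construct")
        if self.n_waves < 2:
            raise ValueError("need at least two waves")
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")
        if self.means not in MEANS:
            raise ValueError(f"means must be one of {MEANS}")
        if self.predictor not in PREDICTORS:
            raise ValueError(f"predictor must be one of {PREDICTORS}")
        if self.scheme == "first_free" and self.n_waves < 3:
            raise ValueError("first_free scheme requires at least 3 waves")
        if not self.construct_labels:
            object.__setattr__(
                self, "construct_labels", tuple(f"c{k+1}" for k in range(self.n_constructs))
            )
        if len(self.construct_labels) != self.n_constructs:
            raise ValueError("construct_labels length must equal n_constructs")


@dataclass
class ModelSpec:
    """A built model: config, free-parameter table, and theta -> slot maps.

    Index-map arrays hold, for every matrix slot entry, the index of the free
    parameter in theta that fills it; equality constraints are encoded by the
    same index appearing in several positions.
    """

    config: ModelConfig
    params: pd.DataFrame  # one row per free parameter: label, slot, start, lower
    mean_idx: np.ndarray  # (K, T)
    psi_idx: np.ndarray  # (K, K)
    sw1_idx: np.ndarray  # (K, K)
    B_idx: np.ndarray  # (T-1, K, K)
    theta_idx: np.ndarray  # (T-1, K, K)
    mug_idx: int = -1
    varg_idx: int = -1
    b_idx: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def n_free(self) -> int:
        return len(self.params)

    @property
    def n_observed(self) -> int:
        p = self.config.n_constructs * self.config.n_waves
        return p + (1 if self.config.predictor != "none" else 0)

    @property
    def variable_names(self) -> list:
        cfg = self.config
        names = [f"{c}_t{t}" for c in cfg.construct_labels for t in range(1, cfg.n_waves + 1)]
        if cfg.predictor != "none":
            names.append("pgi")
        return names

    def start_vector(self) -> np.ndarray:
        return self.params["start"].to_numpy(dtype=float).copy()

    def lower_bounds(self) -> np.ndarray:
        return self.params["lower"].to_numpy(dtype=float).copy()

    # --- serialization -------------------------------------------------

    def to_json(self, theta=None, se=None) -> str:
        doc = {
            "config": {
                "n_constructs": self.config.n_constructs,
                "n_waves": self.config.n_waves,
                "scheme": self.config.scheme,
                "means": self.config.means,
                "predictor": self.config.predictor,
                "construct_labels": list(self.config.construct_labels),
            },
            "parameters": [
                {
                    "label": row.label,
                    "slot": row.slot,
                    "start": float(row.start),
                    "lower": None if not np.isfinite(row.lower) else float(row.lower),
                    **({"estimate": float(theta[i])} if theta is not None else {}),
                    **({"se": float(se[i])} if se is not None else {}),
                }
                for i, row in enumerate(self.params.itertuples())
            ],
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        doc = json.loads(text)
        cfg = doc["config"]
        spec = build_model(
            ModelConfig(
                n_constructs=cfg["n_constructs"],
                n_waves=cfg["n_waves"],
                scheme=cfg["scheme"],
                means=cfg["means"],
                predictor=cfg["predictor"],
                construct_labels=tuple(cfg["construct_labels"]),
            )
        )
        labels = [p["label"] for p in doc["parameters"]]
        if labels != list(spec.params["label"]):
            raise ValueError("parameter table does not match rebuilt specification")
        spec.params["start"] = [p["start"] for p in doc["parameters"]]
        return spec


def build_model(config: ModelConfig) -> ModelSpec:
    """Enumerate the free parameters of the scheme and build index maps."""
    K, T = config.n_constructs, config.n_waves
    labels = config.construct_labels
    rows = []  # (label, slot, start, lower)

    def add(label, slot, start, lower=-np.inf) -> int:
        rows.append({"label": label, "slot": slot, "start": start, "lower": lower})
        return len(rows) - 1

    mean_idx = np.empty((K, T), dtype=int)
    if config.means == "equal_over_waves":
        for k in range(K):
            j = add(f"mu_{labels[k]}", "mean", 0.0)
            mean_idx[k, :] = j
    else:
        for k in range(K):
            for t in range(T):
                mean_idx[k, t] = add(f"mu_{labels[k]}_t{t+1}", "mean", 0.0)

    mug_idx = varg_idx = -1
    b_idx = np.empty(0, dtype=int)
    if config.predictor != "none":
        mug_idx = add("mu_g", "predictor_mean", 0.0)
        varg_idx = add("var_g", "predictor_var", 1.0, lower=1e-10)
        if config.predictor == "on_random_intercepts":
            b_idx = np.array([add(f"b_{labels[k]}", "b", 0.1) for k in range(K)])
        else:  # on_observed
            b_idx = np.array(
                [[add(f"b_{labels[k]}_t{t+1}", "b", 0.1) for t in range(T)] for k in range(K)]
            )

    def sym_block(prefix, slot, diag_start, offdiag_start):
        idx = np.empty((K, K), dtype=int)
        for k in range(K):
            for l in range(k, K):
                if k == l:
                    j = add(f"{prefix}_{labels[k]}", slot, diag_start, lower=1e-10)
                else:
                    j = add(f"{prefix}_{labels[k]}.{labels[l]}", slot, offdiag_start)
                idx[k, l] = idx[l, k] = j
        return idx

    psi_idx = sym_block("psi", "ri_cov", 0.5, 0.0)
    sw1_idx = sym_block("sw1", "wave1_cov", 0.5, 0.0)

    B_idx = np.empty((T - 1, K, K), dtype=int)
    if config.scheme == "constrained":
        for i in range(K):
            for j_ in range(K):
                j = add(f"beta_{labels[i]}~{labels[j_]}", "transition", 0.1 if i == j_ else 0.0)
                B_idx[:, i, j_] = j
    elif config.scheme == "first_free":
        for i in range(K):
            for j_ in range(K):
                B_idx[0, i, j_] = add(
                    f"beta_t2_{labels[i]}~{labels[j_]}", "transition", 0.1 if i == j_ else 0.0
                )
        for i in range(K):
            for j_ in range(K):
                j = add(
                    f"beta_post_{labels[i]}~{labels[j_]}", "transition", 0.1 if i == j_ else 0.0
                )
                B_idx[1:, i, j_] = j
    else:  # free
        for t in range(1, T):
            for i in range(K):
                for j_ in range(K):
                    B_idx[t - 1, i, j_] = add(
                        f"beta_t{t+1}_{labels[i]}~{labels[j_]}",
                        "transition",
                        0.1 if i == j_ else 0.0,
                    )

    theta_idx = np.empty((T - 1, K, K), dtype=int)
    for t in range(1, T):
        for k in range(K):
            for l in range(k, K):
                if k == l:
                    j = add(f"theta_t{t+1}_{labels[k]}", "residual_cov", 0.5, lower=1e-10)
                else:
                    j = add(f"theta_t{t+1}_{labels[k]}.{labels[l]}", "residual_cov", 0.0)
                theta_idx[t - 1, k, l] = theta_idx[t - 1, l, k] = j

    params = pd.DataFrame(rows, columns=["label", "slot", "start", "lower"])
    return ModelSpec(
        config=config,
        params=params,
        mean_idx=mean_idx,
        psi_idx=psi_idx,
        sw1_idx=sw1_idx,
        B_idx=B_idx,
        theta_idx=theta_idx,
        mug_idx=mug_idx,
        varg_idx=varg_idx,
        b_idx=b_idx,
    )


def count_free_parameters(spec: ModelSpec) -> int:
    """Number of distinct free parameters after equality reduction."""
    return spec.n_free


def _structured(spec: ModelSpec, theta: np.ndarray):
    """Unpack theta into the structural matrices."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (spec.n_free,):
        raise ValueError(f"theta must have length {spec.n_free}, got {theta.shape}")
    M = theta[spec.mean_idx]
    Psi = theta[spec.psi_idx]
    Sw1 = theta[spec.sw1_idx]
    B = theta[spec.B_idx]
    Th = theta[spec.theta_idx]
    if spec.config.predictor != "none":
        mu_g = theta[spec.mug_idx]
        var_g = theta[spec.varg_idx]
        b = theta[spec.b_idx]
    else:
        mu_g = var_g = 0.0
        b = None
    return M, Psi, Sw1, B, Th, mu_g, var_g, b


def _within_blocks(Sw1, B, Th, T):
    """Covariance blocks Phi[t][s] = Cov(w_t, w_s) for t >= s (0-based waves)."""
    Phi = [[None] * T for _ in range(T)]
    Phi[0][0] = Sw1
    for t in range(1, T):
        Bt = B[t - 1]
        for s in range(t):
            Phi[t][s] = Bt @ Phi[t - 1][s] if t - 1 >= s else None
        Phi[t][t] = Bt @ Phi[t - 1][t - 1] @ Bt.T + Th[t - 1]
    return Phi


def implied_moments(spec: ModelSpec, theta, validate: bool = False):
    """Model-implied mean vector and covariance of the observed variables.

    Variables are ordered construct-major, wave-minor, with the predictor (if
    any) last. With ``validate=True``, within-wave residual blocks are checked
    for positive semidefiniteness and the offending wave reported.
    """
    cfg = spec.config
    K, T = cfg.n_constructs, cfg.n_waves
    M, Psi, Sw1, B, Th, mu_g, var_g, b = _structured(spec, theta)

    if validate:
        for t in range(T - 1):
            if np.linalg.eigvalsh(Th[t])[0] < -1e-10:
                raise ValueError(f"non-PSD within-wave residual block at wave {t + 2}")
        if np.linalg.eigvalsh(Sw1)[0] < -1e-10:
            raise ValueError("non-PSD wave-1 within covariance")
        if np.linalg.eigvalsh(Psi)[0] < -1e-10:
            raise ValueError("non-PSD random-intercept covariance")

    p_x = K * T
    p = spec.n_observed
    mu = np.empty(p)
    mu[:p_x] = M.reshape(-1)  # index k*T + t
    Sigma = np.empty((p, p))

    if cfg.predictor == "on_random_intercepts":
        Omega = Psi + var_g * np.outer(b, b)
    else:
        Omega = Psi

    Phi = _within_blocks(Sw1, B, Th, T)
    rows = np.arange(K)[:, None] * T  # construct offsets
    for t in range(T):
        for s in range(t + 1):
            block = Omega + Phi[t][s]
            idx_t = (rows + t).ravel()
            idx_s = (rows + s).ravel()
            Sigma[np.ix_(idx_t, idx_s)] = block
            if s != t:
                Sigma[np.ix_(idx_s, idx_t)] = block.T

    if cfg.predictor != "none":
        mu[p_x] = mu_g
        Sigma[p_x, p_x] = var_g
        if cfg.predictor == "on_random_intercepts":
            cov_gx = np.repeat(var_g * b, T)  # same for every wave
        else:  # on_observed: b is (K, T)
            cov_gx = var_g * b.reshape(-1)
            Sigma[:p_x, :p_x] += var_g * np.outer(b.reshape(-1), b.reshape(-1))
            mu[:p_x] = M.reshape(-1)
        Sigma[p_x, :p_x] = cov_gx
        Sigma[:p_x, p_x] = cov_gx

    return mu, Sigma


def standardize(spec: ModelSpec, theta, Sigma=None) -> dict:
    """Standardized solution at theta.

    Returns transition paths scaled by within-process SD ratios, residual and
    random-intercept correlation matrices, per-wave standardized RI loadings
    (RI SD over implied indicator SD, squared = share of variance the stable
    component explains), and, with a predictor, standardized betas of g on the
    random intercepts.
    """
    cfg = spec.config
    K, T = cfg.n_constructs, cfg.n_waves
    M, Psi, Sw1, B, Th, mu_g, var_g, b = _structured(spec, theta)
    if Sigma is None:
        _, Sigma = implied_moments(spec, theta)

    if cfg.predictor == "on_random_intercepts":
        Omega = Psi + var_g * np.outer(b, b)
    else:
        Omega = Psi

    Phi = _within_blocks(Sw1, B, Th, T)
    w_sd = np.empty((T, K))
    for t in range(T):
        d = np.diag(Phi[t][t])
        if np.any(d <= 0):
            raise ValueError(f"zero implied within-process variance at wave {t + 1}")
        w_sd[t] = np.sqrt(d)

    x_sd = np.sqrt(np.diag(Sigma))[: K * T].reshape(K, T)
    if np.any(x_sd == 0):
        raise ValueError("zero implied indicator variance")

    def to_corr(C):
        d = np.sqrt(np.diag(C))
        if np.any(d <= 0):
            return np.full_like(C, np.nan)
        return C / np.outer(d, d)

    out = {
        "transitions_std": np.stack(
            [B[t - 1] * (w_sd[t - 1][None, :] / w_sd[t][:, None]) for t in range(1, T)]
        ),
        "residual_corr": np.stack([to_corr(Th[t - 1]) for t in range(1, T)]),
        "ri_corr": to_corr(Omega),
        "ri_residual_corr": to_corr(Psi),
        "ri_loading_std": np.sqrt(np.diag(Omega))[:, None] / x_sd,  # (K, T)
        "wave1_corr": to_corr(Sw1),
    }
    if cfg.predictor == "on_random_intercepts":
        out["b_std"] = b * np.sqrt(var_g) / np.sqrt(np.diag(Omega))
    elif cfg.predictor == "on_observed":
        out["b_std"] = b * np.sqrt(var_g) / x_sd
    return out
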