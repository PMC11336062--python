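"""L1-penalised maximum-entropy presence-background model.

The model fits a Gibbs density over the background sample,
``raw(x) = exp(eta(x) - logZ)`` with ``eta(x) = sum_j w_j f_j(x)``, by
minimising the convex penalised objective

    L(w) = -(1/m) * sum_presence eta(x_i)
           + log sum_background exp(eta(x_b)) - log(n_background)
           + sum_j lambda_j * |w_j|

The non-smooth L1 term is handled exactly by splitting each weight into
its positive and negative parts (w = u+ - u-, u >= 0), which turns the
problem into a smooth bound-constrained one solved deterministically with
L-BFGS-B.  Suitability is reported either on the raw scale or as the
bounded cloglog transform ``1 - exp(-e^H * raw)`` where H is the entropy
of the fitted density over the training background.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .features import FeatureDef, FeatureExpansion, default_lambdas, expand_features

__all__ = [
    "ModelSettings",
    "MaxentModel",
    "fit_maxent",
    "maxent_objective",
    "predict",
    "predict_stack",
    "variable_contribution",
]

ACTIVE_TOL = 1e-8  # |w| above this counts as an active feature


@dataclass(frozen=True)
class ModelSettings:
    """Tuning-grid cell plus optimiser controls.

    rm is the regularization multiplier scaling every per-feature L1
    penalty; fc the feature class (L, LQ, H or LQH).
    """

    rm: float = 1.0
    fc: str = "LQH"
    n_hinge_knots: int = 32
    convergence_tol: float = 1e-7
    max_iter: int = 2000
    seed: int = 0
    beta_anchors: tuple = ((10, 1.0), (30, 0.2), (100, 0.05))
    beta_hinge: float = 0.5
    beta_indicator: float = 0.25
    lambda_sd_floor: float = 0.01

    def __post_init__(self) -> None:
        if self.rm <= 0:
            raise ValueError("rm must be positive")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be positive")
        if isinstance(self.beta_anchors, list):
            object.__setattr__(
                self, "beta_anchors", tuple(tuple(a) for a in self.beta_anchors)
            )


@dataclass
class MaxentModel:
    """A fitted model: expansion, weights, penalties and normalisation."""

    expansion: FeatureExpansion | None
    weights: np.ndarray
    lambdas: np.ndarray
    log_normaliser: float
    entropy: float
    settings: ModelSettings
    objective: float = np.nan
    background_ref: str | None = None

    @property
    def n_active(self) -> int:
        return int(np.sum(np.abs(self.weights) > ACTIVE_TOL))

    def active_variables(self) -> list[str]:
        if self.expansion is None:
            return []
        out = []
        for var in self.expansion.variables:
            cols = self.expansion.columns_of(var)
            if np.any(np.abs(self.weights[cols]) > ACTIVE_TOL):
                out.append(var)
        return out

    def to_json(self) -> str:
        exp = self.expansion
        doc = {
            "feature_defs": [
                {"variable": fd.variable, "ftype": fd.ftype, "knot": fd.knot,
                 "category": fd.category}
                for fd in (exp.feature_defs if exp else [])
            ],
            "scaling": {k: list(v) for k, v in (exp.scaling if exp else {}).items()},
            "categories": dict(exp.categories) if exp else {},
            "fc": exp.fc if exp else None,
            "n_hinge_knots": exp.n_hinge_knots if exp else None,
            "weights": self.weights.tolist(),
            "lambdas": self.lambdas.tolist(),
            "log_normaliser": self.log_normaliser,
            "entropy": self.entropy,
            "settings": asdict(self.settings),
            "objective": self.objective,
            "background_ref": self.background_ref,
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "MaxentModel":
        doc = json.loads(text)
        exp = None
        if doc.get("fc") is not None:
            exp = FeatureExpansion(
                [FeatureDef(**fd) for fd in doc["feature_defs"]],
                {k: tuple(v) for k, v in doc["scaling"].items()},
                {k: list(v) for k, v in doc.get("categories", {}).items()},
                fc=doc["fc"],
                n_hinge_knots=doc["n_hinge_knots"],
            )
        return cls(
            expansion=exp,
            weights=np.asarray(doc["weights"], float),
            lambdas=np.asarray(doc["lambdas"], float),
            log_normaliser=doc["log_normaliser"],
            entropy=doc["entropy"],
            settings=ModelSettings(**doc["settings"]),
            objective=doc.get("objective", np.nan),
            background_ref=doc.get("background_ref"),
        )


def background_hash(background: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(background).tobytes()).hexdigest()[:16]


def maxent_objective(
    w: np.ndarray,
    presence: np.ndarray,
    background: np.ndarray,
    lambdas: np.ndarray,
) -> float:
    """The penalised objective L(w) at a weight vector."""
    eta_p = presence @ w
    eta_b = background @ w
    return float(
        -eta_p.mean()
        + logsumexp(eta_b)
        - np.log(background.shape[0])
        + np.dot(lambdas, np.abs(w))
    )


def fit_maxent(
    presence: np.ndarray,
    background: np.ndarray,
    settings: ModelSettings,
    lambdas: np.ndarray | None = None,
    expansion: FeatureExpansion | None = None,
) -> MaxentModel:
    """Fit the penalised maximum-entropy model.

    ``presence`` and ``background`` are design matrices over the same
    features. If ``lambdas`` is omitted, the default per-feature penalties
    are derived from ``expansion`` and ``settings.rm``. The fit is
    deterministic given inputs and settings (cold start at w = 0).
    """
    presence = np.asarray(presence, float)
    background = np.asarray(background, float)
    if presence.ndim != 2 or background.ndim != 2:
        raise ValueError("design matrices must be 2-D")
    if presence.shape[0] < 4:
        raise ValueError(f"need >=4 presence rows to fit, got {presence.shape[0]}")
    if background.shape[0] < 2:
        raise ValueError("need >=2 background rows")
    if not (np.isfinite(presence).all() and np.isfinite(background).all()):
        raise ValueError("non-finite values in the design matrices")
    n, J = background.shape
    if lambdas is None:
        if expansion is None:
            raise ValueError("either lambdas or an expansion must be given")
        lambdas = default_lambdas(
            expansion, presence, settings.rm,
            anchors=settings.beta_anchors,
            sd_floor=settings.lambda_sd_floor,
            beta_hinge=settings.beta_hinge,
            beta_indicator=settings.beta_indicator,
        )
    lambdas = np.asarray(lambdas, float)
    if np.any(lambdas < 0):
        raise ValueError("lambdas must be non-negative")

    # degenerate expansion: every feature constant over the joint sample
    both = np.vstack([presence, background])
    if J == 0 or np.all(both.max(axis=0) - both.min(axis=0) == 0):
        w = np.zeros(J)
        return _finalise(w, presence, background, lambdas, settings, expansion)

    p_mean = presence.mean(axis=0)

    def fun_grad(u: np.ndarray):
        w = u[:J] - u[J:]
        eta_b = background @ w
        lse = logsumexp(eta_b)
        p = np.exp(eta_b - lse)
        g = background.T @ p - p_mean  # d/dw of the smooth part
        f = -presence.mean(axis=0) @ w + lse - np.log(n) + lambdas @ (u[:J] + u[J:])
        grad = np.concatenate([g + lambdas, -g + lambdas])
        return f, grad

    res = minimize(
        fun_grad,
        np.zeros(2 * J),
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * (2 * J),
        options={
            "maxiter": settings.max_iter,
            "ftol": 1e-12,  # stop once the objective stalls at machine scale
            "gtol": settings.convergence_tol,
            "maxcor": 20,
            "maxfun": 40 * settings.max_iter,
        },
    )
    # L-BFGS-B reports ABNORMAL on line-search stalls at the optimum; only a
    # hit on the iteration cap counts as non-convergence here
    if res.status == 1:
        gnorm = float(np.max(np.abs(res.jac)))
        raise RuntimeError(
            f"maxent fit did not converge within {settings.max_iter} iterations "
            f"(projected gradient norm {gnorm:.3e})"
        )
    w = res.x[:J] - res.x[J:]
    w[np.abs(w) < 1e-12] = 0.0
    return _finalise(w, presence, background, lambdas, settings, expansion)


def _finalise(w, presence, background, lambdas, settings, expansion) -> MaxentModel:
    eta_b = background @ w
    logZ = float(logsumexp(eta_b))
    logp = eta_b - logZ
    H = float(-np.sum(np.exp(logp) * logp))
    return MaxentModel(
        expansion=expansion,
        weights=w,
        lambdas=lambdas,
        log_normaliser=logZ,
        entropy=max(H, 0.0),
        settings=settings,
        objective=maxent_objective(w, presence, background, lambdas),
        background_ref=background_hash(background),
    )


def predict(model: MaxentModel, rows: pd.DataFrame | np.ndarray, output: str = "cloglog") -> np.ndarray:
    """Score covariate rows on the raw or cloglog scale.

    Raw scores are the normalised Gibbs density ``exp(eta - logZ)`` (they sum
    to 1 over the training background); cloglog maps them into (0, 1) via
    ``1 - exp(-e^H * raw)``, the bounded suitability scale used for maps.
    """
    if output not in ("raw", "cloglog"):
        raise ValueError(f"unknown output scale {output!r}")
    if isinstance(rows, pd.DataFrame):
        if model.expansion is None:
            raise ValueError("model has no feature expansion; pass a design matrix")
        X = expand_features(rows, model.expansion)
    else:
        X = np.asarray(rows, float)
    raw = np.exp(X @ model.weights - model.log_normaliser)
    if output == "raw":
        return raw
    return 1.0 - np.exp(-np.exp(model.entropy) * raw)


def predict_stack(model: MaxentModel, stack, output: str = "cloglog"):
    """Predict over every valid cell of an EnvStack, as a suitability raster."""
    from .raster import RasterLayer

    mask = stack.nodata_mask
    valid = ~mask
    rows = pd.DataFrame(
        {name: stack[name].values[valid] for name in model.expansion.variables}
    )
    scores = predict(model, rows, output=output)
    out = np.zeros(stack.shape, dtype=float)
    out[valid] = scores
    return RasterLayer(
        name="suitability",
        kind="continuous",
        values=out,
        nodata_mask=mask.copy(),
        cell_size=stack.cell_size,
        origin=stack.origin,
    )


def variable_contribution(
    model: MaxentModel,
    presence: pd.DataFrame,
    background: pd.DataFrame,
    n_permutations: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation importance of each source variable, normalised to 100%.

    For every variable, its values are permuted jointly across the pooled
    presence + background rows (all features derived from the variable move
    together), the training AUC is recomputed, and the drop from the
    unpermuted AUC is averaged over ``n_permutations`` seeded draws.
    Negative drops are floored at 0 and the drops rescaled to sum to 100.
    A model with no active variable yields all-zero contributions.
    """
    from .evaluate import auc

    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    exp = model.expansion
    if exp is None:
        raise ValueError("contribution requires a model with a feature expansion")
    Xp = expand_features(presence, exp)
    Xb = expand_features(background, exp)
    m = Xp.shape[0]
    X = np.vstack([Xp, Xb])
    base_scores = X @ model.weights
    base_auc = auc(base_scores[:m], base_scores[m:])
    rng = np.random.default_rng(seed)
    variables = exp.variables
    drops = np.zeros(len(variables))
    if model.n_active > 0:
        for i, var in enumerate(variables):
            cols = exp.columns_of(var)
            acc = 0.0
            for _ in range(n_permutations):
                perm = rng.permutation(X.shape[0])
                Xperm = X.copy()
                Xperm[:, cols] = X[np.ix_(perm, cols)]
                s = Xperm @ model.weights
                acc += base_auc - auc(s[:m], s[m:])
            drops[i] = max(acc / n_permutations, 0.0)
    total = drops.sum()
    if total == 0:
        warnings.warn("no variable permutation lowered the training AUC; "
                      "contributions reported as 0")
        pct = drops
    else:
        pct = 100.0 * drops / total
    out = pd.DataFrame({"variable": variables, "contribution": pct})
    out = out.sort_values(
        ["contribution", "variable"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return out
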