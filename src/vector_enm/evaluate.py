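"""Model validation: spatial blocks, AUC, omission, Boyce, null models.

Validation follows standard presence-background practice: occurrences and
background are split into four spatially contiguous quadrant blocks to
curb spatial autocorrelation between training and testing sites; test AUC
is the rank-based (Mann-Whitney) probability that a presence outscores a
background point; omission is the fraction of test presences scoring
below a threshold taken from the training presences; the continuous Boyce
index checks that the predicted-to-expected presence ratio rises with
suitability; and significance is established against 100 models fitted to
randomly drawn pseudo-occurrences (Raes & ter Steege style null models).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model import ModelSettings, fit_maxent
from .features import build_expansion, expand_features

__all__ = [
    "FoldAssignment",
    "CVResult",
    "NullModelResult",
    "spatial_block_folds",
    "auc",
    "classify_auc",
    "omission_rate",
    "boyce_index",
    "cross_validate",
    "null_model_test",
]


@dataclass
class FoldAssignment:
    """Quadrant-block fold ids (1..k) for presences and background."""

    k: int
    presence_fold: np.ndarray
    background_fold: np.ndarray
    split_lines: dict  # {"x": x_split, "y_left": ..., "y_right": ...}


@dataclass
class CVResult:
    """Per-fold and mean cross-validated test AUC and omission rate."""

    fold_auc: list[float]
    fold_omission: list[float]
    mean_auc: float
    mean_omission: float
    settings: ModelSettings
    fold_n_active: list[int] = field(default_factory=list)
    skipped_folds: list[int] = field(default_factory=list)

    @property
    def mean_n_active(self) -> float:
        return float(np.mean(self.fold_n_active)) if self.fold_n_active else 0.0


@dataclass
class NullModelResult:
    """Observed training AUC against a null distribution of random models."""

    null_aucs: np.ndarray
    observed_auc: float
    percentile_95: float
    significant: bool
    empirical_p: float


def _median_split(values: np.ndarray) -> float:
    """Split line putting floor(n/2) points strictly below it.

    The line is the midpoint between the two middle order statistics, so it
    is recomputable from the data and (for distinct values) balances the two
    sides to within one point.
    """
    s = np.sort(values)
    n = len(s)
    return float((s[(n - 1) // 2] + s[n // 2]) / 2.0)


def spatial_block_folds(
    presence: pd.DataFrame, background: pd.DataFrame, k: int = 4
) -> FoldAssignment:
    """Partition points into 4 contiguous quadrant blocks.

    Presences are split at their median x; each half is split at its own
    median y. Background points are assigned to the quadrant (same split
    lines) containing them. Deterministic; only k = 4 is supported.
    """
    if k != 4:
        raise ValueError("only k=4 quadrant blocks are supported")
    px = presence["x"].to_numpy(float)
    py = presence["y"].to_numpy(float)
    if len(px) < k:
        raise ValueError(f"need >= {k} presence points, got {len(px)}")
    x_split = _median_split(px)
    left = px < x_split
    # guard: with heavy x ties one side can be empty; fall back to rank split
    if left.all() or not left.any():
        order = np.argsort(px, kind="mergesort")
        left = np.zeros(len(px), dtype=bool)
        left[order[: len(px) // 2]] = True
        x_split = float(px[~left].min())
    y_left = _median_split(py[left]) if left.any() else 0.0
    y_right = _median_split(py[~left]) if (~left).any() else 0.0

    def assign(x: np.ndarray, y: np.ndarray) -> np.ndarray:
        is_left = x < x_split
        y_line = np.where(is_left, y_left, y_right)
        low = y < y_line
        # folds: 1 = left-low, 2 = left-high, 3 = right-low, 4 = right-high
        return np.where(is_left, np.where(low, 1, 2), np.where(low, 3, 4))

    pf = assign(px, py)
    bf = assign(background["x"].to_numpy(float), background["y"].to_numpy(float))
    return FoldAssignment(
        k=4,
        presence_fold=pf,
        background_fold=bf,
        split_lines={"x": x_split, "y_left": y_left, "y_right": y_right},
    )


def auc(presence_scores, background_scores) -> float:
    """Rank-based AUC: P(random presence score > random background score).

    Ties count one half (the Mann-Whitney U convention).
    """
    p = np.asarray(presence_scores, float)
    b = np.asarray(background_scores, float)
    if p.size == 0 or b.size == 0:
        raise ValueError("auc requires non-empty presence and background scores")
    ranks = stats.rankdata(np.concatenate([p, b]))
    u = ranks[: p.size].sum() - p.size * (p.size + 1) / 2.0
    return float(u / (p.size * b.size))


def classify_auc(value: float) -> str:
    """Performance band for an AUC value.

    <=0.5 random; (0.5, 0.7) poor to moderate; [0.7, 0.9) moderate to high;
    >=0.9 excellent.
    """
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"AUC {value} outside [0, 1]")
    if value <= 0.5:
        return "random"
    if value < 0.7:
        return "poor to moderate"
    if value < 0.9:
        return "moderate to high"
    return "excellent"


def omission_rate(train_presence_scores, test_presence_scores, rule: str = "mtp") -> float:
    """Fraction of test presences scoring strictly below the threshold.

    The threshold is the minimum training presence score (``mtp``) or the
    10th percentile of the training presence scores (``p10``).
    """
    train = np.asarray(train_presence_scores, float)
    test = np.asarray(test_presence_scores, float)
    if train.size == 0 or test.size == 0:
        raise ValueError("omission_rate requires non-empty score collections")
    if rule == "mtp":
        tau = train.min()
    elif rule == "p10":
        tau = np.percentile(train, 10)
    else:
        raise ValueError(f"unknown omission rule {rule!r}")
    return float(np.mean(test < tau))


def boyce_index(
    presence_scores, background_scores, n_windows: int = 101
) -> float:
    """Continuous Boyce index in [-1, 1].

    ``n_windows`` overlapping windows of width (range/10) with evenly
    spaced midpoints are laid over the background score range; per window
    the presence fraction P and background (expected) fraction E are
    computed, windows with E = 0 are skipped, and the index is the
    Spearman rank correlation between P/E and the window midpoint.
    Returns NaN when fewer than 3 windows are usable or the P/E profile
    is constant.
    """
    p = np.asarray(presence_scores, float)
    b = np.asarray(background_scores, float)
    if p.size < 1:
        raise ValueError("boyce_index requires at least one presence score")
    smin, smax = float(b.min()), float(b.max())
    if smin == smax:
        raise ValueError("background scores have zero range")
    width = (smax - smin) / 10.0
    mids = np.linspace(smin + width / 2.0, smax - width / 2.0, n_windows)
    ratios, used_mids = [], []
    for mid in mids:
        lo, hi = mid - width / 2.0, mid + width / 2.0
        e = np.mean((b >= lo) & (b <= hi))
        if e == 0:
            continue
        pr = np.mean((p >= lo) & (p <= hi))
        ratios.append(pr / e)
        used_mids.append(mid)
    if len(ratios) < 3:
        warnings.warn("fewer than 3 usable Boyce windows; index undefined")
        return float("nan")
    rho = stats.spearmanr(used_mids, ratios).statistic
    return float(rho)


def _fold_designs(
    presence: pd.DataFrame,
    background: pd.DataFrame,
    variables: list[str],
    kinds: dict[str, str],
    fc: str,
    n_hinge_knots: int,
    folds: FoldAssignment,
) -> dict:
    """Per-fold design matrices for one feature class (shared across rm)."""
    out = {}
    for f in range(1, folds.k + 1):
        test_p = presence[folds.presence_fold == f]
        train_p = presence[folds.presence_fold != f]
        train_b = background[folds.background_fold != f]
        if len(test_p) == 0 or len(train_p) < 4 or len(train_b) < 2:
            out[f] = None
            continue
        exp = build_expansion(train_b, variables, kinds, fc=fc, n_hinge_knots=n_hinge_knots)
        out[f] = {
            "expansion": exp,
            "Xp": expand_features(train_p, exp),
            "Xb": expand_features(train_b, exp),
            "Xtest": expand_features(test_p, exp),
            "Xbg_full": expand_features(background, exp),
        }
    return out


def cross_validate(
    presence: pd.DataFrame,
    background: pd.DataFrame,
    variables: list[str],
    kinds: dict[str, str],
    settings: ModelSettings,
    folds: FoldAssignment,
    _designs: dict | None = None,
) -> CVResult:
    """Spatial-block cross-validation of one settings candidate.

    For each fold the model is fitted on the other folds' presences and
    background (feature scaling from the training background), test
    presences of the held-out fold are scored against the *full* background,
    and the omission threshold is the minimum training-presence score.
    Folds without test presences are skipped with a warning.
    """
    if _designs is None:
        _designs = _fold_designs(
            presence, background, variables, kinds, settings.fc,
            settings.n_hinge_knots, folds,
        )
    fold_auc, fold_om, fold_active, skipped = [], [], [], []
    for f in range(1, folds.k + 1):
        d = _designs[f]
        if d is None:
            warnings.warn(f"fold {f} unusable (no test presences or too few "
                          "training points); skipped")
            skipped.append(f)
            continue
        model = fit_maxent(d["Xp"], d["Xb"], settings, expansion=d["expansion"])
        s_test = d["Xtest"] @ model.weights
        s_bg_full = d["Xbg_full"] @ model.weights
        s_train_p = d["Xp"] @ model.weights
        fold_auc.append(auc(s_test, s_bg_full))
        fold_om.append(omission_rate(s_train_p, s_test, rule="mtp"))
        fold_active.append(model.n_active)
    if not fold_auc:
        raise ValueError("every fold was skipped; cannot cross-validate")
    return CVResult(
        fold_auc=fold_auc,
        fold_omission=fold_om,
        mean_auc=float(np.mean(fold_auc)),
        mean_omission=float(np.mean(fold_om)),
        settings=settings,
        fold_n_active=fold_active,
        skipped_folds=skipped,
    )


def null_model_test(
    observed_auc: float,
    background: pd.DataFrame,
    m: int,
    variables: list[str],
    kinds: dict[str, str],
    settings: ModelSettings,
    n_null: int = 100,
    seed: int = 0,
) -> NullModelResult:
    """Raes & ter Steege null-model significance test.

    Each replicate draws m pseudo-presences uniformly without replacement
    from the background support, fits a model with the same settings (no
    cross-validation) and records its training AUC against the full
    background. The observed model is significant when its training AUC
    exceeds the 95th percentile (linear interpolation) of the null
    distribution; the empirical p-value is (1 + #{null >= observed}) /
    (n_null + 1).
    """
    if m < 4:
        raise ValueError(f"need m >= 4 pseudo-presences, got {m}")
    if len(background) <= m:
        raise ValueError("background must have more cells than m")
    rng = np.random.default_rng(seed)
    exp = build_expansion(
        background, variables, kinds, fc=settings.fc, n_hinge_knots=settings.n_hinge_knots
    )
    Xb = expand_features(background, exp)
    null_aucs = np.empty(n_null)
    for i in range(n_null):
        idx = rng.choice(len(background), size=m, replace=False)
        Xp = Xb[idx]
        model = fit_maxent(Xp, Xb, settings, expansion=exp)
        scores = Xb @ model.weights
        null_aucs[i] = auc(scores[idx], scores)
    p95 = float(np.percentile(null_aucs, 95))
    return NullModelResult(
        null_aucs=null_aucs,
        observed_auc=float(observed_auc),
        percentile_95=p95,
        significant=bool(observed_auc > p95),
        empirical_p=float((1 + np.sum(null_aucs >= observed_auc)) / (n_null + 1)),
    )
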