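"""Feature expansion for the maximum-entropy model.

Continuous covariates are min-max scaled to [0, 1] over the background
sample and expanded into linear, quadratic and hinge basis features;
categorical covariates contribute one indicator feature per code under
every feature class. Feature classes:

* ``L``   — linear
* ``LQ``  — linear + quadratic
* ``H``   — hinge (forward and reverse ramps at interior knots)
* ``LQH`` — linear + quadratic + hinge

All features map into [0, 1], which keeps the per-feature L1 penalties
comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FEATURE_CLASSES = ("L", "LQ", "H", "LQH")

# default (sample size, beta) anchors for linear/quadratic features; the
# penalty scale interpolates linearly between anchors and clamps outside
BETA_ANCHORS_LQ = ((10, 1.0), (30, 0.2), (100, 0.05))
BETA_HINGE = 0.5
BETA_INDICATOR = 0.25
SD_FLOOR = 0.01


@dataclass(frozen=True)
class FeatureDef:
    """One basis feature: a transform of a single source variable."""

    variable: str
    ftype: str  # linear | quadratic | forward_hinge | reverse_hinge | indicator
    knot: float | None = None
    category: int | None = None

    @property
    def name(self) -> str:
        if self.ftype == "indicator":
            return f"{self.variable}=={self.category}"
        if self.knot is not None:
            return f"{self.ftype}({self.variable},{self.knot:g})"
        return f"{self.ftype}({self.variable})"


@dataclass
class FeatureExpansion:
    """Feature definitions plus the background scaling that fixes them.

    ``scaling`` maps each continuous variable to its (min, max) over the
    background sample; hinge knots live strictly inside (0, 1) on the
    scaled axis.
    """

    feature_defs: list[FeatureDef]
    scaling: dict[str, tuple[float, float]]
    categories: dict[str, list[int]] = field(default_factory=dict)
    fc: str = "LQH"
    n_hinge_knots: int = 32

    @property
    def variables(self) -> list[str]:
        seen: list[str] = []
        for fd in self.feature_defs:
            if fd.variable not in seen:
                seen.append(fd.variable)
        return seen

    def feature_names(self) -> list[str]:
        return [fd.name for fd in self.feature_defs]

    def columns_of(self, variable: str) -> np.ndarray:
        """Design-matrix column indices owned by one source variable."""
        return np.array(
            [j for j, fd in enumerate(self.feature_defs) if fd.variable == variable],
            dtype=int,
        )


def hinge_knots(n: int) -> np.ndarray:
    """n knots evenly spaced strictly inside (0, 1)."""
    return np.arange(1, n + 1) / (n + 1)


def build_expansion(
    background: pd.DataFrame,
    variables: list[str],
    kinds: dict[str, str],
    fc: str = "LQH",
    n_hinge_knots: int = 32,
) -> FeatureExpansion:
    """Derive a feature expansion from the background sample.

    Scaling ranges and category sets are taken from ``background``; the
    feature class ``fc`` decides which transforms continuous variables get.
    Continuous variables that are constant over the background cannot be
    scaled and are dropped from the expansion (they carry no information).
    """
    if fc not in FEATURE_CLASSES:
        raise ValueError(f"unknown feature class {fc!r}; expected one of {FEATURE_CLASSES}")
    defs: list[FeatureDef] = []
    scaling: dict[str, tuple[float, float]] = {}
    categories: dict[str, list[int]] = {}
    knots = hinge_knots(n_hinge_knots)
    for var in variables:
        if var not in background.columns:
            raise KeyError(f"variable {var!r} missing from background rows")
        col = background[var].to_numpy()
        if kinds.get(var, "continuous") == "categorical":
            codes = sorted(int(c) for c in np.unique(col))
            categories[var] = codes
            defs.extend(FeatureDef(var, "indicator", category=c) for c in codes)
            continue
        vmin, vmax = float(np.min(col)), float(np.max(col))
        if vmin == vmax:
            continue  # constant over background: unscalable, uninformative
        scaling[var] = (vmin, vmax)
        if fc in ("L", "LQ", "LQH"):
            defs.append(FeatureDef(var, "linear"))
        if fc in ("LQ", "LQH"):
            defs.append(FeatureDef(var, "quadratic"))
        if fc in ("H", "LQH"):
            for k in knots:
                defs.append(FeatureDef(var, "forward_hinge", knot=float(k)))
                defs.append(FeatureDef(var, "reverse_hinge", knot=float(k)))
    return FeatureExpansion(defs, scaling, categories, fc=fc, n_hinge_knots=n_hinge_knots)


def expand_features(rows: pd.DataFrame, expansion: FeatureExpansion) -> np.ndarray:
    """Build the (n_rows, n_features) design matrix; every entry in [0, 1]."""
    n = len(rows)
    X = np.empty((n, len(expansion.feature_defs)), dtype=float)
    scaled: dict[str, np.ndarray] = {}
    for var, (vmin, vmax) in expansion.scaling.items():
        if var not in rows.columns:
            raise KeyError(f"variable {var!r} missing from rows")
        scaled[var] = np.clip((rows[var].to_numpy(float) - vmin) / (vmax - vmin), 0.0, 1.0)
    for j, fd in enumerate(expansion.feature_defs):
        if fd.ftype == "indicator":
            if fd.variable not in rows.columns:
                raise KeyError(f"variable {fd.variable!r} missing from rows")
            X[:, j] = (rows[fd.variable].to_numpy() == fd.category).astype(float)
            continue
        v = scaled[fd.variable]
        if fd.ftype == "linear":
            X[:, j] = v
        elif fd.ftype == "quadratic":
            X[:, j] = v * v
        elif fd.ftype == "forward_hinge":
            X[:, j] = np.maximum(0.0, (v - fd.knot) / (1.0 - fd.knot))
        elif fd.ftype == "reverse_hinge":
            X[:, j] = np.maximum(0.0, (fd.knot - v) / fd.knot)
        else:  # pragma: no cover - guarded at construction
            raise ValueError(f"unknown feature type {fd.ftype!r}")
    return X


def beta_for(
    ftype: str,
    m: int,
    anchors=BETA_ANCHORS_LQ,
    beta_hinge: float = BETA_HINGE,
    beta_indicator: float = BETA_INDICATOR,
) -> float:
    """Penalty scale for a feature type at presence sample size m."""
    if ftype in ("linear", "quadratic"):
        ms = np.array([a[0] for a in anchors], dtype=float)
        bs = np.array([a[1] for a in anchors], dtype=float)
        return float(np.interp(m, ms, bs))
    if ftype in ("forward_hinge", "reverse_hinge"):
        return beta_hinge
    if ftype == "indicator":
        return beta_indicator
    raise ValueError(f"unknown feature type {ftype!r}")


def default_lambdas(
    expansion: FeatureExpansion,
    presence_design: np.ndarray,
    rm: float,
    anchors=BETA_ANCHORS_LQ,
    sd_floor: float = SD_FLOOR,
    beta_hinge: float = BETA_HINGE,
    beta_indicator: float = BETA_INDICATOR,
) -> np.ndarray:
    """Per-feature L1 penalties lambda_j = rm * beta(type, m) * s_j / sqrt(m).

    m is the presence count and s_j the standard deviation of feature j over
    the presences, floored at ``sd_floor`` so no feature is ever unpenalised.
    """
    m = presence_design.shape[0]
    if m < 2:
        raise ValueError(f"need >=2 presence rows to set penalties, got {m}")
    sd = np.maximum(presence_design.std(axis=0, ddof=0), sd_floor)
    betas = np.array(
        [beta_for(fd.ftype, m, anchors, beta_hinge, beta_indicator)
         for fd in expansion.feature_defs]
    )
    return rm * betas * sd / np.sqrt(m)
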