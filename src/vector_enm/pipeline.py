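"""The per-species modelling workflow.

Mirrors the field workflow for presence-background vector mapping:
occurrences are deduplicated to unique raster cells (life stages pooled,
species with fewer than four unique cells skipped); a background sample
is drawn from well-surveyed areas (cells where at least ``min_species``
distinct species were collected, optionally buffered); a 20-cell tuning
grid (regularization multiplier 1-5 x feature classes L/LQ/H/LQH) is
cross-validated over shared spatial blocks and the optimum selected by
lowest mean omission then highest mean AUC; the optimum is validated
against 100 null models; permutation contributions drive variable
selection with a +/-0.7 Pearson correlation filter; the reduced variable
set is re-tuned and the final model exported as a cloglog suitability
map with contribution, evaluation and response-curve tables.
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import evaluate as ev
from .features import build_expansion, expand_features
from .model import MaxentModel, ModelSettings, fit_maxent, predict, predict_stack, variable_contribution
from .raster import EnvStack, RasterLayer, extract_values, pearson_correlation_matrix

logger = logging.getLogger("vector_enm")

__all__ = [
    "OccurrenceSet",
    "BackgroundSet",
    "TuningResult",
    "SpeciesReport",
    "SkipVerdict",
    "prepare_occurrences",
    "build_background",
    "tune_models",
    "select_optimal",
    "select_variables",
    "run_species_pipeline",
    "export_report",
    "model_variables",
]

MIN_UNIQUE_CELLS = 4  # species with fewer unique collection cells are not modelled


@dataclass
class SkipVerdict:
    """A species excluded from modelling, with the reason."""

    species: str
    n_unique: int
    reason: str


@dataclass
class OccurrenceSet:
    """Deduplicated presence cells for one species (life stages pooled)."""

    species: str
    cells: pd.DataFrame  # columns x, y, row, col (cell centres)
    n_raw: int
    life_stages_pooled: bool = True

    @property
    def n_unique(self) -> int:
        return len(self.cells)


@dataclass
class BackgroundSet:
    """Background cells sampled from the well-surveyed area."""

    points: pd.DataFrame  # columns x, y, row, col
    eligibility_mask: np.ndarray
    min_species: int
    seed: int
    requested: int

    @property
    def n(self) -> int:
        return len(self.points)


@dataclass
class TuningResult:
    """All grid candidates plus the lexicographically selected optimum."""

    candidates: list[ev.CVResult]
    failures: list[tuple[ModelSettings, str]]
    selected: int
    selection_trace: list[dict]

    @property
    def best(self) -> ev.CVResult:
        return self.candidates[self.selected]


@dataclass
class SpeciesReport:
    """Everything the pipeline produces for one species."""

    species: str
    final_model: MaxentModel
    suitability: RasterLayer
    contribution: pd.DataFrame  # variable, percent, cumulative (cut at >= 80)
    contribution_full: pd.DataFrame
    retained_variables: list[str]
    initial_tuning: TuningResult
    final_tuning: TuningResult
    cv: ev.CVResult
    null: ev.NullModelResult
    boyce: float
    auc_band: str
    occurrences: OccurrenceSet
    background: BackgroundSet
    metadata: dict
    background_covariates: pd.DataFrame | None = None


def model_variables(stack: EnvStack) -> tuple[list[str], dict[str, str]]:
    """Default covariates: every layer except derived truth/suitability maps."""
    names, kinds = [], {}
    for lyr in stack.layers:
        if lyr.name.startswith("truth_") or lyr.name == "suitability":
            continue
        names.append(lyr.name)
        kinds[lyr.name] = lyr.kind
    return names, kinds


def prepare_occurrences(
    records: pd.DataFrame, species: str, stack: EnvStack
) -> OccurrenceSet | SkipVerdict:
    """Filter records to one species and collapse to unique valid cells.

    Life stages are pooled; points on nodata cells are dropped; species
    with fewer than four unique cells get a skip verdict.
    """
    labels = records["species"].astype(str).str.strip()
    sel = records[labels == species.strip()]
    if len(sel) == 0:
        raise ValueError(f"species {species!r} absent from the records")
    row, col = stack.point_to_cell(sel["x"].to_numpy(float), sel["y"].to_numpy(float))
    nr, nc = stack.shape
    inside = (row >= 0) & (row < nr) & (col >= 0) & (col < nc)
    row, col = row[inside], col[inside]
    valid = ~stack.nodata_mask[row, col]
    cells = sorted(set(zip(row[valid].tolist(), col[valid].tolist())))
    n_unique = len(cells)
    logger.info("prepare_occurrences species=%s n_raw=%d n_unique=%d", species, len(sel), n_unique)
    if n_unique < MIN_UNIQUE_CELLS:
        return SkipVerdict(
            species, n_unique,
            f"only {n_unique} unique collection cells (< {MIN_UNIQUE_CELLS})",
        )
    rows = np.array([c[0] for c in cells])
    cols = np.array([c[1] for c in cells])
    x, y = stack.cell_to_center(rows, cols)
    return OccurrenceSet(
        species=species,
        cells=pd.DataFrame({"x": x, "y": y, "row": rows, "col": cols}),
        n_raw=int(len(sel)),
    )


def build_background(
    survey: pd.DataFrame,
    stack: EnvStack,
    n: int = 10000,
    min_species: int = 2,
    radius: float = 250.0,
    seed: int = 0,
) -> BackgroundSet:
    """Sample background cells from the well-surveyed area.

    A cell qualifies when at least ``min_species`` distinct species were
    collected in it; the eligible area is every valid cell within
    ``radius`` map units of a qualifying cell (radius 0 keeps the exact
    cells). Up to ``n`` cells are drawn uniformly without replacement.
    """
    row, col = stack.point_to_cell(survey["x"].to_numpy(float), survey["y"].to_numpy(float))
    nr, nc = stack.shape
    inside = (row >= 0) & (row < nr) & (col >= 0) & (col < nc)
    df = pd.DataFrame(
        {"row": row[inside], "col": col[inside],
         "species": survey["species"].astype(str).str.strip().to_numpy()[inside]}
    )
    counts = df.groupby(["row", "col"])["species"].nunique()
    qualifying = counts[counts >= min_species]
    qual_mask = np.zeros(stack.shape, dtype=bool)
    for (r, c) in qualifying.index:
        qual_mask[r, c] = True
    qual_mask &= ~stack.nodata_mask
    if not qual_mask.any():
        raise ValueError(
            f"no cell has >= {min_species} species collected; cannot build background"
        )
    if radius > 0:
        dist = ndimage.distance_transform_edt(~qual_mask) * stack.cell_size
        eligible = (dist <= radius) & ~stack.nodata_mask
    else:
        eligible = qual_mask
    er, ec = np.nonzero(eligible)
    rng = np.random.default_rng(seed)
    if er.size > n:
        pick = rng.choice(er.size, size=n, replace=False)
        pick.sort()
        er, ec = er[pick], ec[pick]
    x, y = stack.cell_to_center(er, ec)
    logger.info("build_background n_eligible=%d n_sampled=%d seed=%d",
                int(eligible.sum()), er.size, seed)
    return BackgroundSet(
        points=pd.DataFrame({"x": x, "y": y, "row": er, "col": ec}),
        eligibility_mask=eligible,
        min_species=min_species,
        seed=seed,
        requested=n,
    )


def select_optimal(candidates: list[dict]) -> tuple[int, list[dict]]:
    """Lexicographic model selection over tuning candidates.

    Order: minimum mean omission, then maximum mean AUC, then fewest
    active features, then largest regularization multiplier. Each
    candidate dict needs mean_omission, mean_auc, n_active and rm.
    Returns the winning index and a stage-by-stage trace of survivors.
    """
    if not candidates:
        raise ValueError("no surviving candidates to select from")
    idx = list(range(len(candidates)))
    trace = []
    stages = [
        ("min mean_omission", lambda i: candidates[i]["mean_omission"], min),
        ("max mean_auc", lambda i: candidates[i]["mean_auc"], max),
        ("min n_active", lambda i: candidates[i]["n_active"], min),
        ("max rm", lambda i: candidates[i]["rm"], max),
    ]
    for name, key, best in stages:
        target = best(key(i) for i in idx)
        idx = [i for i in idx if key(i) == target]
        trace.append({"stage": name, "value": target, "survivors": list(idx)})
        if len(idx) == 1:
            break
    return idx[0], trace


def tune_models(
    occ: OccurrenceSet,
    bg: BackgroundSet,
    stack: EnvStack,
    settings_base: ModelSettings,
    variables: list[str],
    kinds: dict[str, str],
    folds: ev.FoldAssignment | None = None,
    grid_rm: tuple = (1, 2, 3, 4, 5),
    grid_fc: tuple = ("L", "LQ", "H", "LQH"),
) -> TuningResult:
    """Cross-validate every (rm, fc) grid cell and select the optimum.

    All candidates share one spatial-block fold assignment. Candidates
    whose fit fails are recorded and excluded from selection; if every
    candidate fails, the error propagates.
    """
    pres = extract_values(stack, occ.cells)
    pres = pres[pres["valid"]]
    back = extract_values(stack, bg.points)
    back = back[back["valid"]]
    pres = pres.join(occ.cells[["x", "y"]])
    back = back.join(bg.points[["x", "y"]])
    if folds is None:
        folds = ev.spatial_block_folds(pres, back)
    candidates, failures, meta = [], [], []
    design_cache: dict[str, dict] = {}
    for fc, rm in itertools.product(grid_fc, grid_rm):
        settings = ModelSettings(
            rm=float(rm), fc=fc,
            n_hinge_knots=settings_base.n_hinge_knots,
            convergence_tol=settings_base.convergence_tol,
            max_iter=settings_base.max_iter,
            seed=settings_base.seed,
            beta_anchors=settings_base.beta_anchors,
            beta_hinge=settings_base.beta_hinge,
            beta_indicator=settings_base.beta_indicator,
            lambda_sd_floor=settings_base.lambda_sd_floor,
        )
        if fc not in design_cache:
            design_cache[fc] = ev._fold_designs(
                pres, back, variables, kinds, fc, settings.n_hinge_knots, folds
            )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cv = ev.cross_validate(pres, back, variables, kinds, settings,
                                       folds, _designs=design_cache[fc])
        except (RuntimeError, ValueError) as exc:
            failures.append((settings, str(exc)))
            logger.warning("tune candidate rm=%s fc=%s failed: %s", rm, fc, exc)
            continue
        candidates.append(cv)
        meta.append(
            {
                "mean_omission": cv.mean_omission,
                "mean_auc": cv.mean_auc,
                "n_active": cv.mean_n_active,
                "rm": settings.rm,
                "fc": fc,
            }
        )
    if not candidates:
        raise RuntimeError("all tuning candidates failed to fit")
    selected, trace = select_optimal(meta)
    logger.info("tune_models species=%s selected rm=%s fc=%s omission=%.3f auc=%.3f",
                occ.species, meta[selected]["rm"], meta[selected]["fc"],
                meta[selected]["mean_omission"], meta[selected]["mean_auc"])
    return TuningResult(candidates=candidates, failures=failures,
                        selected=selected, selection_trace=trace)


def select_variables(
    contribs: pd.DataFrame,
    corr: pd.DataFrame,
    cum_threshold: float = 0.8,
    r_threshold: float = 0.7,
) -> list[str]:
    """Contribution-driven variable selection with a correlation filter.

    Step 1 keeps the top-contributing variables until their cumulative
    contribution reaches ``cum_threshold`` (of 100%). Step 2 repeatedly
    finds the retained pair with the largest |Pearson r| and, while it
    exceeds ``r_threshold``, removes the pair member with the lower
    contribution (ties broken by variable name). Variables absent from
    the correlation matrix (categorical covariates) are never removed by
    step 2.
    """
    if len(contribs) == 0:
        raise ValueError("empty contribution table")
    tab = contribs.sort_values(
        ["contribution", "variable"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    cum = tab["contribution"].cumsum()
    cut = int(np.searchsorted(cum.to_numpy(), cum_threshold * 100.0 - 1e-9)) + 1
    retained = tab["variable"].head(cut).tolist()
    contrib_of = dict(zip(tab["variable"], tab["contribution"]))

    def worst_pair(names: list[str]):
        best = None
        for a, b in itertools.combinations(sorted(names), 2):
            if a not in corr.index or b not in corr.columns:
                continue
            r = abs(float(corr.loc[a, b]))
            if best is None or r > best[0]:
                best = (r, a, b)
        return best

    while len(retained) > 1:
        pair = worst_pair(retained)
        if pair is None or pair[0] <= r_threshold:
            break
        _, a, b = pair
        ca, cb = contrib_of[a], contrib_of[b]
        if ca < cb:
            drop = a
        elif cb < ca:
            drop = b
        else:
            drop = max(a, b)  # equal contributions: drop the later name
        retained.remove(drop)
    return retained


def run_species_pipeline(
    records: pd.DataFrame,
    species: str,
    stack: EnvStack,
    config,
) -> SpeciesReport | SkipVerdict:
    """Execute the full per-species workflow.

    Stages: occurrence preparation -> background construction -> spatial
    folds -> initial tuning on all variables -> null-model test on the
    initial optimum -> permutation contribution -> variable selection
    (cumulative cut + correlation filter) -> final tuning on the reduced
    set -> final model, cloglog suitability map, contribution table,
    cross-validation metrics, Boyce index and AUC band. One seed in the
    config controls every random draw; a non-significant null test is
    annotated on the report, not fatal.
    """
    from .config import RunConfig  # local import to avoid a cycle

    if not isinstance(config, RunConfig):
        config = RunConfig.from_dict(dict(config))
    seed = config.seed
    occ = prepare_occurrences(records, species, stack)
    if isinstance(occ, SkipVerdict):
        logger.info("skip species=%s reason=%s", species, occ.reason)
        return occ
    bg = build_background(
        records, stack,
        n=config.background_n, min_species=config.min_species,
        radius=config.background_radius, seed=seed,
    )
    variables, kinds = model_variables(stack)
    base = ModelSettings(
        rm=1.0, fc="LQH",
        n_hinge_knots=config.n_hinge_knots,
        convergence_tol=config.convergence_tol,
        max_iter=config.max_iter,
        seed=seed,
        beta_anchors=config.beta_anchors,
        beta_hinge=config.beta_hinge,
        beta_indicator=config.beta_indicator,
        lambda_sd_floor=config.lambda_sd_floor,
    )
    pres_cov = extract_values(stack, occ.cells)
    pres_cov = pres_cov[pres_cov["valid"]].join(occ.cells[["x", "y"]])
    back_cov = extract_values(stack, bg.points)
    back_cov = back_cov[back_cov["valid"]].join(bg.points[["x", "y"]])
    folds = ev.spatial_block_folds(pres_cov, back_cov)

    initial = tune_models(
        occ, bg, stack, base, variables, kinds, folds=folds,
        grid_rm=config.grid_rm, grid_fc=config.grid_fc,
    )
    best0 = initial.best.settings

    # refit the initial optimum on the full data for the null test and
    # the permutation contributions
    exp0 = build_expansion(back_cov, variables, kinds, fc=best0.fc,
                           n_hinge_knots=best0.n_hinge_knots)
    model0 = fit_maxent(
        expand_features(pres_cov, exp0), expand_features(back_cov, exp0),
        best0, expansion=exp0,
    )
    s_p0 = predict(model0, pres_cov, output="raw")
    s_b0 = predict(model0, back_cov, output="raw")
    observed_auc = ev.auc(s_p0, s_b0)
    null = ev.null_model_test(
        observed_auc, back_cov, m=occ.n_unique,
        variables=variables, kinds=kinds, settings=best0,
        n_null=config.n_null, seed=seed + 1,
    )
    if not null.significant:
        logger.warning("null_model species=%s not significant (p=%.3f)",
                       species, null.empirical_p)

    contribs_full = variable_contribution(
        model0, pres_cov, back_cov,
        n_permutations=config.n_permutations, seed=seed + 2,
    )
    continuous = [v for v in variables if kinds[v] == "continuous"]
    corr = pearson_correlation_matrix(stack, bg.points, layer_names=continuous)
    retained = select_variables(
        contribs_full, corr,
        cum_threshold=config.cum_threshold, r_threshold=config.r_threshold,
    )
    logger.info("select_variables species=%s retained=%s", species, retained)

    final = tune_models(
        occ, bg, stack, base, retained, {v: kinds[v] for v in retained},
        folds=folds, grid_rm=config.grid_rm, grid_fc=config.grid_fc,
    )
    bestf = final.best.settings
    expf = build_expansion(back_cov, retained, kinds, fc=bestf.fc,
                           n_hinge_knots=bestf.n_hinge_knots)
    model = fit_maxent(
        expand_features(pres_cov, expf), expand_features(back_cov, expf),
        bestf, expansion=expf,
    )
    suitability = predict_stack(model, stack, output="cloglog")
    s_p = predict(model, pres_cov, output="cloglog")
    s_b = predict(model, back_cov, output="cloglog")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        boyce = ev.boyce_index(s_p, s_b, n_windows=config.boyce_windows)
    band = ev.classify_auc(final.best.mean_auc)

    contribs_final = variable_contribution(
        model, pres_cov, back_cov,
        n_permutations=config.n_permutations, seed=seed + 3,
    )
    rep_tab = contribs_final.copy()
    rep_tab["cumulative"] = rep_tab["contribution"].cumsum()
    keep = int(np.searchsorted(rep_tab["cumulative"].to_numpy(),
                               config.cum_threshold * 100.0 - 1e-9)) + 1
    rep_cut = rep_tab.head(max(keep, 1)).reset_index(drop=True)

    metadata = {
        "species": species,
        "seed": seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "n_raw": occ.n_raw,
        "n_unique": occ.n_unique,
        "n_background": bg.n,
        "initial_settings": {"rm": best0.rm, "fc": best0.fc},
        "final_settings": {"rm": bestf.rm, "fc": bestf.fc},
        "initial_selection_trace": initial.selection_trace,
        "final_selection_trace": final.selection_trace,
        "retained_variables": retained,
        "null_significant": null.significant,
        "null_empirical_p": null.empirical_p,
        "mean_test_auc": final.best.mean_auc,
        "mean_omission": final.best.mean_omission,
        "boyce": None if np.isnan(boyce) else boyce,
        "auc_band": band,
        "fold_split_lines": folds.split_lines,
    }
    return SpeciesReport(
        species=species,
        final_model=model,
        suitability=suitability,
        contribution=rep_cut,
        contribution_full=contribs_final,
        retained_variables=retained,
        initial_tuning=initial,
        final_tuning=final,
        cv=final.best,
        null=null,
        boyce=boyce,
        auc_band=band,
        occurrences=occ,
        background=bg,
        metadata=metadata,
        background_covariates=back_cov,
    )


def _response_curves(report: SpeciesReport, back_cov: pd.DataFrame, n_grid: int = 50) -> pd.DataFrame:
    """Per-variable response: sweep one variable, others at background mean/mode."""
    model = report.final_model
    exp = model.expansion
    rows = []
    for var in exp.variables:
        base = {}
        for other in exp.variables:
            col = back_cov[other]
            if other in exp.categories:
                base[other] = col.mode().iloc[0]
            else:
                base[other] = float(col.mean())
        if var in exp.categories:
            grid = exp.categories[var]
        else:
            vmin, vmax = exp.scaling[var]
            grid = np.linspace(vmin, vmax, n_grid)
        sweep = pd.DataFrame([dict(base, **{var: g}) for g in grid])
        scores = predict(model, sweep, output="cloglog")
        for g, s in zip(grid, scores):
            rows.append({"variable": var, "value": float(g), "cloglog": float(s)})
    return pd.DataFrame(rows)


def export_report(report: SpeciesReport, out_dir, overwrite: bool = False) -> list[Path]:
    """Write the five per-species artefacts.

    Suitability raster (.asc), contribution CSV (variable, percent,
    cumulative — rows until cumulative >= the reporting threshold),
    evaluation CSV (per-fold and mean AUC/omission, Boyce, AUC band,
    null-model p), response-curve CSV, and a metadata JSON with seeds,
    settings and the selection traces.
    """
    from .io import write_ascii_grid

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    slug = report.species.replace(" ", "_")
    paths = {
        "suitability": out / f"{slug}_suitability.asc",
        "contribution": out / f"{slug}_contribution.csv",
        "evaluation": out / f"{slug}_evaluation.csv",
        "response_curves": out / f"{slug}_response_curves.csv",
        "metadata": out / f"{slug}_metadata.json",
    }
    for p in paths.values():
        if p.exists() and not overwrite:
            raise FileExistsError(f"refusing to overwrite existing file {p}")
    write_ascii_grid(report.suitability, paths["suitability"])
    ctab = report.contribution.rename(columns={"contribution": "percent"})
    ctab.to_csv(paths["contribution"], index=False)
    ev_rows = [
        {"fold": i + 1, "test_auc": a, "omission": o}
        for i, (a, o) in enumerate(zip(report.cv.fold_auc, report.cv.fold_omission))
    ]
    ev_rows.append(
        {
            "fold": "mean",
            "test_auc": report.cv.mean_auc,
            "omission": report.cv.mean_omission,
            "boyce": report.boyce,
            "auc_band": report.auc_band,
            "null_p": report.null.empirical_p,
            "null_significant": report.null.significant,
        }
    )
    pd.DataFrame(ev_rows).to_csv(paths["evaluation"], index=False)
    back_cov = report.background_covariates
    if back_cov is None:
        # baselines degrade to scaling midpoints when covariates were not kept
        exp = report.final_model.expansion
        back_cov = pd.DataFrame(
            {
                var: [exp.categories[var][0]] if var in exp.categories
                else [sum(exp.scaling[var]) / 2.0]
                for var in exp.variables
            }
        )
    _response_curves(report, back_cov).to_csv(paths["response_curves"], index=False)
    paths["metadata"].write_text(json.dumps(report.metadata, indent=2, default=_json_safe))
    return list(paths.values())


def _json_safe(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
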