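"""Eight-step workflow for constructing and selecting a trajectory model.

The steps, run end-to-end by :func:`run_pipeline` or individually:

1.  scoping — fit a fixed-effects-only model at a provisional class count
    and inspect per-subject standardised-residual profiles to suggest the
    random-effect order (none / intercept / slope / quadratic);
2.  class enumeration — sweep the number of classes K, choose the lowest
    BIC among converged fits;
3.  structure refinement — sweep the covariance structures A-G at the
    chosen K;
4.  adequacy — APPA / OCC / relative-entropy thresholds, balanced against
    BIC in :func:`select_favoured`;
5.  graphics — plot-ready tables of class mean trajectories, 95%
    predictive bands and a seeded spaghetti sample;
6.  discrimination — degrees of separation and residual envelopes;
7.  characterisation — concordance of latent classes with an external
    ordinal categorisation (e.g. baseline BMI bands) via weighted kappa;
8.  sensitivity — refits restricted to subjects with at least m
    observations, compared against the main model.

Every sweep carries failed fits as explicit records; nothing is silently
dropped.  All outputs are plain tables (CSV) or JSON; rendering is left to
the caller.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .adequacy import AdequacyReport, adequacy_report
from .data_model import (
    ConfigurationError,
    DataError,
    FittedModel,
    ModelStructure,
    STRUCTURE_CODES,
    SufficientSummaries,
    TimeTransform,
    TrajectoryDataset,
    build_design,
    posterior_to_frame,
)
from .discrimination import (
    ConcordanceTable,
    cross_tabulate,
    degrees_of_separation,
    envelope_residuals,
    model_concordance,
    weighted_kappa,
)
from .gmm_fit import FitConfig, NonConvergenceError, bic, fit, marginal_covariance

__all__ = [
    "FrameworkConfig",
    "ScopingResult",
    "SweepRecord",
    "SweepResult",
    "SelectionRecord",
    "step1_scoping",
    "sweep_classes",
    "sweep_structures",
    "select_favoured",
    "plot_data",
    "bmi_categories",
    "concordance_vs_categories",
    "sensitivity_refit",
    "run_pipeline",
]

#: WHO BMI band cut-points (kg/m^2) used for the default external categorisation
DEFAULT_CATEGORY_CUTS = (18.5, 25.0, 30.0, 35.0)

DEFAULT_GRID = (18.0, 35.0, 50.0, 62.5)


@dataclass(frozen=True)
class FrameworkConfig:
    """Configuration of the full eight-step run."""

    k_range: tuple = (1, 2, 3, 4, 5, 6, 7)
    structures: tuple = STRUCTURE_CODES
    scoping_k: int = 5
    fixed_degree: int = 2
    fit: FitConfig = field(default_factory=FitConfig)
    grid: tuple = DEFAULT_GRID
    spaghetti_sample: int = 50
    sensitivity_min_obs: tuple = (2, 3)
    category_cuts: tuple = DEFAULT_CATEGORY_CUTS
    scoping_ratio_threshold: float = 2.0
    min_class_advisory: float = 0.01
    time_transform: TimeTransform = field(default_factory=TimeTransform)

    def __post_init__(self) -> None:
        if not self.k_range:
            raise ConfigurationError("k_range must be non-empty")
        if not (1 <= self.scoping_k <= 10):
            raise ConfigurationError("scoping_k should be between 1 and 10")
        for code in self.structures:
            if code not in STRUCTURE_CODES:
                raise ConfigurationError(f"unknown structure code {code!r}")

    def structure(self, code: str, n_classes: int) -> ModelStructure:
        return ModelStructure(structure_code=code, n_classes=n_classes,
                              fixed_degree=self.fixed_degree,
                              time_transform=self.time_transform)

    @classmethod
    def from_yaml(cls, path) -> "FrameworkConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        fit_cfg = FitConfig(**raw.pop("fit", {}))
        tt = TimeTransform(**raw.pop("time_transform", {}))
        for key in ("k_range", "structures", "grid", "sensitivity_min_obs", "category_cuts"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(fit=fit_cfg, time_transform=tt, **raw)


# --------------------------------------------------------------------------
# Step 1: scoping
# --------------------------------------------------------------------------

@dataclass
class ScopingResult:
    """Suggested random-effect order from standardised-residual profiles.

    ``suggestion`` is 0 (intercept), 1 (slope) or 2 (quadratic); ``None``
    means the profiles are flat noise and no random effect is indicated.
    ``variance_ratios[k, j]`` compares the between-subject dispersion of
    the order-``j`` per-subject residual-polynomial coefficient in class
    ``k`` with its expectation under pure within-subject noise; a ratio
    near 1 is noise, well above 1 indicates a subject-level random effect
    of that order.
    """

    suggestion: int | None
    variance_ratios: np.ndarray     # (K, 3)
    threshold: float
    scoping_model: FittedModel

    def to_dict(self) -> dict:
        return {"suggestion": self.suggestion,
                "variance_ratios": self.variance_ratios.tolist(),
                "threshold": self.threshold}


def step1_scoping(dataset: TrajectoryDataset, scoping_k: int = 5,
                  config: FrameworkConfig | None = None) -> ScopingResult:
    """Fit a no-random-effects model and read off the residual structure.

    For each class (posterior weights) and each order ``j`` in 0..2, the
    residuals of the fixed-effects-only fit are regressed, per subject, on
    a degree-``j`` polynomial in transformed time; a subject-level random
    effect of order ``j`` inflates the across-subject mean square of the
    top coefficient above its pure-noise value ``[(T_j' T_j)^{-1}]_jj
    sigma_e^2``, where ``sigma_e^2`` is the within-subject noise variance
    estimated from each subject's highest-degree residual mean square
    (which is free of subject-level polynomial effects).  A ratio above
    the threshold (default 2) marks the order as present; the suggestion
    is the highest order present in any class.
    """
    config = config or FrameworkConfig()
    structure = config.structure("A", scoping_k)
    model = fit(dataset, structure, config.fit)
    if not model.converged:
        raise NonConvergenceError(
            "scoping model did not converge; consider fewer provisional classes")
    design = build_design(dataset, structure)
    K = scoping_k
    coef_sq = np.zeros((K, 3))     # weighted mean square of top coefficient
    coef_w = np.zeros((K, 3))
    noise_fac = np.zeros((K, 3))   # weighted mean of [(T_j'T_j)^{-1}]_jj
    rss_w = np.zeros(K)            # pooled within-subject residual SS / df
    df_w = np.zeros(K)
    for i, s in enumerate(design.subjects):
        max_deg = min(2, s.n_obs - 2)  # keep >= 1 residual df
        if max_deg < 0:
            continue
        post_i = model.posterior[i]
        for k in range(K):
            w = post_i[k]
            if w <= 1e-12:
                continue
            r = s.y - s.X @ model.beta[k]
            for j in range(max_deg + 1):
                Tj = s.X[:, : j + 1]
                Gj = np.linalg.inv(Tj.T @ Tj)
                c = Gj @ (Tj.T @ r)
                coef_sq[k, j] += w * c[j] ** 2
                coef_w[k, j] += w
                noise_fac[k, j] += w * Gj[j, j]
                if j == max_deg:
                    rss = float(r @ r - c @ (Tj.T @ r))
                    rss_w[k] += w * max(rss, 0.0)
                    df_w[k] += w * (s.n_obs - j - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ve = np.where(df_w > 0, rss_w / df_w, np.nan)          # (K,)
        ratios = (coef_sq / coef_w) / ((noise_fac / coef_w) * ve[:, None])
    present = np.nanmax(ratios, axis=0) > config.scoping_ratio_threshold
    orders = np.where(present)[0]
    suggestion = int(orders.max()) if orders.size else None
    return ScopingResult(suggestion=suggestion, variance_ratios=ratios,
                         threshold=config.scoping_ratio_threshold,
                         scoping_model=model)


# --------------------------------------------------------------------------
# Steps 2-3: sweeps
# --------------------------------------------------------------------------

@dataclass
class SweepRecord:
    """One candidate fit in a sweep; failures are first-class rows."""

    key: object                     # K (step 2) or structure code (step 3)
    structure: ModelStructure
    model: FittedModel | None
    converged: bool
    bic: float | None
    proportions: list | None
    appa: list | None
    relative_entropy: float | None
    dos: float | None
    error: str | None = None
    adequacy: AdequacyReport | None = None

    def row(self) -> dict:
        return {
            "candidate": self.key,
            "n_params": None if self.model is None else self.model.n_params,
            "converged": self.converged,
            "bic": self.bic,
            "proportions_pct": None if self.proportions is None
            else ": ".join(f"{100 * p:.1f}" for p in self.proportions),
            "appa": None if self.appa is None
            else ": ".join("-" if np.isnan(a) else f"{a:.2f}" for a in self.appa),
            "relative_entropy": self.relative_entropy,
            "dos": self.dos,
            "error": self.error,
        }


@dataclass
class SweepResult:
    records: list[SweepRecord]
    best_key: object | None         # lowest BIC among converged candidates

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame([r.row() for r in self.records])
        frame["selected"] = frame["candidate"] == self.best_key
        return frame

    def record(self, key) -> SweepRecord:
        for r in self.records:
            if r.key == key:
                return r
        raise KeyError(key)

    def converged_records(self) -> list[SweepRecord]:
        return [r for r in self.records if r.converged]


def _fit_record(key, dataset, structure: ModelStructure, fit_config: FitConfig,
                grid) -> SweepRecord:
    try:
        model = fit(dataset, structure, fit_config)
    except (NonConvergenceError, DataError) as exc:
        return SweepRecord(key=key, structure=structure, model=None, converged=False,
                           bic=None, proportions=None, appa=None,
                           relative_entropy=None, dos=None, error=str(exc))
    if not model.converged:
        return SweepRecord(key=key, structure=structure, model=model, converged=False,
                           bic=None, proportions=model.pi.tolist(), appa=None,
                           relative_entropy=None, dos=None,
                           error="failed to converge")
    adq = adequacy_report(model)
    dos = None
    if model.n_classes >= 2:
        try:
            dos = degrees_of_separation(model, np.asarray(grid)).dos
        except Exception as exc:   # singular pooled covariance etc.
            dos = None
    return SweepRecord(key=key, structure=structure, model=model, converged=True,
                       bic=bic(model), proportions=model.pi.tolist(),
                       appa=adq.appa.tolist(),
                       relative_entropy=adq.relative_entropy, dos=dos,
                       adequacy=adq)


def _mark_best(records: list[SweepRecord]):
    ok = [r for r in records if r.converged and r.bic is not None]
    return min(ok, key=lambda r: r.bic).key if ok else None


def sweep_classes(dataset: TrajectoryDataset, structure_code: str,
                  k_range=None, config: FrameworkConfig | None = None) -> SweepResult:
    """Step 2: one fit per candidate class count; lowest-BIC K marked."""
    config = config or FrameworkConfig()
    k_range = tuple(k_range) if k_range is not None else config.k_range
    records = []
    for K in k_range:
        structure = config.structure(structure_code, K)
        fc = dataclasses.replace(config.fit, seed=config.fit.seed + 10 * K)
        records.append(_fit_record(K, dataset, structure, fc, config.grid))
    return SweepResult(records=records, best_key=_mark_best(records))


def sweep_structures(dataset: TrajectoryDataset, n_classes: int,
                     structures=None, config: FrameworkConfig | None = None) -> SweepResult:
    """Step 3: one fit per structure code at fixed K, reported A -> G."""
    config = config or FrameworkConfig()
    structures = tuple(structures) if structures is not None else config.structures
    codes = [c for c in STRUCTURE_CODES if c in structures]
    records = []
    for i, code in enumerate(codes):
        structure = config.structure(code, n_classes)
        fc = dataclasses.replace(config.fit, seed=config.fit.seed + 100 + i)
        records.append(_fit_record(code, dataset, structure, fc, config.grid))
    return SweepResult(records=records, best_key=_mark_best(records))


# --------------------------------------------------------------------------
# Step 4: selection
# --------------------------------------------------------------------------

@dataclass
class SelectionRecord:
    """Outcome of balancing BIC against the adequacy criteria.

    When no candidate satisfies every adequacy threshold the lowest-BIC
    converged candidate is returned with its violations listed — the
    final judgement is surfaced to the analyst, not automated away.
    """

    key: object
    model: FittedModel
    bic: float
    adequacy_passed: bool
    violations: list[str]
    override_reason: str | None
    small_classes: list[int]

    def to_dict(self) -> dict:
        return {"selected": self.key, "bic": self.bic,
                "adequacy_passed": self.adequacy_passed,
                "violations": self.violations,
                "override_reason": self.override_reason,
                "small_classes": self.small_classes}


def select_favoured(sweep: SweepResult,
                    config: FrameworkConfig | None = None) -> SelectionRecord:
    """Lowest-BIC candidate whose adequacy criteria all pass, else the
    lowest-BIC candidate flagged with its violations."""
    config = config or FrameworkConfig()
    ok = sweep.converged_records()
    if not ok:
        raise NonConvergenceError("no converged candidates to select from")
    ranked = sorted(ok, key=lambda r: r.bic)
    chosen = None
    override = None
    for r in ranked:
        if r.adequacy is not None and r.adequacy.all_met:
            chosen = r
            break
    if chosen is None:
        chosen = ranked[0]
    elif chosen is not ranked[0]:
        override = (f"candidate {ranked[0].key} has lower BIC but violates adequacy "
                    f"criteria; {chosen.key} selected instead")
    violations = []
    if chosen.adequacy is not None:
        violations = [name for name, met in chosen.adequacy.thresholds_met.items() if not met]
    small = [k for k, p in enumerate(chosen.model.pi)
             if p < config.min_class_advisory]
    return SelectionRecord(key=chosen.key, model=chosen.model, bic=chosen.bic,
                           adequacy_passed=not violations, violations=violations,
                           override_reason=override, small_classes=small)


# --------------------------------------------------------------------------
# Step 5: plot data
# --------------------------------------------------------------------------

def plot_data(model: FittedModel, dataset: TrajectoryDataset, grid=None,
              spaghetti_sample: int = 50, seed: int = 0) -> dict[str, pd.DataFrame]:
    """Plot-ready tables: mean trajectories, 95% predictive bands, spaghetti.

    The predictive band is ``mean +/- 1.96 sqrt(diag(Z B_k Z' + sigma_k^2))``
    — the marginal subject-level variation within the class, constant in
    time for fixed-effects-only structures and widening wherever the
    random effects inflate the marginal variance.
    """
    grid = np.asarray(grid if grid is not None else DEFAULT_GRID, dtype=float)
    s = model.structure
    t = s.time_transform.apply(grid)
    X = np.vander(t, s.fixed_degree + 1, increasing=True)
    Z = X[:, : s.n_random]
    rows_traj, rows_band = [], []
    for k in range(model.n_classes):
        mu = X @ model.beta[k]
        V = marginal_covariance(model, Z, k)
        half = 1.96 * np.sqrt(np.diag(V))
        for j, tt_ in enumerate(grid):
            rows_traj.append({"class": k + 1, "time": tt_, "mean": mu[j]})
            rows_band.append({"class": k + 1, "time": tt_, "mean": mu[j],
                              "lower": mu[j] - half[j], "upper": mu[j] + half[j]})
    rng = np.random.default_rng(seed)
    ids = model.subject_ids
    take = min(spaghetti_sample, len(ids))
    sample = rng.choice(len(ids), size=take, replace=False)
    chosen = set(np.asarray(ids, dtype=object)[sample])
    assign = {sid: int(a) + 1 for sid, a in zip(ids, model.assignment)}
    frame = dataset.frame
    spag = frame[frame["id"].isin(chosen)].copy()
    spag["class"] = spag["id"].map(assign)
    return {"trajectories": pd.DataFrame(rows_traj),
            "bands": pd.DataFrame(rows_band),
            "spaghetti": spag.reset_index(drop=True)}


# --------------------------------------------------------------------------
# Step 7: concordance with an external categorisation
# --------------------------------------------------------------------------

def bmi_categories(values: np.ndarray, cuts=DEFAULT_CATEGORY_CUTS) -> np.ndarray:
    """Ordinal category index per value from ascending cut-points."""
    return np.searchsorted(np.asarray(cuts, dtype=float), np.asarray(values, dtype=float),
                           side="right")


def concordance_vs_categories(model: FittedModel, categories: np.ndarray,
                              weights: str = "quadratic",
                              optimize_assignment: bool = False,
                              n_categories: int | None = None) -> ConcordanceTable:
    """Cross-tabulate latent classes against an external ordinal categorisation.

    ``categories`` must supply one ordinal index per fitted subject, in
    subject order.  Quadratic disagreement weights are the default for the
    weighted kappa on ordinal bands; set ``optimize_assignment`` to
    maximise over class-label permutations instead of taking the stored
    canonical order.
    """
    categories = np.asarray(categories)
    if categories.shape[0] != model.n_subjects:
        raise DataError(
            f"need one category per subject ({model.n_subjects}), got {categories.shape[0]}")
    if np.isnan(categories.astype(float)).any():
        raise DataError("missing categories present")
    n_cat = n_categories or int(categories.max()) + 1
    table = cross_tabulate(model.assignment, categories.astype(int),
                           n_rows=model.n_classes, n_cols=n_cat)
    kap, assign = weighted_kappa(table, "unweighted", optimize_assignment)
    kap_w, assign_w = weighted_kappa(table, weights, optimize_assignment)
    return ConcordanceTable(table=table,
                            row_labels=[f"class_{k+1}" for k in range(model.n_classes)],
                            col_labels=[f"cat_{c+1}" for c in range(n_cat)],
                            kappa=kap, kappa_weighted=kap_w, weighting=weights,
                            assignment=assign_w)


# --------------------------------------------------------------------------
# Step 8: sensitivity refits
# --------------------------------------------------------------------------

def sensitivity_refit(dataset: TrajectoryDataset, structure: ModelStructure,
                      reference: FittedModel, min_obs_list=(2, 3),
                      fit_config: FitConfig | None = None,
                      grid=None) -> list[dict]:
    """Refit on subjects with >= m observations, for each m.

    Reports per m: class proportions, the maximum absolute deviation of
    each aligned class mean trajectory from the reference on the grid, and
    the unweighted kappa between the two modal assignments on the shared
    subjects (after optimal class alignment).  Failures are recorded rows.
    """
    fit_config = fit_config or FitConfig()
    grid = np.asarray(grid if grid is not None else DEFAULT_GRID, dtype=float)
    out = []
    for m in min_obs_list:
        rec: dict = {"min_obs": int(m)}
        try:
            sub = dataset.filter_min_observations(m)
            model = fit(sub, structure, fit_config)
        except (DataError, NonConvergenceError) as exc:
            rec.update({"failed": True, "error": str(exc)})
            out.append(rec)
            continue
        shared = [i for i, sid in enumerate(model.subject_ids)]
        ref_index = {sid: j for j, sid in enumerate(reference.subject_ids)}
        pairs = [(i, ref_index[sid]) for i, sid in enumerate(model.subject_ids)
                 if sid in ref_index]
        sub_assign = np.array([model.assignment[i] for i, _ in pairs])
        ref_assign = np.array([reference.assignment[j] for _, j in pairs])
        table = cross_tabulate(sub_assign, ref_assign,
                               n_rows=model.n_classes, n_cols=reference.n_classes)
        kap, perm = weighted_kappa(table, "unweighted", optimize_assignment=True)
        dev = np.full(reference.n_classes, np.nan)
        for r, orig in enumerate(perm):
            if r < reference.n_classes and orig < model.n_classes:
                dev[r] = float(np.max(np.abs(model.mean_trajectory(grid, orig)
                                             - reference.mean_trajectory(grid, r))))
        rec.update({
            "failed": False,
            "n_subjects": model.n_subjects,
            "converged": model.converged,
            "proportions": model.pi.tolist(),
            "kappa_vs_main": kap,
            "max_trajectory_deviation": dev.tolist(),
        })
        out.append(rec)
    return out


# --------------------------------------------------------------------------
# End-to-end pipeline
# --------------------------------------------------------------------------

_SUGGESTION_TO_CODE = {None: "A", 0: "C", 1: "D", 2: "F"}


@dataclass
class PipelineResult:
    scoping: ScopingResult
    class_sweep: SweepResult
    structure_sweep: SweepResult
    selection: SelectionRecord
    plots: dict[str, pd.DataFrame]
    discrimination: dict
    concordance: ConcordanceTable
    model_agreement: dict | None
    sensitivity: list[dict]
    log: dict


def run_pipeline(dataset: TrajectoryDataset, config: FrameworkConfig | None = None,
                 out_dir=None) -> PipelineResult:
    """Run steps 1-8 and (optionally) write every report to ``out_dir``.

    Identical dataset, configuration and seed produce byte-identical
    report files.
    """
    config = config or FrameworkConfig()
    log: dict = {"seed": config.fit.seed, "fits": []}

    scoping = step1_scoping(dataset, config.scoping_k, config)
    working_code = _SUGGESTION_TO_CODE.get(scoping.suggestion, "F")
    if working_code not in config.structures:
        working_code = config.structures[0]
    log["scoping_suggestion"] = scoping.suggestion
    log["working_structure"] = working_code

    class_sweep = sweep_classes(dataset, working_code, config.k_range, config)
    if class_sweep.best_key is None:
        raise NonConvergenceError("no class count converged in step 2")
    K = int(class_sweep.best_key)
    log["selected_k"] = K

    structure_sweep = sweep_structures(dataset, K, config.structures, config)
    selection = select_favoured(structure_sweep, config)
    favoured = selection.model
    log["selected_structure"] = selection.key

    plots = plot_data(favoured, dataset, config.grid, config.spaghetti_sample,
                      seed=config.fit.seed)

    disc = degrees_of_separation(favoured, np.asarray(config.grid))
    envelope = envelope_residuals(favoured, dataset)
    discrimination = {"dos": disc.to_dict(),
                      "envelope_parallel": envelope.parallel.tolist()}

    baseline = dataset.baseline_values()
    baseline = baseline.reindex(pd.Index(favoured.subject_ids))
    cats = bmi_categories(baseline.to_numpy(), config.category_cuts)
    concordance = concordance_vs_categories(favoured, cats,
                                            n_categories=len(config.category_cuts) + 1)

    agreement = None
    others = [r for r in structure_sweep.converged_records() if r.key != selection.key]
    if others:
        runner_up = min(others, key=lambda r: r.bic)
        if runner_up.model.n_classes == favoured.n_classes:
            agreement = {"runner_up": runner_up.key,
                         **model_concordance(favoured, runner_up.model).to_dict()}

    sensitivity = sensitivity_refit(dataset, favoured.structure, favoured,
                                    config.sensitivity_min_obs, config.fit,
                                    config.grid)

    for rec in class_sweep.records + structure_sweep.records:
        log["fits"].append({"candidate": str(rec.key), "converged": rec.converged,
                            "n_iter": None if rec.model is None else rec.model.n_iter,
                            "seed": None if rec.model is None else rec.model.seed,
                            "error": rec.error})

    result = PipelineResult(scoping=scoping, class_sweep=class_sweep,
                            structure_sweep=structure_sweep, selection=selection,
                            plots=plots, discrimination=discrimination,
                            concordance=concordance, model_agreement=agreement,
                            sensitivity=sensitivity, log=log)
    if out_dir is not None:
        _write_reports(result, favoured, envelope, Path(out_dir))
    return result


def _write_reports(result: PipelineResult, favoured: FittedModel,
                   envelope, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)

    def dump(name: str, obj) -> None:
        with open(out_dir / name, "w") as fh:
            json.dump(obj, fh, indent=1, sort_keys=True, default=_json_default)

    result.class_sweep.to_frame().to_csv(out_dir / "step2_classes.csv", index=False)
    result.structure_sweep.to_frame().to_csv(out_dir / "step3_structures.csv", index=False)
    dump("scoping.json", result.scoping.to_dict())
    adequacies = {str(r.key): r.adequacy.to_dict()
                  for r in result.structure_sweep.records if r.adequacy is not None}
    dump("adequacy.json", adequacies)
    dump("selection.json", result.selection.to_dict())
    result.plots["trajectories"].to_csv(out_dir / "trajectories.csv", index=False)
    result.plots["bands"].to_csv(out_dir / "bands.csv", index=False)
    result.plots["spaghetti"].to_csv(out_dir / "spaghetti.csv", index=False)
    dump("discrimination.json", result.discrimination)
    envelope.to_frame().to_csv(out_dir / "envelope.csv", index=False)
    dump("concordance_categories.json", result.concordance.to_dict())
    if result.model_agreement is not None:
        dump("concordance_models.json", result.model_agreement)
    dump("sensitivity.json", result.sensitivity)
    dump("log.json", result.log)
    favoured.save_json(out_dir / "favoured_model.json")
    posterior_to_frame(favoured).to_csv(out_dir / "posterior.csv", index=False)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
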