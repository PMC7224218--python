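"""Configuration-driven orchestration of the full analysis.

A study runs env-space construction, COUE decomposition, conservatism tests,
hypervolume comparison, and ensemble niche modelling in sequence, writing
tidy CSV analogues of the three summary tables plus density grids, masks,
suitability rasters, and a run log.  All randomness derives from one global
seed via a spawned generator hierarchy, so runs are idempotent.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coue as coue_mod
from . import enm as enm_mod
from .conservatism import equivalency_test, similarity_test
from .envspace import build_grid, fit_env_space, occurrence_density, project
from .errors import ConfigurationError, NicheShiftError
from .hypervolume import build_hypervolume, compare_hypervolumes
from .occurrences import OccurrenceSet, read_occurrences, write_occurrences
from .raster import write_ascii_grid, Raster
from .synthetic import (BackgroundConfig, Backgrounds, NicheTruth,
                        make_env_backgrounds, make_raster_stack,
                        simulate_species)

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "niche", "tests", "hypervolume", "enm")


@dataclass
class StudyConfig:
    """Validated study configuration; one global seed drives every stage."""

    seed: int = 0
    outdir: str = "study_out"
    grid_resolution: int = 100
    n_components: int = 2
    percentiles: tuple[int, ...] = (75, 100)
    synthetic: dict | None = None
    inputs: dict | None = None
    tests: dict = field(default_factory=lambda: {"n_reps": 199})
    hypervolume: dict = field(default_factory=lambda: {
        "boundary_quantiles": [75, 100], "n_random": 10000, "n_components": 2,
    })
    enm: dict = field(default_factory=lambda: {
        "learners": list(enm_mod.DEFAULT_LEARNERS), "n_pseudo": 1000,
        "eval_frac": 0.3, "inner_test_frac": 0.3, "n_repeats": 10,
    })
    stage_seeds: dict = field(default_factory=dict)  # per-stage overrides

    def __post_init__(self) -> None:
        self.percentiles = tuple(int(p) for p in self.percentiles)
        if self.synthetic is None and self.inputs is None:
            raise ConfigurationError(
                "config needs either a 'synthetic' scenario or 'inputs' paths"
            )
        if self.grid_resolution < 10:
            raise ConfigurationError("grid_resolution must be >= 10")
        if self.inputs is not None:
            required = ("native_occurrences", "invaded_occurrences",
                        "native_background", "invaded_background")
            missing = [k for k in required if k not in self.inputs]
            if missing:
                raise ConfigurationError(f"inputs missing key(s): {missing}")
            for key in required:
                if not Path(self.inputs[key]).exists():
                    raise ConfigurationError(
                        f"input path does not exist: {self.inputs[key]}"
                    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed, "outdir": self.outdir,
            "grid_resolution": self.grid_resolution,
            "n_components": self.n_components,
            "percentiles": list(self.percentiles),
            "synthetic": self.synthetic, "inputs": self.inputs,
            "tests": self.tests, "hypervolume": self.hypervolume,
            "enm": self.enm, "stage_seeds": self.stage_seeds,
        }
        return d

    @property
    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("outdir")  # where outputs land does not change the science
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class StudyReport:
    """Everything a study produced, plus where it was written."""

    config: StudyConfig
    outdir: Path
    coue_table: pd.DataFrame | None = None
    hypervolume_table: pd.DataFrame | None = None
    enm_table: pd.DataFrame | None = None
    coue_metrics: dict = field(default_factory=dict)
    test_results: dict = field(default_factory=dict)
    truth: NicheTruth | None = None


def _stage_seeds(seed: int, overrides: dict | None = None) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(ALL_STAGES))
    seeds = {
        stage: int(child.generate_state(1)[0] % (2**31))
        for stage, child in zip(ALL_STAGES, children)
    }
    for stage, s in (overrides or {}).items():
        if stage not in seeds:
            raise ConfigurationError(f"unknown stage in stage_seeds: {stage!r}")
        seeds[stage] = int(s)
    return seeds


def _write_table(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    out = df.copy()
    out["config_hash"] = config_hash
    out.to_csv(path, index=False, lineterminator="\r\n")


def _load_data(cfg: StudyConfig, seeds: dict[str, int], outdir: Path):
    """Return (occ_native, occ_invaded, backgrounds, variables, truth)."""
    if cfg.synthetic is not None:
        bg_kwargs = dict(cfg.synthetic.get("background", {}))
        bg_kwargs.setdefault("seed", seeds["simulate"])
        bg_cfg = BackgroundConfig(**bg_kwargs)
        backgrounds = make_env_backgrounds(bg_cfg)
        truth_kwargs = dict(cfg.synthetic.get("truth", {}))
        truth_kwargs.setdefault("centroid_native", [0.0] * bg_cfg.k)
        truth_kwargs.setdefault("centroid_shift", [0.0] * bg_cfg.k)
        truth_kwargs.setdefault("niche_sd", 1.0)
        truth_kwargs.setdefault("seed", seeds["simulate"] + 1)
        truth = NicheTruth(**truth_kwargs)
        sim = simulate_species(truth, backgrounds)
        occ_nat, occ_inv = sim.native, sim.invaded
        write_occurrences(occ_nat, outdir / "occurrences_native.csv")
        write_occurrences(occ_inv, outdir / "occurrences_invaded.csv")
        backgrounds.native.to_csv(outdir / "background_native.csv", index=False)
        backgrounds.invaded.to_csv(outdir / "background_invaded.csv", index=False)
        truth.to_json(outdir / "truth.json")
        if bg_cfg.resolution is not None:
            for label, bg in (("native", backgrounds.native),
                              ("invaded", backgrounds.invaded)):
                stack = make_raster_stack(bg, bg_cfg.resolution,
                                          backgrounds.variables)
                for var in stack.names:
                    write_ascii_grid(stack[var],
                                     outdir / f"raster_{label}_{var}.asc")
        variables = backgrounds.variables
        return occ_nat, occ_inv, backgrounds, variables, truth

    occ_nat = read_occurrences(cfg.inputs["native_occurrences"])
    occ_inv = read_occurrences(cfg.inputs["invaded_occurrences"])
    bg_nat = pd.read_csv(cfg.inputs["native_background"])
    bg_inv = pd.read_csv(cfg.inputs["invaded_background"])
    variables = cfg.inputs.get("variables")
    if variables is None:
        variables = [c for c in bg_nat.columns if c not in ("lon", "lat")]
    backgrounds = Backgrounds(
        native=bg_nat, invaded=bg_inv,
        config=BackgroundConfig(n_points=max(10, len(bg_nat)),
                                k=max(2, len(variables))),
    )
    return occ_nat, occ_inv, backgrounds, variables, None


def run_study(cfg: StudyConfig, stages: tuple[str, ...] = ALL_STAGES) -> StudyReport:
    """Execute the pipeline stages in order, writing all artifacts to
    ``cfg.outdir``.  Any stage error aborts with the stage name; artifacts
    from completed stages are preserved."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(yaml.safe_dump(cfg.to_dict()))
    seeds = _stage_seeds(cfg.seed, cfg.stage_seeds)
    report = StudyReport(config=cfg, outdir=outdir)
    chash = cfg.config_hash
    logger.info("study %s -> %s (stages: %s)", chash, outdir, ",".join(stages))

    def write_log() -> None:
        (outdir / "run_log.json").write_text(json.dumps({
            "config_hash": chash, "seed": cfg.seed, "stage_seeds": seeds,
            "stages": list(stages),
        }, indent=1))

    stage = "simulate"
    try:
        occ_nat, occ_inv, backgrounds, variables, truth = _load_data(
            cfg, seeds, outdir)
        report.truth = truth
        if stages == ("simulate",):
            write_log()
            return report

        # --- environmental space and gridded niches (needed by most stages)
        stage = "niche"
        model = fit_env_space(backgrounds.native[variables],
                              backgrounds.invaded[variables],
                              n_components=max(
                                  cfg.n_components,
                                  int(cfg.hypervolume.get("n_components", 2))))
        bg_scores_nat = project(backgrounds.native[variables], model)
        bg_scores_inv = project(backgrounds.invaded[variables], model)
        occ_scores_nat = project(occ_nat.data[variables], model)
        occ_scores_inv = project(occ_inv.data[variables], model)
        model.to_json(outdir / "env_space_model.json")

        grid = build_grid(bg_scores_nat, bg_scores_inv, cfg.grid_resolution)
        grid_nat = occurrence_density(occ_scores_nat, bg_scores_nat, grid,
                                      cfg.percentiles)
        grid_inv = occurrence_density(occ_scores_inv, bg_scores_inv, grid,
                                      cfg.percentiles)
        wx, wy = grid.cell_width
        for label, g in (("native", grid_nat), ("invaded", grid_inv)):
            write_ascii_grid(
                Raster(data=g.z.T[::-1], xll=grid.xmin + wx / 2,
                       yll=grid.ymin + wy / 2, cellsize=wx),
                outdir / f"density_{label}.asc")
            for p in cfg.percentiles:
                write_ascii_grid(
                    Raster(data=g.mask(p).T[::-1].astype(float),
                           xll=grid.xmin + wx / 2, yll=grid.ymin + wy / 2,
                           cellsize=wx),
                    outdir / f"mask_{label}_I{p}.asc")

        if "niche" in stages:
            metrics = coue_mod.compute_coue_metrics(grid_nat, grid_inv,
                                                    cfg.percentiles)
            report.coue_metrics = {"metrics": metrics}
            rows = []
            for p in cfg.percentiles:
                rows.append({
                    "percentile": p,
                    "stability_pct": 100 * metrics.stability[p],
                    "unfilling_pct": 100 * metrics.unfilling[p],
                    "expansion_pct": 100 * metrics.expansion[p],
                    "expansion_nonanalog_pct":
                        100 * metrics.expansion_nonanalog[p],
                    "topology": metrics.topology[p],
                    "schoener_d": metrics.schoener_d,
                    "centroid_shift_magnitude":
                        metrics.centroid_shift_magnitude,
                })
            report.coue_table = pd.DataFrame(rows)

        if "tests" in stages:
            stage = "tests"
            n_reps = int(cfg.tests.get("n_reps", 199))
            eq = equivalency_test(occ_scores_nat, occ_scores_inv,
                                  bg_scores_nat, bg_scores_inv, grid,
                                  n_reps=n_reps, seed=seeds["tests"])
            sim_both = similarity_test(grid_nat, grid_inv, "N<->P",
                                       n_reps=n_reps, seed=seeds["tests"] + 1)
            sim_one = similarity_test(grid_nat, grid_inv, "N->P",
                                      n_reps=n_reps, seed=seeds["tests"] + 2)
            report.test_results = {
                "equivalency": eq, "similarity_both": sim_both,
                "similarity_one": sim_one,
            }
            for name, res in report.test_results.items():
                res.to_json(outdir / f"test_{name}.json")
                res.null_histogram(outdir / f"test_{name}_null.csv")
            if report.coue_table is not None:
                report.coue_table["equivalency_p"] = eq.p_value
                report.coue_table["similarity_p_N<->P"] = sim_both.p_value
                report.coue_table["similarity_p_N->P"] = sim_one.p_value
        if report.coue_table is not None:
            _write_table(report.coue_table, outdir / "coue_metrics.csv", chash)

        if "hypervolume" in stages:
            stage = "hypervolume"
            hv_cfg = cfg.hypervolume
            k_hv = int(hv_cfg.get("n_components", 2))
            n_random = int(hv_cfg.get("n_random", 10000))
            rows = []
            for i, q in enumerate(hv_cfg.get("boundary_quantiles", [75, 100])):
                hv_nat = build_hypervolume(occ_scores_nat[:, :k_hv], q,
                                           n_random=n_random,
                                           seed=seeds["hypervolume"] + 2 * i)
                hv_inv = build_hypervolume(occ_scores_inv[:, :k_hv], q,
                                           n_random=n_random,
                                           seed=seeds["hypervolume"] + 2 * i + 1)
                cmp_ = compare_hypervolumes(hv_nat, hv_inv)
                hv_nat.export_points(outdir / f"hypervolume_native_H{int(q)}.csv")
                hv_inv.export_points(outdir / f"hypervolume_invaded_H{int(q)}.csv")
                rows.append({
                    "boundary_quantile": q,
                    "jaccard": cmp_.jaccard,
                    "centroid_distance": cmp_.centroid_distance,
                    "minimum_distance": cmp_.minimum_distance,
                    "volume_native": cmp_.volume_1,
                    "volume_invaded": cmp_.volume_2,
                    "intersection_volume": cmp_.intersection_volume,
                    "unique_fraction_native_pct": cmp_.unique_fraction_1,
                    "unique_fraction_invaded_pct": cmp_.unique_fraction_2,
                })
            report.hypervolume_table = pd.DataFrame(rows)
            _write_table(report.hypervolume_table,
                         outdir / "hypervolume_metrics.csv", chash)

        if "enm" in stages:
            stage = "enm"
            report.enm_table = _run_enm(cfg, seeds["enm"], occ_nat, occ_inv,
                                        backgrounds, variables, outdir)
            _write_table(report.enm_table, outdir / "enm_evaluation.csv", chash)
    except NicheShiftError as exc:
        raise NicheShiftError(f"stage {stage!r} failed: {exc}") from exc

    write_log()
    return report


def _run_enm(cfg: StudyConfig, seed: int, occ_nat: OccurrenceSet,
             occ_inv: OccurrenceSet, backgrounds: Backgrounds,
             variables: list[str], outdir: Path) -> pd.DataFrame:
    e = cfg.enm
    learners = e.get("learners", list(enm_mod.DEFAULT_LEARNERS))
    n_pseudo = int(e.get("n_pseudo", 1000))

    def make_pa(presences, background, label, pa_seed):
        absences = enm_mod.sample_pseudo_absences(
            background, presences, n=min(n_pseudo, len(background) - len(presences)),
            variables=variables, seed=pa_seed)
        return enm_mod.PADataset(presences=presences, absences=absences,
                                 variables=variables, range_label=label)

    pres_nat = occ_nat.data
    pres_inv = occ_inv.data
    pa_nat = make_pa(pres_nat, backgrounds.native, "native", seed)
    pa_inv = make_pa(pres_inv, backgrounds.invaded, "invaded", seed + 1)
    pa_comb = enm_mod.PADataset(
        presences=pd.concat([pres_nat, pres_inv], ignore_index=True),
        absences=pd.concat([pa_nat.absences, pa_inv.absences],
                           ignore_index=True),
        variables=variables, range_label="combined")

    datasets = {"native": pa_nat, "invaded": pa_inv, "combined": pa_comb}
    rows = []
    ensembles = {}
    for i, (label, pa) in enumerate(datasets.items()):
        plan = enm_mod.split_dataset(
            pa, eval_frac=float(e.get("eval_frac", 0.3)),
            inner_test_frac=float(e.get("inner_test_frac", 0.3)),
            n_repeats=int(e.get("n_repeats", 10)), seed=seed + 10 + i)
        members = enm_mod.fit_members(pa, plan, learners, seed=seed + 20 + i)
        ensemble = enm_mod.build_ensemble(members)
        ensembles[label] = ensemble
        X, y = pa.X, pa.y
        eval_sets = {"E_eval": (X[plan.eval_idx], y[plan.eval_idx])}
        if label in ("native", "combined"):
            eval_sets["E_inv"] = (pa_inv.X, pa_inv.y)
        if label in ("invaded", "combined"):
            eval_sets["E_nat"] = (pa_nat.X, pa_nat.y)
        for set_name, (Xe, ye) in eval_sets.items():
            scores = enm_mod.evaluate_scores(
                ensemble.predict_suitability(Xe), ye)
            member_aucs = []
            member_tsss = []
            for m in members:
                try:
                    s = enm_mod.evaluate_scores(m.predict_suitability(Xe), ye)
                except NicheShiftError:
                    continue
                member_aucs.append(s.auc)
                member_tsss.append(s.tss)
            rows.append({
                "model_range": label, "eval_set": set_name,
                "ensemble_auc": scores.auc, "ensemble_tss": scores.tss,
                "ensemble_auc_band": scores.auc_band,
                "n_members": len(members),
                "member_auc_min": float(np.min(member_aucs)),
                "member_auc_max": float(np.max(member_aucs)),
                "member_tss_min": float(np.min(member_tsss)),
                "member_tss_max": float(np.max(member_tsss)),
            })

    # reciprocal suitability projections + clamping, if rasters are available
    res = (cfg.synthetic or {}).get("background", {}).get("resolution")
    if res:
        for target, bg in (("native", backgrounds.native),
                           ("invaded", backgrounds.invaded)):
            stack = make_raster_stack(bg, res, variables)
            for label, ensemble in ensembles.items():
                raster = enm_mod.project_suitability(ensemble, stack, variables)
                write_ascii_grid(raster,
                                 outdir / f"suitability_{label}_on_{target}.asc")
        clamp = enm_mod.clamping_mask(backgrounds.native[variables],
                                      backgrounds.invaded[variables], variables)
        (outdir / "clamping_native_to_invaded.json").write_text(json.dumps({
            "fractions": clamp.fractions,
            "combined_fraction": clamp.combined_fraction,
        }, indent=1))
    return pd.DataFrame(rows)
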