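"""Reference synthetic scenarios used for validation and calibration studies.

These harnesses wire the synthetic generator through the analysis stages with
fixed, documented geometry so that recovery of known niche dynamics, test
calibration, and model transferability can be measured reproducibly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import enm as enm_mod
from .conservatism import equivalency_test
from .coue import niche_dyn_indices
from .envspace import build_grid, fit_env_space, occurrence_density, project
from .synthetic import (BackgroundConfig, NicheTruth, make_env_backgrounds,
                        simulate_species)

#: geometry of the recovery scenario: niche kernel sd, background spread, and
#: the displacement (in niche-sd units) of the secondary expansion kernel.
RECOVERY_NICHE_SD = 0.6
RECOVERY_SPREAD = 1.5
RECOVERY_EXPANSION_MULT = 4.0


def coue_recovery_estimates(u_true: float, e_true: float, seed: int,
                            n_occurrences: int = 1000,
                            n_background: int = 2000,
                            resolution: int = 100,
                            percentile: int = 75) -> tuple[float, float, float]:
    """Simulate a species with known unfilling/expansion and recover
    (stability, unfilling, expansion) through the full gridded-niche stage.

    Both ranges share one climate (zero background offset), so analogous
    space covers the support and estimates are directly comparable to truth.
    """
    sd = RECOVERY_NICHE_SD
    cfg = BackgroundConfig(n_points=n_background, k=2, offset=0.0,
                           spread=RECOVERY_SPREAD, seed=seed)
    bgs = make_env_backgrounds(cfg)
    truth = NicheTruth(
        centroid_native=[0.0, 0.0], centroid_shift=[0.0, 0.0], niche_sd=sd,
        unfilling_frac=u_true, expansion_frac=e_true,
        n_native=n_occurrences, n_invaded=n_occurrences, seed=seed + 100_000,
        expansion_offset=[RECOVERY_EXPANSION_MULT * sd, 0.0],
    )
    sim = simulate_species(truth, bgs)
    cols = bgs.variables
    model = fit_env_space(bgs.native[cols], bgs.invaded[cols], 2)
    bg_nat = project(bgs.native[cols], model)
    bg_inv = project(bgs.invaded[cols], model)
    occ_nat = project(sim.native.data[cols], model)
    occ_inv = project(sim.invaded.data[cols], model)
    grid = build_grid(bg_nat, bg_inv, resolution)
    grid_nat = occurrence_density(occ_nat, bg_nat, grid)
    grid_inv = occurrence_density(occ_inv, bg_inv, grid)
    return niche_dyn_indices(grid_nat, grid_inv, percentile)


def equivalency_null_pvalue(seed: int, n_per_group: int = 15,
                            n_background: int = 400, resolution: int = 25,
                            n_reps: int = 99) -> float:
    """p-value of the equivalency test on one dataset simulated under the
    null: both 'ranges' draw occurrences from the same kernel over the same
    climate.  Across seeds these p-values should be approximately uniform."""
    rng = np.random.default_rng(seed)
    bg_nat = rng.normal(0.0, 1.5, size=(n_background, 2))
    bg_inv = rng.normal(0.0, 1.5, size=(n_background, 2))
    occ_nat = rng.normal(0.0, 0.6, size=(n_per_group, 2))
    occ_inv = rng.normal(0.0, 0.6, size=(n_per_group, 2))
    grid = build_grid(bg_nat, bg_inv, resolution)
    res = equivalency_test(occ_nat, occ_inv, bg_nat, bg_inv, grid,
                           n_reps=n_reps, seed=seed + 1)
    return res.p_value


def transfer_scenario(shift: float, seed: int, n_presence: int = 150,
                      n_background: int = 1200, n_pseudo: int = 300,
                      learners=enm_mod.DEFAULT_LEARNERS,
                      n_repeats: int = 3) -> dict[str, float]:
    """Reciprocal-transfer experiment with an injected niche shift.

    Returns ensemble AUCs: internal validation on each range's held-out
    evaluation slice, and transfers of the native model to the invaded
    dataset (E_inv), the invaded model to the native dataset (E_nat), and the
    combined-range model to both.
    """
    sd = 0.6
    cfg = BackgroundConfig(n_points=n_background, k=2, offset=0.0, spread=1.5,
                           seed=seed)
    bgs = make_env_backgrounds(cfg)
    truth = NicheTruth(
        centroid_native=[0.0, 0.0], centroid_shift=[shift, 0.0], niche_sd=sd,
        n_native=n_presence, n_invaded=n_presence, seed=seed + 200_000,
    )
    sim = simulate_species(truth, bgs)
    variables = bgs.variables

    def make_pa(presences, background, label, pa_seed):
        absences = enm_mod.sample_pseudo_absences(
            background, presences, n=n_pseudo, variables=variables,
            seed=pa_seed)
        return enm_mod.PADataset(presences=presences, absences=absences,
                                 variables=variables, range_label=label)

    pa_nat = make_pa(sim.native.data, bgs.native, "native", seed + 1)
    pa_inv = make_pa(sim.invaded.data, bgs.invaded, "invaded", seed + 2)
    pa_comb = enm_mod.PADataset(
        presences=pd.concat([sim.native.data, sim.invaded.data],
                            ignore_index=True),
        absences=pd.concat([pa_nat.absences, pa_inv.absences],
                           ignore_index=True),
        variables=variables, range_label="combined")

    out: dict[str, float] = {}
    ensembles = {}
    for i, (label, pa) in enumerate(
            (("native", pa_nat), ("invaded", pa_inv), ("combined", pa_comb))):
        plan = enm_mod.split_dataset(pa, n_repeats=n_repeats, seed=seed + 10 + i)
        members = enm_mod.fit_members(pa, plan, learners, seed=seed + 20 + i)
        ensemble = enm_mod.build_ensemble(members)
        ensembles[label] = ensemble
        X, y = pa.X, pa.y
        out[f"internal_{label}"] = enm_mod.evaluate_scores(
            ensemble.predict_suitability(X[plan.eval_idx]),
            y[plan.eval_idx]).auc

    out["transfer_native_on_inv"] = enm_mod.evaluate(
        ensembles["native"], pa_inv).auc
    out["transfer_invaded_on_nat"] = enm_mod.evaluate(
        ensembles["invaded"], pa_nat).auc
    out["transfer_combined_on_inv"] = enm_mod.evaluate(
        ensembles["combined"], pa_inv).auc
    out["transfer_combined_on_nat"] = enm_mod.evaluate(
        ensembles["combined"], pa_nat).auc
    return out
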