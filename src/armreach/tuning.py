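"""Mixed-integer genetic-algorithm tuning of the seven control parameters.

The objective is the mean homing-in error over the four-target
optimization sequence (target set (i)), each reach starting from the
reset initial posture.  Genes: three proportional gains, three derivative
gains (real-valued) and the prediction time in control steps (integer).
Tournament selection, uniform crossover, Gaussian mutation on the real
genes / integer resampling on the prediction gene, and elitism; fully
deterministic for a fixed seed.  Known optima (e.g. the baseline and
reference parameters when re-tuning an ageing scenario) can be injected
into the initial population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ModelConfig, default_config
from .control import ControlParams
from .simulate import Simulator
from .workspace import TargetSet

UNSTABLE_PENALTY_MM = 1e6  # objective for reaches whose metrics are non-finite


@dataclass
class TuningResult:
    best: ControlParams
    best_objective: float     # mm
    log: pd.DataFrame         # per generation: best and mean objective
    population: np.ndarray    # final population, one genome per row


def evaluate_objective(cp: ControlParams, simulator: Simulator,
                       target_set: TargetSet) -> float:
    """Mean e_h (mm) over the optimization targets, each from reset.

    Unstable reaches contribute their (large) computed e_h rather than
    raising; non-finite metrics are replaced by a fixed penalty.
    """
    vals = []
    for point in target_set.points:
        res = simulator.simulate_reach(cp, point)
        e = res.e_h if np.isfinite(res.e_h) else UNSTABLE_PENALTY_MM
        vals.append(min(e, UNSTABLE_PENALTY_MM))
    return float(np.mean(vals))


def _bounds(cfg: ModelConfig):
    ga = cfg.ga
    lo = np.zeros(7)
    hi = np.array([ga.kp_max] * 3 + [ga.kd_max] * 3 + [ga.n_pred_max], float)
    return lo, hi


def optimize_controls(scenario: str, target_set: TargetSet,
                      config: ModelConfig | None = None,
                      seed: int = 0,
                      seeds_in_population: list[ControlParams] | None = None,
                      population: int | None = None,
                      generations: int | None = None,
                      verbose: bool = False) -> TuningResult:
    """Run the mixed-integer GA for one scenario's control parameters."""
    cfg = config or default_config()
    ga = cfg.ga
    n_pop = population or ga.population
    n_gen = generations or ga.generations
    if n_pop < 2 or n_gen < 1:
        raise ValueError("population must be >= 2 and generations >= 1")
    lo, hi = _bounds(cfg)
    if np.any(hi <= lo):
        raise ValueError("infeasible gene bounds")
    rng = np.random.default_rng(seed)
    sim = Simulator(cfg, scenario)

    def sample_genome():
        g = lo + rng.random(7) * (hi - lo)
        g[6] = rng.integers(0, int(hi[6]) + 1)
        return g

    pop = np.array([sample_genome() for _ in range(n_pop)])
    for i, cp in enumerate(seeds_in_population or []):
        pop[i % n_pop] = np.clip(cp.as_vector(), lo, hi)

    def fitness(genome):
        cp = ControlParams.from_vector(genome)
        return evaluate_objective(cp, sim, target_set)

    fit = np.array([fitness(g) for g in pop])
    rows = []
    sigma = ga.mutation_sigma * (hi - lo)
    for gen in range(n_gen):
        order = np.argsort(fit, kind="stable")
        elite_idx = order[:ga.elites]
        children = [pop[i].copy() for i in elite_idx]
        while len(children) < n_pop:
            # tournament selection of two parents
            parents = []
            for _ in range(2):
                cand = rng.integers(0, n_pop, ga.tournament)
                parents.append(pop[cand[np.argmin(fit[cand])]])
            child = parents[0].copy()
            if rng.random() < ga.crossover_prob:
                take = rng.random(7) < 0.5
                child[take] = parents[1][take]
            # mutation: Gaussian on real genes, resample on the integer gene
            for k in range(6):
                if rng.random() < ga.mutation_prob:
                    child[k] = np.clip(child[k] + rng.normal(0.0, sigma[k]),
                                       lo[k], hi[k])
            if rng.random() < ga.mutation_prob:
                child[6] = rng.integers(0, int(hi[6]) + 1)
            children.append(child)
        pop = np.array(children)
        new_fit = np.empty(n_pop)
        new_fit[:ga.elites] = fit[elite_idx]
        for i in range(ga.elites, n_pop):
            new_fit[i] = fitness(pop[i])
        fit = new_fit
        rows.append({"generation": gen, "best": float(fit.min()),
                     "mean": float(fit.mean())})
        if verbose:
            print(f"gen {gen:3d}  best {fit.min():.4g} mm  mean {fit.mean():.4g} mm")

    ibest = int(np.argmin(fit))
    best = ControlParams.from_vector(pop[ibest], provenance={
        "scenario": scenario, "seed": int(seed), "population": int(n_pop),
        "generations": int(n_gen), "objective_mm": float(fit[ibest]),
        "seeded": bool(seeds_in_population),
    })
    return TuningResult(best=best, best_objective=float(fit[ibest]),
                        log=pd.DataFrame(rows), population=pop)
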