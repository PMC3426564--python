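"""Two-genotype cost function, the DEEP optimizer, ensemble construction
and the variance-stabilized refit.

The cost is the unweighted sum of squared differences between model and data
over the wild-type observations (four gap genes) and the Kr-null
observations (hb, gt, kni), with the model evaluated by the same forward
simulation for both genotypes from one parameter vector.  RMS = sqrt(Phi/N).

DEEP (Differential Evolution Entirely Parallel) splits the population into
branches arranged on a ring.  Each branch runs classical DE
(rand/1/bin mutation-crossover with greedy selection); every communication
period, the best member of each branch replaces the oldest member of the
next branch on the ring, and members that survive unchanged longer than the
age limit are resampled within the bounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .dataset import ExpressionDataset
from .model import (CircuitParameters, CircuitError, ExternalInputSeries,
                    Genotype, MAX_LEVEL, default_bounds)
from .simulate import (DEFAULT_SCHEDULE, Schedule, TIME_CLASSES,
                       IntegrationError, NucleusGrid, initial_state_from_hb,
                       run)
from .contributions import domain_features

logger = logging.getLogger(__name__)

__all__ = ["CostValue", "CostEvaluator", "cost", "OptimizerConfig",
           "DeepResult", "deep_minimize", "Ensemble", "EnsembleScreen",
           "build_ensemble", "vst_refit", "VstRefitResult"]

#: ensemble stage-1 acceptance: RMS below 5% of the maximal expression level
RMS_ACCEPT = 0.05 * MAX_LEVEL


@dataclass(frozen=True)
class CostValue:
    """Sum of squared residuals Phi over N observations; RMS = sqrt(Phi/N)."""

    phi: float
    n: int

    @property
    def rms(self) -> float:
        return float(np.sqrt(self.phi / self.n))


class CostEvaluator:
    """Precompiled two-genotype objective.

    Observation rows are mapped once to (gene, time class, interpolation
    weight) gathers so that each evaluation is a pair of forward
    simulations plus an array subtraction.  Integrator failures yield +inf
    (with a log entry), so the objective is defined everywhere.

    ``method``/``rk4_dt`` select the integration scheme used inside the
    objective; the default is the reference adaptive integrator.  The DEEP
    search uses the fixed-step scheme for throughput (see OptimizerConfig).
    """

    def __init__(self, dataset: ExpressionDataset,
                 schedule: Schedule = DEFAULT_SCHEDULE, *,
                 method: str = "dp45", rtol: float = 1e-6,
                 atol: float = 1e-8, rk4_dt: float = 1.0,
                 transform=None):
        self.dataset = dataset
        self.schedule = schedule
        self.method = method
        self.rtol, self.atol, self.rk4_dt = rtol, atol, rk4_dt
        self.transform = transform
        self.roster = dataset.roster
        grid13 = NucleusGrid.c13()
        self.grid13 = grid13
        self.grid14 = grid13.divided()
        self.init = initial_state_from_hb(dataset.hb_c12_positions,
                                          dataset.hb_c12_levels, grid13,
                                          self.roster)
        self.genotypes = {
            dataset.wt_label: Genotype.wildtype(self.roster),
            dataset.mut_label: Genotype.kr_null(self.roster),
        }
        # gather plan: per genotype, per time class, arrays of
        # (gene index, left node, right node, right weight, obs level)
        obs = dataset.observations
        self._order = []       # row order of the prediction vector
        self._plan = {}
        for glabel in (dataset.wt_label, dataset.mut_label):
            part = obs[obs["genotype"] == glabel]
            plan = []
            for tc_i, tc in enumerate(TIME_CLASSES):
                sub = part[part["time_class"] == tc]
                if not len(sub):
                    continue
                grid = grid13 if tc == "C13" else self.grid14
                pos = sub["position_EL"].to_numpy(float)
                if (pos.min() < grid.positions[0] - 1e-9
                        or pos.max() > grid.positions[-1] + 1e-9):
                    raise CircuitError("observation positions outside grid")
                right = np.clip(np.searchsorted(grid.positions, pos),
                                1, grid.n - 1)
                left = right - 1
                w = ((pos - grid.positions[left])
                     / (grid.positions[right] - grid.positions[left]))
                genes = np.array([self.roster.gap_index(g)
                                  for g in sub["gene"]])
                plan.append((tc_i, genes, left, right, w,
                             sub["level"].to_numpy(float)))
                self._order.extend(sub.index.tolist())
            self._plan[glabel] = plan
        self.n = dataset.n_observations
        order = np.array(self._order)
        if len(order) != self.n:
            raise CircuitError("gather plan does not cover all observations")
        # wild-type flags in prediction-vector order
        self.wt_rows = dataset.wt_mask[order]
        self.row_index = order

    def predict(self, params: CircuitParameters) -> np.ndarray:
        """Model values at every observation, in gather-plan order."""
        out = []
        for glabel, plan in self._plan.items():
            traj = run(params, self.genotypes[glabel], self.dataset.external,
                       self.init, self.schedule, grid=self.grid13,
                       method=self.method, rtol=self.rtol, atol=self.atol,
                       rk4_dt=self.rk4_dt)
            for tc_i, genes, left, right, w, _levels in plan:
                s = traj.states[tc_i]
                vals = s[genes, left] * (1 - w) + s[genes, right] * w
                out.append(vals)
        return np.concatenate(out)

    def observed(self) -> np.ndarray:
        """Observation levels in gather-plan order."""
        return np.concatenate([lv for plan in self._plan.values()
                               for *_ignore, lv in plan])

    def residuals(self, params: CircuitParameters) -> np.ndarray:
        pred, data = self.predict(params), self.observed()
        if self.transform is not None:
            pred, data = self.transform(pred), self.transform(data)
        return pred - data

    def cost(self, params: CircuitParameters) -> CostValue:
        try:
            r = self.residuals(params)
        except IntegrationError as exc:
            logger.warning("integration failed during cost evaluation: %s",
                           exc)
            return CostValue(np.inf, self.n)
        return CostValue(float(r @ r), self.n)

    def __call__(self, vector: np.ndarray) -> float:
        try:
            params = CircuitParameters.from_vector(vector,
                                                   roster=self.roster)
        except CircuitError:
            return np.inf
        return self.cost(params).phi


def cost(params: CircuitParameters, dataset: ExpressionDataset,
         external: ExternalInputSeries | None = None,
         schedule: Schedule = DEFAULT_SCHEDULE, **kwargs) -> CostValue:
    """Two-genotype sum-of-squares cost of one parameter set.

    ``external`` overrides the dataset's own external-input series (they
    are normally the same object)."""
    if external is not None:
        from dataclasses import replace
        dataset = replace(dataset, external=external)
    return CostEvaluator(dataset, schedule, **kwargs).cost(params)


# ---------------------------------------------------------------------------
# DEEP optimizer
# ---------------------------------------------------------------------------

@dataclass
class OptimizerConfig:
    """Control variables of the DEEP optimizer.

    ``np_total`` is the whole population, split evenly over ``branches``
    (>= 4 members per branch).  ``comm_period`` is the number of iterations
    between ring migrations.  ``f``/``cr`` are the DE scale factor and
    crossover rate (rand/1/bin); ``f_dither`` draws the scale factor
    uniformly from [f_dither, f] per trial, which speeds late convergence.
    A member that survives ``age_limit`` iterations unchanged is considered
    stuck in a local minimum and becomes the preferred victim of the next
    migration.  ``target_phi`` stops the run early once the best objective
    falls below it.  ``np_min`` enables linear population-size reduction:
    branch populations shrink from their initial size toward ``np_min``
    (total) over the iteration budget by discarding the worst members,
    which trades late-stage diversity for a much faster endgame on smooth
    landscapes.
    """

    np_total: int = 200
    branches: int = 2
    comm_period: int = 5
    strategy: str = "adaptive"     # "adaptive", "best1" or "rand1"
    f: float = 0.8
    f_dither: float | None = 0.5
    cr: float = 0.9
    pbest_frac: float = 0.10       # adaptive: pbest pool fraction
    archive: bool = True           # adaptive: keep replaced parents
    np_min: int | None = None      # linear population reduction target
    age_limit: int = 20
    seed: int = 0
    max_iter: int = 2000
    bounds: tuple | None = None
    target_phi: float | None = None

    def __post_init__(self):
        if self.np_total < 4 * self.branches:
            raise CircuitError("DEEP needs at least 4 members per branch")


@dataclass
class DeepResult:
    x: np.ndarray
    fun: float
    n_iter: int
    n_eval: int
    converged: bool
    trace: np.ndarray          # best-so-far objective after each iteration
    seed: int
    populations: list = field(default_factory=list, repr=False)


def deep_minimize(objective, config: OptimizerConfig,
                  callback=None) -> DeepResult:
    """Minimize ``objective(vector) -> float`` with DEEP.

    Branches evolve independently by differential evolution with binomial
    crossover and greedy selection; every ``comm_period`` iterations the
    best member of branch k overwrites the oldest member of branch k+1 on
    the ring (the last branch feeds the first).  The mutation base vector
    is set by ``config.strategy``: ``"rand1"`` and ``"best1"`` are the
    classical variants with fixed control variables, ``"adaptive"`` (the
    default for circuit fitting) is current-to-pbest/1 with
    success-history adaptation of F and CR per branch, which converges far
    faster on smooth least-squares landscapes.  Execution is serial and
    fully determined by ``config.seed``; migrations happen at iteration
    boundaries, so the result is what a barrier-synchronized parallel run
    would produce.
    """
    if config.bounds is None:
        raise CircuitError("OptimizerConfig.bounds must be set")
    lo, hi = (np.asarray(b, float) for b in config.bounds)
    m = lo.size
    if not np.all(np.isfinite(lo)) or not np.all(np.isfinite(hi)):
        raise CircuitError("search bounds must be finite")
    adaptive = config.strategy == "adaptive"
    rng = np.random.default_rng(config.seed)
    B = config.branches
    sizes = np.full(B, config.np_total // B)
    sizes[: config.np_total % B] += 1

    pops, costs, ages = [], [], []
    archives = [[] for _ in range(B)]
    mu_f = np.full(B, 0.6)
    mu_cr = np.full(B, 0.9)
    n_eval = 0
    for nb in sizes:
        X = lo + rng.random((nb, m)) * (hi - lo)
        fx = np.array([objective(x) for x in X])
        n_eval += nb
        pops.append(X)
        costs.append(fx)
        ages.append(np.zeros(nb, dtype=int))

    def global_best():
        b = int(np.argmin([c.min() for c in costs]))
        i = int(np.argmin(costs[b]))
        return costs[b][i], pops[b][i].copy()

    best_f, best_x = global_best()
    trace = np.empty(config.max_iter)
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        for b in range(B):
            X, fx, age = pops[b], costs[b], ages[b]
            nb = len(X)
            order = np.argsort(fx)
            n_p = max(2, int(np.ceil(config.pbest_frac * nb)))
            arch = archives[b]
            s_f, s_cr, s_w = [], [], []
            for i in range(nb):
                r1, r2, r3 = _pick3(rng, nb, i)
                if adaptive:
                    cr = float(np.clip(rng.normal(mu_cr[b], 0.1), 0.0, 1.0))
                    f = 0.0
                    while f <= 0.0:
                        f = mu_f[b] + 0.1 * rng.standard_cauchy()
                    f = min(f, 1.0)
                    pbest = X[order[rng.integers(n_p)]]
                    k = rng.integers(nb + len(arch))
                    other = X[k] if k < nb else arch[k - nb]
                    mutant = X[i] + f * (pbest - X[i]) + f * (X[r1] - other)
                else:
                    cr = config.cr
                    f = config.f if config.f_dither is None else \
                        config.f_dither + rng.random() * (config.f
                                                          - config.f_dither)
                    base = X[order[0]] if config.strategy == "best1" \
                        else X[r1]
                    mutant = base + f * (X[r2] - X[r3])
                trial = X[i].copy()
                jrand = rng.integers(m)
                mask = rng.random(m) < cr
                mask[jrand] = True
                trial[mask] = mutant[mask]
                np.clip(trial, lo, hi, out=trial)
                ft = objective(trial)
                n_eval += 1
                if ft <= fx[i]:
                    if adaptive and ft < fx[i]:
                        s_f.append(f)
                        s_cr.append(cr)
                        s_w.append(fx[i] - ft)
                        if config.archive:
                            if len(arch) >= nb:
                                arch[rng.integers(nb)] = X[i].copy()
                            else:
                                arch.append(X[i].copy())
                    X[i], fx[i], age[i] = trial, ft, 0
                    if ft < best_f:
                        best_f, best_x = ft, trial.copy()
                else:
                    age[i] += 1
            if adaptive and s_f:
                w = np.asarray(s_w) / np.sum(s_w)
                sf = np.asarray(s_f)
                mu_f[b] = (1 - 0.1) * mu_f[b] + 0.1 * (np.sum(w * sf ** 2)
                                                       / np.sum(w * sf))
                mu_cr[b] = (1 - 0.1) * mu_cr[b] + 0.1 * float(
                    np.sum(w * np.asarray(s_cr)))
        if it % config.comm_period == 0 and B > 1:
            _migrate(pops, costs, ages)
        if config.np_min is not None:
            frac = it / config.max_iter
            for b in range(B):
                target = int(round(sizes[b] + frac
                                   * (max(4, config.np_min // B)
                                      - sizes[b])))
                while len(pops[b]) > max(4, target):
                    worst = int(np.argmax(costs[b]))
                    pops[b] = np.delete(pops[b], worst, axis=0)
                    costs[b] = np.delete(costs[b], worst)
                    ages[b] = np.delete(ages[b], worst)
                    if len(archives[b]) > len(pops[b]):
                        archives[b] = archives[b][: len(pops[b])]
        trace[it - 1] = best_f
        if callback is not None:
            callback(it, best_f, best_x)
        if config.target_phi is not None and best_f <= config.target_phi:
            converged = True
            break
    return DeepResult(best_x, best_f, it, n_eval, converged,
                      trace[:it].copy(), config.seed,
                      populations=[p.copy() for p in pops])


def _pick3(rng, nb, i):
    idx = rng.permutation(nb)
    picks = [j for j in idx if j != i][:3]
    return picks[0], picks[1], picks[2]


def _migrate(pops, costs, ages):
    """Ring migration: best of branch k replaces the oldest member of
    branch k+1 (the last branch wraps to the first); ages reset."""
    B = len(pops)
    snapshots = []
    for b in range(B):
        ib = int(np.argmin(costs[b]))
        snapshots.append((pops[b][ib].copy(), costs[b][ib]))
    for b in range(B):
        tgt = (b + 1) % B
        oldest = int(np.argmax(ages[tgt]))
        x, fx = snapshots[b]
        pops[tgt][oldest] = x
        costs[tgt][oldest] = fx
        ages[tgt][oldest] = 0


# ---------------------------------------------------------------------------
# ensemble construction
# ---------------------------------------------------------------------------

@dataclass
class EnsembleScreen:
    """Deterministic stand-in for the visual inspection of fitted patterns.

    A candidate passes when (i) its simulated Kr-null gt peak shifts
    anterior over cycle 14A by more than the wild-type gt peak does,
    (ii) the mutant gt peak lies anterior of the wild-type gt peak at T8,
    (iii) mutant hb/gt/kni peak levels at T7 fall below their own mid-cycle
    (T3-T5) maxima, and (iv) model peak positions stay within
    ``max_peak_error`` %EL of the data peaks wherever the data show a
    domain.
    """

    max_peak_error: float = 3.0
    min_level: float = 20.0
    mid_classes: tuple = ("T3", "T4", "T5")

    def check(self, params, evaluator: CostEvaluator) -> dict:
        from .contributions import features_from_trajectory
        ds = evaluator.dataset
        traj = {}
        for glabel, gt in evaluator.genotypes.items():
            traj[glabel] = run(params, gt, ds.external, evaluator.init,
                               evaluator.schedule, grid=evaluator.grid13)
        feats = {g: features_from_trajectory(t, min_level=self.min_level)
                 for g, t in traj.items()}
        wt, mut = feats[ds.wt_label], feats[ds.mut_label]

        def peak(f, gene, tc):
            row = f[(f.gene == gene) & (f.time_class == tc)]
            if not len(row) or not bool(row.present.iloc[0]):
                return np.nan
            return float(row.peak_position.iloc[0])

        def level(f, gene, tc):
            row = f[(f.gene == gene) & (f.time_class == tc)]
            return float(row.peak_level.iloc[0]) if len(row) else np.nan

        checks = {}
        wt_shift = peak(wt, "gt", "T1") - peak(wt, "gt", "T8")
        mut_shift = peak(mut, "gt", "T1") - peak(mut, "gt", "T8")
        checks["gt_shift_larger_in_mutant"] = bool(mut_shift > wt_shift)
        checks["mut_gt_anterior_of_wt_at_T8"] = bool(
            peak(mut, "gt", "T8") < peak(wt, "gt", "T8"))
        for gene in ("hb", "gt", "kni"):
            mid = np.nanmax([level(mut, gene, tc)
                             for tc in self.mid_classes])
            checks[f"mut_{gene}_declines_by_T7"] = bool(
                level(mut, gene, "T7") < mid)
        checks["peak_positions_match_data"] = self._peaks_match(
            ds, traj, feats)
        checks["pass"] = all(v for k, v in checks.items() if k != "pass")
        return checks

    def _peaks_match(self, ds, traj, feats) -> bool:
        from .contributions import domain_features
        obs = ds.observations
        for glabel, f in feats.items():
            part = obs[obs["genotype"] == glabel]
            for (gene, tc), sub in part.groupby(["gene", "time_class"]):
                sub = sub.sort_values("position_EL")
                data_feat = domain_features(sub["position_EL"].to_numpy(),
                                            sub["level"].to_numpy(),
                                            min_level=self.min_level)
                if not data_feat.present:
                    continue
                row = f[(f.gene == gene) & (f.time_class == tc)]
                if not len(row) or not bool(row.present.iloc[0]):
                    return False
                if abs(float(row.peak_position.iloc[0])
                       - data_feat.peak_position) > self.max_peak_error:
                    return False
        return True


@dataclass
class Ensemble:
    """Accepted parameter sets with their RMS and provenance."""

    members: list                  # CircuitParameters
    rms: np.ndarray
    provenance: list               # dicts: seed / run id per member
    log: list = field(default_factory=list, repr=False)

    def __post_init__(self):
        self.rms = np.asarray(self.rms, float)
        if np.any(self.rms >= RMS_ACCEPT):
            raise CircuitError("ensemble members must have RMS below "
                               f"{RMS_ACCEPT:g}")

    def __len__(self):
        return len(self.members)

    def weights(self) -> np.ndarray:
        """Stacked (n_members, n_gap, n_gap + n_external) regulatory-weight
        array (T columns then E columns)."""
        return np.stack([np.hstack([p.T, p.E]) for p in self.members])


def build_ensemble(candidates, dataset: ExpressionDataset,
                   schedule: Schedule = DEFAULT_SCHEDULE,
                   screen: EnsembleScreen | None = None,
                   provenance=None) -> Ensemble:
    """Two-stage ensemble construction.

    Stage 1 keeps candidates with RMS below 5% of the maximal expression
    level (12.75 on the 0-255 scale); stage 2 applies the deterministic
    pattern screen.  Both decisions are logged per candidate.  An empty
    result is a warning, not an error.
    """
    screen = screen or EnsembleScreen()
    evaluator = CostEvaluator(dataset, schedule)
    members, rms_vals, prov, log = [], [], [], []
    provenance = provenance or [{} for _ in candidates]
    for k, params in enumerate(candidates):
        cv = evaluator.cost(params)
        entry = {"candidate": k, "rms": cv.rms,
                 "stage1_pass": bool(cv.rms < RMS_ACCEPT)}
        if entry["stage1_pass"]:
            checks = screen.check(params, evaluator)
            entry["screen"] = checks
            entry["accepted"] = checks["pass"]
        else:
            entry["accepted"] = False
        log.append(entry)
        if entry["accepted"]:
            members.append(params)
            rms_vals.append(cv.rms)
            prov.append(provenance[k])
    if not members:
        logger.warning("ensemble is empty: no candidate passed both filters")
    return Ensemble(members, np.array(rms_vals), prov, log)


# ---------------------------------------------------------------------------
# variance-stabilized refit
# ---------------------------------------------------------------------------

@dataclass
class VstRefitResult:
    params: CircuitParameters
    displacement: float            # ||theta_new - theta_old||_2
    relative_displacement: float   # scaled by the bound widths
    phi_before: float
    phi_after: float
    n_clipped: int


def vst_refit(params: CircuitParameters, dataset: ExpressionDataset,
              external: ExternalInputSeries | None = None,
              config: OptimizerConfig | None = None,
              schedule: Schedule = DEFAULT_SCHEDULE,
              method: str = "rk4", rk4_dt: float = 1.0,
              max_nfev: int = 600) -> VstRefitResult:
    """Re-minimize the square-root-transformed cost, warm-started at an
    accepted optimum of the untransformed cost.

    Fluorescence errors grow roughly linearly with the mean (Poisson-like),
    so residuals of sqrt(model) - sqrt(data) are approximately
    homoscedastic.  Negative model values are clipped at zero before the
    transform (the clip count is reported).
    """
    if external is not None:
        from dataclasses import replace
        dataset = replace(dataset, external=external)
    clip_count = [0]

    def transform(y):
        neg = y < 0
        if neg.any():
            clip_count[0] += int(neg.sum())
            y = np.where(neg, 0.0, y)
        return np.sqrt(y)

    evaluator = CostEvaluator(dataset, schedule, method=method,
                              rk4_dt=rk4_dt, transform=transform)
    x0 = params.to_vector()
    bounds = config.bounds if (config and config.bounds is not None) \
        else default_bounds(params.roster)
    lo, hi = (np.asarray(b, float) for b in bounds)
    x0c = np.clip(x0, lo, hi)

    def res(x):
        try:
            return evaluator.residuals(
                CircuitParameters.from_vector(x, roster=params.roster))
        except IntegrationError:
            return np.full(evaluator.n, 1e6)

    r0 = res(x0c)
    sol = least_squares(res, x0c, bounds=(lo, hi), method="trf",
                        xtol=1e-12, ftol=1e-12, gtol=1e-12,
                        max_nfev=max_nfev)
    new = CircuitParameters.from_vector(sol.x, roster=params.roster)
    disp = float(np.linalg.norm(sol.x - x0))
    rel = float(np.linalg.norm((sol.x - x0) / (hi - lo)))
    return VstRefitResult(new, disp, rel, float(r0 @ r0),
                          float(sol.fun @ sol.fun), clip_count[0])
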