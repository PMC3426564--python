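"""Drive the gene circuit through the cycle-13/14A schedule.

The circuit functions by three rules.  Interphase dynamics (synthesis,
diffusion, decay) run over cycle-13 interphase [0, 16.0] min; mitosis
dynamics (no synthesis) over [16.0, 21.1]; at t = 21.1 the 13th division
doubles the nuclei; interphase dynamics then run to gastrulation.  Cycle 14A
is subdivided into eight equal temporal classes, and the model is compared
to data at nine time points: the cycle-13 midpoint (C13) and the eight class
midpoints (T1-T8).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from .model import (CircuitParameters, CircuitError, ExternalInputSeries,
                    Genotype, NucleusGrid, StateVector, divide)

__all__ = ["Schedule", "Trajectory", "run", "run_pair",
           "initial_state_from_hb", "TIME_CLASSES"]

TIME_CLASSES = ("C13", "T1", "T2", "T3", "T4", "T5", "T6", "T7", "T8")


@dataclass(frozen=True)
class Schedule:
    """Division schedule, in minutes from the start of cycle 13.

    Cycle-13 interphase lasts 16.0 min, its mitosis runs from 16.0 to
    21.1 min, and the division is applied at 21.1 min.  Cycle 14A is split
    into ``n_classes`` equal classes of ``class_duration`` minutes; the
    model ends at gastrulation.
    """

    t_start: float = 0.0
    interphase13_end: float = 16.0
    division_time: float = 21.1
    class_duration: float = 6.25
    n_classes: int = 8

    def __post_init__(self):
        if not (self.t_start < self.interphase13_end < self.division_time):
            raise CircuitError("schedule times must be strictly increasing")

    @property
    def t_end(self) -> float:
        return self.division_time + self.n_classes * self.class_duration

    @property
    def c13_midpoint(self) -> float:
        """Midpoint of the whole cycle 13 (interphase + mitosis); 10.55 min
        for the default schedule."""
        return 0.5 * (self.t_start + self.division_time)

    @property
    def class_midpoints(self) -> np.ndarray:
        k = np.arange(self.n_classes)
        return self.division_time + (k + 0.5) * self.class_duration

    @property
    def comparison_times(self) -> np.ndarray:
        """The nine comparison times: C13 midpoint then T1-T8 midpoints."""
        return np.concatenate([[self.c13_midpoint], self.class_midpoints])

    @property
    def anchor_times(self) -> np.ndarray:
        """External-input anchor times: C12 midpoint (-6.2), C13 midpoint,
        and the eight class midpoints."""
        return np.concatenate([[-6.2, self.c13_midpoint],
                               self.class_midpoints])


DEFAULT_SCHEDULE = Schedule()


@dataclass
class Trajectory:
    """Model solution sampled at the nine comparison time points.

    ``states[0]`` (C13) lives on the cycle-13 grid; ``states[1:]`` (T1-T8)
    on the cycle-14A grid.  Optional dense samples are stored for
    contribution plots.
    """

    genotype: Genotype
    schedule: Schedule
    grid_c13: NucleusGrid
    grid_c14a: NucleusGrid
    times: np.ndarray
    states: list
    dense_times: np.ndarray | None = None
    dense_states: list | None = None

    def __post_init__(self):
        if len(self.states) != len(TIME_CLASSES):
            raise CircuitError("a trajectory holds exactly 9 comparison "
                               "states")

    def state(self, time_class: str) -> np.ndarray:
        return self.states[TIME_CLASSES.index(time_class)]

    def grid(self, time_class: str) -> NucleusGrid:
        return self.grid_c13 if time_class == "C13" else self.grid_c14a

    def profile(self, gene: str, time_class: str) -> np.ndarray:
        a = self.genotype.roster.gap_index(gene)
        return self.state(time_class)[a]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: genotype, gene, time_class, position_EL,
        level — same layout as the observation tables."""
        rows = []
        for tc, state in zip(TIME_CLASSES, self.states):
            grid = self.grid(tc)
            for a, gene in enumerate(self.genotype.roster.gap_genes):
                rows.append(pd.DataFrame({
                    "genotype": self.genotype.label, "gene": gene,
                    "time_class": tc, "position_EL": grid.positions,
                    "level": state[a]}))
        return pd.concat(rows, ignore_index=True)


def initial_state_from_hb(hb_positions, hb_levels, grid: NucleusGrid,
                          roster=None) -> StateVector:
    """Cycle-13 initial condition: Kr, gt and kni are exclusively zygotic
    and start at zero; hb starts from the supplied cycle-12 profile,
    interpolated to the nucleus grid."""
    from .model import DEFAULT_ROSTER
    roster = roster or DEFAULT_ROSTER
    v0 = np.zeros((roster.n_gap, grid.n))
    v0[roster.gap_index("hb")] = np.interp(grid.positions,
                                           np.asarray(hb_positions, float),
                                           np.asarray(hb_levels, float))
    return StateVector(v0, 0.0)


class IntegrationError(RuntimeError):
    """Integrator failure, reporting time and state norm."""


def _segment(kern_args, v, t0, t1, method, rtol, atol, rk4_dt):
    if method == "dp45":
        out = _kernels.dp45_segment(v, t0, t1, *kern_args, rtol, atol)
    elif method == "rk4":
        out = _kernels.rk4_segment(v, t0, t1, rk4_dt, *kern_args)
    else:
        raise CircuitError(f"unknown integration method {method!r}")
    if not np.all(np.isfinite(out)):
        raise IntegrationError(
            f"integration failed on [{t0:g}, {t1:g}] min; "
            f"|v({t0:g})| = {float(np.abs(v).max()):g}")
    return out


def _sweep(kern_args, v, t0, t1, stops, method, rtol, atol, rk4_dt):
    """Integrate [t0, t1] stopping exactly at each requested time; yields
    (t_stop, state) snapshots."""
    t = t0
    out = []
    for ts in stops:
        if ts < t - 1e-12 or ts > t1 + 1e-12:
            raise CircuitError(f"stop time {ts} outside segment")
        v = _segment(kern_args, v, t, ts, method, rtol, atol, rk4_dt)
        out.append((ts, v))
        t = ts
    if t < t1 - 1e-12:
        v = _segment(kern_args, v, t, t1, method, rtol, atol, rk4_dt)
    return v, out


def run(params: CircuitParameters, genotype: Genotype,
        external: ExternalInputSeries, init: StateVector,
        schedule: Schedule = DEFAULT_SCHEDULE, *,
        grid: NucleusGrid | None = None, method: str = "dp45",
        rtol: float = 1e-6, atol: float = 1e-8, rk4_dt: float = 1.0,
        dense: bool = False, dense_dt: float = 0.5) -> Trajectory:
    """Simulate one genotype through the full schedule.

    Comparison samples are produced by stopping the integrator exactly at
    the nine comparison times (no interpolation).  With ``dense=True`` the
    solution is additionally recorded every ``dense_dt`` minutes.
    """
    grid13 = grid or NucleusGrid.c13()
    if grid13.cycle != "C13":
        raise CircuitError("initial grid must be the cycle-13 grid")
    if init.v.shape != (params.roster.n_gap, grid13.n):
        raise CircuitError("initial state does not match the cycle-13 grid")
    if external.t_min > schedule.t_start:
        raise CircuitError("external inputs do not cover the model span")

    Talpha = params.T * genotype.alpha[None, :]
    active = genotype.active
    v = init.v.copy()
    v[~active] = 0.0

    def args(ext_anchors, synthesis):
        return (Talpha, params.E, params.h, params.R, params.D, params.lam,
                active, synthesis, external.times, ext_anchors)

    def stops_in(t0, t1, required):
        req = [t for t in required if t0 + 1e-12 < t <= t1 + 1e-12]
        if dense:
            grid_t = np.arange(np.ceil(t0 / dense_dt) * dense_dt,
                               t1 + 1e-9, dense_dt)
            req = sorted(set(np.round(np.r_[req, grid_t], 9)))
        return req

    ext13 = np.ascontiguousarray(external.on_grid(grid13))
    dense_rec = []
    if dense:
        dense_rec.append((0.0, v.copy()))

    # cycle-13 interphase
    v, snaps = _sweep(args(ext13, True), v, schedule.t_start,
                      schedule.interphase13_end,
                      stops_in(schedule.t_start, schedule.interphase13_end,
                               [schedule.c13_midpoint]),
                      method, rtol, atol, rk4_dt)
    comparison = {}
    for ts, state in snaps:
        if abs(ts - schedule.c13_midpoint) < 1e-9:
            comparison["C13"] = state
        dense_rec.append((ts, state))

    # cycle-13 mitosis (no synthesis)
    v, snaps = _sweep(args(ext13, False), v, schedule.interphase13_end,
                      schedule.division_time,
                      stops_in(schedule.interphase13_end,
                               schedule.division_time, []),
                      method, rtol, atol, rk4_dt)
    dense_rec.extend(snaps)

    # division at 21.1 min
    state14, grid14 = divide(StateVector(v, schedule.division_time), grid13)
    v = state14.v
    ext14 = np.ascontiguousarray(external.on_grid(grid14))
    if dense:
        dense_rec.append((schedule.division_time, v.copy()))

    # cycle-14A interphase to gastrulation
    mids = schedule.class_midpoints
    v, snaps = _sweep(args(ext14, True), v, schedule.division_time,
                      schedule.t_end,
                      stops_in(schedule.division_time, schedule.t_end,
                               list(mids)),
                      method, rtol, atol, rk4_dt)
    for ts, state in snaps:
        hits = np.nonzero(np.abs(mids - ts) < 1e-9)[0]
        if hits.size:
            comparison[TIME_CLASSES[1 + hits[0]]] = state
        dense_rec.append((ts, state))

    states = [comparison[tc] for tc in TIME_CLASSES]
    dense_times = dense_states = None
    if dense:
        dense_times = np.array([t for t, _ in dense_rec])
        dense_states = [s for _, s in dense_rec]
    return Trajectory(genotype, schedule, grid13, grid14,
                      schedule.comparison_times, states,
                      dense_times, dense_states)


def run_pair(params: CircuitParameters, external: ExternalInputSeries,
             init: StateVector, schedule: Schedule = DEFAULT_SCHEDULE,
             mutant: Genotype | None = None, **kwargs):
    """Simulate wild type and the Kr-null mutant from the same parameters.

    Returns (wild-type trajectory, mutant trajectory).  The mutant defaults
    to the Kr null; pass ``mutant`` for other genotypes (e.g. the Kr;kni
    double null)."""
    roster = params.roster
    wt = run(params, Genotype.wildtype(roster), external, init, schedule,
             **kwargs)
    mut = run(params, mutant or Genotype.kr_null(roster), external, init,
              schedule, **kwargs)
    return wt, mut
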