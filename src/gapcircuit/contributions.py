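"""Regulatory-contribution decomposition, domain features and knockout scans.

The total regulatory input to a gene is an additive sum of terms
T[a,b] * alpha_b * v^b and E[a,e] * y_e plus the promoter threshold h_a, so
the strength of each interaction at any point in space and time is simply
its term value.  Domain features (peak position and level, half-maximum
boundaries) summarize expression profiles; shift reports compare them over
time and between genotypes; the graded knockout scan re-simulates the
circuit with the target gene's regulatory output scaled by a coefficient
alpha decreasing from 1 (wild type) to 0 (null).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (CircuitError, CircuitParameters, ExternalInputSeries,
                    Genotype, StateVector)
from .simulate import DEFAULT_SCHEDULE, Schedule, TIME_CLASSES, Trajectory, run

__all__ = ["ContributionDecomposition", "DomainFeatures", "decompose",
           "domain_features", "features_from_trajectory", "shift_report",
           "knockout_scan", "KnockoutScanResult"]


@dataclass
class ContributionDecomposition:
    """Per-regulator contribution terms along a trajectory.

    ``terms[k]`` has shape (n_gap, n_regulators, n_nuclei) at time
    ``times[k]``: entry [a, b] is T[a,b]*alpha_b*v^b (gap regulators) or
    E[a,e]*y_e (external regulators).  The threshold ``h`` completes the
    additive decomposition: sum over regulators + h_a = u^a exactly.
    """

    times: np.ndarray
    time_classes: list
    terms: list
    positions: list
    h: np.ndarray
    regulators: tuple
    targets: tuple

    def total_input(self, k: int) -> np.ndarray:
        """u[a, i] at sample k, reassembled from the terms."""
        return self.terms[k].sum(axis=1) + self.h[:, None]

    def series(self, target: str, regulator: str,
               position: float) -> np.ndarray:
        """Contribution of one regulator to one target gene at a fixed
        position, over all samples (linear interpolation in space)."""
        a = self.targets.index(target)
        b = self.regulators.index(regulator)
        out = np.empty(len(self.terms))
        for k, term in enumerate(self.terms):
            out[k] = np.interp(position, self.positions[k], term[a, b])
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, term in enumerate(self.terms):
            for a, tgt in enumerate(self.targets):
                for b, reg in enumerate(self.regulators):
                    rows.append(pd.DataFrame({
                        "t": self.times[k],
                        "time_class": self.time_classes[k],
                        "target": tgt, "regulator": reg,
                        "position_EL": self.positions[k],
                        "contribution": term[a, b]}))
        return pd.concat(rows, ignore_index=True)


def decompose(trajectory: Trajectory, params: CircuitParameters,
              external: ExternalInputSeries,
              genotype: Genotype | None = None) -> ContributionDecomposition:
    """Evaluate all additive terms of the regulatory input along a
    trajectory.

    Dense samples are used when the trajectory carries them; otherwise the
    nine comparison states.  Activating and repressing terms are separable
    by sign in the result.
    """
    genotype = genotype or trajectory.genotype
    roster = params.roster
    ng, ne = roster.n_gap, roster.n_external
    if trajectory.dense_states is not None:
        times = trajectory.dense_times
        states = trajectory.dense_states
        tclasses = [None] * len(states)
    else:
        times = trajectory.times
        states = trajectory.states
        tclasses = list(TIME_CLASSES)
    Talpha = params.T * genotype.alpha[None, :]
    terms, positions = [], []
    for t, v in zip(times, states):
        grid = (trajectory.grid_c13 if v.shape[1] == trajectory.grid_c13.n
                else trajectory.grid_c14a)
        y = external.at(t, grid)
        term = np.empty((ng, ng + ne, v.shape[1]))
        term[:, :ng] = Talpha[:, :, None] * v[None, :, :]
        term[:, ng:] = params.E[:, :, None] * y[None, :, :]
        terms.append(term)
        positions.append(grid.positions)
    return ContributionDecomposition(
        np.asarray(times, float), tclasses, terms, positions,
        params.h.copy(), roster.gap_genes + roster.external_inputs,
        roster.gap_genes)


# ---------------------------------------------------------------------------
# domain features
# ---------------------------------------------------------------------------

@dataclass
class DomainFeatures:
    """Peak and half-maximum geometry of one expression profile.

    ``present`` is False for profiles with no expression above
    ``min_level`` (features are then absent, not zero).  Half-maximum
    boundaries are NaN when the profile does not fall below half-maximum
    before the region edge.  Equal-maximum ties resolve to the
    anterior-most peak and set ``multimodal``.
    """

    present: bool
    peak_position: float = np.nan
    peak_level: float = np.nan
    half_max_anterior: float = np.nan
    half_max_posterior: float = np.nan
    multimodal: bool = False


def domain_features(positions, levels, min_level: float = 0.0,
                    refine: bool = True) -> DomainFeatures:
    """Extract peak position/level and half-maximum boundaries.

    The peak is the anterior-most global maximum, refined by a parabola
    through the three surrounding points when the maximum is interior.
    Boundaries are linear-interpolated half-maximum crossings nearest the
    peak on either side.
    """
    x = np.asarray(positions, float)
    y = np.asarray(levels, float)
    if x.ndim != 1 or x.shape != y.shape or x.size < 2:
        raise CircuitError("profile must be two equal-length 1-D arrays")
    if np.any(y < 0):
        raise CircuitError("profile levels must be nonnegative")
    ymax = float(y.max())
    if ymax <= min_level:
        return DomainFeatures(present=False)
    i = int(np.argmax(y))           # first (anterior-most) maximum
    interior = np.zeros(x.size, bool)
    interior[1:-1] = (y[1:-1] >= y[:-2]) & (y[1:-1] >= y[2:])
    n_peaks = int(np.count_nonzero(interior & (y >= ymax - 1e-9)))
    if i == 0 or i == x.size - 1:
        n_peaks += 1
    multimodal = n_peaks > 1

    xp, yp = x[i], ymax
    if refine and 0 < i < x.size - 1:
        denom = y[i - 1] - 2 * y[i] + y[i + 1]
        if denom < -1e-12:
            delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
            delta = float(np.clip(delta, -0.5, 0.5))
            xp = x[i] + delta * (x[i + 1] - x[i])
            yp = y[i] - 0.25 * (y[i - 1] - y[i + 1]) * delta

    half = 0.5 * ymax
    lo = hi = np.nan
    for j in range(i, 0, -1):
        if y[j - 1] < half <= y[j]:
            w = (half - y[j - 1]) / (y[j] - y[j - 1])
            lo = x[j - 1] + w * (x[j] - x[j - 1])
            break
    for j in range(i, x.size - 1):
        if y[j + 1] < half <= y[j]:
            w = (y[j] - half) / (y[j] - y[j + 1])
            hi = x[j] + w * (x[j + 1] - x[j])
            break
    return DomainFeatures(True, float(xp), float(yp), float(lo), float(hi),
                          multimodal)


def features_from_trajectory(traj: Trajectory,
                             min_level: float = 0.0) -> pd.DataFrame:
    """Domain features of every gene at every comparison time class."""
    rows = []
    for tc in TIME_CLASSES:
        grid = traj.grid(tc)
        for gene in traj.genotype.roster.gap_genes:
            f = domain_features(grid.positions, traj.profile(gene, tc),
                                min_level=min_level)
            rows.append({"genotype": traj.genotype.label, "gene": gene,
                         "time_class": tc, **f.__dict__})
    return pd.DataFrame(rows)


def shift_report(features_wt: pd.DataFrame,
                 features_mut: pd.DataFrame,
                 start: str = "T1", end: str = "T8") -> dict:
    """Positional-shift summary between time classes and genotypes.

    Within-genotype shift = peak(start) - peak(end) in %EL, positive
    anterior-ward (toward lower %EL).  The per-class offset is
    peak_wt - peak_mut (positive when the mutant domain lies anterior of
    the wild-type domain).
    """
    def peak(f, gene, tc):
        row = f[(f.gene == gene) & (f.time_class == tc)]
        if not len(row) or not bool(row.present.iloc[0]):
            return np.nan
        return float(row.peak_position.iloc[0])

    genes = sorted(set(features_wt.gene) | set(features_mut.gene))
    shifts = pd.DataFrame({
        "gene": genes,
        "wt_shift": [peak(features_wt, g, start) - peak(features_wt, g, end)
                     for g in genes],
        "mut_shift": [peak(features_mut, g, start)
                      - peak(features_mut, g, end) for g in genes],
    })
    offs = []
    for g in genes:
        for tc in TIME_CLASSES:
            offs.append({"gene": g, "time_class": tc,
                         "offset": peak(features_wt, g, tc)
                         - peak(features_mut, g, tc)})
    return {"shifts": shifts, "offsets": pd.DataFrame(offs)}


# ---------------------------------------------------------------------------
# graded knockout scan
# ---------------------------------------------------------------------------

@dataclass
class KnockoutScanResult:
    gene: str
    alphas: np.ndarray
    trajectories: list
    reference_points: dict          # gene -> (position_EL, time_class)
    summary: pd.DataFrame           # level at reference point vs alpha
    monotone: dict = field(default_factory=dict)

    @property
    def all_monotone(self) -> bool:
        return all(self.monotone.values())


def knockout_scan(params: CircuitParameters, external: ExternalInputSeries,
                  init: StateVector,
                  alphas=(1.0, 0.6, 0.4, 0.025, 0.0), gene: str = "Kr",
                  schedule: Schedule = DEFAULT_SCHEDULE,
                  reference_points: dict | None = None,
                  reference_class: str = "T8",
                  tol: float = 1e-6, **run_kwargs) -> KnockoutScanResult:
    """Graded in-silico knockout: scale one gene's regulatory output by each
    alpha and summarize gap-protein levels at fixed reference points.

    Endpoints alpha = 1 and alpha = 0 are exactly the wild-type and null
    simulations.  Reference points default to each gene's wild-type peak
    position at ``reference_class``; monotonicity of level versus alpha is
    checked per gene with tolerance ``tol``.
    """
    alphas = np.asarray(alphas, float)
    if np.any(alphas < 0) or np.any(alphas > 1):
        raise CircuitError("knockout coefficients must lie in [0, 1]")
    roster = params.roster
    trajs = [run(params, Genotype.graded(gene, a, roster), external, init,
                 schedule, **run_kwargs) for a in alphas]

    if reference_points is None:
        wt = trajs[int(np.argmax(alphas))] if np.any(alphas == 1.0) else \
            run(params, Genotype.wildtype(roster), external, init, schedule,
                **run_kwargs)
        reference_points = {}
        grid = wt.grid(reference_class)
        for gname in roster.gap_genes:
            f = domain_features(grid.positions,
                                wt.profile(gname, reference_class))
            reference_points[gname] = (
                f.peak_position if f.present else grid.positions[grid.n // 2],
                reference_class)

    rows = []
    for a, traj in zip(alphas, trajs):
        for gname in roster.gap_genes:
            pos, tc = reference_points[gname]
            grid = traj.grid(tc)
            lvl = float(np.interp(pos, grid.positions,
                                  traj.profile(gname, tc)))
            rows.append({"alpha": a, "gene": gname, "position_EL": pos,
                         "time_class": tc, "level": lvl})
    summary = pd.DataFrame(rows)

    order = np.argsort(alphas)
    monotone = {}
    for gname in roster.gap_genes:
        lv = summary[summary.gene == gname].level.to_numpy()[order]
        monotone[gname] = bool(np.all(np.diff(lv) >= -tol)
                               or np.all(np.diff(lv) <= tol))
    return KnockoutScanResult(gene, alphas, trajs, reference_points,
                              summary, monotone)
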