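"""Synthetic inputs for the whole pipeline.

Two generators are provided, with different purposes:

* the **mechanistic** generator (`default_ground_truth` +
  `simulate_dataset`) draws two-genotype expression tables from a known
  circuit by forward simulation, so that parameter-recovery and
  identifiability analyses have an exact truth to compare against;
* the **phenomenological** generator (`phenomenological_profiles`) builds
  sum-of-Gaussian profiles with the descriptive geometry of the real
  system - wild-type gap domains in 47-92 %EL with modest anterior drift,
  and a Kr-null variant whose posterior gt domain drifts 15 %EL anterior
  while hb/gt/kni levels decline late in cycle 14A - independent of any
  parameter set, for feature-extraction and screening tests.

External inputs emulate the measured dynamics: a Bcd gradient that declines
about twofold between the first and last time class, a Cad profile whose
abdominal plateau decays from mid-cycle and sharpens to a posterior stripe
spanning about 75-90 %EL by gastrulation, and a posterior terminal Tll
domain.  Observational noise is heteroscedastic with variance growing
linearly with the mean (Poisson-like), as seen in fluorescence data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .dataset import ExpressionDataset, OBS_COLUMNS
from .model import (DEFAULT_ROSTER, CircuitParameters, ExternalInputSeries,
                    GeneRoster, MAX_LEVEL, NucleusGrid, REGION)
from .simulate import (DEFAULT_SCHEDULE, Schedule,
                       initial_state_from_hb, run_pair)

__all__ = ["GroundTruth", "NoiseModel", "make_external_inputs",
           "default_ground_truth", "simulate_dataset",
           "phenomenological_profiles"]


@dataclass
class NoiseModel:
    """Heteroscedastic observation noise: Var = c * mean + sigma0^2,
    truncated to the 0-255 fluorescence range."""

    c: float = 0.5
    sigma0: float = 2.0

    def __post_init__(self):
        if self.c < 0:
            raise ValueError("variance slope c must be >= 0")

    def sd(self, mean):
        return np.sqrt(self.c * np.clip(mean, 0.0, None) + self.sigma0 ** 2)

    def apply(self, rng: np.random.Generator, values: np.ndarray):
        noisy = values + rng.standard_normal(values.shape) * self.sd(values)
        return np.clip(noisy, 0.0, MAX_LEVEL)


@dataclass
class GroundTruth:
    """A known circuit plus every input needed to simulate it."""

    params: CircuitParameters
    hb_c12_positions: np.ndarray
    hb_c12_levels: np.ndarray
    external: ExternalInputSeries
    seed: int = 0


# ---------------------------------------------------------------------------
# external inputs
# ---------------------------------------------------------------------------

#: Bcd length constant in %EL and level at the anterior edge of the region
_BCD_LAMBDA = 21.0
_BCD_A0 = 120.0

def make_external_inputs(grid: NucleusGrid | None = None,
                         seed: int | None = None,
                         schedule: Schedule = DEFAULT_SCHEDULE,
                         roster: GeneRoster = DEFAULT_ROSTER
                         ) -> ExternalInputSeries:
    """Anchored Bcd/Cad/Tll profiles over the modeled region.

    Bcd is an exponential gradient whose amplitude peaks at the start of
    cycle 14A and declines linearly to half by the last time class.  Cad is
    a broad abdominal profile that decays from mid-cycle while a posterior
    stripe spanning ~75-90 %EL emerges and dominates by gastrulation.  Tll
    is a posterior terminal sigmoid.  The generator is deterministic; the
    seed is recorded for provenance only.
    """
    grid = grid or NucleusGrid.c14a()
    x = grid.positions
    times = schedule.anchor_times
    nt = times.size

    # per-anchor amplitudes: [C12, C13, T1..T8]
    bcd_amp = np.array([0.90, 1.00, 1.00, 1.00 - 1 / 14, 1.00 - 2 / 14,
                        1.00 - 3 / 14, 1.00 - 4 / 14, 1.00 - 5 / 14,
                        1.00 - 6 / 14, 0.50]) * _BCD_A0
    cad_broad_amp = np.array([140, 150, 150, 150, 130, 105, 80, 55, 35, 18],
                             float)
    cad_stripe_amp = np.array([0, 0, 0, 0, 10, 35, 65, 95, 115, 128], float)
    tll_amp = np.array([40, 60, 90, 100, 110, 115, 118, 120, 120, 120],
                       float)

    bcd_shape = np.exp(-(x - REGION[0]) / _BCD_LAMBDA)
    cad_broad = expit((x - 58.0) / 3.0)
    cad_stripe = expit((x - 75.5) / 1.2) * expit((88.0 - x) / 1.0)
    tll_shape = expit((x - 86.0) / 1.5)

    values = np.empty((roster.n_external, nt, x.size))
    values[0] = bcd_amp[:, None] * bcd_shape[None, :]
    values[1] = (cad_broad_amp[:, None] * cad_broad[None, :]
                 + cad_stripe_amp[:, None] * cad_stripe[None, :])
    values[2] = tll_amp[:, None] * tll_shape[None, :]
    return ExternalInputSeries(times, x, values, roster)


def default_hb_c12(grid: NucleusGrid | None = None):
    """Maternal hb profile at cycle 12: anterior-high step declining across
    the anterior quarter of the region (the posterior hb domain has not yet
    formed)."""
    grid = grid or NucleusGrid.c14a()
    x = grid.positions
    return x.copy(), 110.0 * expit((54.0 - x) / 2.5)


# ---------------------------------------------------------------------------
# mechanistic ground truth
# ---------------------------------------------------------------------------

# Hand-tuned circuit reproducing the qualitative posterior-half topology:
# mutual hb-kni and Kr-gt repression, asymmetric repression driving anterior
# shifts, Cad/Bcd activation, Tll repression of Kr and kni, Gt activation of
# posterior hb.  Versioned fixture: change deliberately, tests depend on its
# qualitative behavior.
_TRUTH_T = np.array([
    #  hb       Kr       gt       kni     (regulator)
    [0.0060, -0.0030,  0.0080, -0.0300],   # -> hb
    [-0.0050,  0.0180, -0.0150, -0.0060],  # -> Kr
    [-0.0320, -0.0400,  0.0200, -0.0120],  # -> gt
    [-0.0300, -0.0040, -0.0300,  0.0150],  # -> kni
])
_TRUTH_E = np.array([
    #  bcd     cad      tll
    [0.0020,  0.0180,  0.0160],   # -> hb
    [0.0360,  0.0120, -0.0600],   # -> Kr
    [0.0040,  0.0270,  0.0060],   # -> gt
    [0.0200,  0.0260, -0.0500],   # -> kni
])
_TRUTH_R = np.array([14.0, 16.0, 16.0, 16.0])
_TRUTH_D = np.array([0.15, 0.12, 0.12, 0.12])
_TRUTH_HALF_LIFE = np.array([9.0, 8.0, 9.0, 9.0])


def default_ground_truth(seed: int = 0) -> GroundTruth:
    """The fixture circuit with its external inputs and initial condition."""
    params = CircuitParameters(T=_TRUTH_T.copy(), E=_TRUTH_E.copy(),
                               R=_TRUTH_R.copy(), D=_TRUTH_D.copy(),
                               lam=np.log(2.0) / _TRUTH_HALF_LIFE)
    external = make_external_inputs(seed=seed)
    pos, hb = default_hb_c12()
    return GroundTruth(params, pos, hb, external, seed)


def simulate_dataset(truth: GroundTruth, noise: NoiseModel | None = None,
                     seed: int = 0,
                     schedule: Schedule = DEFAULT_SCHEDULE
                     ) -> ExpressionDataset:
    """Two-genotype expression tables drawn from a known circuit.

    Wild-type rows cover all four gap genes at the nine comparison time
    points; Kr rows are dropped from the mutant partition (there is no Kr
    product to observe in the null).  Observational noise follows the
    heteroscedastic noise model when given; the same truth with
    ``noise=None`` yields a dataset on which the truth has zero cost.
    """
    roster = truth.params.roster
    grid13 = NucleusGrid.c13()
    init = initial_state_from_hb(truth.hb_c12_positions,
                                 truth.hb_c12_levels, grid13, roster)
    wt, mut = run_pair(truth.params, truth.external, init, schedule,
                       grid=grid13)
    rng = np.random.default_rng(seed)
    frames = []
    for traj, genes in ((wt, roster.gap_genes),
                        (mut, ("hb", "gt", "kni"))):
        df = traj.to_frame()
        df = df[df["gene"].isin(genes)].reset_index(drop=True)
        lv = np.clip(df["level"].to_numpy(float), 0.0, MAX_LEVEL)
        if noise is not None:
            lv = noise.apply(rng, lv)
        df["level"] = lv
        frames.append(df)
    obs = pd.concat(frames, ignore_index=True)[list(OBS_COLUMNS)]
    return ExpressionDataset(obs, truth.external, truth.hb_c12_positions,
                             truth.hb_c12_levels,
                             wt_label=wt.genotype.label,
                             mut_label=mut.genotype.label, roster=roster)


# ---------------------------------------------------------------------------
# phenomenological profiles
# ---------------------------------------------------------------------------

def _drift(start, total_shift, k, n=8):
    """Peak position at class k (1-based) for a domain drifting anterior by
    ``total_shift`` %EL between T1 and T8."""
    return start - total_shift * (k - 1) / (n - 1)


def phenomenological_profiles(seed: int = 0,
                              noise: NoiseModel | None = None,
                              schedule: Schedule = DEFAULT_SCHEDULE,
                              roster: GeneRoster = DEFAULT_ROSTER
                              ) -> ExpressionDataset:
    """Gaussian-bump dataset with the descriptive mutant geometry.

    Wild-type domains drift anterior modestly over cycle 14A; the Kr-null
    variant has a posterior gt domain drifting exactly 15 %EL anterior
    (ending about 10 %EL anterior of its wild-type position), a kni domain
    drifting 1.8 %EL, an hb domain whose late levels fall to half the
    wild-type level, and a depressed, late-declining gt/kni amplitude.
    Intended for feature-extraction and screen tests, not for parameter
    recovery.
    """
    grid13 = NucleusGrid.c13()
    grid14 = NucleusGrid.c14a()
    rng = np.random.default_rng(seed)

    # gene -> (T1 center, T1->T8 anterior drift, width, amplitudes T1..T8)
    wt_spec = {
        "hb": (87.0, 3.0, 3.5,
               np.array([120, 150, 175, 185, 185, 178, 168, 155.0])),
        "Kr": (52.0, 2.5, 4.5,
               np.array([150, 185, 210, 220, 215, 205, 192, 178.0])),
        "gt": (80.5, 5.0, 4.0,
               np.array([110, 135, 155, 165, 162, 152, 140, 128.0])),
        "kni": (68.0, 4.5, 4.0,
                np.array([135, 165, 185, 195, 190, 180, 166, 150.0])),
    }
    mut_spec = {
        "hb": (87.0, 3.0, 3.5,
               np.array([120, 150, 172, 170, 150, 120, 84, 70.0])),
        "gt": (80.5, 15.0, 4.0,
               np.array([90, 115, 135, 145, 130, 105, 75, 55.0])),
        "kni": (66.0, 1.8, 4.0,
                np.array([90, 95, 98, 98, 95, 92, 88, 82.0])),
    }
    # wild-type hb T7 level is 168; the mutant value 84 is exactly half.

    def bump(x, center, width, amp):
        return amp * np.exp(-0.5 * ((x - center) / width) ** 2)

    rows = []
    for glabel, spec in (("wt", wt_spec), ("Kr_null", mut_spec)):
        for gene, (c0, drift, width, amps) in spec.items():
            # C13: nascent domain at 40% of the T1 level
            prof = bump(grid13.positions, c0, width, 0.4 * amps[0])
            rows.append(pd.DataFrame({
                "genotype": glabel, "gene": gene, "time_class": "C13",
                "position_EL": grid13.positions, "level": prof}))
            for k in range(1, 9):
                prof = bump(grid14.positions, _drift(c0, drift, k), width,
                            amps[k - 1])
                rows.append(pd.DataFrame({
                    "genotype": glabel, "gene": gene,
                    "time_class": f"T{k}",
                    "position_EL": grid14.positions, "level": prof}))
    obs = pd.concat(rows, ignore_index=True)
    if noise is not None:
        obs["level"] = noise.apply(rng, obs["level"].to_numpy(float))
    external = make_external_inputs(seed=seed, schedule=schedule,
                                    roster=roster)
    pos, hb = default_hb_c12()
    return ExpressionDataset(obs[list(OBS_COLUMNS)], external, pos, hb,
                             wt_label="wt", mut_label="Kr_null",
                             roster=roster)
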