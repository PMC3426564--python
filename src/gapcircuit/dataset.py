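"""Two-genotype expression dataset consumed by the cost function.

Observations are long-format rows (genotype, gene, time_class, position_EL,
level) on the 0-255 fluorescence scale.  The wild-type partition covers all
four gap genes at the nine comparison time points; the Kr-null partition
covers only hb, gt and kni (there is no Kr protein to stain in the mutant,
and the model is fitted to three genes there).  The dataset also carries the
cycle-12 hb profile used as the initial condition and the external-input
anchor profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (DEFAULT_ROSTER, CircuitError, ExternalInputSeries,
                    GeneRoster, MAX_LEVEL)
from .simulate import TIME_CLASSES

__all__ = ["ExpressionDataset", "OBS_COLUMNS"]

OBS_COLUMNS = ("genotype", "gene", "time_class", "position_EL", "level")


@dataclass
class ExpressionDataset:
    """Observation tables for the simultaneous two-genotype fit."""

    observations: pd.DataFrame
    external: ExternalInputSeries
    hb_c12_positions: np.ndarray
    hb_c12_levels: np.ndarray
    wt_label: str = "wt"
    mut_label: str = "Kr_null"
    roster: GeneRoster = field(default=DEFAULT_ROSTER)

    def __post_init__(self):
        obs = self.observations
        missing = set(OBS_COLUMNS) - set(obs.columns)
        if missing:
            raise CircuitError(f"observations lack columns {sorted(missing)}")
        self.observations = obs = obs.reset_index(drop=True)
        self.hb_c12_positions = np.asarray(self.hb_c12_positions, float)
        self.hb_c12_levels = np.asarray(self.hb_c12_levels, float)

        bad_gene = ~obs["gene"].isin(self.roster.gap_genes)
        if bad_gene.any():
            raise CircuitError(
                f"unknown gap gene(s) {sorted(obs.loc[bad_gene, 'gene'].unique())}")
        bad_tc = ~obs["time_class"].isin(TIME_CLASSES)
        if bad_tc.any():
            raise CircuitError(
                f"unknown time class(es) "
                f"{sorted(obs.loc[bad_tc, 'time_class'].unique())}")
        levels = obs["level"].to_numpy(float)
        bad = np.nonzero(~((levels >= 0) & (levels <= MAX_LEVEL)))[0]
        if bad.size:
            raise CircuitError(
                f"level outside [0, {MAX_LEVEL:g}] at row {bad[0]} "
                f"(level={levels[bad[0]]!r})")
        genotypes = set(obs["genotype"].unique())
        unknown = genotypes - {self.wt_label, self.mut_label}
        if unknown:
            raise CircuitError(f"unknown genotype label(s) {sorted(unknown)}")
        mut = obs[obs["genotype"] == self.mut_label]
        if (mut["gene"] == "Kr").any():
            raise CircuitError("the mutant partition must not contain Kr "
                               "rows: the model is fitted to hb, gt and kni "
                               "only in the Kr-null genotype")

    @property
    def n_observations(self) -> int:
        return len(self.observations)

    @property
    def wt_mask(self) -> np.ndarray:
        """Boolean mask of wild-type observation rows."""
        return (self.observations["genotype"] == self.wt_label).to_numpy()

    def partition(self, genotype_label: str) -> pd.DataFrame:
        return self.observations[
            self.observations["genotype"] == genotype_label]

    def mutant_genes(self) -> list:
        return sorted(self.partition(self.mut_label)["gene"].unique())
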