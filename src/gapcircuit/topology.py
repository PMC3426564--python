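"""Classification of fitted regulatory weights into network topologies.

Each element of the inter-connectivity matrices T and E is classified as
activation (> 0.005), repression (< -0.005) or no interaction (the closed
interval [-0.005, 0.005]).  Votes across an ensemble of fitted circuits
yield a majority topology; consensus circuits are the members whose
classifications agree with the majority everywhere.  Confidence intervals
refine the table: a majority sign whose intervals contain zero in almost
all circuits is downgraded to insignificant, and sign-mixed cells are
flagged ambiguous.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import DEFAULT_ROSTER, CircuitError, GeneRoster, GENE_LETTERS

__all__ = ["InteractionCategory", "VoteTable", "classify_weight", "vote",
           "consensus_circuits", "refine_with_identifiability",
           "SIGN_THRESHOLD"]

#: classification threshold on regulatory weights
SIGN_THRESHOLD = 0.005


class InteractionCategory(str, enum.Enum):
    ACTIVATION = "activation"
    REPRESSION = "repression"
    NO_INTERACTION = "no_interaction"
    INSIGNIFICANT_ACTIVATION = "insignificant_activation"
    INSIGNIFICANT_REPRESSION = "insignificant_repression"
    AMBIGUOUS = "ambiguous"


def classify_weight(w: float,
                    threshold: float = SIGN_THRESHOLD) -> InteractionCategory:
    """Classify one regulatory weight.

    The boundary |w| = threshold maps to no interaction (closed interval,
    the conservative convention)."""
    if not np.isfinite(w):
        raise CircuitError("weight must be finite")
    if w > threshold:
        return InteractionCategory.ACTIVATION
    if w < -threshold:
        return InteractionCategory.REPRESSION
    return InteractionCategory.NO_INTERACTION


@dataclass
class VoteTable:
    """Per-cell classification counts across an ensemble.

    ``counts[a, b]`` = (activation, no interaction, repression) votes for
    regulator b acting on target a; counts sum to the ensemble size in
    every cell.  Ties for the majority are marked ambiguous.
    """

    targets: tuple
    regulators: tuple
    counts: np.ndarray            # (n_targets, n_regulators, 3)
    majority: np.ndarray          # object array of InteractionCategory
    n_circuits: int

    def __post_init__(self):
        if not np.all(self.counts.sum(axis=2) == self.n_circuits):
            raise CircuitError("vote counts must sum to the ensemble size")

    def cell(self, target: str, regulator: str):
        a = self.targets.index(target)
        b = self.regulators.index(regulator)
        return tuple(self.counts[a, b]), self.majority[a, b]

    def to_frame(self) -> pd.DataFrame:
        """Delimited-text layout: rows = targets, columns = regulators,
        cells = 'act/none/rep counts : category'."""
        data = {}
        for b, reg in enumerate(self.regulators):
            col = []
            for a in range(len(self.targets)):
                c = self.counts[a, b]
                col.append(f"{c[0]}/{c[1]}/{c[2]}:{self.majority[a, b].value}")
            data[GENE_LETTERS.get(reg, reg)] = col
        return pd.DataFrame(
            data, index=[GENE_LETTERS.get(t, t) for t in self.targets])


def _weight_matrix(member) -> np.ndarray:
    """(n_gap, n_gap + n_external) weights of one circuit (T then E)."""
    return np.hstack([member.T, member.E])


def vote(ensemble, threshold: float = SIGN_THRESHOLD,
         roster: GeneRoster = DEFAULT_ROSTER) -> VoteTable:
    """Build the vote table of an ensemble (Ensemble or list of
    CircuitParameters)."""
    members = getattr(ensemble, "members", ensemble)
    if not len(members):
        raise CircuitError("vote requires a nonempty ensemble")
    regs = roster.gap_genes + roster.external_inputs
    tgts = roster.gap_genes
    counts = np.zeros((len(tgts), len(regs), 3), dtype=int)
    cats = (InteractionCategory.ACTIVATION,
            InteractionCategory.NO_INTERACTION,
            InteractionCategory.REPRESSION)
    for member in members:
        W = _weight_matrix(member)
        for a in range(len(tgts)):
            for b in range(len(regs)):
                counts[a, b, cats.index(classify_weight(W[a, b],
                                                        threshold))] += 1
    majority = np.empty((len(tgts), len(regs)), dtype=object)
    for a in range(len(tgts)):
        for b in range(len(regs)):
            c = counts[a, b]
            top = np.nonzero(c == c.max())[0]
            majority[a, b] = (cats[top[0]] if top.size == 1
                              else InteractionCategory.AMBIGUOUS)
    return VoteTable(tgts, regs, counts, majority, len(members))


def consensus_circuits(ensemble, topology: VoteTable,
                       threshold: float = SIGN_THRESHOLD) -> list:
    """Members whose per-cell classifications all coincide with the majority
    topology.  Returns the indices of the consensus circuits."""
    members = getattr(ensemble, "members", ensemble)
    out = []
    for k, member in enumerate(members):
        W = _weight_matrix(member)
        ok = True
        for a in range(len(topology.targets)):
            for b in range(len(topology.regulators)):
                if classify_weight(W[a, b], threshold) \
                        != topology.majority[a, b]:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            out.append(k)
    return out


def refine_with_identifiability(topology: VoteTable, intervals,
                                almost_all: float = 0.8) -> VoteTable:
    """Refine a vote table with per-circuit confidence intervals.

    ``intervals`` is a sequence (one entry per circuit) of mappings from
    the two-letter weight label (e.g. ``"HK"``) to objects with
    ``lower``/``upper`` attributes.  For a majority-activation cell whose
    estimates are positive in at least ``almost_all`` of the circuits but
    whose intervals contain zero in at least ``almost_all`` of them, the
    category is downgraded to insignificant activation (symmetrically for
    repression).  Cells whose estimate signs are mixed beyond the
    ``almost_all`` fraction become ambiguous.  Refinement never flips
    activation and repression.
    """
    n = topology.n_circuits
    if len(intervals) != n:
        raise CircuitError("need one interval set per circuit")
    refined = topology.majority.copy()
    for a, tgt in enumerate(topology.targets):
        for b, reg in enumerate(topology.regulators):
            label = GENE_LETTERS[tgt] + GENE_LETTERS[reg]
            cat = topology.majority[a, b]
            if cat not in (InteractionCategory.ACTIVATION,
                           InteractionCategory.REPRESSION):
                continue
            cis = [circ[label] for circ in intervals]
            ests = np.array([0.5 * (ci.lower + ci.upper)
                             if getattr(ci, "estimate", None) is None
                             else ci.estimate for ci in cis])
            sign = 1.0 if cat is InteractionCategory.ACTIVATION else -1.0
            frac_sign = float(np.mean(sign * ests > 0))
            if frac_sign < almost_all:
                refined[a, b] = InteractionCategory.AMBIGUOUS
                continue
            straddle = float(np.mean([ci.lower < 0 < ci.upper
                                      for ci in cis]))
            if straddle >= almost_all:
                refined[a, b] = (
                    InteractionCategory.INSIGNIFICANT_ACTIVATION
                    if sign > 0
                    else InteractionCategory.INSIGNIFICANT_REPRESSION)
    return VoteTable(topology.targets, topology.regulators,
                     topology.counts.copy(), refined, n)
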