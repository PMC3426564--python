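"""Core data model and right-hand-side mathematics of the gap-gene circuit.

The model describes protein concentrations of the four trunk gap genes
(*hb*, *Kr*, *gt*, *kni*) in a 1-D row of blastoderm nuclei spanning the
posterior half of the embryo (47--92% egg length).  Within each nucleus the
synthesis rate of gene ``a`` is a sigmoid function of the total regulatory
input

    u^a_i = sum_b T[a,b] * alpha_b * v^b_i + sum_e E[a,e] * y_e(i, t) + h_a

where ``v`` are gap-protein concentrations, ``y`` the external regulator
concentrations (Bcd, Cad, Tll, supplied as data), ``T``/``E`` the genetic
inter-connectivity matrices, ``h`` a promoter threshold, and ``alpha`` a
per-gene genotype scaling used to express null mutants (``alpha = 0``) and
graded in-silico knockouts.  Between divisions each concentration evolves by

    dv^a_i/dt = R_a * g(u^a_i) + D_a * (v^a_{i-1} - 2 v^a_i + v^a_{i+1})
                - lambda_a * v^a_i

with zero-flux boundary conditions (the missing neighbour term is dropped at
either end).  During mitosis the synthesis term is switched off; at nuclear
division each nucleus is replaced by two daughters inheriting its state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GAP_GENES",
    "EXTERNAL_INPUTS",
    "REGION",
    "GENE_LETTERS",
    "GeneRoster",
    "CircuitParameters",
    "NucleusGrid",
    "Genotype",
    "StateVector",
    "ExternalInputSeries",
    "g",
    "regulation_input",
    "interphase_rhs",
    "mitosis_rhs",
    "divide",
    "parameter_labels",
    "default_bounds",
]

GAP_GENES = ("hb", "Kr", "gt", "kni")
EXTERNAL_INPUTS = ("bcd", "cad", "tll")

#: modeled anteroposterior region in % egg length (anterior = 0%)
REGION = (47.0, 92.0)

#: single-letter labels used in parameter names (first letter = target gene)
GENE_LETTERS = {"hb": "H", "Kr": "K", "gt": "G", "kni": "N",
                "bcd": "B", "cad": "C", "tll": "T"}

#: maximum fluorescence level of the 8-bit expression scale
MAX_LEVEL = 255.0

#: fixed promoter threshold shared by all genes
DEFAULT_H = -3.5


class CircuitError(ValueError):
    """Structural or domain error in circuit inputs."""


@dataclass(frozen=True)
class GeneRoster:
    """Ordered gene labels of the circuit.

    The standard configuration has four gap genes and three external inputs;
    Kr must be present for Kr-null genotypes to be expressible.
    """

    gap_genes: tuple = GAP_GENES
    external_inputs: tuple = EXTERNAL_INPUTS

    def __post_init__(self):
        labels = self.gap_genes + self.external_inputs
        if len(set(labels)) != len(labels):
            raise CircuitError("gene labels must be unique")

    @property
    def n_gap(self) -> int:
        return len(self.gap_genes)

    @property
    def n_external(self) -> int:
        return len(self.external_inputs)

    def gap_index(self, gene: str) -> int:
        try:
            return self.gap_genes.index(gene)
        except ValueError:
            raise CircuitError(f"unknown gap gene {gene!r}") from None


DEFAULT_ROSTER = GeneRoster()


@dataclass
class CircuitParameters:
    """All fitted quantities of the circuit equations.

    Attributes
    ----------
    T : (n_gap, n_gap) array
        Gap-gap regulatory weights; row = target gene, column = regulator.
        Units are inverse concentration (fluorescence units^-1).
    E : (n_gap, n_external) array
        Weights of the external inputs Bcd, Cad, Tll on each gap gene.
    h : (n_gap,) array
        Promoter thresholds (dimensionless); fixed at -3.5 during fitting.
    R : (n_gap,) array
        Maximum synthesis rates (fluorescence units / min); > 0.
    D : (n_gap,) array
        Nearest-neighbour diffusion couplings as they appear in the
        equations (min^-1); >= 0.  The same value applies in both cycles.
    lam : (n_gap,) array
        First-order decay rates (min^-1); > 0.  Protein half-life is
        ln(2)/lam minutes.
    """

    T: np.ndarray
    E: np.ndarray
    R: np.ndarray
    D: np.ndarray
    lam: np.ndarray
    h: np.ndarray | None = None
    roster: GeneRoster = field(default=DEFAULT_ROSTER)

    def __post_init__(self):
        ng, ne = self.roster.n_gap, self.roster.n_external
        self.T = np.asarray(self.T, dtype=float)
        self.E = np.asarray(self.E, dtype=float)
        self.R = np.asarray(self.R, dtype=float).reshape(ng)
        self.D = np.asarray(self.D, dtype=float).reshape(ng)
        self.lam = np.asarray(self.lam, dtype=float).reshape(ng)
        if self.h is None:
            self.h = np.full(ng, DEFAULT_H)
        else:
            self.h = np.asarray(self.h, dtype=float).reshape(ng)
        if self.T.shape != (ng, ng) or self.E.shape != (ng, ne):
            raise CircuitError("T/E shape mismatch with gene roster")
        for name, arr in (("T", self.T), ("E", self.E), ("h", self.h),
                          ("R", self.R), ("D", self.D), ("lam", self.lam)):
            if not np.all(np.isfinite(arr)):
                raise CircuitError(f"non-finite entries in {name}")
        # R and lam are strictly positive for any fitted circuit (the search
        # bounds enforce that); zero is admitted here so that degenerate
        # diagnostic circuits (pure decay, conservative transport) can be
        # simulated.
        if np.any(self.R < 0):
            raise CircuitError("synthesis rates R must be nonnegative")
        if np.any(self.D < 0):
            raise CircuitError("diffusion couplings D must be nonnegative")
        if np.any(self.lam < 0):
            raise CircuitError("decay rates lam must be nonnegative")

    @property
    def half_life(self) -> np.ndarray:
        """Protein half-lives ln(2)/lam in minutes."""
        return np.log(2.0) / self.lam

    # -- free-parameter vector (h is fixed, not part of the vector) -------

    def to_vector(self) -> np.ndarray:
        """Pack the 40 free parameters: per target gene
        [T row (4), E row (3), R, D, lam]."""
        blocks = [
            np.concatenate([self.T[a], self.E[a],
                            [self.R[a], self.D[a], self.lam[a]]])
            for a in range(self.roster.n_gap)
        ]
        return np.concatenate(blocks)

    @classmethod
    def from_vector(cls, vec, h=None, roster: GeneRoster = DEFAULT_ROSTER):
        ng, ne = roster.n_gap, roster.n_external
        per = ng + ne + 3
        vec = np.asarray(vec, dtype=float)
        if vec.size != ng * per:
            raise CircuitError(f"expected {ng * per} free parameters, "
                               f"got {vec.size}")
        blocks = vec.reshape(ng, per)
        return cls(T=blocks[:, :ng].copy(), E=blocks[:, ng:ng + ne].copy(),
                   R=blocks[:, ng + ne].copy(), D=blocks[:, ng + ne + 1].copy(),
                   lam=blocks[:, ng + ne + 2].copy(), h=h, roster=roster)

    def copy(self) -> "CircuitParameters":
        return CircuitParameters(T=self.T.copy(), E=self.E.copy(),
                                 R=self.R.copy(), D=self.D.copy(),
                                 lam=self.lam.copy(), h=self.h.copy(),
                                 roster=self.roster)


def parameter_labels(roster: GeneRoster = DEFAULT_ROSTER) -> list:
    """Labels of the free-parameter vector.

    Regulatory weights use the two-letter field convention (first letter =
    target): ``HK`` is the action of Kr on *hb*.  Rate constants are
    ``R_<gene>``, ``D_<gene>``, ``lam_<gene>``.
    """
    labels = []
    for tgt in roster.gap_genes:
        t = GENE_LETTERS[tgt]
        labels.extend(t + GENE_LETTERS[reg] for reg in roster.gap_genes)
        labels.extend(t + GENE_LETTERS[reg] for reg in roster.external_inputs)
        labels.extend((f"R_{tgt}", f"D_{tgt}", f"lam_{tgt}"))
    return labels


def default_bounds(roster: GeneRoster = DEFAULT_ROSTER):
    """Default biologically-motivated search bounds for the free parameters.

    Regulatory weights in [-0.1, 0.1] (fluorescence^-1), synthesis rates in
    (0, 30] units/min, diffusion couplings in [0, 0.3] min^-1, and decay
    rates constrained to protein half-lives between 5 and 20 minutes.
    Returns (lower, upper) arrays of length 10 * n_gap.
    """
    ng, ne = roster.n_gap, roster.n_external
    lo_block = np.concatenate([np.full(ng + ne, -0.1),
                               [0.5, 0.0, np.log(2.0) / 20.0]])
    hi_block = np.concatenate([np.full(ng + ne, 0.1),
                               [30.0, 0.3, np.log(2.0) / 5.0]])
    return np.tile(lo_block, ng), np.tile(hi_block, ng)


@dataclass(frozen=True)
class NucleusGrid:
    """Uniform 1-D row of nuclei spanning the modeled region.

    Nucleus centres sit at ``x_min + (i - 1/2) * span / n``; the cycle-14A
    grid has exactly twice the nuclei of the cycle-13 grid (one division).
    """

    cycle: str
    n: int
    positions: np.ndarray

    C13_N = 23
    C14A_N = 46

    def __post_init__(self):
        if self.cycle not in ("C13", "C14A"):
            raise CircuitError(f"unknown cycle {self.cycle!r}")
        pos = np.asarray(self.positions, dtype=float)
        if pos.size != self.n or np.any(np.diff(pos) <= 0):
            raise CircuitError("positions must be strictly increasing, one "
                               "per nucleus")
        object.__setattr__(self, "positions", pos)

    @classmethod
    def c13(cls, n: int = C13_N, region=REGION) -> "NucleusGrid":
        return cls("C13", n, _centers(n, region))

    @classmethod
    def c14a(cls, n: int = C14A_N, region=REGION) -> "NucleusGrid":
        return cls("C14A", n, _centers(n, region))

    @property
    def spacing(self) -> float:
        return float(self.positions[1] - self.positions[0])

    def divided(self) -> "NucleusGrid":
        """Grid after the 13th nuclear division: count doubles, spacing
        halves."""
        if self.cycle != "C13":
            raise CircuitError("only a cycle-13 grid can divide")
        lo = self.positions[0] - 0.5 * self.spacing
        hi = self.positions[-1] + 0.5 * self.spacing
        return NucleusGrid("C14A", 2 * self.n, _centers(2 * self.n, (lo, hi)))


def _centers(n: int, region) -> np.ndarray:
    lo, hi = region
    span = hi - lo
    return lo + (np.arange(n) + 0.5) * span / n


@dataclass(frozen=True)
class Genotype:
    """Genotype expressed as per-gap-gene scaling of regulatory output.

    ``alpha[a] = 1`` is the functional allele, ``alpha[a] = 0`` a null.
    Intermediate values implement the graded in-silico knockout scan.  A
    gene with ``alpha = 0`` is treated as a null: its regulatory output
    vanishes and (all four gap genes being zygotic in the modeled region,
    with hb's maternal contribution supplied via the initial condition of
    the wild-type channel) its protein channel is clamped to zero.
    """

    label: str
    alpha: np.ndarray
    roster: GeneRoster = field(default=DEFAULT_ROSTER)

    def __post_init__(self):
        a = np.asarray(self.alpha, dtype=float).reshape(self.roster.n_gap)
        if np.any(a < 0) or np.any(a > 1):
            raise CircuitError("genotype scaling alpha must lie in [0, 1]")
        object.__setattr__(self, "alpha", a)

    @classmethod
    def wildtype(cls, roster: GeneRoster = DEFAULT_ROSTER) -> "Genotype":
        return cls("wt", np.ones(roster.n_gap), roster)

    @classmethod
    def null(cls, *genes: str,
             roster: GeneRoster = DEFAULT_ROSTER) -> "Genotype":
        alpha = np.ones(roster.n_gap)
        for gene in genes:
            alpha[roster.gap_index(gene)] = 0.0
        label = ";".join(f"{g}_null" for g in genes)
        return cls(label, alpha, roster)

    @classmethod
    def kr_null(cls, roster: GeneRoster = DEFAULT_ROSTER) -> "Genotype":
        g = cls.null("Kr", roster=roster)
        return replace(g, label="Kr_null")

    @classmethod
    def graded(cls, gene: str, alpha: float,
               roster: GeneRoster = DEFAULT_ROSTER) -> "Genotype":
        """Graded knockout: scale one gene's regulatory output by alpha."""
        a = np.ones(roster.n_gap)
        a[roster.gap_index(gene)] = alpha
        return cls(f"{gene}_alpha={alpha:g}", a, roster)

    @property
    def active(self) -> np.ndarray:
        """Boolean mask of genes whose protein channel is simulated."""
        return self.alpha > 0.0

    @property
    def is_wildtype(self) -> bool:
        return bool(np.all(self.alpha == 1.0))


@dataclass
class StateVector:
    """Concentrations v[a, i] (fluorescence units, 0-255 scale) at time t
    (minutes from the start of cycle 13)."""

    v: np.ndarray
    t: float

    def __post_init__(self):
        self.v = np.asarray(self.v, dtype=float)
        if self.v.ndim != 2:
            raise CircuitError("state must be a (n_genes, n_nuclei) array")


@dataclass
class ExternalInputSeries:
    """External regulator concentrations anchored at discrete times.

    Values are stored per input on a reference position grid at the anchor
    times t = -6.2 (midpoint of cycle 12), t = 10.55 (midpoint of cycle 13)
    and the eight cycle-14A time-class midpoints, and interpolated piecewise
    linearly in time (clamped outside the anchor range, so the last class
    midpoint value holds until gastrulation).  Spatial evaluation on a
    nucleus grid uses linear interpolation with edge clamping.
    """

    times: np.ndarray
    positions: np.ndarray
    values: np.ndarray  # (n_external, n_times, n_positions)
    roster: GeneRoster = field(default=DEFAULT_ROSTER)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        ne = self.roster.n_external
        if self.values.shape != (ne, self.times.size, self.positions.size):
            raise CircuitError("external-input value array has wrong shape")
        if np.any(np.diff(self.times) <= 0):
            raise CircuitError("anchor times must be strictly increasing")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise CircuitError("external-input values must be finite and "
                               ">= 0")

    def on_grid(self, grid: NucleusGrid) -> np.ndarray:
        """Anchor values re-sampled at the grid's nucleus positions;
        shape (n_external, n_times, grid.n)."""
        ne, nt = self.values.shape[:2]
        out = np.empty((ne, nt, grid.n))
        for e in range(ne):
            for k in range(nt):
                out[e, k] = np.interp(grid.positions, self.positions,
                                      self.values[e, k])
        return out

    def at(self, t: float, grid: NucleusGrid) -> np.ndarray:
        """Concentrations y_e(i, t) on the grid; shape (n_external, n)."""
        anchors = self.on_grid(grid)
        return _interp_time(self.times, anchors, t)

    @property
    def t_min(self) -> float:
        return float(self.times[0])


def _interp_time(times, anchors, t):
    t = float(t)
    if t <= times[0]:
        return anchors[:, 0].copy()
    if t >= times[-1]:
        return anchors[:, -1].copy()
    k = int(np.searchsorted(times, t))
    w = (t - times[k - 1]) / (times[k] - times[k - 1])
    return (1 - w) * anchors[:, k - 1] + w * anchors[:, k]


# ---------------------------------------------------------------------------
# right-hand-side mathematics (reference NumPy implementation; the numba
# kernels in _kernels.py mirror these and are checked against them in tests)
# ---------------------------------------------------------------------------

def g(u):
    """Sigmoid regulation-expression function, g(u) = (u/sqrt(1+u^2)+1)/2.

    Monotone increasing, antisymmetric about (0, 1/2), with limits 0 and 1.
    """
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise CircuitError("regulatory input u must be finite")
    out = 0.5 * (u / np.sqrt(1.0 + u * u) + 1.0)
    return out if out.ndim else float(out)


def total_input(params: CircuitParameters, genotype: Genotype,
                v: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Total regulatory input u[a, i] for all genes and nuclei.

    ``v`` is the (n_gap, n) state, ``y`` the (n_external, n) external
    concentrations at the evaluation time.
    """
    Talpha = params.T * genotype.alpha[None, :]
    return Talpha @ v + params.E @ y + params.h[:, None]


def regulation_input(params: CircuitParameters, genotype: Genotype,
                     state: StateVector, external: ExternalInputSeries,
                     gene: int, nucleus: int, t: float,
                     grid: NucleusGrid) -> float:
    """Total regulatory input u^a_i at one (gene, nucleus, time) point."""
    ng, n = state.v.shape
    if not (0 <= gene < ng and 0 <= nucleus < n):
        raise CircuitError("gene or nucleus index out of range")
    if n != grid.n:
        raise CircuitError("state and grid disagree on nucleus count")
    if t < external.t_min:
        raise CircuitError(f"time {t} precedes the external-input span")
    y = external.at(t, grid)
    u = total_input(params, genotype, state.v, y)
    return float(u[gene, nucleus])


def _laplacian(v: np.ndarray) -> np.ndarray:
    """Nearest-neighbour coupling with zero-flux ends (missing neighbour
    term dropped)."""
    lap = np.zeros_like(v)
    lap[:, 1:] += v[:, :-1] - v[:, 1:]
    lap[:, :-1] += v[:, 1:] - v[:, :-1]
    return lap


def interphase_rhs(params: CircuitParameters, genotype: Genotype,
                   state: StateVector, external: ExternalInputSeries,
                   t: float, grid: NucleusGrid) -> np.ndarray:
    """dv/dt during interphase: synthesis + diffusion - decay."""
    y = external.at(t, grid)
    u = total_input(params, genotype, state.v, y)
    dv = (params.R[:, None] * g(u) + params.D[:, None] * _laplacian(state.v)
          - params.lam[:, None] * state.v)
    dv[~genotype.active] = 0.0
    return dv

def mitosis_rhs(params: CircuitParameters, genotype: Genotype,
                state: StateVector, t: float) -> np.ndarray:
    """dv/dt during mitosis: only transport and decay (no synthesis)."""
    dv = (params.D[:, None] * _laplacian(state.v)
          - params.lam[:, None] * state.v)
    dv[~genotype.active] = 0.0
    return dv


def divide(state: StateVector, grid: NucleusGrid):
    """Nuclear division: each nucleus is replaced by two daughters that
    inherit the mother's state; the inter-nuclear distance is halved."""
    if grid.cycle != "C13":
        raise CircuitError("division applies to a cycle-13 grid only")
    if state.v.shape[1] != grid.n:
        raise CircuitError("state and grid disagree on nucleus count")
    v_new = np.repeat(state.v, 2, axis=1)
    return StateVector(v_new, state.t), grid.divided()
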