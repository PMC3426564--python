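"""Decompose regulatory inputs and run the graded Kr knockout scan.

For the fixture circuit this prints (i) the additive contribution of each
regulator to gt at the gt domain peak, early versus late - showing the
activating Cad input decaying while repression persists - and (ii) the
graded in-silico knockout: gap-protein levels at reference points as the
Kr regulatory output is scaled by alpha = 1 ... 0, which vary monotonically
between the wild-type and null endpoints.
"""

import numpy as np

from gapcircuit import (Genotype, NucleusGrid, initial_state_from_hb,
                        knockout_scan, run, decompose)
from gapcircuit.contributions import features_from_trajectory
from gapcircuit.synthetic import default_ground_truth

truth = default_ground_truth()
grid13 = NucleusGrid.c13()
init = initial_state_from_hb(truth.hb_c12_positions, truth.hb_c12_levels,
                             grid13)
wt = run(truth.params, Genotype.wildtype(), truth.external, init,
         grid=grid13)
dec = decompose(wt, truth.params, truth.external)
feats = features_from_trajectory(wt, min_level=20.0)

print("contributions to the gt regulatory input u at the gt peak:")
for tc in ("T1", "T7"):
    row = feats[(feats.gene == "gt") & (feats.time_class == tc)]
    pos = float(row.peak_position.iloc[0])
    k = list(dec.time_classes).index(tc)
    a = dec.targets.index("gt")
    terms = {reg: float(np.interp(pos, dec.positions[k],
                                  dec.terms[k][a, dec.regulators.index(reg)]))
             for reg in dec.regulators}
    total = sum(terms.values()) + float(dec.h[a])
    pretty = "  ".join(f"{r}:{v:+.2f}" for r, v in terms.items())
    print(f"  {tc} (peak {pos:.1f}%EL): {pretty}  h:{dec.h[a]:+.1f}"
          f"  -> u = {total:+.2f}")
print("the Cad term shrinks between T1 and T7 as the abdominal Cad level "
      "decays; gt increasingly relies on autoactivation.\n")

scan = knockout_scan(truth.params, truth.external, init,
                     alphas=(1.0, 0.6, 0.4, 0.025, 0.0))
print("graded Kr knockout: level at each gene's reference point vs alpha")
piv = scan.summary.pivot(index="alpha", columns="gene", values="level")
print(piv.sort_index(ascending=False).round(1).to_string())
print("monotone in alpha per gene:", scan.monotone)
print("alpha = 1 reproduces the wild type exactly and alpha = 0 the Kr "
      "null; intermediate alphas interpolate monotonically.")
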