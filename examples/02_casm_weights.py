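"""Damaging-vs-neutral discrimination of the CASM weight.

Trains the conservation-controlled amino-acid substitution model on a
synthetic damaging catalog and compares the per-variant likelihood-ratio
weight w = Pr(AAS|D)/Pr(AAS|N) between mutations drawn from the damaging
profile and mutations drawn from the neutral (rate-proportional) model —
the contrast that motivates weighting the burden test.  A Wilcoxon rank-sum
test quantifies the separation.
"""

import numpy as np

from dnmload.casm import mean_weight_contrast
from dnmload.io import MutationEvent
from dnmload.simulate import SimEngine, SimulationConfig, make_fixtures

config = SimulationConfig(seed=21)
engine = SimEngine.build(make_fixtures(config.seed, config))

rng = np.random.default_rng(22)
n = 400
neutral_atoms = engine.sampler.sample_atoms(rng, n)
causal_atoms = np.searchsorted(engine.causal_cum, rng.random(n))

w = engine.sampler.atom_pd / engine.sampler.atom_pn
as_events = lambda atoms: [
    MutationEvent("s", "g", "c", 1, "A", "T", ext_weight=float(w[a])) for a in atoms
]
mean_d, mean_n, p = mean_weight_contrast(
    engine.model, engine.null_dist, as_events(causal_atoms), as_events(neutral_atoms)
)
print(f"mean weight, damaging draws: {mean_d:.3f}")
print(f"mean weight, neutral draws:  {mean_n:.3f}")
print(f"rank-sum p: {p:.3g}")
print(
    "\nDamaging mutations concentrate in truncating and conserved-missense "
    "cells, so their mean weight exceeds the neutral mean."
)
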