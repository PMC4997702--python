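"""Poisson baseline tests for gene-level de novo mutation burden.

Poisson-all counts every protein-altering mutation (missense, nonsense,
stoploss, splice, frameshift and in-frame indels); Poisson-LGD counts only
likely gene-disrupting mutations (nonsense, splice, frameshift).  Each test
compares the observed class count to the expected cohort count under the
gene's mutational model with an upper-tail Poisson p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .rates import SubstitutionSpectrum

ALL_NONSYN = (
    "missense",
    "nonsense",
    "stoploss",
    "splice",
    "frameshift_indel",
    "inframe_indel",
)
LGD = ("nonsense", "splice", "frameshift_indel")


@dataclass(frozen=True)
class PoissonTestInput:
    observed_count: int
    lam: float

    def __post_init__(self):
        if not self.lam > 0:
            raise ValueError("lambda must be > 0")
        if self.observed_count < 0:
            raise ValueError("observed count must be >= 0")


def poisson_test(inp: PoissonTestInput) -> float:
    """Upper-tail p = P(X >= observed), X ~ Poisson(lambda)."""
    if inp.observed_count == 0:
        return 1.0
    return float(stats.poisson.sf(inp.observed_count - 1, inp.lam))


def class_lambda(
    spec: SubstitutionSpectrum,
    t_individuals: int,
    mutation_class: str,
) -> float:
    """Expected cohort count of the included mutation class.

    Per-haploid SNV rates are summed over class entries, the aggregate splice
    and indel rates added where the class includes them, and the total scaled
    by 2 haploid copies x t individuals.
    """
    if mutation_class == "all_nonsyn":
        consequences, with_splice, with_indel = ALL_NONSYN, True, True
    elif mutation_class == "lgd":
        consequences, with_splice, with_indel = LGD, True, True
    else:
        raise ValueError("mutation_class must be 'all_nonsyn' or 'lgd'")
    ent = spec.entries
    rate = float(ent.loc[ent["consequence"].isin(consequences), "rate"].sum())
    if with_splice:
        rate += spec.splice_rate
    if with_indel:
        # simulated indels are all frameshift, which both classes include
        rate += spec.indel_rate_gene
    return 2.0 * t_individuals * rate


def poisson_gene_test(
    spec: SubstitutionSpectrum,
    t_individuals: int,
    observed_count: int,
    mutation_class: str,
) -> float:
    """Convenience wrapper: class lambda + upper-tail Poisson p."""
    lam = class_lambda(spec, t_individuals, mutation_class)
    return poisson_test(PoissonTestInput(observed_count=observed_count, lam=lam))


def count_class_events(events, mutation_class: str) -> int:
    consequences = ALL_NONSYN if mutation_class == "all_nonsyn" else LGD
    return sum(1 for ev in events if ev.consequence in consequences)
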