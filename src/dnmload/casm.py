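"""Conservation-controlled amino-acid substitution model (CASM).

Pr(AAS|D) — the probability of observing a given amino-acid substitution
category in a given conservation bin, conditional on the mutation being
disease-causing — is estimated from a labeled catalog of damaging mutations
by additive (pseudocount) smoothing over the joint category x bin grid.
Paired with the gene's neutral distribution Pr(AAS|N), the ratio
w = Pr(AAS|D) / Pr(AAS|N) is the per-variant likelihood-ratio weight.

The same pseudocount scheme is applied to the neutral distribution when it
appears in the denominator (treating it as a catalog of the same effective
size), so the weight is finite and positive for every annotatable event.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .categories import CATEGORIES, CategorySpace, category_name
from .io import MutationEvent
from .rates import NullAASDistribution

logger = logging.getLogger(__name__)


@dataclass
class DamagingCatalog:
    """Labeled disease-causing mutations used to train Pr(AAS|D)."""

    records: pd.DataFrame  # consequence, aa_ref, aa_alt, cons_score (may be NaN)
    provenance: str = "unspecified"

    def __post_init__(self):
        if not len(self.records):
            raise ValueError("damaging catalog must be nonempty")
        scores = self.records["cons_score"]
        bad = scores.notna() & ((scores < 0) | (scores > 1))
        if bad.any():
            raise ValueError("catalog cons_score outside [0, 1]")

    def __len__(self) -> int:
        return len(self.records)


def read_catalog(path, provenance: str | None = None) -> DamagingCatalog:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["consequence", "aa_ref", "aa_alt", "cons_score"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: catalog missing columns {missing}")
    return DamagingCatalog(df[required], provenance=provenance or str(path))


def write_catalog(catalog: DamagingCatalog, path) -> None:
    catalog.records.to_csv(path, sep="\t", index=False, float_format="%.8g")


@dataclass
class CASMModel:
    """Smoothed Pr(AAS|D) over the (category x conservation bin) grid."""

    space: CategorySpace
    mass: np.ndarray  # (n_cells,), smoothed, sums to 1, all > 0
    pseudocount: float
    n_train: int
    provenance: str = "unspecified"

    def cell_mass(self, cell) -> np.ndarray:
        return self.mass[np.asarray(cell, dtype=int)]

    def to_json(self, path) -> None:
        payload = {
            "bin_edges": self.space.bin_edges.tolist(),
            "categories": list(CATEGORIES),
            "mass": self.mass.tolist(),
            "pseudocount": self.pseudocount,
            "n_train": self.n_train,
            "provenance": self.provenance,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "CASMModel":
        with open(path) as fh:
            payload = json.load(fh)
        if payload["categories"] != list(CATEGORIES):
            raise ValueError("stored model uses a different category vocabulary")
        return cls(
            space=CategorySpace(np.asarray(payload["bin_edges"])),
            mass=np.asarray(payload["mass"]),
            pseudocount=payload["pseudocount"],
            n_train=payload["n_train"],
            provenance=payload.get("provenance", "unspecified"),
        )


def train_casm(
    catalog: DamagingCatalog,
    bins: np.ndarray | None = None,
    pseudocount: float = 0.5,
) -> CASMModel:
    """Additive-smoothing estimate of Pr(AAS|D) from a damaging catalog.

    Records with a missing conservation score contribute their count spread
    uniformly over the bins of their category.
    """
    if not pseudocount > 0:
        raise ValueError("pseudocount must be > 0")
    space = CategorySpace(bins) if bins is not None else CategorySpace()
    counts = np.zeros(space.n_cells)
    for row in catalog.records.itertuples(index=False):
        cat = space.category_index(
            category_name(row.consequence, row.aa_ref, row.aa_alt)
        )
        if row.cons_score is None or (
            isinstance(row.cons_score, float) and np.isnan(row.cons_score)
        ):
            counts[space.cells_of_category(CATEGORIES[cat])] += 1.0 / space.n_bins
        else:
            counts[space.cell_index(cat, space.bin_of(row.cons_score))] += 1.0
    n = len(catalog)
    mass = (counts + pseudocount) / (n + pseudocount * space.n_cells)
    return CASMModel(
        space=space,
        mass=mass,
        pseudocount=pseudocount,
        n_train=n,
        provenance=catalog.provenance,
    )


def smoothed_null_mass(model: CASMModel, null_dist: NullAASDistribution) -> np.ndarray:
    """Pr(AAS|N) with the model's pseudocount scheme applied symmetrically."""
    if null_dist.space.n_bins != model.space.n_bins or not np.allclose(
        null_dist.space.bin_edges, model.space.bin_edges
    ):
        raise ValueError("null distribution and CASM model use different bins")
    n, pc = model.n_train, model.pseudocount
    return (null_dist.mass * n + pc) / (n + pc * model.space.n_cells)


def casm_weight(
    model: CASMModel,
    null_dist: NullAASDistribution,
    event: MutationEvent,
) -> float:
    """Per-variant likelihood-ratio weight w = Pr(AAS|D) / Pr(AAS|N).

    An externally supplied ``ext_weight`` is passed through unchanged.
    """
    if event.ext_weight is not None:
        return float(event.ext_weight)
    if event.consequence is None or event.cons_score is None:
        raise ValueError("event must be annotated before weighting")
    cell = model.space.cell_of(
        event.consequence, event.aa_ref, event.aa_alt, event.cons_score
    )
    pn = smoothed_null_mass(model, null_dist)[cell]
    return float(model.mass[cell] / pn)


# ---------------------------------------------------------------------------
# rank-sum contrast of weight sets


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p for the rank-sum statistic (ties OK)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n, nx = len(pooled), len(x)
    obs = ranks[:nx].sum()
    mean = nx * (n + 1) / 2.0
    hits = 0
    total = comb(n, nx)
    for idx in combinations(range(n), nx):
        if abs(ranks[list(idx)].sum() - mean) >= abs(obs - mean) - 1e-12:
            hits += 1
    return hits / total


def mean_weight_contrast(
    model: CASMModel,
    null_dist: NullAASDistribution,
    set_a: list[MutationEvent],
    set_b: list[MutationEvent],
    exact_max_n: int = 12,
):
    """Compare mean weights of two event sets with a Wilcoxon rank-sum test.

    Returns (mean_a, mean_b, two-sided p).  Small samples use an exact
    permutation of the rank-sum statistic; larger ones a tie-corrected
    normal approximation.
    """
    if not set_a or not set_b:
        raise ValueError("both event sets must be nonempty")
    wa = np.array([casm_weight(model, null_dist, ev) for ev in set_a])
    wb = np.array([casm_weight(model, null_dist, ev) for ev in set_b])
    if np.ptp(np.concatenate([wa, wb])) == 0:
        warnings.warn("identical constant weights in both sets; p = 1")
        return float(wa.mean()), float(wb.mean()), 1.0
    if len(wa) <= exact_max_n and len(wb) <= exact_max_n:
        p = _exact_ranksum_p(wa, wb)
    else:
        p = float(
            stats.mannwhitneyu(wa, wb, alternative="two-sided", method="asymptotic").pvalue
        )
    return float(wa.mean()), float(wb.mean()), float(min(p, 1.0))
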