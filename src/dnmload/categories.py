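"""Amino-acid-substitution category space shared by the null model and CASM.

Every possible coding mutation is mapped to a cell in a fixed two-dimensional
table: an AAS *category* (synonymous, one of the 380 ordered missense pairs,
nonsense, stoploss, splice, frameshift indel, in-frame indel) crossed with a
phylogenetic-conservation *bin* on [0, 1].  Both the neutral distribution
Pr(AAS|N) and the damaging distribution Pr(AAS|D) live on this grid, so their
ratio — the per-variant likelihood-ratio weight — is always well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: ordered (ref -> alt) missense pairs; directionality matters because
#: disease-mutation spectra are not symmetric.
MISSENSE_PAIRS = tuple(
    f"{a}{b}" for a in AMINO_ACIDS for b in AMINO_ACIDS if a != b
)

SNV_CONSEQUENCES = ("synonymous", "missense", "nonsense", "stoploss")
INDEL_CONSEQUENCES = ("frameshift_indel", "inframe_indel")
CONSEQUENCES = SNV_CONSEQUENCES + ("splice",) + INDEL_CONSEQUENCES

#: full category vocabulary: synonymous, 380 missense pairs, then the
#: protein-truncating / non-substitution classes.
CATEGORIES = (
    ("synonymous",)
    + tuple(f"missense_{p}" for p in MISSENSE_PAIRS)
    + ("nonsense", "stoploss", "splice", "frameshift_indel", "inframe_indel")
)

_CATEGORY_INDEX = {name: i for i, name in enumerate(CATEGORIES)}

DEFAULT_BIN_EDGES = np.linspace(0.0, 1.0, 6)


def category_name(consequence: str, aa_ref: str | None, aa_alt: str | None) -> str:
    """Resolve a consequence (+ amino acids for missense) to a category name."""
    if consequence == "missense":
        if not aa_ref or not aa_alt:
            raise ValueError("missense category requires aa_ref and aa_alt")
        return f"missense_{aa_ref}{aa_alt}"
    if consequence not in CONSEQUENCES:
        raise ValueError(
            f"unknown consequence {consequence!r}; allowed: {CONSEQUENCES}"
        )
    return consequence


@dataclass(frozen=True)
class CategorySpace:
    """Indexing helper for the (category x conservation bin) grid."""

    bin_edges: np.ndarray = field(default_factory=lambda: DEFAULT_BIN_EDGES.copy())

    def __post_init__(self):
        edges = np.asarray(self.bin_edges, dtype=float)
        if edges.ndim != 1 or len(edges) < 2:
            raise ValueError("bin_edges must be a 1-d array of >= 2 edges")
        if edges[0] > 0.0 or edges[-1] < 1.0:
            raise ValueError("bin edges must cover [0, 1]")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        object.__setattr__(self, "bin_edges", edges)

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    @property
    def n_categories(self) -> int:
        return len(CATEGORIES)

    @property
    def n_cells(self) -> int:
        return self.n_categories * self.n_bins

    def bin_of(self, score) -> np.ndarray:
        """Map conservation scores in [0,1] to bin indices (right edge closed)."""
        s = np.asarray(score, dtype=float)
        idx = np.searchsorted(self.bin_edges, s, side="right") - 1
        return np.clip(idx, 0, self.n_bins - 1)

    def category_index(self, name: str) -> int:
        return _CATEGORY_INDEX[name]

    def cell_index(self, category, bin_idx) -> np.ndarray:
        cat = np.asarray(category, dtype=int)
        return cat * self.n_bins + np.asarray(bin_idx, dtype=int)

    def cell_of(self, consequence: str, aa_ref, aa_alt, cons_score) -> int:
        cat = self.category_index(category_name(consequence, aa_ref, aa_alt))
        return int(self.cell_index(cat, self.bin_of(cons_score)))

    def cells_of_category(self, name: str) -> np.ndarray:
        cat = self.category_index(name)
        return cat * self.n_bins + np.arange(self.n_bins)
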