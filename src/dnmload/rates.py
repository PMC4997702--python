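"""The neutral mutational model of a gene.

For each gene we enumerate every possible coding SNV (3 per CDS base pair),
attach a context-dependent per-generation per-haploid-bp rate to each, and sum
the rates over the CDS to obtain the gene's expected de novo mutation rate m.
The rate-weighted distribution of the resulting amino-acid substitutions over
the category x conservation-bin grid is the neutral distribution Pr(AAS|N)
used by the likelihood-ratio test and by its Monte-Carlo null simulations.

Splice dinucleotides are modelled as a single aggregate "splice" class with
rate ``splice_site_multiplier * m * (#splice dinucleotides)``; coding indels
as a single aggregate class with rate ``indel_rate_per_bp * L`` (all treated
as frameshift).  Both enter Pr(AAS|N) as their own categories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .categories import CategorySpace, category_name
from .io import (
    ConservationTrack,
    GeneModel,
    MutationEvent,
    default_indel_consequence,
)

logger = logging.getLogger(__name__)

BASES = "ACGT"

CODON_TO_AA = dict(standard_dna_table.forward_table)
for codon in standard_dna_table.stop_codons:
    CODON_TO_AA[codon] = "*"

DEFAULT_SPLICE_MULTIPLIER = 2.0  # two base pairs per splice dinucleotide


@dataclass(frozen=True)
class RateTable:
    """Trinucleotide-context SNV rates plus genome-wide aggregate rates.

    ``rates`` maps (trinucleotide context, alt base) to a per-generation
    per-haploid-bp rate.  ``genome_snv_rate`` and ``genome_indel_rate`` are
    the genome-wide expected de novo SNV / indel counts per trio, used by
    rate calibration.  ``indel_rate_per_bp`` is the per-haploid coding-indel
    rate per CDS base pair (0 disables indels).
    """

    rates: dict[tuple[str, str], float]
    genome_snv_rate: float = 0.0
    genome_indel_rate: float = 0.0
    indel_rate_per_bp: float = 0.0

    def __post_init__(self):
        for (ctx, alt), rate in self.rates.items():
            if not rate > 0:
                raise ValueError(f"rate for ({ctx},{alt}) must be > 0")
        contexts = {ctx for ctx, _ in self.rates}
        for ctx in contexts:
            n_alt = sum(1 for c, _ in self.rates if c == ctx)
            if n_alt != 3:
                raise ValueError(f"context {ctx} has {n_alt} alt entries, need 3")

    def rate(self, context: str, alt: str) -> float:
        key = (context, alt)
        if key not in self.rates:
            raise KeyError(f"rate table has no entry for context {context!r} alt {alt!r}")
        return self.rates[key]

    def scaled(self, snv_scale: float, indel_scale: float = 1.0) -> "RateTable":
        return RateTable(
            rates={k: v * snv_scale for k, v in self.rates.items()},
            genome_snv_rate=self.genome_snv_rate * snv_scale,
            genome_indel_rate=self.genome_indel_rate * indel_scale,
            indel_rate_per_bp=self.indel_rate_per_bp * indel_scale,
        )


def read_rate_table(path) -> RateTable:
    """Read the rate-table TSV (``context  alt  rate`` + ``#key=value`` headers)."""
    meta = {}
    rates = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, val = line[1:].split("=", 1)
                    meta[key.strip()] = float(val)
                continue
            f = line.split("\t")
            if f[0] == "context":
                continue
            rates[(f[0], f[1])] = float(f[2])
    return RateTable(
        rates=rates,
        genome_snv_rate=meta.get("genome_snv_rate", 0.0),
        genome_indel_rate=meta.get("genome_indel_rate", 0.0),
        indel_rate_per_bp=meta.get("indel_rate_per_bp", 0.0),
    )


def write_rate_table(table: RateTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#genome_snv_rate={table.genome_snv_rate:.17g}\n")
        fh.write(f"#genome_indel_rate={table.genome_indel_rate:.17g}\n")
        fh.write(f"#indel_rate_per_bp={table.indel_rate_per_bp:.17g}\n")
        fh.write("context\talt\trate\n")
        for (ctx, alt), rate in sorted(table.rates.items()):
            fh.write(f"{ctx}\t{alt}\t{rate:.17g}\n")


def uniform_rate_table(
    per_alt_rate: float,
    genome_snv_rate: float = 0.0,
    genome_indel_rate: float = 0.0,
    indel_rate_per_bp: float = 0.0,
) -> RateTable:
    """A rate table with the same per-alt rate in all 64 contexts."""
    rates = {
        (a + b + c, alt): per_alt_rate
        for a in BASES
        for b in BASES
        for c in BASES
        for alt in BASES
        if alt != b
    }
    return RateTable(rates, genome_snv_rate, genome_indel_rate, indel_rate_per_bp)


# ---------------------------------------------------------------------------
# spectrum


@dataclass
class SubstitutionSpectrum:
    """All possible coding SNVs of one gene, with rates and consequences."""

    gene_id: str
    entries: pd.DataFrame  # offset, ref, alt, rate, consequence, aa_ref, aa_alt, cons_score
    L: int
    splice_rate: float = 0.0
    indel_rate_gene: float = 0.0

    @property
    def m(self) -> float:
        """Mean per-haploid-bp SNV rate over the CDS."""
        return float(self.entries["rate"].sum()) / self.L

    @property
    def n(self) -> int:
        return 2 * self.L


def classify_snv(codon: str, pos_in_codon: int, alt: str):
    """Consequence and amino acids for one codon substitution."""
    aa_ref = CODON_TO_AA[codon]
    alt_codon = codon[:pos_in_codon] + alt + codon[pos_in_codon + 1 :]
    aa_alt = CODON_TO_AA[alt_codon]
    if aa_ref == aa_alt:
        return "synonymous", aa_ref, aa_alt
    if aa_alt == "*":
        return "nonsense", aa_ref, aa_alt
    if aa_ref == "*":
        return "stoploss", aa_ref, aa_alt
    return "missense", aa_ref, aa_alt


def _cds_positions(gene: GeneModel) -> np.ndarray:
    """Reference position of each cds_seq offset (coding-strand order)."""
    pos = np.concatenate(
        [np.arange(s, e + 1) for s, e in gene.cds_intervals]
    )
    return pos[::-1] if gene.strand == "-" else pos


def enumerate_spectrum(
    gene: GeneModel,
    rates: RateTable,
    cons: ConservationTrack | None = None,
    splice_site_multiplier: float = DEFAULT_SPLICE_MULTIPLIER,
) -> SubstitutionSpectrum:
    """Enumerate all 3L possible SNVs of a gene with rates and consequences."""
    seq = gene.cds_seq
    L = gene.L
    positions = _cds_positions(gene)

    cons_raw = np.full(L, np.nan)
    if cons is not None and len(cons):
        for i in range(L):
            score = cons.get(gene.chrom, int(positions[i]))
            if score is not None:
                cons_raw[i] = score
    n_missing = int(np.isnan(cons_raw).sum())
    if n_missing == L:
        fill = 0.5
        if cons is not None:
            logger.warning(
                "%s: no conservation scores found; filling all sites with 0.5",
                gene.gene_id,
            )
    else:
        fill = float(np.nanmean(cons_raw))
        if n_missing:
            logger.info(
                "%s: filled %d/%d sites with gene-mean conservation %.4f",
                gene.gene_id,
                n_missing,
                L,
                fill,
            )
    cons_filled = np.where(np.isnan(cons_raw), fill, cons_raw)

    rows = {k: [] for k in ("offset", "ref", "alt", "rate", "consequence", "aa_ref", "aa_alt", "cons_score")}
    for i in range(L):
        ref = seq[i]
        prev = seq[i - 1] if i > 0 else gene.flank5
        nxt = seq[i + 1] if i < L - 1 else gene.flank3
        if prev not in BASES or nxt not in BASES or ref not in BASES:
            raise ValueError(
                f"{gene.gene_id}: ambiguous base in context at CDS offset {i}"
            )
        ctx = prev + ref + nxt
        codon_start = 3 * (i // 3)
        codon = seq[codon_start : codon_start + 3]
        for alt in BASES:
            if alt == ref:
                continue
            csq, aa_r, aa_a = classify_snv(codon, i % 3, alt)
            rows["offset"].append(i)
            rows["ref"].append(ref)
            rows["alt"].append(alt)
            rows["rate"].append(rates.rate(ctx, alt))
            rows["consequence"].append(csq)
            rows["aa_ref"].append(aa_r)
            rows["aa_alt"].append(aa_a)
            rows["cons_score"].append(cons_filled[i])
    entries = pd.DataFrame(rows)

    m = float(entries["rate"].sum()) / L
    splice_rate = splice_site_multiplier * m * gene.n_splice_dinucleotides
    indel_rate_gene = rates.indel_rate_per_bp * L
    return SubstitutionSpectrum(
        gene_id=gene.gene_id,
        entries=entries,
        L=L,
        splice_rate=splice_rate,
        indel_rate_gene=indel_rate_gene,
    )


def write_spectrum(spec: SubstitutionSpectrum, path) -> None:
    """Debug dump: one row per possible substitution."""
    spec.entries.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Pr(AAS|N)


@dataclass
class NullAASDistribution:
    """Rate-weighted probability of each (category x conservation bin) cell."""

    gene_id: str
    space: CategorySpace
    mass: np.ndarray  # (n_cells,), sums to 1
    entry_cells: np.ndarray  # cell index of each spectrum entry

    def cell_mass(self, cell) -> np.ndarray:
        return self.mass[np.asarray(cell, dtype=int)]


def null_aas_distribution(
    spec: SubstitutionSpectrum,
    bins: np.ndarray | None = None,
) -> NullAASDistribution:
    """Build Pr(AAS|N): cell mass proportional to summed mutation rate.

    Splice and indel classes contribute their aggregate gene rates, spread
    uniformly over the conservation bins of their category.
    """
    if not len(spec.entries):
        raise ValueError("empty spectrum")
    space = CategorySpace(bins) if bins is not None else CategorySpace()
    ent = spec.entries
    cat_idx = np.array(
        [
            space.category_index(category_name(c, r, a))
            for c, r, a in zip(ent["consequence"], ent["aa_ref"], ent["aa_alt"])
        ]
    )
    bin_idx = space.bin_of(ent["cons_score"].to_numpy())
    entry_cells = space.cell_index(cat_idx, bin_idx)

    mass = np.zeros(space.n_cells)
    np.add.at(mass, entry_cells, ent["rate"].to_numpy())
    if spec.splice_rate > 0:
        mass[space.cells_of_category("splice")] += spec.splice_rate / space.n_bins
    if spec.indel_rate_gene > 0:
        mass[space.cells_of_category("frameshift_indel")] += (
            spec.indel_rate_gene / space.n_bins
        )
    total = mass.sum()
    mass /= total
    return NullAASDistribution(
        gene_id=spec.gene_id, space=space, mass=mass, entry_cells=entry_cells
    )


# ---------------------------------------------------------------------------
# summaries, calibration, annotation


@dataclass(frozen=True)
class GeneRateSummary:
    m: float
    n: int
    snv_expectation: float  # n * m per individual
    indel_expectation: float  # 2 * indel_rate_gene per individual
    splice_expectation: float  # 2 * splice_rate per individual

    @property
    def expected_count_per_individual(self) -> float:
        return self.snv_expectation + self.indel_expectation


def gene_rate_summary(spec: SubstitutionSpectrum) -> GeneRateSummary:
    m = spec.m
    return GeneRateSummary(
        m=m,
        n=spec.n,
        snv_expectation=spec.n * m,
        indel_expectation=2.0 * spec.indel_rate_gene,
        splice_expectation=2.0 * spec.splice_rate,
    )


@dataclass(frozen=True)
class CalibrationResult:
    snv_scale: float
    indel_scale: float
    observed_snv_count: int
    observed_indel_count: int
    n_trios: int


def calibrate_rates(
    events,
    n_trios: int,
    baseline_snv_expectation: float,
    baseline_indel_expectation: float = 0.0,
) -> CalibrationResult:
    """Scale factors matching the genome-wide expected counts to the cohort.

    ``baseline_*_expectation`` are expected de novo counts per trio.  An
    observed indel count of zero yields indel_scale 0 with a warning (the
    indel mutation rate can be set to 0 when indels are not of interest).
    """
    if n_trios < 1:
        raise ValueError("n_trios must be >= 1")
    if not baseline_snv_expectation > 0:
        raise ValueError("baseline SNV expectation must be > 0")
    n_snv = sum(1 for ev in events if ev.mut_type == "SNV")
    n_indel = sum(1 for ev in events if ev.mut_type != "SNV")
    snv_scale = n_snv / (n_trios * baseline_snv_expectation)
    if baseline_indel_expectation > 0:
        indel_scale = n_indel / (n_trios * baseline_indel_expectation)
    else:
        indel_scale = 0.0
    if indel_scale == 0.0:
        logger.warning("indel scale is 0; the indel mutation rate is set to 0")
    return CalibrationResult(
        snv_scale=snv_scale,
        indel_scale=indel_scale,
        observed_snv_count=n_snv,
        observed_indel_count=n_indel,
        n_trios=n_trios,
    )


def annotate_event(
    gene: GeneModel,
    spec: SubstitutionSpectrum,
    event: MutationEvent,
    cons: ConservationTrack | None = None,
) -> MutationEvent:
    """Fill consequence / amino acids / conservation for one event."""
    updates = {}
    if event.mut_type == "SNV":
        if gene.contains(event.pos):
            off = gene.cds_offset(event.pos)
            ref_coding, alt_coding = event.ref, event.alt
            if gene.strand == "-":
                ref_coding = str(Seq(ref_coding).complement())
                alt_coding = str(Seq(alt_coding).complement())
            if gene.cds_seq[off] != ref_coding:
                raise ValueError(
                    f"{event.gene_id}:{event.pos}: ref {event.ref} does not match "
                    f"CDS base {gene.cds_seq[off]}"
                )
            row = spec.entries[
                (spec.entries["offset"] == off) & (spec.entries["alt"] == alt_coding)
            ]
            if not len(row):
                raise ValueError(f"no spectrum entry for {event.gene_id}:{event.pos}")
            row = row.iloc[0]
            updates["consequence"] = row["consequence"]
            updates["aa_ref"] = row["aa_ref"]
            updates["aa_alt"] = row["aa_alt"]
            if event.cons_score is None:
                updates["cons_score"] = float(row["cons_score"])
        elif event.pos in gene.splice_positions():
            updates["consequence"] = "splice"
        else:
            raise ValueError(
                f"{event.gene_id}:{event.pos}: outside CDS and splice dinucleotides"
            )
    else:
        if event.consequence is None:
            updates["consequence"] = default_indel_consequence(event.ref, event.alt)
    if event.cons_score is None and "cons_score" not in updates:
        score = cons.get(event.chrom, event.pos) if cons is not None else None
        if score is None:
            score = float(spec.entries["cons_score"].mean())
            logger.info(
                "%s:%s: conservation missing, filled with gene mean %.4f",
                event.gene_id,
                event.pos,
                score,
            )
        updates["cons_score"] = score
    # never overwrite fields the input already provided
    for fld in ("consequence", "aa_ref", "aa_alt"):
        if getattr(event, fld) is not None:
            updates.pop(fld, None)
    return replace(event, **updates)
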