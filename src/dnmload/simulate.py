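"""Synthetic fixtures and the simulation study.

Generates self-contained synthetic stand-ins for every external input (gene
model + reference, conservation track, context rate table, damaging catalog)
and runs the three simulation experiments: null calibration (type-I error),
power against the Poisson comparators, and recovery of the relative damaging
mutation rate r.

Cohorts are simulated by superposing neutral and causal de novo mutation
processes: the total count is Poisson with mean equal to the neutral cohort
expectation times (1 + r); each mutation is causal with probability
r / (1 + r).  Neutral mutations land on possible coding sites with
probability proportional to the site mutation rate; causal mutations are
drawn from a damaging profile (an LGD fraction plus conservation-tilted
missense), the same recipe used to generate the training catalogs.  Indels
are excluded from the benchmarks by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .casm import CASMModel, DamagingCatalog, train_casm
from .comparators import class_lambda
from .io import ConservationTrack, GeneModel, MutationEvent
from .lrt import NullSampler
from .rates import (
    NullAASDistribution,
    RateTable,
    SubstitutionSpectrum,
    _cds_positions,
    enumerate_spectrum,
    null_aas_distribution,
)

logger = logging.getLogger(__name__)

BASES = "ACGT"
STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class DamagingProfile:
    """Parameters of the synthetic causal-mutation sampler.

    ``lgd_fraction`` is the probability a causal mutation is likely
    gene-disrupting (nonsense here; benchmarks are SNV-only); the remainder
    are missense drawn with probability proportional to site rate times a
    Beta(cons_a, cons_b) density in the site's conservation score, so
    damaging missense concentrates at conserved positions.
    """

    name: str
    lgd_fraction: float
    cons_a: float
    cons_b: float
    rng_id: int


#: profile mimicking a de novo study gene set (higher LGD fraction)
ASD_PROFILE = DamagingProfile("asd", lgd_fraction=0.37, cons_a=6.0, cons_b=1.5, rng_id=11)
#: profile mimicking a disease-mutation database (lower LGD fraction)
HGMD_PROFILE = DamagingProfile("hgmd", lgd_fraction=0.19, cons_a=3.0, cons_b=1.5, rng_id=12)

PROFILES = {p.name: p for p in (ASD_PROFILE, HGMD_PROFILE)}


@dataclass
class SimulationConfig:
    gene_length_bp: int = 2000
    baseline_rate: float = 1.2e-8  # per generation per haploid bp
    r_grid: tuple = tuple(range(20))
    n_cases: int = 5000
    n_cases_null: int = 100_000
    n_reps: int = 1000
    n_reps_null: int = 10_000
    alpha: float = 5e-4
    n_sims: int = 999
    seed: int = 0
    profile: DamagingProfile = ASD_PROFILE
    catalog_size: int = 5000
    pseudocount: float = 0.5
    background_length_bp: int = 30_000
    include_indels: bool = False

    def __post_init__(self):
        if self.gene_length_bp <= 0 or self.baseline_rate <= 0:
            raise ValueError("gene length and baseline rate must be positive")
        if any(r < 0 for r in self.r_grid):
            raise ValueError("r_grid must be >= 0")


@dataclass
class Fixtures:
    gene: GeneModel
    cons_track: ConservationTrack
    rate_table: RateTable
    catalog: DamagingCatalog
    profile: DamagingProfile
    contig_seq: str  # full synthetic contig, for FASTA export


# ---------------------------------------------------------------------------
# fixture generation


def _random_cds(rng: np.random.Generator, length_bp: int) -> str:
    """ATG + random internal non-stop codons + TAA; length rounded to 3."""
    n_codons = max(3, length_bp // 3)
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        codon = "".join(rng.choice(list(BASES), 3))
        if codon not in STOP_CODONS:
            codons.append(codon)
    codons.append("TAA")
    return "".join(codons)


def _mixture_cons(rng: np.random.Generator, size: int) -> np.ndarray:
    """Bimodal conservation scores: a weakly and a strongly conserved mode."""
    low = rng.beta(1.2, 4.0, size)
    high = rng.beta(5.0, 1.3, size)
    pick = rng.random(size) < 0.55
    return np.where(pick, high, low)


def _random_rate_table(rng: np.random.Generator) -> dict:
    """Context-dependent per-alt rates with a CpG transition boost."""
    rates = {}
    for a in BASES:
        for b in BASES:
            for c in BASES:
                ctx = a + b + c
                for alt in BASES:
                    if alt == b:
                        continue
                    rate = float(np.exp(rng.normal(0.0, 0.3)))
                    if b == "C" and c == "G" and alt == "T":
                        rate *= 8.0
                    elif b == "G" and a == "C" and alt == "A":
                        rate *= 8.0
                    rates[(ctx, alt)] = rate
    return rates


def make_gene_fixture(
    seed: int,
    config: SimulationConfig | None = None,
) -> tuple[GeneModel, ConservationTrack, RateTable, str]:
    """Synthetic gene, conservation track and rate table (profile-free part).

    The rate table is scaled so that the fixture gene's mean per-haploid-bp
    SNV rate m equals the configured baseline exactly.
    """
    config = config or SimulationConfig()
    gene_rng = np.random.default_rng([seed, 1])
    cds = _random_cds(gene_rng, config.gene_length_bp)
    L = len(cds)
    flank_left = "".join(gene_rng.choice(list(BASES), 100))
    flank_right = "".join(gene_rng.choice(list(BASES), 100))
    contig = flank_left + cds + flank_right
    gene = GeneModel(
        gene_id="geneA",
        chrom="chrS",
        strand="+",
        cds_intervals=((101, 100 + L),),
        cds_seq=cds,
        flank5=flank_left[-1],
        flank3=flank_right[0],
    )

    cons_rng = np.random.default_rng([seed, 2])
    scores = _mixture_cons(cons_rng, L)
    track = ConservationTrack(
        {("chrS", 101 + i): float(scores[i]) for i in range(L)}
    )

    rate_rng = np.random.default_rng([seed, 3])
    raw = RateTable(
        _random_rate_table(rate_rng),
        genome_snv_rate=72.0,
        genome_indel_rate=5.0,
        indel_rate_per_bp=(0.1 * config.baseline_rate if config.include_indels else 0.0),
    )
    m0 = enumerate_spectrum(gene, raw, track).m
    table = RateTable(
        {k: v * config.baseline_rate / m0 for k, v in raw.rates.items()},
        genome_snv_rate=raw.genome_snv_rate,
        genome_indel_rate=raw.genome_indel_rate,
        indel_rate_per_bp=raw.indel_rate_per_bp,
    )
    return gene, track, table, contig


def _causal_entry_probs(
    spec: SubstitutionSpectrum, profile: DamagingProfile
) -> np.ndarray:
    """Causal sampling probability of each spectrum entry under the profile."""
    ent = spec.entries
    rate = ent["rate"].to_numpy(dtype=float)
    cons = np.clip(ent["cons_score"].to_numpy(dtype=float), 1e-9, 1 - 1e-9)
    csq = ent["consequence"].to_numpy()
    probs = np.zeros(len(ent))
    is_lgd = csq == "nonsense"
    is_mis = csq == "missense"
    if is_lgd.any():
        w = rate * is_lgd
        probs += profile.lgd_fraction * w / w.sum()
    mis_w = rate * stats.beta.pdf(cons, profile.cons_a, profile.cons_b) * is_mis
    probs += (1.0 - profile.lgd_fraction * is_lgd.any()) * mis_w / mis_w.sum()
    return probs / probs.sum()


def make_catalog(
    seed: int,
    profile: DamagingProfile,
    config: SimulationConfig | None = None,
) -> DamagingCatalog:
    """Synthetic damaging-mutation catalog (disease-database stand-in).

    Records are SNV-accessible substitutions sampled from a long random
    background coding sequence under the damaging profile, so the trained
    Pr(AAS|D) concentrates on categories realizable by single-nucleotide
    changes.
    """
    config = config or SimulationConfig()
    bg_rng = np.random.default_rng([seed, 4, profile.rng_id])
    bg_cds = _random_cds(bg_rng, config.background_length_bp)
    bg_gene = GeneModel(
        gene_id="background",
        chrom="chrB",
        strand="+",
        cds_intervals=((1, len(bg_cds)),),
        cds_seq=bg_cds,
        flank5="A",
        flank3="A",
    )
    bg_scores = _mixture_cons(bg_rng, len(bg_cds))
    bg_track = ConservationTrack(
        {("chrB", 1 + i): float(bg_scores[i]) for i in range(len(bg_cds))}
    )
    table = RateTable(_random_rate_table(np.random.default_rng([seed, 3])))
    spec = enumerate_spectrum(bg_gene, table, bg_track)
    probs = _causal_entry_probs(spec, profile)
    idx = bg_rng.choice(len(probs), size=config.catalog_size, p=probs)
    ent = spec.entries.iloc[idx]
    records = pd.DataFrame(
        {
            "consequence": ent["consequence"].to_numpy(),
            "aa_ref": ent["aa_ref"].to_numpy(),
            "aa_alt": ent["aa_alt"].to_numpy(),
            "cons_score": ent["cons_score"].to_numpy(),
        }
    )
    return DamagingCatalog(records, provenance=f"synthetic-{profile.name}")


def make_fixtures(
    seed: int,
    config: SimulationConfig | None = None,
    profile: DamagingProfile | None = None,
) -> Fixtures:
    """All five synthetic inputs for one experiment, deterministically."""
    config = config or SimulationConfig()
    profile = profile or config.profile
    gene, track, table, contig = make_gene_fixture(seed, config)
    catalog = make_catalog(seed, profile, config)
    return Fixtures(
        gene=gene,
        cons_track=track,
        rate_table=table,
        catalog=catalog,
        profile=profile,
        contig_seq=contig,
    )


def write_fixtures(fixtures: Fixtures, out_dir) -> dict:
    """Dump fixtures in the external file dialects; returns the path map."""
    import os

    from .casm import write_catalog
    from .io import write_conservation
    from .rates import write_rate_table

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "fasta": os.path.join(out_dir, "reference.fa"),
        "gff": os.path.join(out_dir, "genes.gff3"),
        "conservation": os.path.join(out_dir, "conservation.bedgraph"),
        "rates": os.path.join(out_dir, "rates.tsv"),
        "catalog": os.path.join(out_dir, "damaging_catalog.tsv"),
    }
    with open(paths["fasta"], "w") as fh:
        fh.write(f">{fixtures.gene.chrom}\n")
        seq = fixtures.contig_seq
        for i in range(0, len(seq), 80):
            fh.write(seq[i : i + 80] + "\n")
    with open(paths["gff"], "w") as fh:
        fh.write("##gff-version 3\n")
        g = fixtures.gene
        for start, end in g.cds_intervals:
            fh.write(
                f"{g.chrom}\tdnmload\tCDS\t{start}\t{end}\t.\t{g.strand}\t0\t"
                f"ID=cds-{g.gene_id};gene_id={g.gene_id}\n"
            )
    write_conservation(fixtures.cons_track, paths["conservation"])
    write_rate_table(fixtures.rate_table, paths["rates"])
    write_catalog(fixtures.catalog, paths["catalog"])
    return paths


# ---------------------------------------------------------------------------
# simulation engine


@dataclass
class SimEngine:
    """Fixtures compiled into the arrays the experiments run on."""

    fixtures: Fixtures
    spectrum: SubstitutionSpectrum
    null_dist: NullAASDistribution
    model: CASMModel
    sampler: NullSampler
    causal_cum: np.ndarray  # cumulative causal sampling probs over entries

    @classmethod
    def build(
        cls,
        fixtures: Fixtures,
        bins: np.ndarray | None = None,
        pseudocount: float = 0.5,
    ) -> "SimEngine":
        spec = enumerate_spectrum(fixtures.gene, fixtures.rate_table, fixtures.cons_track)
        null_dist = null_aas_distribution(spec, bins)
        model = train_casm(fixtures.catalog, bins, pseudocount)
        sampler = NullSampler(spec, null_dist, model)
        causal = _causal_entry_probs(spec, fixtures.profile)
        cum = np.cumsum(causal)
        cum[-1] = 1.0
        return cls(
            fixtures=fixtures,
            spectrum=spec,
            null_dist=null_dist,
            model=model,
            sampler=sampler,
            causal_cum=cum,
        )

    def simulate_cohort_counts(self, rng, n_draws: int, n_cases: int, r: float):
        """Counts, atom indices and causal flags for n_draws cohorts."""
        lam = self.sampler.lam_per_case * n_cases * (1.0 + r)
        ks = rng.poisson(lam, n_draws)
        total = int(ks.sum())
        causal = rng.random(total) < (r / (1.0 + r) if r > 0 else 0.0)
        idx = np.empty(total, dtype=np.int64)
        n_causal = int(causal.sum())
        if total - n_causal:
            idx[~causal] = self.sampler.sample_atoms(rng, total - n_causal)
        if n_causal:
            idx[causal] = np.searchsorted(self.causal_cum, rng.random(n_causal))
        return ks, idx, causal


def simulate_cohort(
    engine: SimEngine,
    n_cases: int,
    r: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[MutationEvent]:
    """One simulated cohort as a variant table (module-dialect events)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    ks, idx, causal = engine.simulate_cohort_counts(rng, 1, n_cases, r)
    gene = engine.fixtures.gene
    positions = _cds_positions(gene)
    ent = engine.spectrum.entries
    samples = rng.integers(0, n_cases, len(idx))
    events = []
    n_entries = len(ent)
    for atom, samp in zip(idx, samples):
        if atom >= n_entries:
            continue  # aggregate splice/indel atom; absent when rates are 0
        row = ent.iloc[int(atom)]
        events.append(
            MutationEvent(
                sample_id=f"case{int(samp)}",
                gene_id=gene.gene_id,
                chrom=gene.chrom,
                pos=int(positions[int(row['offset'])]),
                ref=str(row["ref"]),
                alt=str(row["alt"]),
                consequence=str(row["consequence"]),
                aa_ref=str(row["aa_ref"]),
                aa_alt=str(row["aa_alt"]),
                cons_score=float(row["cons_score"]),
            )
        )
    return events


# ---------------------------------------------------------------------------
# experiments


def _wilson(successes: int, n: int) -> tuple[float, float]:
    lo, hi = proportion_confint(successes, n, alpha=0.05, method="wilson")
    return float(lo), float(hi)


def _mc_pvalues_batched(
    engine: SimEngine,
    rng,
    d_obs: np.ndarray,
    n_cases: int,
    n_sims: int,
) -> np.ndarray:
    """Per-replicate Monte-Carlo p-values, null simulations in one batch."""
    reps = len(d_obs)
    ks, idx = engine.sampler.simulate_counts(rng, reps * n_sims, n_cases)
    d_star, _ = engine.sampler.statistics_from_atoms(ks, idx, n_cases)
    d_star = d_star.reshape(reps, n_sims)
    n1 = np.sum(d_star >= d_obs[:, None] - 1e-12, axis=1)
    return (n1 + 1) / (n_sims + 1)


def _poisson_pvalues(engine: SimEngine, counts: np.ndarray, lam: float) -> np.ndarray:
    return np.where(counts == 0, 1.0, stats.poisson.sf(counts - 1, lam))


def _class_counts(engine: SimEngine, ks, idx, flags) -> np.ndarray:
    draw_ids = np.repeat(np.arange(len(ks)), ks)
    return np.bincount(draw_ids, weights=flags[idx], minlength=len(ks)).astype(int)


def run_cohort_tests(
    engine: SimEngine,
    rng,
    n_cohorts: int,
    n_cases: int,
    r: float,
    n_sims: int,
) -> pd.DataFrame:
    """Simulate cohorts and apply all three tests; one row per cohort."""
    ks, idx, _ = engine.simulate_cohort_counts(rng, n_cohorts, n_cases, r)
    d_obs, r_hat = engine.sampler.statistics_from_atoms(ks, idx, n_cases)
    p_lrt = _mc_pvalues_batched(engine, rng, d_obs, n_cases, n_sims)
    lam_all = class_lambda(engine.spectrum, n_cases, "all_nonsyn")
    lam_lgd = class_lambda(engine.spectrum, n_cases, "lgd")
    counts_all = _class_counts(engine, ks, idx, engine.sampler.atom_nonsyn)
    counts_lgd = _class_counts(engine, ks, idx, engine.sampler.atom_lgd)
    return pd.DataFrame(
        {
            "k_total": ks,
            "D": d_obs,
            "r_hat": r_hat,
            "p_lrt": p_lrt,
            "p_poisson_all": _poisson_pvalues(engine, counts_all, lam_all),
            "p_poisson_lgd": _poisson_pvalues(engine, counts_lgd, lam_lgd),
        }
    )


TEST_COLUMNS = {
    "lrt": "p_lrt",
    "poisson_all": "p_poisson_all",
    "poisson_lgd": "p_poisson_lgd",
}


def type1_experiment(
    config: SimulationConfig,
    alphas=(0.05, 0.01),
    n_sims: int | None = None,
    return_cohorts: bool = False,
):
    """Null (r = 0) calibration: achieved type-I error per test and level."""
    fixtures = make_fixtures(config.seed, config, config.profile)
    engine = SimEngine.build(fixtures, pseudocount=config.pseudocount)
    rng = np.random.default_rng([config.seed, 100])
    n_sims = n_sims if n_sims is not None else config.n_sims
    cohorts = run_cohort_tests(
        engine, rng, config.n_reps_null, config.n_cases_null, 0.0, n_sims
    )
    rows = []
    for test, col in TEST_COLUMNS.items():
        for alpha in alphas:
            hits = int((cohorts[col] <= alpha + 1e-12).sum())
            lo, hi = _wilson(hits, len(cohorts))
            rows.append(
                {
                    "test": test,
                    "alpha": alpha,
                    "achieved": hits / len(cohorts),
                    "ci_low": lo,
                    "ci_high": hi,
                    "n_reps": len(cohorts),
                }
            )
    table = pd.DataFrame(rows)
    return (table, cohorts) if return_cohorts else table


def power_experiment(config: SimulationConfig, n_sims: int | None = None) -> pd.DataFrame:
    """Power of the three tests over the r grid at threshold alpha."""
    fixtures = make_fixtures(config.seed, config, config.profile)
    engine = SimEngine.build(fixtures, pseudocount=config.pseudocount)
    n_sims = n_sims if n_sims is not None else config.n_sims
    if (n_sims + 1) * config.alpha < 1:
        raise ValueError(
            f"n_sims={n_sims} cannot resolve alpha={config.alpha}; "
            f"need n_sims >= {int(np.ceil(1 / config.alpha)) - 1}"
        )
    rows = []
    for r in config.r_grid:
        rng = np.random.default_rng([config.seed, 200, int(round(1000 * r))])
        cohorts = run_cohort_tests(
            engine, rng, config.n_reps, config.n_cases, float(r), n_sims
        )
        for test, col in TEST_COLUMNS.items():
            hits = int((cohorts[col] <= config.alpha + 1e-12).sum())
            lo, hi = _wilson(hits, len(cohorts))
            rows.append(
                {
                    "r": r,
                    "test": test,
                    "power": hits / len(cohorts),
                    "ci_low": lo,
                    "ci_high": hi,
                    "n_reps": len(cohorts),
                }
            )
    return pd.DataFrame(rows)


def recovery_experiment(config: SimulationConfig) -> pd.DataFrame:
    """Mean MLE of r against its simulated value (no Monte-Carlo needed)."""
    fixtures = make_fixtures(config.seed, config, config.profile)
    engine = SimEngine.build(fixtures, pseudocount=config.pseudocount)
    rows = []
    for r in config.r_grid:
        rng = np.random.default_rng([config.seed, 300, int(round(1000 * r))])
        ks, idx, _ = engine.simulate_cohort_counts(
            rng, config.n_reps, config.n_cases, float(r)
        )
        _, r_hat = engine.sampler.statistics_from_atoms(ks, idx, config.n_cases)
        rows.append(
            {
                "r_true": r,
                "mean_r_hat": float(r_hat.mean()),
                "rmse": float(np.sqrt(np.mean((r_hat - r) ** 2))),
                "n_reps": config.n_reps,
            }
        )
    return pd.DataFrame(rows)
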