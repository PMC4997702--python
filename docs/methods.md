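# Methods

## The weighted de novo load test

### Probability model

One gene at a time.  For individual i with k_i observed de novo mutations
in the gene, the joint probability of the genotype and the observed
amino-acid substitutions is

    Pr(G_i, AAS_i | r, m) = (1 - m - r m)^(n - k_i)
        * prod_{j=1..k_i} [ m Pr(AAS_ij | N) + r m Pr(AAS_ij | D) ]

with

- n = 2L, the haploid coding base pairs at risk (L = spliced CDS length);
- m, the gene-average risk-neutral mutation rate per generation per haploid
  bp (the per-site rates are summed over the CDS and divided by L; the
  gene average approximates the site-specific rate in the per-event term);
- r >= 0, the relative rate of disease-causing to risk-neutral de novo
  mutation; r = 0 is the null hypothesis;
- Pr(AAS|N) and Pr(AAS|D), the neutral and damaging distributions of the
  substitution category x conservation bin (below).

Individuals are independent, and mutations within an individual are treated
as independent given the rates (exact under the null; an excellent
approximation under the alternative because per-gene rates are ~1e-4).
Only the sum over individuals of (n - k_i) enters the likelihood, so the
assignment of mutations to individuals is immaterial — asserted as a test.

### Estimation and the statistic

ln L(r) is maximised under the constraint r >= 0 by Newton–Raphson on
t = ln r.  Derivatives on the log scale follow from the chain rule: with
l'(r) and l''(r) the r-scale derivatives,

    dl/dt = r l'(r),     d2l/dt2 = r l'(r) + r^2 l''(r)

    l'(r)  = -mS/(1-m-rm) + sum_j b_j/(a_j + r b_j)
    l''(r) = -m^2 S/(1-m-rm)^2 - sum_j [b_j/(a_j + r b_j)]^2

where a_j = m Pr(AAS_j|N), b_j = m Pr(AAS_j|D) and S = sum_i (n - k_i).
Both formulas are verified against finite differences in the test suite.
Seven fixed starts are used (ln 0.01, ln 0.1, ln 1, ln 5, ln 10, ln 20,
ln 100) with a cap of 20 iterations each.  Safeguards: non-finite steps are
dropped, steps are clipped to 10 log-units, ln r is confined to
[-40, ln(0.5(1-m)/m)] so the genotype term stays in its domain, and every
evaluated iterate competes for the returned maximum together with the
boundary r = 0.  The statistic is D = 2[sup ln L(r) - ln L(0)], floored at
zero; values below 1e-9 are treated as boundary noise and set to exactly 0
(the r = 0 and r -> 0 expressions agree only to floating-point rounding).
The maximiser matches an independent dense-grid + Brent-refinement oracle
to < 1e-5 on random cohorts.

### Monte-Carlo significance

Replicate cohorts are drawn from the **null model only**: the cohort-wide
mutation count is Poisson with mean t(n m + 2 s + 2 g) — s and g the
aggregate splice and coding-indel rates, zero in the default benchmarks —
and each mutation lands on a possible substitution with probability
proportional to its site rate.  D* is recomputed per replicate and

    p = (n1 + 1) / (n2 + 1),   n1 = #{D* >= D_obs}.

Because Pr(AAS|D) never enters the generator, the test is calibrated even
when the damaging model is misspecified; the acceptance experiment
deliberately confirms this by training on a second catalog with a different
category/conservation profile.  Replicates condition on the gene's local
rate, not on the observed count: the total is redrawn each time.  Ties
(D* exactly equal to D_obs, which happens on the discrete weight atoms of a
single gene) are counted into n1, so discreteness can only round p upward.
An optional adaptive stop ends the simulation once n1 >= 50; it only ever
rounds p up further and is off by default.  An asymptotic 50:50
chi-square-mixture p-value is exposed as a diagnostic but never used for
inference.

### Multiple testing and gene sets

Benjamini–Hochberg q-values across genes (statsmodels); Fisher's method
(-2 sum ln p against chi-square with 2k df, scipy) for pathway-level
combination.  Genes with zero observed events still get p = 1 rows so they
can enter a Fisher combination.

## The mutational null model

Per gene, all 3L possible coding SNVs are enumerated; each gets a rate from
a 64-context x 3-alt trinucleotide table (per generation per haploid bp), a
consequence from the standard codon table (synonymous / missense /
nonsense / stoploss), and the site's conservation score.  Context at the
CDS boundary uses the reference flanking base; at internal exon junctions
the spliced neighbour is used (an approximation — the true genomic
neighbour is intronic and is not retained).  The table is an input, so a
richer site-specific rate model can be supplied without code changes.

Splice sites: the two canonical dinucleotides per intron are modelled as a
single aggregate class with rate 2 m per dinucleotide (multiplier
configurable), not per-base table rates.  Coding indels: one aggregate
class per gene, rate proportional to L via a per-bp indel rate, all treated
as frameshift; a rate of 0 disables indels (the default in the
benchmarks).  Both aggregate classes enter Pr(AAS|N) as their own
categories, spread uniformly over conservation bins.

Cohort-level calibration rescales the SNV and indel rate tables so the
genome-wide expected counts match the observed per-trio counts; the two
classes are scaled separately because their ratio is platform-dependent.
Zero observed indels yield an indel scale of 0 with a logged warning.

## CASM: the damaging substitution model

The category vocabulary is fixed: synonymous, 380 ordered missense pairs
(ref -> alt; disease spectra are directional), nonsense, stoploss, splice,
frameshift indel, in-frame indel — crossed with conservation bins (default
5 equal-width bins on [0, 1]).  Pr(AAS|D) is the additively smoothed joint
table

    P_D(c, b) = (count(c, b) + pc) / (N + pc * C)

over a labeled damaging catalog (pseudocount pc = 0.5 by default, C cells,
N records); records without a conservation score spread their count
uniformly over their category's bins.  The same pseudocount scheme is
applied to Pr(AAS|N) in the weight denominator — the null distribution is
smoothed as if it were a catalog of the same size N — so the per-variant
weight w = P_D/P_N is finite and positive for every annotatable event.
Synonymous events keep their (pseudocount-level) cell, giving w ~= 0 rather
than a hard exclusion.  An `ext_weight` column passes an external
per-variant score straight through: the event's damaging mass is taken as
w times its neutral mass, so the likelihood uses the supplied ratio
unchanged.

## Synthetic data generator

The generator emulates one exome gene and its annotation resources:

- **Gene**: ATG + random non-stop codons + TAA; the default 2000 bp is
  rounded down to the nearest codon multiple (1998 bp).  Single exon, plus
  strand, 100 bp random flanks.
- **Conservation**: bimodal per-base mixture (Beta(1.2, 4) and
  Beta(5, 1.3), 45/55) mimicking the valley-and-peak shape of
  phylogenetic-conservation tracks.
- **Rate table**: log-normal context variation (sigma = 0.3) with an
  8-fold CpG transition boost, rescaled so the fixture gene's m equals the
  configured baseline exactly (default 1.2e-8 per generation per haploid
  bp).
- **Damaging catalogs**: SNV-accessible substitutions sampled from a long
  (30 kb) random background coding sequence: nonsense with probability
  equal to the profile's LGD fraction, otherwise missense weighted by site
  rate times a Beta density in conservation (damaging missense is
  conserved-site-enriched).  Two built-in profiles differ in LGD fraction
  (0.37 vs 0.19) and conservation tilt, standing in for a de novo study
  gene set and a disease-mutation database respectively.  Catalogs contain
  no indel or splice records by default, matching the indel-free
  benchmarks.

Cohorts are simulated by superposition: total count ~ Poisson(E_null (1 +
r)), each mutation causal with probability r/(1+r) (algebraically identical
to adding an independent causal Poisson process at rate r E_null).  Neutral
mutations follow site rates; causal mutations follow the damaging profile
restricted to the gene's possible substitutions.

What the generator does **not** emulate: multi-exon genes in the
benchmarks (splice classes are exercised only in unit tests), indel length
spectra, mutation-rate dependence on replication timing or transcribed
strand beyond trinucleotide context, conservation autocorrelation along the
sequence, and real disease-mutation databases.  Passing tests therefore
demonstrate the statistical machinery — calibration, ranking of tests,
estimator consistency — under a faithful but simplified mutational world,
not performance on any real cohort.

## Experiments and problem sizes

- **Null calibration**: 2000 bp gene, 10,000 cases per cohort, 499
  Monte-Carlo simulations per cohort; 20,000 replicate cohorts in
  `scripts/acceptance.py` (binomial SE ~7e-4 at alpha = 0.01) and 2,000 in
  the test suite.  Achieved rates are reported with Wilson 95% CIs.
- **Power**: 2,000 cases, 200 replicates per r over a coarse grid (2, 5,
  8, 11, 14, 17, 19), alpha = 5e-4 resolved by 1,999 simulations per
  replicate.  At this reduced cohort size absolute power tops out around
  50% at r = 19; the comparison surface is the ordering weighted LRT >=
  Poisson-all >= Poisson-LGD at the strongest grid point.
- **Recovery**: 5,000 cases, 200 replicates, r in {1, 5, 10}; the mean MLE
  lands within a few percent of the simulated r.

All experiments are deterministic at a fixed seed: every stream derives
from numpy SeedSequence spawns keyed by (seed, component id), and the
vectorised replicate engine (replicates grouped by event count, Newton
iterations run across the batch) is the same code path as the per-gene API.

## Numerical and design notes

- `log1p` is used for the (1 - m - rm) exponent term so the r = 0 and
  r -> 0 branches agree to full precision; the residual discrepancy floor
  is the 1e-9 boundary tolerance on D.
- Conservation-bin lookup closes the right edge (score 1.0 falls in the
  top bin); bin edges must cover [0, 1].
- Missing conservation at an observed site is filled with the gene's mean
  over possible-mutation sites and logged; a fully absent track falls back
  to 0.5 everywhere.
- Indel consequence, when absent from the input, defaults by the
  length-mod-3 rule (frameshift unless a multiple of 3).
- "All protein-altering" for Poisson-all includes in-frame indels and
  stoploss; LGD is nonsense + splice + frameshift.
- Coordinates are 1-based inclusive except bedGraph (native 0-based
  half-open), converted at a single tested site.
- The Wilcoxon rank-sum contrast of weight sets uses an exact permutation
  of the rank-sum statistic for samples up to 12 per side (ties allowed)
  and a tie-corrected normal approximation above that.

## Limitations

One transcript per gene id; no VCF input (the variant table is a plain
TSV); splice-site rates are an aggregate approximation rather than
table-derived; the Monte-Carlo replicates redraw the total mutation count
(the count-conditional variant is not implemented); power and recovery
magnitudes depend on the synthetic damaging profiles and should not be
read as predictions for any real study.
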