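"""End-to-end gene scan: inputs -> calibration -> per-gene tests -> results.

The scan reads the five external inputs (gene models + reference FASTA,
variant table, conservation track, rate table, damaging catalog or trained
CASM), optionally calibrates the genome-wide SNV/indel rates to the cohort,
runs the weighted likelihood-ratio test per gene with Monte-Carlo
significance, applies Benjamini-Hochberg FDR across genes and writes a
results TSV.  Genes with no observed events still receive p = 1 rows so they
can participate in pathway-level Fisher combination.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import casm as casm_mod
from . import io as io_mod
from . import lrt, rates as rates_mod

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration (missing paths, bad values)."""


@dataclass
class RunConfig:
    gene_models: str
    fasta: str
    variants: str
    rates: str
    conservation: str | None = None
    catalog: str | None = None
    casm_model: str | None = None
    output: str = "results.tsv"
    n_trios: int = 0
    n_sims: int = lrt.DEFAULT_N_SIMS
    seed: int = 0
    calibration: str = "fixed"  # auto | fixed
    pseudocount: float = 0.5
    adaptive_stop: bool = False

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def validate(self) -> None:
        import os

        for name in ("gene_models", "fasta", "variants", "rates"):
            path = getattr(self, name)
            if not path or not os.path.exists(path):
                raise ConfigError(f"{name} path {path!r} does not exist")
        for name in ("conservation", "catalog", "casm_model"):
            path = getattr(self, name)
            if path and not os.path.exists(path):
                raise ConfigError(f"{name} path {path!r} does not exist")
        if not (self.catalog or self.casm_model):
            raise ConfigError("either a damaging catalog or a trained CASM is required")
        if self.calibration not in ("auto", "fixed"):
            raise ConfigError("calibration must be 'auto' or 'fixed'")
        if self.calibration == "auto" and self.n_trios < 1:
            raise ConfigError("auto calibration requires n_trios >= 1")
        if self.n_sims < 1:
            raise ConfigError("n_sims must be >= 1")


def _gene_seed(seed: int, gene_id: str) -> list[int]:
    return [seed, zlib.crc32(gene_id.encode()) % (2**31)]


def run_scan(config: RunConfig) -> pd.DataFrame:
    """Run the full gene scan; writes ``config.output`` and returns the table."""
    config.validate()
    genes = io_mod.read_gene_models(config.gene_models, config.fasta)
    if not genes:
        raise ConfigError("no valid gene models found")
    events = io_mod.read_variant_table(config.variants)
    track = (
        io_mod.read_conservation(config.conservation)
        if config.conservation
        else io_mod.ConservationTrack()
    )
    table = rates_mod.read_rate_table(config.rates)
    if config.casm_model:
        model = casm_mod.CASMModel.from_json(config.casm_model)
    else:
        catalog = casm_mod.read_catalog(config.catalog)
        model = casm_mod.train_casm(catalog, pseudocount=config.pseudocount)

    n_trios = config.n_trios or len({ev.sample_id for ev in events})
    if n_trios < 1:
        raise ConfigError("cohort size could not be determined; set n_trios")
    if config.calibration == "auto":
        cal = rates_mod.calibrate_rates(
            events,
            n_trios,
            table.genome_snv_rate,
            table.genome_indel_rate,
        )
        logger.info(
            "calibration: snv_scale=%.4f indel_scale=%.4f", cal.snv_scale, cal.indel_scale
        )
        table = table.scaled(cal.snv_scale, cal.indel_scale)

    by_gene: dict[str, list] = {g.gene_id: [] for g in genes}
    for ev in events:
        if ev.gene_id in by_gene:
            by_gene[ev.gene_id].append(ev)
        else:
            logger.warning("event %s:%s has no gene model; skipped", ev.gene_id, ev.pos)

    results = []
    for gene in genes:
        spec = rates_mod.enumerate_spectrum(gene, table, track)
        null_dist = rates_mod.null_aas_distribution(spec, model.space.bin_edges)
        annotated = [
            rates_mod.annotate_event(gene, spec, ev, track) for ev in by_gene[gene.gene_id]
        ]
        data = lrt.build_cohort_data(
            gene.gene_id, n_trios, spec, null_dist, model, annotated
        )
        sampler = lrt.NullSampler(spec, null_dist, model)
        rng_seed = _gene_seed(config.seed, gene.gene_id)
        res = lrt.test_gene(
            data,
            sampler,
            n_sims=config.n_sims,
            seed=rng_seed,
            adaptive_stop=config.adaptive_stop,
        )
        results.append(res)

    qvals = lrt.bh_fdr([r.p_value for r in results])
    for res, q in zip(results, qvals):
        res.q_value = float(q)
    io_mod.write_results(results, config.output)
    logger.info("wrote %d gene results to %s", len(results), config.output)
    return io_mod.read_results(config.output)


def run_pathway(results: pd.DataFrame | str, gene_list) -> float:
    """Fisher combination of per-gene p-values for a gene set."""
    df = io_mod.read_results(results) if isinstance(results, str) else results
    gene_list = list(gene_list)
    if not gene_list:
        raise ValueError("gene list is empty")
    present = set(df["gene_id"])
    missing = [g for g in gene_list if g not in present]
    if missing:
        raise KeyError(f"genes absent from results: {missing}")
    pvals = df.set_index("gene_id").loc[gene_list, "p_value"].to_numpy()
    return lrt.fisher_combine(pvals)
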