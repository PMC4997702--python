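import numpy as np
import pytest

from dnmload.simulate import SimEngine, SimulationConfig, make_fixtures


@pytest.fixture(scope="session")
def sim_config():
    """Small but structurally complete study conditions for unit tests."""
    return SimulationConfig(
        gene_length_bp=300,
        background_length_bp=6000,
        catalog_size=1000,
        seed=7,
    )


@pytest.fixture(scope="session")
def fixtures(sim_config):
    return make_fixtures(sim_config.seed, sim_config)


@pytest.fixture(scope="session")
def engine(fixtures):
    return SimEngine.build(fixtures)


@pytest.fixture()
def toy_reference(tmp_path):
    """A small FASTA contig with a hand-readable sequence."""
    seq = "ATGAAATTTCCCGGGTAAACGTACGTACGTAC"
    fasta = tmp_path / "ref.fa"
    fasta.write_text(f">chr1\n{seq}\n")
    return fasta, seq


def write_gff(path, rows):
    lines = ["##gff-version 3"]
    for chrom, start, end, strand, gene_id in rows:
        lines.append(
            f"{chrom}\tsrc\tCDS\t{start}\t{end}\t.\t{strand}\t0\t"
            f"ID=cds-{gene_id}-{start};gene_id={gene_id}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path
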