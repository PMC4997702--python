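"""Gene models, variant tables, conservation tracks and result files.

Coordinate conventions: gene intervals and variant positions are 1-based
inclusive reference coordinates; bedGraph keeps its native 0-based half-open
convention and is converted here, at a single site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .categories import CONSEQUENCES

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "gene_id",
    "n_mutations",
    "m",
    "r_hat",
    "D",
    "p_value",
    "q_value",
    "n_sims",
]

VARIANT_REQUIRED = ["sample_id", "gene_id", "chrom", "pos", "ref", "alt"]
VARIANT_OPTIONAL = ["consequence", "aa_ref", "aa_alt", "cons_score", "ext_weight"]

_DNA = set("ACGT")


class GeneModelError(ValueError):
    """A gene model violates its structural invariants."""


@dataclass(frozen=True)
class GeneModel:
    """A single protein-coding gene model.

    ``cds_intervals`` are 1-based inclusive reference intervals sorted by
    position; ``cds_seq`` is the spliced coding-strand CDS (reverse
    complemented for minus-strand genes).  ``flank5``/``flank3`` are the
    single reference bases flanking the CDS on the coding strand, used for
    trinucleotide context at the gene boundary.
    """

    gene_id: str
    chrom: str
    strand: str
    cds_intervals: tuple[tuple[int, int], ...]
    cds_seq: str
    flank5: str = "N"
    flank3: str = "N"

    def __post_init__(self):
        if self.strand not in "+-":
            raise GeneModelError(f"{self.gene_id}: strand must be + or -")
        ivals = tuple((int(a), int(b)) for a, b in self.cds_intervals)
        object.__setattr__(self, "cds_intervals", ivals)
        last_end = 0
        for start, end in ivals:
            if start > end:
                raise GeneModelError(f"{self.gene_id}: interval {start}>{end}")
            if start <= last_end:
                raise GeneModelError(
                    f"{self.gene_id}: intervals overlap or are unsorted"
                )
            last_end = end
        total = sum(e - s + 1 for s, e in ivals)
        if total != len(self.cds_seq):
            raise GeneModelError(
                f"{self.gene_id}: cds_seq length {len(self.cds_seq)} != "
                f"interval total {total}"
            )
        if len(self.cds_seq) % 3 != 0:
            raise GeneModelError(
                f"{self.gene_id}: CDS length {len(self.cds_seq)} not divisible by 3"
            )
        if not set(self.cds_seq) <= _DNA:
            raise GeneModelError(f"{self.gene_id}: cds_seq contains non-ACGT bases")

    @property
    def L(self) -> int:
        return len(self.cds_seq)

    @property
    def n(self) -> int:
        """Number of haploid coding base pairs at risk: 2 x CDS length."""
        return 2 * self.L

    @property
    def n_introns(self) -> int:
        return len(self.cds_intervals) - 1

    def cds_offset(self, pos: int) -> int:
        """0-based offset into ``cds_seq`` of reference position ``pos``."""
        off = 0
        for start, end in self.cds_intervals:
            if start <= pos <= end:
                fwd = off + (pos - start)
                return fwd if self.strand == "+" else self.L - 1 - fwd
            off += end - start + 1
        raise KeyError(f"position {pos} not in CDS of {self.gene_id}")

    def contains(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.cds_intervals)

    def splice_positions(self) -> frozenset[int]:
        """Reference positions of the canonical splice dinucleotides."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.cds_intervals, self.cds_intervals[1:]):
            out += [e1 + 1, e1 + 2, s2 - 2, s2 - 1]
        return frozenset(out)

    @property
    def n_splice_dinucleotides(self) -> int:
        return 2 * self.n_introns


@dataclass(frozen=True)
class MutationEvent:
    """One observed de novo mutation in one affected individual."""

    sample_id: str
    gene_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    mut_type: str = ""
    consequence: str | None = None
    aa_ref: str | None = None
    aa_alt: str | None = None
    cons_score: float | None = None
    ext_weight: float | None = None

    def __post_init__(self):
        mt = self.mut_type or infer_mut_type(self.ref, self.alt)
        object.__setattr__(self, "mut_type", mt)
        if mt == "SNV" and (len(self.ref) != 1 or len(self.alt) != 1):
            raise ValueError("SNV requires single-base ref and alt")
        if self.ext_weight is not None and not self.ext_weight > 0:
            raise ValueError("ext_weight must be > 0")
        if self.consequence is not None and self.consequence not in CONSEQUENCES:
            raise ValueError(
                f"unknown consequence {self.consequence!r}; allowed: {CONSEQUENCES}"
            )

    @property
    def indel_length(self) -> int:
        return abs(len(self.ref) - len(self.alt))


def infer_mut_type(ref: str, alt: str) -> str:
    if len(ref) == len(alt) == 1:
        return "SNV"
    return "INS" if len(alt) > len(ref) else "DEL"


def default_indel_consequence(ref: str, alt: str) -> str:
    """Frameshift unless the length difference is a multiple of 3."""
    return "frameshift_indel" if abs(len(ref) - len(alt)) % 3 else "inframe_indel"


@dataclass
class ConservationTrack:
    """Per-base conservation scores in [0, 1], keyed by (chrom, 1-based pos)."""

    scores: dict[tuple[str, int], float] = field(default_factory=dict)

    def get(self, chrom: str, pos: int) -> float | None:
        return self.scores.get((chrom, pos))

    def __len__(self) -> int:
        return len(self.scores)


# ---------------------------------------------------------------------------
# gene model input


def _read_fasta(fasta_path):
    from pyfaidx import Fasta

    return Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)


def _slice(fasta, chrom: str, start: int, end: int) -> str:
    """1-based inclusive slice from a pyfaidx Fasta."""
    if chrom not in fasta:
        raise GeneModelError(f"contig {chrom!r} missing from FASTA")
    seq = str(fasta[chrom][start - 1 : end])
    if len(seq) != end - start + 1:
        raise GeneModelError(
            f"interval {chrom}:{start}-{end} out of bounds for contig"
        )
    return seq


def _build_gene(gene_id, chrom, strand, intervals, fasta) -> GeneModel:
    intervals = sorted(intervals)
    parts = [_slice(fasta, chrom, s, e) for s, e in intervals]
    seq = "".join(parts)
    lo, hi = intervals[0][0], intervals[-1][1]
    contig_len = len(fasta[chrom])
    left = _slice(fasta, chrom, lo - 1, lo - 1) if lo > 1 else "N"
    right = _slice(fasta, chrom, hi + 1, hi + 1) if hi < contig_len else "N"
    if strand == "-":
        seq = str(Seq(seq).reverse_complement())
        left, right = str(Seq(right).complement()), str(Seq(left).complement())
    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        cds_intervals=tuple(intervals),
        cds_seq=seq,
        flank5=left,
        flank3=right,
    )


def _gff_gene_id(feature) -> str:
    for key in ("gene_id", "Parent", "ID", "gene"):
        if key in feature.attributes:
            return feature.attributes[key][0]
    raise GeneModelError(f"CDS feature at {feature.seqid}:{feature.start} lacks a gene id")


def read_gene_models(path, fasta_path) -> list[GeneModel]:
    """Read gene models from GFF3 (CDS features) or BED12, plus a FASTA.

    Genes whose spliced CDS length is not a multiple of 3 are rejected with a
    logged reason rather than silently dropped.
    """
    fasta = _read_fasta(fasta_path)
    path = str(path)
    raw: dict[str, dict] = {}
    if path.endswith((".bed", ".bed12")):
        for rec in _parse_bed12(path):
            raw[rec["gene_id"]] = rec
    else:
        import gffutils

        db = gffutils.create_db(
            path, ":memory:", merge_strategy="create_unique", keep_order=True
        )
        for feat in db.features_of_type("CDS"):
            gid = _gff_gene_id(feat)
            rec = raw.setdefault(
                gid,
                {"gene_id": gid, "chrom": feat.seqid, "strand": feat.strand, "intervals": []},
            )
            rec["intervals"].append((feat.start, feat.end))

    genes = []
    for gid, rec in raw.items():
        try:
            genes.append(
                _build_gene(gid, rec["chrom"], rec["strand"], rec["intervals"], fasta)
            )
        except GeneModelError as exc:
            logger.warning("rejected gene %s: %s", gid, exc)
    return genes


def _parse_bed12(path):
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise GeneModelError(f"{path}:{ln}: BED12 requires 12 columns")
            chrom, chrom_start = f[0], int(f[1])
            name, strand = f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            intervals = [
                (chrom_start + st + 1, chrom_start + st + sz)
                for st, sz in zip(starts, sizes)
            ]
            yield {
                "gene_id": name,
                "chrom": chrom,
                "strand": strand,
                "intervals": intervals,
            }


# ---------------------------------------------------------------------------
# variant table


def read_variant_table(tsv_path) -> list[MutationEvent]:
    """Read the de novo mutation table (plain TSV with a header row)."""
    df = pd.read_csv(tsv_path, sep="\t", dtype=str, comment="#")
    missing = [c for c in VARIANT_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{tsv_path}: missing required columns {missing}")
    events = []
    for row_no, row in enumerate(df.itertuples(index=False), 2):
        d = row._asdict()
        try:
            kwargs = {k: d[k] for k in VARIANT_REQUIRED}
            kwargs["pos"] = int(kwargs["pos"])
            for col in VARIANT_OPTIONAL:
                val = d.get(col)
                if val is None or (isinstance(val, float) and np.isnan(val)):
                    continue
                if isinstance(val, str) and (val == "" or val.lower() in ("na", "nan", ".")):
                    continue
                if col in ("cons_score", "ext_weight"):
                    kwargs[col] = float(val)
                else:
                    kwargs[col] = str(val)
            ev = MutationEvent(**kwargs)
            if ev.mut_type != "SNV" and ev.consequence is None:
                ev = replace(ev, consequence=default_indel_consequence(ev.ref, ev.alt))
            if ev.cons_score is not None and not 0.0 <= ev.cons_score <= 1.0:
                raise ValueError(f"cons_score {ev.cons_score} outside [0, 1]")
            events.append(ev)
        except (ValueError, TypeError, KeyError) as exc:
            raise ValueError(f"{tsv_path}: line {row_no}: {exc}") from exc
    return events


def write_variant_table(events, path) -> None:
    cols = VARIANT_REQUIRED + VARIANT_OPTIONAL
    rows = [
        {c: ("" if getattr(ev, c, None) is None else getattr(ev, c)) for c in cols}
        for ev in events
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# conservation


def read_conservation(bedgraph_path) -> ConservationTrack:
    """Read a 4-column bedGraph (0-based half-open) into a per-base track."""
    track = ConservationTrack()
    with open(bedgraph_path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split()
            if len(f) != 4:
                raise ValueError(f"{bedgraph_path}:{ln}: expected 4 columns")
            chrom, start, end, score = f[0], int(f[1]), int(f[2]), float(f[3])
            if not 0.0 <= score <= 1.0:
                raise ValueError(
                    f"{bedgraph_path}:{ln}: score {score} outside [0, 1]"
                )
            for pos in range(start + 1, end + 1):  # to 1-based inclusive
                key = (chrom, pos)
                if key in track.scores:
                    raise ValueError(
                        f"{bedgraph_path}:{ln}: overlapping record at {chrom}:{pos}"
                    )
                track.scores[key] = score
    return track


def write_conservation(track: ConservationTrack, path) -> None:
    """Write a per-base track back out as single-base bedGraph records."""
    with open(path, "w") as fh:
        for (chrom, pos), score in sorted(track.scores.items()):
            fh.write(f"{chrom}\t{pos - 1}\t{pos}\t{score:g}\n")


# ---------------------------------------------------------------------------
# results


def write_results(results, path) -> None:
    """Write per-gene test results, sorted by p-value ascending."""
    rows = []
    for res in results:
        rows.append(
            {
                "gene_id": res.gene_id,
                "n_mutations": res.n_mutations,
                "m": res.m,
                "r_hat": res.r_hat,
                "D": res.D,
                "p_value": res.p_value,
                "q_value": res.q_value,
                "n_sims": res.n_sims,
            }
        )
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if len(df):
        df = df.sort_values(["p_value", "gene_id"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
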