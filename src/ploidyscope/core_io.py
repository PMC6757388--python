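"""Readers/writers and basic assembly statistics.

Internal coordinates are 0-based half-open everywhere; GFF3 (1-based,
inclusive) is converted at the boundary.  FASTA handling goes through
Biopython, GFF3 parsing through gffutils.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("ploidyscope")

_VALID_NT = set("ACGTN")

COPY_LABELS = ("copy1", "copy2", "triplicate", "unpaired", "unassigned")


def setup_logging(level: int = logging.INFO) -> None:
    """Configure package logging to standard error."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("ploidyscope")
    root.handlers.clear()
    root.addHandler(handler)
    root.setLevel(level)


@dataclass
class Assembly:
    """Ordered scaffold collection (uppercase ACGTN sequences)."""

    scaffolds: list[tuple[str, str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for sid, seq in self.scaffolds:
            if sid in seen:
                raise ValueError(f"duplicate scaffold id: {sid}")
            seen.add(sid)
            if not seq:
                raise ValueError(f"empty sequence for scaffold {sid}")
            bad = set(seq) - _VALID_NT
            if bad:
                raise ValueError(f"scaffold {sid} has invalid characters: {sorted(bad)}")
            n_frac = seq.count("N") / len(seq)
            if n_frac > 0.10:
                logger.warning("scaffold %s is %.1f%% N", sid, 100 * n_frac)

    def __len__(self) -> int:
        return len(self.scaffolds)

    @property
    def ids(self) -> list[str]:
        return [sid for sid, _ in self.scaffolds]

    def sequence(self, scaffold_id: str) -> str:
        for sid, seq in self.scaffolds:
            if sid == scaffold_id:
                return seq
        raise KeyError(scaffold_id)

    @property
    def total_length(self) -> int:
        return sum(len(s) for _, s in self.scaffolds)


@dataclass
class GeneModel:
    """A located gene model with spliced, strand-resolved CDS."""

    gene_id: str
    scaffold_id: str
    start: int  # 0-based
    end: int  # half-open
    strand: str
    cds: str
    protein: str
    copy_label: str = "unassigned"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"{self.gene_id}: bad coordinates {self.start}..{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        if self.copy_label not in COPY_LABELS:
            raise ValueError(f"{self.gene_id}: bad copy label {self.copy_label!r}")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass
class AssemblyStats:
    n_scaffolds: int
    total_length: int
    n50: int
    l50: int


@dataclass
class SegmentRecord:
    """A coords-style syntenic segment between two scaffolds.

    Intervals are normalized to start < end; the original orientation is
    retained in ``ref_forward`` / ``qry_forward``.
    """

    ref_scaffold: str
    qry_scaffold: str
    ref_start: int
    ref_end: int
    qry_start: int
    qry_end: int
    pct_identity: float
    ref_forward: bool = True
    qry_forward: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.pct_identity <= 100):
            raise ValueError(f"pct_identity out of range: {self.pct_identity}")

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into ordered (id, uppercase sequence) records."""
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id: {rec.id}")
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    logger.info("read %d FASTA records from %s", len(records), path)
    return records


def read_assembly(path) -> Assembly:
    return Assembly(read_fasta(path))


def write_fasta(records, path, width: int = 80) -> None:
    seqs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)
    logger.info("wrote %d FASTA records to %s", len(seqs), path)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_cds(cds: str) -> str:
    """Translate to the first stop under the standard code."""
    prot = str(Seq(cds[: len(cds) - len(cds) % 3]).translate())
    stop = prot.find("*")
    return prot if stop < 0 else prot[:stop]


def read_gff3(path, assembly: Assembly) -> list[GeneModel]:
    """Read gene/mRNA/CDS features into one GeneModel per mRNA.

    CDS segments are spliced in transcription order; minus-strand CDS are
    reverse-complemented.  Coordinates are converted to 0-based half-open.
    """
    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique", keep_order=True)
    seqs = dict(assembly.scaffolds)
    models: list[GeneModel] = []
    orphans = [f.id for f in db.features_of_type("mRNA") if "Parent" not in f.attributes]
    if orphans:
        raise ValueError(f"mRNA features without gene parents: {orphans}")
    for mrna in db.features_of_type("mRNA", order_by=("seqid", "start")):
        cds_parts = sorted(db.children(mrna, featuretype="CDS"), key=lambda f: f.start)
        if not cds_parts:
            raise ValueError(f"mRNA {mrna.id} has no CDS children")
        if mrna.seqid not in seqs:
            raise ValueError(f"mRNA {mrna.id} on unknown scaffold {mrna.seqid}")
        scaf = seqs[mrna.seqid]
        pieces = []
        for part in cds_parts:
            if part.start < 1 or part.end > len(scaf):
                raise ValueError(f"CDS of {mrna.id} outside scaffold bounds")
            pieces.append(scaf[part.start - 1 : part.end])
        cds = "".join(pieces)
        if mrna.strand == "-":
            cds = reverse_complement(cds)
        start0 = min(p.start for p in cds_parts) - 1
        end0 = max(p.end for p in cds_parts)
        if len(cds) % 3 != 0:
            logger.warning("mRNA %s: CDS length %d not divisible by 3 (partial?)", mrna.id, len(cds))
        gene_id = mrna.attributes.get("Parent", [mrna.id])[0]
        models.append(
            GeneModel(
                gene_id=gene_id,
                scaffold_id=mrna.seqid,
                start=start0,
                end=end0,
                strand=mrna.strand,
                cds=cds,
                protein=translate_cds(cds),
            )
        )
    logger.info("read %d gene models from %s", len(models), path)
    return models


def write_gff3(models, path) -> None:
    """Write single-mRNA gene models as gene/mRNA/CDS triples."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in sorted(models, key=lambda g: (g.scaffold_id, g.start)):
            s1, e1 = m.start + 1, m.end
            base = f"{m.scaffold_id}\tploidyscope\t"
            tail = f"\t{s1}\t{e1}\t.\t{m.strand}\t"
            fh.write(base + "gene" + tail + f".\tID={m.gene_id}\n")
            fh.write(base + "mRNA" + tail + f".\tID={m.gene_id}.mRNA;Parent={m.gene_id}\n")
            fh.write(base + "CDS" + tail + f"0\tID={m.gene_id}.cds;Parent={m.gene_id}.mRNA\n")
    logger.info("wrote %d gene models to %s", len(models), path)


# ---------------------------------------------------------------------------
# Assembly statistics
# ---------------------------------------------------------------------------

def assembly_stats(assembly: Assembly, min_scaffold_len: int = 0) -> AssemblyStats:
    """N50/L50 over scaffolds at least ``min_scaffold_len`` long.

    N50 is the length of the scaffold at which the cumulative sorted
    (descending) length first reaches half of the filtered total; L50 is its
    rank (1-based).
    """
    lengths = sorted((len(s) for _, s in assembly.scaffolds if len(s) >= min_scaffold_len), reverse=True)
    if not lengths:
        raise ValueError(f"no scaffold passes min length {min_scaffold_len}")
    total = sum(lengths)
    cumulative = 0
    for rank, length in enumerate(lengths, start=1):
        cumulative += length
        if 2 * cumulative >= total:
            return AssemblyStats(n_scaffolds=len(lengths), total_length=total, n50=length, l50=rank)
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# Segment tables (show-coords -T column order)
# ---------------------------------------------------------------------------

SEGMENT_COLUMNS = [
    "ref_start",
    "ref_end",
    "qry_start",
    "qry_end",
    "ref_len",
    "qry_len",
    "pct_identity",
    "ref_scaffold",
    "qry_scaffold",
]


def read_segment_table(path, min_len: int = 2000) -> list[SegmentRecord]:
    """Read a tab-separated coords-style table; drop segments < min_len.

    Columns (fixed dialect): ref_start, ref_end, qry_start, qry_end, ref_len,
    qry_len, pct_identity, ref_scaffold, qry_scaffold.  Input coordinates are
    1-based inclusive; inverted intervals are normalized with orientation
    kept as metadata.
    """
    records: list[SegmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < len(SEGMENT_COLUMNS):
                raise ValueError(f"{path}:{lineno}: expected {len(SEGMENT_COLUMNS)} columns, got {len(parts)}")
            try:
                rs, re_, qs, qe = (int(x) for x in parts[:4])
                ident = float(parts[6])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed numeric field") from exc
            ref_fwd = rs <= re_
            qry_fwd = qs <= qe
            if not ref_fwd:
                rs, re_ = re_, rs
            if not qry_fwd:
                qs, qe = qe, qs
            rec = SegmentRecord(
                ref_scaffold=parts[7],
                qry_scaffold=parts[8],
                ref_start=rs - 1,
                ref_end=re_,
                qry_start=qs - 1,
                qry_end=qe,
                pct_identity=ident,
                ref_forward=ref_fwd,
                qry_forward=qry_fwd,
            )
            if rec.length >= min_len:
                records.append(rec)
    logger.info("read %d segments (>=%d bp) from %s", len(records), min_len, path)
    return records


def write_segment_table(records, path) -> None:
    rows = []
    for r in records:
        rs, re_ = r.ref_start + 1, r.ref_end
        qs, qe = r.qry_start + 1, r.qry_end
        if not r.ref_forward:
            rs, re_ = re_, rs
        if not r.qry_forward:
            qs, qe = qe, qs
        rows.append([rs, re_, qs, qe, r.ref_end - r.ref_start, r.qry_end - r.qry_start,
                     r.pct_identity, r.ref_scaffold, r.qry_scaffold])
    pd.DataFrame(rows, columns=SEGMENT_COLUMNS).to_csv(path, sep="\t", header=False, index=False)


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
    logger.info("wrote %d rows to %s", len(df), path)
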