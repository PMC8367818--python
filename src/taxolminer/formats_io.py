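"""Readers and writers for the external formats the pipeline consumes.

Every downstream module works on the in-memory types produced here:
``GeneLocus`` records from GFF3 + a family-label TSV, codon pair alignments
and LTR pairs from FASTA, all-vs-all similarity tables and count matrices
from TSV, and BED-like group output.  Internal gene coordinates are 1-based
inclusive (GFF3 native); BED-style output is 0-based half-open.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import pandas as pd
from Bio import SeqIO

from .codon_evol import CodonPairAlignment, STOP_CODONS
from .ltr_clock import LTRElement

__all__ = [
    "GeneLocus",
    "ExpressionStudy",
    "ParseError",
    "DuplicateGeneError",
    "get_logger",
    "read_annotation",
    "read_family_map",
    "read_codon_alignment",
    "read_codon_pairs",
    "read_ltr_pairs",
    "read_hits",
    "write_groups",
    "read_counts",
    "read_samples",
    "load_config",
    "save_config",
]

HITS_COLUMNS = ["query", "subject", "bitscore", "evalue", "aln_length"]


class ParseError(ValueError):
    pass


class DuplicateGeneError(ValueError):
    pass


def get_logger(name: str = "taxolminer", level: int = logging.INFO) -> logging.Logger:
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
        )
        logger.addHandler(handler)
        logger.setLevel(level)
    return logger


_LOG = get_logger(__name__)


@dataclass(frozen=True)
class GeneLocus:
    """A chromosome-placed, family-labelled gene (1-based inclusive coords)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "?"
    family: str = "unassigned"
    subfamily: str | None = None

    def __post_init__(self):
        if self.start < 1:
            raise ValueError(f"{self.gene_id}: start {self.start} < 1")
        if self.end < self.start:
            raise ValueError(f"{self.gene_id}: end {self.end} < start {self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class ExpressionStudy:
    """A genes x samples count table with per-gene lengths and sample metadata.

    ``samples`` is indexed by sample name with columns tissue, line,
    treatment, time_h, replicate; ``counts`` columns must match its index and
    ``gene_lengths`` must cover every counts row.
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series
    samples: pd.DataFrame

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        missing = self.counts.index.difference(self.gene_lengths.index)
        if len(missing):
            raise ValueError(f"genes without lengths: {list(missing)[:5]} ...")
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("counts columns do not match sample metadata index")

    def columns_for(self, **criteria) -> list[str]:
        """Sample names matching all metadata criteria, e.g. tissue='root'."""
        mask = pd.Series(True, index=self.samples.index)
        for key, value in criteria.items():
            mask &= self.samples[key] == value
        return list(self.samples.index[mask])


def read_family_map(path) -> dict[str, tuple[str, str | None]]:
    """TSV of gene_id -> family [-> subfamily]; '#' comments allowed."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, dtype=str
    )
    if df.shape[1] < 2:
        raise ParseError(f"{path}: family map needs >= 2 columns")
    out = {}
    for row in df.itertuples(index=False):
        sub = row[2] if len(row) > 2 and pd.notna(row[2]) else None
        out[row[0]] = (row[1], sub)
    return out


def read_annotation(
    gff_path, family_map=None, feature_type: str = "gene"
) -> list[GeneLocus]:
    """Read gene records from GFF3, attaching family labels.

    ``family_map`` may be a TSV path or a mapping gene_id -> family (or
    (family, subfamily)).  Genes absent from the map get family
    "unassigned" (warning logged).  Malformed lines and duplicate gene IDs
    raise typed errors.
    """
    gff_path = Path(gff_path)
    # pre-validate column structure so errors can name the offending line
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped or stripped.startswith("#"):
                continue
            if len(stripped.split("\t")) != 9:
                raise ParseError(
                    f"{gff_path}: malformed GFF3 line {lineno}: expected 9 "
                    f"tab-separated fields"
                )
    try:
        db = gffutils.create_db(
            str(gff_path),
            ":memory:",
            merge_strategy="error",
            keep_order=True,
        )
    except ValueError as exc:
        raise DuplicateGeneError(f"{gff_path}: {exc}") from exc

    if family_map is None:
        fam = {}
    elif isinstance(family_map, (str, Path)):
        fam = read_family_map(family_map)
    else:
        fam = {
            k: (v if isinstance(v, tuple) else (v, None))
            for k, v in family_map.items()
        }

    loci = []
    seen = set()
    n_unassigned = 0
    for feat in db.features_of_type(feature_type, order_by=("seqid", "start")):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        if gene_id in seen:
            raise DuplicateGeneError(f"duplicate gene ID {gene_id}")
        seen.add(gene_id)
        family, subfamily = fam.get(gene_id, (None, None))
        if family is None:
            family = "unassigned"
            if fam:
                n_unassigned += 1
        loci.append(
            GeneLocus(
                gene_id=gene_id,
                chrom=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "?",
                family=family,
                subfamily=subfamily,
            )
        )
    if n_unassigned:
        _LOG.warning("%d gene(s) missing from the family map -> 'unassigned'", n_unassigned)
    return loci


def write_annotation(loci: Iterable[GeneLocus], gff_path, family_path=None) -> None:
    """Write loci as a gene-only GFF3 plus an optional family-map TSV."""
    loci = list(loci)
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in loci:
            strand = g.strand if g.strand in "+-" else "."
            fh.write(
                f"{g.chrom}\ttaxolminer\tgene\t{g.start}\t{g.end}\t.\t{strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
    if family_path is not None:
        with open(family_path, "w") as fh:
            fh.write("# gene_id\tfamily\tsubfamily\n")
            for g in loci:
                sub = g.subfamily or ""
                fh.write(f"{g.gene_id}\t{g.family}\t{sub}\n")


def _check_pair(rec_a, rec_b, drop_ambiguous: bool) -> CodonPairAlignment:
    a, b = str(rec_a.seq).upper(), str(rec_b.seq).upper()
    if len(a) != len(b):
        raise ParseError(f"{rec_a.id}/{rec_b.id}: sequences differ in length")
    if len(a) % 3:
        raise ParseError(f"{rec_a.id}/{rec_b.id}: not codon-multiple")
    codons_a, codons_b = [], []
    n_codons = len(a) // 3
    for i in range(n_codons):
        ca, cb = a[3 * i : 3 * i + 3], b[3 * i : 3 * i + 3]
        ambiguous = any(ch not in "ACGT" for ch in ca + cb)
        if ambiguous:
            if drop_ambiguous:
                continue
            raise ParseError(
                f"{rec_a.id}/{rec_b.id}: non-ACGT codon at position {i + 1}"
            )
        stop = ca in STOP_CODONS or cb in STOP_CODONS
        if stop:
            if i == n_codons - 1:
                continue  # trailing stop codon: drop the column
            raise ParseError(
                f"{rec_a.id}/{rec_b.id}: internal stop codon at position {i + 1}"
            )
        codons_a.append(ca)
        codons_b.append(cb)
    return CodonPairAlignment(
        tuple(codons_a), tuple(codons_b), name_a=rec_a.id, name_b=rec_b.id
    )


def read_codon_alignment(path, drop_ambiguous: bool = False) -> CodonPairAlignment:
    """FASTA with exactly two equal-length gapless coding sequences."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ParseError(f"{path}: expected exactly 2 records, found {len(records)}")
    return _check_pair(records[0], records[1], drop_ambiguous)


def read_codon_pairs(path, drop_ambiguous: bool = False) -> list[CodonPairAlignment]:
    """FASTA with consecutive records forming aligned pairs (2n records)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) % 2:
        raise ParseError(f"{path}: odd number of records; pairs expected")
    return [
        _check_pair(records[i], records[i + 1], drop_ambiguous)
        for i in range(0, len(records), 2)
    ]


def read_ltr_pairs(path) -> list[LTRElement]:
    """FASTA of aligned terminal repeats paired by '<id>_5LTR'/'<id>_3LTR'."""
    five, three = {}, {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id.endswith("_5LTR"):
            five[rec.id[:-5]] = str(rec.seq).upper().replace("-", "")
        elif rec.id.endswith("_3LTR"):
            three[rec.id[:-5]] = str(rec.seq).upper().replace("-", "")
        else:
            raise ParseError(f"{path}: record {rec.id} lacks _5LTR/_3LTR suffix")
    unmatched = set(five) ^ set(three)
    if unmatched:
        raise ParseError(f"{path}: unmatched LTR ids {sorted(unmatched)[:5]}")
    return [LTRElement(eid, five[eid], three[eid]) for eid in sorted(five)]


def read_hits(path) -> pd.DataFrame:
    """All-vs-all similarity table: query, subject, bitscore, evalue, aln_length."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=HITS_COLUMNS)
    if (df["bitscore"] < 0).any() or (df["aln_length"] < 0).any():
        raise ParseError(f"{path}: negative bitscore or alignment length")
    return df


def write_groups(groups, path) -> None:
    """Write detected gene groups as a BED-like TSV (0-based half-open).

    Columns: chrom, start, end, label, n_members, member_ids.  Sorted by
    chromosome then start.  An empty group set yields a header-only file.
    """
    rows = [
        {
            "chrom": g.chrom,
            "start": g.span[0] - 1,  # 1-based inclusive -> 0-based half-open
            "end": g.span[1],
            "label": g.label,
            "n_members": len(g.members),
            "member_ids": ",".join(m.gene_id for m in g.members),
        }
        for g in groups
    ]
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "label", "n_members", "member_ids"]
    )
    df = df.sort_values(["chrom", "start"]) if len(df) else df
    df.to_csv(path, sep="\t", index=False)


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise ParseError(f"{path}: negative counts")
    return df


def read_samples(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, dtype={"time_h": float})


def load_config(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def save_config(config: Mapping, path) -> None:
    with open(path, "w") as fh:
        json.dump(dict(config), fh, indent=2, sort_keys=True)
        fh.write("\n")
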