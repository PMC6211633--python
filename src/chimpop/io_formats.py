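"""Readers and writers for the text formats the pipeline touches.

Coordinates are 0-based half-open internally and converted to the 1-based
inclusive convention at every file-format boundary (VCF dialect).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, UnsupportedInputError
from .tree import GeneTree, TreeNode

logger = logging.getLogger(__name__)

SEQ_ALPHABET = frozenset("ACGTN-")
GENE_LABELS = ("B1", "B2", "B3", "other")

#: genotype codes used in VariantMatrix (count of alternate alleles)
GT_MISSING = -1


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class AlleleSequence:
    """A named DNA sequence with gene/region labels and exon-intron features.

    ``features`` are ``(kind, start, end)`` triples with 0-based half-open
    coordinates in the sequence frame; kinds are ``exon`` and ``intron``.
    ``annotations`` carries simulator-planted truths (e.g. the true crossover
    position) so downstream oracle tests can verify recovery.
    """

    id: str
    gene_label: str = "other"
    region_label: str = ""
    sequence: str = ""
    features: list[tuple[str, int, int]] = field(default_factory=list)
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"record {self.id!r}: empty sequence")
        if self.gene_label not in GENE_LABELS:
            raise FormatError(
                f"record {self.id!r}: gene_label {self.gene_label!r} not in {GENE_LABELS}"
            )
        bad = set(self.sequence) - SEQ_ALPHABET
        if bad:
            raise FormatError(
                f"record {self.id!r}: characters {sorted(bad)} outside alphabet ACGTN-"
            )
        n = len(self.sequence)
        spans = []
        for kind, start, end in self.features:
            if kind not in ("exon", "intron"):
                raise FormatError(f"record {self.id!r}: unknown feature kind {kind!r}")
            if not (0 <= start < end <= n):
                raise FormatError(
                    f"record {self.id!r}: feature span ({start},{end}) outside [0,{n})"
                )
            spans.append((start, end))
        spans.sort()
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise FormatError(f"record {self.id!r}: overlapping features")

    def __len__(self) -> int:
        return len(self.sequence)

    def feature_span(self, kind: str) -> Optional[tuple[int, int]]:
        """First feature span of the given kind, or None."""
        for k, s, e in self.features:
            if k == kind:
                return (s, e)
        return None

    def intron_sequence(self) -> Optional[str]:
        span = self.feature_span("intron")
        if span is None:
            return None
        return self.sequence[span[0]: span[1]]


@dataclass
class SampleMetadata:
    sample_id: str
    species_label: str
    region: str
    source: str = "field"


@dataclass
class VariantMatrix:
    """Diploid biallelic genotypes of N samples at P positions.

    ``positions`` are 1-based (VCF convention) and strictly increasing;
    ``genotypes`` is an ``N x P`` int8 array holding the count of alternate
    alleles (0, 1 or 2) with ``-1`` marking a missing call.
    """

    sample_ids: list[str]
    positions: np.ndarray
    genotypes: np.ndarray
    segment_length: int
    chrom: str = "segment"
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        n, p = self.genotypes.shape
        if n != len(self.sample_ids):
            raise FormatError("genotype row count != number of samples")
        if p != len(self.positions):
            raise FormatError("genotype column count != number of positions")
        if n < 2:
            raise FormatError("VariantMatrix requires at least 2 samples")
        if p and (np.any(np.diff(self.positions) <= 0)):
            raise FormatError("positions must be strictly increasing")
        if p and (self.positions[0] < 1 or self.positions[-1] > self.segment_length):
            raise FormatError("positions must lie in [1, segment_length]")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]


@dataclass
class VcfDropLog:
    """Counts of sites removed while reading a VCF."""

    not_biallelic: int = 0
    filter_failed: int = 0

    @property
    def total(self) -> int:
        return self.not_biallelic + self.filter_failed


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _parse_header(header: str) -> tuple[str, str, str]:
    parts = header.split("|")
    seq_id = parts[0]
    gene = parts[1] if len(parts) > 1 and parts[1] in GENE_LABELS else "other"
    region = parts[2] if len(parts) > 2 else ""
    return seq_id, gene, region


def read_fasta(path: Union[str, Path]) -> list[AlleleSequence]:
    """Read FASTA records as :class:`AlleleSequence` objects.

    Header tokens may encode labels as ``id|gene|region``; plain headers get
    ``gene_label='other'`` and an empty region.
    """
    path = Path(path)
    records: list[AlleleSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq_id, gene, region = _parse_header(rec.id)
        if seq_id in seen:
            raise FormatError(f"{path}: duplicate record id {seq_id!r}")
        seen.add(seq_id)
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {seq_id!r} has an empty sequence")
        records.append(
            AlleleSequence(id=seq_id, gene_label=gene, region_label=region, sequence=seq)
        )
    logger.info("read_fasta: %d records from %s", len(records), path)
    return records


def write_fasta(records: list[AlleleSequence], path: Union[str, Path]) -> None:
    """Write records with ``id|gene|region`` headers, 60-column wrapped."""
    out = []
    for r in records:
        header = r.id if r.gene_label == "other" and not r.region_label else (
            f"{r.id}|{r.gene_label}|{r.region_label}"
        )
        out.append(SeqRecord(Seq(r.sequence), id=header, description=""))
    SeqIO.write(out, str(path), "fasta")


# ---------------------------------------------------------------------------
# sample metadata TSV
# ---------------------------------------------------------------------------

METADATA_COLUMNS = ["sample_id", "species_label", "region", "source"]


def read_metadata(path: Union[str, Path]) -> list[SampleMetadata]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing metadata columns {missing}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"{path}: duplicate sample_id {dup!r}")
    return [
        SampleMetadata(r.sample_id, r.species_label, r.region, r.source)
        for r in df.itertuples(index=False)
    ]


def write_metadata(records: list[SampleMetadata], path: Union[str, Path]) -> None:
    import pandas as pd

    df = pd.DataFrame(
        [(m.sample_id, m.species_label, m.region, m.source) for m in records],
        columns=METADATA_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_SNP = frozenset("ACGT")


def read_vcf_biallelic(path: Union[str, Path]) -> tuple[VariantMatrix, VcfDropLog]:
    """Read a single-contig VCF into a :class:`VariantMatrix`.

    Sites that are not biallelic SNPs, or whose FILTER is neither PASS nor
    '.', are dropped and counted in the returned :class:`VcfDropLog`.
    Phased separators are treated as unphased; ``./.`` becomes missing.
    """
    import cyvcf2

    path = Path(path)
    _require_chrom_header(path)
    vcf = cyvcf2.VCF(str(path))
    samples = list(vcf.samples)
    drop = VcfDropLog()
    positions: list[int] = []
    columns: list[np.ndarray] = []
    chroms: set[str] = set()
    contig_lengths = dict(zip(vcf.seqnames, getattr(vcf, "seqlens", []) or []))
    for v in vcf:
        chroms.add(v.CHROM)
        if len(chroms) > 1:
            raise UnsupportedInputError(f"{path}: more than one contig in VCF")
        if v.FILTER is not None:  # cyvcf2: None means PASS or '.'
            drop.filter_failed += 1
            continue
        if (
            len(v.ALT) != 1
            or v.REF not in _SNP
            or v.ALT[0] not in _SNP
            or v.REF == v.ALT[0]
        ):
            drop.not_biallelic += 1
            continue
        col = np.empty(len(samples), dtype=np.int8)
        for i, g in enumerate(v.genotypes):
            a, b = g[0], g[1]
            col[i] = GT_MISSING if (a < 0 or b < 0) else a + b
        positions.append(v.POS)
        columns.append(col)
    vcf.close()
    if not chroms:
        chrom = "segment"
    else:
        chrom = chroms.pop()
    seg_len = int(contig_lengths.get(chrom, 0)) or (max(positions) if positions else 1)
    genotypes = (
        np.stack(columns, axis=1)
        if columns
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    matrix = VariantMatrix(
        sample_ids=samples,
        positions=np.array(positions, dtype=np.int64),
        genotypes=genotypes,
        segment_length=seg_len,
        chrom=chrom,
    )
    logger.info(
        "read_vcf_biallelic: %d sites kept, %d dropped (%d not biallelic, %d filter) from %s",
        matrix.n_sites, drop.total, drop.not_biallelic, drop.filter_failed, path,
    )
    return matrix, drop


def _require_chrom_header(path: Path) -> None:
    with open(path) as fh:
        for line in fh:
            if line.startswith("#CHROM"):
                return
            if not line.startswith("#"):
                break
    raise FormatError(f"{path}: missing #CHROM header line")


_GT_STRINGS = {GT_MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(matrix: VariantMatrix, path: Union[str, Path],
              ref_alt: Optional[list[tuple[str, str]]] = None) -> None:
    """Write a minimal GT-only VCF v4.2 for the matrix.

    ``ref_alt`` optionally supplies per-site (REF, ALT) bases; defaults to
    alternating A/G placeholders since only genotypes matter downstream.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={matrix.chrom},length={matrix.segment_length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids)
            + "\n"
        )
        for j, pos in enumerate(matrix.positions):
            ref, alt = ref_alt[j] if ref_alt else ("A", "G")
            gts = "\t".join(_GT_STRINGS[int(g)] for g in matrix.genotypes[:, j])
            fh.write(f"{matrix.chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

_NEWICK_META = re.compile(r"[\s()\[\]:;,\"']")


def _format_label(label: str) -> str:
    if label is None:
        return ""
    if "\n" in label or "\r" in label:
        raise FormatError(f"label {label!r} cannot be represented in Newick")
    if _NEWICK_META.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def newick_string(tree: GeneTree) -> str:
    """Serialize a tree to Newick with 6-decimal branch lengths."""

    def render(node: TreeNode, is_root: bool) -> str:
        if node.is_leaf:
            s = _format_label(node.name)
        else:
            inner = ",".join(render(c, False) for c in node.children)
            label = ""
            if node.support is not None:
                label = f"{node.support:g}"
            elif node.name:
                label = _format_label(node.name)
            s = f"({inner}){label}"
        if not is_root and node.length is not None:
            s += f":{node.length:.6f}"
        return s

    return render(tree, True) + ";"


def write_newick(tree: GeneTree, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write(newick_string(tree) + "\n")
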