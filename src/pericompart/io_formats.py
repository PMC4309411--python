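"""Readers and writers for the external formats the pipeline touches.

All downstream modules consume only the domain types defined here:
:class:`GeneMapEntry`, :class:`SimilarityHit`, :class:`VariantSite` and
:class:`ExpressionMatrix`.  Conventions follow the input formats: physical
and cDNA coordinates are 1-based, intervals are closed ``[start, end]`` in
bp, and similarity hits use the 12-column BLAST tabular dialect (where
``s_start > s_end`` encodes a minus-strand hit).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

NUCLEOTIDES = frozenset("ACGT")


class FormatError(ValueError):
    """A malformed input file; the message names the offending line."""


@dataclass(frozen=True)
class GeneMapEntry:
    """One mapped gene: identifier, chromosome, genetic (cM) and physical (bp) position."""

    gene_id: str
    chromosome: str
    genetic_pos: float  # cM, non-negative
    physical_pos: int  # bp, 1-based

    def __post_init__(self) -> None:
        if self.genetic_pos < 0:
            raise ValueError(f"negative genetic position for {self.gene_id}")
        if self.physical_pos < 0:
            raise ValueError(f"negative physical position for {self.gene_id}")


@dataclass(frozen=True)
class SimilarityHit:
    """One row of a 12-column BLAST tabular file (-outfmt 6)."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float

    @property
    def minus_strand(self) -> bool:
        """True for a minus-strand hit (subject coordinates reversed)."""
        return self.s_start > self.s_end


@dataclass
class VariantSite:
    """A biallelic SNV on a cDNA reference with per-sample allele read counts.

    ``ref_counts[i]``/``alt_counts[i]`` are the reads supporting the reference
    and alternate allele in sample ``i``; a sample with both zero is missing.
    """

    ref_id: str
    pos: int  # 1-based on the cDNA
    ref_allele: str
    alt_allele: str
    ref_counts: list[int] = field(default_factory=list)
    alt_counts: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.ref_allele not in NUCLEOTIDES or self.alt_allele not in NUCLEOTIDES:
            raise ValueError(f"alleles must be single nucleotides, got "
                             f"{self.ref_allele!r}/{self.alt_allele!r}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt allele are identical")
        if len(self.ref_counts) != len(self.alt_counts):
            raise ValueError("per-sample count vectors differ in length")
        if any(c < 0 for c in self.ref_counts) or any(c < 0 for c in self.alt_counts):
            raise ValueError("negative read count")

    @property
    def n_samples(self) -> int:
        return len(self.ref_counts)

    def is_missing(self, i: int) -> bool:
        return self.ref_counts[i] == 0 and self.alt_counts[i] == 0


# ---------------------------------------------------------------------------
# gene maps

MAP_COLUMNS = ("gene_id", "chromosome", "cM", "bp")


def read_gene_map(path: str | Path) -> list[GeneMapEntry]:
    """Read a TSV gene map with header ``gene_id chromosome cM bp``.

    Entries are returned sorted by ``(chromosome, physical_pos)``; duplicate
    gene ids are rejected.
    """
    path = Path(path)
    entries: list[GeneMapEntry] = []
    seen: set[str] = set()
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header[:4]) != MAP_COLUMNS:
            raise FormatError(
                f"{path}: expected header {MAP_COLUMNS}, got {tuple(header[:4])}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            gene_id, chrom, cm_s, bp_s = parts[:4]
            try:
                entry = GeneMapEntry(gene_id, chrom, float(cm_s), int(bp_s))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if gene_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            entries.append(entry)
    entries.sort(key=lambda e: (e.chromosome, e.physical_pos))
    return entries


def write_gene_map(entries: Iterable[GeneMapEntry], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("\t".join(MAP_COLUMNS) + "\n")
        for e in entries:
            fh.write(f"{e.gene_id}\t{e.chromosome}\t{e.genetic_pos:g}\t{e.physical_pos}\n")


def read_centromeres(path: str | Path) -> dict[str, int]:
    """Read a TSV of ``chromosome<TAB>bp`` centromere positions (with header)."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str, "bp": int})
    if not {"chromosome", "bp"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns chromosome, bp")
    return dict(zip(df["chromosome"], df["bp"]))


def write_centromeres(centromeres: dict[str, int], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("chromosome\tbp\n")
        for chrom, bp in centromeres.items():
            fh.write(f"{chrom}\t{bp}\n")


# ---------------------------------------------------------------------------
# similarity tables (12-column BLAST tabular)


def read_similarity_table(path: str | Path) -> list[SimilarityHit]:
    """Parse a 12-column BLAST tabular file into :class:`SimilarityHit` rows.

    No filtering is performed here; minus-strand hits (s_start > s_end) are
    kept with coordinates exactly as given.
    """
    path = Path(path)
    hits: list[SimilarityHit] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(parts)}")
            try:
                hits.append(SimilarityHit(
                    query_id=parts[0], subject_id=parts[1],
                    pct_identity=float(parts[2]), aln_length=int(parts[3]),
                    mismatches=int(parts[4]), gap_opens=int(parts[5]),
                    q_start=int(parts[6]), q_end=int(parts[7]),
                    s_start=int(parts[8]), s_end=int(parts[9]),
                    evalue=float(parts[10]), bit_score=float(parts[11]),
                ))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_similarity_table(hits: Iterable[SimilarityHit], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for h in hits:
            fh.write("\t".join(str(x) for x in (
                h.query_id, h.subject_id, f"{h.pct_identity:g}", h.aln_length,
                h.mismatches, h.gap_opens, h.q_start, h.q_end, h.s_start,
                h.s_end, f"{h.evalue:g}", f"{h.bit_score:g}")) + "\n")


# ---------------------------------------------------------------------------
# variant tables: minimal VCF subset or flat TSV


def read_variant_table(path: str | Path,
                       sample_ids: Sequence[str] | None = None,
                       ) -> tuple[list[VariantSite], int]:
    """Read biallelic SNVs from a minimal VCF (AD-style counts) or a flat TSV.

    Multi-allelic and indel records are skipped; the skip count is returned
    alongside the sites and logged.  The format is sniffed from the header:
    a ``##fileformat=VCF`` line selects the VCF path, otherwise a TSV with
    header ``ref_id pos ref alt <sample>_ref <sample>_alt ...`` is expected.
    """
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
    if first.startswith("##fileformat=VCF"):
        return _read_vcf(path, sample_ids)
    return _read_variant_tsv(path, sample_ids)


def _read_vcf(path: Path, sample_ids: Sequence[str] | None,
              ) -> tuple[list[VariantSite], int]:
    sites: list[VariantSite] = []
    skipped = 0
    header_samples: list[str] | None = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                header_samples = cols[9:]
                continue
            parts = line.split("\t")
            if header_samples is None:
                raise FormatError(f"{path}:{lineno}: record before #CHROM header")
            if len(parts) < 10:
                raise FormatError(f"{path}:{lineno}: expected FORMAT + sample columns")
            chrom, pos_s, _id, ref, alt = parts[0], parts[1], parts[2], parts[3], parts[4]
            if len(ref) != 1 or len(alt) != 1 or "," in alt or \
                    ref not in NUCLEOTIDES or alt not in NUCLEOTIDES:
                skipped += 1
                continue
            fmt = parts[8].split(":")
            try:
                ad_idx = fmt.index("AD")
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: FORMAT lacks AD field") from exc
            ref_counts, alt_counts = [], []
            for samp in parts[9:]:
                ad = samp.split(":")[ad_idx]
                try:
                    r, a = (int(x) for x in ad.split(",")[:2])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: unreadable AD {ad!r}") from exc
                ref_counts.append(r)
                alt_counts.append(a)
            sites.append(VariantSite(chrom, int(pos_s), ref, alt, ref_counts, alt_counts))
    if sample_ids is not None and header_samples is not None and \
            list(sample_ids) != header_samples:
        raise FormatError(f"{path}: sample columns {header_samples} do not match "
                          f"requested {list(sample_ids)}")
    if skipped:
        logger.info("%s: skipped %d non-biallelic-SNV records", path, skipped)
    return sites, skipped


def _read_variant_tsv(path: Path, sample_ids: Sequence[str] | None,
                      ) -> tuple[list[VariantSite], int]:
    sites: list[VariantSite] = []
    skipped = 0
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["ref_id", "pos", "ref", "alt"]:
            raise FormatError(f"{path}: expected TSV header starting "
                              "ref_id, pos, ref, alt")
        n_samples = (len(header) - 4) // 2
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4 + 2 * n_samples:
                raise FormatError(f"{path}:{lineno}: wrong column count")
            ref, alt = parts[2], parts[3]
            if len(ref) != 1 or len(alt) != 1 or "," in alt or \
                    ref not in NUCLEOTIDES or alt not in NUCLEOTIDES:
                skipped += 1
                continue
            try:
                counts = [int(x) for x in parts[4:]]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: unreadable count") from exc
            sites.append(VariantSite(parts[0], int(parts[1]), ref, alt,
                                     counts[0::2], counts[1::2]))
    if skipped:
        logger.info("%s: skipped %d non-biallelic-SNV records", path, skipped)
    return sites, skipped


def write_variant_tsv(sites: Iterable[VariantSite], sample_ids: Sequence[str],
                      path: str | Path) -> None:
    cols = ["ref_id", "pos", "ref", "alt"]
    for s in sample_ids:
        cols += [f"{s}_ref", f"{s}_alt"]
    with Path(path).open("w") as fh:
        fh.write("\t".join(cols) + "\n")
        for site in sites:
            row = [site.ref_id, str(site.pos), site.ref_allele, site.alt_allele]
            for r, a in zip(site.ref_counts, site.alt_counts):
                row += [str(r), str(a)]
            fh.write("\t".join(row) + "\n")


def write_vcf(sites: Iterable[VariantSite], sample_ids: Sequence[str],
              path: str | Path) -> None:
    """Write sites as a minimal VCF 4.2 subset with AD-only FORMAT."""
    with Path(path).open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allelic depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        for s in sites:
            samples = "\t".join(f"{r},{a}" for r, a in zip(s.ref_counts, s.alt_counts))
            fh.write(f"{s.ref_id}\t{s.pos}\t.\t{s.ref_allele}\t{s.alt_allele}"
                     f"\t.\t.\t.\tAD\t{samples}\n")


# ---------------------------------------------------------------------------
# FASTA and expression matrices


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping."""
    seqs: dict[str, str] = {}
    name: str | None = None
    chunks: list[str] = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif name is not None:
                chunks.append(line.strip())
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with Path(path).open("w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes x conditions TSV expression matrix (gene ids in column 1).

    Values must be non-negative; missing values stay as NaN.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy(dtype=float, na_value=float("nan")) < 0).any():
        raise FormatError(f"{path}: negative expression value")
    return df


def write_expression_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def write_regions_bed(regions, path: str | Path) -> None:
    """Write compartment regions as BED-like TSV: chrom, start, end, label."""
    with Path(path).open("w") as fh:
        fh.write("chromosome\tstart_bp\tend_bp\tlabel\n")
        for r in regions:
            label = "LR_PC" if r.contains_centromere else "LR_flank"
            fh.write(f"{r.chromosome}\t{r.start_bp}\t{r.end_bp}\t{label}\n")
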