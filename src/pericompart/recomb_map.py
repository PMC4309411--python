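"""Per-gene recombination rate from a Marey-style map and compartment calling.

The recombination rate is expressed in cM per gene: for gene *i* on a
chromosome whose genes are ordered by physical position, the windowed rate is
the genetic distance spanned by a centred window of ``W`` genes divided by
``W``.  Low-recombining (LR) regions are maximal runs of genes whose rate is
at least ``fold`` times below the chromosome average, retained only when they
span more than ``min_frac`` of the chromosome's physical length.  The LR
region containing the centromere is the pericentromeric compartment (LR-PC);
other LR regions are flanking LR; everything else is high-recombining (HR).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io_formats import GeneMapEntry

logger = logging.getLogger(__name__)

HR = "HR"
LR_FLANK = "LR_flank"
LR_PC = "LR_PC"


@dataclass
class RateProfile:
    """Windowed recombination rate (cM/gene) for one chromosome's genes."""

    chromosome: str
    gene_ids: list[str]
    rates: np.ndarray  # cM per gene, aligned with gene_ids
    window: int
    mean_rate: float  # chromosome total cM / gene count
    n_clamped: int  # genes whose cM was raised by the isotonic cleaning step


@dataclass
class LrRegion:
    """A called low-recombining region (closed bp interval, gene-index span)."""

    chromosome: str
    start_bp: int
    end_bp: int
    start_gene_index: int
    end_gene_index: int
    contains_centromere: bool = False
    region_id: str = ""


@dataclass(frozen=True)
class CompartmentAnnotation:
    gene_id: str
    label: str  # HR | LR_flank | LR_PC
    region_id: str  # "" for HR


def split_by_chromosome(entries: Sequence[GeneMapEntry],
                        ) -> dict[str, list[GeneMapEntry]]:
    """Group map entries per chromosome, sorted by physical position."""
    out: dict[str, list[GeneMapEntry]] = {}
    for e in entries:
        out.setdefault(e.chromosome, []).append(e)
    for chrom in out:
        out[chrom].sort(key=lambda e: e.physical_pos)
    return out


def _isotonic_cm(cm: np.ndarray) -> tuple[np.ndarray, int]:
    """Make genetic positions non-decreasing by forward clamping.

    cm_i := max(cm_i, cm_{i-1}); returns the cleaned array and the number of
    genes whose position was raised (small map inversions from mapping error
    would otherwise produce negative rates).
    """
    cleaned = np.maximum.accumulate(cm)
    return cleaned, int(np.sum(cleaned > cm))


def windowed_rate(entries: Sequence[GeneMapEntry], window: int = 50) -> RateProfile:
    """Centred windowed recombination rate (cM/gene) for one chromosome.

    For gene i the window is [i - window//2, i - window//2 + window], clamped
    to the chromosome ends; the rate is the cM spanned divided by the number
    of gene intervals in the (possibly clamped) window.
    """
    if not entries:
        raise ValueError("empty chromosome")
    chroms = {e.chromosome for e in entries}
    if len(chroms) != 1:
        raise ValueError(f"entries span multiple chromosomes: {sorted(chroms)}")
    n = len(entries)
    if n < window + 1:
        raise ValueError(
            f"chromosome {entries[0].chromosome} has {n} genes; "
            f"need at least window+1 = {window + 1} (use a smaller window)")
    phys = np.array([e.physical_pos for e in entries])
    if np.any(np.diff(phys) < 0):
        raise ValueError("entries must be sorted by physical position")
    cm_raw = np.array([e.genetic_pos for e in entries], dtype=float)
    cm, n_clamped = _isotonic_cm(cm_raw)
    if n_clamped:
        logger.info("chromosome %s: clamped %d non-monotone genetic positions",
                    entries[0].chromosome, n_clamped)

    half = window // 2
    lo = np.clip(np.arange(n) - half, 0, n - 1 - window)
    hi = lo + window
    rates = (cm[hi] - cm[lo]) / window
    # chromosome mean as cM per gene interval, so a perfectly uniform map has
    # windowed rate == mean rate exactly
    mean_rate = (cm[-1] - cm[0]) / (n - 1)
    return RateProfile(chromosome=entries[0].chromosome,
                       gene_ids=[e.gene_id for e in entries],
                       rates=rates, window=window, mean_rate=mean_rate,
                       n_clamped=n_clamped)


def call_lr_regions(profile: RateProfile, entries: Sequence[GeneMapEntry],
                    fold: float = 20.0, min_frac: float = 0.02,
                    gap_genes: int = 25,
                    chromosome_length: int | None = None) -> list[LrRegion]:
    """Call low-recombining regions on one chromosome.

    Maximal runs of consecutive genes with rate <= mean_rate/fold (ties are
    inside the run) are found; runs separated by fewer than ``gap_genes``
    above-threshold genes are merged; merged runs are kept iff their physical
    span exceeds ``min_frac`` of the chromosome length (max mapped position
    unless ``chromosome_length`` is given).
    """
    if len(profile.rates) != len(entries):
        raise ValueError("profile and entries are not aligned")
    phys = np.array([e.physical_pos for e in entries])
    chrom_len = chromosome_length if chromosome_length is not None else int(phys.max())
    threshold = profile.mean_rate / fold
    low = profile.rates <= threshold

    runs: list[list[int]] = []  # [start_idx, end_idx] inclusive
    start = None
    for i, flag in enumerate(low):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append([start, i - 1])
            start = None
    if start is not None:
        runs.append([start, len(low) - 1])

    # merge runs separated by short high-rate blips
    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 < gap_genes:
            merged[-1][1] = run[1]
        else:
            merged.append(run)

    regions = []
    for k, (a, b) in enumerate(merged):
        span = phys[b] - phys[a]
        if span > min_frac * chrom_len:
            regions.append(LrRegion(
                chromosome=profile.chromosome,
                start_bp=int(phys[a]), end_bp=int(phys[b]),
                start_gene_index=a, end_gene_index=b,
                region_id=f"{profile.chromosome}:LR{len(regions) + 1}"))
    return regions


def assign_compartments(entries: Sequence[GeneMapEntry],
                        regions: Iterable[LrRegion],
                        centromere_bp: dict[str, int],
                        ) -> list[CompartmentAnnotation]:
    """Label every mapped gene HR / LR_flank / LR_PC.

    The LR region containing the centromere (per chromosome) becomes LR_PC;
    other LR regions LR_flank; unlabelled genes HR.  If no region contains
    the centromere on a chromosome that has regions, all its regions are
    LR_flank and a warning is logged.
    """
    by_chrom = split_by_chromosome(entries)
    regions_by_chrom: dict[str, list[LrRegion]] = {}
    for r in regions:
        regions_by_chrom.setdefault(r.chromosome, []).append(r)

    annotations: list[CompartmentAnnotation] = []
    for chrom, chrom_entries in by_chrom.items():
        chrom_regions = regions_by_chrom.get(chrom, [])
        cen = centromere_bp.get(chrom)
        pc_region = None
        if cen is not None:
            for r in chrom_regions:
                if r.start_bp <= cen <= r.end_bp:
                    pc_region = r
                    break
        if chrom_regions and pc_region is None:
            logger.warning("chromosome %s: centromere not inside any LR region; "
                           "all regions labelled LR_flank", chrom)
        for r in chrom_regions:
            r.contains_centromere = r is pc_region
        for i, e in enumerate(chrom_entries):
            label, region_id = HR, ""
            for r in chrom_regions:
                if r.start_gene_index <= i <= r.end_gene_index:
                    label = LR_PC if r is pc_region else LR_FLANK
                    region_id = r.region_id
                    break
            annotations.append(CompartmentAnnotation(e.gene_id, label, region_id))
    return annotations


def two_class_labels(annotations: Iterable[CompartmentAnnotation]) -> dict[str, str]:
    """Collapse to the two-class scheme used in compartment statistics: LR = LR_PC + LR_flank."""
    return {a.gene_id: ("LR" if a.label in (LR_PC, LR_FLANK) else "HR")
            for a in annotations}


def write_labels(annotations: Iterable[CompartmentAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tlabel\tregion_id\n")
        for a in annotations:
            fh.write(f"{a.gene_id}\t{a.label}\t{a.region_id}\n")


def read_labels(path) -> list[CompartmentAnnotation]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["gene_id", "label"]:
            raise ValueError(f"{path}: expected header gene_id, label[, region_id]")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                continue
            out.append(CompartmentAnnotation(
                parts[0], parts[1], parts[2] if len(parts) > 2 else ""))
    return out
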