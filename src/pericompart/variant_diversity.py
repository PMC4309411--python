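"""Per-gene nucleotide diversity (pi, pi_a, pi_s) from cDNA-mapped SNPs.

The workflow mirrors SNP calling on RNA-seq reads mapped to oriented cDNA
references from a panel of inbred lines (each line contributes one haplotype):
filter raw variant sites on minor-allele frequency and read support, locate
the protein-coding region as the longest ATG-initiated open reading frame,
classify each SNP as synonymous / nonsynonymous / noncoding against the
reference codon, and divide per-site heterozygosity sums by fractional
synonymous and nonsynonymous site counts (NG86 convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np

from .io_formats import VariantSite

BASES = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
#: Standard genetic code; '*' marks stop codons.
GENETIC_CODE: dict[str, str] = {
    a + b + c: _AA[16 * i + 4 * j + k]
    for i, a in enumerate(BASES)
    for j, b in enumerate(BASES)
    for k, c in enumerate(BASES)
}
STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")

SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"
NONCODING = "noncoding"


@dataclass(frozen=True)
class OrfAnnotation:
    """Longest ATG-initiated open reading frame on an oriented cDNA.

    ``orf_start``/``orf_end`` are 1-based inclusive and include the stop codon
    when one terminates the frame; ``protein_length`` counts amino acids.
    """

    ref_id: str
    orf_start: int
    orf_end: int
    protein_length: int
    has_stop: bool


@dataclass(frozen=True)
class ClassifiedSnp:
    site: VariantSite
    effect: str  # synonymous | nonsynonymous | noncoding
    codon_index: int | None = None  # 0-based within the ORF
    codon_pos: int | None = None  # 1..3 within the codon


@dataclass
class GeneDiversity:
    gene_id: str
    pi: float
    pi_a: float
    pi_s: float
    n_sites_total: float
    n_sites_syn: float
    n_sites_nonsyn: float
    n_samples_used: int

    @property
    def pia_pis(self) -> float | None:
        """pi_a/pi_s, defined only when pi_s > 0."""
        return self.pi_a / self.pi_s if self.pi_s > 0 else None


# ---------------------------------------------------------------------------
# variant filtering


def sample_genotypes(site: VariantSite) -> list[str | None]:
    """Majority-read allele per sample; None where the sample has no reads.

    Ties go to the reference allele (deterministic).
    """
    out: list[str | None] = []
    for r, a in zip(site.ref_counts, site.alt_counts):
        if r == 0 and a == 0:
            out.append(None)
        else:
            out.append(site.alt_allele if a > r else site.ref_allele)
    return out


def filter_variants(sites: Iterable[VariantSite], maf_min: float = 0.1,
                    min_reads: int = 3, pooled_reads: bool = False,
                    ) -> list[VariantSite]:
    """Remove likely sequencing-error sites.

    A site is retained iff the minor allele has frequency >= ``maf_min``
    (over sample-level genotypes by default, or over pooled reads with
    ``pooled_reads=True``) and is supported by >= ``min_reads`` reads in at
    least one sample.
    """
    kept: list[VariantSite] = []
    for site in sites:
        genos = [g for g in sample_genotypes(site) if g is not None]
        if len(genos) < 2:
            continue
        n_alt = sum(g == site.alt_allele for g in genos)
        n_ref = len(genos) - n_alt
        minor = site.alt_allele if n_alt <= n_ref else site.ref_allele
        if pooled_reads:
            tot_ref = sum(site.ref_counts)
            tot_alt = sum(site.alt_counts)
            tot = tot_ref + tot_alt
            minor_f = min(tot_ref, tot_alt) / tot if tot else 0.0
        else:
            minor_f = min(n_ref, n_alt) / len(genos)
        if minor_f < maf_min:
            continue
        counts = site.alt_counts if minor == site.alt_allele else site.ref_counts
        if max(counts) < min_reads:
            continue
        kept.append(site)
    return kept


# ---------------------------------------------------------------------------
# ORF finding and SNP effect classification


def find_orf(seq: str, ref_id: str = "", min_codons: int = 1,
             ) -> OrfAnnotation | None:
    """Longest ATG-initiated open reading frame on the forward strand.

    Candidate frames run from each ATG to the first in-frame stop (inclusive)
    or to the 3' end truncated to a codon boundary.  The longest wins; ties
    break to the smaller start.  Returns None when no ATG exists or the best
    frame is shorter than ``min_codons`` codons of protein.
    """
    seq = seq.upper()
    best: tuple[int, int, bool] | None = None  # (start0, end0_exclusive, has_stop)
    pos = seq.find("ATG")
    while pos != -1:
        end = pos
        has_stop = False
        for i in range(pos, len(seq) - 2, 3):
            end = i + 3
            if seq[i:i + 3] in STOP_CODONS:
                has_stop = True
                break
        length = end - pos
        if best is None or length > best[1] - best[0]:
            best = (pos, end, has_stop)
        pos = seq.find("ATG", pos + 1)
    if best is None:
        return None
    start0, end0, has_stop = best
    protein_len = (end0 - start0) // 3 - (1 if has_stop else 0)
    if protein_len < min_codons:
        return None
    return OrfAnnotation(ref_id=ref_id, orf_start=start0 + 1, orf_end=end0,
                         protein_length=protein_len, has_stop=has_stop)


def classify_snp(site: VariantSite, orf: OrfAnnotation | None,
                 ref_seq: str) -> ClassifiedSnp:
    """Classify a SNP as synonymous / nonsynonymous / noncoding.

    The alternate allele is substituted into the reference codon with the
    other two positions held at reference, and amino acids compared under
    the standard genetic code.
    """
    if not 1 <= site.pos <= len(ref_seq):
        raise ValueError(f"{site.ref_id}: position {site.pos} outside reference")
    if ref_seq[site.pos - 1].upper() != site.ref_allele:
        raise ValueError(
            f"{site.ref_id}:{site.pos}: ref allele {site.ref_allele} disagrees "
            f"with reference base {ref_seq[site.pos - 1]} (corrupt input)")
    if orf is None or not orf.orf_start <= site.pos <= orf.orf_end:
        return ClassifiedSnp(site, NONCODING)
    offset = site.pos - orf.orf_start
    codon_index = offset // 3
    codon_pos = offset % 3
    codon_start0 = orf.orf_start - 1 + codon_index * 3
    ref_codon = ref_seq[codon_start0:codon_start0 + 3].upper()
    alt_codon = (ref_codon[:codon_pos] + site.alt_allele
                 + ref_codon[codon_pos + 1:])
    effect = (SYNONYMOUS if GENETIC_CODE[ref_codon] == GENETIC_CODE[alt_codon]
              else NONSYNONYMOUS)
    return ClassifiedSnp(site, effect, codon_index, codon_pos + 1)


@lru_cache(maxsize=None)
def codon_site_fractions(codon: str) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts of one codon.

    Each codon position contributes the fraction of its three possible
    single-base changes that preserve the amino acid; a change to or from a
    stop is nonsynonymous.  Fractions sum to 3 per codon.
    """
    codon = codon.upper()
    aa = GENETIC_CODE[codon]
    syn = 0.0
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if GENETIC_CODE[mut] == aa:
                syn += 1 / 3
    return syn, 3.0 - syn


def orf_site_counts(ref_seq: str, orf: OrfAnnotation) -> tuple[float, float]:
    """Fractional synonymous / nonsynonymous site counts over the ORF.

    The terminal stop codon, when present, is excluded.
    """
    n_codons = (orf.orf_end - orf.orf_start + 1) // 3
    if orf.has_stop:
        n_codons -= 1
    syn = nonsyn = 0.0
    for k in range(n_codons):
        start0 = orf.orf_start - 1 + 3 * k
        s, n = codon_site_fractions(ref_seq[start0:start0 + 3])
        syn += s
        nonsyn += n
    return syn, nonsyn


# ---------------------------------------------------------------------------
# diversity estimation


def site_pi(allele_counts: dict[str, int] | Sequence[int]) -> float:
    """Unbiased per-site heterozygosity among n sampled alleles.

    pi_site = (n/(n-1)) * (1 - sum p_i^2), the mean pairwise difference among
    the n alleles.  Undefined (ValueError) for n < 2.
    """
    counts = (list(allele_counts.values())
              if isinstance(allele_counts, dict) else list(allele_counts))
    n = sum(counts)
    if n < 2:
        raise ValueError("site_pi needs at least 2 sampled alleles")
    freqs_sq = sum((c / n) ** 2 for c in counts)
    return (n / (n - 1)) * (1.0 - freqs_sq)


def _site_pi_from_genotypes(site: VariantSite) -> float | None:
    genos = [g for g in sample_genotypes(site) if g is not None]
    if len(genos) < 2:
        return None
    n_alt = sum(g == site.alt_allele for g in genos)
    return site_pi([len(genos) - n_alt, n_alt])


def gene_diversity(gene_id: str, variants: Sequence[VariantSite],
                   orf: OrfAnnotation | None, ref_seq: str,
                   n_samples: int,
                   covered_positions: int | None = None) -> GeneDiversity:
    """Per-gene pi, pi_a and pi_s from filtered variants.

    pi divides the sum of per-site heterozygosities over all retained SNPs by
    the number of covered positions (all reference positions by default);
    pi_s and pi_a divide the synonymous / nonsynonymous heterozygosity sums
    by the ORF's fractional site counts.  Sites where fewer than two samples
    are genotyped are excluded.
    """
    total_sites = covered_positions if covered_positions is not None else len(ref_seq)
    if total_sites <= 0:
        raise ValueError(f"{gene_id}: zero covered positions")
    if orf is not None:
        syn_sites, nonsyn_sites = orf_site_counts(ref_seq, orf)
    else:
        syn_sites = nonsyn_sites = 0.0

    pi_sum = syn_sum = nonsyn_sum = 0.0
    for v in variants:
        h = _site_pi_from_genotypes(v)
        if h is None:
            continue
        pi_sum += h
        effect = classify_snp(v, orf, ref_seq).effect
        if effect == SYNONYMOUS:
            syn_sum += h
        elif effect == NONSYNONYMOUS:
            nonsyn_sum += h

    return GeneDiversity(
        gene_id=gene_id,
        pi=pi_sum / total_sites,
        pi_a=nonsyn_sum / nonsyn_sites if nonsyn_sites > 0 else 0.0,
        pi_s=syn_sum / syn_sites if syn_sites > 0 else 0.0,
        n_sites_total=float(total_sites),
        n_sites_syn=syn_sites,
        n_sites_nonsyn=nonsyn_sites,
        n_samples_used=n_samples,
    )


def rolling_average(values: Sequence[float], window: int = 50) -> np.ndarray:
    """Centred moving mean, window truncated at the series ends.

    NaN entries (e.g. genes with undefined pi_a/pi_s) are skipped within each
    window; a window with no finite value yields NaN.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    if window > x.size:
        raise ValueError("window exceeds series length")
    half_lo = (window - 1) // 2
    half_hi = window // 2
    out = np.empty(x.size)
    for i in range(x.size):
        seg = x[max(0, i - half_lo): min(x.size, i + half_hi + 1)]
        finite = seg[np.isfinite(seg)]
        out[i] = finite.mean() if finite.size else np.nan
    return out


def pooled_pia_pis(diversities: Iterable[GeneDiversity]) -> float | None:
    """Compartment-level pi_a/pi_s as a ratio of site-weighted means.

    (sum pi_a * N_a / sum N_a) / (sum pi_s * N_s / sum N_s): per-gene ratios
    are undefined for most genes at realistic diversities, and their mean is
    biased conditional on pi_s > 0; pooling over sites avoids both problems.
    """
    num_a = den_a = num_s = den_s = 0.0
    for d in diversities:
        num_a += d.pi_a * d.n_sites_nonsyn
        den_a += d.n_sites_nonsyn
        num_s += d.pi_s * d.n_sites_syn
        den_s += d.n_sites_syn
    if den_a == 0 or den_s == 0:
        return None
    mean_a = num_a / den_a
    mean_s = num_s / den_s
    return mean_a / mean_s if mean_s > 0 else None
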