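"""Synthetic inputs with the statistical structure the analysis assumes.

The generator emulates a selfing cereal genome: a Marey-style gene map with a
planted recombination-suppressed pericentromeric segment per chromosome; a
14-haplotype coding-sequence panel whose compartments carry different
pi_a/pi_s targets; a WGD-duplicated gene complement with class-dependent pair
survival (LR-LR default 0); tandem duplications placed with probability
proportional to the local recombination rate; and tissue-expression values
drawn identically for both compartments.  Every output is a pure function of
the :class:`SimConfig` seed (NumPy PCG64 streams, one fixed sub-stream offset
per stage, so adding a stage never perturbs earlier ones).

Mutations are placed on sites categorised by the same effect classifier the
pipeline uses; this circularity is intentional (the estimator, not the
classifier, is under test here) and the classifier itself is cross-checked
against an independently built genetic-code table in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_formats import GeneMapEntry, SimilarityHit, VariantSite
from .variant_diversity import GENETIC_CODE, STOP_CODONS, OrfAnnotation

# sub-stream offsets per stage (PCG64 seeded with (seed, offset))
_STREAM_MAP = 1
_STREAM_PANEL = 2
_STREAM_WGD = 3
_STREAM_TANDEM = 4
_STREAM_EXPR = 5

#: Codons whose third position is fully degenerate and whose first/second
#: position changes are always nonsynonymous and can never create a stop in
#: one step (first base never T).  Used for WGD CDS pairs so planted
#: synonymous/nonsynonymous divergence maps exactly onto codon positions.
FOURFOLD_SAFE = tuple(f + s + t
                      for f, s in ("GC", "GT", "AC", "CC", "GG")
                      for t in "ACGT")

SENSE_CODONS = tuple(c for c, aa in sorted(GENETIC_CODE.items()) if aa != "*")


@dataclass
class SimConfig:
    """Study conditions for the synthetic genome.

    Defaults mirror the emulated study design: 7 chromosomes' worth of
    structure scaled to a testable size, >=20-fold pericentromeric
    recombination suppression, 14 sampled haplotypes, compartment pi_a/pi_s
    targets 0.235 (LR) vs 0.170 (HR), WGD pair survival zero for LR-LR, and
    tandem duplication proportional to the local recombination rate.
    """

    seed: int = 0
    n_chromosomes: int = 2
    genes_per_chromosome: int = 1000
    pc_fraction: float = 0.30  # fraction of genes in the suppressed segment
    suppression_fold: float = 50.0  # PC rate = flank rate / fold
    flank_rate_cm: float = 0.2  # mean cM per gene outside the PC segment
    mean_gene_spacing_bp: int = 25_000
    n_haplotypes: int = 14
    target_pi_s: float = 0.01
    target_pia_pis_lr: float = 0.235
    target_pia_pis_hr: float = 0.170
    orf_codons_min: int = 200
    orf_codons_max: int = 400
    error_sites_per_gene: float = 0.5  # sequencing-error decoys (fail filters)
    wgd_pair_survival: dict[str, float] = field(default_factory=lambda: {
        "HR-HR": 0.30, "LR-HR": 0.15, "LR-LR": 0.0})
    wgd_offset_frac: float = 0.15  # B-copy index offset as fraction of genes
    wgd_ks_log_mean: float = float(np.log(1.3))
    wgd_ks_log_sd: float = 0.2
    wgd_ks_bounds: tuple[float, float] = (0.5, 2.0)
    wgd_ka_ks: float = 0.16
    wgd_cds_codons: int = 200
    n_decoy_old_pairs: int = 15  # saturated (Ks > 3) relic pairs
    n_decoy_transposed: int = 15  # good Ks but non-collinear positions
    n_decoy_recent: int = 5  # near-identical long alignments (filtered)
    n_decoy_weak: int = 30  # weak short hits (filtered)
    tandem_rate_per_cm: float = 1.0  # P(tandem) = rate * local cM/gene
    n_tissues: int = 15
    expr_log_mean: float = 2.0
    expr_log_sd: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.pc_fraction < 1:
            raise ValueError("pc_fraction must be in (0, 1)")
        for k, v in self.wgd_pair_survival.items():
            if not 0 <= v <= 1:
                raise ValueError(f"survival probability {k} outside [0, 1]")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass(frozen=True)
class PlantedRegion:
    chromosome: str
    start_index: int
    end_index: int  # inclusive
    start_bp: int
    end_bp: int


def _chrom_name(i: int) -> str:
    return f"{i + 1}H"


def _gene_id(chrom: str, idx: int) -> str:
    return f"{chrom}g{idx:05d}"


# ---------------------------------------------------------------------------
# stage 1: genome map


def simulate_genome_map(config: SimConfig) -> tuple[
        list[GeneMapEntry], list[PlantedRegion], dict[str, int]]:
    """Gene map with a planted suppressed segment per chromosome.

    Physical positions are cumulative sums of uniform spacings; genetic
    increments are exponential with mean ``flank_rate_cm`` outside the PC
    segment and ``flank_rate_cm / suppression_fold`` inside it.  Returns the
    map, the planted-region truth table and per-chromosome centromere
    positions (the midpoint gene of the planted segment).
    """
    rng = config.rng(_STREAM_MAP)
    n = config.genes_per_chromosome
    entries: list[GeneMapEntry] = []
    truth: list[PlantedRegion] = []
    centromeres: dict[str, int] = {}
    for c in range(config.n_chromosomes):
        chrom = _chrom_name(c)
        spacing = rng.integers(5_000, 2 * config.mean_gene_spacing_bp - 5_000,
                               size=n)
        phys = np.cumsum(spacing)
        pc_len = int(round(config.pc_fraction * n))
        s = (n - pc_len) // 2
        e = s + pc_len - 1
        rates = np.full(n, config.flank_rate_cm)
        rates[s:e + 1] = config.flank_rate_cm / config.suppression_fold
        increments = rng.exponential(rates)
        cm = np.concatenate([[0.0], np.cumsum(increments[:-1])])
        for i in range(n):
            entries.append(GeneMapEntry(_gene_id(chrom, i), chrom,
                                        float(cm[i]), int(phys[i])))
        truth.append(PlantedRegion(chrom, s, e, int(phys[s]), int(phys[e])))
        centromeres[chrom] = int(phys[(s + e) // 2])
    return entries, truth, centromeres


def truth_labels(entries: Sequence[GeneMapEntry],
                 truth: Sequence[PlantedRegion]) -> dict[str, str]:
    """Two-class (HR/LR) labels from the planted truth table."""
    spans = {t.chromosome: (t.start_index, t.end_index) for t in truth}
    labels: dict[str, str] = {}
    idx_in_chrom: dict[str, int] = {}
    for e in sorted(entries, key=lambda e: (e.chromosome, e.physical_pos)):
        i = idx_in_chrom.get(e.chromosome, 0)
        idx_in_chrom[e.chromosome] = i + 1
        s, t = spans[e.chromosome]
        labels[e.gene_id] = "LR" if s <= i <= t else "HR"
    return labels


# ---------------------------------------------------------------------------
# stage 2: coding-sequence panel


def _utr(rng: np.random.Generator, length: int) -> str:
    seq = "".join(rng.choice(list("ACGT"), size=length))
    return seq.replace("ATG", "ACG")  # no start codons upstream of the ORF


def _mean_site_pi(n_hap: int) -> float:
    """Expected per-site heterozygosity under the planted minor-count law
    (minor allele count uniform on 2..n/2)."""
    ms = np.arange(2, n_hap // 2 + 1)
    p = ms / n_hap
    h = (n_hap / (n_hap - 1)) * (1 - p ** 2 - (1 - p) ** 2)
    return float(h.mean())


def _substitution_menu() -> dict[str, dict[str, list[tuple[int, str]]]]:
    """Per codon: synonymous and nonsynonymous (position, alt-base) options."""
    menu: dict[str, dict[str, list[tuple[int, str]]]] = {}
    for codon in SENSE_CODONS:
        syn, nonsyn = [], []
        for pos in range(3):
            for b in "ACGT":
                if b == codon[pos]:
                    continue
                mut = codon[:pos] + b + codon[pos + 1:]
                if mut in STOP_CODONS:
                    continue  # keep planted SNPs sense<->sense
                (syn if GENETIC_CODE[mut] == GENETIC_CODE[codon]
                 else nonsyn).append((pos, b))
        menu[codon] = {"syn": syn, "nonsyn": nonsyn}
    return menu


_MENU = _substitution_menu()


@dataclass
class PanelTruth:
    """Per-gene planted quantities for the coding panel."""

    orf_start: int
    orf_end: int
    n_syn_sites: float
    n_nonsyn_sites: float
    n_syn_snps: int
    n_nonsyn_snps: int
    n_error_sites: int


def simulate_coding_panel(config: SimConfig,
                          entries: Sequence[GeneMapEntry],
                          labels: Mapping[str, str],
                          ) -> tuple[dict[str, str], list[VariantSite],
                                     dict[str, PanelTruth]]:
    """cDNA references plus per-sample variant tables for the haplotype panel.

    Polymorphism counts are tuned so the expected pooled estimates equal
    ``target_pi_s`` and the compartment pi_a/pi_s targets: a site's planted
    minor-allele count is uniform on 2..n/2 haplotypes, and the number of
    synonymous (nonsynonymous) SNPs per gene is Poisson with mean
    ``target * sites / E[site pi]``.  Sequencing-error decoy sites (singleton
    sample, 2 supporting reads) fail both the MAF and read-count filters by
    construction.
    """
    from .variant_diversity import orf_site_counts

    rng = config.rng(_STREAM_PANEL)
    n_hap = config.n_haplotypes
    h_bar = _mean_site_pi(n_hap)
    refs: dict[str, str] = {}
    sites: list[VariantSite] = []
    truth: dict[str, PanelTruth] = {}

    for entry in entries:
        gene = entry.gene_id
        ratio = (config.target_pia_pis_lr if labels[gene] == "LR"
                 else config.target_pia_pis_hr)
        n_codons = int(rng.integers(config.orf_codons_min,
                                    config.orf_codons_max + 1))
        codon_idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
        codons = [SENSE_CODONS[i] for i in codon_idx]
        utr5 = _utr(rng, int(rng.integers(20, 80)))
        utr3 = _utr(rng, int(rng.integers(20, 80)))
        body = "ATG" + "".join(codons) + "TAA"
        seq = utr5 + body + utr3
        refs[gene] = seq
        orf_start = len(utr5) + 1
        orf_end = len(utr5) + len(body)

        # UTR scrubbing guarantees the planted ATG is the first in the cDNA
        assert seq.find("ATG") == orf_start - 1
        orf = OrfAnnotation(gene, orf_start, orf_end,
                            protein_length=n_codons + 1, has_stop=True)
        syn_sites, nonsyn_sites = orf_site_counts(seq, orf)

        k_syn = rng.poisson(config.target_pi_s * syn_sites / h_bar)
        k_nonsyn = rng.poisson(ratio * config.target_pi_s * nonsyn_sites / h_bar)
        used_pos: set[int] = set()

        def plant(kind: str, count: int) -> int:
            planted = 0
            # codons offering the requested substitution type
            options = [k for k in range(n_codons + 1) if _MENU[
                ("ATG" if k == 0 else codons[k - 1])][kind]]
            if not options:
                return 0
            for _ in range(count):
                k = options[int(rng.integers(0, len(options)))]
                codon = "ATG" if k == 0 else codons[k - 1]
                pos_in, alt = _MENU[codon][kind][
                    int(rng.integers(0, len(_MENU[codon][kind])))]
                pos = orf_start + 3 * k + pos_in  # 1-based on the cDNA
                if pos in used_pos:
                    continue
                used_pos.add(pos)
                m = int(rng.integers(2, n_hap // 2 + 1))
                carriers = rng.choice(n_hap, size=m, replace=False)
                depth = rng.integers(5, 20, size=n_hap)
                ref_counts = [0 if i in carriers else int(depth[i])
                              for i in range(n_hap)]
                alt_counts = [int(depth[i]) if i in carriers else 0
                              for i in range(n_hap)]
                sites.append(VariantSite(gene, pos, seq[pos - 1], alt,
                                         ref_counts, alt_counts))
                planted += 1
            return planted

        n_syn = plant("syn", int(k_syn))
        n_nonsyn = plant("nonsyn", int(k_nonsyn))

        n_err = rng.poisson(config.error_sites_per_gene)
        placed_err = 0
        for _ in range(int(n_err)):
            pos = int(rng.integers(1, len(seq) + 1))
            if pos in used_pos:
                continue
            used_pos.add(pos)
            ref_base = seq[pos - 1]
            alt = "ACGT".replace(ref_base, "")[int(rng.integers(0, 3))]
            carrier = int(rng.integers(0, n_hap))
            depth = rng.integers(5, 20, size=n_hap)
            ref_counts = [int(depth[i]) for i in range(n_hap)]
            alt_counts = [0] * n_hap
            ref_counts[carrier] = 0
            alt_counts[carrier] = 2  # below the read-support threshold
            sites.append(VariantSite(gene, pos, ref_base, alt,
                                     ref_counts, alt_counts))
            placed_err += 1

        truth[gene] = PanelTruth(orf_start, orf_end, syn_sites, nonsyn_sites,
                                 n_syn, n_nonsyn, placed_err)
    return refs, sites, truth


# ---------------------------------------------------------------------------
# stage 3: WGD duplication


def _bit_score(identity_pct: float, aln_length: int) -> float:
    """Declared monotone synthetic bit-score formula (not a BLAST emulation)."""
    frac = identity_pct / 100.0
    return 2.0 * aln_length * frac * (1.0 - 0.9 * (1.0 - frac))


def _hit_row(query: str, subject: str, identity_pct: float,
             aln_length: int) -> SimilarityHit:
    score = _bit_score(identity_pct, aln_length)
    evalue = float(max(10.0 ** (-score / 100.0), 1e-180))
    return SimilarityHit(query, subject, round(identity_pct, 2), aln_length,
                         int(round(aln_length * (1 - identity_pct / 100))), 0,
                         1, aln_length, 1, aln_length, evalue,
                         round(score, 1))


def _diverge_pair(rng: np.random.Generator, n_codons: int,
                  ks: float, ka: float) -> tuple[str, str]:
    """A CDS pair from four-fold-degenerate codons with planted divergence.

    Third positions differ with probability ps (the uncorrected synonymous
    difference proportion for ``ks``); first/second positions with
    probability pn each, at most one nonsynonymous change per codon.
    """
    ps = 0.75 * (1 - np.exp(-4 * ks / 3))
    pn = 0.75 * (1 - np.exp(-4 * ka / 3))
    idx = rng.integers(0, len(FOURFOLD_SAFE), size=n_codons)
    a_codons, b_codons = [], []
    for i in idx:
        ca = FOURFOLD_SAFE[i]
        cb = list(ca)
        if rng.random() < ps:
            cb[2] = str(rng.choice([b for b in "ACGT" if b != ca[2]]))
        if rng.random() < pn:
            pos = int(rng.integers(0, 2))
            cb[pos] = str(rng.choice([b for b in "ACG" if b != ca[pos]]))
        elif rng.random() < pn:
            cb[1] = str(rng.choice([b for b in "ACG" if b != ca[1]]))
        a_codons.append(ca)
        b_codons.append("".join(cb))
    return "".join(a_codons), "".join(b_codons)


def _identity(a: str, b: str) -> float:
    same = sum(x == y for x, y in zip(a, b))
    return 100.0 * same / len(a)


@dataclass
class WgdTruth:
    true_pairs: set[tuple[str, str]]  # canonical gene-id tuples
    pair_class: dict[tuple[str, str], str]
    pair_ks: dict[tuple[str, str], float]


def simulate_wgd(config: SimConfig, entries: Sequence[GeneMapEntry],
                 labels: Mapping[str, str],
                 ) -> tuple[list[SimilarityHit], dict[tuple[str, str],
                                                      tuple[str, str]], WgdTruth]:
    """All-vs-all similarity rows, aligned CDS pairs and the truth pair list.

    Chromosomes are taken in consecutive pairs (A, B); ancestral gene i of A
    is paired with gene i + offset of B, survival drawn per compartment
    class.  Decoys exercise every downstream filter: saturated relic pairs
    (Ks > 3), transposed paralogs at non-collinear positions, near-identical
    long alignments, weak short hits, and self-hits.
    """
    rng = config.rng(_STREAM_WGD)
    n = config.genes_per_chromosome
    offset = int(round(config.wgd_offset_frac * n))
    by_chrom: dict[str, list[GeneMapEntry]] = {}
    for e in sorted(entries, key=lambda e: (e.chromosome, e.physical_pos)):
        by_chrom.setdefault(e.chromosome, []).append(e)
    chroms = sorted(by_chrom)

    hits: list[SimilarityHit] = []
    cds: dict[tuple[str, str], tuple[str, str]] = {}
    truth = WgdTruth(set(), {}, {})
    lo, hi = config.wgd_ks_bounds
    genes_in_pairs: set[str] = set()

    def add_pair(ga: str, gb: str, ks: float, ka: float,
                 record_truth: bool, cls: str = "") -> None:
        key = tuple(sorted((ga, gb)))
        seq_a, seq_b = _diverge_pair(rng, config.wgd_cds_codons, ks, ka)
        if key[0] == gb:
            seq_a, seq_b = seq_b, seq_a
        cds[key] = (seq_a, seq_b)
        ident = _identity(seq_a, seq_b)
        length = 3 * config.wgd_cds_codons
        hits.append(_hit_row(ga, gb, ident, length))
        hits.append(_hit_row(gb, ga, ident, length))
        if record_truth:
            truth.true_pairs.add(key)
            truth.pair_class[key] = cls
            truth.pair_ks[key] = ks

    for ci in range(0, len(chroms) - 1, 2):
        ca, cb = chroms[ci], chroms[ci + 1]
        for i in range(n - offset):
            ga = by_chrom[ca][i].gene_id
            gb = by_chrom[cb][i + offset].gene_id
            la, lb = labels[ga], labels[gb]
            cls = "-".join(sorted((la, lb), reverse=True))
            if rng.random() >= config.wgd_pair_survival.get(cls, 0.0):
                continue
            ks = float(np.clip(rng.lognormal(config.wgd_ks_log_mean,
                                             config.wgd_ks_log_sd), lo, hi))
            add_pair(ga, gb, ks, ks * config.wgd_ka_ks, True, cls)
            genes_in_pairs.update((ga, gb))

    all_genes = [e.gene_id for e in entries]
    free = [g for g in all_genes if g not in genes_in_pairs]
    rng.shuffle(free)
    free_iter = iter(free)

    def take_free() -> str | None:
        return next(free_iter, None)

    index_of = {e.gene_id: i for es in by_chrom.values()
                for i, e in enumerate(es)}
    chrom_of = {e.gene_id: e.chromosome for e in entries}
    paired_chrom = {chroms[ci]: chroms[ci + 1]
                    for ci in range(0, len(chroms) - 1, 2)}

    def on_planted_diagonal(ga: str, gb: str) -> bool:
        # a truly transposed paralog must sit off the WGD synteny diagonal
        a, b = sorted((ga, gb), key=lambda g: chrom_of[g])
        if paired_chrom.get(chrom_of[a]) != chrom_of[b]:
            return False
        return abs(index_of[b] - index_of[a] - offset) <= 50

    for _ in range(config.n_decoy_old_pairs):  # saturated relics
        ga, gb = take_free(), take_free()
        if ga is None or gb is None:
            break
        if on_planted_diagonal(ga, gb):
            continue
        add_pair(ga, gb, float(rng.uniform(3.5, 5.0)),
                 0.3 * 3.5, record_truth=False)
    for _ in range(config.n_decoy_transposed):  # good Ks, non-collinear
        ga, gb = take_free(), take_free()
        if ga is None or gb is None:
            break
        if on_planted_diagonal(ga, gb):
            continue
        add_pair(ga, gb, float(rng.uniform(lo, hi)),
                 config.wgd_ka_ks * 1.0, record_truth=False)
    for _ in range(config.n_decoy_recent):  # near-identical long alignments
        ga, gb = take_free(), take_free()
        if ga is None or gb is None:
            break
        which = rng.random()
        if which < 0.5:
            hits.append(_hit_row(ga, gb, 100.0, 400))  # identity rule
        else:
            hits.append(_hit_row(ga, gb, 96.0, 4500))  # bit-score ceiling
    for _ in range(config.n_decoy_weak):  # weak short hits
        ga, gb = take_free(), take_free()
        if ga is None or gb is None:
            break
        hits.append(_hit_row(ga, gb, 40.0, 400))

    for g in all_genes[:: max(1, len(all_genes) // 50)]:  # some self-hits
        hits.append(_hit_row(g, g, 100.0, 3 * config.wgd_cds_codons))
    return hits, cds, truth


# ---------------------------------------------------------------------------
# stage 4: tandem duplication and expression


def simulate_tandem(config: SimConfig, entries: Sequence[GeneMapEntry],
                    labels: Mapping[str, str],
                    ) -> tuple[list[SimilarityHit], set[tuple[str, str]]]:
    """Similarity rows for tandem copies (adjacent gene pairs).

    Gene i duplicates with probability ``tandem_rate_per_cm`` times its
    planted per-gene recombination rate, so LR genes duplicate
    ``suppression_fold`` times less often; the partner is the next gene on
    the chromosome.  A sprinkling of remote same-chromosome decoys exercises
    the translocation rule.
    """
    rng = config.rng(_STREAM_TANDEM)
    by_chrom: dict[str, list[GeneMapEntry]] = {}
    for e in sorted(entries, key=lambda e: (e.chromosome, e.physical_pos)):
        by_chrom.setdefault(e.chromosome, []).append(e)

    hits: list[SimilarityHit] = []
    truth: set[tuple[str, str]] = set()
    used: set[str] = set()
    for chrom, chrom_entries in sorted(by_chrom.items()):
        for i in range(len(chrom_entries) - 1):
            ga, gb = chrom_entries[i].gene_id, chrom_entries[i + 1].gene_id
            if ga in used or gb in used:
                continue
            rate = config.flank_rate_cm / (
                config.suppression_fold if labels[ga] == "LR" else 1.0)
            if rng.random() < min(1.0, config.tandem_rate_per_cm * rate):
                ident = float(rng.uniform(92.0, 99.0))
                hits.append(_hit_row(ga, gb, ident, 600))
                hits.append(_hit_row(gb, ga, ident, 600))
                truth.add((ga, gb))
                used.update((ga, gb))
        # remote decoys: intrachromosomal translocations
        n_decoy = max(1, len(chrom_entries) // 200)
        for _ in range(n_decoy):
            i = int(rng.integers(0, len(chrom_entries) // 3))
            j = int(rng.integers(2 * len(chrom_entries) // 3,
                                 len(chrom_entries)))
            ga, gb = chrom_entries[i].gene_id, chrom_entries[j].gene_id
            if ga in used or gb in used:
                continue
            hits.append(_hit_row(ga, gb, 90.0, 500))
            hits.append(_hit_row(gb, ga, 90.0, 500))
            used.update((ga, gb))
    return hits, truth


def simulate_expression(config: SimConfig,
                        entries: Sequence[GeneMapEntry]) -> "pd.DataFrame":
    """Lognormal expression values i.i.d. across genes, tissues and compartments."""
    import pandas as pd

    rng = config.rng(_STREAM_EXPR)
    gene_ids = [e.gene_id for e in entries]
    values = rng.lognormal(config.expr_log_mean, config.expr_log_sd,
                           size=(len(gene_ids), config.n_tissues))
    cols = [f"tissue{i + 1:02d}" for i in range(config.n_tissues)]
    return pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"),
                        columns=cols)


# ---------------------------------------------------------------------------
# fixture writing (CLI `simulate`)


def write_fixtures(config: SimConfig, out_dir) -> dict[str, str]:
    """Generate every input the pipeline reads and write it under ``out_dir``."""
    from pathlib import Path

    from .io_formats import (write_centromeres, write_expression_matrix,
                             write_fasta, write_gene_map,
                             write_similarity_table, write_variant_tsv)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)

    entries, regions, centromeres = simulate_genome_map(config)
    labels = truth_labels(entries, regions)
    refs, sites, _panel_truth = simulate_coding_panel(config, entries, labels)
    wgd_hits, _cds, wgd_truth = simulate_wgd(config, entries, labels)
    tandem_hits, tandem_truth = simulate_tandem(config, entries, labels)
    expr = simulate_expression(config, entries)

    paths = {
        "map": str(out / "map.tsv"),
        "centromeres": str(out / "cen.tsv"),
        "cdnas": str(out / "cdnas.fasta"),
        "variants": str(out / "calls.tsv"),
        "allvsall": str(out / "allvsall.tsv"),
        "expression": str(out / "expr.tsv"),
    }
    write_gene_map(entries, paths["map"])
    write_centromeres(centromeres, paths["centromeres"])
    write_fasta(refs, paths["cdnas"])
    sample_ids = [f"line{i + 1:02d}" for i in range(config.n_haplotypes)]
    write_variant_tsv(sites, sample_ids, paths["variants"])
    write_similarity_table(wgd_hits + tandem_hits, paths["allvsall"])
    write_expression_matrix(expr, paths["expression"])

    with (out / "truth" / "regions.tsv").open("w") as fh:
        fh.write("chromosome\tstart_index\tend_index\tstart_bp\tend_bp\n")
        for r in regions:
            fh.write(f"{r.chromosome}\t{r.start_index}\t{r.end_index}"
                     f"\t{r.start_bp}\t{r.end_bp}\n")
    with (out / "truth" / "wgd_pairs.tsv").open("w") as fh:
        fh.write("gene_a\tgene_b\tclass\tks\n")
        for key in sorted(wgd_truth.true_pairs):
            fh.write(f"{key[0]}\t{key[1]}\t{wgd_truth.pair_class[key]}"
                     f"\t{wgd_truth.pair_ks[key]:.4f}\n")
    with (out / "truth" / "tandem_pairs.tsv").open("w") as fh:
        fh.write("gene_a\tgene_b\n")
        for ga, gb in sorted(tandem_truth):
            fh.write(f"{ga}\t{gb}\n")
    return paths
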