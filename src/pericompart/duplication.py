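"""Ohnolog (WGD-derived paralog) and local duplicate detection.

From an all-vs-all nucleotide similarity table and a gene map, the ohnolog
pipeline reduces hits to the single best non-self pair per query, filters
pairs too similar or too weak to be WGD-derived, optionally reorders genes by
a reference genome's order within synteny blocks, chains pairs into collinear
regions by dynamic programming, estimates Ka/Ks per pair with the
Nei-Gojobori (1986) counting method plus Jukes-Cantor correction, and trims
the pair set (Ks ceiling, one pair per gene, minimum region strength, region
overlap resolution).  A parallel, simpler path calls local (tandem)
duplicates from best same-chromosome hits within a physical-distance rule,
with remote hits recorded as intrachromosomal translocations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from itertools import permutations
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import GeneMapEntry, SimilarityHit
from .stats import TestResult, chi2_2x2_yates
from .variant_diversity import GENETIC_CODE, STOP_CODONS, codon_site_fractions


@dataclass(frozen=True)
class ParalogPair:
    """An unordered gene pair (canonical: gene_a < gene_b) with hit statistics."""

    gene_a: str
    gene_b: str
    bit_score: float
    pct_identity: float
    aln_length: int
    evalue: float = 0.0

    @staticmethod
    def from_hit(hit: SimilarityHit) -> "ParalogPair":
        a, b = sorted((hit.query_id, hit.subject_id))
        return ParalogPair(a, b, hit.bit_score, hit.pct_identity,
                           hit.aln_length, hit.evalue)


@dataclass(frozen=True)
class PositionedPair:
    """A paralog pair with map-order indices on its two chromosomes."""

    pair: ParalogPair
    chrom_a: str
    idx_a: int
    chrom_b: str
    idx_b: int


@dataclass
class OhnologRegion:
    """A chained collinear block of paralog pairs between two chromosomes."""

    region_id: str
    chrom_a: str
    chrom_b: str
    members: list[PositionedPair]
    orientation: str  # "same" | "inverted"

    @property
    def strength(self) -> int:
        return len(self.members)

    def span_a(self) -> tuple[int, int]:
        idx = [m.idx_a for m in self.members]
        return min(idx), max(idx)

    def span_b(self) -> tuple[int, int]:
        idx = [m.idx_b for m in self.members]
        return min(idx), max(idx)


@dataclass
class OhnologPair:
    """A retained WGD gene pair with divergence estimates and compartment class."""

    pair: ParalogPair
    ka: float | None
    ks: float | None
    ka_ks: float | None
    saturated: bool = False
    pair_class: str = ""  # HR-HR | LR-HR | LR-LR
    region_id: str = ""


@dataclass(frozen=True)
class MolecularClock:
    ks_mean: float
    divergence_time_years: float
    rate: float  # substitutions / site / year


# ---------------------------------------------------------------------------
# best-hit reduction and pair filtering


def _hit_sort_key(h: SimilarityHit):
    # best first: max bit score, then min e-value, then lexicographic subject
    return (-h.bit_score, h.evalue, h.subject_id)


def best_nonself_hits(hits: Iterable[SimilarityHit], rank: int = 1,
                      same_chromosome: Mapping[str, str] | None = None,
                      ) -> list[ParalogPair]:
    """Reduce an all-vs-all table to one pair per query gene.

    Self-hits are discarded, multiple HSPs per subject collapse to the
    best-scoring one, then subjects are ranked by bit score (ties by e-value,
    then subject id) and the ``rank``-th subject is taken.  With
    ``same_chromosome`` (a gene -> chromosome mapping) only subjects on the
    query's chromosome compete, as used for local-duplicate calling.
    """
    by_query: dict[str, dict[str, SimilarityHit]] = {}
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        if same_chromosome is not None:
            qc = same_chromosome.get(h.query_id)
            sc = same_chromosome.get(h.subject_id)
            if qc is None or sc is None or qc != sc:
                continue
        best = by_query.setdefault(h.query_id, {})
        prev = best.get(h.subject_id)
        if prev is None or _hit_sort_key(h) < _hit_sort_key(prev):
            best[h.subject_id] = h

    pairs: list[ParalogPair] = []
    for query in sorted(by_query):
        ranked = sorted(by_query[query].values(), key=_hit_sort_key)
        if len(ranked) >= rank:
            pairs.append(ParalogPair.from_hit(ranked[rank - 1]))
    return pairs


def dedupe_pairs(pairs: Iterable[ParalogPair]) -> list[ParalogPair]:
    """Collapse duplicates of the same unordered pair (keep highest bit score)."""
    best: dict[tuple[str, str], ParalogPair] = {}
    for p in pairs:
        key = (p.gene_a, p.gene_b)
        if key not in best or p.bit_score > best[key].bit_score:
            best[key] = p
    return [best[k] for k in sorted(best)]


def filter_paralog_pairs(pairs: Iterable[ParalogPair],
                         bit_max: float = 8000.0,
                         identity_max: float = 100.0,
                         identity_max_len: int = 200,
                         bit_min: float = 300.0,
                         len_min: int = 500) -> list[ParalogPair]:
    """Drop pairs too similar or too weak to be WGD-derived.

    Removes pairs with bit score > ``bit_max``; pairs at 100% identity over
    more than ``identity_max_len`` bp; and pairs with bit score < ``bit_min``
    AND alignment length < ``len_min``.
    """
    kept = []
    for p in pairs:
        if p.bit_score > bit_max:
            continue
        if p.pct_identity >= identity_max and p.aln_length > identity_max_len:
            continue
        if p.bit_score < bit_min and p.aln_length < len_min:
            continue
        kept.append(p)
    return kept


def position_pairs(pairs: Iterable[ParalogPair],
                   entries: Sequence[GeneMapEntry],
                   ) -> tuple[list[PositionedPair], int]:
    """Attach per-chromosome map-order indices to pairs.

    Genes absent from the map drop their pairs (count returned).  The pair's
    canonical gene order (gene_a < gene_b) fixes which chromosome is A.
    """
    by_chrom: dict[str, list[GeneMapEntry]] = {}
    for e in sorted(entries, key=lambda e: (e.chromosome, e.physical_pos)):
        by_chrom.setdefault(e.chromosome, []).append(e)
    index: dict[str, tuple[str, int]] = {}
    for chrom, chrom_entries in by_chrom.items():
        for i, e in enumerate(chrom_entries):
            index[e.gene_id] = (chrom, i)

    out: list[PositionedPair] = []
    dropped = 0
    for p in pairs:
        if p.gene_a not in index or p.gene_b not in index:
            dropped += 1
            continue
        ca, ia = index[p.gene_a]
        cb, ib = index[p.gene_b]
        out.append(PositionedPair(p, ca, ia, cb, ib))
    return out, dropped


# ---------------------------------------------------------------------------
# reference reordering and map-outlier removal


def reorder_by_reference(genes: Sequence[str],
                         anchors: Mapping[str, int],
                         blocks: Sequence[Sequence[str]],
                         max_anchor_gap: int = 400,
                         ) -> tuple[list[str], int]:
    """Replace map order by reference (anchor) order within synteny blocks.

    ``genes`` is the chromosome's gene order; ``anchors`` maps each gene to
    its ortholog's ordinal position in the reference genome; ``blocks``
    partitions anchored genes into collinear blocks.  Genes without an anchor
    are dropped, as are genes in regions of low orthologous gene density
    (nearest-anchor separation > ``max_anchor_gap`` reference genes).  Within
    each block the output order is reference order; block order along the
    chromosome is preserved.  Returns (reordered genes, number dropped).
    """
    gene_pos = {g: i for i, g in enumerate(genes)}
    dropped = 0
    out: list[str] = []
    # blocks sorted by their first gene's chromosome position
    ordered_blocks = sorted(
        (b for b in blocks if any(g in gene_pos for g in b)),
        key=lambda b: min(gene_pos[g] for g in b if g in gene_pos))
    in_block = {g for b in blocks for g in b}
    dropped += sum(1 for g in genes if g not in in_block)
    for block in ordered_blocks:
        members = [g for g in block if g in gene_pos]
        anchored = [g for g in members if g in anchors]
        dropped += len(members) - len(anchored)
        anchored.sort(key=lambda g: gene_pos[g])
        # density filter: a gene is remote when its anchor sits far from the
        # local anchor neighbourhood (median of a window of 5 in map order)
        keep: list[str] = []
        vals = np.array([anchors[g] for g in anchored], dtype=float)
        for i, g in enumerate(anchored):
            lo, hi = max(0, i - 2), min(len(vals), i + 3)
            med = np.median(vals[lo:hi])
            if len(anchored) > 1 and abs(anchors[g] - med) > max_anchor_gap:
                dropped += 1
            else:
                keep.append(g)
        keep.sort(key=lambda g: anchors[g])
        out.extend(keep)
    return out, dropped


def remove_map_outliers(entries: Sequence[GeneMapEntry], window: int = 51,
                        z_max: float = 5.0) -> list[GeneMapEntry]:
    """Drop genes whose genetic position is far off the local map trend.

    A gene is removed iff |cM - running median| > z_max * running MAD, with
    median and MAD over a centred window; when the local MAD is zero nothing
    is removed there (degenerate-input guard).
    """
    if not entries:
        return []
    cm = np.array([e.genetic_pos for e in entries], dtype=float)
    n = cm.size
    half = window // 2
    keep = []
    for i in range(n):
        seg = cm[max(0, i - half): min(n, i + half + 1)]
        med = np.median(seg)
        mad = np.median(np.abs(seg - med))
        if mad == 0 or abs(cm[i] - med) <= z_max * mad:
            keep.append(entries[i])
    return keep


# ---------------------------------------------------------------------------
# collinear-region detection (dynamic-programming chaining)


def _best_chain(pairs: list[PositionedPair], max_gap: int,
                direction: int) -> list[int]:
    """Indices of the best chain strictly increasing in A and in direction*B."""
    n = len(pairs)
    order = sorted(range(n), key=lambda i: (pairs[i].idx_a,
                                            direction * pairs[i].idx_b))
    score = [1] * n
    prev = [-1] * n
    for oi in range(n):
        i = order[oi]
        for oj in range(oi):
            j = order[oj]
            da = pairs[i].idx_a - pairs[j].idx_a
            db = direction * (pairs[i].idx_b - pairs[j].idx_b)
            if 0 < da <= max_gap and 0 < db <= max_gap * 1:
                if score[j] + 1 > score[i]:
                    score[i] = score[j] + 1
                    prev[i] = j
        # gaps larger than max_gap break the chain
    best = max(range(n), key=lambda i: score[i])
    chain = []
    while best != -1:
        chain.append(best)
        best = prev[best]
    return chain[::-1]


def detect_collinear_regions(pairs: Sequence[PositionedPair],
                             min_pairs: int = 9,
                             max_gap: int = 25) -> list[OhnologRegion]:
    """Chain positioned pairs into collinear regions.

    A chain is strictly increasing in chromosome-A gene index and strictly
    monotone (increasing or decreasing) in chromosome-B index, with index
    gaps <= ``max_gap`` on both chromosomes between consecutive members.
    Maximal-score chains (score = pair count) with >= ``min_pairs`` members
    are reported greedily (best first, members removed); each pair belongs to
    at most one region.
    """
    by_chrom: dict[tuple[str, str], list[PositionedPair]] = {}
    for p in pairs:
        by_chrom.setdefault((p.chrom_a, p.chrom_b), []).append(p)

    regions: list[OhnologRegion] = []
    for (ca, cb) in sorted(by_chrom):
        pool = list(by_chrom[(ca, cb)])
        while pool:
            up = _best_chain(pool, max_gap, +1)
            down = _best_chain(pool, max_gap, -1)
            chain, orientation = ((up, "same") if len(up) >= len(down)
                                  else (down, "inverted"))
            if len(chain) < min_pairs:
                break
            members = [pool[i] for i in chain]
            regions.append(OhnologRegion(
                region_id=f"{ca}|{cb}:R{len(regions) + 1}",
                chrom_a=ca, chrom_b=cb, members=members,
                orientation=orientation))
            chosen = set(chain)
            pool = [p for i, p in enumerate(pool) if i not in chosen]
    return regions


def brute_force_best_chain(pairs: Sequence[PositionedPair],
                           max_gap: int = 25) -> int:
    """Exhaustive maximum monotone-chain size (oracle; use only for <= ~15 pairs)."""
    n = len(pairs)
    best = 0
    for mask in range(1, 1 << n):
        idx = [i for i in range(n) if mask >> i & 1]
        if len(idx) <= best:
            continue
        sel = sorted((pairs[i].idx_a, pairs[i].idx_b) for i in idx)
        a_ok = all(sel[k + 1][0] > sel[k][0]
                   and sel[k + 1][0] - sel[k][0] <= max_gap
                   for k in range(len(sel) - 1))
        if not a_ok:
            continue
        for d in (+1, -1):
            if all(d * (sel[k + 1][1] - sel[k][1]) > 0
                   and abs(sel[k + 1][1] - sel[k][1]) <= max_gap
                   for k in range(len(sel) - 1)):
                best = len(idx)
                break
    return best


# ---------------------------------------------------------------------------
# NG86 Ka/Ks


@lru_cache(maxsize=None)
def _codon_path_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) substitutions between two codons, averaged
    over all shortest substitution pathways; pathways passing through a stop
    codon are excluded unless every pathway does."""
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for perm in permutations(diff):
        cur = codon_a
        syn = nonsyn = 0.0
        through_stop = False
        for pos in perm:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS and nxt != codon_b:
                through_stop = True
            if GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        paths.append((through_stop, syn, nonsyn))
    valid = [p for p in paths if not p[0]] or paths
    syn = sum(p[1] for p in valid) / len(valid)
    nonsyn = sum(p[2] for p in valid) / len(valid)
    return syn, nonsyn


def _jukes_cantor(p: float) -> float | None:
    if p >= 0.75:
        return None
    if p == 0:
        return 0.0
    return float(-0.75 * np.log(1 - 4 * p / 3))


def ng86_ka_ks(cds_a: str, cds_b: str) -> tuple[float | None, float | None,
                                                float | None]:
    """Nei-Gojobori (1986) Ka and Ks with Jukes-Cantor correction.

    Sequences must be aligned, equal length and a multiple of 3; codons
    containing a gap, an ambiguous base, or a stop in either sequence are
    skipped.  Returns (Ka, Ks, Ka/Ks); Ka or Ks is None when the
    proportion of differences is saturated (p >= 0.75), and Ka/Ks is None
    when Ks is 0 or undefined.
    """
    a, b = cds_a.upper(), cds_b.upper()
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    if len(a) % 3:
        raise ValueError("length not divisible by 3")
    s_sites = n_sites = sd = nd = 0.0
    ok = set("ACGT")
    for i in range(0, len(a), 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        if not (set(ca) <= ok and set(cb) <= ok):
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        sa, na = codon_site_fractions(ca)
        sb, nb = codon_site_fractions(cb)
        s_sites += (sa + sb) / 2
        n_sites += (na + nb) / 2
        ds, dn = _codon_path_counts(ca, cb)
        sd += ds
        nd += dn
    if s_sites == 0 or n_sites == 0:
        raise ValueError("no comparable codons")
    ps, pn = sd / s_sites, nd / n_sites
    ks = _jukes_cantor(ps)
    ka = _jukes_cantor(pn)
    ka_ks = None
    if ka is not None and ks is not None and ks > 0:
        ka_ks = ka / ks
    return ka, ks, ka_ks


def clock_rate(ks_mean: float, t_years: float) -> MolecularClock:
    """Substitution rate r = Ks / (2 T) under a molecular clock.

    Ks accumulates along both diverging lineages, hence the factor 2.
    """
    if ks_mean < 0 or t_years <= 0:
        raise ValueError("Ks must be >= 0 and divergence time positive")
    return MolecularClock(ks_mean, t_years, ks_mean / (2 * t_years))


# ---------------------------------------------------------------------------
# ohnolog trimming


def _spans_overlap(x: tuple[int, int], y: tuple[int, int]) -> bool:
    return x[0] <= y[1] and y[0] <= x[1]


def trim_ohnolog_pairs(pairs: Sequence[OhnologPair],
                       regions: Sequence[OhnologRegion],
                       ks_max: float = 3.0,
                       min_pairs: int = 9) -> tuple[list[OhnologPair],
                                                    dict[str, int]]:
    """Final ohnolog-pair trimming; returns (kept pairs, removal counts).

    In order: pairs with Ks > ``ks_max`` (or saturated/undefined Ks) are
    removed; every pair containing a gene that appears in more than one pair
    is removed; pairs outside any region or in regions with fewer than
    ``min_pairs`` members are removed; where two regions overlap in
    gene-index span on either chromosome, the weaker region's pairs are
    removed (ties broken by lower mean Ks winning, then region id).
    """
    counts = {"ks": 0, "multi_pair_gene": 0, "weak_region": 0, "overlap": 0}
    region_of: dict[tuple[str, str], str] = {}
    for r in regions:
        for m in r.members:
            region_of[(m.pair.gene_a, m.pair.gene_b)] = r.region_id

    stage1 = []
    for p in pairs:
        if p.ks is None or p.ks > ks_max:
            counts["ks"] += 1
        else:
            rid = region_of.get((p.pair.gene_a, p.pair.gene_b), "")
            stage1.append(replace(p, region_id=rid))

    gene_uses: dict[str, int] = {}
    for p in stage1:
        gene_uses[p.pair.gene_a] = gene_uses.get(p.pair.gene_a, 0) + 1
        gene_uses[p.pair.gene_b] = gene_uses.get(p.pair.gene_b, 0) + 1
    stage2 = []
    for p in stage1:
        if gene_uses[p.pair.gene_a] > 1 or gene_uses[p.pair.gene_b] > 1:
            counts["multi_pair_gene"] += 1
        else:
            stage2.append(p)

    strong = {r.region_id: r for r in regions if r.strength >= min_pairs}
    stage3 = []
    for p in stage2:
        if p.region_id in strong:
            stage3.append(p)
        else:
            counts["weak_region"] += 1

    # overlap resolution among the strong regions
    def rank(r: OhnologRegion):
        kss = [p.ks for p in stage3 if p.region_id == r.region_id and p.ks is not None]
        mean_ks = float(np.mean(kss)) if kss else np.inf
        return (-r.strength, mean_ks, r.region_id)

    losers: set[str] = set()
    strong_list = sorted(strong.values(), key=rank)
    for i, ri in enumerate(strong_list):
        for rj in strong_list[i + 1:]:
            if ri.region_id in losers or rj.region_id in losers:
                continue
            same_a = ri.chrom_a == rj.chrom_a and _spans_overlap(ri.span_a(), rj.span_a())
            same_b = ri.chrom_b == rj.chrom_b and _spans_overlap(ri.span_b(), rj.span_b())
            cross_ab = ri.chrom_a == rj.chrom_b and _spans_overlap(ri.span_a(), rj.span_b())
            cross_ba = ri.chrom_b == rj.chrom_a and _spans_overlap(ri.span_b(), rj.span_a())
            if same_a or same_b or cross_ab or cross_ba:
                losers.add(rj.region_id)  # rj ranks weaker by sort order

    final = []
    for p in stage3:
        if p.region_id in losers:
            counts["overlap"] += 1
        else:
            final.append(p)

    seen: set[str] = set()
    for p in final:
        for g in (p.pair.gene_a, p.pair.gene_b):
            if g in seen:
                raise AssertionError(f"gene {g} occurs in two final pairs")
            seen.add(g)
    return final, counts


def classify_pairs(pairs: Iterable[OhnologPair],
                   labels: Mapping[str, str]) -> list[OhnologPair]:
    """Attach the HR-HR / LR-HR / LR-LR class from two-class gene labels."""
    out = []
    for p in pairs:
        la = labels.get(p.pair.gene_a, "HR")
        lb = labels.get(p.pair.gene_b, "HR")
        cls = "-".join(sorted((la, lb), reverse=True))  # LR sorts after HR
        cls = {"HR-HR": "HR-HR", "LR-HR": "LR-HR", "LR-LR": "LR-LR"}[cls]
        out.append(replace(p, pair_class=cls))
    return out


# ---------------------------------------------------------------------------
# local duplicates


def call_local_duplicates(hits: Iterable[SimilarityHit],
                          entries: Sequence[GeneMapEntry],
                          frac: float = 0.02,
                          chromosome_lengths: Mapping[str, int] | None = None,
                          ) -> tuple[list[ParalogPair], list[ParalogPair], int]:
    """Split best same-chromosome hits into local duplicates and translocations.

    Per query the best same-chromosome non-self hit is taken; the pair is a
    local duplicate when the physical distance is <= ``frac`` of the
    chromosome length (max mapped position unless given), otherwise an
    intrachromosomal translocation.  Hits to genes absent from the map are
    skipped (count returned).
    """
    pos = {e.gene_id: e.physical_pos for e in entries}
    chrom = {e.gene_id: e.chromosome for e in entries}
    if chromosome_lengths is None:
        chromosome_lengths = {}
        for e in entries:
            chromosome_lengths[e.chromosome] = max(
                chromosome_lengths.get(e.chromosome, 0), e.physical_pos)

    hits_list = list(hits)
    n_skipped = sum(1 for h in hits_list
                    if h.query_id != h.subject_id
                    and (h.query_id not in chrom or h.subject_id not in chrom))
    best = best_nonself_hits(hits_list, rank=1, same_chromosome=chrom)

    local: list[ParalogPair] = []
    trans: list[ParalogPair] = []
    for p in dedupe_pairs(best):
        dist = abs(pos[p.gene_a] - pos[p.gene_b])
        limit = frac * chromosome_lengths[chrom[p.gene_a]]
        (local if dist <= limit else trans).append(p)
    return local, trans, n_skipped


def locally_duplicated_genes(local_pairs: Iterable[ParalogPair]) -> set[str]:
    out: set[str] = set()
    for p in local_pairs:
        out.add(p.gene_a)
        out.add(p.gene_b)
    return out


# ---------------------------------------------------------------------------
# compartment statistics (observed vs expected tables)


@dataclass
class OhnologGeneTable:
    obs_hr: int
    obs_lr: int
    exp_hr: float
    exp_lr: float
    lr_share_pct: float  # % of ohnolog genes in LR
    test: TestResult


@dataclass
class OhnologPairTable:
    obs: dict[str, int]  # HR-HR, LR-HR, LR-LR
    exp: dict[str, float]
    test: TestResult


@dataclass
class LocalDupRow:
    scope: str
    dup_hr: int
    dup_lr: int
    all_hr: int
    all_lr: int
    pct_lr_dup: float
    pct_lr_all: float
    ratio: float
    p_yates: float

    @property
    def depletion_pct(self) -> float:
        """Percentage depletion of local duplication in LR DNA: 100*(1 - ratio)."""
        return 100.0 * (1.0 - self.ratio)


def ohnolog_gene_table(n_ohnolog_hr: int, n_ohnolog_lr: int,
                       n_genes_hr: int, n_genes_lr: int) -> OhnologGeneTable:
    """Observed vs expected ohnolog genes by compartment.

    Expected = total ohnologs x compartment share of all mapped genes;
    tested with a df=1 goodness-of-fit chi-squared.
    """
    from .stats import chi2_gof

    total_ohno = n_ohnolog_hr + n_ohnolog_lr
    total_genes = n_genes_hr + n_genes_lr
    q = n_genes_lr / total_genes
    exp_lr = total_ohno * q
    exp_hr = total_ohno * (1 - q)
    test = chi2_gof([n_ohnolog_hr, n_ohnolog_lr], [exp_hr, exp_lr])
    return OhnologGeneTable(n_ohnolog_hr, n_ohnolog_lr, exp_hr, exp_lr,
                            100.0 * n_ohnolog_lr / total_ohno, test)


def ohnolog_pair_table(obs: Mapping[str, int], lr_gene_fraction: float,
                       ) -> OhnologPairTable:
    """Observed vs expected pair classes under random compartment assignment.

    With q the LR gene fraction, expected shares are (1-q)^2, 2q(1-q), q^2 of
    the pair total for HR-HR, LR-HR and LR-LR.
    """
    from .stats import chi2_gof

    n = sum(obs.get(k, 0) for k in ("HR-HR", "LR-HR", "LR-LR"))
    q = lr_gene_fraction
    exp = {"HR-HR": n * (1 - q) ** 2, "LR-HR": n * 2 * q * (1 - q),
           "LR-LR": n * q ** 2}
    test = chi2_gof([obs.get(k, 0) for k in ("HR-HR", "LR-HR", "LR-LR")],
                    [exp[k] for k in ("HR-HR", "LR-HR", "LR-LR")])
    return OhnologPairTable({k: obs.get(k, 0) for k in exp}, exp, test)


def local_dup_table(dup_hr: int, dup_lr: int, all_hr: int, all_lr: int,
                    scope: str = "total") -> LocalDupRow:
    """One row of the local-duplication depletion table.

    The 2x2 Yates chi-squared contrasts {locally duplicated genes} against
    {all mapped genes} (overlapping categories, as in the reproduction
    tables) split HR vs LR; the ratio column is
    %LR(duplicated) / %LR(all genes).
    """
    pct_dup = 100.0 * dup_lr / (dup_hr + dup_lr)
    pct_all = 100.0 * all_lr / (all_hr + all_lr)
    res = chi2_2x2_yates([[dup_hr, dup_lr], [all_hr, all_lr]])
    return LocalDupRow(scope, dup_hr, dup_lr, all_hr, all_lr,
                       pct_dup, pct_all, pct_dup / pct_all, res.p)


def local_dup_table_disjoint(dup_hr: int, dup_lr: int, all_hr: int,
                             all_lr: int, scope: str = "total") -> LocalDupRow:
    """Variant with disjoint rows: duplicated vs NOT duplicated genes."""
    pct_dup = 100.0 * dup_lr / (dup_hr + dup_lr)
    pct_all = 100.0 * all_lr / (all_hr + all_lr)
    res = chi2_2x2_yates([[dup_hr, dup_lr],
                          [all_hr - dup_hr, all_lr - dup_lr]])
    return LocalDupRow(scope, dup_hr, dup_lr, all_hr, all_lr,
                       pct_dup, pct_all, pct_dup / pct_all, res.p)
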