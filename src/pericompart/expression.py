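"""Expression level and tissue/developmental specificity per gene, with
compartment comparisons.

Specificity is the quotient mean/sd across conditions (undefined for
constant genes), and compartment differences are tested with one-way ANOVA
(HR vs LR) on the mean level and on the specificity quotient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import TestResult, anova_oneway

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExpressionSummary:
    gene_id: str
    mean_level: float
    sd_level: float
    specificity_q: float | None  # mean/sd; undefined when sd == 0


@dataclass(frozen=True)
class CompartmentTest:
    scope: str  # "all" or a chromosome id
    quantity: str  # "mean_level" | "specificity_q"
    result: TestResult | None
    n_hr: int
    n_lr: int
    n_excluded: int  # genes with undefined specificity_q


def rpkm(read_count: int, ref_length: int, library_total: int) -> float:
    """Reads per kilobase of reference per million mapped reads."""
    if ref_length <= 0 or library_total <= 0:
        raise ValueError("ref_length and library_total must be positive")
    return read_count / (ref_length / 1000) / (library_total / 1e6)


def summarize_expression(matrix: pd.DataFrame) -> list[ExpressionSummary]:
    """Per-gene mean, sample sd (n-1) and specificity quotient mean/sd.

    Condition column order does not affect the result.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 conditions")
    means = matrix.mean(axis=1)
    sds = matrix.std(axis=1, ddof=1)
    out = []
    for gene_id in matrix.index:
        m, s = float(means[gene_id]), float(sds[gene_id])
        out.append(ExpressionSummary(str(gene_id), m, s,
                                     m / s if s > 0 else None))
    return out


def compare_compartments(summaries: list[ExpressionSummary],
                         labels: dict[str, str],
                         chromosomes: dict[str, str] | None = None,
                         log1p: bool = False) -> list[CompartmentTest]:
    """One-way ANOVA of HR vs LR on mean level and specificity quotient.

    Run overall and, when gene->chromosome assignments are given, once per
    chromosome.  Genes with undefined specificity are excluded from the
    quotient test (exclusion count reported); an empty compartment skips the
    test with a warning.
    """
    scopes: dict[str, list[ExpressionSummary]] = {"all": list(summaries)}
    if chromosomes:
        for s in summaries:
            chrom = chromosomes.get(s.gene_id)
            if chrom is not None:
                scopes.setdefault(chrom, []).append(s)

    tf = np.log1p if log1p else (lambda v: v)
    tests: list[CompartmentTest] = []
    for scope, genes in scopes.items():
        hr = [s for s in genes if labels.get(s.gene_id) == "HR"]
        lr = [s for s in genes if labels.get(s.gene_id) == "LR"]
        for quantity in ("mean_level", "specificity_q"):
            if quantity == "mean_level":
                a = [tf(s.mean_level) for s in hr]
                b = [tf(s.mean_level) for s in lr]
                n_excl = 0
            else:
                a = [tf(s.specificity_q) for s in hr if s.specificity_q is not None]
                b = [tf(s.specificity_q) for s in lr if s.specificity_q is not None]
                n_excl = (len(hr) - len(a)) + (len(lr) - len(b))
            if len(a) < 2 or len(b) < 2:
                logger.warning("scope %s, %s: a compartment is (nearly) empty; "
                               "test skipped", scope, quantity)
                result = None
            else:
                result = anova_oneway(a, b)
            tests.append(CompartmentTest(scope, quantity, result,
                                         len(a), len(b), n_excl))
    return tests


def compare_by_condition(matrix: pd.DataFrame, labels: dict[str, str],
                         log1p: bool = False) -> list[CompartmentTest]:
    """HR-vs-LR ANOVA on the raw expression values of each condition."""
    tf = np.log1p if log1p else (lambda v: v)
    hr_genes = [g for g in matrix.index if labels.get(str(g)) == "HR"]
    lr_genes = [g for g in matrix.index if labels.get(str(g)) == "LR"]
    tests = []
    for cond in matrix.columns:
        a = tf(matrix.loc[hr_genes, cond].to_numpy(dtype=float))
        b = tf(matrix.loc[lr_genes, cond].to_numpy(dtype=float))
        if len(a) < 2 or len(b) < 2:
            logger.warning("condition %s: a compartment is empty; skipped", cond)
            result = None
        else:
            result = anova_oneway(a, b)
        tests.append(CompartmentTest(str(cond), "level", result,
                                     len(a), len(b), 0))
    return tests
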