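"""Exact association testing of allele counts against a reference population.

For each variant and each comparison population a 2x2 table of alternate
vs reference allele counts is built against the reference population
(African by default)::

                 alt allele   ref allele
    reference        a            b
    comparison       c            d

The two-tailed Fisher exact p-value is computed by enumerating, in
log-space, the hypergeometric point probabilities of every table with the
observed margins and summing those no larger than the observed table's
probability (ties within relative tolerance 1e-12).  The reported odds
ratio is the sample cross-product ratio ``ad/bc`` — the unconditional MLE
for a 2x2 table — with no continuity correction, so zero cells yield 0 or
infinity, both of which remain classifiable as "lower"/"higher in the
reference population".

Bonferroni correction is applied per (gene, comparison population) group:
``m`` is the number of testable variants in the group (or, optionally, the
number of allelic testable variants) and a result is significant iff
``p < alpha / m`` (strict).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .cohort_io import ValidationError
from .frequency_profiling import AllelicStatus, FrequencyTable

logger = logging.getLogger("stratpgx")

#: Relative tolerance for point-probability ties in the two-tailed sum.
TIE_RTOL: float = 1e-12

Direction = Literal["higher_in_ref", "lower_in_ref"]


@dataclass(frozen=True)
class ContingencyTable:
    """Allele-count 2x2 table; rows = (reference, comparison) population,
    columns = (alternate, reference) allele."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency cells must be non-negative")

    @property
    def row_margins(self) -> tuple[int, int]:
        return (self.a + self.b, self.c + self.d)

    @property
    def col_margins(self) -> tuple[int, int]:
        return (self.a + self.c, self.b + self.d)


@dataclass
class AssociationResult:
    """Exact-test outcome for one variant against one comparison population."""

    canonical_id: str
    rsid: Optional[str]
    gene: Optional[str]
    cmp_pop: str
    table: Optional[ContingencyTable]  # None when untestable
    p_two_tailed: Optional[float] = None
    odds_ratio: Optional[float] = None  # math.inf allowed; None = undefined
    bonferroni_m: Optional[int] = None
    significant: bool = False
    direction: Optional[Direction] = None

    @property
    def testable(self) -> bool:
        return self.table is not None


def build_contingency(
    ft: FrequencyTable, variant_index: int, ref_pop: str, cmp_pop: str
) -> Optional[ContingencyTable]:
    """2x2 allele-count table for one variant, or None when untestable
    (zero called alleles in either population)."""
    ri = ft.pop_index(ref_pop)
    ci = ft.pop_index(cmp_pop)
    ref_called = int(ft.called_count[variant_index, ri])
    cmp_called = int(ft.called_count[variant_index, ci])
    if ref_called == 0 or cmp_called == 0:
        return None
    a = int(ft.alt_count[variant_index, ri])
    c = int(ft.alt_count[variant_index, ci])
    return ContingencyTable(a=a, b=ref_called - a, c=c, d=cmp_called - c)


def two_tailed_pvalues(r1: int, r2: int, c1: int) -> tuple[int, np.ndarray]:
    """Two-tailed exact p-values for every table with margins (r1, r2 | c1).

    Returns ``(a_min, pvals)`` where ``pvals[a - a_min]`` is the p-value for
    the table whose top-left cell is ``a``, over the full support
    ``a in [max(0, c1 - r2), min(r1, c1)]``.  Point probabilities are the
    hypergeometric pmf computed in log-space via ``gammaln``.
    """
    if r1 <= 0 or r2 <= 0:
        raise ValidationError("row margins must be positive")
    n = r1 + r2
    if not 0 <= c1 <= n:
        raise ValidationError(f"column margin {c1} outside [0, {n}]")
    a_min = max(0, c1 - r2)
    a_max = min(r1, c1)
    ks = np.arange(a_min, a_max + 1)
    logpmf = (
        gammaln(r1 + 1)
        - gammaln(ks + 1)
        - gammaln(r1 - ks + 1)
        + gammaln(r2 + 1)
        - gammaln(c1 - ks + 1)
        - gammaln(r2 - (c1 - ks) + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )
    pmf = np.exp(logpmf)
    order = np.argsort(pmf, kind="stable")
    sorted_pmf = pmf[order]
    cum = np.cumsum(sorted_pmf)
    # p(a) = sum of probabilities <= pmf(a) * (1 + TIE_RTOL)
    idx = np.searchsorted(sorted_pmf, pmf * (1.0 + TIE_RTOL), side="right")
    pvals = np.minimum(cum[idx - 1], 1.0)
    return a_min, pvals


def fisher_exact_two_tailed(t: ContingencyTable) -> float:
    """Two-tailed Fisher exact p-value for a 2x2 allele-count table.

    Degenerate column margins (no alternate or no reference alleles
    observed at all) admit only one table, so p = 1.
    """
    r1, r2 = t.row_margins
    if r1 <= 0 or r2 <= 0:
        raise ValidationError("row margins must be positive")
    c1 = t.a + t.c
    n = r1 + r2
    if c1 == 0 or c1 == n:
        return 1.0
    a_min, pvals = two_tailed_pvalues(r1, r2, c1)
    return float(pvals[t.a - a_min])


def sample_odds_ratio(t: ContingencyTable) -> Optional[float]:
    """Sample cross-product odds ratio ``ad/bc`` (unconditional MLE).

    Returns ``inf`` when only ``bc`` vanishes, ``0.0`` when only ``ad``
    vanishes, and None (undefined) when both products are zero.
    """
    ad = t.a * t.d
    bc = t.b * t.c
    if ad == 0 and bc == 0:
        return None
    if bc == 0:
        return math.inf
    return ad / bc


def test_variants(
    ft: FrequencyTable,
    ref_pop: str,
    cmp_pops: Optional[Sequence[str]] = None,
) -> list[AssociationResult]:
    """Build tables and compute p/OR for every variant x comparison pop.

    Significance is not set here; apply :func:`bonferroni_correct` next.
    """
    if cmp_pops is None:
        cmp_pops = [p for p in ft.populations if p != ref_pop]
    if ref_pop not in ft.populations:
        raise ValidationError(f"reference population {ref_pop!r} not in table")
    results: list[AssociationResult] = []
    for j, v in enumerate(ft.variants):
        for cmp_pop in cmp_pops:
            table = build_contingency(ft, j, ref_pop, cmp_pop)
            res = AssociationResult(
                canonical_id=v.canonical_id,
                rsid=v.rsid,
                gene=v.gene_name,
                cmp_pop=cmp_pop,
                table=table,
            )
            if table is not None:
                res.p_two_tailed = fisher_exact_two_tailed(table)
                res.odds_ratio = sample_odds_ratio(table)
            results.append(res)
    return results


def bonferroni_correct(
    results: Sequence[AssociationResult],
    alpha: float = 0.05,
    mode: Literal["testable", "allelic"] = "testable",
    allelic_ids: Optional[set[str]] = None,
) -> list[AssociationResult]:
    """Set ``bonferroni_m``, ``significant`` and ``direction`` in place.

    Within each (gene, comparison population) group, ``m`` counts the
    testable variants (mode ``"testable"``) or the testable variants that
    also pass allelic status (mode ``"allelic"``, requires ``allelic_ids``).
    Significance uses the strict inequality ``p < alpha / m``; direction is
    assigned from the odds ratio only for significant results.
    """
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    if mode == "allelic" and allelic_ids is None:
        raise ValidationError("mode='allelic' requires allelic_ids")
    groups: dict[tuple[Optional[str], str], list[AssociationResult]] = {}
    for r in results:
        groups.setdefault((r.gene, r.cmp_pop), []).append(r)
    out = list(results)
    for key, members in groups.items():
        testable = [r for r in members if r.testable]
        if mode == "allelic":
            counted = [r for r in testable if r.canonical_id in allelic_ids]
        else:
            counted = testable
        m = len(counted)
        if m == 0:
            logger.info(
                "stage=association_testing event=empty_group gene=%s cmp=%s",
                key[0],
                key[1],
            )
            continue
        threshold = alpha / m
        for r in testable:
            r.bonferroni_m = m
            r.significant = r.p_two_tailed is not None and r.p_two_tailed < threshold
            r.direction = None
            if r.significant and r.odds_ratio is not None:
                if r.odds_ratio > 1.0:
                    r.direction = "higher_in_ref"
                elif r.odds_ratio < 1.0:
                    r.direction = "lower_in_ref"
    return out


def run_association(
    ft: FrequencyTable,
    status: AllelicStatus,
    ref_pop: str,
    alpha: float = 0.05,
    mode: Literal["testable", "allelic"] = "testable",
) -> list[AssociationResult]:
    """Full association stage: tables, exact tests, grouped Bonferroni."""
    allelic_ids = {
        v.canonical_id for v, flag in zip(ft.variants, status.overall) if flag
    }
    results = test_variants(ft, ref_pop)
    return bonferroni_correct(results, alpha=alpha, mode=mode, allelic_ids=allelic_ids)


def results_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    """Results as a table with the standard serialisation columns."""
    rows = []
    for r in results:
        t = r.table
        rows.append(
            {
                "canonical_id": r.canonical_id,
                "rsid": r.rsid or "",
                "gene": r.gene or "",
                "cmp_pop": r.cmp_pop,
                "a": t.a if t else "",
                "b": t.b if t else "",
                "c": t.c if t else "",
                "d": t.d if t else "",
                "p": "" if r.p_two_tailed is None else r.p_two_tailed,
                "or": (
                    ""
                    if r.odds_ratio is None
                    else ("inf" if math.isinf(r.odds_ratio) else r.odds_ratio)
                ),
                "m": r.bonferroni_m or "",
                "significant": r.significant,
                "direction": r.direction or "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "canonical_id",
            "rsid",
            "gene",
            "cmp_pop",
            "a",
            "b",
            "c",
            "d",
            "p",
            "or",
            "m",
            "significant",
            "direction",
        ],
    )
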