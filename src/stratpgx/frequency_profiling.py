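"""Per-population allele frequencies, allelic status and partition profiles.

Frequencies are computed from called alleles only: each non-missing diploid
genotype contributes two allele observations, so for population ``P`` and
variant ``v``::

    frequency(v, P) = alt_count(v, P) / (2 * n_called_samples(v, P))

A variant is *allelic* when its frequency reaches the cut-off (default 1%)
in at least one super-population.  Allelic variants are then partitioned by
the exact subset of populations in which the alternate allele was observed
at least once — the unit of UpSet-style intersection analysis.
"""

from __future__ import annotations

import logging
from collections import Counter, OrderedDict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_io import (
    GenotypeMatrix,
    MISSING,
    SampleManifest,
    ValidationError,
    VariantRecord,
)

logger = logging.getLogger("stratpgx")


@dataclass
class FrequencyTable:
    """Per-variant, per-population allele counts and frequencies.

    Arrays are variants x populations; ``frequency`` is exactly
    ``alt_count / called_count`` (0 where ``called_count`` is 0, with the
    degenerate cells flagged in ``zero_called``).
    """

    variants: list[VariantRecord]
    populations: list[str]
    alt_count: np.ndarray
    called_count: np.ndarray

    def __post_init__(self) -> None:
        shape = (len(self.variants), len(self.populations))
        if self.alt_count.shape != shape or self.called_count.shape != shape:
            raise ValidationError("frequency arrays do not match variants x populations")
        if (self.alt_count < 0).any() or (self.alt_count > self.called_count).any():
            raise ValidationError("alt_count must satisfy 0 <= alt_count <= called_count")
        with np.errstate(invalid="ignore", divide="ignore"):
            self.frequency = np.where(
                self.called_count > 0, self.alt_count / self.called_count, 0.0
            )
        self.zero_called = self.called_count == 0

    def pop_index(self, pop: str) -> int:
        try:
            return self.populations.index(pop)
        except ValueError:
            raise ValidationError(f"population {pop!r} not in frequency table")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for j, v in enumerate(self.variants):
            for k, pop in enumerate(self.populations):
                rows.append(
                    {
                        "canonical_id": v.canonical_id,
                        "gene": v.gene_name,
                        "population": pop,
                        "alt_count": int(self.alt_count[j, k]),
                        "called_count": int(self.called_count[j, k]),
                        "frequency": float(self.frequency[j, k]),
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "canonical_id",
                "gene",
                "population",
                "alt_count",
                "called_count",
                "frequency",
            ],
        )


@dataclass
class AllelicStatus:
    """Allelic-status flags at a frequency cut-off.

    ``per_population`` is variants x populations (frequency >= cutoff,
    inclusive); ``overall`` is the OR over populations.
    """

    cutoff: float
    populations: list[str]
    per_population: np.ndarray
    overall: np.ndarray


@dataclass
class PartitionProfile:
    """Population presence/absence partition of the allelic variants.

    ``membership[j]`` is the sorted tuple of populations in which allelic
    variant ``j`` (indexed as in the source table) was observed, or None for
    variants excluded by allelic status.  ``counts`` maps each realised
    partition to its variant count; ``percentages`` are of the partitioned
    total; ``containing_totals`` gives, per population, the number of
    partitioned variants whose partition contains that population.
    """

    populations: list[str]
    membership: list[tuple[str, ...] | None]
    counts: "OrderedDict[tuple[str, ...], int]"
    percentages: "OrderedDict[tuple[str, ...], float]"
    containing_totals: "OrderedDict[str, int]"

    @property
    def total_partitioned(self) -> int:
        return sum(self.counts.values())


def compute_frequencies(gm: GenotypeMatrix, manifest: SampleManifest) -> FrequencyTable:
    """Population-stratified alternate-allele frequency table.

    Every sample in the matrix must appear in the manifest.  Missing
    genotypes are excluded from both numerator and denominator.
    """
    pops = list(manifest.present_populations)
    pop_rows: dict[str, list[int]] = {p: [] for p in pops}
    for i, sid in enumerate(gm.samples):
        pop_rows[manifest.population_of(sid)].append(i)

    n_var = gm.n_variants
    alt = np.zeros((n_var, len(pops)), dtype=np.int64)
    called = np.zeros((n_var, len(pops)), dtype=np.int64)
    for k, pop in enumerate(pops):
        rows = pop_rows[pop]
        if not rows:
            continue
        block = gm.calls[rows, :]
        ok = block != MISSING
        alt[:, k] = np.where(ok, block, 0).sum(axis=0)
        called[:, k] = 2 * ok.sum(axis=0)
    ft = FrequencyTable(
        variants=list(gm.variants), populations=pops, alt_count=alt, called_count=called
    )
    if ft.zero_called.any():
        logger.warning(
            "stage=frequency_profiling event=zero_called cells=%d",
            int(ft.zero_called.sum()),
        )
    return ft


def allelic_status(ft: FrequencyTable, cutoff: float = 0.01) -> AllelicStatus:
    """Flag variants reaching ``cutoff`` (inclusive) in >= 1 population."""
    if not 0.0 < cutoff < 1.0:
        raise ValidationError(f"cutoff must be in (0, 1), got {cutoff}")
    per_pop = ft.frequency >= cutoff
    overall = per_pop.any(axis=1)
    logger.info(
        "stage=frequency_profiling event=allelic_status cutoff=%s allelic=%d of=%d",
        cutoff,
        int(overall.sum()),
        len(ft.variants),
    )
    return AllelicStatus(
        cutoff=cutoff,
        populations=list(ft.populations),
        per_population=per_pop,
        overall=overall,
    )


def partition_profile(ft: FrequencyTable, status: AllelicStatus) -> PartitionProfile:
    """Partition allelic variants by the exact set of populations in which
    the alternate allele was observed (``alt_count > 0``).

    Only variants passing overall allelic status are partitioned; each
    belongs to exactly one partition, so partition counts sum to the
    partitioned total.
    """
    pops = list(ft.populations)
    membership: list[tuple[str, ...] | None] = []
    counter: Counter = Counter()
    for j in range(len(ft.variants)):
        if not status.overall[j]:
            membership.append(None)
            continue
        present = tuple(p for k, p in enumerate(pops) if ft.alt_count[j, k] > 0)
        membership.append(present)
        counter[present] += 1
    total = sum(counter.values())
    ordered = OrderedDict(
        sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    )
    percentages = OrderedDict(
        (k, (100.0 * c / total if total else 0.0)) for k, c in ordered.items()
    )
    containing = OrderedDict(
        (p, sum(c for part, c in ordered.items() if p in part)) for p in pops
    )
    return PartitionProfile(
        populations=pops,
        membership=membership,
        counts=ordered,
        percentages=percentages,
        containing_totals=containing,
    )


def variant_type_tally(gm: GenotypeMatrix) -> dict[str, Counter]:
    """Per-gene counts of variants by consequence class.

    Variants without a consequence annotation are tallied as ``UNKNOWN``;
    variants outside any gene are tallied under gene ``UNASSIGNED``.
    """
    tally: dict[str, Counter] = {}
    for v in gm.variants:
        gene = v.gene_name or "UNASSIGNED"
        cls = v.consequence_class or "UNKNOWN"
        tally.setdefault(gene, Counter())[cls] += 1
    return tally


def partition_frame(profile: PartitionProfile) -> pd.DataFrame:
    """Partition counts as a table (one row per realised partition)."""
    rows = [
        {
            "partition": "+".join(part),
            "n_populations": len(part),
            "count": count,
            "percentage": profile.percentages[part],
        }
        for part, count in profile.counts.items()
    ]
    return pd.DataFrame(
        rows, columns=["partition", "n_populations", "count", "percentage"]
    )
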