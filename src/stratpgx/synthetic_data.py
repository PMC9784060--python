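"""Synthetic multi-population cohort generator.

Stands in for the restricted consortium genotype data: every downstream
stage can be exercised against a cohort whose per-population alternate-
allele frequencies, annotation assignments and consequence classes are
known exactly (the :class:`CohortTruth`).

Genotypes are drawn under Hardy-Weinberg equilibrium: for a sample in
population ``P`` and variant ``v`` the diploid dosage is
``Binomial(2, p_P(v))``.  Linkage disequilibrium between variants is not
simulated, because no downstream statistic in this pipeline uses it — all
tests and frequencies operate on per-variant allele counts.

Reproducibility: a single integer seed governs every draw through a
documented stream-splitting rule — ``numpy.random.SeedSequence(seed)`` is
spawned into one child stream per concern (genotypes, missingness,
annotations), so each stage's draws are independently reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort_io import (
    AnnotationRecord,
    AnnotationTable,
    GeneRegion,
    GenotypeMatrix,
    MISSING,
    SampleManifest,
    ValidationError,
    VariantRecord,
)
from collections import OrderedDict

logger = logging.getLogger("stratpgx")

#: Default candidate pharmacogene regions (GRCh38-style coordinates with a
#: 100 bp flank on each side, as used for the three EFV/NVP-metabolising
#: genes the pipeline targets).
DEFAULT_REGIONS: tuple[GeneRegion, ...] = (
    GeneRegion("CYP2A6", "chr19", 41_349_343, 41_356_460),
    GeneRegion("CYP2B6", "chr19", 41_497_104, 41_524_408),
    GeneRegion("UGT2B7", "chr4", 69_916_981, 69_978_805),
)

#: Study-condition population sizes (self-identified individuals per
#: super-population in the cohort the pipeline emulates).
DEFAULT_POPULATION_SIZES: dict[str, int] = {
    "AFR": 1992,
    "AMR": 347,
    "EUR": 503,
    "EAS": 504,
    "SAS": 489,
}

#: Per-gene variant totals in the emulated cohort, used (scaled) by the demo
#: spec so gene sizes keep their realistic proportions.
DEFAULT_VARIANTS_PER_GENE: dict[str, int] = {
    "CYP2A6": 413,
    "CYP2B6": 1586,
    "UGT2B7": 2469,
}

#: Closed consequence vocabulary with sampling weights reflecting the
#: typical composition of intragenic variation (mostly intronic).
CONSEQUENCE_CLASSES: tuple[str, ...] = (
    "intron_variant",
    "missense_variant",
    "synonymous_variant",
    "upstream_gene_variant",
    "downstream_gene_variant",
    "3_prime_UTR_variant",
    "5_prime_UTR_variant",
)
_CONSEQUENCE_WEIGHTS = np.array([0.62, 0.08, 0.06, 0.10, 0.06, 0.05, 0.03])

_NUCS = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimVariant:
    """One simulated variant site with its generating frequencies."""

    gene_name: str
    chrom: str
    pos: int
    ref: str
    alt: str
    freqs: dict[str, float]  # population label -> true alt-allele frequency
    consequence_class: Optional[str] = None

    def __post_init__(self) -> None:
        for pop, p in self.freqs.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(
                    f"frequency {p} for {pop} at {self.chrom}:{self.pos} outside [0, 1]"
                )


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort to be realised."""

    populations: dict[str, int]
    variants: list[SimVariant]
    regions: tuple[GeneRegion, ...] = DEFAULT_REGIONS
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for pop, n in self.populations.items():
            if n < 1:
                raise ValidationError(f"population {pop} sample count {n} < 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValidationError(f"missing_rate {self.missing_rate} outside [0, 1)")
        for v in self.variants:
            if not any(r.contains(v.chrom, v.pos) for r in self.regions):
                raise ValidationError(
                    f"variant {v.chrom}:{v.pos} falls outside every declared region"
                )
            missing = set(self.populations) - set(v.freqs)
            if missing:
                raise ValidationError(
                    f"variant {v.chrom}:{v.pos} lacks frequencies for {sorted(missing)}"
                )


@dataclass
class CohortTruth:
    """Ground truth for a realised cohort.

    ``alt_counts``/``called_counts`` are (population -> array over variants)
    of realised alternate-allele and called-allele counts; annotation
    assignment records which variants were given rsIDs, effect scores and
    phenotype terms by :func:`simulate_annotations`.
    """

    spec: CohortSpec
    alt_counts: dict[str, np.ndarray]
    called_counts: dict[str, np.ndarray]
    known_ids: set[str] = field(default_factory=set)
    scored_ids: set[str] = field(default_factory=set)
    deleterious_ids: set[str] = field(default_factory=set)
    phenotype_ids: set[str] = field(default_factory=set)

    def realized_frequency(self, pop: str) -> np.ndarray:
        called = self.called_counts[pop]
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(called > 0, self.alt_counts[pop] / called, 0.0)
        return f


# ---------------------------------------------------------------------------
# Cohort realisation
# ---------------------------------------------------------------------------


def simulate_cohort(
    spec: CohortSpec,
) -> tuple[GenotypeMatrix, SampleManifest, CohortTruth]:
    """Realise a cohort from its spec: HWE genotypes, then missingness.

    Identical spec (including seed) yields byte-identical output.
    """
    geno_ss, miss_ss = np.random.SeedSequence(spec.seed).spawn(2)
    geno_rng = np.random.default_rng(geno_ss)
    miss_rng = np.random.default_rng(miss_ss)

    pops = list(spec.populations)
    n_var = len(spec.variants)
    freq_mat = np.array(
        [[v.freqs[p] for v in spec.variants] for p in pops]
    )  # pops x variants

    blocks: list[np.ndarray] = []
    samples: list[str] = []
    entries: "OrderedDict[str, str]" = OrderedDict()
    for pi, pop in enumerate(pops):
        n = spec.populations[pop]
        block = geno_rng.binomial(2, freq_mat[pi], size=(n, n_var)).astype(np.int16)
        blocks.append(block)
        for i in range(n):
            sid = f"{pop}{i:05d}"
            samples.append(sid)
            entries[sid] = pop
    calls = np.vstack(blocks) if blocks else np.zeros((0, n_var), dtype=np.int16)

    if spec.missing_rate > 0 and calls.size:
        mask = miss_rng.random(calls.shape) < spec.missing_rate
        calls[mask] = MISSING

    variants = [
        VariantRecord(
            chrom=v.chrom,
            pos=v.pos,
            ref=v.ref,
            alt=v.alt,
            gene_name=v.gene_name,
            consequence_class=v.consequence_class,
        )
        for v in spec.variants
    ]
    gm = GenotypeMatrix(variants=variants, samples=samples, calls=calls)
    manifest = SampleManifest(entries=entries, populations=tuple(pops))

    alt_counts: dict[str, np.ndarray] = {}
    called_counts: dict[str, np.ndarray] = {}
    offset = 0
    for pi, pop in enumerate(pops):
        n = spec.populations[pop]
        block = calls[offset : offset + n]
        offset += n
        called = block != MISSING
        alt_counts[pop] = np.where(called, block, 0).sum(axis=0).astype(np.int64)
        called_counts[pop] = (2 * called.sum(axis=0)).astype(np.int64)

    truth = CohortTruth(
        spec=spec, alt_counts=alt_counts, called_counts=called_counts
    )
    logger.info(
        "stage=synthetic_data event=simulate samples=%d variants=%d seed=%d",
        len(samples),
        n_var,
        spec.seed,
    )
    return gm, manifest, truth


# ---------------------------------------------------------------------------
# Annotation fixture
# ---------------------------------------------------------------------------

#: Curated phenotype vocabulary used by the annotation fixture; includes
#: the antiretroviral-metabolism terms the clinical subset looks for.
PHENOTYPE_TERMS: tuple[str, ...] = (
    "Efavirenz poor metabolism",
    "Efavirenz central nervous system toxicity",
    "Nevirapine toxicity",
    "Lung cancer susceptibility",
    "Tobacco addiction susceptibility",
    "Coumarin resistance",
    "Tramadol response",
    "Smoking behaviour",
)

_HAPLOTYPE_TERMS: tuple[str, ...] = ("*1", "*2", "*6", "*9", "*17", "*18", "*1x2")


def simulate_annotations(
    truth: CohortTruth,
    known_fraction: float = 0.8,
    phenotype_fraction: float = 0.3,
    deleterious_fraction: float = 0.2,
    seed: int = 0,
    score_fraction: float = 0.6,
) -> AnnotationTable:
    """Build a dbSNP/effect-predictor-style annotation fixture.

    A ``known_fraction`` subset of variants receives an rsID (the rest are
    novel by construction); a ``score_fraction`` subset of the known
    variants receives SIFT/PolyPhen scores, of which ``deleterious_fraction``
    are drawn from the deleterious score ranges (SIFT near 0, PolyPhen near
    1) and the rest from neutral ranges; ``phenotype_fraction`` of known
    variants receive curated phenotype strings.  Assignments are recorded on
    the :class:`CohortTruth`.
    """
    for name, frac in (
        ("known_fraction", known_fraction),
        ("phenotype_fraction", phenotype_fraction),
        ("deleterious_fraction", deleterious_fraction),
        ("score_fraction", score_fraction),
    ):
        if not 0.0 <= frac <= 1.0:
            raise ValidationError(f"{name} {frac} outside [0, 1]")

    (ann_ss,) = np.random.SeedSequence([truth.spec.seed, seed, 7]).spawn(1)
    rng = np.random.default_rng(ann_ss)
    ids = [
        VariantRecord(v.chrom, v.pos, v.ref, v.alt).canonical_id
        for v in truth.spec.variants
    ]
    n = len(ids)
    n_known = int(round(known_fraction * n))
    known_idx = rng.choice(n, size=n_known, replace=False)
    known = set(known_idx.tolist())

    items: list[tuple[str, AnnotationRecord]] = []
    rs_counter = 1000
    for i in sorted(known):
        key = ids[i]
        rs_counter += int(rng.integers(1, 5000))
        rsid = f"rs{rs_counter}"
        sift = polyphen = None
        if rng.random() < score_fraction:
            truth.scored_ids.add(key)
            if rng.random() < deleterious_fraction:
                truth.deleterious_ids.add(key)
                sift = float(rng.uniform(0.0, 0.04))
                polyphen = float(rng.uniform(0.7, 1.0))
            else:
                sift = float(rng.uniform(0.2, 1.0))
                polyphen = float(rng.uniform(0.0, 0.3))
        phenos: tuple[str, ...] = ()
        if rng.random() < phenotype_fraction:
            truth.phenotype_ids.add(key)
            k = int(rng.integers(1, 3))
            phenos = tuple(rng.choice(PHENOTYPE_TERMS, size=k, replace=False))
        haplos: tuple[str, ...] = ()
        if rng.random() < 0.15:
            k = int(rng.integers(1, 3))
            haplos = tuple(rng.choice(_HAPLOTYPE_TERMS, size=k, replace=False))
        truth.known_ids.add(key)
        items.append(
            (
                key,
                AnnotationRecord(
                    rsid=rsid,
                    sift_score=sift,
                    polyphen_score=polyphen,
                    phenotype_terms=phenos,
                    haplotype_terms=haplos,
                ),
            )
        )
    logger.info(
        "stage=synthetic_data event=annotations known=%d scored=%d phenotype=%d",
        len(truth.known_ids),
        len(truth.scored_ids),
        len(truth.phenotype_ids),
    )
    return AnnotationTable.from_records(items)


# ---------------------------------------------------------------------------
# Demo spec construction
# ---------------------------------------------------------------------------


def _draw_site_frequencies(
    rng: np.random.Generator,
    pops: Sequence[str],
    differentiated_fraction: float,
    private_fraction: float,
) -> dict[str, float]:
    """Draw per-population frequencies for one site.

    Most sites share a common frequency from a rare-skewed Beta; a
    ``differentiated_fraction`` get independent per-population logit
    perturbations (sd 1.0) and a ``private_fraction`` are private to one
    population at low-to-moderate frequency.
    """
    u = rng.random()
    if u < private_fraction:
        owner = pops[int(rng.integers(len(pops)))]
        f = float(rng.uniform(0.01, 0.12))
        return {p: (f if p == owner else 0.0) for p in pops}
    base = float(np.clip(rng.beta(0.3, 2.5), 1e-4, 0.999))
    if u < private_fraction + differentiated_fraction:
        logit = np.log(base / (1 - base))
        shifted = logit + rng.normal(0.0, 1.0, size=len(pops))
        freqs = 1.0 / (1.0 + np.exp(-shifted))
        return {p: float(f) for p, f in zip(pops, freqs)}
    return {p: base for p in pops}


def default_demo_spec(
    scale: float = 0.25,
    seed: int = 0,
    missing_rate: float = 0.0,
    differentiated_fraction: float = 0.35,
    private_fraction: float = 0.12,
    regions: Sequence[GeneRegion] = DEFAULT_REGIONS,
) -> CohortSpec:
    """A demo cohort mirroring the study conditions, scaled by ``scale``.

    Population sizes and per-gene variant totals follow the emulated
    cohort's proportions (1992/347/503/504/489 samples; 413/1586/2469
    variants) multiplied by ``scale`` with a floor of 2 samples and 5
    variants.
    """
    if scale <= 0:
        raise ValidationError(f"scale must be positive, got {scale}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    pops = {
        p: max(2, int(round(n * scale))) for p, n in DEFAULT_POPULATION_SIZES.items()
    }
    pop_labels = list(pops)
    variants: list[SimVariant] = []
    for region in regions:
        n_var = max(5, int(round(DEFAULT_VARIANTS_PER_GENE.get(region.gene_name, 200) * scale)))
        span = region.stop_bp - region.start_bp
        n_var = min(n_var, span)
        positions = np.sort(
            rng.choice(np.arange(region.start_bp, region.stop_bp + 1), size=n_var, replace=False)
        )
        for pos in positions:
            ref, alt = rng.choice(_NUCS, size=2, replace=False)
            # occasional small indel; the pipeline treats them like SNVs
            if rng.random() < 0.08:
                alt = alt + "".join(rng.choice(_NUCS, size=int(rng.integers(1, 3))))
            consequence = None
            if rng.random() < 0.97:
                consequence = str(
                    rng.choice(CONSEQUENCE_CLASSES, p=_CONSEQUENCE_WEIGHTS)
                )
            variants.append(
                SimVariant(
                    gene_name=region.gene_name,
                    chrom=region.chrom,
                    pos=int(pos),
                    ref=str(ref),
                    alt=str(alt),
                    freqs=_draw_site_frequencies(
                        rng, pop_labels, differentiated_fraction, private_fraction
                    ),
                    consequence_class=consequence,
                )
            )
    return CohortSpec(
        populations=pops,
        variants=variants,
        regions=tuple(regions),
        missing_rate=missing_rate,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Truth serialisation
# ---------------------------------------------------------------------------


def write_truth(truth: CohortTruth, path: str | Path) -> None:
    """Serialise the ground truth as TSV (one row per variant x population)."""
    rows = []
    pops = list(truth.spec.populations)
    for j, v in enumerate(truth.spec.variants):
        key = VariantRecord(v.chrom, v.pos, v.ref, v.alt).canonical_id
        for pop in pops:
            rows.append(
                {
                    "canonical_id": key,
                    "gene": v.gene_name,
                    "population": pop,
                    "true_frequency": v.freqs[pop],
                    "alt_count": int(truth.alt_counts[pop][j]),
                    "called_count": int(truth.called_counts[pop][j]),
                    "known": key in truth.known_ids,
                    "scored": key in truth.scored_ids,
                    "deleterious": key in truth.deleterious_ids,
                    "phenotype": key in truth.phenotype_ids,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
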