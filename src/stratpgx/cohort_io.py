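"""Cohort input/output and normalisation.

Reads multi-sample VCF genotype data together with the sample manifest
(sample -> super-population label), the candidate-gene region table and a
local annotation table (dbSNP-style rsIDs plus SIFT/PolyPhen effect scores
and phenotype/haplotype strings).  Provides the preparation steps of the
analysis: coordinate-style variant ID normalisation, trimming to gene
regions, 100%-call-rate sample filtering, and annotation.

Coordinates are 1-based inclusive throughout (VCF convention); the assembly
is a declared label in the pipeline configuration, never converted.
Multi-allelic VCF rows are split into biallelic records on read, so every
downstream statistic is per alternate allele.
"""

from __future__ import annotations

import logging
import re
from collections import OrderedDict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger("stratpgx")

#: Sentinel for a missing diploid genotype call in :class:`GenotypeMatrix`.
MISSING: int = -1

#: Default super-population labels (continental groupings by self-identified
#: ethnicity, 1000 Genomes style).
DEFAULT_POPULATIONS: tuple[str, ...] = ("AFR", "AMR", "EUR", "EAS", "SAS")

_RSID_RE = re.compile(r"^rs\d+$")


class ValidationError(ValueError):
    """An input violated a documented precondition or invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneRegion:
    """A candidate gene region, 1-based inclusive on both ends."""

    gene_name: str
    chrom: str
    start_bp: int
    stop_bp: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("GeneRegion.chrom must be non-empty")
        if self.start_bp > self.stop_bp:
            raise ValidationError(
                f"GeneRegion {self.gene_name}: start_bp {self.start_bp} > "
                f"stop_bp {self.stop_bp}"
            )

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start_bp <= pos <= self.stop_bp


def region_size(region: GeneRegion) -> int:
    """Region size in base pairs, computed as ``stop_bp - start_bp``.

    This is the plain subtraction rule; it reproduces the published sizes
    for two of the three default pharmacogene regions (see
    ``docs/methods.md`` for the known discrepancy on the third).
    """
    return region.stop_bp - region.start_bp


@dataclass
class SampleManifest:
    """Ordered mapping of sample ID to super-population label."""

    entries: "OrderedDict[str, str]"
    populations: tuple[str, ...] = DEFAULT_POPULATIONS

    def __post_init__(self) -> None:
        seen = set(self.entries.values())
        unknown = seen - set(self.populations)
        if unknown:
            raise ValidationError(
                f"manifest population labels {sorted(unknown)} not in the "
                f"configured set {list(self.populations)}"
            )
        declared = [p for p in self.populations if p in seen]
        if not declared:
            raise ValidationError("manifest declares no populated population")
        # populations with zero samples are simply not declared by this cohort
        self.present_populations: tuple[str, ...] = tuple(declared)

    def population_of(self, sample_id: str) -> str:
        try:
            return self.entries[sample_id]
        except KeyError:
            raise ValidationError(f"sample {sample_id!r} absent from manifest")

    def samples_by_population(self) -> "OrderedDict[str, list[str]]":
        out: "OrderedDict[str, list[str]]" = OrderedDict(
            (p, []) for p in self.present_populations
        )
        for sid, pop in self.entries.items():
            out[pop].append(sid)
        return out

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class VariantRecord:
    """A single biallelic variant with its annotation payload."""

    chrom: str
    pos: int
    ref: str
    alt: str
    canonical_id: str = ""
    rsid: Optional[str] = None
    consequence_class: Optional[str] = None
    gene_name: Optional[str] = None
    sift_score: Optional[float] = None
    polyphen_score: Optional[float] = None
    phenotype_terms: tuple[str, ...] = ()
    haplotype_terms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValidationError(
                f"variant at {self.chrom}:{self.pos} has ref == alt ({self.ref!r})"
            )
        if not self.canonical_id:
            self.canonical_id = normalize_variant_id(
                self.chrom, self.pos, self.ref, self.alt
            )


@dataclass
class GenotypeMatrix:
    """Samples x variants diploid alternate-allele dosages.

    ``calls[i, j]`` is the dosage of sample ``samples[i]`` at variant
    ``variants[j]``: 0, 1, 2 or :data:`MISSING`.
    """

    variants: list[VariantRecord]
    samples: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int16)
        if self.calls.shape != (len(self.samples), len(self.variants)):
            raise ValidationError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValidationError("dosages must be 0, 1, 2 or MISSING")
        if len(set(s for s in self.samples)) != len(self.samples):
            raise ValidationError("duplicate sample IDs")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def call_rates(self) -> np.ndarray:
        """Per-sample fraction of non-missing calls (1.0 if no variants)."""
        if self.n_variants == 0:
            return np.ones(self.n_samples)
        return (self.calls != MISSING).mean(axis=1)

    def subset_variants(self, keep: Sequence[int]) -> "GenotypeMatrix":
        keep = list(keep)
        return GenotypeMatrix(
            variants=[self.variants[j] for j in keep],
            samples=list(self.samples),
            calls=self.calls[:, keep].copy(),
        )

    def subset_samples(self, keep: Sequence[int]) -> "GenotypeMatrix":
        keep = list(keep)
        return GenotypeMatrix(
            variants=list(self.variants),
            samples=[self.samples[i] for i in keep],
            calls=self.calls[keep, :].copy(),
        )


@dataclass(frozen=True)
class AnnotationRecord:
    """Annotation payload for one canonical variant ID."""

    rsid: Optional[str] = None
    sift_score: Optional[float] = None
    polyphen_score: Optional[float] = None
    phenotype_terms: tuple[str, ...] = ()
    haplotype_terms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name, score in (("sift", self.sift_score), ("polyphen", self.polyphen_score)):
            if score is not None and not 0.0 <= score <= 1.0:
                raise ValidationError(f"{name} score {score} outside [0, 1]")


@dataclass
class AnnotationTable:
    """Local stand-in for a dbSNP + effect-predictor annotation source."""

    records: dict[str, AnnotationRecord] = field(default_factory=dict)

    @classmethod
    def from_records(
        cls, items: Iterable[tuple[str, AnnotationRecord]]
    ) -> "AnnotationTable":
        records: dict[str, AnnotationRecord] = {}
        for key, rec in items:
            if key in records:
                raise ValidationError(f"duplicate annotation key {key!r}")
            records[key] = rec
        return cls(records=records)

    def __len__(self) -> int:
        return len(self.records)

    def get(self, canonical_id: str) -> Optional[AnnotationRecord]:
        return self.records.get(canonical_id)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def normalize_variant_id(chrom: str, pos: int, ref: str, alt: str) -> str:
    """Coordinate-style canonical variant ID, e.g. ``chr19:40849872C-T``.

    The ID is a deterministic, whitespace-free function of
    ``(chrom, pos, ref, alt)`` and is unique per tuple, which makes it a
    safe join key between the genotype data and annotation tables.
    """
    if not ref or not alt:
        raise ValidationError("ref and alt alleles must be non-empty")
    if pos < 1:
        raise ValidationError(f"position must be >= 1, got {pos}")
    if not chrom:
        raise ValidationError("chrom must be non-empty")
    return f"{chrom}:{pos}{ref}-{alt}"


def _check_non_overlapping(regions: Sequence[GeneRegion]) -> None:
    by_chrom: dict[str, list[GeneRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom, rs in by_chrom.items():
        rs = sorted(rs, key=lambda r: r.start_bp)
        for prev, cur in zip(rs, rs[1:]):
            if cur.start_bp <= prev.stop_bp:
                raise ValidationError(
                    f"regions {prev.gene_name} and {cur.gene_name} overlap on "
                    f"{chrom}; each variant must map to exactly one gene"
                )


def trim_to_regions(
    gm: GenotypeMatrix, regions: Sequence[GeneRegion]
) -> GenotypeMatrix:
    """Keep only variants inside a gene region and assign gene names.

    A variant is retained iff ``start_bp <= pos <= stop_bp`` on the matching
    chromosome.  Regions on the same chromosome must not overlap.  Samples
    are unchanged.
    """
    if not regions:
        raise ValidationError("region list must be non-empty")
    _check_non_overlapping(regions)
    keep: list[int] = []
    genes: list[str] = []
    for j, v in enumerate(gm.variants):
        for r in regions:
            if r.contains(v.chrom, v.pos):
                keep.append(j)
                genes.append(r.gene_name)
                break
    out = gm.subset_variants(keep)
    out.variants = [replace(v, gene_name=g) for v, g in zip(out.variants, genes)]
    logger.info(
        "stage=cohort_io event=trim kept=%d dropped=%d",
        len(keep),
        gm.n_variants - len(keep),
    )
    return out


def filter_call_rate(
    gm: GenotypeMatrix, min_rate: float = 1.0
) -> tuple[GenotypeMatrix, list[str]]:
    """Drop samples whose call rate over the retained variants is below
    ``min_rate`` (default 1.0, i.e. a 100%-call-rate requirement).

    Returns the filtered matrix and the list of removed sample IDs.
    """
    if not 0.0 < min_rate <= 1.0:
        raise ValidationError(f"min_rate must be in (0, 1], got {min_rate}")
    rates = gm.call_rates()
    keep = [i for i, r in enumerate(rates) if r >= min_rate]
    removed = [gm.samples[i] for i in range(gm.n_samples) if i not in set(keep)]
    if not keep and gm.n_samples:
        logger.warning(
            "stage=cohort_io event=call_rate_filter all %d samples removed",
            gm.n_samples,
        )
    else:
        logger.info(
            "stage=cohort_io event=call_rate_filter removed=%d kept=%d",
            len(removed),
            len(keep),
        )
    return gm.subset_samples(keep), removed


def annotate(gm: GenotypeMatrix, ann: AnnotationTable) -> GenotypeMatrix:
    """Attach rsIDs, effect scores and phenotype/haplotype terms by
    canonical-ID lookup.  Unmatched variants keep ``rsid=None`` and become
    novelty candidates downstream."""
    new_variants = []
    hits = 0
    for v in gm.variants:
        rec = ann.get(v.canonical_id)
        if rec is None:
            new_variants.append(v)
            continue
        hits += 1
        new_variants.append(
            replace(
                v,
                rsid=rec.rsid,
                sift_score=rec.sift_score,
                polyphen_score=rec.polyphen_score,
                phenotype_terms=rec.phenotype_terms,
                haplotype_terms=rec.haplotype_terms,
            )
        )
    logger.info(
        "stage=cohort_io event=annotate matched=%d unmatched=%d",
        hits,
        gm.n_variants - hits,
    )
    return GenotypeMatrix(
        variants=new_variants, samples=list(gm.samples), calls=gm.calls.copy()
    )


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------


def _dosage_from_gt(gt: Optional[tuple], alt_index: int) -> int:
    if gt is None or any(a is None for a in gt):
        return MISSING
    return sum(1 for a in gt if a == alt_index)


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a (plain or bgzipped) VCF into a :class:`GenotypeMatrix`.

    Multi-allelic rows are split into one biallelic record per ALT allele;
    a genotype containing any missing allele is recorded as MISSING for all
    alleles of that row.  A ``CSQ`` INFO field, when present, supplies the
    consequence class (comma-separated per ALT).  IDs of the form ``rs\\d+``
    are kept as rsIDs; the canonical coordinate-style ID is always
    recomputed.
    """
    path = Path(path)
    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            alts = rec.alts or ()
            csq = rec.info.get("CSQ") if "CSQ" in rec.info else None
            if isinstance(csq, str):
                csq_parts = csq.split(",")
            elif csq is None:
                csq_parts = []
            else:
                csq_parts = list(csq)
            gts = [rec.samples[s].get("GT") for s in samples]
            for ai, alt in enumerate(alts, start=1):
                if alt is None or alt == rec.ref:
                    continue
                consequence = None
                if csq_parts:
                    part = csq_parts[ai - 1] if ai - 1 < len(csq_parts) else csq_parts[0]
                    consequence = part if part not in (".", "") else None
                rsid = rec.id if rec.id and _RSID_RE.match(rec.id) else None
                variants.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        rsid=rsid,
                        consequence_class=consequence,
                    )
                )
                columns.append(
                    np.array([_dosage_from_gt(gt, ai) for gt in gts], dtype=np.int16)
                )
    calls = (
        np.stack(columns, axis=1)
        if columns
        else np.zeros((len(samples), 0), dtype=np.int16)
    )
    return GenotypeMatrix(variants=variants, samples=samples, calls=calls)


_GT_FOR_DOSAGE = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a normalized, biallelic, dosage-coded VCF 4.2 file.

    The ID column carries the canonical coordinate-style ID; the consequence
    class, when known, is stored in the ``CSQ`` INFO field so that a round
    trip through :func:`read_vcf` is lossless for dosages, IDs and ordering.
    """
    path = Path(path)
    header = pysam.VariantHeader()
    header.add_meta("source", "stratpgx")
    header.formats.add("GT", 1, "String", "Genotype")
    header.info.add("CSQ", 1, "String", "Consequence class")
    for chrom in dict.fromkeys(v.chrom for v in gm.variants):
        header.contigs.add(chrom)
    for s in gm.samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for j, v in enumerate(gm.variants):
            rec = vf.new_record(
                contig=v.chrom,
                start=v.pos - 1,
                stop=v.pos - 1 + len(v.ref),
                alleles=(v.ref, v.alt),
                id=v.canonical_id,
            )
            if v.consequence_class:
                rec.info["CSQ"] = v.consequence_class
            for i, s in enumerate(gm.samples):
                rec.samples[s]["GT"] = _GT_FOR_DOSAGE[int(gm.calls[i, j])]
            vf.write(rec)


def read_manifest(
    path: str | Path, populations: Sequence[str] = DEFAULT_POPULATIONS
) -> SampleManifest:
    """Read a 2-column TSV (sample_id, population) sample manifest."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValidationError(f"manifest {path} must have 2 columns")
    sid_col, pop_col = df.columns[:2]
    if df[sid_col].duplicated().any():
        dupes = df.loc[df[sid_col].duplicated(), sid_col].tolist()
        raise ValidationError(f"duplicate sample IDs in manifest: {dupes[:5]}")
    entries = OrderedDict(zip(df[sid_col], df[pop_col]))
    return SampleManifest(entries=entries, populations=tuple(populations))


def write_manifest(manifest: SampleManifest, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(manifest.entries), "population": list(manifest.entries.values())}
    ).to_csv(path, sep="\t", index=False)


def read_regions(path: str | Path) -> list[GeneRegion]:
    """Read a 4-column TSV (gene, chrom, start, stop) gene-region table."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str}, comment="#")
    cols = list(df.columns[:4])
    return [
        GeneRegion(
            gene_name=str(row[cols[0]]),
            chrom=str(row[cols[1]]),
            start_bp=int(row[cols[2]]),
            stop_bp=int(row[cols[3]]),
        )
        for _, row in df.iterrows()
    ]


def write_regions(regions: Sequence[GeneRegion], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"gene": r.gene_name, "chrom": r.chrom, "start": r.start_bp, "stop": r.stop_bp}
            for r in regions
        ]
    ).to_csv(path, sep="\t", index=False)


def _join_terms(terms: Sequence[str]) -> str:
    return ";".join(terms)


def _split_terms(cell: object) -> tuple[str, ...]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
        return ()
    return tuple(t for t in str(cell).split(";") if t)


def read_annotations(path: str | Path) -> AnnotationTable:
    """Read the annotation TSV: columns (canonical_id, rsid, sift, polyphen,
    phenotypes, haplotypes); list fields are semicolon-delimited."""
    df = pd.read_csv(path, sep="\t", dtype={"canonical_id": str, "rsid": str})

    def _score(x: object) -> Optional[float]:
        if x is None or (isinstance(x, float) and np.isnan(x)):
            return None
        return float(x)

    items = []
    for _, row in df.iterrows():
        rsid = row.get("rsid")
        if isinstance(rsid, float) and np.isnan(rsid):
            rsid = None
        items.append(
            (
                str(row["canonical_id"]),
                AnnotationRecord(
                    rsid=rsid,
                    sift_score=_score(row.get("sift")),
                    polyphen_score=_score(row.get("polyphen")),
                    phenotype_terms=_split_terms(row.get("phenotypes")),
                    haplotype_terms=_split_terms(row.get("haplotypes")),
                ),
            )
        )
    return AnnotationTable.from_records(items)


def write_annotations(ann: AnnotationTable, path: str | Path) -> None:
    rows = [
        {
            "canonical_id": key,
            "rsid": rec.rsid or "",
            "sift": "" if rec.sift_score is None else rec.sift_score,
            "polyphen": "" if rec.polyphen_score is None else rec.polyphen_score,
            "phenotypes": _join_terms(rec.phenotype_terms),
            "haplotypes": _join_terms(rec.haplotype_terms),
        }
        for key, rec in ann.records.items()
    ]
    pd.DataFrame(
        rows,
        columns=["canonical_id", "rsid", "sift", "polyphen", "phenotypes", "haplotypes"],
    ).to_csv(path, sep="\t", index=False)
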