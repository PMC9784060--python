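"""Consensus deleteriousness scoring, novelty flagging and clinical subsets.

SIFT and PolyPhen predict deleteriousness on opposite scales (SIFT: lower
is more deleterious; PolyPhen: higher is more deleterious).  The consensus
score places both on the PolyPhen orientation and averages them::

    consensus = (w_s * (1 - sift) + w_p * polyphen) / (w_s + w_p)

This is a weighted complementary average in the CONDEL family; the full
published CONDEL weights each algorithm by score distributions over
validated deleterious/neutral variant sets, which requires external
training data, so this module exposes configurable per-algorithm weights
(default 0.5/0.5) and a configurable deleterious cut-off (default 0.522,
the published CONDEL threshold) instead.

Degree of support counts deleterious calls among {SIFT, PolyPhen,
consensus}: 1 = singleton, 2 = doubleton, 3 = consensus; zero deleterious
calls are classed ``none``.

Novel variants are those matching neither the rsID table nor the effect-
score table; the clinical subset combines phenotype/consensus evidence
with allelic status and significant frequency differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import pandas as pd

from .cohort_io import GenotypeMatrix, ValidationError, VariantRecord
from .association_testing import AssociationResult
from .frequency_profiling import AllelicStatus, FrequencyTable

logger = logging.getLogger("stratpgx")

#: Published consensus-deleteriousness classification threshold.
DEFAULT_CONDEL_CUTOFF: float = 0.522
#: Conventional per-algorithm deleterious thresholds.
DEFAULT_SIFT_CUTOFF: float = 0.05  # deleterious when score < cutoff
DEFAULT_POLYPHEN_CUTOFF: float = 0.446  # deleterious when score > cutoff

Support = Literal["none", "singleton", "doubleton", "consensus"]
SubsetMode = Literal["or", "and"]


def condel_score(
    sift: Optional[float],
    polyphen: Optional[float],
    w_sift: float = 0.5,
    w_polyphen: float = 0.5,
) -> Optional[float]:
    """Weighted complementary-average consensus of SIFT and PolyPhen.

    Returns None when either input score is absent (no consensus is
    computable from a single algorithm).
    """
    if w_sift <= 0 or w_polyphen <= 0:
        raise ValidationError("weights must be positive")
    if sift is None or polyphen is None:
        return None
    for name, s in (("sift", sift), ("polyphen", polyphen)):
        if not 0.0 <= s <= 1.0:
            raise ValidationError(f"{name} score {s} outside [0, 1]")
    return (w_sift * (1.0 - sift) + w_polyphen * polyphen) / (w_sift + w_polyphen)


def classify_support(
    sift_flag: Optional[bool],
    polyphen_flag: Optional[bool],
    condel_flag: Optional[bool],
) -> tuple[Support, int]:
    """Degree of support from the three deleterious flags.

    Absent flags (no score available) are excluded; the count of available
    flags is returned alongside so a 2-of-2 call is distinguishable from a
    2-of-3 call.
    """
    flags = [f for f in (sift_flag, polyphen_flag, condel_flag) if f is not None]
    n_del = sum(flags)
    label: Support = ("none", "singleton", "doubleton", "consensus")[n_del]
    return label, len(flags)


@dataclass
class EffectPrediction:
    """Per-variant effect-prediction summary."""

    canonical_id: str
    rsid: Optional[str]
    gene: Optional[str]
    sift_score: Optional[float]
    polyphen_score: Optional[float]
    condel: Optional[float]
    sift_deleterious: Optional[bool]
    polyphen_deleterious: Optional[bool]
    condel_deleterious: Optional[bool]
    degree_of_support: Support
    n_algorithms: int
    phenotype_terms: tuple[str, ...]
    haplotype_terms: tuple[str, ...]
    novel: bool


def predict_effects(
    gm: GenotypeMatrix,
    w_sift: float = 0.5,
    w_polyphen: float = 0.5,
    condel_cutoff: float = DEFAULT_CONDEL_CUTOFF,
    sift_cutoff: float = DEFAULT_SIFT_CUTOFF,
    polyphen_cutoff: float = DEFAULT_POLYPHEN_CUTOFF,
) -> list[EffectPrediction]:
    """Score every (annotated) variant and classify its degree of support."""
    out = []
    for v in gm.variants:
        c = condel_score(v.sift_score, v.polyphen_score, w_sift, w_polyphen)
        sift_flag = None if v.sift_score is None else v.sift_score < sift_cutoff
        poly_flag = (
            None if v.polyphen_score is None else v.polyphen_score > polyphen_cutoff
        )
        condel_flag = None if c is None else c >= condel_cutoff
        label, n_avail = classify_support(sift_flag, poly_flag, condel_flag)
        out.append(
            EffectPrediction(
                canonical_id=v.canonical_id,
                rsid=v.rsid,
                gene=v.gene_name,
                sift_score=v.sift_score,
                polyphen_score=v.polyphen_score,
                condel=c,
                sift_deleterious=sift_flag,
                polyphen_deleterious=poly_flag,
                condel_deleterious=condel_flag,
                degree_of_support=label,
                n_algorithms=n_avail,
                phenotype_terms=v.phenotype_terms,
                haplotype_terms=v.haplotype_terms,
                novel=_is_novel(v),
            )
        )
    return out


def _is_novel(v: VariantRecord) -> bool:
    """Novel = no rsID match and no match in the effect-score table."""
    return v.rsid is None and v.sift_score is None and v.polyphen_score is None


def flag_novel(gm: GenotypeMatrix) -> pd.DataFrame:
    """Report variants absent from both annotation sources.

    Layout: gene, position, reference, alternate, consequence; variants
    whose consequence mapping failed are labelled ``mapping_failure``.
    """
    rows = []
    for v in gm.variants:
        if not _is_novel(v):
            continue
        rows.append(
            {
                "gene": v.gene_name or "",
                "position": v.pos,
                "reference": v.ref,
                "alternate": v.alt,
                "consequence": v.consequence_class or "mapping_failure",
                "canonical_id": v.canonical_id,
            }
        )
    logger.info("stage=effect_prediction event=novel count=%d", len(rows))
    return pd.DataFrame(
        rows,
        columns=["gene", "position", "reference", "alternate", "consequence", "canonical_id"],
    )


@dataclass
class ClinicalSubsetEntry:
    """One clinically flagged variant with its frequency row and per-
    population higher/lower markers relative to the reference population
    (markers only where the comparison was significant)."""

    canonical_id: str
    rsid: Optional[str]
    gene: Optional[str]
    phenotype_terms: tuple[str, ...]
    haplotype_terms: tuple[str, ...]
    frequencies: dict[str, float]
    markers: dict[str, Optional[str]]  # cmp pop -> "higher"/"lower"/None


@dataclass
class ClinicalSubset:
    """Per-gene clinical subsets."""

    mode: SubsetMode
    by_gene: dict[str, list[ClinicalSubsetEntry]] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(len(v) for v in self.by_gene.values())


def select_clinical_subset(
    ft: FrequencyTable,
    status: AllelicStatus,
    assoc: Sequence[AssociationResult],
    effects: Sequence[EffectPrediction],
    ref_pop: str,
    mode: SubsetMode = "or",
) -> ClinicalSubset:
    """Variants of clinical interest.

    A variant qualifies when it (1) carries phenotype associations and/or a
    computable consensus prediction (``mode`` selects OR, the default, or
    AND), (2) is allelic in at least one population, and (3) has a
    significantly different frequency versus at least one comparison
    population.
    """
    if mode not in ("or", "and"):
        raise ValidationError(f"mode must be 'or' or 'and', got {mode!r}")
    eff_by_id = {e.canonical_id: e for e in effects}
    sig_pops: dict[str, set[str]] = {}
    for r in assoc:
        if r.significant:
            sig_pops.setdefault(r.canonical_id, set()).add(r.cmp_pop)

    subset = ClinicalSubset(mode=mode)
    ri = ft.pop_index(ref_pop)
    for j, v in enumerate(ft.variants):
        e = eff_by_id.get(v.canonical_id)
        has_pheno = bool(e.phenotype_terms) if e else bool(v.phenotype_terms)
        has_condel = (e.condel is not None) if e else False
        evidence = (has_pheno or has_condel) if mode == "or" else (has_pheno and has_condel)
        if not evidence:
            continue
        if not status.overall[j]:
            continue
        sig = sig_pops.get(v.canonical_id, set())
        if not sig:
            continue
        freqs = {p: float(ft.frequency[j, k]) for k, p in enumerate(ft.populations)}
        markers: dict[str, Optional[str]] = {}
        for k, p in enumerate(ft.populations):
            if p == ref_pop or p not in sig:
                markers[p] = None
            else:
                markers[p] = (
                    "higher" if ft.frequency[j, k] > ft.frequency[j, ri] else "lower"
                )
        subset.by_gene.setdefault(v.gene_name or "UNASSIGNED", []).append(
            ClinicalSubsetEntry(
                canonical_id=v.canonical_id,
                rsid=v.rsid,
                gene=v.gene_name,
                phenotype_terms=v.phenotype_terms,
                haplotype_terms=v.haplotype_terms,
                frequencies=freqs,
                markers=markers,
            )
        )
    logger.info(
        "stage=effect_prediction event=clinical_subset mode=%s total=%d",
        mode,
        subset.total,
    )
    return subset


def clinical_subset_frame(subset: ClinicalSubset, populations: Sequence[str]) -> pd.DataFrame:
    """Clinical subset as a table mirroring the per-population frequency /
    marker layout (one row per variant)."""
    rows = []
    for gene in sorted(subset.by_gene):
        for e in subset.by_gene[gene]:
            row = {
                "gene": gene,
                "canonical_id": e.canonical_id,
                "rsid": e.rsid or "",
                "haplotypes": ";".join(e.haplotype_terms),
                "phenotypes": ";".join(e.phenotype_terms),
            }
            for p in populations:
                row[f"freq_{p}"] = e.frequencies.get(p, "")
                row[f"marker_{p}"] = e.markers.get(p) or ""
            rows.append(row)
    cols = ["gene", "canonical_id", "rsid", "haplotypes", "phenotypes"]
    for p in populations:
        cols += [f"freq_{p}", f"marker_{p}"]
    return pd.DataFrame(rows, columns=cols)


def effects_frame(effects: Sequence[EffectPrediction]) -> pd.DataFrame:
    rows = [
        {
            "canonical_id": e.canonical_id,
            "rsid": e.rsid or "",
            "gene": e.gene or "",
            "sift": "" if e.sift_score is None else e.sift_score,
            "polyphen": "" if e.polyphen_score is None else e.polyphen_score,
            "condel": "" if e.condel is None else e.condel,
            "degree_of_support": e.degree_of_support,
            "n_algorithms": e.n_algorithms,
            "phenotypes": ";".join(e.phenotype_terms),
            "novel": e.novel,
        }
        for e in effects
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "canonical_id",
            "rsid",
            "gene",
            "sift",
            "polyphen",
            "condel",
            "degree_of_support",
            "n_algorithms",
            "phenotypes",
            "novel",
        ],
    )
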