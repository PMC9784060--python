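"""Pipeline orchestration and summary reporting.

Runs the full analysis from a single configuration: cohort I/O (trim,
filter, annotate) -> frequency profiling -> exact association testing ->
effect prediction -> per-gene summaries, writing every stage's table plus
a run manifest.  Identical configuration and inputs yield byte-identical
outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd
import yaml

from . import cohort_io, frequency_profiling as fp, association_testing as assoc_mod
from . import effect_prediction as eff_mod
from .cohort_io import GenotypeMatrix, SampleManifest, ValidationError
from .effect_prediction import (
    DEFAULT_CONDEL_CUTOFF,
    DEFAULT_POLYPHEN_CUTOFF,
    DEFAULT_SIFT_CUTOFF,
)

logger = logging.getLogger("stratpgx")

__version__ = "0.1.0"


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, loadable from YAML."""

    vcf: str
    manifest: str
    regions: str
    annotations: str
    out_dir: str
    alpha: float = 0.05
    allelic_cutoff: float = 0.01
    min_call_rate: float = 1.0
    bonferroni_mode: Literal["testable", "allelic"] = "testable"
    clinical_mode: Literal["or", "and"] = "or"
    condel_w_sift: float = 0.5
    condel_w_polyphen: float = 0.5
    condel_cutoff: float = DEFAULT_CONDEL_CUTOFF
    sift_cutoff: float = DEFAULT_SIFT_CUTOFF
    polyphen_cutoff: float = DEFAULT_POLYPHEN_CUTOFF
    reference_population: str = "AFR"
    populations: tuple[str, ...] = cohort_io.DEFAULT_POPULATIONS
    assembly: str = "GRCh38"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.reference_population not in self.populations:
            raise ValidationError(
                f"reference population {self.reference_population!r} not in "
                f"configured set {list(self.populations)}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "populations" in raw:
            raw["populations"] = tuple(raw["populations"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["populations"] = list(d["populations"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def format_percent(count: int, total: int) -> str:
    """Percentage of ``count`` over ``total`` to 2 decimals, half-up.

    ``format_percent(100, 413) == '24.21'``.
    """
    if total <= 0:
        return "0.00"
    pct = Decimal(count) * 100 / Decimal(total)
    return str(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class GeneSummary:
    """Per-gene report row: totals, allelic and significant counts, and
    per-comparison-population significance/odds-ratio-direction breakdowns."""

    gene: str
    variants_identified: int
    allelic_count: int
    significant_count: int  # union over comparison populations
    per_pop_significant: dict[str, int] = field(default_factory=dict)
    per_pop_significant_pct: dict[str, str] = field(default_factory=dict)
    per_pop_or_gt1: dict[str, int] = field(default_factory=dict)
    per_pop_or_lt1: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.allelic_count > self.variants_identified:
            raise ValidationError(
                f"{self.gene}: allelic count {self.allelic_count} exceeds "
                f"variant total {self.variants_identified}"
            )


@dataclass
class PipelineResult:
    """In-memory bundle produced by :func:`run_pipeline`."""

    config: PipelineConfig
    genotypes: GenotypeMatrix
    manifest: SampleManifest
    removed_samples: list[str]
    frequencies: fp.FrequencyTable
    status: fp.AllelicStatus
    profile: fp.PartitionProfile
    associations: list[assoc_mod.AssociationResult]
    effects: list[eff_mod.EffectPrediction]
    novel: pd.DataFrame
    clinical: eff_mod.ClinicalSubset
    summaries: list[GeneSummary]


def summarize_gene(
    gene: str,
    gm: GenotypeMatrix,
    status: fp.AllelicStatus,
    associations: Sequence[assoc_mod.AssociationResult],
    cmp_pops: Sequence[str],
) -> GeneSummary:
    """Summary-statistics row for one gene."""
    idx = [j for j, v in enumerate(gm.variants) if v.gene_name == gene]
    if not idx:
        raise ValidationError(f"unknown gene {gene!r}")
    total = len(idx)
    allelic = int(sum(bool(status.overall[j]) for j in idx))
    sig_union: set[str] = set()
    per_sig: dict[str, int] = {p: 0 for p in cmp_pops}
    per_gt1: dict[str, int] = {p: 0 for p in cmp_pops}
    per_lt1: dict[str, int] = {p: 0 for p in cmp_pops}
    for r in associations:
        if r.gene != gene or not r.significant:
            continue
        sig_union.add(r.canonical_id)
        per_sig[r.cmp_pop] += 1
        if r.direction == "higher_in_ref":
            per_gt1[r.cmp_pop] += 1
        elif r.direction == "lower_in_ref":
            per_lt1[r.cmp_pop] += 1
    return GeneSummary(
        gene=gene,
        variants_identified=total,
        allelic_count=allelic,
        significant_count=len(sig_union),
        per_pop_significant=per_sig,
        per_pop_significant_pct={
            p: format_percent(per_sig[p], total) for p in cmp_pops
        },
        per_pop_or_gt1=per_gt1,
        per_pop_or_lt1=per_lt1,
    )


def grand_total(summaries: Sequence[GeneSummary]) -> int:
    """Total variants identified across genes (column-sum convention)."""
    return sum(s.variants_identified for s in summaries)


def summaries_frame(summaries: Sequence[GeneSummary], cmp_pops: Sequence[str]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {
            "gene": s.gene,
            "variants_identified": s.variants_identified,
            "allelic_count": s.allelic_count,
            "significant_count": s.significant_count,
        }
        for p in cmp_pops:
            row[f"sig_{p}"] = s.per_pop_significant.get(p, 0)
            row[f"sig_pct_{p}"] = s.per_pop_significant_pct.get(p, "0.00")
            row[f"or_gt1_{p}"] = s.per_pop_or_gt1.get(p, 0)
            row[f"or_lt1_{p}"] = s.per_pop_or_lt1.get(p, 0)
        rows.append(row)
    total_row = {
        "gene": "TOTAL",
        "variants_identified": grand_total(summaries),
        "allelic_count": sum(s.allelic_count for s in summaries),
        "significant_count": sum(s.significant_count for s in summaries),
    }
    for p in cmp_pops:
        total_row[f"sig_{p}"] = sum(s.per_pop_significant.get(p, 0) for s in summaries)
        total_row[f"sig_pct_{p}"] = ""
        total_row[f"or_gt1_{p}"] = sum(s.per_pop_or_gt1.get(p, 0) for s in summaries)
        total_row[f"or_lt1_{p}"] = sum(s.per_pop_or_lt1.get(p, 0) for s in summaries)
    rows.append(total_row)
    return pd.DataFrame(rows)


def export_upset(profile: fp.PartitionProfile, path: str | Path) -> pd.DataFrame:
    """Write the partition profile as a boolean membership matrix.

    One row per realised partition: a boolean column per population plus
    the member count, ordered by descending count with lexicographic
    population-set tie-breaks (deterministic).  The layout is directly
    consumable by standard UpSet plotting tools.
    """
    rows = []
    items = sorted(profile.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    for part, count in items:
        row = {p: (p in part) for p in profile.populations}
        row["count"] = count
        rows.append(row)
    df = pd.DataFrame(rows, columns=[*profile.populations, "count"])
    df.to_csv(path, sep="\t", index=False)
    return df


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise any failure tagged by stage."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(name, str(exc)) from exc
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline and write the output bundle.

    Stage order mirrors the preparation semantics: read -> trim to gene
    regions -> call-rate filter -> annotate -> frequencies -> allelic
    status -> partitions -> exact tests with grouped Bonferroni -> effect
    predictions -> novelty -> clinical subset -> per-gene summaries.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    with _stage("cohort_io"):
        for p in (config.vcf, config.manifest, config.regions, config.annotations):
            if not Path(p).exists():
                raise FileNotFoundError(f"input file not found: {p}")
        gm = cohort_io.read_vcf(config.vcf)
        manifest = cohort_io.read_manifest(config.manifest, config.populations)
        regions = cohort_io.read_regions(config.regions)
        ann = cohort_io.read_annotations(config.annotations)
        gm = cohort_io.trim_to_regions(gm, regions)
        gm, removed = cohort_io.filter_call_rate(gm, config.min_call_rate)
        gm = cohort_io.annotate(gm, ann)
        manifest = SampleManifest(
            entries={s: manifest.entries[s] for s in gm.samples},
            populations=manifest.populations,
        )

    with _stage("frequency_profiling"):
        ft = fp.compute_frequencies(gm, manifest)
        status = fp.allelic_status(ft, config.allelic_cutoff)
        profile = fp.partition_profile(ft, status)

    with _stage("association_testing"):
        associations = assoc_mod.run_association(
            ft,
            status,
            ref_pop=config.reference_population,
            alpha=config.alpha,
            mode=config.bonferroni_mode,
        )

    with _stage("effect_prediction"):
        effects = eff_mod.predict_effects(
            gm,
            w_sift=config.condel_w_sift,
            w_polyphen=config.condel_w_polyphen,
            condel_cutoff=config.condel_cutoff,
            sift_cutoff=config.sift_cutoff,
            polyphen_cutoff=config.polyphen_cutoff,
        )
        novel = eff_mod.flag_novel(gm)
        clinical = eff_mod.select_clinical_subset(
            ft,
            status,
            associations,
            effects,
            ref_pop=config.reference_population,
            mode=config.clinical_mode,
        )

    with _stage("reporting"):
        cmp_pops = [
            p
            for p in manifest.present_populations
            if p != config.reference_population
        ]
        genes = list(dict.fromkeys(v.gene_name for v in gm.variants if v.gene_name))
        summaries = [
            summarize_gene(g, gm, status, associations, cmp_pops) for g in genes
        ]
        _write_bundle(
            out_dir, config, gm, removed, ft, status, profile, associations,
            effects, novel, clinical, summaries, cmp_pops,
        )

    return PipelineResult(
        config=config,
        genotypes=gm,
        manifest=manifest,
        removed_samples=removed,
        frequencies=ft,
        status=status,
        profile=profile,
        associations=associations,
        effects=effects,
        novel=novel,
        clinical=clinical,
        summaries=summaries,
    )


def _write_bundle(
    out_dir: Path,
    config: PipelineConfig,
    gm: GenotypeMatrix,
    removed: list[str],
    ft: fp.FrequencyTable,
    status: fp.AllelicStatus,
    profile: fp.PartitionProfile,
    associations,
    effects,
    novel: pd.DataFrame,
    clinical,
    summaries,
    cmp_pops,
) -> None:
    cohort_io.write_vcf(gm, out_dir / "normalized.vcf")
    pd.DataFrame({"sample_id": removed}).to_csv(
        out_dir / "removed_samples.tsv", sep="\t", index=False
    )
    ft.to_frame().to_csv(out_dir / "frequencies.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "canonical_id": [v.canonical_id for v in ft.variants],
            "allelic": status.overall,
            **{
                f"allelic_{p}": status.per_population[:, k]
                for k, p in enumerate(status.populations)
            },
        }
    ).to_csv(out_dir / "allelic_status.tsv", sep="\t", index=False)
    fp.partition_frame(profile).to_csv(
        out_dir / "partitions.tsv", sep="\t", index=False
    )
    export_upset(profile, out_dir / "upset_matrix.tsv")
    assoc_mod.results_frame(associations).to_csv(
        out_dir / "associations.tsv", sep="\t", index=False
    )
    eff_mod.effects_frame(effects).to_csv(
        out_dir / "effects.tsv", sep="\t", index=False
    )
    novel.to_csv(out_dir / "novel_variants.tsv", sep="\t", index=False)
    eff_mod.clinical_subset_frame(clinical, ft.populations).to_csv(
        out_dir / "clinical_subset.tsv", sep="\t", index=False
    )
    summaries_frame(summaries, cmp_pops).to_csv(
        out_dir / "gene_summaries.tsv", sep="\t", index=False
    )
    run_manifest = {
        "config": {**asdict(config), "populations": list(config.populations)},
        "seed": config.seed,
        "version": __version__,
        "n_samples": gm.n_samples,
        "n_variants": gm.n_variants,
    }
    with open(out_dir / "run_manifest.json", "w") as fh:
        json.dump(run_manifest, fh, indent=2, sort_keys=True)
    logger.info(
        "stage=reporting event=bundle_written dir=%s files=%d", out_dir, 11
    )
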