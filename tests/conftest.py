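import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from stratpgx import cohort_io, synthetic_data as synth
from stratpgx.cohort_io import GenotypeMatrix, SampleManifest, VariantRecord

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_matrix(dosages, populations, chrom="chr19", start_pos=41_350_000):
    """Build a small GenotypeMatrix + manifest from a dosage array.

    ``dosages`` is samples x variants (may contain MISSING);
    ``populations`` assigns one label per sample row.
    """
    dosages = np.asarray(dosages, dtype=np.int16)
    n_samples, n_variants = dosages.shape
    variants = [
        VariantRecord(chrom=chrom, pos=start_pos + j, ref="C", alt="T")
        for j in range(n_variants)
    ]
    samples = [f"S{i:04d}" for i in range(n_samples)]
    gm = GenotypeMatrix(variants=variants, samples=samples, calls=dosages)
    manifest = SampleManifest(
        entries={s: p for s, p in zip(samples, populations)},
        populations=tuple(dict.fromkeys(populations)),
    )
    return gm, manifest


@pytest.fixture(scope="session")
def demo_cohort():
    """Small simulated cohort with annotations, shared across tests."""
    spec = synth.default_demo_spec(scale=0.06, seed=7, missing_rate=0.0)
    gm, manifest, truth = synth.simulate_cohort(spec)
    ann = synth.simulate_annotations(truth, known_fraction=0.8, seed=7)
    gm = cohort_io.annotate(gm, ann)
    return spec, gm, manifest, truth, ann


@pytest.fixture()
def demo_bundle_dir(tmp_path):
    """Synthetic cohort written to disk as pipeline inputs."""
    spec = synth.default_demo_spec(scale=0.04, seed=11)
    gm, manifest, truth = synth.simulate_cohort(spec)
    ann = synth.simulate_annotations(truth, known_fraction=0.85, seed=11)
    cohort_io.write_vcf(gm, tmp_path / "cohort.vcf")
    cohort_io.write_manifest(manifest, tmp_path / "manifest.tsv")
    cohort_io.write_regions(spec.regions, tmp_path / "regions.tsv")
    cohort_io.write_annotations(ann, tmp_path / "annotations.tsv")
    return tmp_path
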