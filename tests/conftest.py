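import numpy as np
import pandas as pd
import pytest

from csccqc.simulate import SimConfig, simulate_cohort, write_cohort


def make_variant(ref="C", alt="T", tri="TCA", ref_reads=40, alt_reads=20,
                 variant_class="SNV", gene="", effect="other",
                 is_sex_chrom=False, chrom="chr1", pos=1000,
                 sample_id="S001"):
    return {
        "sample_id": sample_id, "chrom": chrom, "pos": pos, "ref": ref,
        "alt": alt, "ref_reads": ref_reads, "alt_reads": alt_reads,
        "trinucleotide_context": tri, "variant_class": variant_class,
        "gene": gene, "effect": effect, "is_sex_chrom": is_sex_chrom,
    }


def variants_frame(rows):
    return pd.DataFrame([make_variant(**r) for r in rows])


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A 6-sample, 1.5 Mb cohort written to disk, with its ground truth."""
    config = SimConfig(n_samples=6, bait_territory_bp=1_500_000, seed=7,
                       cellularity_range=(0.35, 0.9),
                       mean_depth_range=(60.0, 120.0))
    bundle, truth = simulate_cohort(config)
    out_dir = tmp_path_factory.mktemp("cohort")
    manifest = write_cohort(bundle, out_dir)
    return {"dir": out_dir, "manifest": manifest, "bundle": bundle,
            "truth": truth, "config": config}


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
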