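import numpy as np
import pandas as pd
import pytest

from panelscreen.cohort import CohortConfig, generate_cohort
from panelscreen.panels import hereditary_panel


def make_calls(rows):
    """Build a call table from (sample, chrom, pos, ref, alt, class, qual,
    mapq, depth, ref_depth, alt_depth) tuples."""
    cols = ["sample_id", "chrom", "pos", "ref", "alt", "variant_class",
            "qual", "mapq", "depth", "ref_depth", "alt_depth"]
    return pd.DataFrame(rows, columns=cols)


def passing_call(sample="S1", chrom="chr1", pos=100, ref="A", alt="T",
                 vclass="snp", qual=60.0, mapq=50.0, depth=40,
                 ref_depth=20, alt_depth=20):
    return (sample, chrom, pos, ref, alt, vclass, qual, mapq, depth,
            ref_depth, alt_depth)


@pytest.fixture(scope="session")
def panel():
    return hereditary_panel()


@pytest.fixture(scope="session")
def small_config():
    return CohortConfig(
        group_sizes={"BOT": 12, "BOT.V600E": 6, "lgOvCa": 4, "hgOvCa": 25},
        gene_freqs={
            ("TP53", "hgOvCa", "HIGH"): 0.8,
            ("BRCA1", "hgOvCa", "HIGH_OR_MODERATE"): 0.5,
            ("PARP1", "BOT", "HIGH_OR_MODERATE"): 0.4,
            ("FANCA", "BOT.V600E", "MODERATE"): 0.3,
        },
        noise_vaf_rate=1.0,
        other_decoy_rate=0.4,
        lowcov_region_rate=0.05,
        survival_effects=[("PARP1", "RFS", float(np.log(4.0)))],
        response_effects=[("BRCA1", "CR", float(np.log(3.0)))],
        censoring_rate=0.2,
        seed=20240917,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_cohort(small_config)
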