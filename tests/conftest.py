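import numpy as np
import pytest

from tmbserval.cohort import FeatureScaler
from tmbserval.simulate import default_config, simulate_cohort
from tmbserval.train_eval import TrainConfig, _scaled_view


@pytest.fixture(scope="session")
def default_cohort():
    """The 660-patient five-subgroup preset at its default seed."""
    cohort, truth = simulate_cohort(default_config())
    return cohort, truth


@pytest.fixture(scope="session")
def small_cohort():
    """A 1/4-scale cohort for fast training tests."""
    cohort, truth = simulate_cohort(default_config().scaled(0.25))
    return cohort, truth


@pytest.fixture()
def fast_train():
    """Momentum-accelerated config used where wall clock matters."""
    return TrainConfig(learning_rate=0.2, momentum=0.9, max_epochs=3000)


@pytest.fixture()
def scaled_view():
    """Helper: standardized-feature patient dict for a cohort."""

    def _make(cohort):
        scaler = FeatureScaler().fit(cohort.feature_matrix())
        return _scaled_view(cohort, scaler), scaler

    return _make


TOY_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=1>
##INFO=<ID=POP_AF,Number=A,Type=Float,Description="Population allele frequency">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tPA\tPB
1\t100\t.\tA\tG\t50\tPASS\tPOP_AF=0.001\tGT:AD\t0/1:10,6\t0/0:12,0
1\t200\t.\tAT\tA\t50\tPASS\t.\tGT:AD\t0/0:15,0\t0/1:9,5
1\t300\t.\tC\tT,CA\t50\tPASS\tPOP_AF=0.002,0.0005\tGT:AD\t1/2:4,5,3\t0/0:11,0,0
"""


@pytest.fixture()
def toy_vcf(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(TOY_VCF)
    return path
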