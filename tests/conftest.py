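import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

HEADER_COLS = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT"


def make_vcf_text(samples, data_lines):
    """Minimal valid VCF text from sample names and pre-formatted data lines."""
    return (
        "##fileformat=VCFv4.2\n"
        + HEADER_COLS + "\t" + "\t".join(samples) + "\n"
        + "".join(line + "\n" for line in data_lines)
    )


@pytest.fixture
def write_vcf(tmp_path):
    def _write(samples, data_lines, name="test.vcf"):
        path = tmp_path / name
        path.write_text(make_vcf_text(samples, data_lines))
        return path

    return _write
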