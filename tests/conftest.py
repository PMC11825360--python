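import numpy as np
import pysam
import pytest

from svcompare.simulate import build_scenario


@pytest.fixture(scope="session")
def sam_header():
    return pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": "chr1", "LN": 10_000_000}]})


@pytest.fixture(scope="session")
def make_segment(sam_header):
    def _make(name="r1", flag=0, pos=1000, cigar="100M", mapq=60, seq=None):
        a = pysam.AlignedSegment(sam_header)
        a.query_name = name
        a.flag = flag
        a.reference_id = 0
        a.reference_start = pos
        a.mapping_quality = mapq
        a.cigarstring = cigar
        if seq is not None:
            a.query_sequence = seq
        return a
    return _make


@pytest.fixture(scope="session")
def panel_scenario(tmp_path_factory):
    """Small case-vs-control panel: 10 loci covering all SSV and CSV types
    at AFs 0.5 / 1.0, perfect reads."""
    return build_scenario(
        "sv_panel", tmp_path_factory.mktemp("panel"),
        params={"n_loci": 10, "coverage": 120, "afs": [0.5, 1.0]}, seed=1)


@pytest.fixture(scope="session")
def trio_germline_scenario(tmp_path_factory):
    return build_scenario(
        "trio_germline", tmp_path_factory.mktemp("trio_g"),
        params={"n_inherited": 10, "coverage": 40}, seed=5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
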