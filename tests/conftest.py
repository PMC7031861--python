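import numpy as np
import pysam
import pytest

from rms.profiles import EndCountProfile


def make_profile(countn, ref_name="ref", count5=None):
    """Profile whose combined count equals ``countn`` (3'-end track only,
    empty 5'-end track), unless explicit tracks are given."""
    countn = np.asarray(countn, dtype=np.int64)
    if count5 is None:
        count5 = np.zeros_like(countn)
    return EndCountProfile(ref_name=ref_name, count5=count5, count3=countn)


@pytest.fixture
def uniform_profile():
    return make_profile(np.full(30, 1000))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def write_sam(path, reads, ref_name="ref", ref_length=100):
    """Write forward-strand perfect-match records; reads are
    (start_1based, length) or (start_1based, length, flag) tuples."""
    header = {
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": ref_name, "LN": ref_length}],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as sam:
        for i, read in enumerate(reads):
            start, length = read[0], read[1]
            flag = read[2] if len(read) > 2 else 0
            rec = pysam.AlignedSegment(header=pysam.AlignmentHeader.from_dict(header))
            rec.query_name = f"r{i}"
            rec.flag = flag
            rec.reference_id = -1 if flag & 4 else 0
            rec.reference_start = -1 if flag & 4 else start - 1
            rec.mapping_quality = 0 if flag & 4 else 60
            if not flag & 4:
                rec.cigarstring = f"{length}M"
            rec.query_sequence = "A" * length
            sam.write(rec)
    return path
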