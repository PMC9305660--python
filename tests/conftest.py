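import pytest

from clonefish.fixtures import load_fixture
from clonefish.reconstruct import Clone
from clonefish.simulate import SimClone


@pytest.fixture(scope="session")
def cohort():
    """All eight packaged cohort patients, loaded once."""
    return {pid: load_fixture(pid) for pid in "12345678"}


def make_clone(cid, ccfs, aberrations=None):
    return Clone(id=cid,
                 aberration_ids=frozenset(aberrations or {cid}),
                 ccf_by_timepoint=dict(enumerate(ccfs)))


@pytest.fixture
def branched_truth():
    """4-clone, 2-time-point branched truth tree with CCFs on the 0.05
    grid (so noiseless metaphase counts are exact)."""
    return [
        SimClone("A", None, [0.9, 0.9], snv_genes=["DNMT3A", "ASXL1"],
                 cnv_tokens=["del(5)(q14q33)"]),
        SimClone("B", "A", [0.5, 0.2], snv_genes=["TET2", "SRSF2"]),
        SimClone("C", "A", [0.2, 0.6], snv_genes=["RUNX1", "U2AF1"],
                 sv_tokens=["t(9;20)(q11;q11)"]),
        SimClone("D", "C", [0.0, 0.3], snv_genes=["NRAS", "KRAS"]),
    ]
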