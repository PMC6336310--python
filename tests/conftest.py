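import numpy as np
import pytest

from vdjrep.model import Design, DesignRow, RearrangementRecord
from vdjrep.synthetic import GermlineSet, SimConfig, default_design


def make_record(
    sequence_id="r1",
    locus="IGH",
    v_call=("IGHV1-26",),
    d_call=("IGHD1-1",),
    j_call=("IGHJ1",),
    c_call="IgM",
    junction_aa="CARDYW",
    d_alignment_length=8,
    in_frame=True,
    has_stop=False,
):
    """Record factory with productive heavy-chain defaults."""
    if locus != "IGH":
        d_call, d_alignment_length = (), 0
        if junction_aa == "CARDYW":
            junction_aa = "CQQYNSF"
        if c_call == "IgM":
            c_call = "unknown"
    return RearrangementRecord(
        sequence_id=sequence_id,
        locus=locus,
        v_call=tuple(v_call),
        d_call=tuple(d_call),
        j_call=tuple(j_call),
        c_call=c_call,
        junction_aa=junction_aa,
        d_alignment_length=d_alignment_length,
        in_frame=in_frame,
        has_stop=has_stop,
    )


@pytest.fixture
def design2() -> Design:
    """Minimal full factorial: 2 animals per cell (16 animals)."""
    return default_design(2)


@pytest.fixture
def design4() -> Design:
    """Study-scale design: 4 animals per cell (32 animals)."""
    return default_design(4)


@pytest.fixture
def germline() -> GermlineSet:
    return GermlineSet()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20_240_117)


def random_record(rng: np.random.Generator, locus: str = "IGH") -> RearrangementRecord:
    """A random record exercising ambiguity, functionality and motif space."""
    from vdjrep.model import AA_LETTERS

    v_pool = [f"{locus}V{i}" for i in range(1, 9)]
    j_pool = [f"{locus}J{i}" for i in range(1, 5)]
    d_pool = ["IGHD1-1", "IGHD2-3", "IGHD3-1"]
    nv = rng.choice([0, 1, 1, 1, 2, 2, 3])
    v = tuple(rng.choice(v_pool, size=nv, replace=False))
    nj = rng.choice([0, 1, 1, 1, 2])
    j = tuple(rng.choice(j_pool, size=nj, replace=False))
    if locus == "IGH":
        nd = rng.choice([0, 1, 1, 2])
        d = tuple(rng.choice(d_pool, size=nd, replace=False))
        d_len = int(rng.integers(0, 15)) if d else 0
        c = str(rng.choice(["IgM", "IgG1", "IgA", "unknown"]))
    else:
        d, d_len, c = (), 0, "unknown"
    core = "".join(rng.choice(list(AA_LETTERS), size=int(rng.integers(3, 15))))
    anchor = str(rng.choice(["W", "F", "S"]))
    tri = [True, False, None]
    return RearrangementRecord(
        sequence_id=f"rnd{rng.integers(1e9)}",
        locus=locus,
        v_call=v,
        d_call=d,
        j_call=j,
        c_call=c,
        junction_aa="C" + core + anchor,
        d_alignment_length=d_len,
        in_frame=tri[rng.integers(3)],
        has_stop=tri[rng.integers(3)],
    )
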