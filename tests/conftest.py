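import numpy as np
import pytest

from phagescan import tables
from phagescan.rbs import SDModel
from phagescan.seqcore import Genome


@pytest.fixture(scope="session")
def orf_table():
    return tables.load_orf_table()


@pytest.fixture(scope="session")
def terminator_table():
    return tables.load_terminator_table()


@pytest.fixture(scope="session")
def codon_table():
    return tables.load_codon_usage_table()


@pytest.fixture
def rng():
    return np.random.default_rng(20180705)


def random_genome(rng, length=1500, topology="linear", gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(rng.choice(list("ACGT"), size=length, p=p))
    return Genome(id="rand", seq=seq, topology=topology)


def sd_window(pattern_dna: str, template_offset: int, spacing: int, model: SDModel | None = None) -> str:
    """25-nt upstream window with the given SD pattern planted at a chosen
    spacing and a filler that pairs the template essentially nowhere."""
    model = model or SDModel()
    tpl = model.mrna_template
    w = model.window
    off = (w - 1 - spacing - 1) - (model.anchor_index - 1)
    win = []
    for j in range(w):
        t_j = j - off
        if 0 <= t_j < len(tpl) and tpl[t_j] in "CU":
            win.append("G")
        else:
            win.append("C")
    for k, b in enumerate(pattern_dna):
        win[off + template_offset + k] = b
    return "".join(win)
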