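import numpy as np
import pytest

from cghcnv.model import GeneTarget, ProbeDef
from cghcnv.simulate import SimConfig, simulate_panel


def make_probe(probe_id="p1", gene_id="g1", start=0, gc=0.5, length=60,
               orientation="sense"):
    bf = ((1 - gc) / 2, gc / 2, gc - gc / 2, (1 - gc) - (1 - gc) / 2)
    return ProbeDef(probe_id=probe_id, gene_id=gene_id, start=start,
                    length=length, orientation=orientation, gc=gc,
                    base_fractions=bf)


def make_gene(gene_id="g1", starts=(0, 200, 400), seq_length=None, gc=0.5,
              length=60, orientations=None):
    if orientations is None:
        orientations = ["sense"] * len(starts)
    probes = tuple(
        make_probe(f"{gene_id}_p{i}", gene_id, start=s, gc=gc, length=length,
                   orientation=o)
        for i, (s, o) in enumerate(zip(starts, orientations))
    )
    if seq_length is None:
        seq_length = max(s + length for s in starts) + 40
    return GeneTarget(gene_id=gene_id, seq_length=seq_length, probes=probes)


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(n_genes=60, n_offspring=4, seed=7)


@pytest.fixture(scope="session")
def small_panel(small_cfg):
    return simulate_panel(small_cfg)
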