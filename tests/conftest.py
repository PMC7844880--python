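"""Shared fixtures: a small synthetic world reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from seqsentry.mini_aligner import Aligner
from seqsentry.panel_builder import extract_flanks, select_markers
from seqsentry.simulator import SimConfig, simulate_reference_and_panel
from seqsentry.spaced_hash import index_reference

READ_LEN = 150


@pytest.fixture(scope="session")
def small_world():
    """200 kb genome, 90 markers, reduced reference + hash index + aligner."""
    cfg = SimConfig(seed=42, genome_length=200_000, n_markers=90,
                    read_len=READ_LEN)
    genome, candidates = simulate_reference_and_panel(cfg)
    panel = select_markers(candidates, n_target=90, seed=42)
    ref = extract_flanks(genome, panel, read_len=READ_LEN)
    index = index_reference(ref.sequences())
    return {
        "cfg": cfg,
        "genome": genome,
        "candidates": candidates,
        "panel": panel,
        "ref": ref,
        "index": index,
        "aligner": Aligner(index, ref),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def contig_regions(ref):
    return [(c.genome_offset, c.genome_offset + len(c.seq)) for c in ref.contigs]
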