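"""Shared fixtures: a small synthetic world reused across test modules.

All fixtures are generated programmatically with fixed seeds; nothing
is read from disk.
"""

from __future__ import annotations

import numpy as np
import pytest

from sctem import demux, methylation, reference, simulate


@pytest.fixture(scope="session")
def consensus():
    return reference.build_consensus(300, 0.08, seed=1)


@pytest.fixture(scope="session")
def small_world(consensus):
    """60 diverged TE copies, a 96-well plate, and an aligner index."""
    genome, annots = reference.synth_genome(
        consensus, n_copies=60, divergence=0.05, seed=7)
    plate = reference.design_plate(consensus, 96, seed=3)
    ref = methylation.BisulfiteReference(genome)
    return {"consensus": consensus, "genome": genome, "annots": annots,
            "plate": plate, "ref": ref}


@pytest.fixture(scope="session")
def cell_library(small_world):
    """One simulated cell processed through demux/align/extract."""
    params = simulate.CellSimParams(
        cell_id="fix0", well_id="A1", true_methylation=0.8,
        n_read_pairs=2000, seed=42)
    pairs, truth = simulate.simulate_cell(
        small_world["genome"], small_world["annots"],
        small_world["plate"], params)
    by_well, report = demux.demultiplex(pairs, small_world["plate"])
    trimmed, _ = demux.trim_all(by_well["A1"])
    aligned = methylation.align_pairs(trimmed, small_world["ref"])
    calls = methylation.extract_methylation(aligned, trimmed,
                                            small_world["ref"])
    cov = methylation.cov_from_calls(calls, small_world["ref"])
    return {"params": params, "pairs": pairs, "truth": truth,
            "report": report, "trimmed": trimmed, "aligned": aligned,
            "calls": calls, "cov": cov, **small_world}
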