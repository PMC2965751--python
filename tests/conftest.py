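"""Shared fixtures: one small simulated study reused across the suite."""

from __future__ import annotations

import numpy as np
import pytest

import chiptile as ct
from chiptile.normalize import ReplicateSet, combine_replicates, zscore

FIXTURE_SEED = 7
FIXTURE_GENES = 300


@pytest.fixture(scope="session")
def study() -> ct.Fixture:
    """Two chromosomes, 300 genes, three factors x two replicates."""
    return ct.make_fixture(seed=FIXTURE_SEED, n_genes=FIXTURE_GENES)


@pytest.fixture(scope="session")
def ztracks(study) -> dict[str, ct.ZScoreTrack]:
    """Combined + standardized track per factor."""
    out = {}
    for factor, (tracks, _) in study.factors.items():
        reps = ReplicateSet.from_tracks(factor, tracks)
        out[factor] = zscore(combine_replicates(reps))
    return out


@pytest.fixture(scope="session")
def summary(study, ztracks) -> ct.GeneSummaryTable:
    return ct.GeneSummaryTable.build(ztracks, study.genome.annotation)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def toy_annotation() -> ct.GeneAnnotation:
    """Hand-built plus/minus genes used by coordinate-logic tests."""
    genes = [
        ct.Gene("gA", "chr1", 1000, 2000, "+"),
        ct.Gene("gB", "chr1", 2600, 3800, "-"),   # IG to gA = 600
        ct.Gene("gC", "chr1", 4200, 5400, "+"),   # IG to gB = 400
        ct.Gene("gD", "chr2", 500, 1400, "-"),
    ]
    return ct.GeneAnnotation(genes, {"chr1": 6000, "chr2": 2000})
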