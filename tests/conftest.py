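"""Shared fixtures: the default synthetic benchmark and its derived data.

Everything heavy is session-scoped so the screening, calibration and
all-vs-all stages run once for the whole suite.
"""

from __future__ import annotations

import numpy as np
import pytest

from hhdscope.pairwise_align import SubstitutionMatrix, all_vs_all, calibrate_karlin
from hhdscope.profile_hmm import build_profile, calibrate, search
from hhdscope.synthetic_data import default_benchmark


@pytest.fixture(scope="session")
def benchmark():
    """The default study conditions: 5 families x 40 members, 500 decoys."""
    return default_benchmark(seed=42)


@pytest.fixture(scope="session")
def calibrated_hmm(benchmark):
    hmm = build_profile(benchmark.seed_msa)
    median_len = int(np.median([len(s.residues) for s in benchmark.database]))
    return calibrate(hmm, n_decoys=5000, decoy_length=median_len, seed=42)


@pytest.fixture(scope="session")
def benchmark_hits(benchmark, calibrated_hmm):
    return search(calibrated_hmm, benchmark.database, e_threshold=1e-5)


@pytest.fixture(scope="session")
def blosum():
    return SubstitutionMatrix()


@pytest.fixture(scope="session")
def karlin(blosum):
    return calibrate_karlin(blosum, seed=42, n_decoys=1000)


@pytest.fixture(scope="session")
def planted_domain_seqs(benchmark):
    """The planted domain sequences themselves (no envelopes, no flanks)."""
    return [m for fam in benchmark.family_alignments.values() for m in fam.members]


@pytest.fixture(scope="session")
def family_of(benchmark):
    out = {}
    for fam, msa in benchmark.family_alignments.items():
        for m in msa.members:
            out[m.id] = fam
    return out


@pytest.fixture(scope="session")
def subfamily_of(benchmark):
    return dict(benchmark.evolved.subfamily)


@pytest.fixture(scope="session")
def domain_scores(planted_domain_seqs, blosum, karlin):
    """All-vs-all local-alignment table over the planted domains."""
    return all_vs_all(planted_domain_seqs, blosum, karlin)
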