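"""Profile HMM estimation, scoring semantics, calibration, search."""

import math

import numpy as np
import pytest

from hhdscope.alphabet import AA_INDEX, AMINO_ACIDS, BACKGROUND
from hhdscope.core_io import Msa, Sequence
from hhdscope.profile_hmm import (
    CalibrationError, ModelError, ProfileHmm, StateError, build_profile,
    calibrate, score_sequence, search, viterbi_path,
)


def uniform_toy_hmm(k: int, consensus: str) -> ProfileHmm:
    """Hand-built profile: sharp emissions on a consensus, flat transitions."""
    em = np.tile(BACKGROUND * 0.1, (k, 1))
    for j, c in enumerate(consensus):
        em[j, AA_INDEX[c]] += 0.9
    em /= em.sum(axis=1, keepdims=True)
    t = np.full(k - 1, 1.0)
    return ProfileHmm(
        match_emissions=em,
        insert_emissions=BACKGROUND.copy(),
        background=BACKGROUND.copy(),
        t_mm=t * 0.8, t_mi=t * 0.1, t_md=t * 0.1,
        t_im=t * 0.6, t_ii=t * 0.4,
        t_dm=t * 0.7, t_dd=t * 0.3,
        column_map=list(range(1, k + 1)),
    )


def test_identical_sequences_give_sharp_match_states():
    msa = Msa([Sequence(f"s{i}", "ACDEFGHIKL") for i in range(3)])
    hmm = build_profile(msa, pseudocount_alpha=0.3)
    assert hmm.n_match_states == 10
    for j, c in enumerate("ACDEFGHIKL"):
        assert hmm.match_emissions[j, AA_INDEX[c]] >= 0.9


def test_gap_majority_column_becomes_insert():
    rows = ["AC-DE", "AC-DE", "ACWDE", "A--DE", "AC-DE"]
    msa = Msa([Sequence(f"s{i}", r) for i, r in enumerate(rows)])
    hmm = build_profile(msa, match_gap_threshold=0.5)
    # column 3 is 80% gapped -> insert; the others are match states
    assert hmm.column_map == [1, 2, 4, 5]


def test_all_gap_columns_rejected():
    msa = Msa([Sequence("a", "A-"), Sequence("b", "-C")])
    with pytest.raises(ModelError):
        build_profile(msa, match_gap_threshold=0.1)


def test_planted_consensus_recovered_in_emissions(benchmark):
    fam = benchmark.specs[1]
    msa = benchmark.family_alignments[fam.name]
    hmm = build_profile(msa)
    for col, group in fam.effective_conserved.items():
        state = hmm.column_map.index(col)
        argmax = AMINO_ACIDS[int(np.argmax(hmm.match_emissions[state]))]
        assert argmax in group, (col, group, argmax)


def test_forward_never_below_viterbi():
    hmm = uniform_toy_hmm(6, "ACDEFG")
    rng = np.random.default_rng(2)
    for _ in range(10):
        seq = "".join(rng.choice(list(AMINO_ACIDS), rng.integers(3, 20)))
        v = score_sequence(hmm, seq, "viterbi")
        f = score_sequence(hmm, seq, "forward")
        assert f >= v - 1e-9


def test_consensus_path_uses_all_match_states():
    msa = Msa([Sequence(f"s{i}", "ACDEFGHIKL") for i in range(4)])
    hmm = build_profile(msa, pseudocount_alpha=0.2)
    path, _ = viterbi_path(hmm, "ACDEFGHIKL")
    assert [s for s, _, _ in path] == ["M"] * 10
    assert [j for _, _, j in path] == list(range(1, 11))


def test_forward_matches_hand_enumerated_path_sum():
    """Toy 2-state profile, length-2 sequence: the forward score equals
    the log-sum over the 5 possible local paths (4 single-state
    placements and one M1->M2 diagonal)."""
    hmm = uniform_toy_hmm(2, "AC")
    seq = "AC"
    lm = np.log2(hmm.match_emissions / BACKGROUND[None, :])
    entry = exit_ = -math.log2(2)
    terms = []
    for i, j in [(0, 0), (0, 1), (1, 0), (1, 1)]:  # single match placements
        terms.append(entry + lm[j, AA_INDEX[seq[i]]] + exit_)
    terms.append(entry + lm[0, AA_INDEX["A"]] + math.log2(0.8)
                 + lm[1, AA_INDEX["C"]] + exit_)
    expect = np.logaddexp2.reduce(terms)
    assert score_sequence(hmm, seq, "forward") == pytest.approx(float(expect), abs=1e-9)
    # and Viterbi is the max over the same paths
    assert score_sequence(hmm, seq, "viterbi") == pytest.approx(float(max(terms)), abs=1e-9)


def test_emission_and_transition_normalisation(benchmark):
    hmm = build_profile(benchmark.seed_msa)
    assert np.allclose(hmm.match_emissions.sum(axis=1), 1.0, atol=1e-9)
    assert np.allclose(hmm.t_mm + hmm.t_mi + hmm.t_md, 1.0, atol=1e-9)
    assert np.allclose(hmm.t_im + hmm.t_ii, 1.0, atol=1e-9)
    assert np.allclose(hmm.t_dm + hmm.t_dd, 1.0, atol=1e-9)


def test_calibration_deterministic(benchmark):
    hmm1 = build_profile(benchmark.seed_msa)
    hmm2 = build_profile(benchmark.seed_msa)
    calibrate(hmm1, n_decoys=600, decoy_length=120, seed=9)
    calibrate(hmm2, n_decoys=600, decoy_length=120, seed=9)
    assert hmm1.gumbel.mu == hmm2.gumbel.mu
    assert hmm1.gumbel.lambda_gumbel == hmm2.gumbel.lambda_gumbel


def test_calibration_tail_self_consistent(calibrated_hmm):
    """~1% of fresh decoys should have a Gumbel P-value <= 0.01."""
    from hhdscope.alphabet import sample_background
    rng = np.random.default_rng(77)
    scores = []
    for _ in range(300):
        seq = sample_background(rng, 200)
        scores.append(score_sequence(calibrated_hmm, seq, "viterbi"))
    frac = np.mean([calibrated_hmm.gumbel.pvalue(s) <= 0.01 for s in scores])
    assert 0.0 <= frac <= 0.04  # 300 draws: expect ~3 +- Poisson noise


def test_minimum_decoys_enforced(benchmark):
    hmm = build_profile(benchmark.seed_msa)
    with pytest.raises(ValueError):
        calibrate(hmm, n_decoys=100)


def test_search_requires_calibration(benchmark):
    hmm = build_profile(benchmark.seed_msa)
    with pytest.raises(StateError):
        search(hmm, benchmark.database)


def test_empty_database_gives_no_hits(calibrated_hmm):
    assert search(calibrated_hmm, []) == []


def test_decoy_only_database_nearly_hit_free(calibrated_hmm):
    from hhdscope.alphabet import sample_background
    rng = np.random.default_rng(31)
    decoys = [Sequence(f"d{i}", sample_background(rng, 250)) for i in range(1000)]
    hits = search(calibrated_hmm, decoys, e_threshold=1e-5)
    assert len(hits) <= 1


def test_two_domain_proteins_yield_two_hits(benchmark, benchmark_hits):
    two_dom = {}
    for r in benchmark.truth.rows:
        two_dom.setdefault(r.protein_id, []).append((r.dom_start, r.dom_end))
    two_dom = {k: v for k, v in two_dom.items() if len(v) == 2}
    assert two_dom, "benchmark should contain two-domain proteins"
    hits_by_target = {}
    for h in benchmark_hits:
        hits_by_target.setdefault(h.target_id, []).append(h)
    found_both = 0
    for pid, intervals in two_dom.items():
        hits = hits_by_target.get(pid, [])
        matched = 0
        for s, e in intervals:
            for h in hits:
                inter = max(0, min(e, h.end) - max(s, h.start) + 1)
                union = max(e, h.end) - min(s, h.start) + 1
                if inter / union >= 0.8:
                    matched += 1
                    break
        if matched == 2:
            found_both += 1
    assert found_both >= 0.8 * len(two_dom)


def test_evalue_monotone_in_database_size(calibrated_hmm, benchmark):
    from hhdscope.alphabet import sample_background
    rng = np.random.default_rng(13)
    base = benchmark.database[:50]
    extra = [Sequence(f"pad{i}", sample_background(rng, 250)) for i in range(150)]
    small = {(h.target_id, h.start): h.e_value
             for h in search(calibrated_hmm, base)}
    large = {(h.target_id, h.start): h.e_value
             for h in search(calibrated_hmm, base + extra)}
    shared = set(small) & set(large)
    assert shared
    for key in shared:
        assert large[key] >= small[key]


def test_model_json_round_trip(tmp_path, calibrated_hmm):
    p = tmp_path / "model.json"
    calibrated_hmm.to_json(p)
    back = ProfileHmm.from_json(p)
    assert back.n_match_states == calibrated_hmm.n_match_states
    assert np.allclose(back.match_emissions, calibrated_hmm.match_emissions)
    assert back.gumbel.mu == calibrated_hmm.gumbel.mu
    seq = "ACDEFGHIKLMNPQRSTVWY"
    assert score_sequence(back, seq) == pytest.approx(
        score_sequence(calibrated_hmm, seq))
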