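"""Pairwise alignment with affine gaps and Karlin-Altschul statistics.

Global (Needleman-Wunsch) and local (Smith-Waterman) protein alignment
under BLOSUM62 with BLASTP-default affine gap penalties, plus bit-score
and E-value statistics for local scores. The affine convention is the
BLAST one: a gap of length L costs ``gap_open + L * gap_extend`` (both
negative). The dynamic programming itself is delegated to Biopython's
PairwiseAligner; this module owns the scoring conventions, identity and
coverage bookkeeping, and the E-value calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .alphabet import AA_INDEX, AMINO_ACIDS, BACKGROUND, sample_background

LN2 = math.log(2.0)


class UndefinedIdentityError(ZeroDivisionError):
    pass


@dataclass
class SubstitutionMatrix:
    """A symmetric residue scoring matrix with affine gap penalties."""

    name: str = "BLOSUM62"
    gap_open: int = -11   # cost of opening a gap (BLAST convention)
    gap_extend: int = -1  # cost per gap residue

    def __post_init__(self) -> None:
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be non-positive")
        self._bio = substitution_matrices.load(self.name)
        idx = [self._bio.alphabet.index(a) for a in AMINO_ACIDS]
        self.scores: np.ndarray = np.asarray(self._bio)[np.ix_(idx, idx)].astype(int)
        if not np.array_equal(self.scores, self.scores.T):
            raise ValueError(f"{self.name} is not symmetric")
        expected = float(BACKGROUND @ self.scores @ BACKGROUND)
        if expected >= 0:
            raise ValueError(
                f"{self.name}: expected score {expected:.3f} under background "
                "is non-negative; Karlin-Altschul statistics undefined"
            )

    def score(self, a: str, b: str) -> int:
        return int(self.scores[AA_INDEX[a], AA_INDEX[b]])

    def aligner(self, mode: str) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = self._bio
        aligner.mode = mode
        # Biopython charges open_gap_score for the first gap residue and
        # extend_gap_score afterwards; the BLAST convention charges
        # gap_open once plus gap_extend per residue including the first.
        aligner.open_gap_score = self.gap_open + self.gap_extend
        aligner.extend_gap_score = self.gap_extend
        return aligner


@dataclass
class KarlinParams:
    """Karlin-Altschul parameters for local-alignment score statistics.

    ``lam`` and ``K`` define the classical bit-score transform. Raw local
    scores are integers, so their E-value distribution is discrete; a
    decoy calibration therefore also stores the empirical survival curve
    of background scores (at ``ref_length`` x ``ref_length`` search
    space) and uses it for E-values in the bulk, switching to the
    exponential Karlin-Altschul tail beyond the calibration range. E-values
    scale with the pairwise search space m*n.
    """

    lam: float
    K: float
    ref_length: int = 78
    surv_scores: np.ndarray | None = None  # ascending integer score atoms
    surv_e: np.ndarray | None = None       # reference E-value at each atom

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lam) and self.lam > 0):
            raise ValueError("lambda must be finite and positive")
        if not (np.isfinite(self.K) and self.K > 0):
            raise ValueError("K must be finite and positive")

    def bit_score(self, raw: float) -> float:
        return (self.lam * raw - math.log(self.K)) / LN2

    def _reference_e(self, raw: float) -> float:
        """E-value at the calibration search space (ref_length^2)."""
        if self.surv_scores is not None and raw <= self.surv_scores[-1]:
            i = int(np.searchsorted(self.surv_scores, raw, side="left"))
            return float(self.surv_e[i])
        # exponential tail anchored at the last calibration atom
        if self.surv_scores is not None:
            s0, e0 = float(self.surv_scores[-1]), float(self.surv_e[-1])
            return e0 * math.exp(-self.lam * (raw - s0))
        return self.ref_length**2 * self.K * math.exp(-self.lam * raw)

    def e_value(self, raw: float, m: int, n: int) -> float:
        return max(m * n / self.ref_length**2 * self._reference_e(raw), 1e-300)

    def pair_pvalue(self, raw: float, m: int, n: int) -> float:
        return -math.expm1(-self.e_value(raw, m, n))


#: Classical gapped BLOSUM62 (open 11, extend 1) constants, usable when a
#: decoy calibration is not wanted.
EMBEDDED_GAPPED_BLOSUM62 = KarlinParams(lam=0.267, K=0.041)


@dataclass
class AlignmentResult:
    """One scored pairwise alignment."""

    raw_score: int
    aligned_a: str
    aligned_b: str
    n_identities: int
    n_aligned_cols: int
    coverage_a: float
    coverage_b: float
    len_a: int
    len_b: int
    mode: str
    bit_score: float | None = None
    e_value: float | None = None

    def __post_init__(self) -> None:
        if self.n_identities > self.n_aligned_cols and self.n_aligned_cols > 0:
            raise ValueError("identities exceed aligned columns")


def _result_from_alignment(aln, a: str, b: str, mode: str) -> AlignmentResult:
    text_a, text_b = str(aln[0]), str(aln[1])
    n_id = sum(1 for x, y in zip(text_a, text_b) if x == y and x != "-")
    span_a = aln.aligned[0]
    span_b = aln.aligned[1]
    cov_a = (span_a[-1][1] - span_a[0][0]) / len(a) if len(span_a) else 0.0
    cov_b = (span_b[-1][1] - span_b[0][0]) / len(b) if len(span_b) else 0.0
    return AlignmentResult(
        raw_score=int(round(aln.score)),
        aligned_a=text_a,
        aligned_b=text_b,
        n_identities=n_id,
        n_aligned_cols=len(text_a),
        coverage_a=cov_a,
        coverage_b=cov_b,
        len_a=len(a),
        len_b=len(b),
        mode=mode,
    )


def global_align(a: str, b: str, matrix: SubstitutionMatrix | None = None) -> AlignmentResult:
    """Optimal global alignment with affine gaps (Needleman-Wunsch)."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    matrix = matrix or SubstitutionMatrix()
    aln = matrix.aligner("global").align(a, b)[0]
    return _result_from_alignment(aln, a, b, "global")


def local_align(
    a: str,
    b: str,
    matrix: SubstitutionMatrix | None = None,
    karlin: KarlinParams | None = None,
) -> AlignmentResult:
    """Optimal local alignment with affine gaps (Smith-Waterman).

    With ``karlin`` supplied the result carries a bit score and an
    E-value over the pairwise search space m*n.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    matrix = matrix or SubstitutionMatrix()
    aligner = matrix.aligner("local")
    score = aligner.score(a, b)
    if score <= 0:
        result = AlignmentResult(0, "", "", 0, 0, 0.0, 0.0, len(a), len(b), "local")
    else:
        result = _result_from_alignment(aligner.align(a, b)[0], a, b, "local")
    if karlin is not None:
        result.bit_score = karlin.bit_score(result.raw_score)
        result.e_value = karlin.e_value(result.raw_score, len(a), len(b))
    return result


def percent_identity(result: AlignmentResult, mode: str = "aligned_cols") -> float:
    """Identity fraction of an alignment under a chosen denominator.

    Modes: ``aligned_cols`` (alignment columns including gap columns),
    ``shorter_seq``, ``longer_seq``.
    """
    denom = {
        "aligned_cols": result.n_aligned_cols,
        "shorter_seq": min(result.len_a, result.len_b),
        "longer_seq": max(result.len_a, result.len_b),
    }.get(mode)
    if denom is None:
        raise ValueError(f"unknown identity mode {mode!r}")
    if denom == 0:
        raise UndefinedIdentityError("zero-length identity denominator")
    return result.n_identities / denom


def ungapped_lambda(matrix: SubstitutionMatrix, background: np.ndarray | None = None) -> float:
    """Solve sum_ij p_i p_j exp(lambda s_ij) = 1 for lambda by bisection."""
    p = BACKGROUND if background is None else np.asarray(background, float)
    s = matrix.scores

    def f(lam: float) -> float:
        return float(p @ np.exp(lam * s) @ p) - 1.0

    lo, hi = 1e-8, 2.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 100:
            raise ValueError("lambda bisection diverged")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if hi - lo < 1e-9:
            break
        if f(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def calibrate_karlin(
    matrix: SubstitutionMatrix | None = None,
    background: np.ndarray | None = None,
    seed: int = 0,
    n_decoys: int = 1000,
    decoy_length: int = 78,
    k_source: str = "decoys",
    tail_min_count: int = 20,
) -> KarlinParams:
    """Karlin-Altschul parameters for the given scoring system.

    Lambda is the ungapped analytical solution (bisection to 1e-9). With
    ``k_source='decoys'`` the local-alignment score distribution of
    ``n_decoys`` background decoy pairs supplies both K (median-matched)
    and the empirical survival curve used for bulk E-values; atoms with
    fewer than ``tail_min_count`` exceedances are dropped in favour of
    the exponential tail. ``k_source='embedded'`` takes the classical
    gapped BLOSUM62 constant instead and no empirical curve.
    """
    matrix = matrix or SubstitutionMatrix()
    if n_decoys < 100:
        raise ValueError("n_decoys must be >= 100")
    lam = ungapped_lambda(matrix, background)
    if k_source == "embedded":
        return KarlinParams(lam=lam, K=EMBEDDED_GAPPED_BLOSUM62.K,
                            ref_length=decoy_length)
    if k_source != "decoys":
        raise ValueError(f"unknown k_source {k_source!r}")
    rng = np.random.default_rng([seed, 101])
    aligner = matrix.aligner("local")
    scores = np.empty(n_decoys, dtype=int)
    for i in range(n_decoys):
        a = sample_background(rng, decoy_length)
        b = sample_background(rng, decoy_length)
        scores[i] = int(aligner.score(a, b))
    # P(S >= s) = 1 - exp(-E(s)); median-matching K: 0.5 = exp(-E(s_med))
    s_med = float(np.median(scores))
    K = math.log(2.0) / (decoy_length**2 * math.exp(-lam * s_med))
    atoms = np.arange(scores.min(), scores.max() + 1)
    exceed = np.array([(scores >= s).sum() for s in atoms])
    keep = exceed >= tail_min_count
    surv = exceed[keep] / n_decoys
    ref_e = -np.log1p(-np.clip(surv, None, 1 - 1e-12))
    ref_e[surv >= 1.0] = np.inf
    ref_e = np.where(np.isfinite(ref_e), ref_e, -np.log(1e-12))
    return KarlinParams(
        lam=lam, K=K, ref_length=decoy_length,
        surv_scores=atoms[keep], surv_e=ref_e,
    )


def all_vs_all(
    sequences,
    matrix: SubstitutionMatrix | None = None,
    karlin: KarlinParams | None = None,
    identity_mode: str = "longer_seq",
):
    """All-against-all local alignment of a sequence collection.

    Returns a pandas DataFrame (id_a, id_b, raw, bits, evalue, identity,
    coverage_a, coverage_b) with one row per unordered pair; scores are
    symmetric so each pair appears once.
    """
    import pandas as pd

    matrix = matrix or SubstitutionMatrix()
    karlin = karlin or calibrate_karlin(matrix, k_source="embedded")
    rows = []
    seqs = list(sequences)
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            a, b = seqs[i], seqs[j]
            res = local_align(a.residues, b.residues, matrix, karlin)
            rows.append({
                "id_a": a.id,
                "id_b": b.id,
                "raw": res.raw_score,
                "bits": round(res.bit_score, 3),
                "evalue": res.e_value,
                "identity": round(percent_identity(res, identity_mode), 5)
                if res.n_aligned_cols else 0.0,
                "coverage_a": round(res.coverage_a, 4),
                "coverage_b": round(res.coverage_b, 4),
            })
    return pd.DataFrame(rows)
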