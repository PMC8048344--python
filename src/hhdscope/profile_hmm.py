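"""Profile hidden Markov model: build, score, calibrate, search.

A position-specific probabilistic model of a domain family is estimated
from a seed alignment (match/insert/delete states, per-state emission and
transition probabilities with Henikoff position-based sequence weighting
and background pseudocounts). Sequences are scored in local mode by
Viterbi (and forward) log-odds in bits against the background null;
flanking residues outside the aligned envelope cost nothing beyond the
uniform entry/exit transitions. Statistical significance comes from a
Gumbel fit to the Viterbi scores of i.i.d. background decoys, and a
database search reports non-overlapping domain envelopes below an
E-value threshold with the E-value scaled by the number of target
sequences — no query-coverage filter is applied.

The model is deliberately simpler than HMMER's (single Gumbel on Viterbi
bits, uniform local entry/exit, no acceleration filters); it is built
for transparent desk-scale screening of planted synthetic databases.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import gumbel_r, kstest

from .alphabet import AA_INDEX, AMINO_ACIDS, BACKGROUND, GAP, sample_background
from .core_io import Msa, Sequence

logger = logging.getLogger("hhdscope.profile_hmm")

_NEG = -1e30  # effective -infinity in bit space


class ModelError(ValueError):
    pass


class CalibrationError(RuntimeError):
    pass


class StateError(RuntimeError):
    """Operation requires a calibrated model."""


@dataclass
class GumbelParams:
    """Gumbel law fitted to background Viterbi bit scores."""

    mu: float
    lambda_gumbel: float
    n_calibration_decoys: int
    seed: int
    ks_statistic: float = float("nan")

    def __post_init__(self) -> None:
        if not self.lambda_gumbel > 0:
            raise ValueError("lambda_gumbel must be positive")

    def pvalue(self, score: float) -> float:
        """P(S >= score) for one background sequence."""
        return float(gumbel_r.sf(score, loc=self.mu, scale=1.0 / self.lambda_gumbel))


@dataclass
class DomainHit:
    """One domain envelope detected in a target sequence."""

    target_id: str
    start: int  # 1-based inclusive on the target
    end: int
    bit_score: float
    e_value: float
    profile_start: int  # 1-based profile match states covered
    profile_end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError("invalid envelope coordinates")
        if self.e_value <= 0:
            raise ValueError("e_value must be positive")


def _henikoff_weights(columns: np.ndarray) -> np.ndarray:
    """Position-based sequence weights (rows: sequences, cols: alignment).

    Each column distributes one unit of weight: a residue in a column
    with r distinct residues, s of its own kind, receives 1/(r*s).
    Gap cells receive nothing. Weights are normalised to mean 1.
    """
    n, L = columns.shape
    w = np.zeros(n)
    for j in range(L):
        col = columns[:, j]
        mask = col >= 0
        if not mask.any():
            continue
        vals, counts = np.unique(col[mask], return_counts=True)
        r = len(vals)
        lookup = dict(zip(vals.tolist(), counts.tolist()))
        for i in np.where(mask)[0]:
            w[i] += 1.0 / (r * lookup[col[i]])
    if w.sum() == 0:
        w[:] = 1.0
    return w * n / w.sum()


@dataclass
class ProfileHmm:
    """A profile HMM over match/insert/delete states.

    ``match_emissions`` has one probability row per match state;
    transitions are per-state (M/I/D outgoing triples). ``column_map``
    records which seed-alignment column each match state came from
    (1-based), so downstream conservation coordinates stay anchored.
    """

    match_emissions: np.ndarray          # (k, 20)
    insert_emissions: np.ndarray         # (20,)
    background: np.ndarray               # (20,)
    t_mm: np.ndarray                     # (k-1,) M_j -> M_{j+1}
    t_mi: np.ndarray
    t_md: np.ndarray
    t_im: np.ndarray
    t_ii: np.ndarray
    t_dm: np.ndarray
    t_dd: np.ndarray
    column_map: list[int]
    gumbel: GumbelParams | None = None

    def __post_init__(self) -> None:
        k = self.n_match_states
        if k < 1:
            raise ModelError("profile needs at least one match state")
        if not np.allclose(self.match_emissions.sum(axis=1), 1.0, atol=1e-9):
            raise ModelError("match emissions must sum to 1")
        if not np.isclose(self.insert_emissions.sum(), 1.0, atol=1e-9):
            raise ModelError("insert emissions must sum to 1")
        out = np.stack([self.t_mm + self.t_mi + self.t_md,
                        self.t_im + self.t_ii,
                        self.t_dm + self.t_dd])
        if not np.allclose(out, 1.0, atol=1e-9):
            raise ModelError("outgoing transition probabilities must sum to 1")
        # log-odds emission scores in bits; log2 transitions
        self._lm = np.log2(self.match_emissions / self.background[None, :])
        self._ltmm = np.log2(self.t_mm)
        self._ltmi = np.log2(self.t_mi)
        self._ltmd = np.log2(np.maximum(self.t_md, 1e-300))
        self._ltim = np.log2(self.t_im)
        self._ltii = np.log2(self.t_ii)
        self._ltdm = np.log2(np.maximum(self.t_dm, 1e-300))
        self._ltdd = np.log2(np.maximum(self.t_dd, 1e-300))
        # uniform local entry and exit over match states
        self._entry = -math.log2(k)
        self._exit = -math.log2(k)

    @property
    def n_match_states(self) -> int:
        return self.match_emissions.shape[0]

    @property
    def is_calibrated(self) -> bool:
        return self.gumbel is not None

    # -- serialization ----------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "alphabet": AMINO_ACIDS,
            "match_emissions": self.match_emissions.tolist(),
            "insert_emissions": self.insert_emissions.tolist(),
            "background": self.background.tolist(),
            "transitions": {
                name: getattr(self, name).tolist()
                for name in ("t_mm", "t_mi", "t_md", "t_im", "t_ii", "t_dm", "t_dd")
            },
            "column_map": self.column_map,
            "gumbel": None if self.gumbel is None else {
                "mu": self.gumbel.mu,
                "lambda": self.gumbel.lambda_gumbel,
                "n_calibration_decoys": self.gumbel.n_calibration_decoys,
                "seed": self.gumbel.seed,
                "ks_statistic": self.gumbel.ks_statistic,
            },
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "ProfileHmm":
        payload = json.loads(Path(path).read_text())
        tr = payload["transitions"]
        g = payload.get("gumbel")
        return cls(
            match_emissions=np.array(payload["match_emissions"]),
            insert_emissions=np.array(payload["insert_emissions"]),
            background=np.array(payload["background"]),
            t_mm=np.array(tr["t_mm"]), t_mi=np.array(tr["t_mi"]),
            t_md=np.array(tr["t_md"]), t_im=np.array(tr["t_im"]),
            t_ii=np.array(tr["t_ii"]), t_dm=np.array(tr["t_dm"]),
            t_dd=np.array(tr["t_dd"]),
            column_map=list(payload["column_map"]),
            gumbel=None if g is None else GumbelParams(
                mu=g["mu"], lambda_gumbel=g["lambda"],
                n_calibration_decoys=g["n_calibration_decoys"],
                seed=g["seed"], ks_statistic=g["ks_statistic"],
            ),
        )


def _encode(seq: str) -> np.ndarray:
    """Residues to alphabet indices; unknown 'X' becomes -1 (background)."""
    return np.array([AA_INDEX.get(c, -1) for c in seq], dtype=int)


def build_profile(
    msa: Msa,
    match_gap_threshold: float = 0.5,
    pseudocount_alpha: float = 0.5,
) -> ProfileHmm:
    """Estimate a profile HMM from a seed alignment.

    Columns whose gap fraction is strictly below ``match_gap_threshold``
    become match states. Emissions are Henikoff-weighted counts smoothed
    with ``alpha`` background pseudocounts; transitions are estimated
    from the observed per-sequence state paths with Laplace pseudocounts.
    """
    n = len(msa.members)
    cols = np.array(
        [[AA_INDEX.get(c, -1) if c != GAP else -2 for c in m.residues] for m in msa.members]
    )
    gap_frac = (cols == -2).mean(axis=0)
    match_cols = np.where(gap_frac < match_gap_threshold)[0]
    if len(match_cols) == 0:
        raise ModelError("alignment yields zero match columns")
    k = len(match_cols)
    weights = _henikoff_weights(np.where(cols >= 0, cols, -1))

    alpha = float(pseudocount_alpha)
    em = np.tile(alpha * BACKGROUND, (k, 1))
    for j_idx, j in enumerate(match_cols):
        for i in range(n):
            a = cols[i, j]
            if a >= 0:
                em[j_idx, a] += weights[i]
            elif a == -1:  # unknown residue: spread over background
                em[j_idx] += weights[i] * BACKGROUND
    em /= em.sum(axis=1, keepdims=True)

    # observed state path per sequence: match columns give M (residue) or
    # D (gap); residues in non-match columns are I attached to the
    # preceding match state. I->D is not modelled (plan7-style) and such
    # rare observed transitions are skipped.
    is_match_col = np.zeros(cols.shape[1], dtype=bool)
    is_match_col[match_cols] = True
    cM = np.zeros((k - 1, 3)) if k > 1 else np.zeros((0, 3))  # M -> M/I/D
    cI = np.zeros((max(k - 1, 0), 2))                         # I -> M/I
    cD = np.zeros((max(k - 1, 0), 2))                         # D -> M/D
    for i in range(n):
        w = weights[i]
        states: list[tuple[str, int]] = []
        j_idx = -1
        for j in range(cols.shape[1]):
            if is_match_col[j]:
                j_idx += 1
                states.append(("M" if cols[i, j] != -2 else "D", j_idx))
            elif cols[i, j] != -2:
                states.append(("I", j_idx))
        for (s1, j1), (s2, _) in zip(states, states[1:]):
            if j1 < 0 or j1 >= k - 1:
                continue
            if s1 == "M":
                cM[j1][{"M": 0, "I": 1, "D": 2}[s2]] += w
            elif s1 == "I" and s2 in ("M", "I"):
                cI[j1][0 if s2 == "M" else 1] += w
            elif s1 == "D" and s2 in ("M", "D"):
                cD[j1][0 if s2 == "M" else 1] += w

    def norm(c: np.ndarray) -> np.ndarray:
        c = c + 1.0  # Laplace pseudocount
        return c / c.sum(axis=1, keepdims=True)

    mm_mi_md, im_ii, dm_dd = norm(cM), norm(cI), norm(cD)
    return ProfileHmm(
        match_emissions=em,
        insert_emissions=BACKGROUND.copy(),
        background=BACKGROUND.copy(),
        t_mm=mm_mi_md[:, 0], t_mi=mm_mi_md[:, 1], t_md=mm_mi_md[:, 2],
        t_im=im_ii[:, 0], t_ii=im_ii[:, 1],
        t_dm=dm_dd[:, 0], t_dd=dm_dd[:, 1],
        column_map=[int(j) + 1 for j in match_cols],
    )


# ---------------------------------------------------------------------------
# scoring


def _emission_row(hmm: ProfileHmm, a: int) -> np.ndarray:
    """Match log-odds for residue index ``a`` across states (0 for 'X')."""
    if a < 0:
        return np.zeros(hmm.n_match_states)
    return hmm._lm[:, a]


def _viterbi_matrices(hmm: ProfileHmm, encoded: np.ndarray):
    """Local Viterbi DP. Returns (VM, VI, VD) of shape (L+1, k)."""
    k = hmm.n_match_states
    L = len(encoded)
    VM = np.full((L + 1, k), _NEG)
    VI = np.full((L + 1, k), _NEG)
    VD = np.full((L + 1, k), _NEG)
    # D-chain helper: cumulative DD costs
    cdd = np.concatenate([[0.0], np.cumsum(hmm._ltdd)])  # (k,)
    for i in range(1, L + 1):
        e = _emission_row(hmm, encoded[i - 1])
        prevM, prevI, prevD = VM[i - 1], VI[i - 1], VD[i - 1]
        # into M_j from M/I/D at j-1 of previous row, or local entry
        fromM = np.concatenate([[_NEG], prevM[:-1] + hmm._ltmm])
        fromI = np.concatenate([[_NEG], prevI[:-1] + hmm._ltim])
        fromD = np.concatenate([[_NEG], prevD[:-1] + hmm._ltdm])
        VM[i] = e + np.maximum.reduce([fromM, fromI, fromD,
                                       np.full(k, hmm._entry)])
        # into I_j (emits at background: no emission term)
        VI[i] = np.maximum(
            np.concatenate([prevM[:-1] + hmm._ltmi, [_NEG]]),
            np.concatenate([prevI[:-1] + hmm._ltii, [_NEG]]),
        )
        # into D_j from M_{j'} via DD chain, same row: prefix-max scan
        base = np.concatenate([[_NEG], VM[i][:-1] + hmm._ltmd])  # enter D at j from M_{j-1}
        VD[i] = np.maximum.accumulate(base - cdd) + cdd
    return VM, VI, VD


def score_sequence(
    hmm: ProfileHmm, seq: str | Sequence, algorithm: str = "viterbi"
) -> float:
    """Local log-odds score of a sequence against the profile, in bits."""
    residues = seq.residues if isinstance(seq, Sequence) else seq
    if not residues:
        raise ValueError("empty sequence")
    encoded = _encode(residues)
    if algorithm == "viterbi":
        VM, _, _ = _viterbi_matrices(hmm, encoded)
        return float(np.max(VM) + hmm._exit)
    if algorithm == "forward":
        return _forward_score(hmm, encoded)
    raise ValueError(f"unknown algorithm {algorithm!r}")


def _forward_score(hmm: ProfileHmm, encoded: np.ndarray) -> float:
    """Local forward log-odds in bits (log-sum over all paths)."""
    k = hmm.n_match_states
    L = len(encoded)
    FM = np.full((L + 1, k), _NEG)
    FI = np.full((L + 1, k), _NEG)
    FD = np.full((L + 1, k), _NEG)
    for i in range(1, L + 1):
        e = _emission_row(hmm, encoded[i - 1])
        shift = lambda v, t: np.concatenate([[_NEG], v[:-1] + t])
        FM[i] = e + np.logaddexp2.reduce([
            shift(FM[i - 1], hmm._ltmm),
            shift(FI[i - 1], hmm._ltim),
            shift(FD[i - 1], hmm._ltdm),
            np.full(k, hmm._entry),
        ], axis=0)
        FI[i] = np.logaddexp2(
            np.concatenate([FM[i - 1][:-1] + hmm._ltmi, [_NEG]]),
            np.concatenate([FI[i - 1][:-1] + hmm._ltii, [_NEG]]),
        )
        # sequential D-chain (forward is not on the search hot path)
        FD[i, 0] = _NEG
        for j in range(1, k):
            FD[i, j] = np.logaddexp2(FM[i, j - 1] + hmm._ltmd[j - 1],
                                     FD[i, j - 1] + hmm._ltdd[j - 1])
    return float(np.logaddexp2.reduce(FM[1:].ravel()) + hmm._exit)


def viterbi_path(hmm: ProfileHmm, seq: str) -> tuple[list[tuple[str, int, int]], float]:
    """Best local state path and its bit score.

    The path is (state, target_pos, profile_state) triples with 1-based
    coordinates; D entries carry the target_pos of the last emitted
    residue. Ties in the traceback prefer match continuation over insert
    over delete over a fresh local entry, for reproducibility.
    """
    encoded = _encode(seq)
    VM, VI, VD = _viterbi_matrices(hmm, encoded)
    i, j = np.unravel_index(int(np.argmax(VM)), VM.shape)
    bits = float(VM[i, j] + hmm._exit)
    path: list[tuple[str, int, int]] = []
    state = "M"
    tol = 1e-6
    while True:
        path.append((state, int(i), int(j) + 1))
        if state == "M":
            e = _emission_row(hmm, encoded[i - 1])[j]
            target = VM[i, j] - e
            if j > 0 and abs(target - (VM[i - 1, j - 1] + hmm._ltmm[j - 1])) < tol:
                i, j, state = i - 1, j - 1, "M"
            elif j > 0 and abs(target - (VI[i - 1, j - 1] + hmm._ltim[j - 1])) < tol:
                i, j, state = i - 1, j - 1, "I"
            elif j > 0 and abs(target - (VD[i - 1, j - 1] + hmm._ltdm[j - 1])) < tol:
                i, j, state = i - 1, j - 1, "D"
            else:
                break  # local entry
        elif state == "I":
            if abs(VI[i, j] - (VM[i - 1, j] + hmm._ltmi[j])) < tol:
                i, state = i - 1, "M"
            else:
                i, state = i - 1, "I"
        else:  # D
            if j > 0 and abs(VD[i, j] - (VD[i, j - 1] + hmm._ltdd[j - 1])) < tol:
                j, state = j - 1, "D"
            else:
                j, state = j - 1, "M"
    return list(reversed(path)), bits


# ---------------------------------------------------------------------------
# calibration and search


def calibrate(
    hmm: ProfileHmm,
    n_decoys: int = 5000,
    decoy_length: int | None = None,
    seed: int = 0,
) -> ProfileHmm:
    """Fit a Gumbel law to background decoy Viterbi scores (in place).

    Decoys are i.i.d. background-composition sequences of
    ``decoy_length`` (callers typically pass the median database length).
    """
    if n_decoys < 500:
        raise ValueError("n_decoys must be >= 500")
    length = decoy_length or 200
    rng = np.random.default_rng([seed, 211])
    k = hmm.n_match_states
    L = length
    # vectorised Viterbi across all decoys at once (same length)
    enc = rng.choice(len(AMINO_ACIDS), size=(n_decoys, L), p=BACKGROUND)
    VMp = np.full((n_decoys, k), _NEG)
    VIp = np.full((n_decoys, k), _NEG)
    VDp = np.full((n_decoys, k), _NEG)
    best = np.full(n_decoys, _NEG)
    cdd = np.concatenate([[0.0], np.cumsum(hmm._ltdd)])
    neg_col = np.full((n_decoys, 1), _NEG)
    for i in range(L):
        e = hmm._lm[:, enc[:, i]].T  # (n, k)
        fromM = np.concatenate([neg_col, VMp[:, :-1] + hmm._ltmm], axis=1)
        fromI = np.concatenate([neg_col, VIp[:, :-1] + hmm._ltim], axis=1)
        fromD = np.concatenate([neg_col, VDp[:, :-1] + hmm._ltdm], axis=1)
        VM = e + np.maximum.reduce([fromM, fromI, fromD,
                                    np.full((n_decoys, k), hmm._entry)])
        VI = np.maximum(
            np.concatenate([VMp[:, :-1] + hmm._ltmi, neg_col], axis=1),
            np.concatenate([VIp[:, :-1] + hmm._ltii, neg_col], axis=1),
        )
        base = np.concatenate([neg_col, VM[:, :-1] + hmm._ltmd], axis=1)
        VD = np.maximum.accumulate(base - cdd[None, :], axis=1) + cdd[None, :]
        best = np.maximum(best, VM.max(axis=1))
        VMp, VIp, VDp = VM, VI, VD
    scores = best + hmm._exit
    if np.ptp(scores) < 1e-9:
        raise CalibrationError("degenerate decoy score distribution")
    mu, scale = gumbel_r.fit(scores)
    ks = kstest(scores, gumbel_r(loc=mu, scale=scale).cdf).statistic
    hmm.gumbel = GumbelParams(
        mu=float(mu), lambda_gumbel=float(1.0 / scale),
        n_calibration_decoys=n_decoys, seed=seed, ks_statistic=float(ks),
    )
    logger.info("calibrated: mu=%.2f lambda=%.3f KS=%.4f", mu, 1 / scale, ks)
    return hmm


def _best_envelope(hmm: ProfileHmm, seq: str) -> tuple[float, int, int, int, int] | None:
    """(bits, target_start, target_end, profile_start, profile_end)."""
    if not seq:
        return None
    path, bits = viterbi_path(hmm, seq)
    t_positions = [i for s, i, j in path if s in ("M", "I")]
    p_states = [j for s, i, j in path if s in ("M", "D")]
    if not t_positions:
        return None
    return bits, min(t_positions), max(t_positions), min(p_states), max(p_states)


def search(
    hmm: ProfileHmm,
    database: list[Sequence],
    e_threshold: float = 1e-5,
) -> list[DomainHit]:
    """Screen a protein database for domain hits with E < ``e_threshold``.

    E-values are the per-sequence Gumbel P-value scaled by the number of
    target sequences. After a hit is accepted its envelope is masked and
    the flanking segments are rescanned, so multiple non-overlapping
    domains per target are reported. Hits are returned best-score first.
    """
    if not hmm.is_calibrated:
        raise StateError("profile must be calibrated before search")
    n_targets = len(database)
    hits: list[DomainHit] = []
    for target in database:
        segments = [(target.residues, 0)]  # (subsequence, offset)
        while segments:
            segment, offset = segments.pop()
            if len(segment) < 5:
                continue
            env = _best_envelope(hmm, segment)
            if env is None:
                continue
            bits, t1, t2, p1, p2 = env
            e_value = max(n_targets * hmm.gumbel.pvalue(bits), 1e-300)
            if e_value >= e_threshold:
                continue
            hits.append(DomainHit(
                target_id=target.id,
                start=offset + t1, end=offset + t2,
                bit_score=round(bits, 2), e_value=e_value,
                profile_start=p1, profile_end=p2,
            ))
            segments.append((segment[: t1 - 1], offset))
            segments.append((segment[t2:], offset + t2))
    return sorted(hits, key=lambda h: (-h.bit_score, h.target_id, h.start))


def extract_hit_sequences(hits: list[DomainHit], database: list[Sequence]) -> list[Sequence]:
    """Cut the envelope subsequences of hits out of their target proteins."""
    by_id = {s.id: s for s in database}
    out = []
    for h in hits:
        target = by_id[h.target_id]
        out.append(Sequence(
            f"{h.target_id}/{h.start}-{h.end}",
            target.residues[h.start - 1 : h.end],
            taxon=target.taxon,
        ))
    return out
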