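"""Terminal-inverted-repeat detection and element-candidate filtering.

The detector finds pairs of disjoint arms (arm5 before arm3 on the same
contig) such that arm5 aligns to the reverse complement of arm3 with a local
alignment score above a threshold, under einverted-style scoring (match +3,
mismatch -4, linear gap penalty 12, minimum score 50, maximum outer span
80 kb). Two search paths share these semantics:

* exact path (short contigs): a full local-alignment dynamic program over
  S x revcomp(S), restricted to cells that keep the two arms disjoint;
* seeded path (long contigs): reverse-complement k-mer seed pairs are grouped
  by anti-diagonal (an inverted repeat without indels keeps i + j constant),
  and each seed cluster is aligned locally with Bio.Align.PairwiseAligner
  under the same scoring.

Competing hits that overlap in the same arm role are reduced to the best
scoring one; nested pairs (one insert fully inside another) do not overlap
arm-wise and are all reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .seq_io import Contig, Interval, revcomp

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IRScoring:
    """einverted-convention alignment parameters (all exposed in config)."""

    match: int = 3
    mismatch: int = -4
    gap_penalty: int = 12
    min_score: int = 50
    max_separation: int = 80000

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch) or self.gap_penalty <= 0:
            raise ValueError("require match > 0 > mismatch and gap_penalty > 0")


@dataclass(frozen=True)
class TIRPair:
    contig_id: str
    arm5: Interval
    arm3: Interval
    insert: Interval
    score: int
    arm_identity_pct: float
    n_mismatches: int
    n_gaps: int

    @property
    def arm5_len(self) -> int:
        return self.arm5.length

    @property
    def arm3_len(self) -> int:
        return self.arm3.length


def _make_pair(contig_id, s1, e1, s2, e2, score, matches, mismatches, gaps) -> TIRPair:
    columns = matches + mismatches + gaps
    identity = 100.0 * matches / columns if columns else 0.0
    return TIRPair(
        contig_id=contig_id,
        arm5=Interval(contig_id, s1, e1),
        arm3=Interval(contig_id, s2, e2),
        insert=Interval(contig_id, s1, e2),
        score=int(score),
        arm_identity_pct=identity,
        n_mismatches=int(mismatches),
        n_gaps=int(gaps),
    )


def _dedup(candidates: list[TIRPair]) -> list[TIRPair]:
    """Best-score-wins among hits sharing either arm locus; sorted by position."""
    order = sorted(
        candidates,
        key=lambda p: (-p.score, p.arm5.start, p.arm5.end, p.arm3.start, p.arm3.end),
    )
    accepted: list[TIRPair] = []
    for cand in order:
        if any(
            cand.arm5.overlaps(a.arm5) or cand.arm3.overlaps(a.arm3)
            for a in accepted
        ):
            continue
        accepted.append(cand)
    accepted.sort(key=lambda p: (p.arm5.start, p.arm3.start))
    return accepted


# ---------------------------------------------------------------------------
# exact path
# ---------------------------------------------------------------------------

def _exact_dp_matrix(seq: str, scoring: IRScoring) -> np.ndarray:
    """Local-alignment DP of S (rows) vs revcomp(S) (cols), cells a+b <= n.

    Cell (a, b) scores alignments pairing a prefix-suffix arm combination
    whose arm5 ends at sequence index a-1 and whose arm3 starts at index n-b;
    the a+b <= n restriction keeps the arms disjoint.
    """
    n = len(seq)
    X = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    Y = np.frombuffer(revcomp(seq).encode("ascii"), dtype=np.uint8)
    g = scoring.gap_penalty
    H = np.zeros((n + 1, n + 1), dtype=np.int32)
    n_code = ord("N")
    for a in range(1, n):
        bmax = n - a
        if bmax < 1:
            break
        xa = X[a - 1]
        yb = Y[:bmax]
        sub = np.where(
            (yb == xa) & (xa != n_code) & (yb != n_code),
            scoring.match,
            scoring.mismatch,
        ).astype(np.int32)
        prev = H[a - 1]
        part = np.maximum(prev[0:bmax] + sub, prev[1 : bmax + 1] - g)
        np.maximum(part, 0, out=part)
        # left-gap chains: H[a][b] = max(part[b], H[a][b-1] - g), solved by scan
        idx = np.arange(1, bmax + 1, dtype=np.int64) * g
        chain = np.maximum.accumulate(part + idx) - idx
        H[a, 1 : bmax + 1] = np.maximum(part, chain)
    return H


def _traceback(H, X, Y, scoring, a, b):
    """Walk back from cell (a, b) preferring diagonal > up > left moves."""
    g = scoring.gap_penalty
    n_code = ord("N")
    matches = mismatches = gaps = 0
    while H[a, b] > 0:
        h = H[a, b]
        is_match = X[a - 1] == Y[b - 1] and X[a - 1] != n_code
        s = scoring.match if is_match else scoring.mismatch
        if h == H[a - 1, b - 1] + s:
            matches += int(is_match)
            mismatches += int(not is_match)
            a -= 1
            b -= 1
        elif h == H[a - 1, b] - g:
            gaps += 1
            a -= 1
        elif h == H[a, b - 1] - g:
            gaps += 1
            b -= 1
        else:  # pragma: no cover - recurrence guarantees a predecessor
            break
    return a, b, matches, mismatches, gaps


def _find_exact(contig: Contig, scoring: IRScoring) -> list[TIRPair]:
    seq = contig.seq
    n = len(seq)
    H = _exact_dp_matrix(seq, scoring)
    X = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    Y = np.frombuffer(revcomp(seq).encode("ascii"), dtype=np.uint8)
    cells = np.argwhere(H >= scoring.min_score)
    if len(cells) == 0:
        return []
    scores = H[cells[:, 0], cells[:, 1]]
    order = np.lexsort((cells[:, 1], cells[:, 0], -scores))
    accepted: list[TIRPair] = []
    for idx in order:
        a, b = int(cells[idx, 0]), int(cells[idx, 1])
        tip5, tip3 = a - 1, n - b  # inner-most consumed genome positions
        if any(
            p.arm5.start <= tip5 < p.arm5.end or p.arm3.start <= tip3 < p.arm3.end
            for p in accepted
        ):
            continue
        a0, b0, matches, mismatches, gaps = _traceback(H, X, Y, scoring, a, b)
        s1, e1 = a0, a
        s2, e2 = n - b, n - b0
        if e1 <= s1 or e2 <= s2:
            continue
        if e2 - s1 > scoring.max_separation:
            continue
        cand = _make_pair(
            contig.id, s1, e1, s2, e2, H[a, b], matches, mismatches, gaps
        )
        if any(
            cand.arm5.overlaps(p.arm5) or cand.arm3.overlaps(p.arm3)
            for p in accepted
        ):
            continue
        accepted.append(cand)
    accepted.sort(key=lambda p: (p.arm5.start, p.arm3.start))
    return accepted


# ---------------------------------------------------------------------------
# seeded path
# ---------------------------------------------------------------------------

_BASE_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


def _seed_pairs(seq: str, k: int, max_separation: int):
    """All (i, j) with S[i:i+k] == revcomp(S[j:j+k]), i+k <= j, span <= max_sep."""
    n = len(seq)
    if n < 2 * k:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    enc = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].astype(
        np.int64
    )
    m = n - k + 1
    fwd = np.zeros(m, dtype=np.int64)
    rc = np.zeros(m, dtype=np.int64)
    has_n = np.zeros(m, dtype=bool)
    for t in range(k):
        window = enc[t : t + m]
        fwd = fwd * 4 + window
        rc = rc + (3 - window) * (4**t)
        has_n |= window == 4
    valid = ~has_n
    vi = np.flatnonzero(valid)
    fc = fwd[vi]
    rcc = rc[vi]
    order = np.argsort(rcc, kind="stable")
    rcc_sorted = rcc[order]
    vj_sorted = vi[order]
    lo = np.searchsorted(rcc_sorted, fc, side="left")
    hi = np.searchsorted(rcc_sorted, fc, side="right")
    counts = hi - lo
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    i_rep = np.repeat(vi, counts)
    starts = np.cumsum(counts) - counts
    within = np.arange(total) - np.repeat(starts, counts)
    j_all = vj_sorted[np.repeat(lo, counts) + within]
    keep = (j_all >= i_rep + k) & (j_all + k - i_rep <= max_separation)
    return i_rep[keep], j_all[keep]


def _clusters(i_arr, j_arr, k, bucket_width=64, max_seed_gap=1500):
    """Group seeds sharing an anti-diagonal band into candidate arm loci."""
    d = i_arr + j_arr
    bucket = d // bucket_width
    order = np.lexsort((i_arr, bucket))
    i_s, j_s, b_s = i_arr[order], j_arr[order], bucket[order]
    if len(i_s) == 0:
        return []
    breaks = np.flatnonzero(
        (np.diff(b_s) != 0) | (np.diff(i_s) > max_seed_gap)
    )
    bounds = np.concatenate([[0], breaks + 1, [len(i_s)]])
    return [
        (i_s[lo:hi], j_s[lo:hi]) for lo, hi in zip(bounds[:-1], bounds[1:])
    ]


def _aligner(scoring: IRScoring, mode: str) -> Align.PairwiseAligner:
    mat = substitution_matrices.Array("ACGTN", dims=2)
    for x in "ACGTN":
        for y in "ACGTN":
            mat[x, y] = (
                scoring.match if (x == y and x != "N") else scoring.mismatch
            )
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = mat
    aligner.open_gap_score = -scoring.gap_penalty
    aligner.extend_gap_score = -scoring.gap_penalty
    return aligner


def _find_seeded(
    contig: Contig,
    scoring: IRScoring,
    seed_k: int,
    pad: int,
    min_seeds: int,
    min_extent: int,
) -> list[TIRPair]:
    seq = contig.seq
    n = len(seq)
    i_arr, j_arr = _seed_pairs(seq, seed_k, scoring.max_separation)
    aligner = _aligner(scoring, "local")
    candidates: list[TIRPair] = []
    for ci, cj in _clusters(i_arr, j_arr, seed_k):
        if len(ci) < min_seeds:
            continue
        imin, imax = int(ci.min()), int(ci.max())
        jmin, jmax = int(cj.min()), int(cj.max())
        if imax + seed_k - imin < min_extent:
            continue
        w5s, w5e = max(0, imin - pad), min(n, imax + seed_k + pad)
        w3s, w3e = max(0, jmin - pad), min(n, jmax + seed_k + pad)
        if w5e > w3s:  # keep candidate arm windows disjoint
            mid = (imax + seed_k + jmin) // 2
            w5e, w3s = min(w5e, mid), max(w3s, mid)
        if w5e - w5s < seed_k or w3e - w3s < seed_k:
            continue
        a_seq = seq[w5s:w5e]
        b_seq = revcomp(seq[w3s:w3e])
        alignments = aligner.align(a_seq, b_seq)
        if alignments.score < scoring.min_score:
            continue
        best = alignments[0]
        t_blocks, q_blocks = best.aligned
        t0, t1 = int(t_blocks[0][0]), int(t_blocks[-1][1])
        q0, q1 = int(q_blocks[0][0]), int(q_blocks[-1][1])
        s1, e1 = w5s + t0, w5s + t1
        s2, e2 = w3e - q1, w3e - q0
        if e1 > s2 or e2 - s1 > scoring.max_separation:
            continue
        counts = best.counts()
        candidates.append(
            _make_pair(
                contig.id,
                s1,
                e1,
                s2,
                e2,
                alignments.score,
                counts.identities,
                counts.mismatches,
                counts.gaps,
            )
        )
    return _dedup(candidates)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def find_inverted_repeats(
    contig: Contig,
    scoring: IRScoring = IRScoring(),
    *,
    exact_len_max: int = 2000,
    seed_k: int = 13,
    pad: int = 200,
    min_seeds: int = 3,
    min_extent: int = 25,
) -> list[TIRPair]:
    """Find inverted-repeat arm pairs on one contig.

    Contigs up to ``exact_len_max`` bp are searched exhaustively; longer
    contigs use reverse-complement k-mer seeding with local realignment.
    Reported scores are reproducible by globally aligning arm5 against
    revcomp(arm3) under the same scoring.
    """
    if contig.length <= exact_len_max:
        return _find_exact(contig, scoring)
    return _find_seeded(contig, scoring, seed_k, pad, min_seeds, min_extent)


def filter_candidates(
    pairs: list[TIRPair],
    min_insert: int = 6000,
    max_insert: int = 80000,
    min_tir: int = 100,
    max_tir: int = 8000,
) -> list[TIRPair]:
    """Apply the element-candidate size filters (bounds inclusive)."""
    return [
        p
        for p in pairs
        if min_insert <= p.insert.length <= max_insert
        and min_tir <= p.arm5_len <= max_tir
        and min_tir <= p.arm3_len <= max_tir
    ]


_IDENTITY_ALIGNER = Align.PairwiseAligner()
_IDENTITY_ALIGNER.mode = "global"
_IDENTITY_ALIGNER.match_score = 1
_IDENTITY_ALIGNER.mismatch_score = -1
_IDENTITY_ALIGNER.open_gap_score = -5
_IDENTITY_ALIGNER.extend_gap_score = -2


def tir_identity(pair: TIRPair, contig: Contig) -> float:
    """Percent identity of arm5 vs revcomp(arm3) under global affine alignment.

    Identity is matches over alignment columns (gapped columns included),
    times 100.
    """
    arm5 = contig.seq[pair.arm5.start : pair.arm5.end]
    arm3rc = revcomp(contig.seq[pair.arm3.start : pair.arm3.end])
    best = _IDENTITY_ALIGNER.align(arm5, arm3rc)[0]
    counts = best.counts()
    return 100.0 * counts.identities / best.length


def recompute_pair(pair: TIRPair, contig: Contig, scoring: IRScoring) -> TIRPair:
    """Re-score a pair by global alignment of its arms (integrity check)."""
    arm5 = contig.seq[pair.arm5.start : pair.arm5.end]
    arm3rc = revcomp(contig.seq[pair.arm3.start : pair.arm3.end])
    aligner = _aligner(scoring, "global")
    score = aligner.score(arm5, arm3rc)
    return replace(pair, score=int(score))
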