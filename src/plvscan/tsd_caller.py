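"""Target-site-duplication calling from element flanks.

Integrase-mediated insertion duplicates a short stretch of host sequence on
both sides of the element. The caller extracts 50 bp flanks, then slides and
pads: every combination of duplication length (4-25 bp) and per-side offset
(0-3 bp between the TIR boundary and the duplication copy) is scored, and the
best mismatch-bounded candidate is reported. Short homopolymeric matches are
flagged as low complexity (spurious rather than integrase-generated).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, replace

from .seq_io import Contig, Interval, revcomp

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TSDCall:
    element_id: str | None
    left_copy: str
    right_copy: str
    consensus: str
    length_bp: int
    n_mismatches: int
    left_offset_bp: int
    right_offset_bp: int
    low_complexity: bool
    # inward corrections (bp) applied to the element boundary by the
    # junction-aware caller; offsets are relative to the corrected boundary
    shift_left_bp: int = 0
    shift_right_bp: int = 0

    @property
    def score(self) -> int:
        return (self.length_bp - self.n_mismatches) - self.n_mismatches


@dataclass(frozen=True)
class TSDConservation:
    """Per-genome summary: fraction of elements with a credible TSD."""

    n_elements: int
    n_conserved: int  # call present, mismatches within cap, not low-complexity
    n_exact: int  # as above but with zero mismatches

    @property
    def frac_conserved(self) -> float | None:
        if self.n_elements == 0:
            return None
        return self.n_conserved / self.n_elements

    @property
    def frac_exact(self) -> float | None:
        if self.n_elements == 0:
            return None
        return self.n_exact / self.n_elements


def extract_flanks(
    contig: Contig, element: Interval, flank_bp: int = 50
) -> tuple[str, str]:
    """Sequence immediately 5' and 3' of an element, truncated at contig ends."""
    if element.contig_id != contig.id or element.end > contig.length:
        raise ValueError("element does not lie inside contig")
    left = contig.seq[max(0, element.start - flank_bp) : element.start]
    right = contig.seq[element.end : element.end + flank_bp]
    if len(left) < flank_bp or len(right) < flank_bp:
        logger.warning(
            "element %s:%d-%d is near a contig edge; flanks truncated to %d/%d bp",
            contig.id,
            element.start,
            element.end,
            len(left),
            len(right),
        )
    return left, right


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def flag_low_complexity(tsd: str) -> bool:
    """True when the motif has <= 2 distinct bases or one base at >= 80%."""
    if not tsd:
        raise ValueError("empty TSD sequence")
    counts = Counter(tsd)
    return len(counts) <= 2 or max(counts.values()) / len(tsd) >= 0.8


def _search_tsd(
    left: str,
    right: str,
    min_tsd: int,
    max_tsd: int,
    max_offset: int,
    max_mismatch: int,
    asym_penalty: int,
):
    """Exhaustive candidate search over (length, left offset, right offset).

    ``asym_penalty`` docks the score per bp of |o_l - o_r|: a register that
    pairs the two copies at unequal offsets can extend a true duplication by
    chance columns, which a symmetric register cannot, so the pipeline's
    boundary-tolerant caller discounts such candidates. The standalone
    caller uses 0 (pure matches - mismatches).
    """
    best = None
    best_key = None
    for L in range(min_tsd, max_tsd + 1):
        for o_l in range(0, max_offset + 1):
            if o_l + L > len(left):
                continue
            left_copy = left[len(left) - o_l - L : len(left) - o_l]
            for o_r in range(0, max_offset + 1):
                if o_r + L > len(right):
                    continue
                right_copy = right[o_r : o_r + L]
                mism = _hamming(left_copy, right_copy)
                if mism > max_mismatch or mism > L // 5:
                    continue
                score = (L - mism) - mism - asym_penalty * abs(o_l - o_r)
                key = (score, L, -(o_l + o_r), -mism)
                if best_key is None or key > best_key:
                    best_key = key
                    best = (left_copy, right_copy, mism, o_l, o_r, score)
    return best


def call_tsd(
    left: str,
    right: str,
    min_tsd: int = 4,
    max_tsd: int = 25,
    max_offset: int = 3,
    max_mismatch: int = 2,
    element_id: str | None = None,
) -> TSDCall | None:
    """Exhaustive sliding/padding search for a duplicated flank motif.

    For every length L in [min_tsd, max_tsd] and offsets (o_l, o_r) in
    [0, max_offset]^2, the left copy is the last L bases of the left flank
    before an o_l-bp pad and the right copy the first L bases of the right
    flank after an o_r-bp pad. A candidate is valid when its Hamming mismatch
    count is <= max_mismatch and <= floor(L/5). The best candidate maximizes
    matches - mismatches; ties break toward longer L, then smaller total
    offset, then fewer mismatches. The consensus takes the left-copy base at
    mismatched positions.
    """
    if not left or not right:
        raise ValueError("flanks must be non-empty")
    best = _search_tsd(
        left, right, min_tsd, max_tsd, max_offset, max_mismatch, 0
    )
    if best is None:
        return None
    left_copy, right_copy, mism, o_l, o_r, _ = best
    return TSDCall(
        element_id=element_id,
        left_copy=left_copy,
        right_copy=right_copy,
        consensus=left_copy,
        length_bp=len(left_copy),
        n_mismatches=mism,
        left_offset_bp=o_l,
        right_offset_bp=o_r,
        low_complexity=flag_low_complexity(left_copy),
    )


def _near_rc_palindrome(s: str) -> bool:
    """True when s equals its reverse complement at register shift -1/0/+1.

    A spurious duplication candidate drawn from within a TIR arm pairs a
    stretch against its own mirror image (possibly one column out of
    register), so its copies are forced into this structure; genuine host
    duplications have it only by chance.
    """
    rc = revcomp(s)
    return s == rc or s[1:] == rc[:-1] or s[:-1] == rc[1:]


def call_tsd_near_boundary(
    contig: Contig,
    element: Interval,
    flank_bp: int = 50,
    junction_slop: int = 20,
    min_tsd: int = 4,
    max_tsd: int = 25,
    max_offset: int = 3,
    max_mismatch: int = 2,
    element_id: str | None = None,
) -> TSDCall | None:
    """TSD call tolerant of TIR/TSD junction ambiguity.

    When the host base just outside one TIR complements the base outside the
    other — systematically the case across a reverse-complement-palindromic
    duplication — the inverted-repeat alignment extends symmetrically past
    the true junction and the reported element boundary swallows the TSD (and
    can drift further on chance matches). This wrapper reruns the caller at
    symmetric inward boundary shifts e = 0..junction_slop and keeps the
    best-scoring call. A shifted call reinterprets alignment columns as
    duplication sequence, so at e > 0 the copies must abut the shifted
    boundary exactly (offsets 0) and match perfectly: requiring zero
    mismatches stops chance mismatch-budget candidates from hijacking deep
    shifts, while a genuinely swallowed duplication scores its full length
    and beats the truncated unshifted reading. Ties go to the smaller shift.
    Beyond 5 bp the candidate must additionally be non-palindromic under
    reverse complement: a spurious deep candidate drawn from within a TIR arm
    pairs a stretch with its own mirror image and is therefore always an
    rc-palindrome, whereas shallow spurious shifts (<= 5 bp) cannot push a
    boundary materially. The winning shift is reported in
    ``boundary_shift_bp`` so the element boundary itself can be corrected;
    offsets are relative to the corrected boundary.
    """
    best_call = None
    best_key = None
    # Symmetric shifts are evaluated first. Off-by-one asymmetric shifts
    # (a gapped over-extension can leave the sides one column apart) are
    # considered afterwards but must beat the best symmetric reading by >= 2:
    # a candidate that keeps the register of a shallower duplication while
    # annexing one chance junction column gains exactly +1 and so never
    # clears the margin.
    shift_pairs = [(e, e) for e in range(0, junction_slop + 1)]
    shift_pairs += [
        p
        for e in range(1, junction_slop + 1)
        for p in ((e, e - 1), (e - 1, e))
    ]
    for e_l, e_r in shift_pairs:
        e = max(e_l, e_r)
        start, end = element.start + e_l, element.end - e_r
        if start >= end:
            break
        left = contig.seq[max(0, start - flank_bp) : start]
        right = contig.seq[end : end + flank_bp]
        if not left or not right:
            continue
        if e == 0:
            min_len = min_tsd
        elif e <= 5:
            min_len = max(min_tsd, 5)
        else:  # deep shifts demand longer, fully matching evidence
            min_len = max(min_tsd, 6)
        found = _search_tsd(
            left,
            right,
            min_len,
            max_tsd,
            max_offset if e == 0 else 0,
            max_mismatch if e == 0 else 0,
            asym_penalty=2,
        )
        if found is None:
            continue
        left_copy, right_copy, mism, o_l, o_r, score = found
        if e > 5 and _near_rc_palindrome(left_copy):
            continue
        if e_l != e_r:
            if best_key is not None and score < best_key[0] + 2:
                continue
            score -= 1  # asymmetric readings rank below symmetric peers
        key = (score, -e, len(left_copy), -mism)
        if best_key is None or key > best_key:
            best_key = key
            best_call = TSDCall(
                element_id=element_id,
                left_copy=left_copy,
                right_copy=right_copy,
                consensus=left_copy,
                length_bp=len(left_copy),
                n_mismatches=mism,
                left_offset_bp=o_l,
                right_offset_bp=o_r,
                low_complexity=flag_low_complexity(left_copy),
                shift_left_bp=e_l,
                shift_right_bp=e_r,
            )
    return best_call


def tsd_conservation_summary(
    calls: dict[str, TSDCall | None],
    element_ids: list[str],
    max_mismatch: int = 2,
) -> TSDConservation:
    """Fraction of elements carrying a credible (non-flagged) TSD call.

    The strict numerator (zero mismatches) is reported alongside, since
    "conserved" may reasonably mean exact duplication.
    """
    n_conserved = n_exact = 0
    for eid in element_ids:
        call = calls.get(eid)
        if call is None or call.low_complexity or call.n_mismatches > max_mismatch:
            continue
        n_conserved += 1
        if call.n_mismatches == 0:
            n_exact += 1
    if not element_ids:
        logger.warning("TSD conservation summary over zero elements: not available")
    return TSDConservation(len(element_ids), n_conserved, n_exact)
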