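"""Sequence-based poly(A) tail calling.

The tail is read from the clip bases lying between the aligned 3' end and
the 3' ligation adapter, in biological orientation.  A tail is the longest
A-dominated interval (purity >= ``min_purity``) whose endpoints are A and
which is anchored to a segment boundary: at most ``anchor_nt`` *non-A*
bases may separate it from the alignment end or from the adapter.  The
anchor keeps internal A-rich genomic stretches from being mistaken for a
tail, and counting only non-A bases makes the call monotone under
elongation (appending A's can never shrink a tail).  Ties between
equal-length candidates resolve toward the alignment end, where the
templated cleavage position sits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

__all__ = ["TailCall", "call_tail", "write_tails_tsv"]

MIN_PURITY = 0.85
ANCHOR_NT = 5


@dataclass(frozen=True)
class TailCall:
    read_id: str
    tail_length: int
    purity: float  # A fraction in the called tail; 1.0 by convention when empty
    tail_span: tuple[int, int] = (0, 0)  # [start, end) within the segment


def call_tail(
    read_id: str,
    segment: str,
    min_purity: float = MIN_PURITY,
    anchor_nt: int = ANCHOR_NT,
) -> TailCall:
    """Call the poly(A) tail within a 3'-clip ``segment``.

    ``segment`` runs from the aligned 3' end (position 0) to the adapter,
    already in biological orientation (tails on '-' alignments must be
    reverse-complemented by the caller; :mod:`nanoterm.read_ingest` does).
    """
    n = len(segment)
    if n == 0:
        return TailCall(read_id, 0, 1.0)
    is_a = [c in "Aa" for c in segment]
    prefix = [0] * (n + 1)
    for i, a in enumerate(is_a):
        prefix[i + 1] = prefix[i] + a
    a_positions = [i for i, a in enumerate(is_a) if a]
    if not a_positions:
        return TailCall(read_id, 0, 1.0)

    def non_a_before(i: int) -> int:
        return i - prefix[i]

    def non_a_after(j: int) -> int:
        return (n - j) - (prefix[n] - prefix[j])

    best: tuple[int, int, int] | None = None  # (-length, start, end)
    for i in a_positions:
        if best is not None and (n - i) < -best[0]:
            break  # no interval starting here can beat the incumbent
        for j in reversed(a_positions):
            if j < i:
                break
            length = j - i + 1
            if best is not None and length < -best[0]:
                break
            if non_a_before(i) > anchor_nt and non_a_after(j + 1) > anchor_nt:
                continue  # not anchored at either boundary
            a_count = prefix[j + 1] - prefix[i]
            if a_count / length >= min_purity:
                cand = (-length, i, j + 1)
                if best is None or cand < best:
                    best = cand
                break  # longest purity-passing end for this start
    if best is None:
        return TailCall(read_id, 0, 1.0)
    _, s, e = best
    a_count = prefix[e] - prefix[s]
    return TailCall(read_id, e - s, a_count / (e - s), (s, e))


def write_tails_tsv(calls: Iterable[TailCall], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\ttail_length\tpurity\n")
        for c in calls:
            fh.write(f"{c.read_id}\t{c.tail_length}\t{c.purity:.4f}\n")
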