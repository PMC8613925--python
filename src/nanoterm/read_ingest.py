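"""Alignment filtering, soft-clip adapter search, and read orientation.

Full-length nascent-RNA cDNA reads carry a template-switch oligo (TSO) at
the biological 5' end and a ligation adapter at the biological 3' end.
Finding both in the soft clips (a) certifies that neither end of the RNA
was truncated and (b) fixes the read's biological strand, independent of
the alignment strand.  Reads missing either adapter are never emitted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import edlib
import pysam

__all__ = [
    "TSO_SEQ",
    "ADAPTER3_SEQ",
    "FLAG_FILTER_MASK",
    "AlignmentRecord",
    "AdapterHit",
    "OrientedRead",
    "filter_alignments",
    "find_adapter",
    "orient_read",
    "ingest_bam",
    "write_reads_tsv",
]

#: template-switching oligo searched at the biological 5' end (terminal GGG kept)
TSO_SEQ = "AAGCAGTGGTATCAACGCAGAGTACATGGG"
#: 3' ligation adapter searched at the biological 3' end
ADAPTER3_SEQ = "ATTGATGGTGCCTACAG"

#: unmapped (4) + secondary (256) + supplementary (2048)
FLAG_FILTER_MASK = 2308

#: aligned bases adjacent to the clip included in the adapter search space
FLANK_NT = 20

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class AlignmentRecord:
    """A primary alignment reduced to what adapter search needs."""

    read_id: str
    chrom: str
    aln_strand: str
    aln_start: int
    aln_end: int
    left_clip_seq: str
    right_clip_seq: str
    left_flank_seq: str
    right_flank_seq: str
    mapq: int
    flags: int


@dataclass(frozen=True)
class AdapterHit:
    adapter: str          # "TSO" or "ADAPTER3"
    clip_side: str        # "left" or "right"
    offset_from_alignment: int  # proximal adapter edge relative to the alignment boundary
    edit_distance: int
    matched_span: tuple[int, int] = (0, 0)  # [start, end) within the clip (flank excluded)


@dataclass(frozen=True)
class OrientedRead:
    """A read with certified biological ends.

    ``five_prime_pos``/``three_prime_pos`` are the genomic coordinates of the
    aligned portion's biological ends (half-open convention: the 3' end on
    '+' is the exclusive alignment end).  ``three_prime_gap`` is the number
    of read bases between the alignment end and the 3' adapter — for
    polyadenylated reads this contains the tail, so ``tail_segment`` holds
    that stretch in biological orientation for the tail caller.
    """

    read_id: str
    chrom: str
    bio_strand: str
    five_prime_pos: int
    three_prime_pos: int
    three_prime_gap: int
    tso_hit: AdapterHit
    adapter3_hit: AdapterHit
    tail_segment: str = ""


def _clips_and_flanks(aln: pysam.AlignedSegment) -> tuple[str, str, str, str]:
    seq = aln.query_sequence or ""
    cig = aln.cigartuples or []
    left = cig[0][1] if cig and cig[0][0] == 4 else 0
    right = cig[-1][1] if cig and cig[-1][0] == 4 else 0
    aligned = seq[left: len(seq) - right if right else len(seq)]
    return (
        seq[:left],
        seq[len(seq) - right:] if right else "",
        aligned[:FLANK_NT],
        aligned[-FLANK_NT:] if aligned else "",
    )


def filter_alignments(
    alignments: Iterable[pysam.AlignedSegment], min_mapq: int = 0
) -> Iterator[AlignmentRecord]:
    """Drop unmapped/secondary/supplementary records (flag mask 2308) and
    records below ``min_mapq``; convert survivors to AlignmentRecord."""
    for aln in alignments:
        if aln.flag & FLAG_FILTER_MASK:
            continue
        if aln.mapping_quality < min_mapq:
            continue
        lclip, rclip, lflank, rflank = _clips_and_flanks(aln)
        yield AlignmentRecord(
            read_id=aln.query_name,
            chrom=aln.reference_name,
            aln_strand="-" if aln.is_reverse else "+",
            aln_start=aln.reference_start,
            aln_end=aln.reference_end,
            left_clip_seq=lclip,
            right_clip_seq=rclip,
            left_flank_seq=lflank,
            right_flank_seq=rflank,
            mapq=aln.mapping_quality,
            flags=aln.flag,
        )


def _edlib_best(query: str, text: str, k: int) -> tuple[int, list[tuple[int, int]]] | None:
    if not text:
        return None
    res = edlib.align(query, text, mode="HW", task="locations", k=k)
    if res["editDistance"] < 0:
        return None
    locs = [(s, e + 1) for s, e in res["locations"]]
    return res["editDistance"], locs


def find_adapter(
    clip_seq: str,
    flank_seq: str,
    adapter_seq: str,
    max_edits: int,
    side: str = "right",
    min_overlap: int = 12,
) -> AdapterHit | None:
    """Best semi-global match of ``adapter_seq`` in clip + 20-nt aligned flank.

    ``side`` names which clip is searched: for a left clip the flank sits to
    the right of the clip and the adapter may be 5'-truncated at the read
    start; for a right clip the flank sits to the left and the adapter may be
    3'-truncated at the read end.  Truncated terminal matches are accepted
    down to ``min_overlap`` adapter bases with a proportionally scaled edit
    budget.  On ties the hit nearest the alignment boundary wins.
    """
    if not adapter_seq:
        raise ValueError("adapter_seq must be non-empty")
    if side == "left":
        text = clip_seq + flank_seq
        boundary = len(clip_seq)  # alignment starts here
    else:
        text = flank_seq + clip_seq
        boundary = len(flank_seq)  # alignment ends here

    candidates: list[tuple[float, int, int, int, int]] = []

    def consider(query: str, k_budget: int, trunc: int) -> None:
        best = _edlib_best(query, text, k_budget)
        if best is None:
            return
        dist, locs = best
        for s, e in locs:
            # offset of the adapter's proximal edge from the alignment boundary
            off = boundary - e if side == "left" else s - boundary
            # rank: untruncated first, then fewest edits, then closest to boundary
            candidates.append((trunc + dist / len(adapter_seq), dist, abs(off), off, (s, e)))

    consider(adapter_seq, max_edits, 0)
    if len(clip_seq) < len(adapter_seq) and not candidates:
        # terminal truncation: the distal adapter end may be missing
        for keep in range(len(adapter_seq) - 1, min_overlap - 1, -1):
            sub = adapter_seq[-keep:] if side == "left" else adapter_seq[:keep]
            k = max(0, int(round(max_edits * keep / len(adapter_seq))))
            consider(sub, k, 1)
            if candidates:
                break
    if not candidates:
        return None
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    _, dist, _, off, (s, e) = candidates[0]
    # matched span reported in clip coordinates, clamped to the clip
    if side == "left":
        span = (max(0, s), min(len(clip_seq), e))
    else:
        span = (max(0, s - len(flank_seq)), max(0, e - len(flank_seq)))
    return AdapterHit(
        adapter="", clip_side=side, offset_from_alignment=off,
        edit_distance=dist, matched_span=span,
    )


def _named(hit: AdapterHit | None, adapter: str) -> AdapterHit | None:
    if hit is None:
        return None
    return AdapterHit(adapter, hit.clip_side, hit.offset_from_alignment,
                      hit.edit_distance, hit.matched_span)


def orient_read(
    rec: AlignmentRecord,
    max_edits_tso: int = 6,
    max_edits_a3: int = 4,
    min_overlap: int = 12,
) -> OrientedRead | None:
    """Search both adapters in both clips and fix the biological strand.

    On a forward alignment of a sense-strand cDNA the TSO is in the left
    clip and the 3' adapter in the right clip; a reverse alignment carries
    both as reverse complements on swapped sides.  Conflicting or missing
    hits return ``None`` — only double-adapter reads are trusted.
    """
    # '+' configuration: TSO left (as printed), ADAPTER3 right (as printed)
    tso_fwd = find_adapter(rec.left_clip_seq, rec.left_flank_seq, TSO_SEQ,
                           max_edits_tso, "left", min_overlap)
    a3_fwd = find_adapter(rec.right_clip_seq, rec.right_flank_seq, ADAPTER3_SEQ,
                          max_edits_a3, "right", min_overlap)
    # '-' configuration: both reverse-complemented, sides swapped
    tso_rev = find_adapter(rec.right_clip_seq, rec.right_flank_seq, revcomp(TSO_SEQ),
                           max_edits_tso, "right", min_overlap)
    a3_rev = find_adapter(rec.left_clip_seq, rec.left_flank_seq, revcomp(ADAPTER3_SEQ),
                          max_edits_a3, "left", min_overlap)

    def pick(fwd: AdapterHit | None, rev: AdapterHit | None) -> tuple[str, AdapterHit] | None:
        if fwd is not None and (rev is None or fwd.edit_distance <= rev.edit_distance):
            return "+", fwd
        if rev is not None:
            return "-", rev
        return None

    tso = pick(tso_fwd, tso_rev)
    a3 = pick(a3_fwd, a3_rev)
    if tso is None or a3 is None or tso[0] != a3[0]:
        return None
    strand, tso_hit = tso
    _, a3_hit = a3

    if strand == "+":
        five, three = rec.aln_start, rec.aln_end
        # clip bases between the alignment end and the adapter start
        tail_segment = rec.right_clip_seq[: a3_hit.matched_span[0]]
    else:
        five, three = rec.aln_end, rec.aln_start
        # reference-forward left clip holds revcomp(adapter) then revcomp(tail)
        tail_segment = revcomp(rec.left_clip_seq[a3_hit.matched_span[1]:])
    return OrientedRead(
        read_id=rec.read_id,
        chrom=rec.chrom,
        bio_strand=strand,
        five_prime_pos=five,
        three_prime_pos=three,
        three_prime_gap=max(0, a3_hit.offset_from_alignment),
        tso_hit=_named(tso_hit, "TSO"),
        adapter3_hit=_named(a3_hit, "ADAPTER3"),
        tail_segment=tail_segment,
    )


def ingest_bam(
    path: str,
    min_mapq: int = 0,
    max_edits_tso: int = 6,
    max_edits_a3: int = 4,
    min_overlap: int = 12,
) -> tuple[list[OrientedRead], dict[str, int]]:
    """Stream a SAM/BAM file into oriented reads plus stage counts."""
    counts = {"input": 0, "primary": 0, "double_adapter": 0}
    out: list[OrientedRead] = []
    with pysam.AlignmentFile(path, check_sq=False) as fh:

        def counted() -> Iterator[pysam.AlignedSegment]:
            for aln in fh:
                counts["input"] += 1
                yield aln

        for rec in filter_alignments(counted(), min_mapq=min_mapq):
            counts["primary"] += 1
            oread = orient_read(rec, max_edits_tso, max_edits_a3, min_overlap)
            if oread is not None:
                counts["double_adapter"] += 1
                out.append(oread)
    return out, counts


def write_reads_tsv(reads: Iterable[OrientedRead], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tchrom\tbio_strand\tfive_prime_pos\tthree_prime_pos\t"
                 "tso_edit\tadapter3_edit\tthree_prime_gap\n")
        for r in reads:
            fh.write(f"{r.read_id}\t{r.chrom}\t{r.bio_strand}\t{r.five_prime_pos}\t"
                     f"{r.three_prime_pos}\t{r.tso_hit.edit_distance}\t"
                     f"{r.adapter3_hit.edit_distance}\t{r.three_prime_gap}\n")
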