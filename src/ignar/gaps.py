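"""Assembly N-gap resolution from locally mapped read pairs.

Automates the manual workflow of extracting read pairs mapped around an
assembly gap and stitching the missing sequence back together: N-runs are
located, flanking pairs collected from a SAM file, and the gap filled by
greedy overlap-consensus extension from the left flank until the right-flank
anchor is reached.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple, Union

from .models import GapRecord, MappedRead, ReadPair

_N_RUN = re.compile(r"N+")


def find_gaps(scaffold: str, min_run: int = 10,
              scaffold_name: str = "scaffold",
              flank_window: int = 500) -> List[GapRecord]:
    """Maximal runs of N of length >= min_run, in coordinate order."""
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    gaps = []
    for m in _N_RUN.finditer(scaffold):
        if m.end() - m.start() >= min_run:
            gaps.append(GapRecord(scaffold=scaffold_name, start=m.start(),
                                  end=m.end(), flank_window=flank_window))
    return gaps


def _pairs_from_alignments(records) -> List[ReadPair]:
    by_name: dict = {}
    for rec in records:
        if rec.is_unmapped:
            continue
        read = MappedRead(
            name=rec.query_name,
            seq=rec.query_sequence or "",
            start=rec.reference_start,
            end=rec.reference_end,
            strand="-" if rec.is_reverse else "+",
        )
        by_name.setdefault(rec.query_name, []).append(read)
    pairs = []
    for name, mates in sorted(by_name.items()):
        r1 = mates[0]
        r2 = mates[1] if len(mates) > 1 else None
        pairs.append(ReadPair(name=name, read1=r1, read2=r2,
                              proper_pair=r2 is not None))
    return pairs


def collect_flanking_reads(alignments, gap: GapRecord) -> List[ReadPair]:
    """Read pairs with at least one mate overlapping the gap's flank window.

    *alignments* may be a SAM path, an open ``pysam.AlignmentFile``, or an
    iterable of aligned segments.  Pairs whose mates sit on opposite flanks
    of the gap are flagged as straddling.  SAM stores sequences in scaffold
    (forward) orientation, so no re-complementing is needed downstream.
    """
    import pysam

    if isinstance(alignments, (str, bytes)) or hasattr(alignments, "__fspath__"):
        with pysam.AlignmentFile(str(alignments), "r") as fh:
            pairs = _pairs_from_alignments(fh)
    else:
        pairs = _pairs_from_alignments(alignments)

    win_start = gap.start - gap.flank_window
    win_end = gap.end + gap.flank_window
    selected = []
    for pair in pairs:
        mates = pair.mates()
        if not any(m.start < win_end and m.end > win_start for m in mates):
            continue
        straddles = (
            len(mates) == 2
            and ((mates[0].end <= gap.start and mates[1].start >= gap.end)
                 or (mates[1].end <= gap.start and mates[0].start >= gap.end))
        )
        selected.append(ReadPair(name=pair.name, read1=pair.read1,
                                 read2=pair.read2, proper_pair=pair.proper_pair,
                                 straddles_gap=straddles))
    return selected


@dataclass(frozen=True)
class GapFill:
    """Result of one gap assembly attempt."""

    gap: GapRecord
    status: str  # "filled" | "unfillable" | "unjoined"
    fill: str = ""
    support: Tuple[int, ...] = ()

    @property
    def min_support(self) -> int:
        return min(self.support) if self.support else 0


def _best_overlap(contig: str, seq: str, min_overlap: int,
                  max_mismatch: int) -> Optional[int]:
    """Longest ov >= min_overlap where contig's suffix matches seq's prefix
    with <= max_mismatch mismatches and seq extends past the contig."""
    max_ov = min(len(contig), len(seq) - 1)  # require non-empty extension
    for ov in range(max_ov, min_overlap - 1, -1):
        mm = 0
        tail = contig[len(contig) - ov:]
        ok = True
        for a, b in zip(tail, seq):
            if a != b:
                mm += 1
                if mm > max_mismatch:
                    ok = False
                    break
        if ok:
            return ov
    return None


def assemble_gap(pairs: Sequence[ReadPair], gap: GapRecord, scaffold: str,
                 min_overlap: int = 30, max_mismatch: int = 1,
                 anchor_len: int = 50,
                 max_extension: Optional[int] = None) -> GapFill:
    """Reconstruct the gap sequence by greedy overlap extension.

    The contig is seeded with the known left-flank anchor; at every step all
    reads whose prefix overlaps the contig suffix by at least *min_overlap*
    with at most *max_mismatch* mismatches become extension candidates, the
    appended bases are decided by majority vote among candidates (ties go to
    the candidate with the longest overlap, then the lexicographically
    smallest read name), and extension stops once the right-flank anchor
    appears in the contig.  Returns "unfillable" when no read anchors the
    left flank and "unjoined" when the flanks cannot be connected.
    """
    left_start = max(0, gap.start - anchor_len)
    left_anchor = scaffold[left_start:gap.start]
    if "N" in left_anchor:
        left_anchor = left_anchor[left_anchor.rfind("N") + 1:]
    right_anchor = scaffold[gap.end:gap.end + anchor_len]
    if "N" in right_anchor:
        right_anchor = right_anchor[:right_anchor.index("N")]
    ra_probe = right_anchor[:max(min_overlap, 1)]
    if not left_anchor or not ra_probe:
        return GapFill(gap=gap, status="unfillable")

    reads: List[Tuple[str, str]] = []
    seen = set()
    max_read_len = 0
    for pair in pairs:
        for mate in pair.mates():
            if mate.seq and (mate.name, mate.seq) not in seen:
                seen.add((mate.name, mate.seq))
                reads.append((mate.name, mate.seq))
                max_read_len = max(max_read_len, len(mate.seq))
    if not reads:
        return GapFill(gap=gap, status="unfillable")

    if max_extension is None:
        max_extension = gap.length + 4 * max_read_len + len(right_anchor)

    contig = left_anchor
    support: List[int] = []
    first_step = True
    while True:
        idx = contig.find(ra_probe, len(left_anchor))
        if idx != -1:
            fill = contig[len(left_anchor):idx]
            return GapFill(gap=gap, status="filled", fill=fill,
                           support=tuple(support[:len(fill)]))
        if len(contig) - len(left_anchor) > max_extension:
            return GapFill(gap=gap, status="unjoined")

        candidates = []
        for name, seq in reads:
            ov = _best_overlap(contig, seq, min_overlap, max_mismatch)
            if ov is not None:
                candidates.append((ov, name, seq))
        if not candidates:
            return GapFill(gap=gap,
                           status="unfillable" if first_step else "unjoined")
        first_step = False
        # best candidate: longest overlap, then smallest name
        candidates.sort(key=lambda c: (-c[0], c[1]))
        best_ov, _, best_seq = candidates[0]
        ext_len = len(best_seq) - best_ov
        new_bases = []
        for j in range(ext_len):
            votes: dict = {}
            for ov, _, seq in candidates:
                if ov + j < len(seq):
                    base = seq[ov + j]
                    votes[base] = votes.get(base, 0) + 1
            best_base = best_seq[best_ov + j]
            chosen = max(votes, key=lambda b: (votes[b], b == best_base, b))
            new_bases.append(chosen)
            support.append(votes[chosen])
        contig += "".join(new_bases)


def patch_scaffold(scaffold: str, gap: GapRecord,
                   fill: str) -> Tuple[str, List[Tuple[int, int]]]:
    """Replace the gap's N-run with *fill*.

    Returns the patched scaffold and a coordinate-offset table: positions at
    or beyond the original gap end shift by ``len(fill) - gap.length``.
    """
    if not fill:
        raise ValueError("fill must be non-empty")
    if "N" in fill:
        raise ValueError("fill must not contain N")
    if scaffold[gap.start:gap.end].strip("N"):
        raise ValueError("gap span does not cover an N-run")
    patched = scaffold[:gap.start] + fill + scaffold[gap.end:]
    offsets = [(gap.end, len(fill) - gap.length)]
    return patched, offsets
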