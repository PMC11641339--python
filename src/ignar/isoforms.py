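"""Isoform reconstruction from spliced alignments.

Splice junctions are read off alignment CIGAR skip operations, fragments are
grouped by their maximal junction chain (the isoform signature), chains are
mapped back onto a locus model to name the domain content of each isoform,
and locus expression is quantified in FPKM.
"""
from __future__ import annotations

import re
from typing import Dict, List, Optional, Sequence, Tuple

from .models import (
    CONSTANT_DOMAINS,
    ExpressionRecord,
    IsoformCall,
    JunctionChain,
    LocusModel,
    SplicedAlignment,
)

_CIGAR_TOKEN = re.compile(r"(\d+)([A-Za-z=])")


def blocks_from_alignment(pos: int, cigar: str) -> Tuple[Tuple[int, int], ...]:
    """Genomic match blocks of an alignment (0-based half-open intervals).

    *pos* is the 1-based leftmost mapping position as in SAM.  M and D
    consume reference into the current block, N closes the block and opens
    the next, S and I consume no reference.  Other operations are rejected.
    """
    if pos < 1:
        raise ValueError("pos must be a 1-based position >= 1")
    consumed = sum(len(m.group(0)) for m in _CIGAR_TOKEN.finditer(cigar))
    if consumed != len(cigar) or not cigar:
        raise ValueError(f"malformed CIGAR string: {cigar!r}")
    blocks: List[Tuple[int, int]] = []
    cur_start = pos - 1
    cur_len = 0
    for m in _CIGAR_TOKEN.finditer(cigar):
        n, op = int(m.group(1)), m.group(2)
        if op in ("M", "D"):
            cur_len += n
        elif op == "N":
            if cur_len == 0:
                raise ValueError(f"malformed CIGAR: skip before match in {cigar!r}")
            blocks.append((cur_start, cur_start + cur_len))
            cur_start += cur_len + n
            cur_len = 0
        elif op in ("S", "I"):
            pass
        else:
            raise ValueError(f"unsupported CIGAR operation {n}{op!r}")
    if cur_len > 0:
        blocks.append((cur_start, cur_start + cur_len))
    return tuple(blocks)


def read_spliced_alignments(sam_path) -> List[SplicedAlignment]:
    """Load mapped records from a SAM file as spliced alignment blocks."""
    import pysam

    out = []
    with pysam.AlignmentFile(str(sam_path), "r") as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            out.append(SplicedAlignment(
                fragment_id=rec.query_name,
                blocks=blocks_from_alignment(rec.reference_start + 1,
                                             rec.cigarstring)))
    return out


def collapse_isoforms(alignments: Sequence[SplicedAlignment],
                      min_support: int = 2) -> List[JunctionChain]:
    """Group fragments by identical junction chain.

    Fragments without junctions form a single unspliced class.  Chains with
    support below *min_support* are dropped.  Output is sorted by support
    (descending) then leftmost coordinate.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    groups: Dict[Tuple, List[SplicedAlignment]] = {}
    for aln in alignments:
        groups.setdefault(aln.junctions(), []).append(aln)
    chains = []
    for junctions, members in groups.items():
        if len(members) < min_support:
            continue
        leftmost = min(a.blocks[0][0] for a in members)
        chains.append(JunctionChain(junctions=junctions,
                                    support=len(members), leftmost=leftmost))
    chains.sort(key=lambda c: (-c.support, c.leftmost, c.junctions))
    return chains


def assign_domains(chain: JunctionChain, locus: LocusModel) -> IsoformCall:
    """Map a junction chain onto a locus model's exons and domains.

    Every junction must land on exon boundaries; junctions that do not are
    reported as novel and the domain content is best-effort.  The short-form
    flag is set when the C4 and C5 exons are both skipped while C1-C3 are
    retained; skipping only one of them is flagged atypical instead.
    """
    end_to_exon = {e: i for i, (s, e) in enumerate(locus.exons)}
    start_to_exon = {s: i for i, (s, e) in enumerate(locus.exons)}

    exon_indices: List[int] = []
    novel: List[Tuple[int, int]] = []
    for donor, acceptor in chain.junctions:
        d = end_to_exon.get(donor)
        a = start_to_exon.get(acceptor)
        if d is None or a is None:
            novel.append((donor, acceptor))
            continue
        if not exon_indices or exon_indices[-1] != d:
            exon_indices.append(d)
        exon_indices.append(a)

    domains = tuple(locus.domain_map[i] for i in exon_indices)
    present = set(domains)
    c4, c5 = "C4" in present, "C5" in present
    core = {"C1", "C2", "C3"} <= present
    short_form = core and not c4 and not c5
    atypical = core and (c4 != c5)
    return IsoformCall(chain=chain, exon_indices=tuple(exon_indices),
                       domains=domains, short_form=short_form,
                       novel_junctions=tuple(novel), atypical=atypical)


def compute_fpkm(fragments: int, exonic_length: int, total_fragments: int,
                 locus: str = "") -> ExpressionRecord:
    """Fragments per kilobase of exonic model per million mapped fragments."""
    if exonic_length <= 0:
        raise ValueError("exonic_length must be > 0")
    if total_fragments <= 0:
        raise ValueError("total_fragments must be > 0")
    if fragments < 0:
        raise ValueError("fragments must be >= 0")
    fpkm = fragments * 1e9 / (total_fragments * exonic_length)
    return ExpressionRecord(locus=locus, fragments=fragments,
                            exonic_length=exonic_length,
                            total_fragments=total_fragments, fpkm=fpkm)
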