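"""Translated locus search: six-frame translation, Smith-Waterman local
protein alignment with affine gaps, and clustering of high-scoring hits into
candidate loci.

This replaces an external tblastn step for locating immunoglobulin-like loci
on genomic scaffolds with an in-package equivalent: every reading frame is
split at stop codons and each stop-free segment is aligned locally against
the protein query; hits above the score threshold are single-linkage
clustered along the genome into locus calls.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

from .models import LocusCall, TranslatedHit
from .synthetic import revcomp

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODON_AA: Dict[str, str] = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    _CODON_AA[_stop] = "*"

FRAMES = (1, 2, 3, -1, -2, -3)

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_MATRIX_ALPHABET = set(str(_BLOSUM62.alphabet))

#: BLAST-style affine gap penalties: a gap of length k costs open + k*extend.
DEFAULT_GAP_OPEN = 11
DEFAULT_GAP_EXTEND = 1


def _translate_frame(dna: str) -> str:
    """Translate one frame; codons containing non-ACGT become X, stops are *."""
    out = []
    for i in range(0, len(dna) - 2, 3):
        out.append(_CODON_AA.get(dna[i:i + 3], "X"))
    return "".join(out)


def six_frame_translate(dna: str) -> Dict[int, str]:
    """All six translation frames of *dna* (stops retained as ``*``).

    Frames +1..+3 read the forward strand from offsets 0..2; frames -1..-3
    read the reverse complement likewise.  Coordinates map back to the
    forward strand via :func:`frame_span_to_genomic`.
    """
    dna = dna.upper()
    rc = revcomp(dna)
    frames = {}
    for f in (1, 2, 3):
        frames[f] = _translate_frame(dna[f - 1:])
        frames[-f] = _translate_frame(rc[f - 1:])
    return frames


def frame_span_to_genomic(frame: int, aa_start: int, aa_end: int,
                          seq_len: int) -> Tuple[int, int]:
    """Forward-strand genomic span of residues [aa_start, aa_end) in *frame*."""
    off = abs(frame) - 1
    start = off + 3 * aa_start
    end = off + 3 * aa_end
    if frame > 0:
        return (start, end)
    return (seq_len - end, seq_len - start)


def _sanitize(protein: str) -> str:
    return "".join(c if c in _MATRIX_ALPHABET else "X" for c in protein.upper())


def make_aligner(gap_open: int = DEFAULT_GAP_OPEN,
                 gap_extend: int = DEFAULT_GAP_EXTEND,
                 matrix=None) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix if matrix is not None else _BLOSUM62
    # PairwiseAligner charges open on the first gapped position, so a gap of
    # length k costs open + (k-1)*extend; shift by one extend to get the
    # BLAST convention open + k*extend.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


@dataclass(frozen=True)
class LocalAlignment:
    score: float
    query_span: Tuple[int, int]
    target_span: Tuple[int, int]


def local_align(query: str, target: str,
                gap_open: int = DEFAULT_GAP_OPEN,
                gap_extend: int = DEFAULT_GAP_EXTEND,
                matrix=None) -> LocalAlignment:
    """Optimal local alignment score and spans under BLOSUM62 affine scoring.

    Residues absent from the substitution matrix are treated as X.  An empty
    target (or a best score of zero) yields score 0 with empty spans.
    """
    if not query:
        raise ValueError("query must be non-empty")
    query = _sanitize(query)
    target = _sanitize(target)
    if not target:
        return LocalAlignment(0.0, (0, 0), (0, 0))
    aligner = make_aligner(gap_open, gap_extend, matrix)
    score = aligner.score(query, target)
    if score <= 0:
        return LocalAlignment(0.0, (0, 0), (0, 0))
    aln = aligner.align(query, target)[0]
    qblocks, tblocks = aln.aligned
    return LocalAlignment(
        score=float(score),
        query_span=(int(qblocks[0][0]), int(qblocks[-1][1])),
        target_span=(int(tblocks[0][0]), int(tblocks[-1][1])),
    )


def _frame_segments(protein: str, min_len: int):
    """Stop-free segments of a translated frame with their aa offsets."""
    pos = 0
    for seg in protein.split("*"):
        if len(seg) >= min_len:
            yield pos, seg
        pos += len(seg) + 1


def find_hits(scaffold: str, query: str, min_score: float = 60,
              min_segment: int = 12, gap_open: int = DEFAULT_GAP_OPEN,
              gap_extend: int = DEFAULT_GAP_EXTEND) -> List[TranslatedHit]:
    """Score the query against every stop-free segment of all six frames."""
    if min_score <= 0:
        raise ValueError("min_score must be > 0")
    L = len(scaffold)
    hits: List[TranslatedHit] = []
    for frame, protein in six_frame_translate(scaffold).items():
        for offset, segment in _frame_segments(protein, min_segment):
            res = local_align(query, segment, gap_open, gap_extend)
            if res.score >= min_score:
                a, b = res.target_span
                span = frame_span_to_genomic(frame, offset + a, offset + b, L)
                hits.append(TranslatedHit(frame=frame, genomic_span=span,
                                          score=res.score,
                                          query_span=res.query_span))
    hits.sort(key=lambda h: (h.genomic_span, -h.score))
    return hits


def cluster_hits(hits: List[TranslatedHit], max_cluster_gap: int,
                 scaffold_name: str = "scaffold") -> List[LocusCall]:
    """Single-linkage clustering of hits along the genome."""
    calls: List[LocusCall] = []
    cluster: List[TranslatedHit] = []

    def flush():
        if cluster:
            span = (min(h.genomic_span[0] for h in cluster),
                    max(h.genomic_span[1] for h in cluster))
            calls.append(LocusCall(scaffold=scaffold_name, span=span,
                                   hits=tuple(cluster),
                                   label=f"locus_{len(calls) + 1}"))
            cluster.clear()

    env_end = None
    for hit in sorted(hits, key=lambda h: h.genomic_span):
        if env_end is not None and hit.genomic_span[0] - env_end > max_cluster_gap:
            flush()
            env_end = None
        cluster.append(hit)
        env_end = max(env_end or 0, hit.genomic_span[1])
    flush()
    return calls


def call_loci(scaffold: str, query: str, min_score: float = 60,
              max_cluster_gap: int = 50_000,
              scaffold_name: str = "scaffold",
              min_segment: int = 12) -> List[LocusCall]:
    """Translated search plus clustering: candidate locus calls, left to right."""
    if max_cluster_gap <= 0:
        raise ValueError("max_cluster_gap must be > 0")
    hits = find_hits(scaffold, query, min_score=min_score,
                     min_segment=min_segment)
    return cluster_hits(hits, max_cluster_gap, scaffold_name)
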