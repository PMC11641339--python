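"""VNAR sequence analysis.

Positional delimitation of the VNAR framework and hypervariable regions,
cysteine census, type I/II classification with predicted disulfide-bond
sets, constant-domain cysteine checks, longest-ORF extraction, and an
IUPAC-aware in-silico PCR.

The region scheme lays the fixed regions FR1, CDR1, FR2, HV2, FR3a, HV4 and
FR3b down consecutively from the FR1 start (their total length is constant
for a scheme), delimits CDR3 as the residues between the FR3b end and the
FR4 anchor motif, and records cysteine positions per region.  Type I domains
carry a noncanonical FR2 cysteine and two or more CDR3 cysteines (three
predicted bonds: FR1-FR3b, FR2-CDR3, CDR3-FR4); type II domains carry a
CDR1 cysteine and at least one CDR3 cysteine (two predicted bonds: FR1-FR3b
and CDR1-CDR3).
"""
from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from Bio.Data.IUPACData import ambiguous_dna_values

from .models import (
    CysteineCensus,
    DisulfideBond,
    PrimerSpec,
    VnarAnnotation,
    VnarScheme,
)
from .synthetic import revcomp

# ---------------------------------------------------------------------------
# ORF extraction

_STOPS = {"TAA", "TAG", "TGA"}
_CODON = {}
from Bio.Data import CodonTable as _CT

for _c, _a in _CT.unambiguous_dna_by_id[1].forward_table.items():
    _CODON[_c] = _a


@dataclass(frozen=True)
class OrfResult:
    protein: str
    frame: int  # forward frame 1..3; 0 when absent
    span: Tuple[int, int]  # nucleotide span, 0-based half-open
    status: str  # "ok" | "no-start"


def longest_orf(transcript: str) -> OrfResult:
    """Longest ATG-initiated open reading frame over the three forward frames.

    ORFs run from an ATG to the next in-frame stop (or the end of the frame);
    ties are broken by the leftmost start.  Returns status "no-start" when no
    ATG exists.
    """
    if len(transcript) < 3:
        raise ValueError("transcript must be at least 3 nt")
    seq = transcript.upper()
    best: Optional[Tuple[int, int, int]] = None  # (aa_len, start_nt, frame)
    for frame in (0, 1, 2):
        start: Optional[int] = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i:i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in _STOPS:
                length = (i - start) // 3
                cand = (length, start, frame)
                if best is None or (cand[0], -cand[1]) > (best[0], -best[1]):
                    best = cand
                start = None
        if start is not None:
            end = len(seq) - (len(seq) - frame) % 3
            length = (end - start) // 3
            cand = (length, start, frame)
            if best is None or (cand[0], -cand[1]) > (best[0], -best[1]):
                best = cand
    if best is None:
        return OrfResult("", 0, (0, 0), "no-start")
    length, start, frame = best
    end = start + 3 * length
    protein = "".join(_CODON.get(seq[i:i + 3], "X")
                      for i in range(start, end, 3))
    return OrfResult(protein, frame + 1, (start, end), "ok")


# ---------------------------------------------------------------------------
# annotation and typing

TYPE_I = "I"
TYPE_II = "II"
CANONICAL_ONLY = "canonical-only"
UNCLASSIFIED = "unclassified"


def _cys_positions(seq: str, span: Tuple[int, int]) -> Tuple[int, ...]:
    s, e = span
    return tuple(i for i in range(s, e) if seq[i] == "C")


@dataclass(frozen=True)
class TypeCall:
    type_call: str
    bonds: Tuple[DisulfideBond, ...]
    unpaired: Tuple[Tuple[str, int], ...]
    candidates: Tuple[str, ...] = ()
    flags: Tuple[str, ...] = ()


def classify_type(annotation: VnarAnnotation) -> TypeCall:
    """Type call and predicted disulfide bonds from cysteine placement only.

    Type I pairs the first CDR3 cysteine with FR2 and the last with FR4;
    type II pairs CDR1 with CDR3; every annotated domain keeps the canonical
    FR1-FR3b bond.  A sequence with cysteines in both FR2 and CDR1 is
    ambiguous and left unclassified with both candidate calls listed.
    """
    cys = annotation.cys_positions
    fr1 = cys.get("FR1", ())
    fr3b = cys.get("FR3b", ())
    fr2 = cys.get("FR2", ())
    cdr1 = cys.get("CDR1", ())
    cdr3 = cys.get("CDR3", ())
    fr4 = cys.get("FR4", ())
    flags: List[str] = []

    all_cys = [(region, pos) for region, positions in cys.items()
               for pos in positions]

    if not fr1 or not fr3b:
        return TypeCall(UNCLASSIFIED, (), tuple(all_cys),
                        flags=("missing-canonical-cysteine",))

    canonical = DisulfideBond(residue_a=("FR1", fr1[0]),
                              residue_b=("FR3b", fr3b[0]))
    bonds: List[DisulfideBond] = [canonical]
    paired = {("FR1", fr1[0]), ("FR3b", fr3b[0])}

    if fr2 and cdr1:
        return TypeCall(UNCLASSIFIED, (), tuple(all_cys),
                        candidates=(TYPE_I, TYPE_II),
                        flags=("ambiguous-fr2-and-cdr1-cysteines",))

    if fr2 and len(cdr3) >= 2:
        call = TYPE_I
        bonds.append(DisulfideBond(("FR2", fr2[0]), ("CDR3", cdr3[0])))
        paired.update({("FR2", fr2[0]), ("CDR3", cdr3[0])})
        if fr4:
            partner = ("FR4", fr4[0])
        else:
            partner = ("FR4", annotation.regions["FR4"][0])
            flags.append("fr4-partner-unconfirmed")
        bonds.append(DisulfideBond(("CDR3", cdr3[-1]), partner))
        paired.update({("CDR3", cdr3[-1]), partner})
    elif cdr1 and len(cdr3) >= 1:
        call = TYPE_II
        bonds.append(DisulfideBond(("CDR1", cdr1[0]), ("CDR3", cdr3[0])))
        paired.update({("CDR1", cdr1[0]), ("CDR3", cdr3[0])})
    elif len(all_cys) == 2:
        call = CANONICAL_ONLY
    else:
        return TypeCall(UNCLASSIFIED, (canonical,),
                        tuple(p for p in all_cys if p not in paired),
                        flags=("cysteine-pattern-unrecognised",))

    unpaired = tuple(p for p in all_cys if p not in paired)
    return TypeCall(call, tuple(bonds), unpaired, flags=tuple(flags))


def annotate_vnar(protein: str,
                  scheme: Optional[VnarScheme] = None) -> VnarAnnotation:
    """Annotate one VNAR amino-acid sequence under a positional scheme.

    The fixed regions are laid down from the FR1 start (position 0); CDR3
    runs from the FR3b end to the FR4 anchor match.  Sequences without the
    canonical cysteines or without an FR4 anchor are annotated best-effort
    with diagnostic flags.
    """
    scheme = scheme or VnarScheme()
    if len(protein) < scheme.fixed_total:
        raise ValueError(
            f"sequence length {len(protein)} is shorter than the scheme's "
            f"fixed-region total {scheme.fixed_total}")
    protein = protein.upper()
    regions: Dict[str, Tuple[int, int]] = dict(scheme.fixed_spans(0))
    flags: List[str] = []

    tail_start = scheme.fixed_total
    m = re.search(scheme.fr4_anchor, protein[tail_start:])
    if m:
        fr4_start = tail_start + m.start()
        regions["CDR3"] = (tail_start, fr4_start)
        regions["FR4"] = (fr4_start,
                          min(len(protein), fr4_start + scheme.fr4_length))
    else:
        regions["CDR3"] = (tail_start, len(protein))
        regions["FR4"] = (len(protein), len(protein))
        flags.append("no-fr4-anchor")

    cys_positions = {region: _cys_positions(protein, span)
                     for region, span in regions.items()}

    fr1_cys_abs = regions["FR1"][0] + scheme.canonical_cys[0]
    fr3b_cys_abs = regions["FR3b"][0] + scheme.canonical_cys[1]
    if protein[fr1_cys_abs] != "C" or protein[fr3b_cys_abs] != "C":
        flags.append("canonical-cysteine-displaced-or-absent")

    annotation = VnarAnnotation(
        sequence=protein, regions=regions, cys_positions=cys_positions,
        flags=tuple(flags), scheme=scheme)
    result = classify_type(annotation)
    return dataclasses.replace(
        annotation,
        type_call=result.type_call,
        predicted_bonds=result.bonds,
        flags=tuple(flags) + result.flags)


def census(annotations: Sequence[VnarAnnotation]) -> CysteineCensus:
    """CDR3 cysteine-count census over a set of annotated sequences."""
    return CysteineCensus(tuple(a.cdr3_cys_count for a in annotations))


# ---------------------------------------------------------------------------
# constant-domain checks


@dataclass(frozen=True)
class ConstantDomainReport:
    cys_counts: Mapping[str, int]  # per constant domain present
    linker_cys: bool


def check_constant_domains(protein: str,
                           domain_spans: Mapping[str, Tuple[int, int]],
                           linker_span: Optional[Tuple[int, int]] = None
                           ) -> ConstantDomainReport:
    """Cysteine count per constant domain plus the C3-C4 linker flag.

    *domain_spans* maps domain labels to amino-acid spans on *protein*; only
    C1..C5 entries are counted.  When a linker span is given, cysteines in it
    are excluded from the C3 count and flagged separately.
    """
    if not domain_spans:
        raise ValueError("domain boundaries are required")
    linker = set(range(*linker_span)) if linker_span else set()
    counts: Dict[str, int] = {}
    for dom in ("C1", "C2", "C3", "C4", "C5"):
        if dom not in domain_spans:
            continue
        s, e = domain_spans[dom]
        counts[dom] = sum(1 for i in range(s, e)
                          if protein[i] == "C" and i not in linker)
    linker_cys = any(protein[i] == "C" for i in linker)
    return ConstantDomainReport(cys_counts=counts, linker_cys=linker_cys)


# ---------------------------------------------------------------------------
# in-silico PCR

_IUPAC = {k: set(v) for k, v in ambiguous_dna_values.items()}


def _matches(primer: str, window: str) -> int:
    """Mismatch count of a primer against an equal-length template window."""
    mm = 0
    for p, b in zip(primer, window):
        if b not in _IUPAC.get(p, {p}):
            mm += 1
    return mm


def _site_hits(template: str, site: str, max_mismatch: int,
               exact_idx: range) -> List[Tuple[int, int]]:
    hits = []
    n = len(site)
    for pos in range(len(template) - n + 1):
        window = template[pos:pos + n]
        if any(window[i] not in _IUPAC.get(site[i], {site[i]})
               for i in exact_idx):
            continue
        mm = _matches(site, window)
        if mm <= max_mismatch:
            hits.append((pos, mm))
    return hits


@dataclass(frozen=True)
class Amplicon:
    start: int  # 5' end of the forward primer site (0-based)
    end: int    # one past the 5' end of the reverse primer site
    seq: str
    fwd_mismatches: int
    rev_mismatches: int

    @property
    def length(self) -> int:
        return self.end - self.start


def in_silico_pcr(template: str, fwd: PrimerSpec, rev: PrimerSpec,
                  max_len: int = 5000) -> List[Amplicon]:
    """Predict PCR products of a primer pair on a template.

    Primer matching is IUPAC-aware; a hit needs at most ``max_mismatch``
    mismatches overall and none within the 3'-terminal ``three_prime_exact``
    bases.  The reverse primer is matched against the reverse complement
    (its site on the forward strand is the primer's reverse complement, with
    the 3' end leftmost).  An amplicon spans from the forward primer's 5'
    end through the reverse primer's 5' end inclusive.
    """
    if fwd.orientation != "forward" or rev.orientation != "reverse":
        raise ValueError("expected a forward and a reverse primer, in order")
    template = template.upper()
    f = fwd.sequence.upper()
    r_site = revcomp(rev.sequence.upper())

    f_exact = range(max(0, len(f) - fwd.three_prime_exact), len(f))
    r_exact = range(0, min(rev.three_prime_exact, len(r_site)))

    f_hits = _site_hits(template, f, fwd.max_mismatch, f_exact)
    r_hits = _site_hits(template, r_site, rev.max_mismatch, r_exact)

    products = []
    for fpos, fmm in f_hits:
        for rpos, rmm in r_hits:
            if rpos < fpos + len(f):
                continue
            end = rpos + len(r_site)
            if end - fpos > max_len:
                continue
            products.append(Amplicon(start=fpos, end=end,
                                     seq=template[fpos:end],
                                     fwd_mismatches=fmm, rev_mismatches=rmm))
    products.sort(key=lambda a: (a.start, a.end))
    return products
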