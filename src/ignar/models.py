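"""Core data types shared across the IgNAR analysis modules.

Coordinates are 0-based half-open throughout the package; conversion to the
1-based conventions of SAM/GTF happens only at the I/O boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

#: Domain labels recognised in a locus model.  ``hinge`` names the short
#: connector exon found between the VNAR exon and C1 in ten-exon loci.
DOMAIN_LABELS = ("leader", "VNAR", "hinge", "C1", "C2", "C3", "C4", "C5", "tail")
CONSTANT_DOMAINS = ("C1", "C2", "C3", "C4", "C5")


@dataclass(frozen=True)
class LocusModel:
    """Genomic architecture of one IgNAR locus.

    Parameters
    ----------
    name : str
        Locus label, e.g. ``"GcIgNAR1-like"``.
    scaffold : str
        Name of the scaffold the exons live on.
    strand : str
        ``"+"`` or ``"-"``.
    exons : tuple of (int, int)
        Ordered, non-overlapping exon spans in 0-based half-open scaffold
        coordinates.
    domain_map : mapping int -> str
        Exon index (0-based) to domain label.  Exactly one exon carries the
        VNAR; each constant domain C1..C5 maps to at most one exon.
    linker_cys : bool
        Whether the C3-C4 linker region carries an extra cysteine codon.
    """

    name: str
    scaffold: str
    strand: str
    exons: Tuple[Tuple[int, int], ...]
    domain_map: Mapping[int, str]
    linker_cys: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        prev_end = -1
        for start, end in self.exons:
            if end <= start:
                raise ValueError(f"empty or inverted exon span ({start}, {end})")
            if start < prev_end:
                raise ValueError("exons must be non-overlapping and increasing")
            prev_end = end
        labels = list(self.domain_map.values())
        for label in labels:
            if label not in DOMAIN_LABELS:
                raise ValueError(f"unknown domain label {label!r}")
        if labels.count("VNAR") != 1:
            raise ValueError("exactly one exon must carry the VNAR domain")
        for dom in CONSTANT_DOMAINS:
            if labels.count(dom) > 1:
                raise ValueError(f"constant domain {dom} mapped to multiple exons")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon_of_domain(self, label: str) -> Optional[int]:
        """Return the exon index carrying *label*, or None."""
        for idx, dom in self.domain_map.items():
            if dom == label:
                return idx
        return None

    def exon_length(self, idx: int) -> int:
        start, end = self.exons[idx]
        return end - start


@dataclass(frozen=True)
class IsoformModel:
    """An exon chain of a locus together with a relative abundance."""

    locus: LocusModel
    chain: Tuple[int, ...]
    abundance: float = 1.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.abundance < 0:
            raise ValueError("abundance must be >= 0")
        if any(b <= a for a, b in zip(self.chain, self.chain[1:])):
            raise ValueError("exon chain indices must be strictly increasing")
        if any(i < 0 or i >= self.locus.n_exons for i in self.chain):
            raise ValueError("exon chain index outside locus")

    @property
    def short_form(self) -> bool:
        """True iff C4 and C5 are both skipped while C1-C3 are retained."""
        doms = {self.locus.domain_map.get(i) for i in self.chain}
        return ("C4" not in doms and "C5" not in doms
                and {"C1", "C2", "C3"} <= doms)

    @property
    def transcript_length(self) -> int:
        return sum(self.locus.exon_length(i) for i in self.chain)

    def junctions(self) -> Tuple[Tuple[int, int], ...]:
        """Splice junctions (donor_end, acceptor_start) implied by the chain."""
        ex = self.locus.exons
        return tuple((ex[a][1], ex[b][0]) for a, b in zip(self.chain, self.chain[1:]))


def _check_dist(dist: Mapping, what: str) -> None:
    total = sum(dist.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{what} probabilities must sum to 1 (got {total})")
    if any(p < 0 or p > 1 for p in dist.values()):
        raise ValueError(f"{what} probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class RepertoireConfig:
    """Parameters of a synthetic VNAR repertoire.

    ``framework_template`` maps the fixed regions FR1, CDR1, FR2, HV2, FR3a,
    HV4, FR3b to amino-acid strings; every generated sequence keeps the same
    total length from FR1 through FR3b, with substitutions applied only inside
    CDR1/HV2/HV4.  CDR3 length and cysteine count are drawn from the two
    discrete distributions.  ``fr2_cys`` / ``cdr1_cys`` select type-I-like
    versus type-II-like noncanonical cysteine placement.
    """

    n_sequences: int
    framework_template: Mapping[str, str]
    hv_mut_rate: float
    cdr3_length_dist: Mapping[int, float]
    cdr3_cys_dist: Mapping[int, float]
    fr2_cys: bool = False
    cdr1_cys: bool = False
    fr4_template: str = "WGQGTVVTVN"
    fr2_cys_offset: int = 7
    cdr1_cys_offset: int = 3
    fr4_cys: Optional[bool] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.hv_mut_rate <= 1.0):
            raise ValueError("hv_mut_rate must lie in [0, 1]")
        if self.n_sequences < 0:
            raise ValueError("n_sequences must be >= 0")
        _check_dist(self.cdr3_length_dist, "cdr3_length_dist")
        _check_dist(self.cdr3_cys_dist, "cdr3_cys_dist")
        missing = {"FR1", "CDR1", "FR2", "HV2", "FR3a", "HV4", "FR3b"} - set(
            self.framework_template
        )
        if missing:
            raise ValueError(f"framework_template missing regions: {sorted(missing)}")
        max_cys = max(self.cdr3_cys_dist)
        min_len = min(self.cdr3_length_dist)
        if max_cys > min_len:
            raise ValueError("cdr3_cys_dist allows more cysteines than the "
                             "shortest CDR3 can hold")


@dataclass(frozen=True)
class GapRecord:
    """A run of N in a scaffold with the flank window used to gather reads."""

    scaffold: str
    start: int
    end: int
    flank_window: int = 500

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("gap end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MappedRead:
    """One mate of a pair: sequence plus its mapped interval and strand."""

    name: str
    seq: str
    start: int
    end: int
    strand: str


@dataclass(frozen=True)
class ReadPair:
    name: str
    read1: MappedRead
    read2: Optional[MappedRead]
    proper_pair: bool = True
    straddles_gap: bool = False

    def mates(self) -> Tuple[MappedRead, ...]:
        return (self.read1,) if self.read2 is None else (self.read1, self.read2)


@dataclass(frozen=True)
class TranslatedHit:
    """A local protein alignment of the query against one translation frame."""

    frame: int  # one of +1, +2, +3, -1, -2, -3
    genomic_span: Tuple[int, int]  # forward-strand, 0-based half-open
    score: float
    query_span: Tuple[int, int]


@dataclass(frozen=True)
class LocusCall:
    scaffold: str
    span: Tuple[int, int]
    hits: Tuple[TranslatedHit, ...]
    label: str


@dataclass(frozen=True)
class SplicedAlignment:
    """Genomic match blocks of one spliced fragment (skips removed)."""

    fragment_id: str
    blocks: Tuple[Tuple[int, int], ...]

    def __post_init__(self) -> None:
        prev_end = None
        for start, end in self.blocks:
            if end <= start:
                raise ValueError("empty alignment block")
            if prev_end is not None and start <= prev_end:
                raise ValueError("blocks must be strictly increasing")
            prev_end = end

    def junctions(self) -> Tuple[Tuple[int, int], ...]:
        return tuple((a[1], b[0]) for a, b in zip(self.blocks, self.blocks[1:]))


@dataclass(frozen=True)
class JunctionChain:
    """The maximal ordered junction list of a fragment class."""

    junctions: Tuple[Tuple[int, int], ...]
    support: int
    leftmost: int

    def __post_init__(self) -> None:
        for donor, acceptor in self.junctions:
            if donor >= acceptor:
                raise ValueError("junction donor_end must precede acceptor_start")


@dataclass(frozen=True)
class ExpressionRecord:
    """Locus-level expression in FPKM units."""

    locus: str
    fragments: int
    exonic_length: int
    total_fragments: int
    fpkm: float


@dataclass(frozen=True)
class IsoformCall:
    chain: JunctionChain
    exon_indices: Tuple[int, ...]
    domains: Tuple[str, ...]
    short_form: bool
    novel_junctions: Tuple[Tuple[int, int], ...] = ()
    atypical: bool = False


@dataclass(frozen=True)
class VnarScheme:
    """Positional definition of the VNAR framework.

    The fixed regions FR1, CDR1, FR2, HV2, FR3a, HV4, FR3b are laid down
    consecutively from the FR1 start; CDR3 runs from the FR3b end to the FR4
    anchor match; FR4 is located by ``fr4_anchor`` (a regular expression).
    ``canonical_cys`` gives the offsets of the two invariant cysteines within
    FR1 and FR3b respectively.
    """

    region_lengths: Mapping[str, int] = field(
        default_factory=lambda: {
            "FR1": 25, "CDR1": 8, "FR2": 10, "HV2": 8,
            "FR3a": 16, "HV4": 6, "FR3b": 15,
        }
    )
    fr4_anchor: str = r"[YW]G.G"
    fr4_length: int = 10
    canonical_cys: Tuple[int, int] = (21, 10)

    FIXED_ORDER = ("FR1", "CDR1", "FR2", "HV2", "FR3a", "HV4", "FR3b")
    HYPERVARIABLE = ("CDR1", "HV2", "HV4")

    def __post_init__(self) -> None:
        missing = set(self.FIXED_ORDER) - set(self.region_lengths)
        if missing:
            raise ValueError(f"scheme missing region lengths: {sorted(missing)}")
        fr1_off, fr3b_off = self.canonical_cys
        if not (0 <= fr1_off < self.region_lengths["FR1"]):
            raise ValueError("FR1 canonical cysteine offset outside FR1")
        if not (0 <= fr3b_off < self.region_lengths["FR3b"]):
            raise ValueError("FR3b canonical cysteine offset outside FR3b")

    @property
    def fixed_total(self) -> int:
        """Total residue count from the FR1 start through the FR3b end."""
        return sum(self.region_lengths[r] for r in self.FIXED_ORDER)

    def fixed_spans(self, offset: int = 0) -> dict:
        """Spans of the fixed regions laid down from *offset*."""
        spans = {}
        pos = offset
        for region in self.FIXED_ORDER:
            spans[region] = (pos, pos + self.region_lengths[region])
            pos = spans[region][1]
        return spans


@dataclass(frozen=True)
class DisulfideBond:
    """A cysteine pairing, either geometric (with a distance) or predicted.

    ``residue_a`` / ``residue_b`` are (chain-or-region, position) keys.
    """

    residue_a: Tuple[str, object]
    residue_b: Tuple[str, object]
    distance: Optional[float] = None
    klass: Optional[str] = None
    domains: Optional[Tuple[str, str]] = None


@dataclass(frozen=True)
class VnarAnnotation:
    """Per-sequence VNAR annotation under a positional scheme."""

    sequence: str
    regions: Mapping[str, Tuple[int, int]]
    cys_positions: Mapping[str, Tuple[int, ...]]
    type_call: str = "unclassified"
    predicted_bonds: Tuple[DisulfideBond, ...] = ()
    flags: Tuple[str, ...] = ()
    scheme: Optional[VnarScheme] = None

    def region_seq(self, region: str) -> str:
        start, end = self.regions[region]
        return self.sequence[start:end]

    @property
    def cdr3_cys_count(self) -> int:
        return len(self.cys_positions.get("CDR3", ()))


@dataclass(frozen=True)
class CysteineCensus:
    """CDR3 cysteine-count census over a repertoire."""

    counts: Tuple[int, ...]

    @property
    def n(self) -> int:
        return len(self.counts)

    @property
    def histogram(self) -> dict:
        hist: dict = {}
        for c in self.counts:
            hist[c] = hist.get(c, 0) + 1
        return hist

    def fraction_ge(self, k: int) -> float:
        """Fraction of sequences with at least *k* CDR3 cysteines."""
        if not self.counts:
            return 0.0
        return sum(1 for c in self.counts if c >= k) / self.n

    def fraction_eq(self, k: int) -> float:
        """Fraction of sequences with exactly *k* CDR3 cysteines."""
        if not self.counts:
            return 0.0
        return sum(1 for c in self.counts if c == k) / self.n


@dataclass(frozen=True)
class PrimerSpec:
    """An amplification primer over the IUPAC nucleotide alphabet."""

    name: str
    sequence: str
    orientation: str  # "forward" | "reverse"
    max_mismatch: int = 0
    three_prime_exact: int = 3

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("primer sequence must be non-empty")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError("orientation must be 'forward' or 'reverse'")
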