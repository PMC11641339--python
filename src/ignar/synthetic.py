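"""Synthetic IgNAR data generation.

Every input the analysis modules consume can be produced here: genomic loci
with known exon/intron architecture, scaffolds with masked N-gaps, paired-end
genomic reads with true placements, spliced transcriptome fragments from
isoform mixtures, and VNAR amino-acid repertoires with controlled
hypervariable-region diversity and CDR3 cysteine-count distributions.

The packaged default architectures mirror the two expressed nurse-shark IgNAR
loci: a ten-exon locus (leader, VNAR, hinge connector, one exon per constant
domain C1-C5, two tail exons) and a nine-exon locus without the hinge exon.
The VNAR sits in exon 2 in both, and each constant domain is encoded by a
single exon, so skipping the C4 and C5 exons yields the short-form transcript
with three constant domains.
"""
from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .models import (
    IsoformModel,
    LocusModel,
    RepertoireConfig,
    SplicedAlignment,
    VnarScheme,
)

# ---------------------------------------------------------------------------
# constants

AA20 = "ACDEFGHIKLMNPQRSTVWY"
AA_NO_CYS = AA20.replace("C", "")

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
CODONS_BY_AA: Dict[str, Tuple[str, ...]] = {}
for codon, aa in _STANDARD.forward_table.items():
    CODONS_BY_AA.setdefault(aa, tuple())
    CODONS_BY_AA[aa] = CODONS_BY_AA[aa] + (codon,)
STOP_CODONS = tuple(_STANDARD.stop_codons)

# VNAR framework templates.  Canonical cysteines: FR1 offset 21, FR3b offset
# 10.  The _CYS variants carry the noncanonical cysteine that distinguishes
# type-I-like (FR2) from type-II-like (CDR1) domains.
FR1_TEMPLATE = "ARVDQTPQTITKETGESLTINCVLR"
CDR1_TEMPLATE = "DSNSALSS"
CDR1_TEMPLATE_CYS = "DSNCALSS"
FR2_TEMPLATE = "TYWYRKKSGE"
FR2_TEMPLATE_CYS = "TYWYRKKCGE"
HV2_TEMPLATE = "STNEESIS"
FR3A_TEMPLATE = "KGRYVETVNSGSKSFS"
HV4_TEMPLATE = "LRINDL"
FR3B_TEMPLATE = "ATVEDSGTYYCKAQG"
CDR3_TEMPLATE_TYPE1 = "ASCPDGYWRCDV"  # two cysteines, pairs with FR2 and FR4
CDR3_TEMPLATE_TYPE2 = "ASGYDCWRDV"    # one cysteine, pairs with CDR1
FR4_TEMPLATE_TYPE1 = "WGQGCTVVTV"     # anchor WGQG + partner cysteine
FR4_TEMPLATE_TYPE2 = "WGQGTVVTVN"

DEFAULT_FRAMEWORK = {
    "FR1": FR1_TEMPLATE,
    "CDR1": CDR1_TEMPLATE,
    "FR2": FR2_TEMPLATE,
    "HV2": HV2_TEMPLATE,
    "FR3a": FR3A_TEMPLATE,
    "HV4": HV4_TEMPLATE,
    "FR3b": FR3B_TEMPLATE,
}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n)) if n else ""


def _random_protein(rng: np.random.Generator, n: int, alphabet: str = AA_NO_CYS) -> str:
    return "".join(rng.choice(list(alphabet), size=n)) if n else ""


def _back_translate(rng: np.random.Generator, protein: str) -> str:
    """Choose a random synonymous codon for every residue."""
    parts = []
    for aa in protein:
        codons = CODONS_BY_AA[aa]
        parts.append(codons[rng.integers(0, len(codons))])
    return "".join(parts)


# ---------------------------------------------------------------------------
# locus construction


@dataclass(frozen=True)
class LocusConfig:
    """Architecture parameters of a synthetic IgNAR locus.

    Exon/intron lengths not dictated by the locus architecture itself are
    fixed defaults here: coding exons land in the 270-330 bp range and introns
    are drawn uniformly from 300-2000 bp unless given explicitly.
    """

    name: str = "GcIgNAR1-like"
    scaffold_name: str = "synthetic_scaffold"
    has_hinge: bool = True
    leader_aa: int = 19  # residues after the initiator Met
    hinge_aa: int = 7
    constant_aa: int = 99
    linker_aa: int = 6  # C3-C4 linker, encoded at the end of the C3 exon
    tail1_aa: int = 30
    tail2_aa: int = 24
    utr5: int = 30
    utr3: int = 60
    flank: int = 500
    intron_lengths: Optional[Tuple[int, ...]] = None
    intron_range: Tuple[int, int] = (300, 2000)
    linker_cys: bool = True
    fr2_cys: bool = True
    cdr1_cys: bool = False
    cdr3_template: str = CDR3_TEMPLATE_TYPE1
    fr4_template: str = FR4_TEMPLATE_TYPE1
    constant_cys_offsets: Tuple[int, int] = (21, 87)
    c1_extra_cys: int = 54
    constant_domain_nt: Optional[Mapping[str, int]] = None
    scheme: VnarScheme = field(default_factory=VnarScheme)
    seed: int = 0

    @property
    def n_exons(self) -> int:
        return 10 if self.has_hinge else 9


@dataclass(frozen=True)
class SyntheticLocus:
    """A built locus: model, scaffold, and the planted coding truth."""

    model: LocusModel
    scaffold: str
    cds: str
    protein: str
    #: amino-acid span each exon contributes to the full protein
    exon_aa_spans: Tuple[Tuple[int, int], ...]
    #: full-protein span per domain label (tail spans both tail exons)
    domain_aa_spans: Mapping[str, Tuple[int, int]]
    linker_aa_span: Optional[Tuple[int, int]]
    vnar_protein: str
    scheme: VnarScheme
    config: LocusConfig

    def full_chain(self) -> Tuple[int, ...]:
        return tuple(range(self.model.n_exons))

    def transcript_seq(self, chain: Sequence[int]) -> str:
        return "".join(self.scaffold[s:e] for s, e in
                       (self.model.exons[i] for i in chain))

    def coding_seq(self, chain: Sequence[int]) -> str:
        """Spliced coding sequence of a chain (UTRs and stop removed)."""
        parts = []
        for i in chain:
            a, b = self.exon_aa_spans[i]
            if b > a:
                parts.append(self.cds[3 * a:3 * b])
        return "".join(parts)

    def protein_for_chain(self, chain: Sequence[int]) -> Tuple[str, Dict[str, Tuple[int, int]]]:
        """Protein of an isoform chain plus its per-domain amino-acid spans."""
        protein = []
        spans: Dict[str, Tuple[int, int]] = {}
        pos = 0
        for i in chain:
            a, b = self.exon_aa_spans[i]
            if b <= a:
                continue
            label = self.model.domain_map[i]
            seg = self.protein[a:b]
            if label in spans:  # tail split over two exons
                spans[label] = (spans[label][0], pos + len(seg))
            else:
                spans[label] = (pos, pos + len(seg))
            protein.append(seg)
            pos += len(seg)
        return "".join(protein), spans

    def linker_span_for_chain(self, chain: Sequence[int]) -> Optional[Tuple[int, int]]:
        """C3-C4 linker span in the chain's protein coordinates, if present."""
        if self.linker_aa_span is None:
            return None
        c3_exon = self.model.exon_of_domain("C3")
        if c3_exon is None or c3_exon not in chain:
            return None
        _, spans = self.protein_for_chain(chain)
        c3s, c3e = spans["C3"]
        return (c3e - self.config.linker_aa, c3e)


def _vnar_protein(config: LocusConfig) -> str:
    cdr1 = CDR1_TEMPLATE_CYS if config.cdr1_cys else CDR1_TEMPLATE
    fr2 = FR2_TEMPLATE_CYS if config.fr2_cys else FR2_TEMPLATE
    return (FR1_TEMPLATE + cdr1 + fr2 + HV2_TEMPLATE + FR3A_TEMPLATE
            + HV4_TEMPLATE + FR3B_TEMPLATE + config.cdr3_template
            + config.fr4_template)


def build_locus(config: LocusConfig) -> SyntheticLocus:
    """Construct a synthetic IgNAR locus and its carrying scaffold.

    The protein is designed first (leader, VNAR, optional hinge, constant
    domains with their cysteine placements, tail) and back-translated with
    random synonymous codons, so the concatenated coding exons translate
    without internal stop codons by construction.  All coding exon lengths
    are multiples of three, which keeps every exon-skipping chain in frame.
    """
    rng = np.random.default_rng(config.seed)

    n_introns = config.n_exons - 1
    if config.intron_lengths is not None:
        introns = tuple(config.intron_lengths)
        if len(introns) != n_introns:
            raise ValueError(
                f"{config.name}: expected {n_introns} intron lengths, "
                f"got {len(introns)}")
        if any(l <= 0 for l in introns):
            raise ValueError("intron lengths must be positive")
    else:
        lo, hi = config.intron_range
        introns = tuple(int(rng.integers(lo, hi + 1)) for _ in range(n_introns))

    # per-domain residue counts, honouring explicit nt overrides
    constant_aa: Dict[str, int] = {}
    for dom in ("C1", "C2", "C3", "C4", "C5"):
        if config.constant_domain_nt and dom in config.constant_domain_nt:
            nt = config.constant_domain_nt[dom]
            if nt % 3 != 0:
                raise ValueError(
                    f"constant-domain exon length for {dom} ({nt} nt) is not "
                    "a multiple of 3")
            constant_aa[dom] = nt // 3
        else:
            constant_aa[dom] = config.constant_aa

    def constant_domain(n: int, extra_mid: bool) -> str:
        seq = list(_random_protein(rng, n))
        o1, o2 = config.constant_cys_offsets
        seq[o1], seq[o2] = "C", "C"
        if extra_mid:
            seq[config.c1_extra_cys] = "C"
        return "".join(seq)

    linker = "GSG" + ("C" if config.linker_cys else "S") + "GS"
    if len(linker) != config.linker_aa:
        linker = (linker + "GS" * config.linker_aa)[: config.linker_aa]

    segments: List[Tuple[str, str]] = []  # (domain label, protein segment)
    segments.append(("leader", "M" + _random_protein(rng, config.leader_aa)))
    segments.append(("VNAR", _vnar_protein(config)))
    if config.has_hinge:
        segments.append(("hinge", _random_protein(rng, config.hinge_aa)))
    for dom in ("C1", "C2", "C3", "C4", "C5"):
        seg = constant_domain(constant_aa[dom], extra_mid=(dom == "C1"))
        if dom == "C3":
            seg += linker
        segments.append((dom, seg))
    segments.append(("tail", _random_protein(rng, config.tail1_aa)))
    segments.append(("tail", _random_protein(rng, config.tail2_aa)))

    protein = "".join(seg for _, seg in segments)
    cds = _back_translate(rng, protein)
    translated = str(Seq(cds).translate())
    if "*" in translated:
        raise AssertionError("internal stop codon in designed frame")

    # exon nucleotide pieces
    exon_nt: List[str] = []
    exon_aa_spans: List[Tuple[int, int]] = []
    aa_pos = 0
    for i, (label, seg) in enumerate(segments):
        n_aa = len(seg)
        piece = cds[3 * aa_pos: 3 * (aa_pos + n_aa)]
        if i == 0:
            piece = _random_dna(rng, config.utr5) + piece
        if i == len(segments) - 1:
            stop = STOP_CODONS[rng.integers(0, len(STOP_CODONS))]
            piece = piece + stop + _random_dna(rng, config.utr3)
        exon_nt.append(piece)
        exon_aa_spans.append((aa_pos, aa_pos + n_aa))
        aa_pos += n_aa

    # lay exons and introns on the scaffold
    scaffold_parts = [_random_dna(rng, config.flank)]
    pos = config.flank
    exons: List[Tuple[int, int]] = []
    for i, piece in enumerate(exon_nt):
        exons.append((pos, pos + len(piece)))
        scaffold_parts.append(piece)
        pos += len(piece)
        if i < len(exon_nt) - 1:
            intron = "GT" + _random_dna(rng, introns[i] - 4) + "AG"
            scaffold_parts.append(intron)
            pos += len(intron)
    scaffold_parts.append(_random_dna(rng, config.flank))
    scaffold = "".join(scaffold_parts)

    domain_map = {i: label for i, (label, _) in enumerate(segments)}
    model = LocusModel(
        name=config.name,
        scaffold=config.scaffold_name,
        strand="+",
        exons=tuple(exons),
        domain_map=domain_map,
        linker_cys=config.linker_cys,
    )

    domain_aa_spans: Dict[str, Tuple[int, int]] = {}
    for (label, _), (a, b) in zip(segments, exon_aa_spans):
        if label in domain_aa_spans:
            domain_aa_spans[label] = (domain_aa_spans[label][0], b)
        else:
            domain_aa_spans[label] = (a, b)
    c3a, c3b = domain_aa_spans["C3"]
    linker_span = (c3b - config.linker_aa, c3b) if config.linker_cys else None

    return SyntheticLocus(
        model=model,
        scaffold=scaffold,
        cds=cds,
        protein=protein,
        exon_aa_spans=tuple(exon_aa_spans),
        domain_aa_spans=domain_aa_spans,
        linker_aa_span=linker_span,
        vnar_protein=_vnar_protein(config),
        scheme=config.scheme,
        config=config,
    )


# ---------------------------------------------------------------------------
# packaged fixtures


def gcignar1_locus(seed: int = 11, **overrides) -> SyntheticLocus:
    """Ten-exon, type-I-flavoured locus (VNAR at exon 2, C1-C5 at exons 4-8)."""
    params = dict(
        name="GcIgNAR1-like", has_hinge=True, fr2_cys=True, cdr1_cys=False,
        cdr3_template=CDR3_TEMPLATE_TYPE1, fr4_template=FR4_TEMPLATE_TYPE1,
        seed=seed)
    params.update(overrides)
    return build_locus(LocusConfig(**params))


def gcignar2_locus(seed: int = 22, **overrides) -> SyntheticLocus:
    """Nine-exon, type-II-flavoured locus (VNAR at exon 2, C1-C5 at exons 3-7)."""
    params = dict(
        name="GcIgNAR2-like", has_hinge=False, fr2_cys=False, cdr1_cys=True,
        cdr3_template=CDR3_TEMPLATE_TYPE2, fr4_template=FR4_TEMPLATE_TYPE2,
        seed=seed)
    params.update(overrides)
    return build_locus(LocusConfig(**params))


#: 0-based exon chains of the eleven packaged ten-exon-locus isoforms:
#: six full-constant-domain variants (hinge exon 2 and tail exon usage vary)
#: and five short forms skipping the C4 and C5 exons (indices 6 and 7).
GCIGNAR1_CHAINS: Tuple[Tuple[int, ...], ...] = (
    (0, 1, 2, 3, 4, 5, 6, 7, 8, 9),
    (0, 1, 2, 3, 4, 5, 6, 7, 8),
    (0, 1, 2, 3, 4, 5, 6, 7, 9),
    (0, 1, 3, 4, 5, 6, 7, 8, 9),
    (0, 1, 3, 4, 5, 6, 7, 8),
    (0, 1, 3, 4, 5, 6, 7, 9),
    (0, 1, 2, 3, 4, 5, 8, 9),
    (0, 1, 2, 3, 4, 5, 8),
    (0, 1, 2, 3, 4, 5, 9),
    (0, 1, 3, 4, 5, 8, 9),
    (0, 1, 3, 4, 5, 8),
)

#: 0-based exon chains of the four packaged nine-exon-locus isoforms.
GCIGNAR2_CHAINS: Tuple[Tuple[int, ...], ...] = (
    (0, 1, 2, 3, 4, 5, 6, 7, 8),
    (0, 1, 2, 3, 4, 5, 6, 8),
    (0, 1, 2, 3, 4, 5, 6, 7),
    (0, 1, 2, 3, 4, 7, 8),
)


def isoform_fixture(locus: SyntheticLocus,
                    chains: Sequence[Tuple[int, ...]],
                    abundances: Optional[Sequence[float]] = None) -> List[IsoformModel]:
    if abundances is None:
        abundances = [1.0] * len(chains)
    return [
        IsoformModel(locus=locus.model, chain=tuple(chain), abundance=a,
                     name=f"{locus.model.name}-{k + 1}")
        for k, (chain, a) in enumerate(zip(chains, abundances))
    ]


def gcignar1_fixture(seed: int = 11) -> Tuple[SyntheticLocus, List[IsoformModel]]:
    locus = gcignar1_locus(seed=seed)
    return locus, isoform_fixture(locus, GCIGNAR1_CHAINS)


def gcignar2_fixture(seed: int = 22) -> Tuple[SyntheticLocus, List[IsoformModel]]:
    locus = gcignar2_locus(seed=seed)
    return locus, isoform_fixture(locus, GCIGNAR2_CHAINS)


@dataclass(frozen=True)
class ThreeLocusFixture:
    scaffold: str
    scaffold_name: str
    models: Tuple[LocusModel, ...]
    query: str  # VNAR-like protein query


def shift_locus(model: LocusModel, offset: int) -> LocusModel:
    return dataclasses.replace(
        model, exons=tuple((s + offset, e + offset) for s, e in model.exons))


def three_locus_scaffold(seed: int = 7, spacer: int = 60_000,
                         scaffold_name: str = "synthetic_scaffold") -> ThreeLocusFixture:
    """One scaffold carrying three IgNAR-like loci separated by *spacer* bp."""
    rng = np.random.default_rng(seed)
    loci = [
        gcignar1_locus(seed=seed + 1, scaffold_name=scaffold_name),
        gcignar2_locus(seed=seed + 2, scaffold_name=scaffold_name),
        gcignar2_locus(seed=seed + 3, scaffold_name=scaffold_name,
                       name="GcIgNAR3-like"),
    ]
    parts: List[str] = []
    models: List[LocusModel] = []
    pos = 0
    for i, loc in enumerate(loci):
        models.append(shift_locus(loc.model, pos))
        parts.append(loc.scaffold)
        pos += len(loc.scaffold)
        if i < len(loci) - 1:
            parts.append(_random_dna(rng, spacer))
            pos += spacer
    query = loci[0].vnar_protein
    return ThreeLocusFixture("".join(parts), scaffold_name, tuple(models), query)


# ---------------------------------------------------------------------------
# gap masking


def mask_gap(scaffold: str, span: Tuple[int, int]) -> Tuple[str, str]:
    """Replace *span* with N and return (gapped scaffold, hidden truth)."""
    start, end = span
    if start < 0 or end > len(scaffold) or start > end:
        raise ValueError(f"span {span} outside scaffold of length {len(scaffold)}")
    truth = scaffold[start:end]
    return scaffold[:start] + "N" * (end - start) + scaffold[end:], truth


# ---------------------------------------------------------------------------
# genomic read simulation


@dataclass(frozen=True)
class SimulatedPair:
    name: str
    seq1: str          # forward mate, as sequenced
    seq2: str          # reverse mate, as sequenced (reverse-complemented)
    pos1: int          # 0-based leftmost positions on the truth scaffold
    pos2: int
    insert: int


@dataclass(frozen=True)
class GenomicReadSet:
    pairs: Tuple[SimulatedPair, ...]
    read_len: int
    scaffold_name: str
    scaffold_len: int

    def write_fastq(self, path1, path2) -> None:
        qual = "I" * self.read_len
        with open(path1, "w") as f1, open(path2, "w") as f2:
            for p in self.pairs:
                f1.write(f"@{p.name}/1\n{p.seq1}\n+\n{qual}\n")
                f2.write(f"@{p.name}/2\n{p.seq2}\n+\n{qual}\n")

    def write_sam(self, path) -> None:
        """True placements against the ungapped scaffold, as SAM."""
        import pysam

        header = {"HD": {"VN": "1.6", "SO": "unsorted"},
                  "SQ": [{"SN": self.scaffold_name, "LN": self.scaffold_len}]}
        rl = self.read_len
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            for p in self.pairs:
                for which, (seq, pos, mpos, flag) in enumerate(
                    [(p.seq1, p.pos1, p.pos2, 0x1 | 0x2 | 0x20 | 0x40),
                     (revcomp(p.seq2), p.pos2, p.pos1, 0x1 | 0x2 | 0x10 | 0x80)]
                ):
                    a = pysam.AlignedSegment(out.header)
                    a.query_name = p.name
                    a.query_sequence = seq
                    a.flag = flag
                    a.reference_id = 0
                    a.reference_start = pos
                    a.mapping_quality = 60
                    a.cigartuples = [(0, rl)]
                    a.next_reference_id = 0
                    a.next_reference_start = mpos
                    a.template_length = p.insert if which == 0 else -p.insert
                    out.write(a)


def simulate_genomic_reads(scaffold: str, coverage: float = 30.0,
                           read_len: int = 100, insert: int = 300,
                           err: float = 0.0, seed: int = 0,
                           insert_sd: float = 0.0,
                           scaffold_name: str = "synthetic_scaffold") -> GenomicReadSet:
    """Simulate paired-end reads from an ungapped truth scaffold.

    The pair count follows coverage x L / (2 x read_len).  The forward mate
    starts at the fragment's left end; the reverse mate is the
    reverse-complement of the fragment's right end, so mates sit on opposite
    strands at the configured insert size.  Substitution errors are applied
    per base at rate *err*; no indel errors are modelled.
    """
    if not (0.0 <= err <= 1.0):
        raise ValueError("err must lie in [0, 1]")
    if insert < read_len:
        raise ValueError("insert must be >= read_len")
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    L = len(scaffold)
    if insert > L:
        raise ValueError("insert exceeds scaffold length")

    rng = np.random.default_rng(seed)
    n_pairs = int(round(coverage * L / (2 * read_len)))
    bases = np.array(list("ACGT"))

    def mutate(seq: str) -> str:
        if err == 0.0:
            return seq
        arr = np.array(list(seq))
        hits = np.flatnonzero(rng.random(len(arr)) < err)
        for i in hits:
            choices = [b for b in "ACGT" if b != arr[i]]
            arr[i] = choices[rng.integers(0, 3)]
        return "".join(arr)

    pairs = []
    for k in range(n_pairs):
        if insert_sd > 0:
            isize = int(round(rng.normal(insert, insert_sd)))
            isize = max(read_len, min(isize, L))
        else:
            isize = insert
        p = int(rng.integers(0, L - isize + 1))
        frag = scaffold[p:p + isize]
        seq1 = mutate(frag[:read_len])
        seq2 = mutate(revcomp(frag[-read_len:]))
        pairs.append(SimulatedPair(
            name=f"sim_{k:06d}", seq1=seq1, seq2=seq2,
            pos1=p, pos2=p + isize - read_len, insert=isize))
    return GenomicReadSet(tuple(pairs), read_len, scaffold_name, L)


# ---------------------------------------------------------------------------
# spliced read simulation


@dataclass(frozen=True)
class SplicedReadSet:
    alignments: Tuple[SplicedAlignment, ...]
    source: Tuple[str, ...]  # isoform name per fragment (planted truth)
    scaffold_name: str
    scaffold_len: int

    def write_sam(self, path, scaffold: Optional[str] = None) -> None:
        import pysam

        header = {"HD": {"VN": "1.6", "SO": "unsorted"},
                  "SQ": [{"SN": self.scaffold_name, "LN": self.scaffold_len}]}
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            for aln in self.alignments:
                a = pysam.AlignedSegment(out.header)
                a.query_name = aln.fragment_id
                a.flag = 0
                a.reference_id = 0
                a.reference_start = aln.blocks[0][0]
                a.mapping_quality = 60
                cig = []
                for i, (s, e) in enumerate(aln.blocks):
                    if i:
                        cig.append((3, s - aln.blocks[i - 1][1]))  # N
                    cig.append((0, e - s))  # M
                a.cigartuples = cig
                if scaffold is not None:
                    a.query_sequence = "".join(scaffold[s:e] for s, e in aln.blocks)
                a.mapping_quality = 60
                out.write(a)


def simulate_spliced_reads(isoforms: Sequence[IsoformModel],
                           n_fragments: int, read_len: int = 150,
                           seed: int = 0) -> SplicedReadSet:
    """Simulate spliced alignments of full-length transcript fragments.

    Fragments model full-length-capture cDNA evidence: each fragment's
    alignment runs from a random offset inside its chain's first exon to a
    random offset inside the last exon, covering every splice junction of the
    isoform, so the fragment's junction chain is the isoform's signature.
    Fragment counts per isoform are multinomial in the abundances.
    *read_len* is enforced as the minimum fragment span.
    """
    if not isoforms:
        raise ValueError("at least one isoform is required")
    weights = np.array([iso.abundance for iso in isoforms], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("abundances must not all be zero")
    shortest = min(iso.transcript_length for iso in isoforms)
    if read_len > shortest:
        raise ValueError(
            f"read_len {read_len} exceeds the shortest isoform ({shortest} nt)")

    probs = weights / weights.sum()
    rng = np.random.default_rng(seed)
    locus = isoforms[0].locus
    scaffold_len = max(e for _, e in locus.exons) + 1

    alignments: List[SplicedAlignment] = []
    source: List[str] = []
    for k in range(n_fragments):
        iso = isoforms[rng.choice(len(isoforms), p=probs)]
        exons = [locus.exons[i] for i in iso.chain]
        L = iso.transcript_length
        first_len = exons[0][1] - exons[0][0]
        last_len = exons[-1][1] - exons[-1][0]
        s = int(rng.integers(0, min(first_len, max(1, L - read_len + 1))))
        t_max = min(last_len - 1, L - read_len - s)
        t = int(rng.integers(0, t_max + 1)) if t_max > 0 else 0
        blocks = [list(span) for span in exons]
        blocks[0][0] += s
        blocks[-1][1] -= t
        alignments.append(SplicedAlignment(
            fragment_id=f"frag_{k:06d}",
            blocks=tuple((a, b) for a, b in blocks)))
        source.append(iso.name)
    return SplicedReadSet(tuple(alignments), tuple(source),
                          locus.scaffold, scaffold_len)


# ---------------------------------------------------------------------------
# VNAR repertoire generation


@dataclass(frozen=True)
class RepertoireResult:
    names: Tuple[str, ...]
    sequences: Tuple[str, ...]
    truth: Tuple[Mapping, ...]  # per-sequence planted spans and counts
    config: RepertoireConfig

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, seq in zip(self.names, self.sequences):
                fh.write(f">{name}\n{seq}\n")

    def write_truth_tsv(self, path) -> None:
        import csv

        keys = list(self.truth[0].keys()) if self.truth else []
        with open(path, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=keys, delimiter="\t")
            w.writeheader()
            for row in self.truth:
                w.writerow(row)


def default_repertoire_config(**overrides) -> RepertoireConfig:
    defaults = dict(
        n_sequences=100,
        framework_template=dict(DEFAULT_FRAMEWORK),
        hv_mut_rate=0.3,
        cdr3_length_dist={10: 0.3, 12: 0.4, 14: 0.3},
        cdr3_cys_dist={1: 0.3, 2: 0.7},
        fr2_cys=True,
        cdr1_cys=False,
        seed=0,
    )
    defaults.update(overrides)
    return RepertoireConfig(**defaults)


def generate_repertoire(config: RepertoireConfig) -> RepertoireResult:
    """Generate a VNAR repertoire with planted region spans.

    Substitutions touch only CDR1/HV2/HV4 (uniform over the non-identical
    amino acids, never introducing a cysteine), so framework positions and
    the canonical FR1/FR3b cysteines are invariant.  Configured noncanonical
    cysteine positions (FR2 or CDR1) are protected from mutation so the
    cysteine census stays controlled by the configuration.  CDR3 length and
    cysteine count follow the configured discrete distributions.
    """
    rng = np.random.default_rng(config.seed)
    scheme = VnarScheme()
    fr4_cys = config.fr2_cys if config.fr4_cys is None else config.fr4_cys

    len_vals = sorted(config.cdr3_length_dist)
    len_probs = np.array([config.cdr3_length_dist[v] for v in len_vals])
    cys_vals = sorted(config.cdr3_cys_dist)
    cys_probs = np.array([config.cdr3_cys_dist[v] for v in cys_vals])

    names, seqs, truth = [], [], []
    for k in range(config.n_sequences):
        parts: List[str] = []
        spans: Dict[str, Tuple[int, int]] = {}
        pos = 0
        for region in VnarScheme.FIXED_ORDER:
            template = config.framework_template[region]
            protected: set = set()
            chars = list(template)
            if region == "FR2" and config.fr2_cys:
                chars[config.fr2_cys_offset] = "C"
                protected.add(config.fr2_cys_offset)
            if region == "CDR1" and config.cdr1_cys:
                chars[config.cdr1_cys_offset] = "C"
                protected.add(config.cdr1_cys_offset)
            if region in VnarScheme.HYPERVARIABLE and config.hv_mut_rate > 0:
                for i in range(len(chars)):
                    if i in protected or chars[i] == "C":
                        continue
                    if rng.random() < config.hv_mut_rate:
                        options = [a for a in AA20 if a != chars[i] and a != "C"]
                        chars[i] = options[rng.integers(0, len(options))]
            seg = "".join(chars)
            spans[region] = (pos, pos + len(seg))
            parts.append(seg)
            pos += len(seg)

        cdr3_len = int(len_vals[rng.choice(len(len_vals), p=len_probs)])
        n_cys = int(cys_vals[rng.choice(len(cys_vals), p=cys_probs)])
        # the FR4 anchor is a framework motif: redraw CDR3s that would create
        # a premature anchor match, so the planted CDR3/FR4 boundary is the
        # one the positional scheme recovers
        for _ in range(100):
            cdr3 = list(_random_protein(rng, cdr3_len))
            if n_cys:
                cys_pos = sorted(rng.choice(cdr3_len, size=n_cys, replace=False))
                for i in cys_pos:
                    cdr3[i] = "C"
            probe = "".join(cdr3) + config.fr4_template[:3]
            m = re.search(scheme.fr4_anchor, probe)
            if m is None or m.start() >= cdr3_len:
                break
        spans["CDR3"] = (pos, pos + cdr3_len)
        parts.append("".join(cdr3))
        pos += cdr3_len

        fr4 = list(config.fr4_template)
        if fr4_cys and "C" not in fr4:
            fr4[4] = "C"
        spans["FR4"] = (pos, pos + len(fr4))
        parts.append("".join(fr4))
        pos += len(fr4)

        seq = "".join(parts)
        names.append(f"vnar_{k:05d}")
        seqs.append(seq)
        truth.append({
            "name": names[-1],
            **{f"{r}_start": spans[r][0] for r in spans},
            **{f"{r}_end": spans[r][1] for r in spans},
            "cdr3_len": cdr3_len,
            "cdr3_cys": n_cys,
            "fr2_cys": config.fr2_cys,
            "cdr1_cys": config.cdr1_cys,
        })
    return RepertoireResult(tuple(names), tuple(seqs), tuple(truth), config)
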