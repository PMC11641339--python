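"""Geometric disulfide-bond detection and classification on 3D structures.

Cysteine sulfur (SG) atoms are paired greedily by distance; bonds are mapped
onto per-chain domain ranges and classified as intra-domain, inter-domain,
or inter-chain.  The inter-chain class captures the dimerisation bond formed
by the C3-C4 linker cysteines of homodimeric heavy-chain-only antibodies;
the expectation checks flag constant domains that lack an internal bond and
linker cysteines whose bond is not inter-chain.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

from .models import DisulfideBond

#: typical S-S bond length is ~2.05 A; 2.5 A separates bonded from packed pairs
DEFAULT_THRESHOLD = 2.5

INTRA = "intra-domain"
INTER_DOMAIN = "inter-domain"
INTER_CHAIN = "inter-chain"
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class SulfurAtom:
    chain: str
    resnum: int
    icode: str
    coord: Tuple[float, float, float]

    @property
    def resid(self) -> str:
        return f"{self.resnum}{self.icode}".strip()

    @property
    def key(self) -> Tuple[str, str]:
        return (self.chain, self.resid)

    @property
    def sort_key(self) -> Tuple[str, int, str]:
        return (self.chain, self.resnum, self.icode)


def _load_sulfurs(structure) -> List[SulfurAtom]:
    """Cysteine SG atoms from a PDB path or a Bio.PDB structure."""
    if isinstance(structure, (list, tuple)) and (
            not structure or isinstance(structure[0], SulfurAtom)):
        return list(structure)
    if isinstance(structure, (str, bytes)) or hasattr(structure, "__fspath__"):
        from Bio.PDB import PDBParser

        parser = PDBParser(QUIET=True)
        structure = parser.get_structure("model", str(structure))
    atoms: List[SulfurAtom] = []
    model = next(structure.get_models())
    for chain in model:
        for residue in chain:
            if residue.get_resname().strip() != "CYS":
                continue
            if "SG" not in residue:
                continue
            het, resseq, icode = residue.get_id()
            coord = residue["SG"].get_coord()
            atoms.append(SulfurAtom(chain=chain.get_id(), resnum=int(resseq),
                                    icode=icode.strip(),
                                    coord=(float(coord[0]), float(coord[1]),
                                           float(coord[2]))))
    return atoms


def _distance(a: SulfurAtom, b: SulfurAtom) -> float:
    return math.dist(a.coord, b.coord)


def detect_disulfides(structure, threshold: float = DEFAULT_THRESHOLD
                      ) -> List[DisulfideBond]:
    """Greedy nearest-pair matching of SG atoms within *threshold* Angstrom.

    Every sulfur joins at most one bond; candidate pairs are consumed in
    order of increasing distance with ties broken by (chain, residue number).
    Distances are reported to 0.01 A.  The result is invariant under atom
    order in the input.
    """
    atoms = sorted(_load_sulfurs(structure), key=lambda a: a.sort_key)
    candidates = []
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            d = _distance(atoms[i], atoms[j])
            if d <= threshold:
                candidates.append((d, atoms[i], atoms[j]))
    candidates.sort(key=lambda c: (c[0], c[1].sort_key, c[2].sort_key))
    used: set = set()
    bonds = []
    for d, a, b in candidates:
        if a.key in used or b.key in used:
            continue
        used.update({a.key, b.key})
        bonds.append(DisulfideBond(residue_a=a.key, residue_b=b.key,
                                   distance=round(d, 2),
                                   klass=INTER_CHAIN if a.chain != b.chain
                                   else None))
    return bonds


DomainRanges = Mapping[str, Sequence[Tuple[int, int, str]]]


def _label_of(domain_ranges: DomainRanges, chain: str, resid: str) -> str:
    num = int("".join(ch for ch in resid if ch.isdigit() or ch == "-") or 0)
    for start, end, label in domain_ranges.get(chain, ()):
        if start <= num <= end:
            return label
    return UNASSIGNED


def _check_ranges(domain_ranges: DomainRanges) -> None:
    for chain, ranges in domain_ranges.items():
        ordered = sorted(ranges)
        for (s1, e1, l1), (s2, e2, l2) in zip(ordered, ordered[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"overlapping domain ranges on chain {chain}: "
                    f"{l1}({s1}-{e1}) and {l2}({s2}-{e2})")


@dataclass(frozen=True)
class BondSummary:
    by_class: Mapping[str, int]
    by_domain: Mapping[str, int]
    flags: Tuple[str, ...]


def classify_bonds(bonds: Sequence[DisulfideBond],
                   domain_ranges: DomainRanges
                   ) -> Tuple[List[DisulfideBond], BondSummary]:
    """Assign intra-domain / inter-domain / inter-chain classes to bonds.

    Raises on overlapping domain ranges.  Flags are raised when a constant
    domain named in the ranges lacks an internal bond and when a linker
    cysteine's bond is not inter-chain.
    """
    _check_ranges(domain_ranges)
    annotated: List[DisulfideBond] = []
    by_class: Dict[str, int] = {}
    by_domain: Dict[str, int] = {}
    internal_bonded: set = set()  # (chain, domain) with an intra-domain bond
    flags: List[str] = []

    for bond in bonds:
        chain_a, resid_a = bond.residue_a
        chain_b, resid_b = bond.residue_b
        dom_a = _label_of(domain_ranges, chain_a, str(resid_a))
        dom_b = _label_of(domain_ranges, chain_b, str(resid_b))
        if chain_a != chain_b:
            klass = INTER_CHAIN
        elif dom_a == dom_b and dom_a != UNASSIGNED:
            klass = INTRA
            internal_bonded.add((chain_a, dom_a))
        else:
            klass = INTER_DOMAIN
            flags.append(f"inter-domain-bond:{chain_a}:{dom_a}-{dom_b}")
        for dom in {dom_a, dom_b}:
            by_domain[dom] = by_domain.get(dom, 0) + 1
        by_class[klass] = by_class.get(klass, 0) + 1
        annotated.append(DisulfideBond(residue_a=bond.residue_a,
                                       residue_b=bond.residue_b,
                                       distance=bond.distance, klass=klass,
                                       domains=(dom_a, dom_b)))
        for side_dom in (dom_a, dom_b):
            if "linker" in side_dom.lower() and klass != INTER_CHAIN:
                flags.append(f"linker-cysteine-not-inter-chain:{side_dom}")

    for chain, ranges in sorted(domain_ranges.items()):
        for start, end, label in ranges:
            if label.startswith("C") and label[1:].isdigit():
                if (chain, label) not in internal_bonded:
                    flags.append(f"no-internal-bond:{chain}:{label}")

    return annotated, BondSummary(by_class=by_class, by_domain=by_domain,
                                  flags=tuple(flags))


def unpaired_report(structure, domain_ranges: Optional[DomainRanges] = None,
                    threshold: float = DEFAULT_THRESHOLD
                    ) -> List[Tuple[str, str, str]]:
    """Cysteines whose sulfur joins no detected bond: (chain, resid, domain)."""
    atoms = sorted(_load_sulfurs(structure), key=lambda a: a.sort_key)
    bonds = detect_disulfides(atoms, threshold)
    bonded = {bond.residue_a for bond in bonds} | {bond.residue_b for bond in bonds}
    out = []
    for atom in atoms:
        if atom.key in bonded:
            continue
        label = (_label_of(domain_ranges, atom.chain, atom.resid)
                 if domain_ranges else UNASSIGNED)
        out.append((atom.chain, atom.resid, label))
    return out
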