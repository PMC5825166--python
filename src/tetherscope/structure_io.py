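"""Read/write single-chain protein structures and resolve domains.

The pipeline operates on X-ray structures that contain exactly one
polypeptide chain; heteroatoms and waters are discarded on load and, for
alternate-location groups, only the highest-occupancy conformer is kept.
Domains are identified by SCOPe-style inclusive residue ranges, common
domains of a structure pair are mapped by global sequence alignment, and
domain-domain interface residues are detected with a van-der-Waals-radii
plus margin distance criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import yaml
from Bio import Align
from scipy.spatial.distance import cdist

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "DomainDefinition",
    "ResidueMapping",
    "InterfaceSet",
    "StructureError",
    "MultiChainError",
    "BoundaryError",
    "PairingError",
    "DefinitionError",
    "DEFAULT_VDW_RADII",
    "read_structure",
    "write_structure",
    "extract_domain",
    "map_common_domain",
    "interface_residues",
    "load_domain_config",
]

#: Element-based van der Waals radii in Angstrom. The interface criterion
#: needs only heavy atoms for crystal structures; H is included for
#: completeness. The table is a plain mapping so callers can substitute
#: their own.
DEFAULT_VDW_RADII: Mapping[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "H": 1.20,
}
_FALLBACK_RADIUS = 1.70


class StructureError(ValueError):
    """Input text does not yield a usable polypeptide structure."""


class MultiChainError(StructureError):
    """More than one polypeptide chain present; caller must select one."""


class BoundaryError(KeyError):
    """A domain segment cannot be resolved against the structure."""


class PairingError(ValueError):
    """Two structures do not form a valid identical-domain pair."""


class DefinitionError(ValueError):
    """Domain definitions are inconsistent (e.g. overlapping)."""


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    xyz: tuple[float, float, float]
    occupancy: float = 1.0

    @property
    def coords(self) -> np.ndarray:
        return np.asarray(self.xyz, dtype=float)


@dataclass(frozen=True)
class Residue:
    chain: str
    number: int
    icode: str
    name: str
    atoms: tuple[Atom, ...]

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.number, self.icode)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Atom | None:
        return self.atom("CA")


@dataclass
class Structure:
    """One polypeptide chain: ordered residues with their atoms."""

    id: str
    residues: list[Residue]

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def chain_id(self) -> str:
        return self.residues[0].chain if self.residues else ""

    def ca_coords(self) -> np.ndarray:
        """N x 3 array of Cα coordinates; raises if a residue lacks Cα."""
        coords = []
        for r in self.residues:
            ca = r.ca
            if ca is None:
                raise StructureError(
                    f"{self.id}: residue {r.key} has no CA atom"
                )
            coords.append(ca.xyz)
        return np.asarray(coords, dtype=float)

    def sequence(self) -> str:
        return "".join(_one_letter(r.name) for r in self.residues)

    def residue_index(self) -> dict[tuple[str, int, str], int]:
        return {r.key: i for i, r in enumerate(self.residues)}


@dataclass(frozen=True)
class DomainDefinition:
    """Inclusive residue ranges, SCOPe style: [(chain, start, end), ...]."""

    domain_id: str
    segments: tuple[tuple[str, int, int], ...]

    def __post_init__(self):
        for chain, start, end in self.segments:
            if end < start:
                raise DefinitionError(
                    f"{self.domain_id}: segment {chain}:{start}-{end} empty"
                )

    def contains(self, residue: Residue) -> bool:
        return any(
            residue.chain == chain and start <= residue.number <= end
            for chain, start, end in self.segments
        )


@dataclass(frozen=True)
class ResidueMapping:
    """Collinear residue-index correspondence between two structures."""

    pairs: tuple[tuple[int, int], ...]
    identity_fraction: float

    def __post_init__(self):
        prev_a, prev_b = -1, -1
        for ia, ib in self.pairs:
            if ia <= prev_a or ib <= prev_b:
                raise ValueError("mapping must be strictly increasing")
            prev_a, prev_b = ia, ib

    def __len__(self) -> int:
        return len(self.pairs)

    def a_indices(self) -> list[int]:
        return [ia for ia, _ in self.pairs]

    def b_indices(self) -> list[int]:
        return [ib for _, ib in self.pairs]

    def b_for_a(self, ia: int) -> int:
        for a, b in self.pairs:
            if a == ia:
                return b
        raise KeyError(f"residue index {ia} not mapped")


@dataclass(frozen=True)
class InterfaceSet:
    """Residues of two domains in atomic contact, with the contact list."""

    residue_indices: frozenset[int]
    contacts: tuple[tuple[tuple[int, str], tuple[int, str], float], ...]

    def __contains__(self, idx: int) -> bool:
        return idx in self.residue_indices


def _one_letter(resname: str) -> str:
    info = gemmi.find_tabulated_residue(resname)
    if info is None or not info.is_amino_acid():
        return "X"
    code = info.one_letter_code.upper()
    return code if code.isalpha() else "X"


def _collapse_altlocs(atoms: list[tuple[str, str, str, tuple, float]]):
    """Keep the highest-occupancy conformer per atom name (ties: first)."""
    best: dict[str, tuple[int, Atom]] = {}
    order: list[str] = []
    for pos, (name, altloc, element, xyz, occ) in enumerate(atoms):
        if name not in best:
            order.append(name)
            best[name] = (pos, Atom(name, element, xyz, occ))
        elif occ > best[name][1].occupancy:
            best[name] = (best[name][0], Atom(name, element, xyz, occ))
    return [best[n][1] for n in order]


def read_structure(
    pdb_text: str, structure_id: str = "", chain: str | None = None
) -> Structure:
    """Parse PDB text into a single-chain :class:`Structure`.

    Only the first MODEL is read. HETATM records, waters and non-amino-acid
    residues are dropped; alternate locations are collapsed to the
    highest-occupancy conformer. If more than one polypeptide chain remains
    a :class:`MultiChainError` is raised unless ``chain`` selects one.
    """
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise StructureError("no models in PDB text")
    st.setup_entities()
    model = st[0]

    chains: dict[str, list[Residue]] = {}
    for ch in model:
        residues: list[Residue] = []
        for res in ch:
            if res.het_flag != "A" or res.name == "HOH":
                continue
            info = gemmi.find_tabulated_residue(res.name)
            if info is not None and not info.is_amino_acid():
                continue
            raw = [
                (
                    a.name,
                    a.altloc,
                    a.element.name,
                    (a.pos.x, a.pos.y, a.pos.z),
                    a.occ,
                )
                for a in res
            ]
            atoms = _collapse_altlocs(raw)
            residues.append(
                Residue(
                    chain=ch.name,
                    number=res.seqid.num,
                    icode=res.seqid.icode.strip(),
                    name=res.name,
                    atoms=tuple(atoms),
                )
            )
        if any(r.ca is not None for r in residues):
            chains[ch.name] = residues

    if not chains:
        raise StructureError("no polypeptide ATOM records found")
    if chain is not None:
        if chain not in chains:
            raise StructureError(f"chain {chain!r} not found")
        picked = chains[chain]
    elif len(chains) > 1:
        raise MultiChainError(
            f"{sorted(chains)}: more than one polypeptide chain; "
            "pass chain= to select one"
        )
    else:
        picked = next(iter(chains.values()))
    return Structure(id=structure_id or st.name or "structure", residues=picked)


def write_structure(s: Structure) -> str:
    """Serialize a structure back to PDB text (ATOM records, one chain)."""
    st = gemmi.Structure()
    st.name = s.id
    model = gemmi.Model("1")
    chain = gemmi.Chain(s.chain_id or "A")
    for r in s.residues:
        res = gemmi.Residue()
        res.name = r.name
        res.seqid = gemmi.SeqId(r.number, r.icode or " ")
        for a in r.atoms:
            atom = gemmi.Atom()
            atom.name = a.name
            atom.element = gemmi.Element(a.element)
            atom.pos = gemmi.Position(*a.xyz)
            atom.occ = a.occupancy
            res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st.make_pdb_string()


def extract_domain(s: Structure, d: DomainDefinition) -> Structure:
    """Return the sub-structure inside the definition's segments.

    Residue numbering, order and coordinates are preserved. Each segment
    must select at least one residue, otherwise a BoundaryError is raised.
    """
    selected: list[Residue] = []
    for chain, start, end in d.segments:
        seg = [
            r
            for r in s.residues
            if r.chain == chain and start <= r.number <= end
        ]
        if not seg:
            raise BoundaryError(
                f"{s.id}: segment {chain}:{start}-{end} matches no residues"
            )
        selected.extend(seg)
    # preserve file order, drop duplicates from overlapping segments
    index = s.residue_index()
    seen: set[tuple[str, int, str]] = set()
    ordered = []
    for r in sorted(selected, key=lambda r: index[r.key]):
        if r.key not in seen:
            seen.add(r.key)
            ordered.append(r)
    return Structure(id=f"{s.id}:{d.domain_id}", residues=ordered)


def _global_alignment(seq_a: str, seq_b: str):
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner.align(seq_a, seq_b)[0]


def map_common_domain(
    a: Structure,
    b: Structure,
    mode: str = "identical",
    min_identity: float = 0.9,
) -> ResidueMapping:
    """Map the common domain of ``a`` onto ``b`` by global alignment.

    In ``identical`` mode (same protein crystallized twice, possibly with
    small terminal differences) only identically-matching aligned columns
    are kept and the mapping must reach ``min_identity`` over aligned
    columns, else a PairingError is raised. In ``homolog`` mode all
    aligned non-gap columns are mapped and the identity fraction is merely
    reported.
    """
    if mode not in ("identical", "homolog"):
        raise ValueError(f"unknown mapping mode {mode!r}")
    seq_a, seq_b = a.sequence(), b.sequence()
    if not seq_a or not seq_b:
        raise PairingError("empty sequence")
    aln = _global_alignment(seq_a, seq_b)
    pairs: list[tuple[int, int]] = []
    n_aligned = n_identical = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        for off in range(a1 - a0):
            ia, ib = a0 + off, b0 + off
            n_aligned += 1
            same = seq_a[ia] == seq_b[ib]
            n_identical += same
            if mode == "homolog" or same:
                pairs.append((ia, ib))
    if n_aligned == 0:
        raise PairingError(f"{a.id} vs {b.id}: no aligned columns")
    identity = n_identical / n_aligned
    if mode == "identical" and identity < min_identity:
        raise PairingError(
            f"{a.id} vs {b.id}: identity {identity:.3f} < {min_identity} "
            "in identical-domain mode"
        )
    return ResidueMapping(pairs=tuple(pairs), identity_fraction=identity)


def _domain_atoms(s: Structure, d: DomainDefinition):
    idx, coords, radii_key, labels = [], [], [], []
    for i, r in enumerate(s.residues):
        if d.contains(r):
            for a in r.atoms:
                idx.append(i)
                coords.append(a.xyz)
                radii_key.append(a.element)
                labels.append(a.name)
    return np.array(idx), np.asarray(coords, float), radii_key, labels


def interface_residues(
    s: Structure,
    da: DomainDefinition,
    db: DomainDefinition,
    radii: Mapping[str, float] | None = None,
    margin: float = 0.5,
) -> InterfaceSet:
    """Residues of ``da``/``db`` with atoms closer than r_vdw(a)+r_vdw(b)+margin.

    The inequality is strict: a pair at exactly the threshold distance is
    not a contact. Domains must be disjoint.
    """
    radii = DEFAULT_VDW_RADII if radii is None else radii
    ia_set = {i for i, r in enumerate(s.residues) if da.contains(r)}
    ib_set = {i for i, r in enumerate(s.residues) if db.contains(r)}
    if ia_set & ib_set:
        raise DefinitionError(
            f"domains {da.domain_id} and {db.domain_id} overlap"
        )
    idx_a, xyz_a, el_a, name_a = _domain_atoms(s, da)
    idx_b, xyz_b, el_b, name_b = _domain_atoms(s, db)
    if len(idx_a) == 0 or len(idx_b) == 0:
        return InterfaceSet(frozenset(), ())
    dists = cdist(xyz_a, xyz_b)
    ra = np.array([radii.get(e, _FALLBACK_RADIUS) for e in el_a])
    rb = np.array([radii.get(e, _FALLBACK_RADIUS) for e in el_b])
    thresholds = ra[:, None] + rb[None, :] + margin
    hits = np.argwhere(dists < thresholds)
    residues: set[int] = set()
    contacts = []
    for i, j in hits:
        residues.add(int(idx_a[i]))
        residues.add(int(idx_b[j]))
        contacts.append(
            (
                (int(idx_a[i]), name_a[i]),
                (int(idx_b[j]), name_b[j]),
                float(dists[i, j]),
            )
        )
    return InterfaceSet(frozenset(residues), tuple(contacts))


def load_domain_config(text: str) -> dict:
    """Parse a YAML/JSON domain config.

    Layout::

        structure: path/to.pdb
        domains:
          - id: d1
            segments: [[A, 1, 120]]
        functional_residues: [23, 57]
    """
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict) or "domains" not in cfg:
        raise ValueError("config must be a mapping with a 'domains' list")
    domains = [
        DomainDefinition(
            domain_id=str(d["id"]),
            segments=tuple(
                (str(c), int(s), int(e)) for c, s, e in d["segments"]
            ),
        )
        for d in cfg["domains"]
    ]
    return {
        "structure": cfg.get("structure"),
        "domains": domains,
        "functional_residues": [
            int(x) for x in cfg.get("functional_residues", [])
        ],
    }
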