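"""In-silico control constructs: amputated, swapped and chimeric structures.

Three controls disentangle the effect of domain tethering from
crystal-packing artefacts:

* amputated domain (AD) — the tethered copy with its extra domains
  deleted, leaving the common domain's coordinates untouched;
* swapped domain — the isolated copy rigidly grafted into the
  multi-domain scaffold in place of the common domain;
* chimera — a single-domain homolog grafted into a multi-domain
  partner's scaffold, with junction residues trimmed alternately from
  the two parents until no short inter-parent contacts remain.

No refinement is performed after grafting: the downstream elastic-network
and contact analyses are purely distance-based and tolerate junction gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .structure_io import (
    DomainDefinition,
    ResidueMapping,
    Residue,
    Atom,
    Structure,
    extract_domain,
)
from .superpose import Superposition, apply_superposition, kabsch_superpose

__all__ = [
    "ConstructRecord",
    "ChimeraFailureError",
    "amputate",
    "swap_common_domain",
    "build_chimera",
]


class ChimeraFailureError(RuntimeError):
    """Junction clash not resolvable within the trimming budget."""


@dataclass
class ConstructRecord:
    """Provenance of an in-silico construct."""

    kind: str                                  # amputated | swapped | chimera
    source_ids: tuple[str, ...]
    trimmed: dict[str, int] = field(default_factory=dict)   # junction side -> residues removed
    provenance: list[tuple[str, tuple[str, int, str]]] = field(
        default_factory=list
    )                                          # (parent id, original residue key)


def _transform_residue(r: Residue, sup: Superposition) -> Residue:
    atoms = tuple(
        Atom(
            name=a.name,
            element=a.element,
            xyz=tuple(apply_superposition(sup, np.asarray(a.xyz)[None, :])[0]),
            occupancy=a.occupancy,
        )
        for a in r.atoms
    )
    return Residue(r.chain, r.number, r.icode, r.name, atoms)


def amputate(
    md: Structure, common: DomainDefinition
) -> tuple[Structure, ConstructRecord]:
    """Delete the tethered domains, keeping only the common domain.

    Coordinates are bit-identical to the parent; only residues outside
    the common-domain definition are removed.
    """
    kept = extract_domain(md, common)
    kept.id = f"{md.id}:AD"
    record = ConstructRecord(
        kind="amputated",
        source_ids=(md.id,),
        provenance=[(md.id, r.key) for r in kept.residues],
    )
    return kept, record


def swap_common_domain(
    md: Structure,
    id_: Structure,
    mapping: ResidueMapping,
    common: DomainDefinition,
) -> tuple[Structure, ConstructRecord]:
    """Graft the isolated domain into the multi-domain scaffold.

    The isolated structure is rigidly superposed (Kabsch on mapped Cα)
    onto the tethered copy's common domain; the common domain is then
    replaced by the transformed isolated copy while the uncommon domains
    keep their coordinates. Only mutually resolved common-domain
    residues are replaced; common-domain residues of the scaffold with
    no counterpart are dropped so the product's sequence matches the
    scaffold over mutually resolved positions.
    """
    md_index = md.residue_index()
    common_res = extract_domain(md, common).residues
    common_idx = {md_index[r.key] for r in common_res}

    xa, xb, mapped_md, mapped_id = [], [], {}, []
    for ia, ib in mapping.pairs:
        ra, rb = md.residues[ia], id_.residues[ib]
        if ia not in common_idx:
            continue
        if ra.ca is None or rb.ca is None:
            continue
        xa.append(ra.ca.xyz)
        xb.append(rb.ca.xyz)
        mapped_md[ia] = ib
        mapped_id.append(ib)
    if len(xa) < 3:
        raise ValueError("need at least 3 mapped CA for the graft")
    sup = kabsch_superpose(np.asarray(xa), np.asarray(xb))

    residues: list[Residue] = []
    record = ConstructRecord(kind="swapped", source_ids=(md.id, id_.id))
    for i, r in enumerate(md.residues):
        if i in common_idx:
            if i not in mapped_md:
                continue  # not resolved in the isolated member
            donor = id_.residues[mapped_md[i]]
            moved = _transform_residue(donor, sup)
            # keep scaffold numbering for a drop-in replacement
            moved = Residue(r.chain, r.number, r.icode, donor.name, moved.atoms)
            residues.append(moved)
            record.provenance.append((id_.id, donor.key))
        else:
            residues.append(r)
            record.provenance.append((md.id, r.key))
    return Structure(id=f"{md.id}:swapped", residues=residues), record


def _min_interparent_distance(
    part_a: list[Residue], part_b: list[Residue]
) -> float:
    xa = np.asarray([a.xyz for r in part_a for a in r.atoms], float)
    xb = np.asarray([a.xyz for r in part_b for a in r.atoms], float)
    if xa.size == 0 or xb.size == 0:
        return np.inf
    return float(cdist(xa, xb).min())


def build_chimera(
    single: Structure,
    multi: Structure,
    homolog_map: ResidueMapping,
    host_domain: DomainDefinition,
    clash: float = 2.0,
    max_trim: int = 9,
) -> tuple[Structure, ConstructRecord]:
    """Graft a single-domain homolog into a multi-domain scaffold.

    ``homolog_map`` maps residues of ``single`` onto residues of
    ``multi``; ``host_domain`` names the scaffold domain being replaced.
    The homolog is superposed on the host domain via the mapped Cα, the
    host domain is excised, and the transformed homolog grafted in.
    While any atom of the graft lies closer than ``clash`` Å to an atom
    of the scaffold, one residue is removed alternately from the graft
    terminus and the scaffold terminus at the offending junction,
    starting with the graft side, up to ``max_trim`` residues per side.
    """
    if len(homolog_map) < max(3, len(single.residues) // 2):
        raise ValueError("homolog mapping must cover at least half of the graft")
    multi_index = multi.residue_index()
    host_res = extract_domain(multi, host_domain).residues
    host_idx = sorted(multi_index[r.key] for r in host_res)
    host_set = set(host_idx)

    xa, xb = [], []
    for i_single, i_multi in homolog_map.pairs:
        if i_multi not in host_set:
            continue
        rs, rm = single.residues[i_single], multi.residues[i_multi]
        if rs.ca is None or rm.ca is None:
            continue
        xa.append(rm.ca.xyz)
        xb.append(rs.ca.xyz)
    if len(xa) < 3:
        raise ValueError("homolog mapping does not cover the host domain")
    sup = kabsch_superpose(np.asarray(xa), np.asarray(xb))
    graft = [_transform_residue(r, sup) for r in single.residues]

    scaffold_before = [multi.residues[i] for i in range(min(host_idx))]
    scaffold_after = [
        multi.residues[i]
        for i in range(max(host_idx) + 1, len(multi.residues))
        if i not in host_set
    ]

    # Alternate trimming across the junction termini, graft (downstream
    # parent at the N-junction) first, until no inter-parent clash remains.
    trims = {"graft-N": 0, "graft-C": 0, "scaffold-N": 0, "scaffold-C": 0}
    cycle = ["graft-N", "scaffold-C", "graft-C", "scaffold-N"]
    turn = 0
    while True:
        scaffold = scaffold_before + scaffold_after
        if _min_interparent_distance(graft, scaffold) >= clash:
            break
        trimmed = False
        for attempt in range(len(cycle)):
            side = cycle[(turn + attempt) % len(cycle)]
            if side == "graft-N" and trims[side] < max_trim and len(graft) > 3:
                graft = graft[1:]
            elif side == "scaffold-C" and trims[side] < max_trim and scaffold_before:
                scaffold_before = scaffold_before[:-1]
            elif side == "graft-C" and trims[side] < max_trim and len(graft) > 3:
                graft = graft[:-1]
            elif side == "scaffold-N" and trims[side] < max_trim and scaffold_after:
                scaffold_after = scaffold_after[1:]
            else:
                continue
            trims[side] += 1
            turn = (turn + attempt + 1) % len(cycle)
            trimmed = True
            break
        if not trimmed:
            raise ChimeraFailureError(
                f"clash below {clash} Å persists after trimming {trims}"
            )

    chain = multi.chain_id or "A"
    residues: list[Residue] = []
    record = ConstructRecord(
        kind="chimera", source_ids=(single.id, multi.id), trimmed=dict(trims)
    )
    number = 0
    for parent_id, part in (
        (multi.id, scaffold_before),
        (single.id, graft),
        (multi.id, scaffold_after),
    ):
        for r in part:
            number += 1
            residues.append(Residue(chain, number, "", r.name, r.atoms))
            record.provenance.append((parent_id, r.key))
    return Structure(id=f"{multi.id}:chimera", residues=residues), record
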