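"""Energetic frustration: native-vs-decoy Z-scores on a contact potential.

Local frustration asks whether the amino acids actually found at a
contact (or a residue's whole contact set) are energetically as good as
the alternatives. The native energy is compared with an ensemble of
decoys and the frustration index is the Z-score

    index = (mean(E_decoys) - E_native) / sd(E_decoys)

so a native arrangement more stable than typical decoys scores positive.
Items with index > 0.78 are minimally frustrated, index < -1 highly
frustrated, and everything in between (boundaries included) neutral.

Three indices are computed:

* mutational frustration (MFI), per contact — decoys mutate the contact
  pair to every other amino-acid pair with the structural context fixed;
* configurational frustration (CFI), per contact — decoys keep the
  native pair but re-sample the structural context (distance class and
  burial) from the structure's own empirical distributions;
* single-residue frustration (SRLF), per residue — decoys substitute the
  19 alternative identities and re-score all of the residue's contacts.

Contacts are Cα pairs within 5 Å, at least 2 apart in sequence. The
energy model is deliberately lightweight: a symmetric 20x20 contact
table (the packaged default is derived from hydropathy
complementarity), a two-level distance-class weight and a linear burial
bonus. It is a pluggable stand-in for heavier coarse-grained force
fields; the decoy/Z-score machinery is independent of the table used.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .structure_io import Structure, _one_letter

__all__ = [
    "AA_ORDER",
    "Contact",
    "ContactPotential",
    "ContactEnergyModel",
    "FrustrationProfile",
    "UndefinedIndexError",
    "contact_list",
    "frustration_index",
    "decoys_mutational",
    "decoys_configurational",
    "srlf",
    "classify_frustration",
    "structure_frustration",
]

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

# Kyte-Doolittle hydropathy, the basis of the default contact table.
_HYDROPATHY = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8,
    "G": -0.4, "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8,
    "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5, "R": -4.5,
    "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}


class UndefinedIndexError(ValueError):
    """Decoy ensemble has zero energy spread; Z-score undefined."""


@dataclass(frozen=True)
class Contact:
    i: int
    j: int
    distance: float


@dataclass
class ContactPotential:
    """Symmetric 20x20 contact energy table over AA_ORDER."""

    table: np.ndarray
    name: str = "custom"

    def __post_init__(self):
        t = np.asarray(self.table, float)
        if t.shape != (20, 20):
            raise ValueError("potential table must be 20x20")
        if not np.allclose(t, t.T):
            raise ValueError("potential table must be symmetric")
        if not np.all(np.isfinite(t)):
            raise ValueError("potential table must be finite")
        self.table = t

    def energy(self, a: str, b: str) -> float:
        return float(self.table[AA_ORDER.index(a), AA_ORDER.index(b)])

    @classmethod
    def from_csv(cls, text: str, name: str = "csv") -> "ContactPotential":
        df = pd.read_csv(io.StringIO(text), index_col=0)
        df = df.loc[list(AA_ORDER), list(AA_ORDER)]
        return cls(table=df.to_numpy(float), name=name)

    def to_csv(self) -> str:
        df = pd.DataFrame(self.table, index=list(AA_ORDER), columns=list(AA_ORDER))
        return df.to_csv(float_format="%.4f")

    @classmethod
    def default(cls) -> "ContactPotential":
        """Packaged hydropathy-complementarity table."""
        text = (
            resources.files("tetherscope.data")
            .joinpath("contact_potential.csv")
            .read_text()
        )
        return cls.from_csv(text, name="hydropathy-v1")


def hydropathy_potential() -> ContactPotential:
    """Contact energies from pairwise hydropathy products.

    e(a, b) = -h(a) h(b) / 9 - (h(a) + h(b)) / 18, favouring
    hydrophobic-hydrophobic burial; used to generate the packaged table.
    """
    h = np.array([_HYDROPATHY[a] for a in AA_ORDER])
    table = -np.outer(h, h) / 9.0 - (h[:, None] + h[None, :]) / 18.0
    return ContactPotential(table=table, name="hydropathy-v1")


@dataclass
class ContactEnergyModel:
    """Pairwise energy = table * distance-class weight + burial bonus."""

    potential: ContactPotential
    class_boundary: float = 4.25          # Å; short vs long contact
    class_weights: tuple[float, float] = (1.2, 1.0)
    burial_beta: float = -0.05            # per neighbouring contact

    def distance_class(self, d: float) -> int:
        return 0 if d < self.class_boundary else 1

    def pair_energy(
        self, a: str, b: str, dclass: int, burial_i: int, burial_j: int
    ) -> float:
        return (
            self.potential.energy(a, b) * self.class_weights[dclass]
            + self.burial_beta * (burial_i + burial_j)
        )


@dataclass
class FrustrationProfile:
    """Per-residue SRLF and per-contact MFI/CFI with class labels."""

    srlf: dict[int, float]
    srlf_class: dict[int, str]
    contacts: list[Contact]
    mfi: dict[tuple[int, int], float]
    cfi: dict[tuple[int, int], float]
    mfi_class: dict[tuple[int, int], str] = field(default_factory=dict)
    cfi_class: dict[tuple[int, int], str] = field(default_factory=dict)
    decoy_count: int = 0
    seed: int | None = None

    def missing_residues(self, n_residues: int) -> list[int]:
        return [i for i in range(n_residues) if i not in self.srlf]


def contact_list(
    s: Structure | np.ndarray, cutoff: float = 5.0, min_seq_sep: int = 2
) -> list[Contact]:
    """Cα contacts: distance <= cutoff (inclusive) and |i - j| >= min_seq_sep."""
    coords = s if isinstance(s, np.ndarray) else s.ca_coords()
    coords = np.asarray(coords, float)
    if coords.shape[0] == 0:
        return []
    d = squareform(pdist(coords))
    contacts = []
    n = coords.shape[0]
    for i in range(n):
        for j in range(i + min_seq_sep, n):
            if d[i, j] <= cutoff:
                contacts.append(Contact(i, j, float(d[i, j])))
    return contacts


def frustration_index(e_native: float, e_decoys: np.ndarray) -> float:
    """Z-score of the native energy against the decoy ensemble.

    Positive when the native is more stable (lower energy) than the
    decoy mean; uses the sample (n-1) standard deviation.
    """
    e = np.asarray(e_decoys, float)
    if e.size < 2:
        raise UndefinedIndexError("need at least 2 decoys")
    sd = e.std(ddof=1)
    if sd == 0:
        raise UndefinedIndexError("zero decoy energy spread")
    return float((e.mean() - e_native) / sd)


def _burials(contacts: list[Contact], n: int) -> np.ndarray:
    counts = np.zeros(n, int)
    for c in contacts:
        counts[c.i] += 1
        counts[c.j] += 1
    return counts


def _sequence(s: Structure) -> list[str]:
    return [_one_letter(r.name) for r in s.residues]


def decoys_mutational(
    c: Contact,
    model: ContactEnergyModel,
    burials: np.ndarray,
    n: int = 1000,
    seed: int | None = None,
) -> np.ndarray:
    """Energies of the contact under amino-acid pair substitution.

    All structural parameters (distance class, burial) stay native. With
    n >= 400 the full 20x20 grid of ordered pairs is enumerated (the
    native pair appears exactly once); smaller n draws pairs at random
    with the given seed.
    """
    dclass = model.distance_class(c.distance)
    bi, bj = int(burials[c.i]), int(burials[c.j])
    if n >= 400:
        return np.array(
            [
                model.pair_energy(a, b, dclass, bi, bj)
                for a in AA_ORDER
                for b in AA_ORDER
            ]
        )
    rng = np.random.default_rng(seed)
    picks = rng.integers(0, 20, size=(n, 2))
    return np.array(
        [
            model.pair_energy(AA_ORDER[a], AA_ORDER[b], dclass, bi, bj)
            for a, b in picks
        ]
    )


def decoys_configurational(
    c: Contact,
    s: Structure,
    model: ContactEnergyModel,
    n: int = 1000,
    seed: int | None = None,
    contacts: list[Contact] | None = None,
) -> np.ndarray:
    """Energies of the native pair in re-sampled structural contexts.

    Distance classes and burial counts are drawn from the structure's
    own empirical distributions (all contacts and all residues
    respectively), emulating the alternative configurations a contact
    could adopt during folding.
    """
    if len(s.residues) < 10:
        raise ValueError("structure too small (<10 residues) to resample")
    contacts = contact_list(s) if contacts is None else contacts
    if not contacts:
        raise ValueError("structure has no contacts to resample from")
    seq = _sequence(s)
    a, b = seq[c.i], seq[c.j]
    burials = _burials(contacts, len(s.residues))
    dclasses = np.array([model.distance_class(x.distance) for x in contacts])
    rng = np.random.default_rng(seed)
    pick_d = rng.choice(dclasses, size=n)
    pick_bi = rng.choice(burials, size=n)
    pick_bj = rng.choice(burials, size=n)
    return np.array(
        [
            model.pair_energy(a, b, int(d), int(bi), int(bj))
            for d, bi, bj in zip(pick_d, pick_bi, pick_bj)
        ]
    )


def _residue_energy(
    identity: str,
    idx: int,
    seq: list[str],
    contacts: list[Contact],
    model: ContactEnergyModel,
    burials: np.ndarray,
) -> float:
    total = 0.0
    for c in contacts:
        if c.i != idx and c.j != idx:
            continue
        other = c.j if c.i == idx else c.i
        total += model.pair_energy(
            identity,
            seq[other],
            model.distance_class(c.distance),
            int(burials[c.i]),
            int(burials[c.j]),
        )
    return total


def srlf(
    residue: int,
    s: Structure,
    model: ContactEnergyModel,
    contacts: list[Contact] | None = None,
) -> float:
    """Single-residue frustration: exhaustive identity substitution.

    Native energy is the sum over the residue's contacts; the 19
    alternative identities are re-scored with the structural context
    fixed. Raises UndefinedIndexError when all identities are
    isoenergetic and ValueError for an isolated residue.
    """
    contacts = contact_list(s) if contacts is None else contacts
    seq = _sequence(s)
    burials = _burials(contacts, len(s.residues))
    if not any(c.i == residue or c.j == residue for c in contacts):
        raise ValueError(f"residue {residue} participates in no contacts")
    native_aa = seq[residue]
    e_native = _residue_energy(native_aa, residue, seq, contacts, model, burials)
    e_decoys = np.array(
        [
            _residue_energy(aa, residue, seq, contacts, model, burials)
            for aa in AA_ORDER
            if aa != native_aa
        ]
    )
    return frustration_index(e_native, e_decoys)


def classify_frustration(index: float) -> str:
    """minimal if > 0.78, high if < -1, neutral otherwise (bounds inclusive)."""
    if not np.isfinite(index):
        raise ValueError("index must be finite")
    if index > 0.78:
        return "minimal"
    if index < -1.0:
        return "high"
    return "neutral"


def structure_frustration(
    s: Structure,
    model: ContactEnergyModel | None = None,
    n_decoys: int = 1000,
    seed: int = 0,
) -> FrustrationProfile:
    """Full frustration profile of a structure.

    Residues with unknown identities or no contacts are reported as
    missing rather than scored; contacts whose decoy ensembles have no
    spread are likewise omitted.
    """
    if model is None:
        model = ContactEnergyModel(ContactPotential.default())
    contacts = contact_list(s)
    seq = _sequence(s)
    burials = _burials(contacts, len(s.residues))
    profile = FrustrationProfile(
        srlf={}, srlf_class={}, contacts=contacts, mfi={}, cfi={},
        decoy_count=n_decoys, seed=seed,
    )
    for idx in range(len(s.residues)):
        if seq[idx] == "X":
            continue
        try:
            value = srlf(idx, s, model, contacts)
        except (ValueError, UndefinedIndexError):
            continue
        profile.srlf[idx] = value
        profile.srlf_class[idx] = classify_frustration(value)
    for k, c in enumerate(contacts):
        if seq[c.i] == "X" or seq[c.j] == "X":
            continue
        key = (c.i, c.j)
        seq_pair_native = model.pair_energy(
            seq[c.i], seq[c.j], model.distance_class(c.distance),
            int(burials[c.i]), int(burials[c.j]),
        )
        try:
            mut = decoys_mutational(c, model, burials, n=max(n_decoys, 400))
            profile.mfi[key] = frustration_index(seq_pair_native, mut)
            profile.mfi_class[key] = classify_frustration(profile.mfi[key])
        except UndefinedIndexError:
            pass
        try:
            conf = decoys_configurational(
                c, s, model, n=n_decoys, seed=seed + k, contacts=contacts
            )
            profile.cfi[key] = frustration_index(seq_pair_native, conf)
            profile.cfi_class[key] = classify_frustration(profile.cfi[key])
        except (ValueError, UndefinedIndexError):
            pass
    return profile
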