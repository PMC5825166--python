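"""Per-pair orchestration and the cohort statistics used downstream.

``analyze_pair`` runs the full comparative battery on one tethered /
isolated structure pair: common-domain mapping, superposition and
deviation flags, interface classification, communicability-centrality
differences, elastic-network fluctuations and cross-correlation with the
Rv coefficient, frustration class changes, and the amputated / swapped
control constructs. ``analyze_homolog_pair`` runs the reduced battery
for homologous (non-identical) pairs, restricted to identical,
structurally equivalent functional residues, optionally including an
in-silico chimera. Classical statistics (two-sample KS, Spearman,
upper-quartile cutoffs) are thin wrappers over scipy kept here so every
report draws them from one place.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import anm as anm_mod
from . import network as net_mod
from .constructs import amputate, swap_common_domain, build_chimera
from .frustration import (
    ContactEnergyModel,
    ContactPotential,
    structure_frustration,
)
from .structure_io import (
    DomainDefinition,
    InterfaceSet,
    ResidueMapping,
    Structure,
    extract_domain,
    interface_residues,
    map_common_domain,
)
from .superpose import (
    DeviationCategory,
    DeviationProfile,
    classify_pair,
    contiguous_regions,
    deviation_profile,
)

__all__ = [
    "AnalysisConfig",
    "PairReport",
    "HomologReport",
    "ks_two_sample",
    "spearman",
    "quartile_cutoff",
    "analyze_pair",
    "analyze_homolog_pair",
    "report_to_json",
    "residue_table",
]


@dataclass
class AnalysisConfig:
    """All fixed thresholds of the comparative pipeline, in one place."""

    network_cutoff: float = 5.0        # Å, Cα contact network
    anm_cutoff: float = 15.0           # Å, elastic network
    gdt_cutoff: float = 4.0            # Å
    interface_margin: float = 0.5      # Å beyond vdW radii sum
    coc_threshold: float = 1.5         # |Δ normalized centrality|
    coupling_threshold: float = 0.7    # |cross-correlation|
    rmsd_cutoff: float = 1.0           # Å, significant global deviation
    gdt_deviation_cutoff: float = 5.0  # on 100 - GDT
    trim: int = 5                      # residues removed per terminus
    variance_fraction: float = 0.80    # ANM mode selection
    n_decoys: int = 1000
    seed: int = 0
    interface_radii: dict | None = None  # vdW table override
    mapping_mode: str = "identical"

    def __post_init__(self):
        for name in (
            "network_cutoff", "anm_cutoff", "gdt_cutoff", "interface_margin",
            "coc_threshold", "coupling_threshold", "rmsd_cutoff",
            "gdt_deviation_cutoff",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PairReport:
    md_id: str
    id_id: str
    n_mapped: int
    rmsd: float
    gdt: float
    deviation_score: float                 # 100 - GDT
    significant_global: bool
    category: str
    flagged_positions: list[int]           # mapped-position indices
    flagged_regions: list[tuple[int, int]]
    interface_positions: list[int]
    functional_positions: list[int]
    distances: np.ndarray
    centrality_flags: list[int]
    centrality_delta: np.ndarray
    fluctuation_md: np.ndarray             # normalized, trimmed
    fluctuation_id: np.ndarray
    rv: float
    coupling_md: float
    coupling_id: float
    cross_correlation_md: np.ndarray
    cross_correlation_id: np.ndarray
    frustration_changes: list[int]
    frustration_md_class: dict[int, str]
    frustration_id_class: dict[int, str]
    rv_md_ad: float | None = None
    rv_id_ad: float | None = None
    rv_md_swapped: float | None = None
    ks_id_vs_ad: tuple[float, float] | None = None
    ks_md_vs_swapped: tuple[float, float] | None = None


@dataclass
class HomologReport:
    single_id: str
    multi_id: str
    n_compared: int
    compared_positions: list[tuple[int, int]]
    fluctuation_single: np.ndarray
    fluctuation_multi: np.ndarray
    rv_functional: float
    rv_chimera_multi: float | None = None
    chimera_trims: dict | None = None


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p-value).

    D is the supremum ECDF difference; the p-value uses the asymptotic
    Kolmogorov distribution with effective size n_x n_y / (n_x + n_y).
    """
    x = np.asarray(list(x), float)
    y = np.asarray(list(y), float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (mid-ranks on ties)."""
    x = np.asarray(list(x), float)
    y = np.asarray(list(y), float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman undefined for constant input")
    return float(sps.spearmanr(x, y).statistic)


def quartile_cutoff(values: Sequence[float]) -> float:
    """Upper-quartile (75th percentile, linear interpolation) cutoff."""
    v = np.asarray(list(values), float)
    if v.size < 4:
        raise ValueError("need at least 4 values")
    return float(np.percentile(v, 75))


def _sub_structure(s: Structure, indices: Sequence[int]) -> Structure:
    return Structure(id=s.id, residues=[s.residues[i] for i in indices])


def _anm_profiles(
    coords: np.ndarray, cfg: AnalysisConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Raw square fluctuations and normalized cross-correlation matrix."""
    model = anm_mod.build_anm(coords, cutoff=cfg.anm_cutoff)
    modes = anm_mod.select_modes_80(model, cfg.variance_fraction)
    flucs = anm_mod.square_fluctuations(model, modes)
    cc = anm_mod.cross_correlation(model, modes)
    return flucs, cc


def _trimmed_z(values: np.ndarray, trim: int) -> np.ndarray:
    return anm_mod.normalize_fluctuations(values, trim=trim).normalized


def analyze_pair(
    md: Structure,
    id_: Structure,
    common: DomainDefinition,
    other_domains: Sequence[DomainDefinition] = (),
    cfg: AnalysisConfig | None = None,
    functional_residues: Sequence[int] = (),
    run_constructs: bool = True,
    run_frustration: bool = True,
    interface_radii: dict | None = None,
) -> PairReport:
    """Run the full comparative battery on a tethered/isolated pair.

    ``md`` is the multi-domain member, ``id_`` the isolated member,
    ``common`` the common-domain definition on ``md``, and
    ``other_domains`` the tethered domains (needed for interface
    detection). ``functional_residues`` are residue numbers on the
    common domain. All comparisons are carried out on the
    mutually-resolved mapped residues of the common domain.
    """
    cfg = cfg or AnalysisConfig()
    radii = interface_radii or cfg.interface_radii

    md_common = extract_domain(md, common)
    mapping = map_common_domain(md_common, id_, mode=cfg.mapping_mode)
    map_a = mapping.a_indices()     # indices into md_common
    map_b = mapping.b_indices()     # indices into id_

    xa = md_common.ca_coords()[map_a]
    xb = id_.ca_coords()[map_b]
    dev = deviation_profile(xa, xb, gdt_cutoff=cfg.gdt_cutoff)

    # interface residues of the common domain, expressed as mapped positions
    iface_positions: set[int] = set()
    if other_domains:
        md_index = md.residue_index()
        common_keys = [md_common.residues[i].key for i in map_a]
        pos_of_md_idx = {md_index[k]: p for p, k in enumerate(common_keys)}
        for dom in other_domains:
            iface = interface_residues(
                md, common, dom, radii=radii, margin=cfg.interface_margin
            )
            for idx in iface.residue_indices:
                if idx in pos_of_md_idx:
                    iface_positions.add(pos_of_md_idx[idx])

    functional_positions = [
        p
        for p, i in enumerate(map_a)
        if md_common.residues[i].number in set(functional_residues)
    ]

    category = classify_pair(set(dev.flagged), iface_positions)

    # contact-network centrality on the mapped common domain of each member
    md_mapped = _sub_structure(md_common, map_a)
    id_mapped = _sub_structure(id_, map_b)
    prof_md = net_mod.centrality_profile(
        net_mod.build_network(md_mapped, cutoff=cfg.network_cutoff)
    )
    prof_id = net_mod.centrality_profile(
        net_mod.build_network(id_mapped, cutoff=cfg.network_cutoff)
    )
    delta = np.abs(prof_md.normalized - prof_id.normalized)
    centrality_flags = [int(i) for i in np.flatnonzero(delta > cfg.coc_threshold)]

    # elastic-network dynamics on the full structures, restricted to the
    # mapped common-domain residues afterwards: the tethered domains shape
    # the MD member's modes, which is the effect under study
    md_index_full = md.residue_index()
    md_full_positions = [md_index_full[md_common.residues[i].key] for i in map_a]
    flucs_md_full, cc_md_full = _anm_profiles(md.ca_coords(), cfg)
    flucs_id_full, cc_id_full = _anm_profiles(id_.ca_coords(), cfg)
    fluc_md = _trimmed_z(flucs_md_full[md_full_positions], cfg.trim)
    fluc_id = _trimmed_z(flucs_id_full[map_b], cfg.trim)
    cc_md = cc_md_full[np.ix_(md_full_positions, md_full_positions)]
    cc_id = cc_id_full[np.ix_(map_b, map_b)]
    rv = anm_mod.rv_coefficient(cc_md, cc_id)
    coupling_md = anm_mod.coupling_fraction(cc_md, cfg.coupling_threshold)
    coupling_id = anm_mod.coupling_fraction(cc_id, cfg.coupling_threshold)

    # frustration class changes over mapped residues
    frustration_changes: list[int] = []
    class_md: dict[int, str] = {}
    class_id: dict[int, str] = {}
    if run_frustration:
        model = ContactEnergyModel(ContactPotential.default())
        fp_md = structure_frustration(
            md, model, n_decoys=cfg.n_decoys, seed=cfg.seed
        )
        fp_id = structure_frustration(
            id_, model, n_decoys=cfg.n_decoys, seed=cfg.seed + 1
        )
        for p, (ia, ib) in enumerate(zip(md_full_positions, map_b)):
            ca = fp_md.srlf_class.get(ia)
            cb = fp_id.srlf_class.get(ib)
            if ca is None or cb is None:
                continue
            class_md[p], class_id[p] = ca, cb
            if ca != cb:
                frustration_changes.append(p)

    report = PairReport(
        md_id=md.id,
        id_id=id_.id,
        n_mapped=len(mapping),
        rmsd=dev.rmsd,
        gdt=dev.gdt,
        deviation_score=dev.deviation_score,
        significant_global=(
            dev.rmsd > cfg.rmsd_cutoff
            or dev.deviation_score > cfg.gdt_deviation_cutoff
        ),
        category=category.value,
        flagged_positions=dev.flagged,
        flagged_regions=contiguous_regions(dev.flagged),
        interface_positions=sorted(iface_positions),
        functional_positions=functional_positions,
        distances=dev.distances,
        centrality_flags=centrality_flags,
        centrality_delta=delta,
        fluctuation_md=fluc_md,
        fluctuation_id=fluc_id,
        rv=rv,
        coupling_md=coupling_md,
        coupling_id=coupling_id,
        cross_correlation_md=cc_md,
        cross_correlation_id=cc_id,
        frustration_changes=frustration_changes,
        frustration_md_class=class_md,
        frustration_id_class=class_id,
    )

    if run_constructs and other_domains:
        # amputated control: tethered member minus its extra domains
        ad, _ = amputate(md, common)
        flucs_ad, cc_ad_full = _anm_profiles(ad.ca_coords(), cfg)
        ad_positions = map_a  # AD preserves md_common ordering
        cc_ad = cc_ad_full[np.ix_(ad_positions, ad_positions)]
        fluc_ad = _trimmed_z(flucs_ad[ad_positions], cfg.trim)
        report.rv_md_ad = anm_mod.rv_coefficient(cc_md, cc_ad)
        report.rv_id_ad = anm_mod.rv_coefficient(cc_id, cc_ad)
        report.ks_id_vs_ad = ks_two_sample(fluc_id, fluc_ad)

        # swapped control: isolated member grafted into the tethered scaffold
        full_mapping = _compose_common_mapping(md, md_common, mapping)
        swapped, _ = swap_common_domain(md, id_, full_mapping, common)
        flucs_sw_full, cc_sw_full = _anm_profiles(swapped.ca_coords(), cfg)
        sw_index = swapped.residue_index()
        sw_positions = [
            sw_index[md_common.residues[i].key]
            for i in map_a
            if md_common.residues[i].key in sw_index
        ]
        cc_sw = cc_sw_full[np.ix_(sw_positions, sw_positions)]
        fluc_sw = _trimmed_z(flucs_sw_full[sw_positions], cfg.trim)
        if cc_sw.shape == cc_md.shape:
            report.rv_md_swapped = anm_mod.rv_coefficient(cc_md, cc_sw)
        report.ks_md_vs_swapped = ks_two_sample(fluc_md, fluc_sw)

    return report


def _compose_common_mapping(
    md: Structure, md_common: Structure, mapping: ResidueMapping
) -> ResidueMapping:
    """Re-index a (md_common -> id) mapping to full-md residue indices."""
    md_index = md.residue_index()
    pairs = tuple(
        (md_index[md_common.residues[ia].key], ib) for ia, ib in mapping.pairs
    )
    return ResidueMapping(pairs=pairs, identity_fraction=mapping.identity_fraction)


def analyze_homolog_pair(
    single: Structure,
    multi: Structure,
    host_domain: DomainDefinition,
    functional_residues: Sequence[int],
    cfg: AnalysisConfig | None = None,
    run_chimera: bool = True,
) -> HomologReport:
    """Compare a single-domain protein with its multi-domain homolog.

    Only topologically equivalent positions with identical amino acids
    that appear in ``functional_residues`` (residue numbers on
    ``single``) enter the comparison: normalized fluctuations at those
    positions and the Rv of the functional-residue cross-correlation
    sub-matrices, optionally against an in-silico chimera.
    """
    cfg = cfg or AnalysisConfig()
    host = extract_domain(multi, host_domain)
    mapping = map_common_domain(single, host, mode="homolog")
    seq_s, seq_h = single.sequence(), host.sequence()
    functional = set(functional_residues)
    compared = [
        (ia, ib)
        for ia, ib in mapping.pairs
        if seq_s[ia] == seq_h[ib]
        and single.residues[ia].number in functional
    ]
    if not compared:
        raise ValueError("no identical functional residues mapped")

    multi_index = multi.residue_index()
    pos_s = [ia for ia, _ in compared]
    pos_m = [multi_index[host.residues[ib].key] for _, ib in compared]

    flucs_s, cc_s_full = _anm_profiles(single.ca_coords(), cfg)
    flucs_m, cc_m_full = _anm_profiles(multi.ca_coords(), cfg)
    z_s = _trimmed_z(flucs_s, cfg.trim)
    z_m = _trimmed_z(flucs_m, cfg.trim)
    trim = cfg.trim

    def _zs(z, positions, n):
        out = []
        for p in positions:
            q = p - trim
            out.append(z[q] if 0 <= q < z.size else np.nan)
        return np.asarray(out)

    fl_s = _zs(z_s, pos_s, len(single.residues))
    fl_m = _zs(z_m, pos_m, len(multi.residues))
    cc_s = cc_s_full[np.ix_(pos_s, pos_s)]
    cc_m = cc_m_full[np.ix_(pos_m, pos_m)]
    rv_functional = anm_mod.rv_coefficient(cc_s, cc_m)

    report = HomologReport(
        single_id=single.id,
        multi_id=multi.id,
        n_compared=len(compared),
        compared_positions=compared,
        fluctuation_single=fl_s,
        fluctuation_multi=fl_m,
        rv_functional=rv_functional,
    )

    if run_chimera:
        full_mapping = ResidueMapping(
            pairs=tuple(
                (ia, multi_index[host.residues[ib].key])
                for ia, ib in mapping.pairs
            ),
            identity_fraction=mapping.identity_fraction,
        )
        chimera, record = build_chimera(
            single, multi, full_mapping, host_domain
        )
        flucs_c, cc_c_full = _anm_profiles(chimera.ca_coords(), cfg)
        # functional positions inside the chimera: grafted single residues
        prov = {key: i for i, (pid, key) in enumerate(record.provenance)
                if pid == single.id}
        pos_c = [
            prov[single.residues[ia].key]
            for ia, _ in compared
            if single.residues[ia].key in prov
        ]
        if len(pos_c) == len(compared):
            cc_c = cc_c_full[np.ix_(pos_c, pos_c)]
            report.rv_chimera_multi = anm_mod.rv_coefficient(cc_c, cc_m)
        report.chimera_trims = record.trimmed
    return report


def residue_table(report: PairReport) -> pd.DataFrame:
    """Per-mapped-residue TSV-ready table of the structural comparison."""
    n = report.distances.size
    flagged = set(report.flagged_positions)
    iface = set(report.interface_positions)
    functional = set(report.functional_positions)
    return pd.DataFrame(
        {
            "position": np.arange(n),
            "distance_A": np.round(report.distances, 4),
            "flagged": [int(i in flagged) for i in range(n)],
            "interface": [int(i in iface) for i in range(n)],
            "functional": [int(i in functional) for i in range(n)],
            "centrality_delta": np.round(report.centrality_delta, 4),
        }
    )


def report_to_json(report: PairReport) -> str:
    """Summary JSON: scores to 4 decimals, p-values in scientific form."""

    def _fmt_ks(ks):
        if ks is None:
            return None
        return {"D": round(ks[0], 4), "p": float(f"{ks[1]:.4e}")}

    payload = {
        "md": report.md_id,
        "id": report.id_id,
        "n_mapped": report.n_mapped,
        "rmsd": round(report.rmsd, 4),
        "gdt": round(report.gdt, 4),
        "deviation_score": round(report.deviation_score, 4),
        "significant_global": bool(report.significant_global),
        "category": report.category,
        "flagged_regions": report.flagged_regions,
        "n_centrality_flags": len(report.centrality_flags),
        "rv": round(report.rv, 4),
        "coupling_md": round(report.coupling_md, 4),
        "coupling_id": round(report.coupling_id, 4),
        "n_frustration_changes": len(report.frustration_changes),
        "rv_md_ad": None if report.rv_md_ad is None else round(report.rv_md_ad, 4),
        "rv_id_ad": None if report.rv_id_ad is None else round(report.rv_id_ad, 4),
        "rv_md_swapped": (
            None if report.rv_md_swapped is None else round(report.rv_md_swapped, 4)
        ),
        "ks_id_vs_ad": _fmt_ks(report.ks_id_vs_ad),
        "ks_md_vs_swapped": _fmt_ks(report.ks_md_vs_swapped),
    }
    return json.dumps(payload, indent=2)
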