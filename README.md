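# tetherscope

Many protein domains exist in two lives: as (part of) a stand-alone
protein, and tethered to extra domains inside a multi-domain protein.
`tetherscope` is a Python toolkit for structural bioinformaticians who
want to quantify what that tethering does to the domain itself. Given a
pair of PDB structures sharing a common domain — the multi-domain member
(MD) and the isolated member (ID) — it compares the two copies across
four layers:

1. **Structure** — Kabsch superposition of the mapped Cα atoms;
   global RMSD and a single-threshold (4 Å) GDT score found by a
   MaxSub-style seed-extend search; local deviation regions as residues
   with Cα–Cα distance > mean + 2σ of the distance distribution,
   categorized by overlap with the domain–domain interface
   (interface residues: any atom pair across domains closer than
   r_vdw sum + 0.5 Å).
2. **Residue-communication network** — Cα contact graph (≤ 5 Å edges);
   communicability centrality coc(i) = [exp(A)]_ii, z-scored per
   domain; residues flagged when |coc_MD − coc_ID| > 1.5.
3. **Dynamics** — anisotropic network model (15 Å cutoff,
   distance-dependent springs γ(d) = γ₀(d₀/d)²); modes covering 80% of
   variance; normalized square fluctuations (5 residues trimmed per
   terminus); cross-correlation matrices C_ij compared by the Rv
   coefficient trace(AB)/√(tr(AA)·tr(BB)) and by the fraction of pairs
   with |C_ij| ≥ 0.7.
4. **Energetic frustration** — native-vs-decoy Z-scores
   (mean(E_decoy) − E_native)/sd(E_decoy) on a pluggable contact
   potential: mutational and configurational indices per contact, a
   single-residue index per residue, classes minimal (> 0.78) /
   neutral / high (< −1).

Because "the tethered copy differs" could always be a crystal-packing
artefact, the package also builds the in-silico controls: the
**amputated domain** (MD minus its extra domains), the **swapped
domain** (ID rigidly grafted into MD's scaffold) and homolog
**chimeras** with automatic junction-clash trimming. A synthetic
structure generator produces bead-domain pairs with known ground truth
so every stage is testable without downloading a single PDB file.

## Worked example

Generate a synthetic tethered/isolated pair (60-residue common domain +
40-residue tethered domain, 12 interface contacts, 0.2 Å coordinate
noise) and run the full battery:

```python
from tetherscope import SyntheticSpec, make_multidomain, analyze_pair, AnalysisConfig
from tetherscope.pipeline import report_to_json
from tetherscope.synthetic import SYNTHETIC_CA_RADII

md, id_, truth = make_multidomain(SyntheticSpec(seed=3))
report = analyze_pair(
    md, id_,
    truth["domain_definitions"][0],       # the common domain
    truth["domain_definitions"][1:],      # the tethered domain(s)
    cfg=AnalysisConfig(n_decoys=400),
    interface_radii=SYNTHETIC_CA_RADII,   # Cα-only synthetic structures
)
print(report_to_json(report))
```

which prints (abridged):

```json
{
  "n_mapped": 60,
  "rmsd": 0.4831,
  "gdt": 100.0,
  "deviation_score": 0.0,
  "significant_global": false,
  "category": "non-interface-only",
  "n_centrality_flags": 0,
  "rv": 0.7796,
  "coupling_md": 0.0751,
  "coupling_id": 0.1282,
  "n_frustration_changes": 3,
  "rv_id_ad": 0.9954,
  "rv_md_swapped": 0.9972
}
```

Reading the numbers: the two copies of the common domain are nearly
identical in conformation (RMSD 0.48 Å from the planted 0.2 Å noise,
GDT 100, no significant global deviation, no centrality flags), yet
their motions differ — the Rv coefficient between the MD and ID
cross-correlation matrices is only 0.78. The controls pin the cause on
tethering rather than the coordinates themselves: the amputated domain,
which shares MD's exact coordinates but lacks the tethered domain, moves
like ID (Rv 0.995), while the swapped construct, which keeps MD's
scaffold, moves like MD (Rv 0.997). Three residues change frustration
class between the members.

The same battery is available from the shell:

```sh
tetherscope synth --spec spec.yaml --seed 7 --out synth/
tetherscope pair  --md synth/md.pdb --id synth/id.pdb --config cfg.yaml --out out/
tetherscope homolog --single s.pdb --multi m.pdb --config cfg.yaml \
    --functional functional.txt --out out/
```

`pair` writes `summary.json`, a per-residue `residues.tsv` (deviation,
flags, interface/functional annotation, centrality differences) and the
two cross-correlation matrices as TSV.

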