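# mdinteract

Geometric interaction profiling of metalloprotein–ligand MD trajectories,
with QM/MM boundary utilities.

`mdinteract` is built for the structural analysis that follows a molecular
dynamics study of a small-molecule inhibitor bound in a metal-containing
protein groove — the kind of system exemplified by the Sonic Hedgehog
(Shh) signalling domain, whose binding groove holds a Zn(II) ion
coordinated by histidine, aspartate and glutamate sidechains, bound by the
macrolactone inhibitor robotnikinin. From multi-model PDB trajectories it
computes:

- **Ion coordination** — ion-centred radial pair-count profiles (RDFs),
  their running number integrals, first-peak/first-minimum detection, mean
  coordination numbers `CN = N(r_min)`, carboxylate denticity fractions
  (bidentate / monodentate / unbound) and solvent-access counts.
- **Hydrogen bonds** — purely geometric occupancy statistics: a
  donor–H···acceptor triple is bonded in a frame when the H···A distance
  is `< 3.0 Å` and the deviation from linearity is `< 35°`; occupancy is
  the percentage of bonded frames, and mean contact distances average over
  *all* frames.
- **Contacts and stacking** — per-frame closest-atom distance series
  between residue and ligand functional groups, and classification of
  aromatic ring pairs as parallel-displaced (`θ ≤ 30°`) or T-shaped
  (`θ ≥ 60°`) from centroid distance and best-fit-plane normals.
- **Fluctuation-corrected per-residue RMSD heatmaps** — per-residue
  heavy-atom RMSD of a ligand-loaded trajectory against an apo reference
  after one global Cα fit, minus the apo system's own mean per-residue
  fluctuation, clamped at zero: only motion *beyond* natural fluctuation
  survives.
- **SASA** — Shrake–Rupley solvent-accessible surface area on a
  deterministic Fibonacci point lattice with Bondi radii, plus the summary
  convention `mean ± z·sd/√n`.
- **QM/MM boundary utilities** — the link-atom parameter table
  {ρ, r₀, k_L} per residue type and basis set, link-atom placement at
  `L = Cα + ρ(Cβ − Cα)`, the harmonic correction `E = k_L (r − r₀)²`, and
  electrostatic-embedding point-charge export with a global charge scale
  factor (default 0.666, which maps a TIP3P water oxygen from −0.83 e to
  the −0.55 e a bulk QM calculation assigns).

Because production MD trajectories are rarely shipped with a paper, the
package includes first-class synthetic-trajectory generators
(`mdinteract.synthetic_data`) that emulate each scenario with closed-form
ground truth — planted coordination numbers, H-bond occupancies, stacking
classes, fluctuation regimes — so every analysis operator is testable
against a known answer.

## Worked example

Generate a synthetic Zn(II)-site trajectory (100 frames, five O/N partner
atoms at 2.0 Å with 0.05 Å positional noise, ten shell waters beyond 6 Å)
and profile it:

```sh
mdinteract generate zn-site --out fixtures --seed 7 --frames 100
mdinteract profile --config config.yaml
```

with `config.yaml`:

```yaml
trajectory: fixtures/zn_site.pdb
output_dir: out
ion:
  center: {residue_name: ZN}
  partners: {element: [O, N]}
  bin_width: 0.05
  r_max: 10.0
  cutoff: 2.83
solvent:
  partners: {residue_name: HOH}
  radius: 5.0
sasa:
  target: {residue_name: LIG}
  context: {residue_name: ZN}
  n_sphere_points: 960
```

prints

```json
{
  "ion": {
    "cutoff": 2.83,
    "first_minimum": 2.2750000000000004,
    "mean_cn": 5.0,
    "peak_position": 1.975,
    "solvent_mean_count": 0.0
  },
  "n_atoms": 16,
  "n_frames": 100,
  "sasa": {
    "ci_half_width": 0.3864903536232192,
    "level": 95.0,
    "mean": 218.31118128245345,
    "n": 100,
    "sd": 1.9719257939013461
  }
}
```

Reading: the RDF peaks at 1.975 Å (the generator placed partners at
2.0 Å), its first minimum sits at 2.28 Å where the profile goes empty, and
counting partners within the 2.83 Å cutoff recovers the planted
coordination number of exactly 5.0 in every frame. No water ever comes
within 5 Å of the ion (`solvent_mean_count` 0.0). The ligand's SASA is
218.3 Å² with a 95% confidence half-width of 0.39 Å² over 100 frames.
The run also writes `out/rdf.tsv`, `out/rdf_integral.tsv`,
`out/sasa_series.tsv`, `out/report.json` and a `run_log.json` with the
config hash; rerunning the same config is byte-identical.

The other subcommands follow the same pattern: `mdinteract heatmap`
(needs `empty_trajectory`), `mdinteract rdf`, `mdinteract sasa`,
`mdinteract link-prep --basis TZ|DZ`, and `mdinteract generate` for the
remaining scenarios (`hbond`, `fluctuating-protein`, `stacked-rings`).
Everything is equally usable as a library; see `docs/methods.md` for the
models, conventions and their rationale.

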