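# vstriage

Structure-based virtual-screening triage for hit finding against lipid
kinases (built around a PI5P4K-style campaign, but generic): the library
takes a screening deck from raw SMILES through alert/property filtering,
3D pharmacophore pose filtering with exclusion volumes, consensus pooling
of multi-engine docking ranks, and Tanimoto/k-medoids diversity selection
of a purchase set, and computes the standard compound-quality metrics
used to judge the resulting hits.

## Who it is for

Computational chemists running (or auditing) a docking-based triage who
want each funnel stage as a tested, deterministic, standalone step with
plain-text inputs and outputs — and a synthetic-deck generator that
plants ground truth at every stage so the whole funnel can be validated
without commercial libraries or docking licences.

## The funnel

1. **Stage-1 filter** — substructure alerts (PAINS-like and reactive
   motifs, extensible from SMARTS CSVs) plus property cuts: remove
   compounds with >4 aromatic rings, >10 rotatable bonds, >3 H-bond
   donors, clogP > 5 or TPSA > 125 Å² (strict inequalities).
2. **Pharmacophore filter** — docked poses are kept when ≥ *m* of *n*
   projected feature spheres (1.4 Å radius acceptor/donor sites; 2-of-4
   by default) each contain a complementary ligand heavy atom and no
   heavy atom enters an exclusion sphere.
3. **Consensus pool** — the union of each scoring engine's top-*N*
   (default 1000) candidates, ordered by a scale-free positional key:
   best rank across engines, then mean rank where present, then id.
4. **Stage-2 filter** — remove pooled compounds with logD > 5 **and**
   PSA > 100 Å² (AND/OR configurable).
5. **Diversity selection** — Morgan fingerprints (radius 4, 2048 bits),
   Tanimoto distance, PAM k-medoids into *k* clusters (default 960);
   take each cluster's best-ranked member, add unselected global top-50
   compounds, trim the worst-ranked back to the target size.
6. **Metrics** — ligand efficiency LE = 1.364·pIC50/HAC (kcal/mol per
   heavy atom), lipophilic ligand efficiency LLE = pIC50 − logP, hit
   rate, and the unbound brain:plasma ratio
   K<sub>p,uu</sub> = (C<sub>brain</sub>·fu<sub>brain</sub>)/(C<sub>plasma</sub>·fu<sub>plasma</sub>).

A formula/mass module computes the "calcd" m/z values quoted in MS
characterization (monoisotopic to 4 d.p., average to 1 d.p.).

## Worked example

```python
>>> from vstriage import monoisotopic_mass, average_mass
>>> monoisotopic_mass("C16H15N4OS+")     # [M+H]+ of a thienopyrimidine hit
311.0967
>>> average_mass("C13H12N3O2S2+")
306.4

>>> from vstriage import ligand_efficiency, lipophilic_ligand_efficiency, hit_rate
>>> ligand_efficiency(6.70, 20)          # pIC50 6.70, 20 heavy atoms
0.46
>>> lipophilic_ligand_efficiency(6.70, 2.80)
3.9
>>> hit_rate(5, 960)                     # five actives in a 960-compound set
0.5
```

A complete synthetic screen, generated and then triaged end to end:

```bash
$ triage simulate --out sim --seed 1
$ triage run --config sim/run.yaml
{
  "ingest": 3000,
  "stage1_filter": 2952,
  "pharmacophore": 2509,
  "consensus_pool": 2057,
  "stage2_filter": 1743,
  "cluster_select": 960
}
```

The counts are the funnel: 3000 deck members, 48 planted stage-1
violators removed, 2509 pharmacophore passers, three top-1000 engine
lists pooling to 2057 unique compounds, 314 logD/PSA violators removed
to leave 1743, and a diverse 960-compound purchase set selected from
960 k-medoids clusters. Stage reports (`stage1_verdicts.csv`,
`consensus_pool.csv`, `purchase_set.csv`, ...) and a run manifest land
in `sim/run/`.

## Layout

| module | contents |
| --- | --- |
| `vstriage.formula_mass` | formula parser, monoisotopic/average masses |
| `vstriage.deck_io` | SMILES/CSV tables, SDF poses, CSV reports |
| `vstriage.descriptor_filters` | descriptors, alerts, stage-1/2 filters |
| `vstriage.pharmacophore3d` | feature/exclusion model, pose matching |
| `vstriage.consensus_pool` | top-N pooling, global rank |
| `vstriage.diversity_picker` | fingerprints, PAM k-medoids, selection |
| `vstriage.efficiency_metrics` | LE, LLE, hit rate, Kp,uu |
| `vstriage.synthetic_deck` | planted-truth generators |
| `vstriage.cli_pipeline`, `vstriage.cli` | orchestration and `triage` CLI |

See `docs/methods.md` for the model assumptions, parameter rationale,
and known limitations.
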