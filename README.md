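# woundpep

Label-free peptidomics of proteolytic environments such as wound fluids:
from peptide-identification tables to filtered, protein-mapped peptidomes;
cleavage-site and terminal profiles; group comparisons; per-protein
coverage maps; and antimicrobial scoring.

## The problem

Endogenous peptides are generated in vivo by the interplay of substrate
proteins and proteases, so the peptidome of a body fluid is a readout of
its proteolytic state. Tandem-MS identification tables give, per sample,
peptide sequences with **spectral counts** (the number of matched spectra,
a semi-quantitative abundance proxy). `woundpep` turns such tables into
comparable group-level profiles:

- **Filtering**: replicate concatenation (per-sequence count summing) and a
  spectral-count cutoff (default ≥ 4) to suppress low-evidence hits.
- **Cleavage-site profiling**: each peptide's last residue is the **P1**
  and its first residue the **P1′** of the cleavage events that created it;
  peptide ends coinciding with the parent protein's own termini are
  excluded (no protease made them). Profiles are spectral-count-weighted
  residue frequencies, optionally collapsed into side-chain classes
  (acidic / basic / polar / nonpolar) and compared to the Swiss-Prot
  background composition.
- **Terminal tables**: aggregated counts of the 4 proximal residues of
  either peptide end (MEROPS tetrapeptide convention) — candidate epitopes
  for terminal-specific antibodies.
- **Comparisons**: exact Venn partitions of 2–5 peptide sets,
  intersectional peptides (present in every sample of a group), top-k
  differential peptides between groups, protein-substrate abundance pies,
  occurrence-based outlier flags, Welch/paired t statistics, and a simple
  rule-based protease attribution over P1 specificities.
- **Regions and antimicrobial scores**: per-residue coverage profiles
  (peptide-alignment maps), region-confined spectral sums,
  literature-peptide cross-matching, and the **antimicrobial score** =
  prediction × spectral count (predictions in [0, 1] from an external
  predictor file or a built-in composition heuristic, cutoff 0.7).

A first-class synthetic generator (`woundpep.synthetic`) performs
in-silico digestion with planted ground truth — P1 cleavage preferences,
substrate weights, core peptides, abundance hotspots — so every stage is
testable without clinical data.

## Worked example

Simulate the default three-group study (sterile acute wound fluid plus
non-infected and infected dressing-like groups; the dressing groups plant
an acidic cleavage preference with D+E carrying 40% of the P1 mass, and
the infected group plants a 10× abundance hotspot in a hemoglobin-β
C-terminal toy region), then run the pipeline:

```python
import woundpep as wp

db, models, n_samples = wp.study_design()
ds, truth = wp.simulate_dataset(db, models, n_samples,
                                peptides_per_sample=2500, seed=1)
filtered = ds.map_tables(lambda t: wp.apply_spectral_cutoff(t, 4))
mapped = wp.map_dataset(filtered, db)
cleavage = wp.cleavage_site_records(wp.map_dataset(ds, db))

print(wp.summarize_dataset(ds)[["peptides_before_mean", "peptides_after_mean",
                                "fraction_above_cutoff"]].round(3))

p1 = wp.aa_composition(ds.groups["non_infected"], "P1",
                       cleavage_records=cleavage)
print({k: round(v, 3) for k, v in sorted(wp.group_composition(p1).items())})

region, enrichment = truth.hotspots["infected"][0]
print(wp.region_spectral_sum(mapped, region, mode="confined").group_totals)
```

Output:

```
              peptides_before_mean  peptides_after_mean  fraction_above_cutoff
group
acute                     2760.000              778.000                  0.282
infected                  2753.667              794.333                  0.288
non_infected              2752.333              811.667                  0.295
{'acidic': 0.382, 'basic': 0.098, 'nonpolar': 0.32, 'polar': 0.2}
{'acute': 0, 'infected': 426, 'non_infected': 0}
```

Reading it: each simulated sample yields ~2,750 unique peptides of which
~29% survive the ≥ 4 cutoff; the recovered acidic P1 share in the
non-infected group (0.382) sits within two percentage points of the
planted 0.40 (against ~0.10 expected under uniform cleavage); and the
planted hemoglobin-region hotspot appears only in the infected group's
confined region sum.

A command-line layer mirrors the library:

```bash
woundpep simulate --outdir sim --seed 1
woundpep summarize sim/manifest.yaml --out summary.tsv
woundpep profile sim/manifest.yaml --fasta sim/proteins.fasta --outdir profiles
woundpep terminals sim/manifest.yaml --end C --out cterm.tsv
woundpep compare sim/manifest.yaml infected acute --fasta sim/proteins.fasta
woundpep ampscore sim/manifest.yaml --fasta sim/proteins.fasta --builtin
woundpep coverage sim/manifest.yaml --fasta sim/proteins.fasta --accession HBB_CTERM_TOY
woundpep litmatch sim/manifest.yaml --references refs.tsv
```

See `docs/methods.md` for the generative model, parameter defaults and
their rationale, numerical conventions, and known limitations.

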