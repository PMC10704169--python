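# halolip

Lipidome informatics for halophilic archaea (Halobacteria).

Halobacteria build their membranes from diether core lipids — archaeol
(AR, two C20 phytanyl chains ether-linked to glycerol), extended archaeol
(Ext-AR, one chain elongated to C25) and their unsaturated variants —
decorated with phospho- and glycosyl head groups (PG, Me-PGP, PGS, PA,
PE, PI, Gly-PG, MGD/DGD/TGD and their sulfated forms, Gly-AHH lipids),
plus cardiolipin-type twin-core lipids (BPG, glyco-cardiolipins),
menaquinones (MK) and the C50 carotenoid bacterioruberin. Because each
taxon expresses a characteristic subset of this space, the lipidome is a
chemotaxonomic signal: clustering strains by their lipid profiles can
recover the phylogeny inferred from 16S rRNA.

`halolip` implements that whole workflow as a reusable, tested pipeline:

* **`lipid_library`** — combinatorial enumeration of lipid species with
  exact elemental compositions (condensation bookkeeping: one H2O per
  covalent junction), adduct m/z, and rule-based in-silico MS² spectra
  exported as an MSP library. Fragmentation rules live in an editable TSV
  (`src/halolip/data/fragment_rules.tsv`); the shipped defaults are
  reconstructions of generic ether-lipid CID behaviour.
* **`features_io`** — aligned feature tables (CSV/TSV) and MS² spectra
  (MGF), internal-standard RT correction (piecewise linear, anchors
  deviating > 0.8 min excluded), minimum-height and 10× blank filters,
  coverage statistics.
* **`annotation`** — library matching at 0.01 Da (MS¹) / 0.05 Da (MS²)
  with a four-component total score (MS¹ similarity, dot product, reverse
  dot product, matched fraction; accepted above 70%), collapse of adduct
  forms and RT isomers into unique lipids, internal-standard
  semi-quantification, per-class summaries.
* **`core_chains`** — mapping intact polar lipids back to their diether
  cores (cardiolipins count twice), unsaturation and C25-chain
  statistics, and the exact chain↔molecule conversion: with no
  di-extended archaeol, a C25 chain fraction *f* equals an Ext-AR
  molecule fraction of 2·*f*.
* **`molecular_network`** — feature-based molecular networking: spectra
  cleaned (precursor ± 17 Da excluded, top 6 peaks per 50 Da window),
  modified cosine with optimal one-to-one peak assignment (direct or
  precursor-shifted matches), edges above cosine 0.7 with ≥ 6 shared
  peaks, pruning of blank-involved and m/z < 500 nodes and of components
  smaller than 4, and component categorization (majority lipid class or
  dominant-taxon unknown).
* **`chemotax_phylo`** — log/z-score scaling, hierarchical clustering
  under complete/single/Ward/average linkage with Newick export, PCA,
  PLS-DA VIP scores (NIPALS), p-distances with pairwise deletion,
  Saitou–Nei neighbor joining with bootstrap support, and
  dendrogram-vs-phylogeny concordance (adjusted Rand index at a k-way
  cut; Robinson–Foulds distance).
* **`synthetic_data`** — a seeded generator of a seven-strain,
  three-order culture study (triplicates, blanks, internal standard,
  unknown analogs, contaminants, toy 16S alignment) with a ground-truth
  table, so the full pipeline is testable end to end without raw data.

## Worked example

The whole pipeline runs from one command-line tool:

```sh
halolip build-library -o run        # wrote 780 spectra to run/library.msp
halolip simulate -o run --seed 42   # 175 features / 174 spectra
halolip annotate -o run             # annotated 123 features -> 87 unique lipids
halolip cores -o run
halolip network -o run
halolip chemotax -o run
halolip report -o run
```

`run/report.json` then contains (seed 42):

```
"coverage":  {"n_features": 175, "n_with_ms2": 174, "n_annotated": 123,
              "pct_annotated": 70.69, "n_network": 123, "pct_network": 70.69}
"network":   {"n_nodes": 123, "n_identified": 88, "n_unknown": 35,
              "n_analogs": 20, "n_new": 15}
"concordance": ari = 1.0 for complete, single, ward and average linkage
```

Reading the numbers: of 174 MS²-bearing features, 123 were annotated
against the in-silico library (70.69% — far higher than a real study,
because the simulation emits mostly known lipids); the filtered
molecular network keeps 123 nodes of which 88 are identified, 20 are
unknown analogs sitting in identified components and 15 are candidate
new structures in all-unknown components (these are the planted
order-specific "novel family" features). Cutting the strain dendrogram
at k = 3 recovers the three taxonomic orders exactly (adjusted Rand
index 1.0) under all four linkage criteria, and `run/core_summary.tsv`
recovers each strain's planted unsaturation and C25-chain percentages,
e.g. `Ht_turkmenica: pct_c25_chains 13.26, pct_ext_ar 26.51` against a
ground truth of 13.44 / 26.88.

The same API is available from Python; see the module docstrings
(`halolip.synthetic_data.simulate`, `halolip.annotation.annotate_features`,
`halolip.molecular_network.build_network`, ...).

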