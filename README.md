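# taxbridge

Marker-gene (16S/18S/ITS) amplicon surveys answer "who is there?" in a
microbial community, but the abundance tables that sequencing pipelines
produce — MrDNA's per-rank OTU tables, Anacapa's ASV tables with a
semicolon-joined `sum.taxonomy` column, QIIME 2's `.qza`-wrapped feature
tables — rarely match the input formats that the accessible GUI and
web-based analysis tools expect. taxbridge reads any of those three
dialects into one canonical model, validates it against sample metadata,
repairs taxonomy lineages, optionally rarefies, and writes ready-to-run
inputs for STAMP, ranacapa, Cytoscape, QIIME 2, Excel pivot analysis, and
the Piphillin functional-inference workflow (including KEGG BRITE
annotation of the KO abundances that come back).

It is aimed at instructors and researchers who receive processed
amplicon data and want to move it between tools without hand-editing
spreadsheets or writing one-off scripts.

## The core computations

* **Strict-hierarchy repair.** Profile tools such as STAMP require that
  no taxonomic rank be classified beneath an unclassified one. The
  lineage `Proteobacteria; Gammaproteobacteria; Enterobacteriales;
  unclassified; Escherichia; unclassified` violates this (the family is
  unclassified while the genus is not). `repair_lineage` either *fills*
  each interior gap with a named placeholder
  `unclassified_<nearest classified ancestor>` — preserving the deeper
  classification — or *truncates* everything below the first gap.

* **Rarefaction.** Each sample's counts are subsampled without
  replacement to a common depth *d* (a multivariate hypergeometric
  draw), repeated up to 10 iterations, averaged and rounded half-up.
  Samples shallower than *d* are dropped with a warning.

* **Upload co-chunking.** The Piphillin web server caps uploads at
  10 MB. Representative sequences and their abundance rows are split
  greedily, in input order, into FASTA + CSV chunk pairs whose
  serialized FASTA each stays under the cap
  (`piphillinseqs1.fasta` / `piphillinotu.csv1.csv`, …).

* **KO annotation.** Returned gene tables carry bare K numbers; parsing
  the KEGG BRITE `.keg` hierarchy offline attaches descriptions and the
  A/B/C category path to every KO, with multi-path KOs resolved to a
  single primary path (lexicographically first) plus a sidecar listing.

## Worked example

```python
from taxbridge import Lineage, repair_lineage, lineage_is_strict

lin = Lineage(("Bacteria", "Proteobacteria", "Gammaproteobacteria",
               "Enterobacteriales", None, "Escherichia", None))
print("strict before repair:", lineage_is_strict(lin))
fixed = repair_lineage(lin, mode="fill")
print("strict after repair: ", fixed.is_strict())
print("repaired lineage:    ", ";".join(fixed.labels()))
```

prints

```
strict before repair: False
strict after repair:  True
repaired lineage:     Bacteria;Proteobacteria;Gammaproteobacteria;Enterobacteriales;unclassified_Enterobacteriales;Escherichia;unclassified
```

The interior family gap became the named node
`unclassified_Enterobacteriales` (so STAMP accepts the row while the
genus *Escherichia* survives); the trailing species slot stays labeled
`unclassified`. Rarefying a two-feature table to depth 40:

```python
import pandas as pd
from taxbridge import FeatureTable, rarefy

counts = pd.DataFrame({"S1": [90, 10], "S2": [40, 5]}, index=["ASV_1", "ASV_2"])
table = FeatureTable(counts, [fixed, repair_lineage(Lineage(("Bacteria",) + (None,) * 6))])
print(rarefy(table, depth=40, iterations=10, seed=7).counts)
```

```
       S1  S2
ASV_1  36  36
ASV_2   4   4
```

S2's total was exactly 45, so its subsample keeps the 8:1 skew; both
columns now sum to the common depth (±1 from iteration averaging).

## Command line

```sh
taxbridge community --input-dialect anacapa --table asv_table.txt \
    --metadata metadata.txt --seqs rep_seqs.fasta \
    --rarefy-depth 1000 --rarefy-iters 3 --seed 42 --out results/
taxbridge functional --piphillin-tar results.tar --keg ko00001.keg \
    --run-dir results/output/<stamp>/
```

`community` writes a time-stamped run folder with `excel/`, `stamp/`,
`ranacapa/`, `cytoscape/`, `qiime2/`, `piphillin/` and `functional/`
subfolders plus a `manifest.tsv` of every file with byte count and
SHA-256 digest; `functional` fills `functional/` from the inference
result archives. `taxbridge fixture` generates a synthetic dataset with
a ground-truth manifest for testing.

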