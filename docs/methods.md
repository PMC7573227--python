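# Methods

## Canonical model

All computation happens on a small set of in-memory types. A lineage is
always exactly seven ranks (kingdom/domain, phylum, class, order,
family, genus, species — the two ladder spellings differ only at the
top); inputs with fewer annotated ranks are right-padded with explicit
unclassified markers and inputs with more (e.g. subspecies strains) are
truncated with a warning. Unclassified slots are `None` internally and
render as the literal `unclassified` in every output, so a blank taxon
cell can never reach a downstream file. On ingest, the tokens
`unclassified`, `unknown`, `na`, the empty string and bare rank
prefixes such as `g__` (all case-insensitive) are recognized as
unclassified.

Feature tables are non-negative integer count matrices. Fractional
cells are rejected rather than rounded: a table of relative abundances
is a different quantity, and silently rounding it would corrupt every
downstream total. Whole-valued floats (a common CSV artifact) are
accepted and coerced.

## Dialect ingestion

Delimiters are sniffed per file from the header line (tab preferred,
comma fallback), since the supported pipelines mix `.csv` and
tab-separated deliveries.

MrDNA-style deliveries are one table per rank with no feature IDs. The
deepest provided file defines the features; IDs are synthesized as
`F0000`, `F0001`, … in input order. Lineages above the deepest rank are
reconstructed by matching each feature's count vector against the
shallower-rank tables — a parent with a single child shares its count
vector exactly, so a unique match identifies the ancestor. Where the
match is absent or ambiguous (the usual case for multi-child parents),
the deepest file's semicolon-joined `taxonomy` path column is used when
present; otherwise unresolved ranks stay unclassified. The exact column
layout of commercial deliveries varies by contract; the layout the
fixture generator freezes (rank-name first column, optional `taxonomy`
path column, then samples) is one plausible rendering, not a claim
about any vendor's exact format.

`.qza` artifacts are treated purely as zip containers: the text export
under the internal `data/` directory is extracted and parsed; no
artifact provenance or metadata semantics are interpreted. Piphillin
result archives carry no fixed member names, so members are recognized
by content shape — a delimited table whose first column is all
`K#####` (gene) or `ko#####`/`map#####` (pathway) identifiers.

## Strict-hierarchy repair

`fill` mode names each interior gap `unclassified_<nearest classified
ancestor>`; consecutive gaps chain (`unclassified_unclassified_X`),
which guarantees every placeholder has a unique parent and the repaired
lineage is strict by construction. A gap at the top rank has no
ancestor and becomes `unclassified_root`, keeping the filled node
distinct from the unclassified marker so written files parse back to
the same lineage. `fill` is the default because the deeper
classification (the genus in the classic interior-gap example) is worth
preserving; `truncate` is offered for conservative users and discards
everything below the first gap. Trailing gaps are left as unclassified
markers in both modes — they do not violate strictness.

## Rarefaction

Subsampling without replacement is a multivariate hypergeometric draw
(`numpy.random.Generator.multivariate_hypergeometric`) per sample and
iteration, seeded once per call, so identical (seed, depth, iterations)
inputs give bit-identical outputs. Iterations are capped at 10.
Averaged counts are rounded half-up (`floor(x + 0.5)`); features whose
rounded average is zero in every retained sample are dropped. With one
iteration every retained column sums exactly to the depth; with
averaging, rounding can move a column total by a count or two. Whether
iterations should be averaged or kept separate is a genuinely open
design point; averaging was chosen because it yields one table that
every downstream writer can consume, and is documented here rather than
hidden. Samples shallower than the depth are dropped with a recorded
warning instead of failing the run, mirroring common practice.

## Upload chunking

The functional-inference upload cap is enforced on serialized FASTA
bytes (canonical single-line records, LF endings, 2^20-byte MB).
Packing is greedy first-fit in input order — deterministic and
order-preserving; chunk count is not minimized beyond greedy. The
paired abundance CSV is written per chunk with the FASTA header IDs
verbatim in its first column; the cap is enforced for the FASTA only
and an oversized CSV merely warns, since the documented limit concerns
the sequence file.

## Exports

SPF hierarchy columns are named `Level_1`…`Level_7` (the consumer
accepts arbitrary hierarchy names). The SPF writer *rejects* non-strict
input rather than repairing it silently — repair is an explicit,
logged protocol step. The multi-chunk naming
`piphillinseqs<i>.fasta` / `piphillinotu.csv<i>.csv` reproduces the
upstream server workflow's established naming, duplicated extension and
all. Run folders are `output/<YYYYMMDD-HHMMSS>Z` in UTC with `-1`, `-2`
collision suffixes; the timestamp is injectable so tests and
reproducibility checks can compare runs file-by-file via the manifest
(path, bytes, SHA-256). ranacapa receives raw counts, not relative
abundances, since it rarefies internally. All writers conserve sample
totals exactly; round-trips through the matching readers are
cell-exact.

## Functional annotation

The KEGG BRITE `.keg` file is parsed offline: A/B/C lines open category
levels, `D` lines hold `K#####  <symbols>; <description> [tags]`
entries; trailing bracketed tags (`[EC:…]`, `[PATH:…]`) are stripped
from names. A KO under several C categories keeps every path; the
primary row uses the lexicographically first so the functional SPF has
one parent per node, and the full list goes to a sidecar file. KOs
absent from the hierarchy degrade to `unannotated` rather than failing
the run. Pathway-level tables are annotated by matching their
`ko#####` IDs against C-level pathway names. A live KEGG fetcher could
sit behind the same parsing contract, but the offline file is the
tested ground truth — trading currency for determinism.

Merging chunked inference results is an element-wise sum over the union
of IDs (absent IDs contribute zero), which is associative and
commutative, so the chunk order of uploads cannot change the merged
table.

## Synthetic data generator

The generator emulates the study conditions used throughout the test
suite: 12 samples × 100 features by default, lineages drawn from a
consistent synthetic taxonomy tree, log-normal feature abundances
multinomially sampled to ≈5 000 reads per sample (±20%), 250 bp
random-nucleotide sequences, and a 15% per-rank probability of a
classification gap at ranks 3–7 — producing both strict and non-strict
lineages, as real classifiers do. It can also emit a small BRITE
hierarchy (including one KO under two categories), a Piphillin-style
result archive with fixed member metadata (so generation is
byte-identical under a fixed seed), and metadata with deliberately
disallowed sample-ID characters. It does not emulate sequencing error,
chimeras, compositional correlation between taxa, or any real reference
taxonomy — passing tests demonstrate format and computation
correctness, not biological fidelity of any particular dataset.

The acceptance script scales the chunking check to a ~30 MB sequence
set (150 records × 200 kb) and the end-to-end reproducibility check to
the default 100 × 12 fixture; both sizes keep the full run in seconds
while exercising multi-chunk splitting and every export target.

## Known limitations

* BIOM-HDF5 ingestion/emission is out of scope (text exports only), as
  are raw-read processing, diversity statistics, and the inference
  server's algorithm itself.
* MrDNA lineage reconstruction is heuristic where per-rank tables are
  the only linkage (count-vector ties fall back to the path column or
  to unclassified).
* Sample-ID validation enforces one conservative alphabet (letters,
  digits, underscore) for all targets; per-tool relaxations beyond the
  period rule are not modeled.
* Alignment/tree construction is delegated to external MAFFT/FastTree
  binaries when present and skipped with a warning otherwise; trees are
  built from the pre-rarefaction sequence set, since they describe
  features, not counts.
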