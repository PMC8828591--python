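# annogap

Retrospective audit of taxonomic annotation gaps in DNA barcode corpora.

Public sequence databases hold large numbers of barcode sequences annotated
no deeper than kingdom level ("uncultured fungus"-style names). `annogap`
replays deposition history to ask, for each such sequence, whether a more
resolved name was already available at the time it was deposited:

* sequences are clustered into **compound clusters** (>= 80% identity, greedy
  centroid) and, within those, into **species hypotheses** (single linkage at
  a 3.0% distance threshold by default);
* each cluster receives a conflict-aware **consensus lineage** (low-resolution
  annotations are ignored unless contradictory);
* every kingdom-level sequence is classified against records released at
  least 7 days earlier: **FN_CLOSE** (a better-annotated co-member of its
  species hypothesis was available), **FN_REASONABLE** (only of its compound
  cluster), or **TP** (no qualifying match — a genuine dark-taxon candidate);
* metadata analyses: journal-list based "mycologist" scoring, country-of-
  collection comparison, and the yearly false-negative trend.

A synthetic-corpus generator with planted taxonomy, divergence structure,
release dates and masking — plus a ground-truth oracle that classifies
queries from planted memberships alone — makes every stage testable without
any database downloads.

## Command line

```sh
# Generate a synthetic corpus (corpus.fasta, metadata.tsv, truth.tsv)
annogap simulate --config sim.yaml --seed 42 --out sim/

# Cluster, replay deposition history, write audit tables + report JSON
annogap audit --fasta sim/corpus.fasta --metadata sim/metadata.tsv \
    --journals journals.txt --out audit/

# Render a human-readable summary (optionally with plots)
annogap report --audit-dir audit/ --out report/ --plots
```

`journals.txt` lists journal names scored as mycological, one per line
(`#` comments allowed); matching is normalization-insensitive (case,
whitespace, punctuation, `&` vs `and`). Without it, mycologist fractions are
reported as absent. All machine outputs are files; logs go to stderr. Exit
codes: 0 success, 2 usage/config error, 1 runtime error. Outputs are only
overwritten with `--force`.

### Input formats

FASTA (ids are accessions up to the first whitespace) plus a tab-separated
metadata table with header
`accession  release_date  lineage  country  journal  study_id`:
ISO-8601 dates and a semicolon-delimited seven-rank lineage
(`kingdom;phylum;class;order;family;genus;species`; empty fields,
`unidentified`, `sp.` and `incertae sedis` count as unidentified).

## Package layout

| module | role |
|---|---|
| `annogap.corpus` | ranks, lineages, sequence records, FASTA/TSV I/O |
| `annogap.clustering` | pairwise identity, compound clusters, species hypotheses |
| `annogap.consensus` | conflict-aware consensus lineage assignment |
| `annogap.audit` | availability policy, query classification, aggregation |
| `annogap.metadata` | journal scoring, country comparison, yearly trend |
| `annogap.simulate` | synthetic corpora with planted ground truth |
| `annogap.cli` | `annogap simulate / audit / report` |
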