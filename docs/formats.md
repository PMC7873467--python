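# File formats

All tabular files are UTF-8, tab-separated, with `#` comment lines
ignored. Identifiers are plain strings; no symbol/Ensembl mapping is
performed.

## Expression matrix (`*.tsv`)

First column `feature_id` (unique within a class), remaining columns
sample IDs, cells log2-scale expression. Rows with missing values are
dropped on load with a logged count; non-numeric cells are an error.

```
feature_id	P1_EC	P1_EU	P2_EC	P2_EU
MRNA0001	7.81	7.65	8.02	7.70
```

## Sample sheet (`samples.tsv`)

Columns `sample_id`, `patient_id`, `condition` (EC = ectopic lesion,
EU = eutopic endometrium). Every sample in a matrix must appear here,
and each patient must have exactly one EC and one EU sample per class.

```
sample_id	patient_id	condition
P1_EC	P1	EC
P1_EU	P1	EU
```

## Interaction table (`interactions.tsv`)

Columns `mirna_id`, `target_id`, `target_class` ∈ {mRNA, lncRNA}.
Duplicate rows are collapsed with a logged count.

```
mirna_id	target_id	target_class
miR-202-3p	RP11-96D1.10	lncRNA
```

## Seed gene list (`seeds.txt`)

One gene identifier per line; blank lines and `#` comments ignored.

## Gene sets (`*.gmt`)

Standard GMT: per line, set name, description, then members, all
tab-separated (≥ 3 fields). Set names must be unique, sets non-empty.

## ceRNA network edge list (`cerna_edges.tsv`)

One row per competing pair with its hypergeometric evidence:
`lncrna_id`, `mrna_id`, `T`, `t`, `N`, `r`, `p_value`,
`shared_mirnas` (comma-joined). Round-trips through
`ceranet.io.read_network_edgelist`.

## GraphML export

Nodes carry a `node_class` attribute (mRNA/lncRNA, plus miRNA in
triple sub-networks); edges carry the same evidence fields with
`shared_mirnas` comma-joined.

## Truth manifest (`truth.json`, synthetic fixtures)

JSON with keys `planted_de` (class → feature → Up/Down),
`planted_pairs`, `pair_mirnas`, `hub_lncrnas`, `disease_lncrnas`,
`seed_genes`, and the generator `config`.
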