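# faircube

Experiment-design-driven FAIRification of wide-format omics results
matrices.

Supplementary tables in metabolomics and proteomics papers typically
flatten a three-dimensional result — molecular entities × experimental
treatments × quantitation types — into a two-dimensional spreadsheet by
composing condition and statistic into the column header (e.g.
`R. chinensis 'Old Blush' sepals — average`). That format is readable by
humans but opaque to software: the factors of the experiment, their
levels, the statistic each cell reports, and the sample size behind it
are all implicit. `faircube` makes them explicit. It is written for data
curators and stewards who retrofit published results matrices into
machine-actionable form, and for experimentalists who want to publish
their matrices that way from the start.

## What it does

Given a delimited wide matrix, a declarative header grammar and offline
ontology term maps, `faircube`:

1. **Unpacks** every composed column header into one factor level per
   independent variable plus a quantitation type, producing a tidy
   `DataCube` (entities × observed treatments × quantitation types).
2. **Infers the experimental design**: with factors $F_1,\dots,F_k$ and
   level sets $L_1,\dots,L_k$, the theoretical treatment space is the
   cartesian product $L_1 \times \dots \times L_k$ with
   $n_{theo} = \prod_i |L_i|$ combinations. Comparing against the
   $n_{obs}$ treatments actually reported classifies the design:
   *single-factor* ($k=1$), *full factorial* ($k\ge2$,
   $n_{obs}=n_{theo}$) or *fractional factorial* ($k\ge2$,
   $0 < n_{obs} < n_{theo}$).
3. **Annotates** compound names, cultivar/taxon names, anatomy parts and
   statistic labels with ontology terms (ChEBI, NCBITaxon, Plant
   Ontology, STATO) from local term-map files — exact match only, no
   fuzzy guessing — and records what stayed unresolved.
4. **Packages** the tidy cube as a Tabular Data Package
   (`datapackage.json` schema descriptor + CSV) with deterministic
   byte-identical output, validates packages, and writes a minimal
   ISA-Tab investigation stub referencing them.
5. **Converts to RDF** with deterministically minted IRIs and answers
   data-level queries with SPARQL: *which independent variables does the
   study have, with which levels?* and *what sample size was the mean
   computed over?* — answers contractually equal to the in-memory model.
6. **Compares studies**: identifier-keyed metabolite overlap (CURIE →
   InChI → label fallback) with Venn/UpSet-ready disjoint region counts.

A deterministic generator (`faircube.fixtures`) produces synthetic
exemplar studies with the structure of a rose-scent metabolite table: 61
compounds, cultivar (6 levels) × flower part (3 levels), 8 of 18
combinations observed, sample mean + standard error of the mean at
n = 3 technical replicates.

## Worked example

```sh
faircube make-fixture --out fix --seed 7
faircube fairify --input fix/matrix.csv --header-spec fix/header_spec.yaml \
    --term-map fix/termmap_chemical.yaml --term-map fix/termmap_taxon.yaml \
    --term-map fix/termmap_anatomy.yaml --term-map fix/termmap_statistic.yaml \
    --factor-domain "rose cultivar=taxon" --factor-domain "organism part=anatomy" \
    --study-id rose-exemplar --unit "ng g-1" --sample-size 3 \
    --replicate-semantics technical --out run
faircube inspect-design run/package
```

prints

```
Design classification: fractional_factorial
Treatments: 8 observed of 18 theoretical
Variable 'rose cultivar' (6 levels): R. chinensis 'Old Blush', R. hybrida 'Crimson Arrow', R. hybrida 'Damask Pearl', R. hybrida 'Garden Ember', R. hybrida 'Moonlight Veil', R. hybrida 'Silver Thorn'
Variable 'organism part' (3 levels): petal, sepal, stamen
Replicate semantics: technical
Group sizes: unspecified
Caveat: sample size reflects technical replication: the standard error estimates measurement variability, not biological variability
```

i.e. two categorical independent variables were recovered from the
headers; of the 6 × 3 = 18 possible cultivar × part treatments only 8
appear in the matrix, so the design is a fractional factorial. The
same answers are available from the RDF graph:

```sh
faircube query --graph run/graph.ttl --name predictors
# variable,n_levels,levels
# rose cultivar,6,R. chinensis 'Old Blush'; ...
# organism part,3,petal; sepal; stamen
faircube query --graph run/graph.ttl --name sample-size \
    --treatment "R. chinensis 'Old Blush' / sepal"
# treatment,qtype,sample_size
# R. chinensis 'Old Blush' / sepal,sample_mean,3
```

and two FAIRified packages can be compared:

```sh
faircube compare runA/package runB/package --out cmp
# shared=40 only_rose-exemplar=21 only_rose-second=10
```

The library surface mirrors the CLI: `read_matrix` / `unpack_headers`,
`infer_design`, `annotate_cube`, `write_package` / `read_package` /
`validate_package`, `build_graph` / `query_predictors` /
`query_sample_size` / `export_plot_table`, `compare_studies`, and the
generators in `faircube.fixtures`.

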