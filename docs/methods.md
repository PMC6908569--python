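# Methods

## The data-cube model

A results matrix is treated as a three-dimensional data cube:

* **molecular entities** — the measured compounds, identified by a
  verbatim source label, a normalized label, and (when resolved) a ChEBI
  term and InChI string;
* **treatments** — tuples of factor levels, one level per independent
  variable, in factor declaration order;
* **quantitation types** — the statistic a cell reports. Two canonical
  types are recognized (`sample_mean`, `standard_error_of_mean`); any
  other label is carried as `other`.

Measurements are cells keyed by (entity, treatment, quantitation type);
the key is unique within a cube. Missing cells are retained as records
with a missing value rather than dropped, so the matrix ↔ cube mapping
is lossless and cube shape stays auditable. `check_cube` validates every
structural invariant (referential integrity, key uniqueness, level
membership, sample-size presence for statistics that require one) and
reports violations with machine-readable codes instead of raising.

A sample mean must carry the size of the sample it was computed over.
As a package policy the SEM carries the same sample size (it derives
from the same n); this keeps the "what n was this computed over?" query
answerable for both statistics.

Replicate semantics (`technical` / `biological` / `unspecified`) are an
explicit attribute, never assumed: when replication is technical, the
SEM estimates measurement variability, not biological variability, and
the design report says so. The exemplar default is technical with
n = 3 — a single biomaterial assayed three times per condition.

## Header unpacking

The header grammar is configuration, not code. A `HeaderSpec` is an
ordered list of rules; each rule is a regular expression whose named
capture groups are routed either to a named factor or to the
quantitation-type slot. Headers are normalized before matching (trim,
collapse whitespace runs, typographic quotes/dashes → ASCII). Exactly
one rule must match a header: zero matches and multiple matches are
distinct, reported errors. A synonym table canonicalizes captured
tokens (`sepals` → `sepal`, `average` → the mean); a built-in table then
maps statistic labels to canonical quantitation types.

Strict mode raises on the first problem; lenient mode collects all
findings (unmatched/ambiguous headers, unparseable cells) into one
report, drops the offending columns and marks offending cells missing.

Canonical cube ordering is independent of input column order: levels
sort lexicographically within each factor, treatments by level tuple,
quantitation types mean-first. Permuting the input columns therefore
yields an identical cube. Sample size is not matrix content — it enters
via configuration (a constant or per-treatment mapping), reflecting
that this information typically lives in separate study metadata.

The dialect (delimiter, decimal mark, row-label column) is always
declared, never sniffed; comma-decimal inputs must say so.

## Design inference

The theoretical treatment space is the cartesian product of the factor
level sets, enumerated in lexicographic (factor order, level order)
order. Classification is a trichotomy: `single_factor` (one factor),
`full_factorial` (≥ 2 factors, all combinations observed),
`fractional_factorial` (≥ 2 factors, a strict non-empty subset). Only
crossed categorical factors are modelled; blocking, nesting and
covariates are rejected with a clear error. Balance is not classified —
group sizes may vary per treatment and are carried as data.

A level that never appears in any column is unrecoverable from the
matrix, so design inference reports the design *of the observed level
sets*; the synthetic generator correspondingly only plants fractional
layouts that cover every level at least once.

## Annotation

Term maps are local files, one per domain (chemical, taxon, anatomy,
statistic): a dictionary from normalized label to one or more candidate
terms plus an alias table. Resolution is exact match on the normalized
label, then the alias table. A label with multiple candidates is
`ambiguous`; a miss is `unresolved`; neither is an error. There is no
fuzzy matching: silently guessing identifiers would reintroduce the
imprecision the mapping exists to remove. Aliases that point at two
targets are rejected at load time.

Label normalization: NFC, typographic → ASCII, Greek transliteration
from a fixed closed table (β → beta …), whitespace collapse, case fold.
It is idempotent, which makes annotation idempotent.

Factor → domain routing (e.g. `rose cultivar` → taxon) is explicit
configuration, since nothing in a header says which ontology applies.
Annotation only attaches terms; values, shapes and ordering are never
touched, and original labels are always preserved.

## Tabular Data Package layout

One denormalized `measurements` resource: entity label, CURIE and InChI
columns, one column per factor, quantitation type, value, unit, sample
size. Column-level semantics are declared per schema field (`rdfType`
IRIs); cell-level chemical identity lives in the identifier columns.
The descriptor also carries a cube-metadata block (factors, level order,
terms, quantitation types, entity registry) that makes the package a
lossless serialization: `read_package(write_package(c))` equals `c` up
to canonical ordering.

Writing is deterministic — fixed field order, LF line endings, shortest
round-trip decimal rendering with `.` decimal mark, missing cells as the
empty string with the token declared in `missingValues` — so identical
cubes give byte-identical packages. The validator re-checks descriptor
well-formedness, schema/data arity, declared types, missing-token
discipline and term-IRI syntax, and reports all findings.

The ISA-Tab output is deliberately an investigation *stub*: ontology
sources, investigation, study and study-assay sections with one data
package reference per assay column. Sample-level study/assay tables are
out of scope.

## Triple model and queries

The RDF rendering (normative for this package, documented rather than
claimed identical to any external artifact) emits: one study node; one
design node typed by classification; one node per independent variable
with a position literal and its level nodes (also positioned, so the
graph preserves declaration order exactly); one node per observed
treatment linked to its member levels; and one measurement-datum node
per cube measurement with exactly one entity link, one treatment link,
one quantitation-type link, a decimal value literal, a unit literal and
a sample-size literal where required. Entity nodes carry term IRIs and
InChI literals when resolved.

Which OBO classes stand behind the concepts (sample mean, SEM,
fractional factorial design, …) is configuration in a vocabulary map;
the shipped defaults use OBO-style CURIEs and PURLs and can be
overridden wholesale. Instance IRIs are minted from the study id plus a
content hash of the node's identifying tuple — no blank nodes, so
rebuilding the same inputs yields an IRI-identical statement set.

Values are typed `xsd:decimal` rather than `xsd:double` because the
Turtle serializer truncates doubles to seven significant digits, which
would break serialization round-trip equality.

The two canonical queries run as SPARQL over the graph. Their contract
is defined by results, not syntax: answers must equal what the in-memory
`DesignModel`/`DataCube` reports (tested as an oracle-equivalence
property over randomized designs). The N-Triples serializer sorts lines
so equal graphs serialize byte-identically.

## Cross-study comparison

Entities join on the most reliable key available per entity — CURIE,
then InChI, then normalized label — with the key type recorded per
entity so mixed-confidence joins are auditable. Output is plain set
algebra: per-study sets, intersection, exclusives, a membership matrix
and disjoint (UpSet-convention) region counts sorted descending with a
lexicographic tie-break. Inclusion–exclusion holds by construction and
is property-tested anyway. No overlap-significance testing is provided.

## The synthetic generator

The generator emulates the *structure* of a targeted metabolite
profiling supplementary table, not its numbers. Defaults: 61 compounds;
cultivar (6 levels, reference 'Old Blush') × flower part (3 levels);
observed layout = all cultivars at sepals ∪ reference cultivar at all
parts, i.e. 6 + 3 − 1 = 8 of 18 combinations; sample mean + SEM;
n = 3 technical replicates; unit `ng g-1`; complete matrices and full
chemical-map coverage, with knobs for missing-cell rate and withheld
map entries.

Value model: concentrations are log-normal (positive, right-skewed, as
metabolite abundances are), `exp(N(ln 50, 1))` per compound with a
per-treatment effect `N(0, 0.5)` and cell noise `N(0, 0.25)`; the SEM is
a planted per-cell dispersion (mean × CV, CV ~ U(0.05, 0.30)) divided by
√n, so the mean/SEM relationship is internally consistent and checkable
to machine precision. Everything derives from one seed;
identical parameters give byte-identical files.

The chemical identifiers in the generated term maps are **synthetic**:
CHEBI-style accessions and InChI strings minted deterministically from
the compound label. They exercise the identifier plumbing (resolution,
join keys, IRIs) but are not real chemistry. What passing tests show is
that the pipeline recovers planted structure exactly — factor counts,
level sets, observed/theoretical treatment counts, classification,
quantitation types, sample sizes, overlap regions. What they cannot
show: robustness to real-world header idiosyncrasies beyond the modelled
perturbations (case/quote noise, missing tokens, ragged rows,
non-numeric cells), real nomenclature ambiguity, or agreement with any
real study's concentration values.

A generic k-factor generator (`generate_custom_study`) backs the design
recovery sweep (1–4 factors, 2–6 levels, full and level-covering
fractional layouts); a paired generator plants exact overlap counts
(default 40 shared of 61 and 50, giving 40/21/10 regions) for
comparison tests.

## Problem sizes and numeric choices

Tests and the acceptance script run at the exemplar scale (61 × 8 × 2 =
976 measurements, ~7 000 triples) plus randomized property sweeps of
100 round-trip cubes and 50 graph-oracle designs — a few seconds in
total. Tolerances: SEM consistency is asserted at 1e−9 absolute; all
other planted quantities are integers recovered exactly. Ties in region
counts break lexicographically; cube canonical order is defined in the
ingest section; degenerate inputs (empty cube, empty selection, zero
overlap) are exercised explicitly.

## Known limitations

* No spreadsheet-binary or PDF table extraction — input is delimited
  text.
* No live ontology lookups; the resolver contract allows plugging a
  client in, but the shipped path is offline term maps.
* No ontology reasoning; terms are opaque labelled identifiers.
* No statistical analysis (ANOVA, power, overlap significance): the
  package's job is to make designs and statistics explicit enough that
  such analyses can be configured correctly downstream.
* W3C RDF Data Cube (`qb:`) alignment is noted as future work; the
  graph model is OBO-anchored.
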