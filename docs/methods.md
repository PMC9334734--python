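# Methods

## Scope and data model

The package operates entirely downstream of external annotation tools: it
consumes InterProScan 5 tabular output, OrthoFinder `Orthogroups.tsv`
tables, protein FASTA, a flat protein→gene isoform map, and BLAST outfmt-6
homology hits. It never runs InterProScan, OrthoFinder, an aligner, or
BLAST itself; alignments are inputs. Coordinates are 1-based inclusive
everywhere (the InterProScan convention) and converted to half-open Python
slices only inside sequence-slicing code.

A domain hit is addressable in two namespaces: its member-database
accession (Pfam `PF…`, SMART `SM…`, PANTHER `PTHR…`, Gene3D `G3DSA:…`,
Phobius signal-peptide/transmembrane strings) and its integrated InterPro
accession (`IPR\d{6}`) when present. PANTHER subfamily ids
(`PTHR10887:SF470`) are kept verbatim and additionally indexed under their
family prefix, because published screens mix family- and subfamily-level
matching. Rule catalogs may reference either namespace; this mirrors
figure legends and supplementary tables in the comparative-immunogenomics
literature, which freely mix IPR, SMART and Gene3D symbols.

## Family rules

A family rule is a small DNF expression: an ordered list of clauses
labelled strict / relaxed / alternate, each with a required accession set,
an optional forbidden set, and an optional minimum number of distinct hit
intervals (`min_distinct_hits`, so "contains two TIR domains" is
expressible; intervals are merged before counting so overlapping
same-domain calls from different databases are not double-counted). The
first satisfied clause wins, so a strict match always dominates a relaxed
one. Forbidden sets are an extension beyond published required-domain
tables: they are needed to express classifications like "orphan TIR"
(a TIR domain and nothing else diagnostic) or adapter families defined by
*lacking* Death-like domains. Families are deliberately **not** mutually
exclusive — a C-type lectin domain legitimately contributes to several
lectin families' relaxed clauses — and the screen reports every match.

The shipped catalog (`immunome/data/default_rules.yaml`, ~110 families
across 16 functional groups) transcribes the strict/relaxed required-domain
sets used in a published gastropod immunome survey, including its one
alternate-clause family (the bivalve-style complement factor B defined by
von Willebrand A + Sushi + EGF + Pentraxin domains). The per-family
`reported_count` fields are that survey's published gene counts, kept as
descriptive metadata only; they play no role in matching. Published counts
reflect domain mining *plus* orthology vetting *plus* manual inspection,
so exact reproduction of hand-curated families from raw annotations is not
claimed; the pipeline instead reports pre- and post-vetting counts
explicitly.

## Vetting, rescue, and overlap statistics

Vetting annotates each domain-matched gene with whether any of its isoform
ids (or the gene id itself — orthogroup tables exist at both id levels)
shares an orthogroup with a reference gene of the same family. By default
every domain-matched gene is retained; an optional policy
(`require_orthology_for_relaxed`) diverts relaxed-only genes without
orthology support to the reject report. This deterministic policy is the
package's replacement for a by-hand curation step, which no rule set can
reproduce exactly. Rescue returns focal-species genes co-grouped with
references but missed by the screen (TAB1-like cases where the only
visible domain is a generic phosphatase domain); rescue and screen are
disjoint by construction. Homology evidence uses best-hit-per-query
filtering with configurable thresholds; the default (e-value ≤ 1e-5, no
bitscore floor) is a conventional BLAST screening cutoff, stated in config
because no principled value exists at this granularity.

Named orthogroup subsets ("common to mollusks and humans but not flies")
have no universally agreed formalization, so subset definitions are
explicit parameters: an *exact* subset requires the non-empty species set
to equal the stated set; an include/exclude subset requires all listed
inclusions (or at least one member of each listed group) present and all
exclusions absent. The invariant `at_least_two + single_species == total`
is checked on every computation.

## Architecture analytics

Member databases fragment repeat regions (LRRs especially) arbitrarily, so
architecture reasoning runs on merged intervals: per canonical label,
overlapping or book-ended (stop+1 = start) hits union into one interval
retaining all source accessions. Merging is idempotent and
order-invariant. The shipped label map covers the signatures used in
TLR-architecture work (TIR; five LRR subtypes plus the ribonuclease-
inhibitor-like fold; the cysteine-rich C-terminal LRR cap as its own label;
ROC/COR; Mbt; EF-hand; CARD; Death; RLR C-terminal domain; Phobius
signal-peptide and transmembrane calls). Domain extraction takes the
longest isoform per gene (ties broken by lexicographically smallest
protein id — deterministic and logged; the choice is arbitrary but stable)
and emits one region per merged interval, so dual-TIR genes yield two
regions. Presence/absence matrices count matched *proteins* per species,
not genes, matching how cross-species comparison figures are tabulated.

## Phylogenetics

**Model.** The JTT exchangeabilities and stationary frequencies are the
published empirical values as distributed with standard phylogenetics
software, embedded as constants; the generator is normalized to one
expected substitution per site per unit time and validated for
reversibility (π_i q_ij = π_j q_ji to 1e-10) and zero row sums. Rate
heterogeneity combines a proportion p_inv of invariable sites with k
equal-probability discrete-gamma categories represented by category means
(Yang's approximation). Variable-category rates are divided by (1 − p_inv)
so the mixture's expected rate is exactly 1 — this keeps distances in
substitutions/site regardless of p_inv. Defaults: k = 4, p_inv = 0.2,
α = 1.0. The gamma shape is a supplied parameter, never estimated. A note
on p_inv: the source survey's methods state a "proportion of invariable
sites of 2", which cannot be a proportion; it is read here as 0.2 and
exposed as config.

**Distances.** Pairwise ML distances maximize the +I+Γ mixture likelihood
over site-pattern counts, with pairwise deletion of gapped/ambiguous
columns (standard distance-matrix practice). P(t) is computed from the
eigendecomposition of the symmetrized generator (numerically stable for
reversible models). Optimization is bounded Brent on t ∈ [1e-8, 50] to
absolute tolerance 1e-8; hitting the upper bound returns the bound with a
saturation warning. Identical sequences short-circuit to 0. The estimator
is deterministic — no randomness enters distance computation.

**Trees.** Neighbor joining uses the Studier–Keppler Q criterion with
deterministic smallest-(i,j) tie-breaking; negative branch lengths are
clamped to zero with the deficit transferred to the sibling branch so pair
distances are preserved. NJ is exact on additive matrices (verified to
1e-9 on random instances). Bootstrap resamples alignment columns with a
seeded generator; replicates with a zero-comparable-sites pair are skipped
and supports normalized by completed replicates. Supports are attached to
the point tree's internal bipartitions as percentages (integer-rounded in
Newick labels). Robinson–Foulds distance and the group-concordance report
(a group is concordant iff some bipartition separates exactly that group;
otherwise outliers are members outside the maximum-F1 covering clade)
operate on canonical bipartition sets. A multi-species tree can reuse the
same machinery without bootstrap where replicate cost is prohibitive.

## Synthetic data

The generator's defaults define the verification conditions: five species
(one focal gastropod, a bivalve, a second gastropod, human, fly — matching
the five-proteome design of the source survey), planted families
TLR 5 / SRCR 3 / MyD88 2 / PARP 2, 50 background genes, 1–3 isoforms per
gene with the domain suite planted on the longest isoform, domain lengths
50–200 residues with 5–50 residue spacers. The planted families were
chosen for pairwise-disjoint diagnostic accessions so planted truth is
unambiguous; background decoys come from an accession pool disjoint from
the catalog so they can satisfy no clause. Orthogroups group each planted
gene with one named ortholog per non-focal species (those ortholog ids
double as the reference catalog for vetting tests); background genes get
singleton orthogroups. Generation is byte-deterministic for a fixed
config and ends with a self-audit that re-parses and re-screens the
emitted files against the planted truth.

What the generator does *not* emulate — and what passing tests therefore
do not show about real data: annotation noise (false or missing domain
calls), partially annotated isoforms, orthogroup inference errors,
paralog-rich orthogroups mixing families, indels (evolved alignments are
gap-free; gap handling is tested with hand-built fixtures), and
compositional heterogeneity across sites beyond the +I+Γ mixture. Recovery
of planted truth with precision = recall = 1 demonstrates internal
correctness of the machinery, not robustness to noisy annotations.

The sequence evolver draws the root from stationary frequencies, assigns
each site one rate from the invariant/gamma mixture, and applies
P(b·rate) down each branch; it is validated against analytic expectations
(stationary root composition, single-branch substitution counts within 3
standard errors, saturation of pairwise identity to Σπ²) and serves as the
independent simulation oracle for the distance and tree estimators.

## Verification problem sizes

The acceptance script uses: 4,096 exhaustive signature subsets × 5 rules;
20 synthetic proteomes (~62 genes each) for planted-truth recovery; 100
random additive matrices of 8–16 taxa for NJ exactness; 10 sequence pairs
of length 5,000 at each of t ∈ {0.1, 0.5, 1.0} for distance recovery; 20
8-taxon simulations of length 2,000 for topology recovery; and a B = 100
bootstrap run twice under one seed for reproducibility. These sizes give
stable statistics at desk scale; the same machinery runs unchanged on
study-scale inputs (tens of thousands of proteins, B = 1000).

## Known limitations

- Rule matching sees only accession presence and interval counts, not
  domain order or copy-number beyond `min_distinct_hits`.
- The vetting retention policy is deterministic and cannot reproduce
  judgment calls of manual curation; compiled immunomes from real data
  should be reviewed.
- NJ with clamped negative branches is a heuristic on non-additive
  matrices; no ML or Bayesian tree search is provided.
- α (gamma shape) is fixed, not estimated; distances under a badly
  misspecified α are biased.
- Saturated pairs report the optimizer bound (50 substitutions/site)
  rather than an infinite distance.
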