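# Methods

This note documents the models implemented in `genefam-bd`, the defaults
they ship with, the design choices made where several formulations were
defensible, and what the synthetic data do and do not emulate.

## Data model

Trees are rooted as given and never rerooted: outgroup rooting (for the
TAS1R family, GPRC6A) is the caller's responsibility and happens before
export to Newick.  Polytomies are allowed everywhere; operations over
children are defined pairwise.  Branches are identified by the id of
their child node, so "the tetrapod stem" is the branch whose child is
`tetrapod_ancestor`.  Presence matrices hold one of three states per
species × clade cell — `absent`, `intact`, `pseudogene` — plus an
optional copy number (`1:2` = two intact copies).  Gene-model coordinates
are 0-based half-open; for minus-strand genes the exon list is in
transcription order, not genomic order.

## Ortholog classification

A rooted gene tree is labelled by the **species-overlap rule**: an
internal node is a duplication iff the species sets of at least two of
its children intersect.  Under a polytomy any overlapping pair suffices
(the conservative reading of the pairwise definition).  On simulated
gene trees this rule recovers every true duplication node both of whose
daughter lineages left descendants in overlapping species, and never
labels a node with species-disjoint children as a duplication.

Clades are the connected components obtained by cutting the tree at
*clade-separating* duplications.  Which duplications separate clades is
a taxonomic decision, so it is driven by a user-supplied map from species
to named groups (Amphibia, Chondrichthyes, ...):

- a duplication confined to one species never separates anything
  (within-species copies such as the two zebrafish TAS1R2B genes);
- at **clade** level, a duplication confined to a single taxon group does
  not separate (the amphibian TAS1R3B1/TAS1R3B2 split, the three
  chondrichthyan TAS1R6 subclades);
- at **subclade** level every multi-species duplication separates.

Species without a group entry act as their own singleton group.  Labels
are deterministic: components are ordered by their lexicographically
smallest gene id, and a display-name map can rename them.

Two collapses of a labelled gene tree to a clade tree are provided.
`collapse_to_clade_tree` yields one leaf per ortholog clade — the input
reconciliation expects — by hoisting each component's gene content to the
top of the component; when a clade's tips are interleaved with nested
duplication subtrees this necessarily simplifies the within-component
branching order.  `collapse_pure_subtrees` is the faithful alternative
used for parsimony bounds: it contracts only maximal single-clade
subtrees, keeping one leaf per contiguous chunk, and therefore preserves
the exact branching structure of the gene tree.

## Event reconstruction

`dollo_reconstruct` is matrix-only Dollo parsimony: each clade is gained
exactly once, at the MRCA of its carriers (pseudogenes count as carriers
— a disabled copy is still evidence of ancestral presence), and one loss
is placed on the stem of every maximal carrier-free subtree below the
origin.  For a fixed single origin this loss set is minimal: any history
must lose the clade at least once inside each maximal carrier-free
subtree, and one loss at its stem suffices; moving the origin rootward of
the MRCA only adds carrier-free subtrees.  The test suite checks the
count against exhaustive enumeration of all single-origin assignments on
random trees of up to six leaves.

`reconcile` is LCA (most-parsimonious duplication–loss) reconciliation of
the clade tree: every node maps to the species-tree LCA of its descendant
carriers; a node one of whose children maps to the same species node is a
duplication, placed on the branch leading to that node, and both daughter
lineages exist at the mapped node.  Clade origins are thereby pushed
rootward relative to matrix-only Dollo (never tipward — an asserted
invariant).  Losses are then placed per lineage: on the off-path side
branches between where a lineage starts and where it ends, and by the
Dollo rule below each leaf clade's carrier MRCA.  When sister clades
arise by duplication both origins sit on the same species branch, in the
order given by the clade-tree topology; the method does not time events
within a branch.

Two bookkeeping decisions matter for reading the output.  First, when an
ancestral lineage splits at a *speciation* (e.g. the cartilaginous-fish
TAS1R6 versus the bony-vertebrate ancestor of TAS1R1/2A/2B/5), the
descendant clades are renamings of the same gene, not new events; these
handoffs are stored as `divergences`, separate from the four event kinds
(origin, duplication, loss, pseudogenization), and `EventMap.replay`
applies both so that replaying from the root reproduces the input matrix
exactly.  Ancestral lineages are labelled `anc(<members>)`.  Second, copy
number above one within a species is ignored by reconstruction:
species-specific duplications are visible in the matrix but deliberately
excluded from the event narrative, so on simulations the inferred
duplication count equals the number of *multi-species* true duplications
when no losses occurred, and inferred duplications + losses never exceed
the true event count (both asserted over seeded replicates via the
faithful chunk collapse).

Pseudogenization is reported as an event on the terminal branch of each
pseudogene carrier; nothing in the matrix dates the inactivation, so the
terminal branch is the latest-possible (and only defensible) placement.

## Synteny

Adjacencies are unordered symbol pairs; strand and orientation are
ignored because conserved-block arguments at this scale do not use them.
The family cluster can be collapsed to one token so flanking adjacencies
(DVL1, MXRA8 around the TAS1R cluster) are comparable across species
whose clusters differ in content; two genes separated only by the
collapsed cluster count as adjacent across it.  Each adjacency is
reconstructed as an independent binary character under Dollo (single
gain at the carrier MRCA), matching the conserved-ancestral-block
reasoning; a Fitch-style unrestricted alternative was considered and
rejected because independent gains of the same gene adjacency are
implausible at these scales.  Ancestral adjacency sets are assembled
into maximal simple paths; symbols with more than two inferred
neighbours are reported as conflicts — they are data (evidence of
lineage-specific rearrangement), not errors.  Output is deterministic:
paths start at lexicographically smallest endpoints and each path is
oriented to its smaller reading; cycles are cut at their smallest
symbol.  The module reports clusters and adjacencies only; it does not
classify translocation types or compute rearrangement distances.

## Motif scanning

Upstream windows cover up to L = 300 bp immediately 5' of the start
codon (the window the regulatory analysis used), truncated at scaffold
edges and reverse-complemented for minus-strand genes so they always
read on the coding strand.  Offsets are negative, −1-based positions
relative to the A of ATG.  Scanning accepts IUPAC degenerate words and
covers both strands by default (the conserved-alignment figure implies
the coding strand, but strandedness is not stated, so it is
configurable and hits report their strand).  A motif is called conserved
when at least `min_species` species have a hit inside a configurable
offset band.  PWMs are count matrices with additive pseudocounts
(p = (n + pc)/(N + 4·pc), default pc = 0.5); PWM similarity is the mean
column-wise Pearson correlation over the best ungapped offset with both
strands searched and a minimum overlap of six columns — identical
matrices score 1.0, and the score is symmetric and invariant to
reverse-complementing either input.  Uniform (zero-variance) columns
correlate 1 with an equal column and 0 otherwise.  De novo motif
discovery (MEME-style EM) is out of scope; the module consumes a word or
a PWM.

## Assay statistics

The response of a well is the signed trapezoidal integral of
luminescence minus baseline from stimulus onset to the end of recording,
in RLU; the baseline is the pre-onset mean and negative areas are not
floored.  The positive-response rule is strict in both senses: mean AUC
strictly above 10,000 RLU **and** BH-adjusted q strictly below 0.01.
The test is a one-sided Welch t-test (treatment > buffer control); Welch
was chosen because equal variances are not defensible across ligands.
Duplicate wells are averaged within each independent experiment first,
making the experiment the unit of replication and avoiding
pseudo-replication; rows with fewer than two experiments are flagged
untestable and never called positive.  The BH family is all ligand rows
of one receptor pair — the family is not dictated by the assay design,
so it is documented here and configurable.  Buffer controls are matched
per receptor pair (per plate); a global-control variant would only
change the pairing of the t-test.  Ligand concentrations at or above
100 mM are unreliable because of osmolarity artefacts; the package treats
this as an input caveat, not a hard error.  Class enrichment (are all
responders essential amino acids?) is the hypergeometric upper tail
P[X ≥ k], i.e. the one-sided Fisher exact test.  Dose–response curves
are least-squares Hill fits R = Rmax·c^h/(EC50^h + c^h) with positivity
bounds on EC50 and h ∈ [0.01, 10]; non-convergence is reported in the
result object, never raised.

## Synthetic data

`simulate_family` runs a Gillespie birth–death(–pseudogenization)
process along a dated species tree: each intact copy duplicates at rate
λ, dies at rate μ and pseudogenizes at rate ψ (events per lineage per
Ma); pseudogenes can still be deleted but no longer duplicate.  Every
duplication spawns a new clade label, so the truth records each clade's
origin branch, every per-branch event, the surviving gene tree and the
tip matrix.  Default rates are λ = 0.002 and μ = 0.001 — chosen so a
single root gene on the 473-Ma vertebrate tree produces families of
roughly the TAS1R's size (a handful to a dozen surviving clades) with
occasional extinctions, i.e. a slow birth–death regime rather than the
rapid turnover of large chemoreceptor repertoires.  The fixture's node
ages use the two anchors the family history quotes (jawed-vertebrate
split ~473 Ma, bony-vertebrate crown ~435 Ma); other ages are
conventional order-of-magnitude values that only scale simulator branch
durations.  The simulator draws copy genealogies but not sequences: no
substitution model, no alignment noise, no assembly artefacts.  Passing
tests therefore demonstrate the correctness of the inference logic given
a correct gene tree, not robustness to gene-tree estimation error.

`simulate_upstream` produces i.i.d. background sequence at a given GC
content with the motif word planted at recorded offsets; optionally the
background is resampled until the planted occurrence is unique, so exact
recovery can be asserted.  Real promoters are not i.i.d., so the
background-rate checks validate the scanner, not a genomic null model.
`simulate_assay` draws per-well AUCs as normals around the control mean
(+Δ for responders) with the published replicate structure (six
independent experiments × duplicate wells); default Δ = 30,000 RLU and
σ = 5,000 RLU give essentially full power at n = 6, which is the regime
the strict rule was designed for.  Real plates have correlated wells and
heavier tails; the FDR-control property is asserted under the normal
null only.

All generators are pure functions of (configuration, seed); no
wall-clock seeding exists anywhere in the package.

## Fixture provenance and open points

The 21-taxon matrix, the 11-clade topology, the gene orders around the
TAS1R cluster and the assay margins are transcribed from the study this
package reimplements.  Cells that the narrative states directly
(carrier lists for TAS1R4/5/7/8, the lungfish TAS1R3B and whale-shark
TAS1R3C pseudogenes, the bichir and elephant-fish repertoires, the
DVL1/MXRA8 flanks and the ACAP3–PUSL1–LPAR6–INTS11–CPTP chain) are
authoritative; rows only shown graphically (turtle, crocodilian,
sterlet, bowfin) and the shark memberships of the TAS1R6-2/6-3 subclades
are fixture choices flagged in `fixture.PROVENANCE` and are not used as
acceptance quantities.  The branching order of TAS1R7 versus TAS1R8
within the non-(TAS1R3/TAS1R4) half of the clade tree is not resolved by
the data; both orders give identical origin placements, and the fixture
fixes one.  Whether gar-like neopterygians carry TAS1R4 is read as "no"
from the absence of the gene in neopterygians; the fixture omits gar
entirely and covers the neopterygians with bowfin and two teleosts.
The coelacanth's duplicated TAS1R2A copies are kept as within-species
copies, not subclades.  Exact identities of the eight non-essential
amino acids in the 17-ligand panel are not recorded; the fixture stores
the margins (17 tested, 9 essential) plus the six named responders, and
the placeholder ligand names used for plate simulation are marked
synthetic.

The upstream-window fixture plants only the Oct word ATGCAAAT; the
second conserved Oct-like motif of the original analysis has no printed
consensus and is therefore not encoded.  Published likelihood-based tree
tests and de novo motif statistics require sequence data and external
tools that are out of scope here; the property suite on simulated data
stands in for them.

## Numerical and determinism notes

Newick parsing is delegated to dendropy; numeric internal labels are
stored as support values, non-numeric ones become node ids, and unnamed
internal nodes get deterministic preorder ids.  All event lists, clade
labels, assembled paths and reports are deterministically ordered, and
`genefam-bd run` with a fixed seed produces byte-identical reports.
Loss placement ties under polytomies are broken rootward, matching the
single-gain reading of Dollo.  Hill fitting uses analytic-free
least squares with data-driven initial values (max response, first dose
reaching half-max); flat data converge to Rmax ≈ 0 and are flagged
rather than rejected.
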