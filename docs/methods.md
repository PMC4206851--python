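# Methods

## The lattice model

The Klein four-group structure on N = {C, U, A, G} is fixed once, via
C=00, U=01, A=10, G=11 with bitwise addition mod 2; it does not depend on
the chosen ordering.  An *ordering* (a permutation of the four letters,
written as a 4-character string) defines the embedding of the 64 triplets
into {0..3}³: the base at triplet position *i* contributes its rank on
axis *i*, so CCC sits at the origin under the canonical ordering CUAG and
UCC, CUC, CCU are the three unit vectors.  Distances are Manhattan
(taxi-cab); adjacency means distance one, i.e. a single-position change
between consecutive ranks.  The diameter of the lattice is 9 (corner to
opposite corner).

Named subsets use a three-character pattern syntax (N = any, Y = {C,U},
R = {A,G}, or a literal base per position), which covers the walls
(first-position classes), floors (third-position classes), the corner
condominiums (e.g. YYY and its translates) and the primeval RNY set,
plus the literal name `SGwT` for the 8-triplet subgroup-with-a-tail
{CCC, CUC, CCU, CUU, CCA, CUA, CAA, CUG} of the rear wall.

## Isometries

An isometry is stored in the normal form (translation v, axis
permutation M) with v ∈ {C,G}³; its action permutes the three positions
of a triplet and then Klein-adds v component-wise.  The composition rule
(T_v1 M1)(T_v2 M2) = T_(v1 ⊕ M1·v2)(M1 M2) follows from conjugating
translations through permutations; equality is structural on the normal
form, which is unique.  Only corner translations are admitted as
isometries — a general Klein translation (e.g. by AAU) need not preserve
distances and is exposed separately as `translate_set`.  Corner
translations preserve Manhattan distance exactly under orderings whose
ranks place complement pairs at 0↔3 and 1↔2 (the canonical CUAG among
them); the property tests quantify over that family.

Group closure is a fixed-point iteration over composition; stabilizers
are brute-force scans (the ambient group has at most 48 elements).
`classify_small_group` labels groups of order ≤ 8 from the order, the
commutativity flag and the multiset of element orders, which separates
all isomorphism classes in that range — in particular the dihedral group
of order 8 (five involutions) from the quaternion group (one).  The
setwise stabilizer of the three-walls anticodon hotel CNN ∪ UNN ∪ GNN
has order 8 with element-order census {1:1, 2:5, 4:2}, and is therefore
reported as `dihedral(8)`; the classifier deliberately derives the label
from the census rather than hard-coding a name.

## Code tables

The standard genetic code is stored by family box.  The two anticodon
tables are generated from wobble rules rather than transcribed:

* standard: NNC and NNU codons of a box share the 5'G anticodon (the
  reverse complement of the NNC codon); NNA codons get their 5'U reverse
  complement, NNG codons their 5'C reverse complement; stop codons are
  never assigned.  The 16 ANN triplets are unused, and the three reverse
  complements of the stop codons (UUA, UCA, CUA) are also unused; 45
  distinct elongator anticodons remain.
* human: the boxes of Phe, Cys, Ser(AGY), Tyr, His, Asp, Asn and Gly
  keep the 5'G anticodon; the boxes of Ala, Pro, Thr, Val, Ser(UCN),
  Leu(CUN), Arg(CGN) and Ile use instead the 5'A anticodon (reverse
  complement of the NNU codon), flagged `inosine-5prime`; 3'A and 3'G
  codons behave as in the standard set.  Eight GNN and eight ANN
  triplets are unused, again with 45 used anticodons.

Inosine's capacity to read 3'A codons is recorded as the flag only; the
mapping keeps each purine-start anticodon serving exactly two codons,
which is what makes the used/unused bookkeeping come out at 45/16.  The
three exceptional human genes sometimes listed for Ile, Tyr and Asn are
treated as pseudogenes and excluded.  Selenocysteine decoding of UGA is
out of scope.  The initiator tRNA is a separate species with the same
CAU anticodon as elongator Met, giving 46 species in both tables.

Amino-acid property tables (polar requirement from the classical
chromatographic scale; hydropathy from the Kyte–Doolittle index) ship
with the package.  The four-color classing of polar requirement uses the
quartile split of the 20 values by default, since no bin edges are
published for the figure coloring; Ser is flagged `mixed` because its
two codon families fall in different polarity classes.

## Quotient graphs

Codon-level graphs put an edge at Manhattan distance one.  The quotient
by synonymy has the occurring labels as vertices and joins two distinct
labels iff some triplet of one is adjacent to some triplet of the other.
For the SGC the quotient is over all 64 codons (Stop included, 21
vertices); for a tRNA code it is over the 45 *used anticodon* triplets,
each labeled by the amino acid it serves (Stop absent, initiator merged
with Met, 20 vertices).  Building over anticodons is what makes the two
tRNA codes' graphs differ — a quotient over decoded codons would be
identical for both.  An ordering and its reverse produce the same edge
set, so the 24 orderings give at most (and in fact exactly) 12 distinct
graphs per code; canonical representatives are the lexicographically
smaller member of each pair.

The claim that a tRNA quotient graph is an edge-subgraph of the SGC
quotient graph on shared vertices is *measured*, not assumed: an
anticodon adjacency has no reason to correspond to a codon adjacency,
and `subgraph_violations` reports the offending edges (168 summed over
the 12 orderings and both tRNA codes).  The `report` command logs a
warning rather than failing.

## Centralities and ANOVA

Degree is the raw incident-edge count.  Closeness is
(n_c − 1)/Σd within the vertex's connected component (networkx with
`wf_improved=False`), finite on disconnected graphs.  Betweenness is the
unnormalized endpoint-excluding pass-through count with unordered pairs
counted once.  Eigenvector centrality is computed by power iteration on
the adjacency matrix (uniform start, tolerance 1e-12), taken nonnegative
and normalized to unit maximum; tests verify A·v = λ·v at 1e-10 against
a dense eigendecomposition.  Means are per-vertex arithmetic means over
the 12 graphs of a code.

The one-way ANOVA is the classic SSB/SSW decomposition with the upper
F-tail for p (degenerate all-equal input returns F = 0, p = 1); it is
cross-checked against `scipy.stats.f_oneway` on random matrices.  The
cross-code comparison uses three groups (SGC, S-tRNA-C, H-tRNA-C) of
per-amino-acid mean centralities.  The subset of amino acids entering
the comparison is configurable; the default is all 20 (every vertex
common to the three codes' graphs), under which degree (p ≈ 0.016) and
closeness (p ≈ 3e-6) separate the codes at the 0.05 level while
betweenness (p ≈ 0.35) and eigenvector (p ≈ 0.45) do not.

## Prism census

The triangular prism is detected over all 6-vertex subsets.  In the
default *induced* mode the induced subgraph must be exactly a prism
(nine edges, 3-regular, containing a triangle — which excludes K₃,₃, the
only other cubic graph on six vertices); a non-induced mode accepts any
spanning prism.  Records are deduplicated by vertex set and carry their
two cap triangles.  Under the default construction the standard-tRNA
census finds prisms in 11 of the 12 orderings (all but CUAG), with the
three recurrent compositions {Asn,Gln,His,Lys,Pro,Thr} (6 orderings),
{Asp,Gln,Glu,His,Leu,Val} (4) and {Cys,Gly,Leu,Phe,Trp,Val} (2), plus
rarer families; the human-tRNA graphs contain no full prism in any
ordering, only cap pairs one matching edge short.  Published counts for
this family of models differ (10 of 12, and two human orderings with a
prism); those figures trace to manual reading of drawn graphs, and the
exhaustive search here finds additional prisms (each edge of which has
been audited against the underlying anticodon adjacencies) while finding
no completion of the human near-prisms.  The acceptance suite asserts
the published values and is allowed to stay red on this layer rather
than weakening the search.

Coloring assigns each vertex its property bin class (ordering
independent); cut vertices are articulation points by depth-first
search.

## Randomized codes

`random_code(seed, scheme)` provides null models: `shuffle-labels`
permutes the 20 amino-acid labels over the standard synonymous blocks
(Stop fixed), preserving the block-size multiset and hence the quotient
vertex count; `shuffle-codons` deals the 64 codons randomly into blocks
of the standard sizes.  Both are reproducible for a fixed seed.

## Problem sizes and determinism

Everything is desk-scale: 64 triplets, groups of order ≤ 48, graphs of
≤ 21 vertices, 12 orderings per code.  The full test suite (including
the exhaustive 6-subset × 720-bijection prism oracle and brute-force
betweenness enumeration on graphs up to 15 vertices) runs in a few
minutes on one CPU; the acceptance script in under a minute.  All
reported quantities are deterministic; randomness appears only in the
null-model generator and is seed-controlled.

## Known limitations

* The small-group classifier covers orders 1–8 (plus elementary abelian
  and cyclic cases generally); larger groups are reported as
  `unclassified(order=n)`.
* The prism-census discrepancies above; likewise the published
  "disconnected by Glu" observation for the human AGUC graph is not
  reproduced (that graph is connected here, articulation points
  {Arg, His, Leu, Tyr}).
* Codon-level polarity values are not modeled; Ser's two polarity
  classes are encoded only as the `mixed` flag.
* RNA alphabet only; single triplets, not sequences.
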