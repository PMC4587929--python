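# Methods

## Scope and model

`barcode-audit` evaluates a CO1 barcode reference library: a set of
aligned sequences, each tied to a specimen with a prior (morphological)
species identification. All analyses treat the species labels as given
and ask how well the sequences separate and recover them; nothing here
delimits species.

### K2P distances and pairwise deletion

Distances use the Kimura 2-parameter model,
`d = -1/2 ln[(1-2P-Q) sqrt(1-2Q)]`, with transitions (A↔G, C↔T)
and transversions counted over the sites where both sequences carry an
unambiguous A/C/G/T. IUPAC ambiguity codes are treated as missing, not
partially matched: fractional substitution counts would have no
counterpart in the percent-precision reporting downstream, and
"pairwise deletion" is the convention the field's distance tools apply.
Two failure modes are surfaced rather than hidden:

* fewer than `min_overlap` comparable sites (default 100 — conservative
  for ≥500 bp barcodes, configurable) → distance undefined;
* non-positive logarithm argument at extreme divergence → undefined,
  never clamped to a large value, because a clamped pair would corrupt
  maximum-distance summaries silently.

Undefined pairs propagate explicitly: summaries skip and count them,
single-linkage clustering treats them as "not below threshold", and NJ
refuses an incomplete matrix.

Distances are stored as proportions and formatted as percentages with
two decimals (round-half-even) in reports.

### Gap screening

Per species: specimen count, mean and maximum intraspecific pairwise
distance, and the minimum distance to any other species (nearest
neighbour). A species is flagged when its maximum intraspecific
distance is **strictly greater** than the screening threshold (default
2.2%); species pairs with minimum interspecific distance strictly below
the same threshold are reported separately as potential haplotype
sharing. The strict inequality matters only for specimens exactly at
the threshold and is pinned by a test.

### Threshold OTUs and concordance

OTUs at threshold t are connected components of the graph joining
specimens with d < t (single-linkage closure). This is an explicit,
reproducible proxy for index-number style barcode clusters, whose exact
algorithm is not published in implementable detail; single linkage
reproduces the phenomenology the audit needs — a species spanning
several OTUs, an OTU containing several species — with a transparent
rule. OTU labels are the lexicographically smallest member specimen ID,
so partitions compare across runs. Note single linkage *chains*: a
species can have a maximum intraspecific distance above the threshold
yet remain one OTU if intermediate haplotypes bridge the gap. This is a
real feature of threshold clustering, and the synthetic generator
exploits it to produce flagged-but-single-OTU species.

### Neighbor joining and bootstrap

Saitou–Nei NJ on the Q-criterion, with two documented conventions the
literature leaves open: ties in Q resolve to the lowest-index pair
(deterministic under specimen order), and negative branch lengths are
clamped to zero by default with a counter (`allow_negative` disables
it). The unrooted tree gets a trifurcating root. On an additive matrix
the implementation inverts the tree exactly (tested to 1e-9 against
tip-to-tip path sums on random trees, and against an independent NJ
implementation for topology).

Bootstrap resamples alignment columns with replacement, recomputes K2P
and NJ per replicate, and attaches to each internal edge of the
full-data tree the percentage of replicates containing its bipartition.
Replicates with undefined distances are dropped and counted. Both the
full-data tree and the resampling stream run over specimens sorted by
ID, so supports are independent of input order; a single master seed
spawns per-replicate streams. Species monophyly is assessed on edge
bipartitions of the unrooted tree; singletons are trivially
monophyletic.

### Identification simulation

Leave-one-out over every retained query, on the precomputed matrix (no
realignment per query — queries and references come from one
alignment). "Below threshold" is strict (<) and configurable in
effect through the tie tolerance `tie_tol` (default 0: exact equality
on stored doubles defines a tie).

* **BM**: nearest neighbour, no cut-off; ties resolve to *correct* if
  any tied match is conspecific, because the criterion has no ambiguous
  category and a coin-flip would be irreproducible. The tied species
  set is recorded so the liberal rule is auditable.
* **BCM**: nearest neighbour below t; no match below t → no ID; a
  nearest-distance tie spanning species → ambiguous.
* **ASB**: all matches below t must agree; a mixture → ambiguous; a
  single wrong species → incorrect (an empty column in practice for a
  healthy library).

Excluding singletons removes them from the query set only; they stay in
the reference, where they can still attract wrong matches. Tallies
always sum to the query count (asserted in the type).

### Threshold selection

*Cumulative error*: over a grid (default 0.1–10% in 0.1% steps,
bracketing every threshold in common use), count per threshold the
queries with no conspecific match within it (false positives — non-
increasing in t) and the queries with ≥2 species within it (false
negatives — non-decreasing). The optimum minimizes the sum; ties go to
the smallest threshold (conservative identification).

*Density minimum*: Gaussian KDE over all defined pairwise distances
(Silverman bandwidth by default, overridable and logged), evaluated on
512 grid points spanning the data. The selected transition is the
*first interior local minimum* — with an intraspecific bump near zero
and the interspecific bulk further out, that is the gap. A unimodal
density returns an explicit "no transition found". Because the
function sees only the matrix, no species-label information enters the
choice.

### Haplotype networks

Sequences collapse to haplotypes by exact identity over {A,C,G,T,-}:
the gap is a fifth character state, so indel variants are distinct
haplotypes. Sequences containing N join a haplotype only when exactly
one is compatible at all unambiguous sites, otherwise they are held out
and reported. Naming is h1, h2, … by descending frequency (ties by
smallest member ID).

The network adds connections level by level in ascending mutational
step count (five-state Hamming distance), connecting components whose
membership is frozen at the start of each level — so equally
parsimonious alternative connections all survive, giving a network with
reticulations rather than a tree. Connections longer than `max_steps`
(default 25) are never drawn; multi-step connections decompose into
single-step edges through inferred intermediates (differing positions
mutated in ascending positional order — one deterministic choice among
the equivalent paths). The classical 95% parsimony-connection
probability rule is *not* implemented; the fixed step cap is the
primary control, which is how the analysis is typically run on
closely related species groups.

## The synthetic generator

The generator emulates the statistical shape of a large regional
crustacean barcode survey; its defaults are the package's study
conditions:

| parameter | default | rationale |
|---|---|---|
| species / barcodes | 205 / 1332 | survey scale; exercises every stage at realistic n |
| singleton species | 26 | the singleton arithmetic in BM (forced errors) |
| max specimens per species | 32 | right-skewed abundance, one heavily sampled species |
| sequence length | 600 bp | inside the usual 514–667 bp barcode range |
| base composition | A .26 C .19 G .19 T .36 | AT-rich arthropod mitochondrial profile |
| ts:tv ratio | 2 | typical mitochondrial bias |
| intraspecific scatter | ≤1% | star-like low variation around a founder |
| interspecific floor | ≥5% | sister-species separation; realized inter distances run ~5–54% |
| deep splits | 13 species, 2.36–14.87% | six chained (one OTU), six two-OTU, one three-OTU |
| sharing pair | 9+7 specimens, 7 haplotypes, 2 shared | recent-divergence signature |

Construction is mutation-based, not coalescent: a root sequence with
*exact* target base counts (largest-remainder apportionment, shuffled);
founders placed by 30–120 substitutions from the root, redrawn until
every founder clears the interspecific floor in realized K2P (checked
with ~0.7 pp headroom for specimen scatter); specimens scattered 0–3
substitutions around their founder. Deep splits grow a sub-founder one
substitution at a time until the realized K2P depth first crosses the
target (overshoot < ~0.2 pp at 600 bp); chained splits interpose
way-points every ~1.5% so single linkage at 2.2% keeps one OTU while
the total depth exceeds the screening threshold; deep-split cluster
members are exact copies of their sub-founder so the engineered depth
is the realized maximum. The sharing pair is built from seven explicit
haplotypes on disjoint mutated positions, with one specimen of species
B alone on a haplotype otherwise carried by species A — forcing exactly
one non-singleton best-match error and one BCM "incorrect", the
pattern a genuine haplotype-sharing pair produces.

Mutations preserve the target composition: transversion targets are
drawn proportionally to it and proposals are accepted with a
Metropolis–Hastings rule whose stationary distribution is the target,
so even founders 20% diverged from the root stay on-composition.

What the generator does **not** emulate: coalescent genealogy within
species (structure is star-like plus engineered splits), site-rate
heterogeneity, codon structure, indels (off by default; the alignment
is exact by construction), sequencing error and ragged fragment
lengths. Passing the parameter-recovery suite therefore shows the
*analysis stack* recovers engineered truth under realistic distance
structure; it does not validate alignment quality or model fit on real
data, where homology error adds tolerance to any reproduced distance.

## Problem sizes

The test suite builds the 205-species library once per session; the
full suite runs in well under a minute. The acceptance script runs the
complete stack on the 1332-barcode library (the all-pairs matrix has
886k pairs) and computes bootstrap support with 200 replicates on a
~80-specimen subset containing the sharing pair, the deepest split and
six ordinary species — enough to show the 99–100% species-cluster
supports the full analysis produces, at a fraction of the cost of
bootstrapping 1332 taxa (full-library NJ itself takes a few seconds and
is part of the `audit` command).

## Known limitations

* The OTU proxy is single linkage at a fixed threshold; it will not
  reproduce refinement steps of graph-based cluster algorithms on
  pathological geometries.
* NJ tie-breaking and negative-branch clamping are *this package's*
  documented conventions, not claims about other software; topologies
  can differ at effectively zero-length edges.
* The density-minimum threshold depends on bandwidth; Silverman's rule
  on ~1e6 distances gives sub-0.5 pp bandwidths and a stable gap
  minimum, but small libraries may smooth the intraspecific mode away
  entirely (the explicit "no transition" result).
* Haplotype networks are step-count-equivalent to classical statistical
  parsimony but may draw different reticulations where ties admit
  alternatives; intermediate placement is one deterministic choice
  among equivalents.
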