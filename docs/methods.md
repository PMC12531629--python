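# Methods

This note documents the models and procedures implemented in `hthcons`, the
defaults and why they were chosen, what the synthetic benchmarks do and do
not demonstrate, and the numerical conventions.

## Conservation scoring

A *reference residue set* is an ordered list of (1-based position, residue)
pairs on an ungapped reference protein. Positions are mapped to alignment
columns by counting the reference row's non-gap symbols; a mapped column
whose reference residue differs from the expectation is reported as a
warning rather than an error, since curated alignments of distant homologs
occasionally disagree with literature numbering by a residue.

Two scoring schemes are implemented over the mapped columns:

* **Log-odds PSSM.** Per column, counts over the N reference rows are
  smoothed with background-proportional pseudocounts:
  `p_a = (c_a + β·q_a)/(N + β)`, entry `log2(p_a/q_a)`. Defaults: uniform
  background `q = 1/20`, `β = 1`. With a single reference row (the common
  case, mirroring the use of one well-characterised protein as the
  reference), a matching residue scores `log2(10.5) ≈ 3.39` and any other
  residue scores −1. The reference sequence attains the maximal achievable
  score by construction (tested).
* **BLOSUM62.** Row *i* of the realised *n* × 21 matrix is the BLOSUM62 row
  of reference residue *i* extended by a gap state. Both schemes score gaps
  and the ambiguity code `X` with the same fixed gap penalty, −0.12 by
  default. The gap penalty is stated in the source methodology for the
  BLOSUM variant only; applying it to the PSSM as well gives missing data a
  uniform treatment and is configurable. Its magnitude is tiny relative to
  the integer BLOSUM range; it is implemented exactly as stated rather than
  rescaled.

Raw scores are sums over the set; `per_residue = raw/n` is emitted alongside
because cross-category comparability depends on set size. Binning into four
categories (extremely_low/low/medium/high) defaults to population quartiles
— the only parameter-free reading when no fixed thresholds are given — with
a fixed-breakpoint override; scores equal to a boundary fall into the lower
bin. A helper merges the two lowest bins for three-way summaries.

Genome-level summaries: `best_per_genome` keeps the maximum raw score per
(genome, category) with ties to the smallest protein id;
`paired_interface_table` joins per-protein DNA-binding-domain scores with
per-genome interface scores and fits an ordinary least-squares line plus
Pearson correlation per class, reporting slope 0 with an undefined (NaN)
correlation for degenerate classes.

## Substitution models, likelihood, and ancestral reconstruction

Models are reversible 20-state rate matrices `q_ij = R_ij π_j` (symmetric
exchangeability R), normalised to one expected substitution per site per
unit branch length. The default is the Poisson-type model (equal
exchangeabilities, uniform frequencies); a PAML/WAG-style rate file can be
loaded. Transition matrices use the symmetric similarity transform
`D^{1/2} Q D^{-1/2}` and an eigendecomposition — reversibility guarantees a
real spectrum — with a direct `scipy` matrix exponential as fallback when
extreme stationary frequencies overflow the transform. Rows are clipped at
zero and renormalised; `t = 0` returns the exact identity.

Column likelihoods follow Felsenstein's pruning recursion with per-column
rescaling against underflow; gaps and `X` are missing data (conditional
likelihood 1 for all states). An impossible configuration reports `-inf`.
Marginal posteriors at internal nodes come from the standard two-pass
algorithm (downward conditionals × upward partials, normalised per column);
posteriors are invariant to the per-column rescaling. Columns in which every
tip below a node is gapped carry a gap flag and read out as `-` in the MAP
sequence — domain-edge erosion should not be imputed into ancestors.

MAP residues break ties alphabetically; posteriors within `1e-6` of the
column maximum count as tied. The tolerance makes MAP calls stable under
round trips through the 8-decimal state-table format (knife-edge ties are
common on symmetric topologies).

Likelihood is invariant under rerooting for these reversible models
(tested to 1e-9), so trees rooted by outgroup or midpoint give identical
reconstructions up to node naming.

## Trees

Neighbor joining is the canonical Saitou–Nei algorithm: Q-matrix
minimisation, standard branch-length formulas, ties broken by the
lexicographically smallest id pair (cluster id = smallest member tip id),
negative branch lengths clamped to zero with the deficit moved to the
sister branch so the joined pair's path length is conserved. On additive
inputs NJ reproduces the generating tree exactly (consistency; tested at
RF 0 and 1e-9 on path lengths). Distances are p-distance or the 20-state
Poisson correction `-(19/20)·ln(1 − 20p/19)` with +∞ at saturation
(p ≥ 0.95), computed over columns where both rows hold residues.

Rooting: outgroup rooting splits the outgroup's pendant edge at its
midpoint; midpoint rooting bisects the longest tip-to-tip path. Both
conserve total branch length.

## Alignment and curation

Pairwise alignment is global Needleman–Wunsch with affine gaps (Gotoh; the
first gap symbol of a run costs `gap_open`, each further one `gap_extend`).
Defaults: open −11, extend −0.123 — the extension value follows the
alignment-parameter study that identified it as a good penalty for domain
alignments; the open penalty follows common practice. Multiple alignment is
progressive profile–profile merging ("once a gap, always a gap") along a
guide tree, by default UPGMA (scipy average linkage) over k-mer (k = 3)
Sørensen distances, so the most similar sequences merge first. Profile
column scores are frequency-weighted BLOSUM62 expectations; for two single
sequences this reduces exactly to the pairwise DP, which is verified against
an independent implementation. A hook for an external aligner command is
provided for fidelity runs on real data.

Curation quantifies two informal notions. "Extremely long" = ungapped
length > 1.5 × the median (robust to outliers; configurable). "Contributing
to gappy regions" is a two-part rule: a row is removed if (a) its own gap
fraction exceeds 0.5, or (b) at least half of its residues sit in columns
that are ≥ 80% gaps. The loop applies the length filter once, then
alternates alignment and pruning until nothing is removed or `max_iter`
(default 5) is reached; all removals are reported per iteration, and the
loop is idempotent at its fixed point (tested).

## Classification

"Bitscore" clustering is approximated by raw global-alignment scores
normalised by self-scores: an edge joins two sequences when their score is
at least `rel_threshold` × the smaller self-score, and classes are
single-linkage connected components. This is deliberately the simplest
faithful stand-in for a clustering whose full specification lives outside
the main methodological text, and is isolated behind the module interface.
Raising the threshold only refines the partition (tested). Labels: a cluster
containing a designated seed sequence takes the seed's class; a seedless
cluster with orthology annotations takes the majority annotation's
`<stem>-like` class (ties to the alphabetically first stem); otherwise
`unassigned`. The label set is configurable; the four named classes are
defaults rather than a fixed ten-class taxonomy.

## The synthetic benchmark generator

The generator produces the structure the analysis assumes: a Yule tree
(waiting time Exp(k·birth_rate) with k lineages, plus a final Exp(n·rate)
interval, so expected root-to-tip depth is `Σ_{k=2..n} 1/(k·rate)`),
sequences evolved by exact per-branch transition probabilities, and
*site constraints* — at a constrained site, within its active clade, the
chain runs under the model whose stationary frequencies boost the target
residue by `exp(λ)`. The boosted model keeps the parent model's rate
normalisation: a constraint reshapes stationary preferences without
rescaling the clock (normalising the boosted matrix to 1 sub/site would make
off-target rates diverge as λ grows). Gaps arrive per site per branch with
probability `gap_rate` and are irreversible along a lineage, emulating
domain-edge erosion. Everything is deterministic given the seed, and the
truth (tree, all node sequences, clade labels) is returned.

Benchmark presets plant residue sets whose sizes mirror the packaged
reference sets: `ar1_gain` activates a 10-site patch at the stem of a clade
holding ~25% of tips *and* keeps 3 base-contact sites constrained from the
root (so the family-wide signal and the clade-restricted one coexist, which
is what the headline contrast tests); `base_contacts_global` constrains 3
sites from the root; `backbone_patchy` constrains 7 sites from the root at
half strength and switches them off in two disjoint subclades. Default
conditions: 64 taxa, λ = 4, 100 sites, branch scale 0.1. The branch scale
was chosen once so that the simulated family resembles a curated
within-family domain alignment (~60% mean pairwise identity): at saturating
divergence the family has no alignable core — the generator plants no
family-wide structural constraint — and re-alignment of such data is
impossible for any aligner.

For scoring, `functional_reference` builds the stand-in for a
well-characterised reference protein: the true root sequence with the
target residue substituted at every constrained site. It is synthetic and
labelled as such; with no insertions in the simulation, its positions
coincide with alignment columns.

What passing these benchmarks shows: the pipeline recovers planted
clade-restricted conservation as a score contrast on true clades (tips and
reconstructed ancestors), at the simulated divergence, under a correctly
specified substitution model. What it does not show: robustness to model
misspecification, to rate heterogeneity across sites or lineages, to
insertions (the simulator emits deletions only), to alignment error at
saturating divergence, or to real structural conservation patterns.

## Determinism and numerics

All stages are deterministic: fixed RNG streams per seed, lexicographic
tie-breaks (NJ pairs, MAP residues, best-per-genome), stable orderings in
every writer, and floats printed with fixed formats. CLI reruns are
byte-identical (tested). Notable tolerances: pruning vs enumeration 1e-10;
NJ on additive input 1e-9; state-table posteriors 1e-6; MAP tie tolerance
1e-6; probability rows in state tables renormalised with a warning when
their sum falls outside [0.99, 1.01].

## Known limitations

* Codon-level evolution is out of scope; reconstruction operates on amino
  acids directly.
* No rate heterogeneity (site classes) in either the simulator or the
  likelihood machinery.
* The progressive aligner targets desk-scale family sizes (hundreds of
  sequences), not proteome-scale datasets; use the external-aligner hook
  for large or highly diverged real data.
* The similarity clustering is a stand-in, not a reimplementation of any
  specific published classification; class labels beyond the seeded ones
  depend on the annotation tags supplied.
* A simulated family where every row becomes all-gap at a site retains one
  sentinel residue in the alignment row to keep the container invariant;
  at the default gap rates this path is effectively never taken.
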