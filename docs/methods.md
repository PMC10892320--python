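# Methods

This note documents the models, numerical choices and deliberate limitations
behind `gamoscan`. Nothing here asserts an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Variant genetic code

The default codon table is the standard nuclear code with UGA reassigned to
tryptophan, as in *Blepharisma*; UAA and UAG terminate. Observed stops in
sequenced gamone 1 homologs are UAA only, and the status of UAG is not
attested, so UAG is kept as a stop by default and the whole table is
user-overridable from a two-column TSV. Codons containing IUPAC ambiguity
characters translate to `X` with a logged warning rather than failing, so
partially ambiguous records survive the pipeline. ORF search is forward-frame
only by default (deposited coding sequences are forward); a `six_frame` flag
adds the reverse complement. Internally all coordinates are 0-based
half-open; every user-facing report is 1-based inclusive.

## Percent identity

The published homology table states only that identity was "calculated using
ClustalW", which leaves the denominator unspecified. Both plausible
conventions are implemented and every report header names the one in use:

* `aligned_columns` (default) — identities over columns where both sequences
  have residues;
* `shorter_seq` — identities over the length of the shorter ungapped
  sequence.

Pairwise alignments are global Needleman–Wunsch with affine gaps
(BLOSUM62, gap open 10, extend 1) via Biopython's `PairwiseAligner`.
Progressive multiple alignment is *not* reimplemented: the reference
alignment was manually curated, which is irreproducible by definition, so the
pipeline ingests aligned FASTA/Clustal. Reported identities are rounded to
one decimal; internal values are not.

## Column masking

As an automated stand-in for manual curation of ambiguous regions, a mask
drops (a) columns containing any gap, and (b) columns whose Shannon entropy
(natural log, over residues present) exceeds a threshold (default 1.5),
together with `flank_extension` neighbours. Each dropped column is logged
with its rule. The reference analysis retained 197 of the aligned positions;
that figure depends on manual curation and is treated as non-reproducible —
the mask's column count is logged for qualitative comparison only.

## Property groups and cross-boundary sites

The six amino-acid property groups follow the volume/polarity clustering of
Miyata et al. (1979): {C}, {A G P S T}, {N D Q E}, {H K R}, {I L M V},
{F W Y}. The source analysis cites this scheme but never prints its
membership, so the table ships as an editable TSV and every report echoes the
table used. A species' group at a column is the group of its residues when at
least `majority_fraction` of them (default 1.0, strict unanimity; 0.5
available) fall in one group, else *ambiguous*. A column is flagged when two
or more species hold distinct non-ambiguous groups. Strict unanimity matches
the species-level single-residue statements the analysis is built on.

Region calling slides a centred window (default 10 columns) of flagged-site
density: runs of columns at density ≥ 0.3 become hypervariable ("mutable")
regions, runs at ≤ 0.05 conserved regions, runs shorter than 10 columns are
discarded, and coordinates are mapped to a chosen reference row (default: the
first record). The defaults were chosen so planted regions at the widths seen
in real pheromone data (≈12–53 columns) are recoverable; all four parameters
are exposed in the config because the original regions were delineated by
inspection. Note the source text itself gives one region as 132–151 in one
place and 132–150 in another; this package reports its own boundaries and
does not arbitrate.

## Sequons and hydropathy

Sequons are N-X-S/T with X ≠ P by default (the standard glycobiology rule,
toggleable since the original counts may reflect a plain N-X-S/T scan).
Hydropathy is a centred moving average of Kyte–Doolittle values, default
window 9; unknown residues are excluded from the window mean with a log
message.

## Phylogenetics

**Model.** WAG exchangeabilities and equilibrium frequencies (shipped as data
files, values as distributed with R phangorn 2.12.1 and spot-checked against
the published matrix). The rate matrix is scaled to one expected substitution
per site; transition matrices come from the symmetric eigendecomposition of
Π½QΠ^{-½}, computed once per model and reused for every branch length.
Model frequencies are used as is (+F empirical frequencies were not stated in
the reference analysis and are not implemented). Among-site rate variation is
Yang's discrete gamma with k = 4 equal-probability categories represented by
their bin means; the bin mean is computed in closed form from the regularised
incomplete gamma function and is exactly mean-one. (A caution documented by a
test: at alpha = 100 the outer bin means still deviate ~13 % from 1; the
all-rates-equal limit is approached like 1.27/√alpha.)

**Likelihood.** Felsenstein pruning over pattern-compressed columns, gamma
categories stacked on a leading axis; gaps and `X` are missing data
(all-ones partials). With ≤ ~16 taxa no scaling is needed in double
precision. Per-site log-likelihoods are exposed for the topology tests.

**Search.** Exhaustive enumeration of unrooted binary topologies by stepwise
addition, with user-fixed resolved subtrees collapsed to effective OTUs
(hard-capped at 9 effective leaves, i.e. 135 135 topologies). This replaces a
heuristic tree search exactly at the scale the package targets and mirrors
how the reference analysis kept its topology space to 15 trees.

**Branch lengths.** Coordinate-wise optimisation: for each edge the
conditionals on both sides are cached so the likelihood in that one length
costs a single transition-matrix application; the scalar problem is solved by
bounded Brent on [1e-8, 20]. Sweeps repeat until the total lnL improves by
less than `tol` (default 1e-6) or 50 sweeps, returning a convergence flag.
Initial length 0.1. The gamma shape is fitted by bounded scalar search
(default bounds 0.02–50) with branch lengths re-optimised per candidate, on
the provisional ML topology; all topologies are then refitted under the final
shape so their likelihoods are comparable.

**Bootstrap.** Nonparametric column resampling; each replicate re-runs the
full constrained topology search with warm-started branch lengths, a looser
tolerance (1e-2, ≤2 sweeps) and the shape fixed at its MLE — replicate
winners are effectively decided by large likelihood gaps, not the last
decimals of branch lengths. Support is the bipartition frequency on the
original ML tree's internal edges. The replicate stream is a single seeded
generator, so equal seeds give identical supports.

**Topology tests.** All tests run on the per-site lnL matrix via RELL
(resampling estimated log-likelihoods), realised as multinomial column
weights so memory stays bounded. KH: centred resampled ΔlnL against the ML
topology, one-sided. SH: simultaneous comparison with per-topology centring.
AU: multiscale bootstrap over scales 0.5–1.4 (step 0.1, 10 000 replicates per
scale by default), inverse-normal transform of the bootstrap proportions,
weighted least squares of z on (d√r + c/√r), p = 1 − Φ(d − c). Degenerate
cases (a topology with per-site lnL identical to the ML tree) return p = 1
for all three tests. This is a Shimodaira-2002-style implementation; no
bit-compatibility with CONSEL is claimed. The ML row has ΔlnL = 0 and
p_KH = p_SH = 1 by construction.

## Synthetic families

The generator produces what the analysis assumes: an ancestor drawn from the
model's equilibrium frequencies evolves along a species tree under WAG+Γ
(default alpha 1.28), with per-site rates multiplied by region factors
(conserved ×0.1, hypervariable ×5 by default). Strains within a species form
a caterpillar subtree with 0.01-substitutions/site edges — a star-like stand-
in adequate for the analyses tested, not a model of within-species history.
Property-switch columns override the substitution process: each species is
forced to a residue from a distinct group, keeping the planted truth
unambiguous. Common sequons are planted in the ancestor and their three motif
columns are protected from substitution; species-specific extras are forced
per strain; *accidental* sequons are scrubbed wherever that does not touch a
planted feature, so the recorded sequon truth is exact for every seed. Coding
DNA is back-generated with uniform synonymous-codon weights under the variant
code (so tryptophans are TGA half the time), terminated by UAA. Indels are
not simulated by default (the true alignment is gap-free); an `indel_blocks`
option writes gap blocks to exercise the column mask.

The `gamone1_preset` fixes the family shape to the published one — five
species with strain counts (4, 3, 2, 3, 3), 305-aa proteins, conserved
regions 31–51 / 197–218 / 234–286, hypervariable regions 132–151 / 287–298
with switch columns planted inside them (including positions 135, 142 and
287), four common sequons plus species-specific extras giving per-strain
counts of 4–6 — and calibrates species branch lengths once, by nonnegative
least squares on pairwise distances inverted from target identities
(within-species ≥ 95 %, cross-group means 67–76 %, the two Mk4-like species
~88–91 %). The inversion accounts for the region rate structure and the
forced-different switch columns. These are fixed properties of the stated
world, not tuning knobs.

What a green test on synthetic data does *not* establish: correctness of any
manual alignment curation, behaviour under real indel patterns or
sequencing artefacts, or recovery of the published alpha and masked-column
count (both depend on an irreproducible curated alignment and are logged for
qualitative comparison only). Validation against the deposited accessions is
provided separately (`scripts/validate_accessions.py`) for environments with
database access.

## Bioassay units

Exponent counting starts at the undiluted sample (2^0), so a sample positive
only undiluted titres at 2 U/mL and pairs observed up to dilution 2^N give
2^(N+1) U/mL. A series positive at the deepest dilution tested is flagged
right-censored. Non-monotone series (a negative well below a positive
dilution) are rejected under `strict=True` and resolved by the maximum
positive exponent otherwise; the source protocol does not discuss such cases.

## Known limitations

* No heuristic tree search (NNI/SPR): the package is deliberately exact and
  small-scale; beyond 9 effective OTUs the user must fix subtrees.
* The AU implementation follows the published construction but is not a
  CONSEL replacement; extremely one-sided bootstrap proportions fall back to
  the raw proportion at scale ≈ 1.
* Percent identity from pairwise alignments can differ from MSA-derived
  identity when indels are present; both are intentional, documented modes.
* The simulator's within-species model (short caterpillar) is not a
  population-genetic model; do not use it to test coalescent-scale questions.
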