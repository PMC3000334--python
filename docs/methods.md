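# Methods

This note documents the models implemented in `barcodiag`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that affect reproducibility.

## Distances and the barcode gap

Distances are Kimura 2-parameter: with P and Q the proportions of
transition (A↔G, C↔T) and transversion differences over the L_comp sites
comparable for a pair, d = −½ln(1−2P−Q) − ¼ln(1−2Q). *Pairwise deletion*
means each pair is compared only at columns where both sequences carry an
unambiguous base; IUPAC ambiguity codes are excluded outright rather than
partially matched (unbiased distances at the cost of a little information).
Two degenerate outcomes are flagged per pair and excluded from every
summary, but counted: *undefined* (no comparable sites) and *saturated*
(either logarithm's argument ≤ 0, i.e. divergence beyond what the
correction can invert).

Divergence summaries follow the two conventions that make a congeneric
library's numbers interpretable: the intraspecific distribution pools every
within-species pairwise distance over species with ≥ 2 members, while the
interspecific distribution holds one value per unordered species pair (the
mean over that pair's cross-species comparisons), so k species always give
C(k, 2) interspecific comparisons. Pooling (rather than per-species
averaging) of the intraspecific set is a choice; both conventions are
common, and the overlap-window and histogram functions consume the same
sets, so the choice is applied consistently. The overlap window defaults to
the closed interval [2 %, 4 %] and is configurable, including open
boundaries. Standard deviations use ddof = 1.

## Neighbour joining and differentiation

NJ is the standard Saitou–Nei agglomeration on the K2P matrix. Three
conventions fix the output completely:

* **Tie-break.** The Q-criterion minimiser is the lowest (row, column)
  index pair in the current working order; freshly joined clusters are
  appended at the end of that order.
* **Negative branches.** A negative branch length at a join is clamped to
  zero and the deficit moved to the sibling edge, preserving the pair's
  path length (the convention of mainstream distance-tree software); raw
  values are retained on the nodes as `raw_length`.
* **Termination.** The final three clusters are joined by the three-taxon
  closed form, so the tree is unrooted with a trifurcating root node.

Bootstrap supports resample alignment columns with replacement, recompute
the distance matrix (pairwise deletion re-applied) and the NJ tree per
replicate, and score each internal bipartition of the reference tree by the
percentage of replicates containing it. Replicates that produce undefined
or saturated pairs are redrawn, with a budget of 10× the replicate count.
100 replicates is the default.

Monophyly needs a root: the outgroup's tip edge when an outgroup is named,
midpoint rooting otherwise. The differentiation criterion is two-part — a
multi-member species must be monophyletic on the rooted tree and share no
haplotype with another species; a singleton species is judged on the
haplotype criterion alone. NJ rather than maximum likelihood is a
deliberate scope decision: for COI barcode libraries with deep interspecific
and shallow intraspecific divergence the two give near-identical topologies,
and NJ keeps the bootstrap loop fast and fully deterministic.

## Haplotypes

Two records share a haplotype when they agree at every column where both
have unambiguous bases *and* that shared coverage is at least `min_overlap`
columns (default 300), extended by transitive closure; records with fewer
than `min_overlap` unambiguous bases are excluded from collapsing and
reported. With truncated sequences present, haplotype totals therefore
depend on `min_overlap`: a full-length sequence and a consistent truncated
one count as one haplotype, which is the permissive reading. Ambiguity
codes never *match* anything but also never *mismatch* — they are simply
non-comparable columns.

## Segregating-sites assignment

The assignment test treats each candidate taxon's sequences as a coalescent
sample under the infinite-sites model. The sampling distribution of the
number of segregating sites S in a sample of size n at scaled mutation rate
θ is the classical alternating sum

P(Sₙ = k) = Σᵢ₌₂ⁿ (−1)ⁱ C(n−1, i−1) · (i−1)/(θ+i−1) · (θ/(θ+i−1))ᵏ,

equivalently the distribution of a sum of independent geometric counts, one
per coalescent level. Terms are evaluated in log-magnitude form and summed
with compensated (fsum) accumulation, and the result clamped to [0, 1]; the
alternating series is verified in the test suite against an exact
geometric-convolution oracle (agreement ≤ 1e−10 on the tested grid) and
against Monte-Carlo coalescent simulation. Cancellation grows with n; for
sample sizes in the hundreds the closed form approaches double-precision
limits, a known property of this series rather than of this implementation.

Per query: columns where the query itself is gapped or ambiguous are
dropped from all counts (query-wise pairwise deletion), candidate taxa are
scored by L_j = P(S = S′_j | n_j + 1, θ̂_j) with θ̂_j the taxon's own
Watterson estimate on those columns, and posteriors follow from a uniform
(configurable) prior. Choices worth stating:

* **Risk = 1 − posterior** (0–1 loss). The loss function is a pluggable
  hook (`loss=` argument); the transparent default is reported throughout.
* **Singleton candidates** (n = 1) have no θ̂; they are scored as a
  two-sequence pseudo-sample with θ borrowed as the median θ̂ of the
  multi-member candidates, and flagged.
* **Monomorphic candidates** have θ̂ = 0, a point mass at S′ = 0: a query
  adding any new segregating site receives zero likelihood from them. If
  every candidate scores zero the result is "unassignable", not an error.
* **Ties** are broken lexicographically by taxon label and reported.

Diagnostic sites are *simple* diagnostics: columns where the taxon is fixed
for one unambiguous state that never occurs unambiguously in the rest of
the library. Compound (combination) diagnostics are not counted, so the
count is conservative; distinct haplotypes can legitimately show zero
diagnostic sites.

Leave-one-out validation withholds one seeded-random member of every taxon
with ≥ 3 sequences and assigns it against the remainder, emitting the
standard assignment-table columns (taxon, query, n, diagnostic sites,
posterior, risk).

## NB restriction typing

NlaIII (CATG, cut after position 4) and BamHI (G^GATCC, cut after
position 1) are digested in silico; fragment lengths always sum to the
amplicon length. The diagnostic-site coordinates are configuration
(`NBWindows`, TOML-serialisable, 1-based inclusive on the 658-bp barcode
frame). The shipped defaults — monomorphic NlaIII at 112–115, diagnostic
NlaIII at 629–632, diagnostic BamHI at 639–644, legacy-amplicon overlap
starting at barcode position 299 — reproduce the classic fragment
arithmetic: the 378-bp legacy amplicon digests to ~350 bp (NlaIII, N+) or
~360 bp (BamHI, B+) versus uncut, and an NlaIII digest of the barcode
amplicon gives three bands (N+) or two (N−) thanks to the extra monomorphic
site. The 18 bp of the legacy amplicon upstream of the barcode frame are
not recoverable from barcode data, so legacy digests are simulated on a
synthetic amplicon (a fixed motif-free 18-bp pad plus the barcode's 3′
360 bp); this shifts no diagnostic fragment by more than the pad itself.
Typing is by window state, not by genome-wide motif search: a window
covered by gaps or N is *undeterminable*, deliberately distinct from
site-absent. Chance CATG motifs elsewhere in a real barcode add further
digest bands; `simulate_nb_amplicon` builds motif-scrubbed amplicons when
the isolated band arithmetic is wanted.

## Synthetic data

The generator emulates a multi-species barcode reference library under the
K80 substitution process — chosen to match the K2P estimator's assumptions,
since the package's distance analyses are K2P. On a star phylogeny
(default): each species ancestor receives Poisson(inter·L/2) substitution
events from a uniform-random root, each individual Poisson(intra·L/2)
events from its species ancestor, so a pair of lineages sits approximately
`inter` (resp. `intra`) apart. Substitutions pick a uniform site, with
transition probability κ/(κ+2) (κ = 2 by default); multiple hits are
allowed, so realised K2P distances shrink slightly below event counts at
high divergence — the truth table records realised event counts. Defaults
(36 species × 5 members, 658 bp, intra 0.66 %, inter 14.02 %) mirror a
well-separated congeneric library at desk scale. Optional structure:
subspecies ancestors interposed at a configurable divergence, per-species
NB-window planting, 3′-preserving truncation of a configurable fraction of
records (off by default; the audited analyses operate on length-filtered
libraries), an injected shared haplotype, a `topology="yule"` mode that
evolves species ancestors along a random-join binary tree rescaled to the
same mean pairwise divergence (spreading species-pair distances the way a
real phylogeny does, including close sister pairs), and an engineered
paraphyly (a
~2.9 % internal split in the penultimate species with the last species'
singleton nested on the far side), which produces exactly one
differentiation failure, 35/36.

What the generator does **not** emulate: codon structure and selection on
COI, rate variation among sites, indels and pseudogenes (numts), realistic
phylogenetic topology between species (star by default), geographic
population structure, and sequencing error beyond truncation. Passing tests
therefore demonstrate the correctness of the algorithms under the model's
assumptions and realistic divergence scales — not robustness to every
artefact of field data.

Held-out query sampling never depletes a species below one remaining
reference member, since a query whose species has no references left is
unanswerable by construction.

## Numerical and scale choices

Distance matrices are computed by one-hot matrix products (exact integer
site counts), making a 100-replicate bootstrap on a ~180-sequence library a
few seconds' work. Acceptance-style checks run at desk scale: a 36 × 5
library for divergence/assignment statistics, 100 held-out queries, 10⁶
Monte-Carlo replicates for the segregating-sites grid, and 100 random
additive trees (5–12 taxa) for NJ exactness, recovered to 1e−9. The
Monte-Carlo comparison of P(Sₙ = k) is screened per grid point at 4σ — the
family-wise-calibrated bound for 189 simultaneous comparisons — alongside
the exact convolution oracle at 1e−10, which is the stronger check.

## Known limitations

* Haplotype totals under partial missing data depend on `min_overlap`; no
  single convention recovers a historical count exactly.
* The alternating-series P(Sₙ = k) loses precision for n in the hundreds.
* Risk values are not comparable to tools using a different loss function.
* NB window coordinates are configuration, not a claim about the historical
  assay's exact cut positions; real-assay fragment sizes may differ by a
  few bp.
* The simulator's default star phylogeny makes between-species distances
  nearly exchangeable; the `yule` topology mode restores realistic spread
  but neither reproduces the correlated divergences of any particular
  genus.
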