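# barcodiag

DNA-barcode diagnostics for invasive-moth surveillance.

Regulatory entomologists intercepting tussock moths (gypsy moth, nun moth
and their relatives) need to answer three questions from a single COI
barcode sequence: *which species is this specimen*, *which subspecies or
geographic lineage does it belong to* (a proxy for traits such as female
flight ability), and *what would the legacy restriction-digest assay have
said about it*. `barcodiag` is a toolkit for building and auditing the COI
reference library those answers depend on, and for making the assignments
themselves.

## What it computes

**Barcode gap.** Pairwise Kimura 2-parameter distances with pairwise
deletion,

&nbsp;&nbsp;&nbsp;&nbsp;*d* = −½ ln(1 − 2*P* − *Q*) − ¼ ln(1 − 2*Q*),

where *P* and *Q* are the transition and transversion proportions over the
sites comparable for each pair. Intraspecific distances are pooled across
species; interspecific comparisons are per-species-pair means (a library of
*k* species yields C(*k*, 2) of them). Summaries, an overlap-window count
and a divergence histogram quantify the gap.

**Species differentiation.** A neighbour-joining tree (Saitou–Nei, with a
fixed tie-break and MEGA-style negative-branch clamping) with nonparametric
bootstrap supports from alignment-column resampling. A species counts as
successfully differentiated when its barcodes form a monophyletic cluster
and share no haplotype with another species; a singleton species needs only
the haplotype criterion.

**Bayesian assignment.** Each candidate taxon's sample of *n* sequences
with *S* segregating sites gives Watterson's θ̂ = *S*/*a*ₙ,
*a*ₙ = Σᵢ₌₁ⁿ⁻¹ 1/*i*. A query is scored per taxon by the infinite-sites
probability of the segregating-site count after it joins the sample,
P(*S*ₙ₊₁ = *S*′ | θ̂); posteriors follow from a uniform prior and the
reported risk is 1 − posterior. Leave-one-out validation and per-taxon
diagnostic-site counts reproduce the shape of a standard assignment table.

**NB restriction typing.** In-silico NlaIII/BamHI digestion reproduces the
four-haplotype key of the legacy two-enzyme assay (N±B±, fragment sizes
~350/~360 bp vs uncut), the two-vs-three NlaIII band counts on the barcode
amplicon, and a comparison report that flags NB classes shared between
species — the misdiagnosis hazard barcodes remove.

**Synthetic libraries.** A K80 simulator generates reference libraries with
configurable within/between-species divergence, subspecies structure,
singletons, truncated sequences, planted restriction sites, an engineered
paraphyly scenario, and a ground-truth table — so every stage is testable
end to end.

## Worked example

```sh
python examples/barcode_gap.py
```

```
library: 180 records, 36 species
intraspecific:  mean 0.66%  SD 0.34%  range 0.00-2.00%  (n=360 pairwise)
interspecific:  mean 13.90%  SD 1.43%  range 10.24-17.70%  (n=630 species pairs)
between/within ratio: 21-fold
overlap window [2%, 4%]: 1/360 intra, 0/630 inter
histogram modes: intra in [0%,1%), inter in [14%,15%)
```

Within-species variation (0.66 % on average) sits far below between-species
divergence (13.9 % across the 630 species pairs): the 21-fold separation is
the barcode gap, and the near-empty 2–4 % overlap window means almost no
comparison is ambiguous. `examples/tree_differentiation.py`,
`examples/assignment_demo.py`, `examples/nb_typing.py` and
`examples/full_audit.py` walk through the other capabilities the same way.

A thin CLI wraps the same functions:

```sh
barcodiag simulate --n-species 36 --members 5 --seed 1 --out sim/
barcodiag audit --library sim/library.fasta --metadata sim/metadata.tsv --out audit/
barcodiag assign --library sim/library.fasta --metadata sim/metadata.tsv --level species --out loo/
```

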