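# Methods

## Conservation model

The unit of analysis is the −5/+5 residue window around a mapped
phospho-residue on a human seed protein, compared independently against
each vertebrate ortholog in a pre-aligned family (a star comparison: every
species against the seed, no tree weighting). Coordinates are 1-based on
the ungapped seed; alignment columns are internal. Windows shrink at
sequence termini rather than being padded, so a site 3 residues from the
C-terminus has 5 + 3 = 8 flanking positions and its per-species scores are
multiples of 1/8.

Per species, the window score is

```
identical flank residues / comparable flank residues
```

gated on the central phospho-acceptor: serine and threonine are
interchangeable acceptors, so S↔T conserves the center, while replacement
by tyrosine or any other residue — or a gap — does not, and a lost center
forces the species score to 0 regardless of flank identity. The site-level
aggregates are the arithmetic mean of numeric species scores ("M") and the
fraction of scored species whose center is conserved ("N").

Three residue states are deliberately distinct:

* **gap (`-`)** in the ortholog window — an evolutionary loss: kept in the
  denominator, counted as non-conserved;
* **unknown (`X`)** — unretrievable sequence data: removed from the
  denominator; an unknown *central* residue makes the species
  `Incomplete` (as does a conserved center with zero comparable flanks,
  which would otherwise yield an undefined 0/0 treated as 1);
* **absent species** — `NA`, excluded from every aggregate. The mean is
  `NA` exactly when no non-self species is numeric.

The human self-comparison is trivially 1.0; it is shown in the per-species
columns but excluded from M and N by default (`include_self=True` restores
the all-species reading). A note on aggregation: for the window
configuration {1, 1, 0.875, 0.875, 0.75, 0.625} the defined mean is 0.854;
no alternative simple aggregation of those values was adopted, and the
arithmetic mean over scored species is used throughout.

**Splice variants.** Families may carry several variants per species. The
per-species score uses the variant maximizing the window score — the most
favorable ortholog evidence — with deterministic tie-breaks: higher central
conservation, then longer ungapped sequence, then lexicographically
smallest variant id. Averaging across variants and scoring only a canonical
variant were considered; the maximum was chosen because variant sets are
incomplete and uncurated, and a single intact variant is positive evidence
of conservation. Selection is therefore invariant to member order.

## Motifs and the selection filter

Motifs are allowed-residue sets indexed by offset (−5…+5) plus an allowed
central-acceptor set. The default library is ATM/ATR `[S/T]Q`, Plk1
`[D/E]X[S/T]`, a minimal and a strict CDK consensus (`[S/T]P`,
`[S/T]PX[K/R]`), a basophilic Chk1/2 consensus (`RXX[S/T]`) and the Plk1
Polo-box docking consensus `S-[pS/pT]-P`. Only the ATM/ATR and Plk1
strings are canonical fixed points; the others follow Scansite-style
consensus definitions from the motif literature and live in an editable
YAML file (`phosconet/data/default_motifs.yaml`), not in code. Matching is
Boolean by design — position-weight scoring and network-context kinase
prediction are out of scope; an external prediction table (NetworKIN-style
output) can be attached and is consumed purely as annotations.

Per-site annotation: motifs are matched on the ungapped human seed;
experimentally known kinases always win (provenance `known`) and motif- or
table-derived kinases are attached with provenance `predicted` only when no
kinase is known. Motif conservation is the fraction of non-NA species
whose selected-variant window satisfies the motif on the ortholog side,
with required slots on gaps/unknowns counting as failure.

The selection filter keeps sites that (a) were observed at least twice,
(b) have central conservation rate ≥ a threshold and (c) have motif
conservation ≥ the same threshold for a named consensus (default Plk1).
The threshold defaults to 1.0 — the criterion must hold in *every* scored
species — because the species subset over which "conserved" should be
judged is a genuinely open choice; it is exposed as a 0–1 parameter and the
species roster is configurable.

## Synthetic data

The simulator generates what the analysis consumes: aligned families of 11
vertebrate species (the seed plus 10), phosphosite tables and ground truth.
Evolution is a star phylogeny — each lineage diverges independently from
the human root — because the statistic aggregates independent per-species
comparisons, so lineage correlation would not change its expectation and
the star keeps the oracle analytic: each position substitutes with
probability `p_sub_neutral` (default 0.3, a realistic deep-vertebrate
divergence), reduced by `constraint_factor` (default 0.2) inside true-site
windows; substitutions draw uniformly from the 19 alternative residues and
true-site centers flip only S↔T. Decoy sites have S/T centers but evolve
neutrally. Species drop out with probability `p_species_missing`,
truncation replaces a terminal segment with `X` (exercising `Incomplete`),
and extra splice variants are exon-skip gap segments. The model is
substitution-only, so emitted families are alignments by construction; an
optional gap mode inserts gap segments to exercise gap handling. There is
no indel evolution, no codon/dN–dS model and no rate variation across
lineages — passing tests show the scorer and filter recover planted
constraint under this idealized model, not that they are robust to
alignment error or heterogeneous divergence in real ortholog sets.

Site positions are placed uniformly among layouts with pairwise spacing
≥ 11 (windows never overlap) via the standard minimum-gap transform.
Observation counts for true sites are 1 + Poisson(1.2) (so always ≥ 1);
the synthetic curated-collection generator emits 244 sites over 33 proteins
with mixed residues, kinases and sources to mirror the shape of a manually
collected site table. All randomness flows from one integer seed
(`numpy.random.default_rng`); cohorts derive per-protein child seeds from a
`SeedSequence`, and identical configuration plus seed gives byte-identical
outputs end to end.

## Numerical and format choices

* Scores are exact rational fractions of small integers; no tolerances are
  needed anywhere in the scoring path.
* Table output uses 3 decimals on the 0–1 scale with literal `NA` /
  `Incomplete` tokens; writer∘reader is the identity at that precision
  (re-writing a read table is byte-identical).
* JSON network export is lossless (import∘export is identity, floats
  round-trip via IEEE-754 repr); GraphML flattens per-site detail into
  JSON-encoded node attributes for graph-tool interoperability.
* Figures strip volatile metadata so a fixed input yields fixed bytes.
* Problem sizes in the test suite (families of 400 residues, cohorts of a
  few proteins, 200 replicates for the parameter-recovery study) were
  chosen as the smallest sizes at which the binomial 3-SD checks are
  informative.

## Known limitations

Pre-aligned input is trusted (no realignment, no alignment-quality
weighting); conservation is identity-based (no substitution-matrix
similarity); motif matching is Boolean; edges of the assembled network are
curated input, never inferred; and module grouping of proteins is an
optional input column, since no membership rule is computed.
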