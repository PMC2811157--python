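# phosconet

Cross-species conservation scoring, kinase-motif annotation and network
assembly for protein phosphorylation sites.

## The problem

Signaling networks — the DNA damage response (DDR) is the motivating case —
are wired by phosphorylation: ATM/ATR, Chk1/2, Cdk1/2 and Plk1 write
phospho-marks onto adaptor and effector proteins, and Polo-box domain (PBD)
docking onto primed phospho-sites recruits Plk1 to its substrates.
Functionally important phospho-sites tend to evolve under purifying
selection, so a practical way to prioritize the in-vivo mapped sites on a
protein is to ask: *is the residue, and its local sequence context,
conserved across vertebrate orthologs — and does it sit in a recognizable
kinase consensus?*

`phosconet` implements that analysis as a reusable library for
computational biologists: it scores the evolutionary conservation of mapped
phospho-sites across aligned vertebrate ortholog families, annotates sites
with kinase-consensus and PBD docking motifs, filters for recurrently
observed sites with conserved consensus, and assembles the result into an
annotated, exportable signaling network. A seeded simulator generates
ortholog families with the statistical structure the analysis assumes, so
the whole pipeline is testable without database access.

## The statistic

For a phospho-residue at seed position $p$ (1-based, ungapped human
coordinates) the conservation unit is the 11-mer window $p-5 \ldots p+5$
(shrunk, not padded, at sequence termini). For each species $s$ (best
splice variant, star comparison against the human seed):

$$
c_s \;=\; \frac{\#\{\text{flank positions identical to the seed}\}}
               {\#\{\text{comparable flank positions}\}}
\quad\text{if the central S/T/Y is conserved, else } c_s = 0,
$$

where the central residue is conserved if identical **or** an S↔T
interchange (S/T→Y and everything else breaks it); an ortholog-side
alignment gap is comparable-but-not-conserved (evolutionary loss), an
unknown residue `X` is removed from the denominator (missing data), and a
site whose central residue cannot be retrieved is reported `Incomplete`
rather than scored. The site-level score is the arithmetic mean of $c_s$
over scored species (column **M** of the output table), alongside the
central-residue conservation rate (column **N**). Species without an
ortholog are `NA`.

Motifs are offset-indexed allowed-residue sets — ATM/ATR `[S/T]Q`, Plk1
`[D/E]-X-[S/T]`, CDK `[S/T]P`, PBD docking `S-[pS/pT]-P` — matched on the
human seed and re-evaluated on each species' window to give a per-motif
conservation fraction. The selection filter keeps sites observed at least
twice whose phospho-residue **and** consensus motif are conserved across
the scored species.

## Worked example

`examples/02_score_conservation.py` scores a hand-built S-Q site (seed
position 10) against five orthologs:

```
site DEMO S10
  H.sap: 1.000 (center conserved: True)
  M.mul: 1.000 (center conserved: True)
  M.mus: 0.900 (center conserved: True)
  R.nor: 0.900 (center conserved: True)
  B.tau: NA
  ...
  X.tro: 0.800 (center conserved: True)
  D.rer: 0.000 (center conserved: False)
mean window conservation (M): 0.720
central conservation rate (N): 0.800
```

Rhesus is identical (1.0); mouse differs at one of ten flanking residues
(0.9); rat additionally swaps the central S for T, which is a permitted
interchange (still 0.9); frog carries two window substitutions (0.8);
zebrafish has lost the phospho-acceptor entirely, which forces its score to
0 regardless of the flanks. The mean over the five scored non-human species
is 0.720 and the central residue survives in 4/5 of them (0.800). The other
examples cover the simulator (`01`), motif annotation plus the
recurrent-conserved-site filter (`03`) and network export/plotting (`04`).

A thin CLI wraps the same functions for shell use:

```bash
phosconet simulate --out-dir demo --seed 7
phosconet run --site-table demo/sites.tsv --family-dir demo/families --out-dir demo
```

which writes the per-species conservation table, motif annotations, the
filtered site list, JSON/GraphML network exports, a summary figure and a
run manifest.

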