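# alphoid

Analysis of centromeric α-satellite DNA, built around the gorilla alphoid
consensus set: monomer segmentation, protein-recognition-domain (PRD)
annotation, A/B monomer typing, higher-order-repeat (HOR) detection,
suprachromosomal-family (SF) assignment, characterization of the 189-bp
insertion monomer, majority-rule consensus building, and neighbor-joining
phylogenetics — plus a ground-truthed synthetic-array simulator so every
stage can be tested without downloading sequence databases.

## Background

Primate centromeres are built from α-satellite DNA: ~171-bp monomers
repeated head-to-tail over hundreds of kilobases.  Monomers descend from
two ancestral types — A-type monomers carrying the 17-bp pJα motif
(`CTAPyGGTGPuAAAAGGAA`) and B-type monomers carrying the 17-bp CENP-B box
(`PyTTCGTTGGAAPuCGGGA`) — and either form heterogeneous *monomeric* arrays
(10–40% divergence between monomers) or *higher-order repeats*: multi-monomer
units repeated nearly identically (<2% divergence between corresponding
positions of adjacent units).  HOR families with common monomer composition
and chromosomal distribution form suprachromosomal families.  In gorilla,
SF1 is dimeric (gJ1–gJ2, A–B), SF2 is octameric
(gD1.0–gD1.3–gD1.4–gD2.1–gD1.2–gD2.0–gD1.1–gD2.2, B–B–B–A–B–A–B–A) and SF3
is pentameric (gW1–gW5, B–B–B–A–A).  The SF2 unit periodically contains an
extra-long 189-bp monomer created by a tandem duplication that interrupted
the CENP-B box, copied ~22 bp upstream, regenerated a complete box, and
(with a nearby 4-bp deletion) left a net 18-bp insertion.

The 19 published gorilla consensus sequences (a general, an A-type and a
B-type consensus plus 16 family/monomeric consensuses) ship as package data
over an extended alphabet: IUPAC degeneracy codes plus gap codes
`F` = −/A, `I` = −/C, `J` = −/G (and `O` = −/T, added by this package).

## What the package computes

- **Segmentation** (`alphoid.segmentation`): orientation detection by
  local alignment on both strands, tandem-period estimation by shift
  autocorrelation, and an exact dynamic program that tiles an array with
  copies of a reference consensus, minimizing total edit distance
  (degenerate reference symbols match their expansion bases; gap-code
  positions are optional).
- **PRD & A/B typing** (`alphoid.motifs`): degenerate 17-mer scans for
  both motifs with mismatch counts, core/full conservation calls, and
  nearest-consensus A/B typing by p-distance.
- **HOR detection** (`alphoid.hor`): `d[k]`, the mean p-distance between
  monomers `i` and `i+k` (pairwise global alignment, gap/ambiguous columns
  removed), and a period call requiring `d[k] ≤ 0.10` plus dominance over
  the off-period background.
- **SF assignment** (`alphoid.families`): nearest family consensus per
  monomer plus a concordance rule (HOR period == family unit count, ≥80%
  majority, optional cyclic order match).
- **Insertion characterization** (`alphoid.insertions`): tandem-duplication
  analysis of extra-long monomers against a B-type reference — net
  insertion, duplication unit, copy number (1–3), interruption position on
  the CENP-B 17-mer, and the regenerated downstream box.
- **Consensus building** (`alphoid.consensus`): reference-projected
  alignment and strict >50% majority-rule consensus with the extended
  ambiguity alphabet.
- **Phylogenetics** (`alphoid.phylo`): p-distance with pairwise deletion,
  Saitou–Nei neighbor-joining with deterministic tie-breaking, and
  column-resampling bootstrap supports.
- **Simulation** (`alphoid.synthetic`): arrays with known monomer
  boundaries, source consensuses, A/B labels, HOR period, strand, and
  insertion copy number.

## Worked example

Simulate four SF2 HOR units at 1% substitution noise and run the full
pipeline:

```sh
alphoid simulate --sf SF2 --n-units 4 --sub-rate 0.01 --seed 7 --out sf2
# sim_SF2_7: 5532 bp -> sf2.fasta
alphoid run --in sf2.fasta --out results
# 1 arrays -> results
```

`results/report.json` then contains (abridged):

```json
{
  "hor": {"d_at_period": 0.019759, "label": "octameric", "n_units": 4, "period": 8},
  "sf": "SF2",
  "order_match": true,
  "n_monomers": 32,
  "insertions": [
    {"monomer_id": "sim_SF2_7/2", "net_insertion": 19, "dup_unit_len": 22,
     "copies": 1, "box_break_pos": 14, "regenerated_box_core_intact": true}
  ]
}
```

Reading: the 5532-bp array segments into 32 monomers; the HOR detector
finds an 8-monomer period with ~2% divergence between corresponding
monomers of adjacent units (the injected noise), so the array is octameric
SF2 with the published unit succession (`order_match`).  Each unit's
extra-long monomer is recognized as one copy of a 22-bp tandem duplication
that interrupts the CENP-B box at pattern position 14 and regenerates a
core-intact box downstream.  The net insertion is 19 bp against the
pipeline's default reference, the 170-bp general B-type consensus
(189 − 170); against the 171-bp SF2 B-type consensus gD1.0 it is the
canonical 18 bp.

The library surface mirrors the CLI: see `alphoid.run_pipeline`,
`alphoid.segment_monomers`, `alphoid.call_hor`, etc.

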