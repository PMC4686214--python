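# tmabquant

Quantitative peptidomics with multiplex TMAB stable-isotope labels: detection
of 4–5-plex peak groups in MS1 peak lists, capped run-relative peptide
ratios, fold-change classification, and proteasome cleavage-site (P1)
preference analysis — plus a synthetic degradome/spectrum generator so the
whole pipeline is testable without instrument data.

## The problem

Endogenous intracellular peptides are mostly products of proteasome cleavage,
so their levels read out proteasome activity toward natural substrates —
useful, for example, when asking whether polyglutamine-expanded huntingtin
impairs the proteasome in striatal cells. The measurement works by labeling
each sample's peptides with one of five isotopologues of the amine-reactive
TMAB tag (D0/D3/D6/D9/D12), pooling, and acquiring one LC-MS run per pooled
set. Each peptide then appears as a *peak group*: co-eluting isotope clusters
offset by

```
Δ(m/z) = n_labels × (tag mass shift difference) / z ,
n_labels = (0 if N-terminally acetylated else 1) + #Lys
```

Relative levels per replicate are the representative intensity of each
channel divided by the within-run mean of the reference-condition channels,
capped to the quantifiable range [0.20, 5.0] (a ~5:1 signal-to-noise floor),
averaged over charge/label forms, summarized per condition as mean ± SD with
Student's t-test, and classified: decrease ≤ 0.80 < no change < 1.25 ≤
increase. Mapping each peptide back to its protein gives the cleavage sites
that produced it (2 for internal fragments, 1 for protein-terminal ones), and
tallying the P1 residue — the residue N-terminal to each cleaved bond — per
category exposes the protease's specificity (hydrophobic P1 ⇒
chymotrypsin-like β5, basic ⇒ β2, acidic ⇒ β1).

Mind the D9→D12 channel: its spacing is 3 × (¹³C−¹²C) = 3.0101 Da, about
9 mDa less than the 3 × (²H−¹H) = 3.0188 Da of the other steps. The detector
computes every spacing per tag pair.

## Worked example

Simulate a 5-plex study — 2 control + 3 treated replicates, proteasome
products suppressed to 0.35× in the treated condition, 10 % of peptides
exempt — and run every stage:

```
tmabquant all --config examples/demo_config.yaml --out demo_out
```

`demo_out/summary.tsv` then contains per-peptide, per-condition rows such as

```
peptide_id  condition  mean    sd      n  p_value   stars  category  heat_bin
pep00001    control    1.000   0.015   2                   no_change grey
pep00001    treated    0.355   0.058   3  0.00069   ***    decrease  bright_green
pep00007    treated    0.879   0.142   3  0.51              no_change grey
```

— the treated/control ratio of pep00001 recovers the simulated 0.35 effect
and is classified as a significant decrease, while the exempt pep00007 stays
near 1. `demo_out/p1_classes.tsv` aggregates the cleavage-site analysis:

```
residue_class  decrease  no_change  increase
hydrophobic    0.736     0.438      0.750
basic          0.031     0.188      0.000
acidic         0.037     0.063      0.000
```

— decreased (proteasome-product) peptides carry predominantly hydrophobic P1
residues, the chymotrypsin-like signature. `groups.tsv`, `ratios.tsv`,
`merged.tsv`, `cleavage_sites.tsv`, rank-order plot data/SVG, the replicate
heat map, and a manifest (config hash, seed, row counts) are written
alongside. Rerunning with the same seed reproduces every table byte for
byte.

The same stages are available as library calls (`tmabquant.detect`,
`tmabquant.quantify`, `tmabquant.cleavage`, `tmabquant.synthetic`) and as
individual subcommands (`simulate`, `detect`, `quantify`, `cleavage`,
`report`).

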