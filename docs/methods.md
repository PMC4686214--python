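# Methods

`tmabquant` implements label-based relative quantification of endogenous
peptides (a peptidome, largely proteasome products) from multiplexed MS1 peak
lists, together with a cleavage-site preference analysis and a synthetic data
generator that makes every stage testable end to end.

## The measurement model

Samples are labeled with 4-trimethylammoniumbutyryl (TMAB) N-hydroxysuccinimide
esters. The tag acylates free peptide N-termini and lysine ε-amines (tyrosine
adducts are reversed with hydroxylamine during work-up and are not modelled),
so a peptide carries

    n_labels = (0 if N-terminally acetylated else 1) + #Lys

tags. Five isotopologues — D0, D3, D6, D9 (deuterium) and D12 (9 × ²H + 3 ×
¹³C) — are chemically equivalent, so up to five samples pooled in one LC-MS
run appear as a *peak group*: co-eluting isotope clusters offset by

    Δ(m/z) = n_labels × (shift_b − shift_a) / z .

Two numerical points matter here:

* the D9→D12 step is 3 × (¹³C−¹²C) = 3.01006 Da, not 3 × (²H−¹H) = 3.01883 Da;
  all spacing arithmetic is done per tag pair, never with a uniform "3.02 Da";
* the tag carries a fixed quaternary-ammonium charge. We adopt the convention
  that each tag contributes one charge and any remaining charge is protons, so
  observable species have z ≥ n_labels. Real spectra can violate this; the
  simulator and detector share the convention, which keeps the pipeline
  self-consistent. The D0 acyl cation mass (C₇H₁₄NO⁺ = 128.10699 Da, the
  group replacing one amine hydrogen minus an electron) is configurable;
  ratio quantification is independent of its exact value, which only enters
  peptide–group identity matching.

Residue monoisotopic masses come from pyteomics' standard table; variable
modifications (Met oxidation, Cys cyanylation, …) are generic
`(position, Δmass)` pairs that shift the neutral mass but never the label
count.

## Peak detection

Input is a centroided peak list per run (TSV: `run_id, rt_min, mz, intensity`;
mzML is accepted read-only). Detection has two stages.

**Deisotoping.** Peaks are scanned in ascending m/z; each unassigned peak
seeds a chain extended upward at ¹³C/z spacing (10 ppm m/z and 0.2 min
co-elution tolerances by default). The charge explaining the most members
wins, ties to the higher charge; companion-less seeds become singletons of
undetermined charge. Chains start at the lowest peak of an envelope — the
monoisotopic peak — and are capped at `max_isotopomers` (default 3) members.
The cap is load-bearing: the inter-channel tag spacing is within ~9 mDa of
three ¹³C steps, i.e. inside a 10 ppm window above ~900 m/z for z = 1, so an
unbounded chain could walk from one channel's envelope into the next — in
particular into a *suppressed* channel whose monoisotopic peak is weaker than
the preceding channel's tail, which is precisely the biology of interest.
Below ~3 kDa the fourth isotopomer is negligible, so the cap costs nothing.

**Peak-group search.** Clusters are examined in descending representative
intensity. For each seed, every hypothesis (n_labels ≤ 8, seed-is-channel-t)
predicts the other channels' monoisotopic positions; the hypothesis matching
the most co-eluting same-charge clusters wins (ties prefer label counts
present among supplied identifications, then unclaimed clusters, then smaller
n_labels). Groups need ≥ 2 present channels; absent channels are recorded as
missing. A cluster claimed by two groups flags both as ambiguous. Each
channel is quantified by the *most intense* member peak of its cluster
(usually the monoisotopic or the one-¹³C peak) — robust to envelope shape and
the convention used in manual analyses of this chemistry. A channel whose
cluster collides with an unrelated co-eluting cluster (any member within the
ppm tolerance) is overlap-flagged and excluded from quantification; a wholly
overlapped group is unquantifiable and renders white in the heat map.

## Quantification

Within each run the denominator is the mean representative intensity of the
run's reference-condition channels. Every usable channel, including the
reference replicates themselves, yields `intensity / denominator`; reference
self-ratios therefore average exactly 1 per run. A missing non-reference
channel with a present reference is evidence the peptide fell below the
detection limit and is reported at the lower cap.

Ratios are capped at 0.20 (reflecting a typical 5:1 signal-to-noise floor) and
optionally 5.0; capped-low values enter means as 0.20. Whether such values
should instead be excluded from the SD is ambiguous; including them at the cap
reproduces summaries of the form "≤0.20 ± 0.01" and is the default. Forms of
one peptide (different charge states and/or label counts) are averaged to a
single value per replicate. Per condition we report mean, sample SD (n−1), n,
and a two-sample two-tailed equal-variance Student's t-test against the
reference self-ratios (no multiple-testing correction, by design — the
downstream analysis treats categories, not individual p-values, as the
signal).

Fold-change categories: decrease ≤ 0.80 < no_change < 1.25 ≤ increase; the
printed 0.81–1.24 band is read as the half-open interval (0.80, 1.25) — a
two-decimal rounding, not a gap. Heat-map bins: < 0.60 bright green,
0.60–0.80 dark green, (0.80, 1.20) grey, 1.20–1.40 dark red, > 1.40 bright
red, missing white. Both are pure functions of the mean and re-derivable from
the summary table.

## Cleavage-site analysis

Peptides are located in their named protein by exact substring search
(multi-locus matches take the first occurrence, are flagged, and are excluded
from frequency tables). An internal fragment requires two cleavages (the bond
before its first residue and after its last), a protein-terminal fragment one,
a full-length protein none — so mixed sets always yield more sites than
peptides. Protein N-terminal status is granted for start ≤ 2 (initiator-Met
removal is co-translational processing, not proteolysis), and an acetylated
N-terminus is never counted as a cleavage. The P1 residue is the residue
N-terminal to the cleaved bond; for a peptide's C-side site it equals the
peptide's last residue.

Observations are counted once per detection (per replicate by default, per
experiment optionally — the mode is recorded in output metadata), so frequency
tables reflect how often peptides are seen. Counts are tallied per fold-change
category and aggregated into residue classes: hydrophobic {L,I,M,V,F,Y,W},
basic {K,R}, acidic {D,E}. Conditions can be pooled into one table.

## The synthetic generator

The generator emulates the study design, not the instrument:

* **Proteome** — i.i.d. sequences from SwissProt-like residue frequencies,
  Met-initiated, default 250–500 residues.
* **Degradome** — peptides of 6–30 residues whose flanking P1 residues follow
  a configurable weight vector (default: 65 % of the mass on the hydrophobic
  set, led by Leu at 30 %, mimicking chymotrypsin-like preference). Both
  flanking residues are drawn from the weights *first*, then a concrete
  (start, end) pair is chosen uniformly among all compatible positions; this
  ordering keeps the empirical P1 distribution equal to the weights (a
  window-constrained draw would deplete rare residues such as Trp).
  Protein-terminal fragments (15 % by default, half of N-terminal ones
  acetylated) are drawn proteome-wide the same way. Internal cuts are
  restricted to positions 2…len−1 so ground truth matches the counting rules
  above.
* **Abundances** — `base × effect(condition) × lognormal(0, cv)` with a
  lognormal base spread (σ = 1) around 10⁴ counts. A configurable fraction of
  peptides (default 10 %) is exempt from condition effects, mirroring
  peptides that do not require proteasome processing.
* **Spectra** — one isotope cluster per (peptide, charge, channel) at the
  exact theoretical m/z, Poisson heavy-isotope envelope (rate 0.55 per kDa,
  three isotopomers — see the deisotoping cap above), optional ppm-scale m/z
  jitter, RT jitter, an optional per-deuterium RT offset, exponential noise
  peaks, detection-limit censoring (censored channels are flagged in ground
  truth), and injected co-eluting interferents placed 0.45 isotopomer steps
  off a random channel. One envelope is shared by all channels of a peptide:
  the tags replace defined atoms and do not change the stochastic
  natural-isotope content.

What the generator does **not** emulate: chromatographic peak shapes (the
detector operates on centroid lists), MS/MS identification (identities are an
input), ionization efficiency differences between forms, and correlated
(non-lognormal) replicate structure. Passing tests therefore demonstrate the
correctness of the arithmetic, detection logic and statistics under the
stated model, not instrument-level robustness.

## Benchmarks and problem sizes

* **Round trip** (noise-free, ~50 peptides, 5-plex): 100 % of ground-truth
  peak groups must be recovered with all test-channel ratios within 10⁻⁶ of
  the design effect and reference self-ratio means exactly 1.
* **Parameter recovery**: ~200 peptides, 6 + 6 replicates, effect 0.35,
  replicate CV 0.15, benchmark noise (2 ppm jitter, 500 noise peaks/run, 2 %
  overlap injection, 25 % second charge states). With the within-run
  reference-mean normalization the per-peptide mean ratio has relative SD
  ≈ 0.15·√(2/6) ≈ 8.7 %, so a ±15 % band captures ~91 % of peptides in
  expectation and a single 200-peptide draw fluctuates around the 90 %
  threshold; the shipped check therefore pools five seeded repetitions
  (~900 affected peptides). Exempt peptides must center on 1.0.
* **P1 recovery**: ~10,000 sites from ~1,100 proteins; the hydrophobic P1
  fraction must recover the generating 0.65 within 3 binomial σ, and the full
  20-residue distribution must pass a χ² goodness-of-fit at α = 0.01.

All randomness flows from `numpy.random.SeedSequence` children of a single
seed; reruns are byte-identical, including serialized TSVs.

## Known limitations

* The fixed-charge convention (z ≥ n_labels) excludes real-world species
  observed at lower charge; both sides of the pipeline share the convention.
* Group→peptide identity assignment is by neutral mass + label count within
  10 ppm; near-isobaric peptides can swap identities in dense simulations.
* The overlap detector flags any co-eluting cluster within tolerance — it
  does not attempt to deconvolve overlapped intensities, matching the
  conservative white-out treatment of overlapped cells.
* With caps enabled, strongly suppressed peptides (true ratio < 0.2) are
  reported at 0.20 by design; their means are upper bounds, not estimates.
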