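# Methods

## Problem and model

A lysine site is represented by the peptide segment of `2L + 1` residues
centered on it.  Its annotation is a 4-vector `l ∈ {+1, -1}⁴` over the
types (acetylation, crotonylation, methylation, succinylation); the
all-negative vector is the legal "other" class of unannotated lysines,
which contributes to feature denominators but to no type numerator.

**Features.**  The unit of evidence is the *location-fixed di-residue*:
an ordered pair of adjacent residues `αβ` at window positions
`(i, i+1)`, `i ∈ {-L..-2} ∪ {1..L-1}` (the two pairs touching the center
lysine are skipped, leaving `2(L-1)` pairs per segment).  On a training
set of `a` segments, each pair-at-location key gets a total count `N`
(segments carrying it) and four type-restricted counts `N_type`; a
multi-labeled segment counts once per active type.  The key encodes as
`ρ_type = N_type / N ∈ [0,1]⁴`, and a segment as the concatenation of its
keys' ρ-vectors in ascending start-position order — `8(L-1)` features,
laid out in blocks of four with the type order fixed as above.  The
features blend sequence context with training labels, so they are
supervised and must be refitted per fold (the `DiresidueEncoder`
transformer makes this explicit).

**Engine.**  The label-`v` score of a query is the Gaussian-kernel
weighted mean of the ±1 training labels.  The masked engine (`gkpr`,
default) measures the distance for label `v` only on the `v`-th slot of
every block — each label is scored on its own proportions — while the
baseline (`gkr`) uses the full distance for every label.  `S_v ∈ [-1, 1]`
always (convex combination of ±1), and `S_v ≥ 0` predicts the label, ties
included.

**Evaluation.**  Overall metrics operate on per-site label *sets*:
aiming `|L∩L*|/|L*|`, coverage `|L∩L*|/|L|`, accuracy `|L∩L*|/|L∪L*|`,
absolute true `[L = L*]`, absolute false `(|L∪L*|-|L∩L*|)/4`, each
averaged over sites.  Per-label metrics are the usual confusion rates,
with AUROC/AUPR computed from the continuous `S_v` scores (the only
per-label continuous quantity the model defines).

## Parameters

| Parameter | Default | Meaning |
|---|---|---|
| `L` (`half_width`) | 13 | window half width; 96 features. 24 used for wide-window comparisons (184 features) |
| `θ` (`theta`) | 1/6 | kernel width; supported grid {1/2, 1/4, 1/6, 1/8, 1/16, 1/32} |
| `engine` | `gkpr` | masked per-label distances; `gkr` = unmasked baseline |
| `folds` / `mode` | 5 / `general` | `strict` partitions proteins, not records |

With `θ = 1/6` the exponent is `-18·d`, so the weighting is sharply
concentrated on the nearest training segments.

## Numerical and design choices

* **Terminal padding** repeats the single terminal residue into every
  missing slot ("nearest residue" reading); positions are 1-based in all
  file dialects, signed `-L..L` internally.
* **Non-standard residues** (B, J, O, U, Z, X, `*`) collapse to one
  unknown symbol `X` that is counted like any letter; anything else is an
  error.  Duplicate segments from different proteins are retained — they
  matter for strict CV.
* **Unseen keys** (`N = 0`, possible because held-out folds are encoded
  with a table they did not contribute to) encode as `ρ = (0,0,0,0)`:
  no training evidence supports any type.  The denominator `N` counts the
  whole training set, including the "other" class.
* **Exponent stabilization.**  Weights are computed as
  `exp(-(d - min d)/2θ²)`.  The score is a ratio, so subtracting the
  per-query minimal distance changes nothing mathematically while
  guaranteeing the nearest record has weight 1 (denominator ≥ 1, no
  underflow, no epsilon needed).  At `θ = 1/6`, unshifted weights
  underflow already at `d ≈ 40`.
* **Feature layout.**  Block `j` (0-based, ascending start position)
  holds features `4j + v` for the label-`v` slots, 1-based `v`; this is
  the indexing the masked distance uses.
* **Empty-set conventions.**  A metric ratio with an empty denominator
  set contributes 1 when both sets are empty and 0 otherwise; absolute
  true counts two empty sets as a match.  These conventions are certified
  by the bundled Q16778 evaluation: the published five-metric quintet
  (0.8250, 0.8250, 0.8167, 0.8000, 0.0625) is reproduced only under them.
  Precision/F1 with zero denominators report 0.
* **Folds** are as equal as possible (remainder on the first folds);
  strict mode balances protein counts, not record counts.  The overall
  report is the mean of per-fold metrics; per-label confusion metrics and
  ROC/PR areas are computed on the pooled out-of-fold predictions, which
  keeps the curves well defined.  Reported AUROC/AUPR are NaN for a label
  absent (or universal) in the evaluated set.

## Synthetic data

The generator mirrors the model's own assumption — type-specific residue
pairs at fixed window positions.  Labels are drawn first (independent
per-type Bernoulli prevalences; when several types fire, the co-annotation
is kept with probability `multilabel_rate`, else one label is kept at
random), then residues are drawn iid from a background frequency table
(default uniform over the 20 amino acids, center forced to K), and for
each active label its designated (position, pair) slots are overwritten
with the motif pair with probability `m·q₀ / (1 + (m-1)·q₀)` — an odds
multiplier `m` on the background pair probability `q₀`.  Segments are
concatenated into synthetic proteins so FASTA extraction round-trips and
protein-grouped CV is exercisable.

Default conditions, chosen once as the package's recovery regime:
100 proteins × 10 sites (n = 1000), `L = 13`, prevalences
(0.40, 0.10, 0.12, 0.30) — imbalanced, with roughly a third of sites
unannotated — `multilabel_rate = 0.5`, and per type six motif positions
(each type owns every fourth eligible position) at odds multiplier 2000,
the strength of a sharp consensus motif: a motif slot carries its pair in
≈ 83% of active segments.  Under these conditions general 5-fold CV
absolute true exceeds 0.95, and with multipliers forced to 1 it collapses
onto the constant label-prior baseline — the paired check the acceptance
suite runs.

What the generator does **not** emulate: real proteome composition,
homology between proteins, overlapping windows around adjacent lysines,
and position-*independent* compositional biases.  Passing recovery tests
therefore show the estimator recovers the generative structure it
assumes, not that real-data performance transfers; published full-scale
benchmarks require the external datasets (see README).

## Problem sizes

The test suite and acceptance script run at n ≤ 1000 sites, `L ≤ 13` for
CV (plus dimension checks at `L = 24`); oracle-equivalence checks use 50
training segments and 20 queries at tolerance 1e-12.  These sizes were
chosen so the full pipeline, including the paired strong/null CV runs,
executes in a few seconds on one CPU.

## Known limitations

* No class rebalancing: the engine inherits the training prevalences.
* AUROC/AUPR need both classes present for a label in the evaluated set.
* `Dataset.with_half_width` can only shrink windows (exact under the
  repeat-terminal padding); growing requires re-extraction from FASTA.
* The unseen-key fallback `ρ = 0` is this package's choice; any constant
  in `[0,1]⁴` would be defensible, and 0 reads "no evidence, no support".
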