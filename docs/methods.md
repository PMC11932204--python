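# Methods

## Problem setting

A microRNA of 18–25 nt is paired with a 25-nt candidate target site (CTS)
cut from a 3'UTR; the task is a binary call: validated target site or
decoy. Sequences shorter than 25 nt are right-padded (`-`); the pad symbol
never pairs and contributes nothing to any feature. The CTS string is
stored in the orientation that aligns index-by-index with the microRNA
(site read 3'→5'), so complementary helices run along the matrix diagonal.
All coordinates are 0-based; UTR windows are half-open.

## Pairing-preference model

The feature map enumerates canonical pair runs (AU, CG, GC, GU, UA, UG;
microRNA base first):

* singles, any (i, j): 25·25·6 = 3750 features;
* doubles, start offset d = j − i ∈ [−2, 2]: 25·5·36 = 4500;
* triples, d ∈ [−1, 1]: 25·3·216 = 16,200;

24,450 bits in total. The index space is kept at the full product size;
runs that would cross position 24 on either strand are simply infeasible
and their bits stay 0. A bit is set iff every constituent position is
non-pad and forms the named pair type.

The preference model is a single sigmoid neuron over these bits, fitted by
minibatch Adam on binary cross-entropy. Weights start at zero (the problem
is convex), so a fit is bit-reproducible from (data, epochs, batch size,
seed). Defaults: 5 epochs, batch 128, learning rate 1e-3, no class
reweighting (a `class_weight="balanced"` flag exists). A grid-search
helper scans epochs {5, 10, 20, 30, 40} × batch {32, 64, 128, 256} and
selects by validation AUPRC, breaking ties toward smaller epochs, then
smaller batch.

The learned weight vector, bias excluded, is the DP scoring dictionary: a
run of k pairs ending at (i, j) scores its dedicated feature weight when
its offset lies inside the feature window, and the sum of its constituent
single-pair weights otherwise (singles exist for every (i, j), so the
lookup is total). The bias is excluded because a constant offset per
matched run would distort the structure maximization.

## Duplex dynamic program

`dp[i][j]` is the best total weight over non-crossing structures of the
prefixes `mic[0..i]` × `cts[0..j]`; transitions skip base i, skip base j,
or match k ∈ {1, 2, 3} consecutive pairs ending at (i, j). Borders are
zero and filling starts at [1, 1]: position 0 of either strand never pairs
(the 5'-terminal microRNA nucleotide is anchored in Argonaute). Ties break
with fixed precedence diag-3 > diag-2 > diag-1 > up > left, which favors
longer matched runs and makes backtracking deterministic.

Three 25×25 tables are kept: scores S1, backpointers BT1, and MFE1, where
MFE1[i, j] is the 37 °C free energy of the substructure backtracked from
(i, j) — computed literally by per-cell backtracking (625 traces of ≤ 25
steps; an incremental scheme was not worth the correctness risk).

## Free-energy model

For a structure with ≥ 1 pair:

* intermolecular initiation +4.09 kcal/mol;
* nearest-neighbor stack for adjacent pairs with zero gap on both strands
  (Turner 2004 table, canonical pairs including GU, 0.1 kcal/mol
  precision);
* bulge initiation for one-sided gaps, internal-loop initiation for
  two-sided gaps (total unpaired length; tabulated to 30 nt,
  Jacobson–Stockmayer extrapolation `ΔG(n) = ΔG(30) + 1.75·R·T·ln(n/30)`
  beyond);
* +0.45 kcal/mol per helix terminus closed by a weak pair, where a helix
  is a maximal stacked run. The penalty applies to AU/UA **and** GU/UG
  termini (the standard convention for weak ends); an isolated single-pair
  helix has two termini and can incur it twice.

The empty structure has ΔG = 0: with no pairs there is no initiation
event. Sequence-dependent terminal mismatches, loop-asymmetry terms,
dangling ends, and coaxial stacking are deliberately out of scope — the
model is the category-level decomposition above. All tables ship as
plain-text TSV package data.

## Feature stacks and scaling

Per sample, four 25×25 float32 channels (microRNA on rows):

* `mx1` — rRNA-derived pair probability at each predicted pair, else 0;
* `dps` — S1; * `dpm` — MFE1; * `bp` — pair probability at every (r, c).

Raw channels have incompatible ranges (probabilities [0, 1], energies
≈ −40..+5 kcal/mol, unbounded DP weights), so a per-channel min–max
scaler, fitted on the training split only and persisted with the model, is
applied by default; `scale_inputs=False` restores raw channels. A channel
constant on the fit data keeps an identity map (with a warning).

## Classifier

Four parallel branches, one per channel, each: 3 × (3×3 conv with
size-preserving padding → ReLU → 2×2 max-pool with floor semantics →
dropout 0.25), filters 32/64/128, spatial plan 25 → 12 → 6 → 3. Flattened
branch outputs are concatenated, then dense 128 → dense 64 → dropout 0.25
→ one sigmoid unit. Loss is binary cross-entropy under minibatch Adam
(default lr 1e-3); training runs for exactly the configured number of
epochs — no early stopping — recording per-epoch loss and validation
AUPRC. Defaults follow the tuned values (20 epochs, batch 256); a
grid-search helper scans epochs {5, 20, 30, 40} × batch
{32, 64, 128, 256, 512} by validation AUPRC.

All layers are implemented in numpy with explicit backprop (validated
against finite differences in the test suite). Everything —
initialization, batch order, dropout masks — draws from one seeded
generator, so runs are single-threaded and bit-deterministic; there is no
fast nondeterministic mode because the numpy implementation is already
single-threaded.

The classification threshold is selected where the precision and recall
curves intersect (validation split when available, else training), and is
stored in the model artifact together with parameters, config, and the
fitted scaler; save → load → predict is bit-identical.

## Evaluation protocol

Precision/recall/specificity are evaluated on a fixed grid of 100
thresholds evenly spaced on [0, 1] (step 1/99, traversed 1 → 0); the grid
is chosen so that reported thresholds are exact members (k/99). A sample
is called positive when probability ≥ threshold. AUPRC is the trapezoid
sum over the traversal, clipped to [0, 1]; a random scorer approaches the
positive prevalence. Conventions for empty denominators: precision := 1
with no positive calls, NPV := 1 with no negative calls.

Two scorers are compared by paired bootstrap: resample the test set with
replacement at full size (single-class resamples redrawn and counted),
1000 iterations, mean AUPRC difference, one-sided p = proportion of
resamples with diff ≤ 0, and 95% percentile CIs per scorer. For identical
score vectors every difference is exactly 0, so this convention reports
p = 1.

## Synthetic corpus

The generator emulates the sample-construction rules of a curated
target-site corpus without downloads. Defaults (chosen once): 100
positives, up to 5 decoys each (~600 samples), 300-nt UTRs, microRNAs
20–25 nt uniform over ACGU. Each positive UTR carries one implanted 25-nt
window complementary to the microRNA seed (positions 1–7), plus — with
probability 0.5 — a 3'-compensatory complement at positions 21–24, and
0–2 random mismatches at unanchored positions; implant coordinates are
recorded as ground truth. Decoys are random non-overlapping windows of the
same UTR, disjoint from the implant, retained only when the predicted
duplex has ΔG37 < 0.

The plausibility filter needs a scoring dictionary before any preferences
exist. A uniform dictionary makes the DP maximize pair count, which yields
loop-riddled structures of mostly positive energy and starves the
generator; `ScoreDict.run_biased()` (near-diagonal triples +6,
singles/doubles −9) is therefore the generation default — the DP then
predicts contiguous helix-like structures and the filter behaves like an
energy-minimizing tool's MFE < 0 rule. Exact (mic, cts, label) duplicates
are collapsed; splits are stratified 70/10/20 with largest-remainder
rounding per class.

What the synthetic corpus does *not* emulate: real 3'UTR base composition
and length distributions (real UTRs average ~2.5 kb), non-canonical seed
binding, cross-microRNA site sharing, and curation noise. Passing the
end-to-end checks therefore demonstrates that the pipeline's machinery —
feature encoding, DP, energies, training, thresholding, scanning — works
and that planted signal of realistic shape is recovered; it does not
certify real-data performance.

## Study problem sizes

The packaged end-to-end study (`mirsite.pipeline.run_study`, also driven
by `scripts/acceptance.py`) uses the 600-sample corpus above, preference
training at the tuned 5 epochs / batch 128, and a reduced classifier width
— filters 8/16/32, dense 64/32, 12 epochs, batch 32, lr 3e-3 — sized so a
single-CPU run finishes in minutes while retaining ample capacity for the
uncontested 420-sample training split. Sliding-window localization scans
every held-out positive UTR at step 1 and counts a hit when the
top-probability window overlaps the implant.

## Known limitations

* The duplex model forbids crossing pairs, intramolecular folding, and
  pseudoknots, and scores at most triple runs with dedicated weights.
* The energy model is category-level (no terminal mismatches, asymmetry
  penalties, or dangles) and fixed at 37 °C.
* Out-of-window double/triple runs fall back to sums of single weights —
  an interpolation choice, not a learned quantity.
* Internal loops below the physical minimum (size 1) cannot arise from the
  structure decomposition; the lookup clamps to the smallest tabulated
  size for totality.
* Real-corpus performance figures require the curated corpora and are out
  of scope here.
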