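# Methods

## Experimental design being modelled

Four rainbow trout genotype groups — age-matched wild (Wa), size-matched
wild (Ws), domesticated (D) and the F1 wild × domesticated hybrid (WD) —
with six fish per group, each hybridized on a two-channel oligo array
against a common reference pool built from the Ws fish. Expression is the
log2 ratio of the sample channel over the reference channel, so all
inference is relative to one shared baseline. The domesticated-genome dose
(0% wild, 50% hybrid, 100% domesticated) provides the covariate for the
regression fallback of the inheritance classifier.

## Synthetic-data generator

Ground truth is drawn per gene: with probability `fraction_affected` the
gene gets a genotype mode from `mode_weights` (additive, D-dominant,
D-recessive, overdominant, no-effect); with probability
`stage_effect_fraction` it differs only between Wa and Ws (stage-only);
otherwise it is unaffected. Group means on the log2 scale follow the mode
exactly: additive hybrids at the parental midpoint, D-dominant at the D
mean, D-recessive at the wild mean, overdominant half a parental difference
beyond D. The parental difference is exactly `effect_size_log2` with random
sign — a fixed magnitude rather than a distribution, so recovery studies run
at a stated, interpretable effect size.

Measurement model, per spot: the sample channel is
`2^(mu_group + fish_noise + spot_noise) + background`, the reference channel
`2^(ref_pool + spot_noise) + background`. Fish-level noise is normal on the
log2 scale with `sd = log2(1 + biological_cv)` (a log-normal
coefficient-of-variation model); spot-level technical noise uses half that
spread and is independent across replicate probes of a gene; the reference
pool is the Ws mean plus pool noise shrunk by √n. Background is
gamma-distributed with mean `background_mean` (shape 4). Dye bias multiplies
the sample channel by `2^bias(A)` where `bias(A) = amplitude / (1 +
exp((A − 8)/1.5))` — a smooth, monotone low-intensity inflation that gives
LOWESS a non-trivial curve to remove. A fraction of spots is flagged bad or
absent; a fraction of genes is spotted on two probes sharing a gene name.

Key defaults: 6 fish/group; `effect_size_log2 = 2`; `biological_cv = 0.1`;
`dye_bias_amplitude = 0.5` log2 units; `background_mean = 50`;
`flagged_fraction = 0.05`; `replicate_probe_fraction = 0.1`;
`expressed_fraction = 0.25` with expressed baselines at log2 ≈ 12 ± 1.5 and
unexpressed at ≈ 5 ± 1, which reproduces a realistic ~20–25% present-call
rate on a 44K-style array; `mode_weights` = 0.40/0.35/0.25 for
recessive/additive/dominant (overdominance off by default — the classifier
has no such output label, and simulated overdominant genes land in the
additive bin, which the generator exists to demonstrate). Within-group
biological variance for liver mRNAs is not an empirically estimated
quantity here; the CV default is a plausible round figure and is the single
most influential free parameter for power.

What the generator does **not** emulate: spatial slide artifacts, print-tip
effects, scanner saturation, spike-in controls, correlated co-expression
between genes, or heavy-tailed biological variation. Passing tests therefore
demonstrate that the machinery is correct and well calibrated under a clean
log-normal measurement model — not that real scans of this design would
yield any particular gene list.

## Preprocessing

Channels are floored at 1.0 before log2 (removing domain errors), giving per
spot `M = log2(ch2/ch1)` and `A = (log2 ch2 + log2 ch1)/2`. LOWESS (span 0.3
of good spots, statsmodels implementation, interpolated onto all spots) is
fitted to good-flagged spots only and subtracted from every spot, so flagged
spots are corrected but never influence the fit and matrices stay
rectangular. Rows are centered on their across-sample median (even counts:
mean of the two middle values), an idempotent baseline transformation.
Presence filtering runs last, on pre-normalization raw values: a probe is
kept iff its raw sample-channel signal is ≥ 300 in **every** replicate of at
least one group (protecting group-specific expression) and it is flagged
good in ≥ 75% of samples. The rule text is embedded in the filter report so
alternative readings remain auditable.

LOWESS carries the usual assumption that most spots are unregulated. A
regulated gene shifts its own mean intensity A, so if a large share of the
array carries strong effects the intensity fit absorbs real biology and
biases every gene at nearby A. The recovery benchmarks therefore embed
genes of interest in a predominantly null background array, which is also
the realistic regime (a few hundred regulated mRNAs on a 44K array).

## Testing composition

Per entity: equal-variance one-way ANOVA across the four groups (vectorised;
zero between- and within-group variance gives F = 0, p = 1 by convention),
BH step-up across entities on the omnibus p-values, then Tukey HSD
(studentized-range p with pooled within-group variance; Tukey–Kramer for
unequal n) for entities passing BH. List membership for a pairing requires
the BH-adjusted omnibus, the pairwise Tukey p and `max(fc, 1/fc) ≥ 2`
simultaneously, where `fc = 2^(Δ mean log2)` (median centering cancels in
this difference, so fold changes are insensitive to the baseline step).
This is the only composition in which each correction acts on the scale it
is defined for; BH applied per pairing to the Tukey p-values is available
behind `bh_on="pairwise"` for comparison. Exact fold-change ties (fc = 1)
count as up; they cannot co-occur with the 2-fold filter. Replicate
collapse keeps the first probe in array order among same-named members.
Running Tukey only on BH-passing entities also keeps the studentized-range
integrations (the expensive part) proportional to the discovery count.

## Inheritance classification

Classification operates on the combined D-vs-wild significant list (the
union of the D-vs-Wa and D-vs-Ws lists at α = 0.05, fold ≥ 2), re-running
the omnibus/BH/Tukey machinery on exactly that list. The decision tree under
a chosen wild reference W ∈ {Wa, Ws}: both WD-vs-W and WD-vs-D Tukey
contrasts significant at raw α ⇒ additive; only WD-vs-W ⇒ D-dominant; only
WD-vs-D ⇒ D-recessive; neither ⇒ ordinary least squares of back-transformed
(non-log) per-fish expression on dose 0/50/100 across the W, WD and D fish,
two-sided slope test: p ≤ α ⇒ resembling-additive (counted with additive),
else no-effect. The fallback applies only to the neither-contrast-significant
branch — one-contrast cases already have defined labels. A numerically
perfect zero-residual linear fit with non-zero slope is declared significant
rather than undefined (it arises only in noise-free synthetic data). The
four-way tree covers all 2×2 significance patterns, so every entity gets
exactly one label. Concordance compares the four summary bins (r, d, a with
resembling-additive folded into a, Ne) between the two references within the
shared/unique partition (A/B/C); percentages are shares of the concordant
total, rounded half-up to one decimal.

A composite classifier of this shape has two chances to call an effect on a
truly null gene (the Tukey path and the slope test), so its bare
false-positive rate slightly exceeds the per-test α (~6% at α = 0.05 in our
simulations). Gating by the differential-expression stage first — as the
workflow prescribes — removes essentially all null genes before
classification, which is why the pipeline-level no-effect false-positive
rate is far below α.

## Reporting

Hierarchical clustering uses scipy's agglomerative linkage on Euclidean
distances (average linkage by default; complete/single/ward configurable),
which resolves ties by original index order and places lower-index subtrees
left, so leaf orders are deterministic. PCA centers entities across samples
without rescaling (the matrix is already on a common log2 scale) and takes
sample scores from the SVD. Functional rollups count up/down members per
umbrella category from a required two-column gene → category map; the
pipeline ships a synthetic random map as a stand-in for annotation lookups,
which are out of scope.

## Problem sizes and numerical choices

The shipped analysis configuration uses a 6,000-gene array (≈6,600 spots
with replicate probes) — the full study geometry at reduced spot count — and
the benchmark routines use 200 genes per mode embedded in 7,200 null spots
(recovery), 200 replicates of 2,000 null genes (FDR), and 10,000 spots
(dye-bias attenuation); these sizes give Monte-Carlo standard errors well
inside the margins being tested while keeping any run to minutes on one
core. All randomness flows from a single integer seed through separate
spawned streams for truth, scans and category maps, and every output file is
written with fixed formatting, so identically configured runs are
byte-identical. Scan files use `%.17g` floats and round-trip parsing, making
write → read lossless at float64 precision.

## Known limitations

* The generator's independence assumptions (genes, fish, spots) understate
  the correlation structure of real arrays; FDR control shown here is for
  exchangeable nulls.
* Significance thresholds interact with the fixed effect magnitude: with a
  2-log2-unit parental difference almost every affected gene is detected, so
  list sizes track the simulator's affected fraction more than the α level.
* The presence rule and the BH/Tukey composition are reasonable readings of
  standard practice, parameterized rather than uniquely determined;
  alternatives are switchable and recorded in output provenance.
* Stage-only genes are classified relative to whichever wild group is the
  reference, so they surface as genotype effects under Wa and as no-effect
  under Ws by construction — the A/B/C partition plus concordance is exactly
  the instrument that separates them.
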