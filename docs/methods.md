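# Methods

## Model

Pause detection is cast as anomaly detection on two features per codon:
mean-normalized occupancy `u_i = c_i / mean(c)` and normalized position
`x_i = (i+1)/L` (1-based position over ORF length in codons, stop codon
excluded everywhere). Normalization by the ORF mean removes expression
level from the profile; the positional feature lets the detector absorb
the systematically elevated coverage at ORF ends (initiation/termination
ramps) instead of calling it pausing. No closed-form convention for `x`
is canonical; `(i+1)/L` maps the ramp-affected termini of ORFs of any
length onto comparable coordinates and is strictly increasing in `(0, 1]`.

ORFs are ranked by TPM (`total counts / kilobase of CDS`, rescaled to sum
to 10⁶) and cut into five quantile bins (linear-interpolation quantiles;
a TPM exactly on an interior edge goes to the lower bin, which makes the
partition order-independent). One Extended Isolation Forest is trained per
bin on the pooled `(u, x)` points of all its ORFs — codons are compared
only against similarly expressed genes, so low-expression transcripts are
not swamped by the absolute coverage of high expressors.

### Extended Isolation Forest

Each forest holds 200 trees. A tree is grown on a uniform subsample
(without replacement) of ψ points, where ψ is the rounded mean ORF length
of the bin — the subsample then scales naturally with the bin's typical
transcript. Depth is capped at ⌈log₂ ψ⌉: anomalies isolate in fewer than
average cuts, so deeper resolution only refines the uninteresting bulk.
At each node the cut is a random hyperplane — normal vector uniform on the
unit circle, intercept point uniform inside the node's bounding box (the
fully extended construction; axis-parallel cuts introduce artefactual
axis-aligned score structure in 2-D). Leaves record their point count
`m`; a query's path length is the number of edges traversed plus
`c(m) = 2H(m−1) − 2(m−1)/m` (with `H(i) ≈ ln i + γ`), the expected extra
depth had the leaf been grown out. The anomaly score is
`s = 2^(−E[path]/c(ψ)) ∈ (0, 1]`.

Within each bin, codons whose score reaches the 0.95 score quantile
(linear interpolation; threshold ties all flagged) are pausing peaks, so
the flag rate is 5% per bin up to discreteness. The called codon is the
ribosome P site; A = +1 and E = −1 codons. Analyses that anchor elsewhere
take an explicit site/offset parameter.

Determinism: one root seed expands through `numpy` `SeedSequence` spawning
into per-bin and per-tree streams, so results are bit-reproducible and
independent of evaluation order. The scoring hot loop is a numba kernel;
a pure-numpy traversal of the same trees is kept and tested bit-identical.

### z-score baseline

The conventional alternative scores position `i` of ORF `g` as
`z = (u_gi − mean_i)/sd_i`, where the moments pool all ORFs of the bin
long enough to reach position `i`; each ORF's last 10 codons are excluded
(ORFs differ in length, and termination-adjacent positions would otherwise
mix into interior statistics). Population SD is used (configurable);
positions with zero SD or fewer than two covering ORFs are undefined
(NaN). The EIF path scores all codons including the final 10 — its
positional feature handles the terminal ramps explicitly.

## P-site annotation

Footprint 5′ ends (nt, relative to the A of the start AUG) are converted
to codon counts in three steps. (1) Read lengths without clear 3-nt
periodicity are dropped; "clear" is quantified as modal reading-frame
fraction ≥ 0.6 (no canonical number exists; 0.6 is comfortably above the
uniform 1/3 and is configurable), with a minimum of 100 reads per length.
(2) Per retained length, the P-site offset is the modal distance from the
5′ end to the initiation codon over reads starting upstream of the AUG;
mode ties break toward the smaller offset for determinism. (3) Each read
increments codon `⌊(five_prime_offset + offset)/3⌋`; reads outside the CDS
are dropped and logged, so annotated counts plus logged drops equal input
reads.

## Synthetic translatome

The generator emulates the coverage features that matter to pause calling:

| parameter | default | meaning |
|---|---|---|
| `n_orfs` | 2000 | translatome size |
| `length_median` / `length_sigma` | 400 codons / 0.45 | log-normal ORF lengths (min 50) |
| `expression_median` / `expression_sigma` | 2 reads/codon / 1.4 | log-normal mean coverage; σ=1.4 spans ≈3 orders of magnitude |
| `nb_size` | 10 | negative-binomial shape r; variance = m + m²/r ≈ 2m at m=10, mimicking overdispersed RiboSeq counts |
| `ramp_height` / `ramp_width` | 2× / 20 codons | exponential coverage ramps at both ORF ends |
| `dwell_sigma` | 0.35 | log-normal per-codon dwell multipliers when no explicit map is given |
| `pauses_per_orf` | 1 | injected ground-truth spikes |

Counts are negative-binomial draws (Gamma–Poisson mixture) with mean
`expression × ramp_i × dwell(codon at i+1)`: occupancy at an annotated
P-site position is governed by the codon being decoded in the A site, the
decoding-wait mechanism. Sequences are drawn from a configurable
codon-usage table (uniform over the 61 sense codons by default). Replicate
libraries share one layout (sequences, expression, dwell) and differ only
in counting noise.

The injected-pause benchmark first flattens natural outliers — any
normalized count greater than **2× the per-ORF population SD** is replaced
by the ORF mean — then adds Uniform(2.5, 3)·SD at one random position per
ORF. ORFs with zero SD skip flattening and use the pooled translatome SD
for the spike magnitude. Recovery is summarized by the rank (Mann–Whitney)
AUC of anomaly scores against the injected labels, and by the TPR/FPR of
the 0.95-quantile flag set.

What the generator does **not** emulate: ligation/PCR sequence bias,
nucleotide-level periodicity artefacts, 5′UTR/3′UTR signal, multi-isoform
genes, or correlated dwell along the message beyond the ramp. Passing the
benchmarks therefore demonstrates correct machinery and recoverability of
planted signal under realistic count noise — not performance on any
particular real library. Two structural consequences are worth noting,
and the acceptance run makes both visible: after flattening, every
injected spike (≥2.5 SD) exceeds every surviving natural value (≤2 SD),
so the measured TPR is essentially 1; and with a hard 5% flag budget and
~0.2% spike prevalence the FPR is pinned near
`(0.05 − 0.002·TPR)/0.998 ≈ 0.048` — on data with heavy score ties the
flagged fraction (hence FPR) can be substantially larger.

## Enrichment statistics

Every enrichment is a 2×2 Fisher's exact test of pause sites against
background positions. The background universe defaults to all codon
positions of the analyzed ORFs minus the pause sites; edge sites without
the required flanking context are dropped and logged. The odds ratio is
the sample OR `(ad)/(bc)` with a Haldane–Anscombe 0.5 added to every cell
only when some cell is zero (closed-form and reproducible; a conditional
MLE adds nothing at these table sizes). P-values come from the exact
two-sided hypergeometric test and are Benjamini–Hochberg adjusted within
each analysis; "significant" means q < 0.05 throughout. O/N triplet
analysis maps each pause site to the optimality classes of its E, P, A
codons (8 categories); bicodon analysis conditions on an anchor P-site
codon and tests downstream (or, site-swapped, upstream) partners against
the anchor's translatome-wide partner frequencies.

Condition comparisons use a Theil–Sen fit (slope = median of pairwise
slopes, intercept = median of `y − slope·x`); outliers are codons whose
absolute residual exceeds 3× the (unscaled) median absolute deviation —
`k` is a documented choice, not a canonical constant.

## Logos, motifs, tAI

Logo matrices use `H(l,i) = q(l,i)·log₂(q(l,i)/p_i)` with `0·log 0 = 0`;
`p` is the residue frequency of the analyzed proteome (pseudocount-floored
and renormalized so degenerate synthetic proteomes keep log ratios
finite). Individual `H(l,i)` are signed — positive iff `q > p` — and the
column sum is not a non-negative divergence. Enriched E-P-A tripeptides
(Fisher + BH against background tripeptides) are clustered on the
restricted Damerau–Levenshtein (optimal string alignment) distance with
average (UPGMA) linkage; the dendrogram is cut at k = 5 clusters by
default. Only the distance is forced by the analysis; linkage and cut are
configurable.

tAI follows the classical definition: absolute adaptiveness
`W_c = Σ (1−s)·tGCN` over recognizing anticodons under eukaryote-standard
wobble rules (NNU read by A₃₄(→I) and G₃₄; NNC by G₃₄ and I; NNA by U₃₄
and I; NNG by C₃₄ and U₃₄), with the classical optimized `s` constraints
(0 for Watson–Crick, 0.41 G:U, 0.28 I:C, 0.9999 I:A, 0.68 U:G) shipped as
an editable TSV. `w = W/max(W)`; unserved codons receive the geometric
mean of nonzero `w`; gene tAI is the geometric mean of `w` over codons.

## Metagene traces

A trace is the mean of a per-codon signal at each offset from a set of
anchors (offsets in codons, negative = already translated; per-offset `n`
excludes positions outside the ORF). The background repeats the statistic
over seeded random anchor sets of equal size drawn uniformly over all
codon positions (1000 draws by default); the 2.5/97.5 percentiles of
those draws give the confidence band. Residue-keyed scales
(Kyte–Doolittle hydrophobicity and Zamyatnin side-chain volumes ship as
TSVs) are applied through each ORF's translation; window size is a
required parameter.

## Disome path

Disome footprints form two read-length populations ~3 nt apart; the
length histogram is split at the antimode between its two dominant local
maxima (raw histogram by default — smoothing can erase the narrow
inter-population gap; ties break toward the lower length) and each
population runs through the standard pipeline independently. A disome
call is the P site of the 3′ trailing ribosome; the leading ribosome sits
`displacement` codons downstream (default 10 ≈ one 30-nt monosome
footprint — the true nt→codon geometry is not knowable from the data
alone, so the parameter is explicit and logged). Long-population calls
shift back one codon before framing, matching the one-codon footprint
difference. Frames outside the ORF are dropped and logged.

## Problem sizes and runtime

The acceptance run uses translatomes of 2000 ORFs (≈0.9 M codons),
averages the injected-pause metrics over five seeds and runs the
replicate benchmark at the same scale (~3 min total on one CPU); the
hyperparameter-robustness sweep in the test suite uses 500-ORF
translatomes, and unit tests use 150–300 ORFs — sizes chosen so the
anomaly task stays non-trivial while the full suite remains desk-scale.

## Known limitations

* The engine accepts d ≥ 2 but is contract-tested only at d = 2, the
  pipeline's native dimensionality.
* Score ordering under anisotropic rescaling is consistent only in the
  Monte-Carlo sense: intercepts are drawn from rescaled bounding boxes,
  so interior near-ties can reorder.
* One CDS per ORF id; no isoforms, no UTR modeling, no nucleotide-level
  (sub-codon) pause resolution.
* BH adjustment is not idempotent (no step-up procedure is); the package
  asserts dominance (q ≥ p) and rank monotonicity instead.
* The tAI wobble table encodes eukaryote-standard decoding; organisms
  with modified wobble repertoires need a custom pairing table.
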