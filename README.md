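# ribopause

Unsupervised detection of ribosome pausing sites in ribosome-profiling
(RiboSeq) and disome-seq data.

## The problem

RiboSeq measures per-codon ribosome occupancy, but the data are noisy and
coverage scales with translation level: naive outlier calling either drowns
in noise or only describes highly expressed genes. `ribopause` treats pause
detection as a two-dimensional anomaly-detection problem. For each ORF the
raw counts are normalized by the ORF mean (`u_i = c_i / mean(c)`) and paired
with the normalized codon position (`x_i = (i+1)/L`), so that the elevated
coverage ramps near initiation and termination are comparable across ORFs
of any length. ORFs are stratified into five expression bins by TPM
quantiles — (0–20%), [20–40%), [40–60%), [60–80%), [80–100%] — and within
each bin an **Extended Isolation Forest** (EIF) is trained on the pooled
`(u, x)` points, so every codon is judged only against similarly expressed
genes.

An EIF isolates points with random hyperplane cuts; anomalies are separated
after few cuts. The anomaly score of a codon is

    s = 2^(−E[path] / c(ψ)),   c(n) = 2H(n−1) − 2(n−1)/n,

with ψ the per-tree subsample size (the rounded mean ORF length of the bin,
depth-capped at ⌈log₂ ψ⌉), 200 trees per forest, and `H` the harmonic
number. Codons whose score reaches the bin's 0.95 quantile are labeled
**pausing peaks**; the called codon is interpreted as the ribosome P site
(A = +1, E = −1).

Around this core the package provides the standard downstream analyses:
position-specific z-score baseline, Fisher's-exact / Benjamini–Hochberg
enrichment of codons, amino acids, optimal/non-optimal (O/N) codon
triplets and bicodon pairs at ribosome sites, Theil–Sen outlier comparison
between conditions, sequence-logo information content and tripeptide-motif
clustering (restricted Damerau–Levenshtein distance), tRNA adaptation
index (tAI) from tRNA gene copy numbers with wobble constraints,
anchor-centered metagene traces with bootstrap backgrounds, and the
disome-seq path (read-length population splitting, per-population calling,
leading/trailing ribosome site frames).

A seeded synthetic-translatome generator with ground truth (negative-
binomial counts, expression spanning three orders of magnitude, coverage
ramps, codon-specific dwell times, injected pause spikes) backs the
validation benchmarks and the test suite.

## Worked example

```python
import ribopause as rp

cfg = rp.SimConfig(n_orfs=300, length_median=150, dwell={"CCG": 5.0}, seed=42)
profiles, sequences, truth = rp.generate_translatome(cfg)
partition = rp.partition_by_tpm(rp.compute_tpm(profiles))
calls = rp.call_pauses(rp.normalize_profiles(profiles), partition,
                       n_trees=200, seed=42)

print(f"codons scored: {len(calls):,}; pausing peaks: "
      f"{int(calls['is_pause'].sum()):,} ({calls['is_pause'].mean():.1%})")

enr = rp.site_feature_enrichment(calls, sequences, site="A",
                                 feature_map=lambda c: c)
top = enr.sort_values("odds_ratio", ascending=False).head(3)
for _, row in top.iterrows():
    print(f"A-site {row['feature']}: OR={row['odds_ratio']:.2f}  q={row['q']:.2e}")
```

Output:

```
codons scored: 51,018; pausing peaks: 2,553 (5.0%)
A-site CCG: OR=111.03  q=0.00e+00
A-site CGA: OR=1.04  q=8.77e-01
A-site ATC: OR=1.02  q=8.86e-01
```

The simulation gives codon CCG a 5× dwell time; the pipeline flags 5% of
codons as pausing peaks (the 0.95-quantile threshold) and the enrichment
analysis ranks CCG first at the A site by two orders of magnitude, with
every other codon near odds ratio 1.

The same pipeline is exposed as a CLI:

```bash
ribopause simulate --n-orfs 2000 --seed 1 --out sim/
ribopause call --counts sim/counts.tsv --out run/ --trees 200 --quantile 0.95 --seed 1
ribopause enrich --calls run/calls.tsv --fasta sim/cds.fa --site A --out enrich.tsv
```

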