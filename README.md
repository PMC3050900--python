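# butolscreen

A tested re-implementation of the computational side of a pooled
genomic-library screen for solvent-tolerance genes in *Escherichia coli*:
a plasmid library of 2–3 kb genomic inserts is propagated through serial
batch transfers under rising n-butanol concentrations, two-channel
comparative-hybridization arrays read out which genes' inserts were
enriched or depleted, and candidate genes are validated one by one with
plate-reader growth kinetics. The package covers every analysis stage and
ships a synthetic-data module that emulates the whole experiment with
known ground truth, so the statistics can be exercised and verified
offline.

## What it computes

**Array stage.** Per scan, M = log2(sample/reference) is LOWESS-normalized
against A = ½·log2(sample·reference) to remove intensity-dependent dye
bias (near-background spots are excluded from the trend fit). Probe-level
ratios are summarized per gene by the median, giving each gene an
*enrichment profile* across the challenge steps. A one-sample two-sided
Student's t of the profile against 0 calls genes enriched (mean > 0) or
depleted (mean < 0) at p < α; genes with the same call in the solvent-free
control arm are subtracted as general growth advantage. Benjamini–Hochberg
correction is available behind a flag.

**Clustering.** CAST (Cluster Affinity Search Technique) over affinities
s(i,j) = (Pearson r + 1)/2 groups genes with similar profiles: grow one
cluster from the highest-connectivity seed, add outside genes with mean
affinity ≥ t, remove members below t, repeat until stable.

**GO enrichment.** Per term, counts (k, n, K, N) give a log2 odds ratio
log2((k/n)/(K/N)) and a one-sided hypergeometric tail p-value
P(X ≥ k), corrected across terms (BH default, BY optional); annotation is
propagated to ancestor terms.

**Growth kinetics.** µ_max is the slope of ln OD600 — either the maximum
over sliding windows of consecutive readings, or a single fit over a fixed
OD band (preferred for ratio statistics). With the tolerance ratio
T = µ_max(0.5 % butanol)/µ_max(0 %), the screen statistics are

    IIE  = (T_clone / T_WT − 1) · 100        (improvement in the inhibitory effect, %)
    RSGR = (µ_clone,0% / µ_WT,0% − 1) · 100  (change of solvent-free growth rate, %)

scored over four biological replicates with a two-sample Student's t on
the per-replicate tolerance ratios.

## Worked example

`examples/tolerance_screen.py` simulates the validation experiment for one
candidate clone whose true tolerance improvement is 49.1 %:

```
example fit: WT rep 1 at 0% -> mu_max 0.487/h over 2.8-6.2 h, R^2 0.9971
   (the fixed-OD-band fit under-reads every strain by the same factor,
    which cancels in the tolerance ratios below)
IIE  = +49.8 +- 6.7 %   (encoded 49.1%)
RSGR = +0.3 +- 4.6 %   (encoded 0%)
p = 4.21e-07 over 4 replicates -> significant: True
```

The recovered IIE matches the encoded effect within the replicate scatter,
and the replicate t-test flags the clone as significantly more tolerant.
The other scripts in `examples/` walk through library simulation,
normalization and candidate calling, CAST clustering, GO enrichment, and
the end-to-end pipeline; each prints the numbers it computes with a line
on what they mean.

## Command line

A thin CLI wraps the library:

```
butolscreen run       --seed 3 --outdir out/          # full synthetic screen
butolscreen simulate  --seed 2 --outdir data/         # write scans + truth tables
butolscreen cgh       --indir data/ --outdir calls/   # normalize + call candidates
butolscreen cluster   --profiles calls/profiles_butanol.tsv --outdir clust/
butolscreen go        --study hits.txt --population all.txt --associations gene2go.tsv --out go.tsv
butolscreen screen    --growth growth.tsv --out screen.tsv
butolscreen validate  --indir data/ --growth growth.tsv
```

All tables are TSV; report tables carry a `# config_hash` / `# seed`
provenance header, and rerunning with the same config and seed reproduces
them byte for byte. A YAML config (see `ScreenConfig.from_yaml`) fixes
every generator and stage parameter.

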