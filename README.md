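# phosbench

Benchmark statistics and stoichiometry estimation for multiplexed
quantitative phosphoproteomics.

Phosphoproteomics studies quantify tens of thousands of phosphopeptides by
label-free quantification (LFQ), SILAC, or isobaric tandem mass tags (TMT)
read out at the MS2 or MS3 level. Each method trades accuracy against
precision differently: MS2-measured TMT is precise but suffers *ratio
compression* (co-isolated, unregulated precursors contribute reporter
signal, shrinking measured ratios toward the sample average), which
SPS-MS3 acquisition partly rescues at a signal-to-noise cost. phosbench
implements the statistics used to quantify these trade-offs on controlled
mixed-species spike-in designs, plus a regression estimator that converts
TMT multiplexing into absolute phosphorylation-site stoichiometry. A
bundled simulator with known ground truth makes every statistic testable
without raw mass-spectrometry data.

It is aimed at computational proteomics researchers who want reference
implementations of these benchmark statistics, or a controlled synthetic
test bed for method comparisons.

## What's inside

**Stoichiometry by 3D multiple regression** (`phosbench.stoichiometry`).
For a phosphosite observed across the channels *j* of a multiplexed run,
mass conservation ties the phosphopeptide intensity *P_j*, its
non-phosphorylated counterpart *N_j*, and the protein level *T_j*
together through unknown positive response factors *a*, *b*:

    a·P_j + b·N_j = T_j

Dividing by *T_j* (p = P/T, n = N/T) reduces the conservation plane to a
line, n = c0 + c1·p, fitted by ordinary least squares; the response
factors follow as a = −c1/c0, b = 1/c0, and the per-channel occupancy
(the fraction of protein copies phosphorylated) as

    s_j = a·P_j / (a·P_j + b·N_j) ∈ [0, 1].

The two-sided t-test p-value of H0: c1 = 0 scores fit quality per site;
occupancies outside [0, 1] are flagged "illegal" and excluded from
summaries. `occupancy_error_sweep` reproduces the accuracy-vs-coverage
trade-off of tightening the p-value cutoff.

**Benchmark statistics** (`phosbench.benchstats`).

* SAM (significance analysis of microarrays): d = r/(s + s0) with
  automatic background-variance offset s0, permutation-calibrated delta
  and FDR (seeded, exhaustive when feasible);
* ROC curves and AUC from d-scores against known spike-in labels;
* mean-squared-error decomposition, MSE = bias² + variance;
* the ratio-decompression slope: OLS of one method's extreme log2 ratios
  on a compressed reference (slope > 1 = recovered dynamic range);
* a least-squares estimator of the co-isolation contamination fraction
  from reporter-channel profiles.

**Data model and filters** (`phosbench.tables`). A feature × sample
intensity table with species / localization-probability / condition /
replicate metadata; canonical long TSV plus a mapped MaxQuant
"Phospho (STY)Sites.txt"-style import; quantile normalization;
localization-probability and min-replicate filters; within-replicate
log2 ratios; SILAC triplet splitting; k-nearest-neighbour imputation.

**Simulator** (`phosbench.simulate`). Two preset designs — a yeast
1:4:10 spike-in into a 1:1:1 human background ("fig2-mix") and a
10–90% occupancy series across a TMT10-style plex ("fig6-stoich") —
crossed with method profiles (tmt-ms2, tmt-ms3, lfq, silac) that model
co-isolation contamination, multiplicative and additive noise, and
intensity-dependent dropout.

## Worked example

Estimate stoichiometry on a simulated MS3-style occupancy series
(9 channels at 10–90% true occupancy, 3 technical replicates, 200 sites):

```python
from phosbench import (StoichDesign, MethodProfile, simulate_stoichiometry_plex,
                       batch_stoichiometry, filter_by_slope_p, fits_to_frame)

design = StoichDesign(n_sites=200, n_tech_replicates=3)
ms3 = MethodProfile(name="tmt-ms3", contamination_alpha=4.0,
                    contamination_beta=46.0, noise_cv=0.10)
phospho, nonphospho, protein, truth = simulate_stoichiometry_plex(design, ms3, seed=123)

matching = {f"p_{s}": (f"np_{s}", None) for s in truth["site_ids"]}
fits, skipped = batch_stoichiometry(phospho, nonphospho, None, matching)
kept = filter_by_slope_p(fits, 1e-4)
frame = fits_to_frame(kept)
print(f"{len(kept)} of {len(fits)} sites pass the slope p-value cutoff 1e-4")
for ch in ("ch1", "ch5", "ch9"):
    true_occ = truth["occupancy_by_channel"][ch]
    est = frame[f"occ_{ch}"].dropna()
    print(f"channel {ch}: true {true_occ:.2f}, estimated median "
          f"{est.median():.3f} (MAD {(est - est.median()).abs().median():.3f})")
```

prints

```
200 of 200 sites pass the slope p-value cutoff 1e-4
channel ch1: true 0.10, estimated median 0.125 (MAD 0.014)
channel ch5: true 0.50, estimated median 0.490 (MAD 0.023)
channel ch9: true 0.90, estimated median 0.867 (MAD 0.014)
```

The low-occupancy channel is slightly overestimated and the high one
slightly underestimated: residual co-isolation pulls estimates toward the
background occupancy, exactly the bias the slope p-value filter and the
MS3-style acquisition are there to limit.

The same pipeline is available from the shell:

```sh
phosbench simulate fig6-stoich --method tmt-ms3 --seed 123 --out-dir sim/
phosbench stoich --phospho sim/phospho.tsv --nonphospho sim/nonphospho.tsv \
    --protein-constant-one --matching sim/matching.tsv --out stoich.tsv
```

Every command writes a `<output>.run.json` record (parameters, seed, row
counts per filter stage) sufficient to reproduce the run bit-identically.

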