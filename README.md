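# proteotype

Plasma-proteome endotyping for aptamer-based affinity proteomics (SOMAscan-style)
RFU matrices, built around a cohort design with two chronic airway diseases —
COPD and severe asthma — profiled on ~1233 probes in ~85 subjects.

Chronic airway diseases hide molecular *endotypes*: patient subgroups defined by
shared underlying biology rather than clinical presentation. `proteotype`
implements the full analysis chain used to find and characterize them from a
probe × subject relative-fluorescence-unit (RFU) matrix plus a clinical table:

1. **QC & normalization** — probe QC filtering, iterated median signal
   normalization (each sample scaled until the median of its probe-wise ratios
   to the per-probe median reference is 1), log2 transform, and a per-disease
   storage-time artifact scan (Spearman).
2. **Differential abundance** — per-probe Welch *t* on log2 RFU between
   diseases, Benjamini–Hochberg FDR control, covariate-adjusted OLS variant
   (`log2RFU ~ group + age + BMI + sex`), confounder scans with hypergeometric
   over-representation, and cross-platform Spearman validation.
3. **Endotype discovery** — PCA embedding and whole-proteome k-means on
   z-scored probes (best of *n* restarts by within-cluster SS, silhouette-based
   *k* selection when *k* is not fixed), any-pairwise cluster signatures
   (union of probes with q ≤ 0.05 in ≥1 cluster contrast), and protein *blocks*
   (hierarchical clustering of signature probes on 1 − Pearson correlation,
   average linkage).
4. **Set enrichment** — two bespoke scores over a per-probe statistic *s*:
   - directional **NES**: probes ranked by *s*; weighted Kolmogorov–Smirnov
     running sum (hits weighted |s|^w, misses uniform); ES = signed extremum;
     NES = ES / mean |ES_null| of matching sign over R random same-size sets;
     p = (1 + #{null at least as extreme}) / (R + 1);
   - non-directional **EMD ratio**: Wasserstein-1 distance between in-set and
     out-of-set statistics, reported as observed / mean(random-set null);
   plus enrichment networks (edges between sets sharing >50 % of members,
   min-size denominator), hypergeometric overlap (e.g. against exosomal marker
   lists), cellular-location composition χ², and marker correlation density.
5. **Origin & traits** — tissue-of-origin z-scores against a gene × tissue
   atlas (z per tissue across genes, one-sided Mann–Whitney group vs
   background, BH across tissues) and per-probe linear association with
   continuous clinical traits (e.g. annualized Kco decline).
6. **Clinical statistics** — pooled/Welch *t* from raw data *or* printed
   summaries, Fisher exact, ANOVA / Mann–Whitney / Kruskal–Wallis,
   Kaplan–Meier with log-rank, and per-subject OLS annual-change slopes.
7. **Synthetic cohorts** — a generator with recoverable ground truth
   (disease shifts, endotype blocks, covariate slopes, a shared exosome latent
   factor, storage drift, longitudinal Kco, exponential exacerbation times) so
   every stage is tested against a known world.

## Worked example

```python
import proteotype as pt

cfg = pt.default_config(seed=1)                 # 1233 probes, 34 COPD + 51 asthma
matrix, annotation, clinical, truth = pt.simulate_cohort(cfg)

matrix, annotation, qc = pt.qc_filter(matrix, annotation)
matrix, scale = pt.median_normalize(matrix)
log2m = pt.log2_transform(matrix)

de = pt.differential_abundance(log2m, clinical.subjects["disease"])
print(len(de.significant(0.05)))                # -> 420 probes at BH q <= 0.05

copd = [s for s in log2m.subject_ids
        if clinical.subjects.loc[s, "disease"] == "COPD"]
sub = pt.ProteomeMatrix(log2m.values[copd], log_transformed=True)
endo = pt.kmeans_endotypes(sub, k=3, seed=1)
print(endo.labels.value_counts().to_dict())     # -> {1: 13, 2: 12, 3: 9}
```

The differential count (420) is the number of probes separating the two
simulated diseases at FDR 0.05 — the synthetic world plants 365 truly shifted
probes at 1 residual SD, and block/covariate structure contributes the rest.
The k-means labels partition the 34 simulated COPD subjects into three
endotypes, relabeled 1..k by decreasing size for determinism.

The same run from the shell:

```bash
proteotype run --seed 1 --out my_run   # writes TSV/GMT/JSON artifacts + run_report.json
proteotype report my_run
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the pipeline end to end on the default synthetic cohort — QC,
normalization, disease differential with confounder and storage scans,
per-disease endotyping and protein blocks, both enrichment scores with
permutation nulls, the enrichment network, exosome-marker overlap,
tissue-of-origin z-scores, trait association and the clinical statistics
layer — printing each stage's counts and writing the target JSON.

See `docs/methods.md` for the statistical model, parameter defaults, and the
limits of what the synthetic cohorts can establish.
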