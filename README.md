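# regged

Detection of renal **glomerulus-enriched genes** from paired compartment
expression profiles, plus the comparison toolkit around it: cross-dataset
gene-list analysis, digital-differential-display (DDD) library-frequency
testing, and ΔΔCt qPCR quantification — all exercisable on synthetic data
with known ground truth.

## The problem

Microdissected human kidney yields two tissue fractions: the **glomerulus**
(the filtration unit, including podocytes) and the surrounding
**tubulointerstitium**. When the two fractions are hybridised and
normalised separately, a systematic affine offset between the profile
blocks can masquerade as differential expression. Under the assumption that
only a small subset of genes is compartment-specific, the offset can be
estimated from the bulk of the data and removed before selection.

## The method

1. **Aggregate profiles.** For each compartment, the per-probeset mean
   across all samples: `g_i`, `t_i` (log2 units).
2. **Sorted line fits.** Both profiles are reordered by ascending value of
   one compartment (ties broken by probeset ID) and an OLS line `y = m·x + c`
   is fitted to each against the shared 1-based rank `x`.
3. **Adjustment map.** The tubulointerstitial profile is calibrated onto
   the glomerular one with slope `a = m_glom / m_tub` (dynamic-range ratio)
   and intercept `b = c_glom − c_tub` (base-expression offset).
4. **Symmetric averaging.** Steps 2–3 are repeated with the other sort
   order; the final map is the componentwise mean of the two adjustments.
5. **Selection.** With `d_i = g_i − (a·t_i + b)`, probesets with
   `d_i > mean(d) + k·SD(d)` (default `k = 2`, sample SD) are called
   glomerulus-enriched; the selected probesets are collapsed to a
   non-redundant annotated gene list.

The companion modules compute presence/absence matrices and Venn regions
over named gene lists, one-sided Fisher's exact tests on pooled cDNA/EST
library counts (cluster vs. rest × pool A vs. pool B), and
`fold = 2^(−ΔΔCt)` with per-sample normalisation to the mean of two
reference genes.

## Worked example

```python
from regged import SimulationConfig, simulate_compartment_pair, glomerular_enrichment

cfg = SimulationConfig(seed=1)          # 22,283 probesets, 6+6 samples,
glom, tub, truth = simulate_compartment_pair(cfg)   # 3% enriched by 2 log2 units
res = glomerular_enrichment(glom, tub)

print(res.calibration.final_map)
# LinearMap(slope=0.9529382615591504, intercept=1.0328213821092531)
print(round(res.enrichment.threshold, 4), res.enrichment.n_selected)
# 0.8866 668
enriched = set(truth.enriched_probeset_ids)
print(len(set(res.enrichment.selected_probesets) & enriched) / len(enriched))
# 1.0
```

The recovered final map is close to the configured distortion
(0.9392, 1.1790) — the residual difference comes from the enriched subset
and measurement noise — and every truly enriched probeset clears the
mean + 2·SD threshold at this effect size.

The same pipeline is available from the shell:

```sh
regged simulate --outdir sim/
regged enrich --glom sim/glom.tsv --tub sim/tub.tsv --out enrich/
regged compare --lists a.txt --lists b.txt --names A --names B --out cmp/
```

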