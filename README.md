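# microdial

Systems-level analysis of drug-induced neurotransmitter responses from in
vivo microdialysis study records.

Decades of rat microdialysis literature report how systemically administered
neuropsychiatric drugs shift extracellular neurotransmitter and metabolite
concentrations in specific brain regions, as a peak percent of the pre-drug
baseline (100% = no change). `microdial` turns a curated table of such study
records into quantitative, testable answers to questions like: *do drugs in
the same ATC pharmacological subgroup evoke similar neurochemical response
patterns? Does chemical structure? Which predicted protein targets are
associated with which transmitter responses, and which annotation space —
ATC codes or predicted targets — carries more information about the
response?* It is a library for pharmacologists and cheminformaticians
working from Python; a thin CLI covers the two shell-worthy operations
(synthetic-data generation and the end-to-end pipeline).

## The method

1. **Fixed-effect pooling.** Replicate studies of the same
   drug/dose/region/neurochemical/route condition are pooled by the
   animal-weighted mean
   `x̄ = (1/N) Σᵢ nᵢ xᵢ`, `N = Σᵢ nᵢ`,
   where `xᵢ` is study *i*'s peak %-of-baseline effect and `nᵢ` its animal
   count. Robustness: leave-one-out jackknife with a χ²/Fisher direction
   test, one-factor-at-a-time covariate ANOVA, and a replicate-agreement
   reproducibility statistic.
2. **Ternary response fingerprints.** Per compound, the activity at each
   (region, neurochemical) tuple is the minimum pooled response across doses
   and peak times; activities are ternarised (+1 above / −1 below / 0 at
   baseline; absent = not measured).
3. **Missing-data-aware similarity.** Compound pairs are compared only over
   tuples measured for both; the up/down bit expansion feeds a
   Tanimoto/Jaccard coefficient (Rogers–Tanimoto and signed-agreement
   variants selectable). Pairs sharing an ATC class (intra) are contrasted
   with pairs that do not (inter) via a two-sample Kolmogorov–Smirnov test;
   the same contrast runs in chemical space (Morgan fingerprints, radius 2,
   2048 bits, Tanimoto).
4. **Frequency maps and clustering.** Up/down response fractions per
   (region, transmitter) tuple, and complete-linkage Euclidean clustering of
   the activity matrix after a completeness filter (missing cells imputed at
   baseline).
5. **Target association.** Given a binary drug × target prediction matrix
   (external tool, probability threshold 0.5) filtered to brain-expressed
   targets, the *hit percentage* of target *g* at neurochemical *c* is the
   share of drugs responding at *c* that are predicted active at *g*;
   100%-hit links are the candidate target–transmitter associations.
6. **Mutual information.** Normalized mutual information
   `NMI = I(X;Y)/mean(H(X), H(Y))` between every annotation label (ATC code
   or predicted target) and every response tuple, with per-pair missing-drug
   removal, aggregated per label and ranked by median.

Because the underlying literature corpus cannot ship with the package, a
first-class synthetic generator (`microdial.synth`) produces study-record
bundles with planted class structure, configurable missingness and noise,
and planted transmitter-driving targets — so every claim above is testable
as a parameter-recovery problem.

## Worked example

```python
import microdial as md
from microdial.synth import SimConfig, generate_all

bundle = generate_all(SimConfig(seed=0))          # 30 drugs, 6 ATC classes, 8x8 grid
ds = bundle.dataset
fps = md.response_fingerprint(md.build_activity_matrix(md.pool_dataset(ds)))
res = md.intra_inter_atc(fps, ds.annotations, metric="jaccard_updown")
d, p = md.ks_two_sample(res.intra.values, res.inter.values)
print(res.intra.median, res.inter.median, d, p)
```

Running `python examples/03_fingerprints_and_similarity.py` (the same
computation with commentary) prints:

```
fingerprints: 1354 measured cells over 8 regions x 8 neurochemicals; 353 up, 318 down, 683 no-change
response space: intra-ATC median 0.56 (n=60) vs inter 0.15 (n=375); KS D=0.98, p=8.2e-94
chemical space: intra median 0.51 vs inter 0.13
leaving each ATC code out shifts the medians by SD 0.021 (intra) / 0.011 (inter)
```

Same-class drugs are far more similar in neurochemical response space than
cross-class drugs (0.56 vs 0.15, KS p ≈ 1e-93) — the planted class coherence
the generator put in — and the contrast is stable under leave-one-class-out
exclusion. The other scripts in `examples/` walk through loading and
summarising (`01`), meta-analysis (`02`), frequency maps and clustering
(`04`), target association with exact planted-driver recovery (`05`) and
mutual-information ranking (`06`).

The pipeline end-to-end, from the shell:

```bash
microdial pipeline run --synth --seed 1 --out run/   # all stages + manifest.json
microdial synth --seed 1 --out inputs/               # just the input files
```

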