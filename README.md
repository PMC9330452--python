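# tuberelax

Multi-exponential transverse-relaxation (T2) analysis of potato tuber
tissues from multi-spin-echo (MSE) MRI, built for plant physiologists
who want to track water status in the cortex, the flesh (perimedullary
zone) and the pith of growing tubers without destructive sampling.

MSE imaging acquires one magnitude image per echo at times
t = TE, 2·TE, …, n·TE (here TE = 6.5 ms, 256 echoes). The mean signal
of a tissue region decays as a discrete mixture of exponentials,

    S(t) = Σ_j I0_j · exp(−t / T2_j),

where each pool j is a water compartment: I0_j, expressed as a
percentage of Σ I0 (the *relative intensity*), measures the size of the
pool, and T2_j its relaxation time. Tuber tissues are well described by
two pools — a fast-relaxing minor pool, component (1), with T2 below
100 ms and a slow-relaxing major pool, component (2), above 200 ms —
and the fitted (I0, T2) pairs separate the pith (longer T2, larger slow
pool) from cortex and flesh.

The package covers the full chain:

- **`tuberelax.phantom`** — synthetic MSE acquisitions of elliptical
  tubers (skin / cortex / heterogeneous flesh / brighter pith, optional
  vascular ring) with per-tissue bi-exponential decay and Rician
  (magnitude) noise, plus a simulator of tidy long-format measurement
  tables. No real scans are needed anywhere.
- **`tuberelax.segmentation`** — automatic tissue ROIs: Otsu threshold
  for the background split, a 5×5 erosion to strip the skin, a 3-pixel
  erosion strip for the cortex, a Kapur maximum-entropy threshold on a
  late echo (TE = 130 ms) for the pith, flesh as the remainder.
- **`tuberelax.relaxometry`** — ROI decay extraction, removal of echoes
  with SNR < 7 (Rayleigh-corrected background noise estimate), bounded
  least-squares multi-exponential fitting, and model-order selection by
  R², global fitting standard error and per-parameter standard errors.
- **`tuberelax.stats`** — normality-gated group comparisons (Student t
  / Mann–Whitney; ANOVA + Tukey HSD / Kruskal–Wallis + Bonferroni) with
  compact letter displays, correlation-matrix PCA, water-content
  utility WC (%) = (FW − DW)/FW × 100.
- **`tuberelax.pipeline`** / CLI `tuberelax` — one-config orchestration
  with a checksummed run manifest.

The numbered scripts under `analysis/` run the study end to end
(simulate → segment → fit → compare) and write tables under `results/`.

## Worked example

Simulate the reference acquisition (eight tubers on a 2×4 grid, noise
at 2 % of the peak signal), segment it, and fit every tissue:

```python
import tuberelax as tx

spec = tx.default_phantom_spec(noise_sigma=2.0, seed=1)
img, truth = tx.generate_phantom(spec)       # (256, 160, 160) stack
labels = tx.segment_tissues(img)             # cortex/flesh/pith per tuber
table = tx.fit_all_tissues(img, labels)      # tidy long table of fits
print(table.pivot_table(index="tissue", columns="variable", values="value")
           [["i0_rel_2", "t2_1", "t2_2"]].round(2))
```

```
variable  i0_rel_2   t2_1    t2_2
tissue
cortex       80.40  65.58  270.41
flesh        75.38  62.43  270.88
pith         86.62  55.00  349.10
```

Each row is the mean over eight tubers: `i0_rel_2` is the slow pool's
share of the total signal in percent, `t2_1`/`t2_2` the fast and slow
T2 in ms. The generative ground truth was cortex 81 %/64/268, flesh
76 %/61/268, pith 88 %/52/353, so the chain recovers the slow-pool T2
within ~1 % and the pool fractions within ~1.5 points at this noise
level; the pith values are pulled slightly toward the flesh by the few
boundary pixels the entropy threshold misassigns.

Letter displays then summarise the tissue effect (groups sharing no
letter differ at α = 0.05):

```python
groups = {t: table[(table.tissue == t) & (table.variable == "t2_2")].value
          for t in ("pith", "cortex", "flesh")}
out = tx.compare_many(groups, grouping_factor="tissue")
print(out.letters)   # {'pith': 'a', 'cortex': 'b', 'flesh': 'b'}
```

The same chain is available from the shell:

```sh
tuberelax run --out results/demo --seed 1
tuberelax phantom generate --out results/demo --seed 1
tuberelax segment run --image results/demo/phantom.tiff --out results/demo
tuberelax relax fit --image results/demo/phantom.tiff \
    --labels results/demo/labels.tiff --out results/demo
tuberelax stats compare --table results/demo/fits.csv --by tissue \
    --out results/demo
```

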