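# laglayer

Lag-resolved layered-embedding encoding analysis for event-locked neural
recordings.

## The scientific problem

Layered language models transform each word's representation through a stack
of nonlinear layers. A natural question for the neuroscience of language is
whether this *spatial* hierarchy of layers maps onto the *temporal* dynamics
of cortical activity during comprehension: do embeddings from deeper layers
best predict neural activity at later times relative to word onset?

`laglayer` implements the full analysis needed to ask that question with
intracranial (ECoG-style) recordings:

1. **Encoding models.** For every combination of electrode, layer and lag, an
   ordinary least-squares regression predicts the mean high-gamma signal in a
   200 ms window centred at `onset + lag` from that layer's per-word
   embeddings (reduced to 50 principal components per layer, fold-safe).
   Ten-fold cross-validation yields one held-out prediction per word, and the
   performance is the Pearson correlation `r = corr(ŷ, y)` across words.
2. **The lag-layer statistic.** For each layer ℓ with encoding curve
   `r_ℓ(λ)` over lags λ, the peak lag is `λ*_ℓ = argmax_λ r_ℓ(λ)`. The
   headline statistic is the Pearson (and Spearman) correlation between the
   layer index ℓ and `λ*_ℓ`. A positive correlation means deeper layers peak
   later in time.
3. **Inference.** Significance comes from (a) the exact null distribution of
   the sample Pearson correlation, (b) a layer-index permutation test
   (indices shuffled, peak lags fixed, add-one p-value), and (c) an
   *interpolation control*: pseudo-layers built by linearly interpolating
   between the first and last layers' embeddings, which mimic a trivial
   "mixture of previous and current word" account — a real layered hierarchy
   must beat them.
4. **Screening and contrasts.** Phase-randomization surrogates with a
   max-over-lags/max-over-electrodes null and Benjamini–Hochberg FDR select
   responsive electrodes; Levene's test compares peak-lag spread between
   regions; paired t-tests contrast peak lags across predictability
   conditions; per-word orthogonalization removes the best layer's
   information from any other layer.
5. **Synthetic ground truth.** A generator plants a configurable lag-layer
   gradient: each layer's information drives each electrode inside a
   Hamming-shaped window at a planted, layer-specific lag with a chosen
   signal-to-noise ratio. Three regimes — a nonlinear layer chain, a linear
   interpolation chain, and an i.i.d. null — make every inferential claim
   testable without any external data. Symbolic psycholinguistic embeddings
   (phoneme features, morpheme one-hots, POS/TAG syntax, dense token
   semantics) provide the classical baseline representations.

Who it is for: researchers who want to run, extend, or stress-test
lag-resolved layer-wise encoding analyses on their own recordings or on
simulated data with known ground truth.

## Worked example

```python
import laglayer as ll

# A desk-scale dataset: 800 words, 24 nonlinearly chained layers, 4
# electrodes, planted peak lags rising from -100 ms to +400 ms, SNR 2.
cfg = ll.SyntheticConfig(seed=1)
ds = ll.generate_neural_dataset(cfg)

rec = ll.smooth_hamming(ll.despike(ds.recording))
enc = ll.EncodingConfig(lag_min=-500, lag_max=700, lag_step=25,
                        window=200, pca_k=50)
events = ds.events.assign_folds(enc.n_folds)

tensor = ll.encode_layerwise(rec, events, ds.embeddings, enc)   # (4, 24, 49)
mat = ll.average_over_electrodes(tensor)                        # (24, 49)
res = ll.lag_layer_analysis(mat, tensor.lags, tensor.layer_ids,
                            K=10_000, seed=1)
print(f"lag-layer r = {res.r_pearson:.3f}, "
      f"exact p = {res.p_exact:.2e}, permutation p = {res.p_permutation:.2e}")
```

Output:

```
lag-layer r = 0.995, exact p = 8.13e-24, permutation p = 1.00e-04
```

The planted gradient is recovered almost perfectly (`r ≈ 0.99` against a
planted Pearson correlation of 1.0 for the lag map itself), the exact p-value
is far below any conventional threshold, and the permutation p sits at its
add-one floor `1/(K+1)` — no shuffled layer ordering comes close.

The same analysis is scriptable from a shell:

```bash
laglayer run --out myrun --seed 1        # simulate -> preprocess -> encode -> stats
laglayer report --enc myrun/encoding.h5 --out myrun/report.png
```

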