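# crossmap

Tools for **zero-shot language-to-vision mapping**: estimating a linear map
from distributional word vectors onto visual feature vectors, and for
evaluating — behaviourally and statistically — how well such a map
extrapolates to words that have no visual training data at all.

## The problem

Distributional semantic models (word2vec-style embeddings) encode word
meaning from text co-occurrence alone; deep-CNN penultimate-layer
activations encode what things look like.  If the two geometries are
systematically related, a simple map between them lets a model *imagine*
what a word's referent looks like — even for words it never saw an image
of.  The interesting scientific questions are *where* this works: does it
fail for abstract words, or for words that are linguistically far from all
visually grounded vocabulary?

`crossmap` implements the full experimental pipeline around that question:

1. **Mapping** — given a language space `L` and an image-feature inventory,
   estimate `M` by least squares so that `v̂ = M·l` for word vector `l` and
   (SVD-reduced) visual vector `v`:

   `M = argmin Σᵢ ‖vᵢ − M·lᵢ‖²`   (no intercept, no regularisation by default)

   in two training regimes: *prototype* (one pair per label, the mean of
   its image vectors) and *exemplar* (k individual image vectors per
   label, default k = 20).  The visual side is reduced from its raw
   dimensionality (e.g. 4096) to d′ = 300 by truncated SVD, separately per
   regime.

2. **Retrieval** — predictions are cashed out as images: the exemplar
   scheme retrieves the image with maximal cosine to `v̂`; the prototype
   scheme first retrieves the most similar prototype and then the image
   most similar to *that prototype*.

3. **Neighborhood metrics** — how a target word sits relative to the
   visually grounded ("training") part of the lexicon: the number of
   training labels among its k = 50 nearest neighbors, the rank and cosine
   of the nearest training item, and the mean rank / mean cosine over all
   training items: `mts(w) = (1/n) Σᵢ cos(w, tᵢ)`.

4. **Item selection** — two designs for 2AFC experiments: a five-condition
   design crossing a concreteness median split with far/near/maximum
   visual-neighbor conditions (23 items each, 115 total), and a binned
   decorrelation sampler (10×10 equal-width grid, ≤4 items per cell) that
   weakens the natural correlation between concreteness and mean
   training-item similarity.

5. **Simulation** — a synthetic-world generator producing coupled
   language/vision spaces with a planted linear map and a tunable
   concreteness–groundedness correlation, plus a 2AFC choice simulator
   with participant and item random intercepts and catch trials.

6. **Analysis** — mixed-effects logistic regression with crossed random
   intercepts (Laplace approximation), likelihood-ratio backward
   elimination of fixed effects, Wald inference, marginal/conditional R²
   (with π²/3 as the logistic residual variance), catch-trial exclusions
   and per-condition performance summaries.

## Worked example

```python
import numpy as np
from crossmap import (
    SyntheticWorldConfig, generate_world,
    CrossModalMapping, retrieve_image, ImageInventory,
)

world = generate_world(SyntheticWorldConfig(
    n_words=500, lang_dim=24, vis_dim=32, n_training_labels=120,
    images_per_label=10, noise_sd=0.2, seed=7,
))

model = CrossModalMapping.from_spaces(
    world.lang, world.inventory, regime="exemplar",
    target_dim=24, exemplar_k=10, seed=7,
).fit()
print(model.summary())

# zero-shot: predict an image for a word with no visual training data
word = [w for w in world.lang.labels if w not in set(world.training_labels)][0]
v_hat = model.predict(world.lang.vector(word))
reduced = ImageInventory(
    world.inventory.image_ids, world.inventory.labels,
    model.projection.transform(world.inventory.matrix),
)
print(word, "->", retrieve_image(v_hat, reduced, scheme="exemplar"))
```

Output:

```
Cross-modal linear mapping (least squares, no intercept)
========================================================
regime:           exemplar
input dim:        24
output dim:       24
training pairs:   1200
training labels:  120
solver rank:      24
residual SSQ:     1174.09
w00120 -> w00024_img002
```

The summary reports the training regime, the dimensions of `M`
(`input dim × output dim`), how many (word, image) pairs the estimate used
and the residual sum of squares.  The last line is the zero-shot
retrieval: the predicted visual vector for a word outside the training set
resolves to a concrete image id from the inventory.

The same pipeline is scriptable from the shell:

```bash
crossmap simulate --design exp12 --k 8 --seed 7 --out data/
crossmap analyze --trials data/trials.csv --design exp12 --out report/
```

which writes a fit report (coefficients, variance components, elimination
trace, R²) as JSON and a readable table.

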