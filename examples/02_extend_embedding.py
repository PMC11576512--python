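"""Extend the dimension embedding to new images via ridge regression.

Dimension values are known only for the images the behavioural embedding
was trained on; a per-dimension ridge map from image feature vectors
(synthetic here) predicts them for any image.
"""

import numpy as np

from objdim import (fit_dimension_predictor, generate_embedding,
                    predict_dimensions)

rng = np.random.default_rng(0)
emb = generate_embedding(400, 66, seed=0)

# synthetic image features: noisy linear mixtures of the true dimensions
mixing = rng.normal(size=(66, 128))
features = emb.values @ mixing + 0.2 * rng.standard_normal((400, 128))

predictor = fit_dimension_predictor(features, emb, seed=0)
predicted = predict_dimensions(predictor, features)

print(f"cross-validated explained variance per dimension: "
      f"median {np.median(predictor.cv_score):.3f}, "
      f"min {predictor.cv_score.min():.3f}")
print(f"chosen ridge penalties span "
      f"{predictor.chosen_penalty.min():g} .. {predictor.chosen_penalty.max():g}")
print(f"fraction of negative predicted values: {np.mean(predicted < 0):.3f}")
print("-> predictions are deliberately not clipped at zero; rectification")
print("   happens later, in the tuning-profile and sparseness analyses.")
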