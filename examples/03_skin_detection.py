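"""Histogram-likelihood skin detection on simulated pixel data.

Draws a labeled pixel database (Gaussian skin cloud vs off-skin
uniform colors), trains the paired 32x32x32 histograms and measures
held-out accuracy of the likelihood-ratio classifier.
"""

import numpy as np

import facecolor as fc

train = fc.simulate_skin_patches(10000, 10000, seed=21)
model = fc.train_skin_model(
    train.loc[train.label == "skin", ["R", "G", "B"]].to_numpy(),
    train.loc[train.label == "nonskin", ["R", "G", "B"]].to_numpy())
print(f"trained: {model.skin_hist.size} bins/class, "
      f"{model.skin_count} skin / {model.nonskin_count} nonskin pixels")

held = fc.simulate_skin_patches(2000, 2000, seed=22)
img = (held[["R", "G", "B"]].to_numpy().astype(float) / 255.0).reshape(1, -1, 3)
pred = fc.classify_image(img, model)[0]
truth = (held["label"] == "skin").to_numpy()
print(f"held-out accuracy: {100 * (pred == truth).mean():.1f}%  (n = {len(held)})")
print("a tie (equal likelihoods) is classified nonskin:",
      fc.classify_pixel((100, 100, 100),
                        fc.train_skin_model([[100] * 3], [[100] * 3])))
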