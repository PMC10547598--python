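# rootsense

Image-based prediction of boiled sweetpotato root sensory attributes —
flesh-colour intensity (0–10 anchored scale) and mealiness by hand (0–10) —
from RGB photographs of root cross-sections.

The pipeline mirrors a deployed phenotyping workflow:

1. **synthgen** – synthetic boiled-root scenes with exact ground truth
   (masks, boxes, colour/mealiness scores), so every stage is testable with
   no external data. Flesh colour is encoded by a six-anchor palette
   (0 white, 1 cream, 3 yellow, 5 yellow-orange, 8 orange, 10 deep orange);
   mealiness by a monotone speckle-grain texture.
2. **detection** – training-free root detector (background-contrast map →
   Otsu → morphology → connected components) plus IoU / mAP@0.5 evaluation
   for any detector, including imported external detections.
3. **segmentation** – per-ROI 2-cluster K-means background elimination;
   border-majority cluster selection; background set to black.
4. **features_colour** – mean RGB, per-channel histograms, dominant colours
   via K-means, and mean HSV / CIELAB (D65) of the masked root pixels.
5. **features_texture** – graininess statistics (Canny-style edge density,
   connected components, gradient magnitude, local variance) restricted to
   the mask interior, plus a pluggable embedding interface with an offline
   handcrafted default.
6. **modelling** – linear / KNN / decision-tree / SVM / random-forest /
   gradient-boosting regressors and a small custom neural network with
   early stopping on validation MAE; classification on the discrete scale
   codes; MAE/MSE/R², macro precision/recall/F1, cross-validation, and
   per-variety error analysis.
7. **data_io / cli** – PNG/JPEG/TIFF images, sensory ground-truth CSVs,
   normalized centre-format box annotations, prediction CSV export, and a
   click CLI orchestrating the whole pipeline.

## Test

```sh
python -m pytest -q
```

The suite includes per-module unit tests, hypothesis property tests, and
`tests/test_acceptance.py` which checks the acceptance criteria (worked
table examples, split counts, synthetic parameter-recovery R² ≥ 0.80,
colour-clustering agreement ≤ 5 levels, and the property suites).

## CLI

```sh
rootsense synth    --n-images 200 --out data --seed 42 --noise-sd 5
rootsense detect   --images data/images --out runs/det
rootsense segment  --images data/images --out runs/seg
rootsense features --images data/images --ground-truth data/ground_truth.csv \
                   --out runs/features.csv
rootsense train    --features runs/features.csv --attribute flesh_colour \
                   --family random_forest --out runs/model.pkl
rootsense evaluate --features runs/features.csv --model runs/model.pkl \
                   --out runs/report.json
rootsense predict  --images data/images --model runs/model.pkl \
                   --out runs/predictions.csv
```

Stage parameters can also be set in a TOML config passed with `--config`
(sections `[detection]`, `[segmentation]`, `[colour]`, `[texture]`); flags
override file values.

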