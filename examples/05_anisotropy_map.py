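"""End-to-end anisotropy mapping: train on one half, map the unseen half.

Mirrors the embryo-scale workflow: a single large annotated image is split at
mid-height, an axes-only (2-output) CNN is trained on the top windows with
20% validation, and the bottom half's anisotropy map is predicted and
compared with its ground truth.
"""

import numpy as np

from epishape import (
    ArchSpec,
    TissueSpec,
    TrainConfig,
    chicken_workflow,
    generate_tissue,
    ground_truth_map,
)

tissue = generate_tissue(
    TissueSpec(height=512, width=512, mean_cell_area=1600.0,
               stretch_factor=1.8, orientation_mode="smooth", seed=12)
)

# a reduced variant of the 3x(64@5) mapping architecture keeps this demo fast
arch = ArchSpec([(16, 5), (16, 5), (16, 5)], n_outputs=2)
shape_map, model, report = chicken_workflow(
    tissue.image, tissue.labels, arch=arch,
    config=TrainConfig(max_epochs=10, seed=0),
)

truth = ground_truth_map(tissue.labels[512 // 2:], tile=128, overlap=0.25)
print(f"training windows      : {report['n_train_windows']}")
print(f"map size              : {shape_map.shape[0]} x {shape_map.shape[1]} "
      "(one pixel per 128x128 window, 25% overlap)")
print(f"predicted anisotropy  : {np.nanmean(shape_map.anisotropy):.3f} (map mean)")
print(f"true anisotropy       : {np.nanmean(truth.anisotropy):.3f}")
print(f"anisotropy MAE        : {report['mae_anisotropy']:.3f}")
shape_map.to_csv("anisotropy_map.csv")
print("map written to anisotropy_map.csv (row, col, L, l, alpha, anisotropy)")
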