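"""Evaluate a multi-label prediction matrix with micro-F and macro-F.

Builds a toy 6-document, 4-label task, scores an imperfect prediction and
prints both label-based F-measures. Micro-F pools tp/fp/fn over labels and
so is dominated by the frequent label; macro-F averages per-label F1 and
punishes mistakes on rare labels much harder.
"""

import numpy as np

from mule import LabelMatrix, confusion_counts, macro_f, micro_f, per_label_f1

gold = LabelMatrix.from_dense(np.array([
    #  L0 L1 L2 L3
    [1, 0, 0, 0],
    [1, 1, 0, 0],
    [1, 0, 0, 0],
    [1, 0, 1, 0],
    [1, 0, 0, 0],
    [1, 0, 0, 1],
]))

# the model nails the frequent label L0 but misses the rare L2 and L3
pred = LabelMatrix.from_dense(np.array([
    [1, 0, 0, 0],
    [1, 1, 0, 0],
    [1, 0, 0, 0],
    [1, 0, 0, 0],
    [1, 1, 0, 0],
    [1, 0, 0, 0],
]))

counts = confusion_counts(pred, gold)
print("per-label F1:", np.round(per_label_f1(counts), 3))
print(f"micro-F = {micro_f(counts):.4f}   (frequent-label mistakes dominate)")
print(f"macro-F = {macro_f(counts):.4f}   (each label weighs 1/L, rare misses hurt)")
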