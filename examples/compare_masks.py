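"""Compare a perturbed 'prediction' against its ground-truth mask.

Shows the full overlap report: Dice, Hausdorff and mean surface distance,
conformity index, both directions of the degree of inclusion, and the
center-of-mass motion vector decomposed into LR/AP/CC.
"""

from etecim import PerturbationSpec, compare_masks, perturb_mask
from etecim.phantoms import PhantomSpec, make_ellipsoid_mask

gt = make_ellipsoid_mask(
    PhantomSpec(shape="ellipsoid", lattice=(20, 48, 48), spacing=(1.0, 1.0, 2.5),
                semi_axes=(12.0, 10.0, 15.0))
).mask
pred = perturb_mask(
    gt, PerturbationSpec(translation=(2, 1, 1), boundary_flip_rate=0.15, seed=11)
)

rep = compare_masks(pred, gt)
print(f"DSC                 : {rep.dsc:.3f}   (1 = perfect overlap)")
print(f"conformity index    : {rep.ci:.3f}   (Jaccard; DSC = 2 CI/(1+CI))")
print(f"Hausdorff distance  : {rep.hd:.2f} mm  (worst surface mismatch)")
print(f"mean surface dist   : {rep.msd:.2f} mm")
print(f"DI(pred in gt)      : {rep.di_pred_in_gt:.3f}   (1 - this = overtreated fraction)")
print(f"DI(gt in pred)      : {rep.di_gt_in_pred:.3f}   (1 - this = missed fraction)")
print(f"COM shift LR/AP/CC  : {rep.lr:+.2f} / {rep.ap:+.2f} / {rep.cc:+.2f} mm")
print(f"motion vector       : {rep.mv:.2f} mm")
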