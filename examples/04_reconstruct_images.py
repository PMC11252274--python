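"""Reconstruct stimuli from EEG with the toy double-conditioned LDM.

Runs the whole reconstruction study at a very small scale: parametric
stimulus images -> latent autoencoder -> unconditionally pretrained
denoiser -> EEG encoder (EEGNet+) -> selective fine-tuning of encoder +
cross-attention + projectors -> PLMS sampling -> n-way top-1 evaluation
with the inter-trial null control.  Takes a few minutes on one CPU core.
"""

from vepdecode.experiments import ReconstructionContrastConfig, \
    reconstruction_contrast
from vepdecode.sim import SessionSpec

cfg = ReconstructionContrastConfig(
    spec=SessionSpec(n_classes=8, images_per_class=15),
    n_way=8, max_test_images=40, max_null_windows=40,
    plms_steps=15, ae_epochs=20, pretrain_epochs=15, finetune_epochs=6)
res = reconstruction_contrast(seed=1, cfg=cfg)

pct = lambda x: f"{100 * x:.1f}%"
print(f"encoder test accuracy:        {pct(res['encoder_test_accuracy'])}")
print(f"best-of-5 {cfg.n_way}-way top-1:      {pct(res['best_of_samples'])}")
print(f"mean-of-5 {cfg.n_way}-way top-1:      {pct(res['mean_of_samples'])}")
print(f"null control mean-of-5:       {pct(res['null_mean_of_samples'])}")
print(f"chance level:                 {pct(res['chance'])}")
print(f"stimulus-driven excess:       {res['excess_in_se']:.1f} standard errors")
print(f"null offset from chance:      {res['null_offset_in_se']:.1f} standard errors")
print(f"point-biserial r (classifier correct vs reconstruction): "
      f"{res['point_biserial_r']:.2f}")
print(f"frozen UNet backbone unchanged: {res['frozen_backbone_unchanged']}")
# Real trials reconstruct their class far above chance; gray-screen segments
# (no stimulus information) stay at chance on the mean-over-samples
# aggregate (best-of-5 is an order statistic and sits above chance even for
# stimulus-independent input) — the contrast shows the model is driven by
# the EEG input, not by the generative prior alone.
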