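# vessnet

Pixel-wise retinal blood-vessel segmentation with a dual-residual-stream
encoder–decoder, plus the pieces around it that make a vessel-segmentation
study runnable end to end: deterministic dataset augmentation, a
class-balanced training recipe, pixel-wise evaluation metrics, a
vessel-pixel-count retinopathy screening rule, and a seeded synthetic-fundus
generator so the whole pipeline works without any clinical download.

Retinal vessels are a biomarker: diabetic retinopathy shows up as vessel
growth (leakage, neovascularization), hypertensive retinopathy as vessel
narrowing. Both start from an accurate binary vessel mask of a fundus
photograph — a hard segmentation problem because vessels are thin,
low-contrast, and outnumbered roughly 9:1 by background pixels.

## The network

Vess-Net is a 16-convolution-layer encoder–decoder (four blocks a side, two
3×3 convolutions per block, each with batch normalization) threaded by two
residual streams:

* **Inner stream — six projection skip paths (IRSP-1..6).** In every block
  except the first encoder and last decoder block, the block input is
  passed through a 1×1 convolution + BN and added elementwise to the output
  of the block's second convolution:

  encoder: `Yᵢ = S(Eᵢ) + F(Eᵢ)`  decoder: `Zⱼ = S′(Dⱼ) + F(Dⱼ)`

  where `S`/`S′` are the second-convolution outputs and `F` the projected
  block inputs.

* **Outer stream — four identity skip paths (ORSP-1..4).** The activation
  after the first ReLU of encoder block *i*, `T(Eᵢ)`, is added unchanged
  after the first ReLU of the matching decoder block:

  `T′(Dⱼ) = K(Dⱼ) + T(Eᵢ)`

Downsampling is 2×2 max pooling with stored argmax indices; the decoder
upsamples by index-preserving max unpooling, so odd sizes
(447 → 223 → 111 → 55 → 27) round-trip exactly and the deepest feature map
stays at 27×27 for a 447×447 input. The final 3×3 convolution has two
filters (vessel / non-vessel); softmax gives per-pixel class probabilities.

Training follows the published recipe: cross-entropy weighted by
median-frequency class balancing (`w_c = median(freq)/freq_c`), Adam with
constant learning rate 5·10⁻⁴ and denominator epsilon 10⁻⁶, mini-batches of
7 with partial batches dropped, 15 epochs with reshuffling, gradient
clipping by global L2 norm. The network and its gradients are implemented
directly on NumPy (im2col convolutions, explicit reverse-mode passes), so
no deep-learning framework is required.

Evaluation is pixel-wise: `Se = tp/(tp+fn)`, `Sp = tn/(tn+fp)`,
`Acc = (tp+tn)/total`, and AUC of the ROC swept over all probability
thresholds. Screening compares vessel-pixel counts of two registered
visits: a relative change beyond a threshold (default ±5%) flags
diabetic-suspect (growth) or hypertensive-suspect (shrinkage).

## Worked example

`python examples/train_and_evaluate.py` trains a width-scaled network
(base 8 channels) on 36 flip-expanded 64×64 synthetic pairs for the
standard 15-epoch schedule and evaluates 4 held-out pairs:

```
epoch  loss    train-acc
    1  0.8095  0.6120
    8  0.5344  0.7442
   15  0.4251  0.7988

held-out (4 images, pooled pixels):
  Se  = 0.9432   (vessel pixels recovered)
  Sp  = 0.8258   (background pixels kept)
  Acc = 0.8389
  AUC = 0.9484   (threshold-free separability)
```

The class-balanced loss deliberately trades specificity for sensitivity:
94% of vessel pixels are recovered even though vessels are only ~11% of
the image. Other examples: `examples/architecture_table.py` (the full
layer/parameter table, e.g. ECon-4_2 at 2,359,808 + 1024 parameters),
`examples/synthesize_and_augment.py` (the deterministic 20 → 1920
expansion), `examples/screen_visits.py` (a +13% vessel-count change
flagged as diabetic-suspect).

A thin CLI wraps the same calls:

```
vessnet plan --size 447
vessnet synth --n 32 --size 128 --seed 1 --out data/
vessnet train --data data/ --out model.npz
vessnet evaluate --model model.npz --data data/ --out report.tsv
vessnet screen --prev visit1_mask.png --curr visit2_mask.png
```

## Scope

The package does not ship clinical data, downloaders, or pretrained
weights, and the synthetic generator makes no claim of photorealism — see
`docs/methods.md` for what the synthetic results do and do not show about
real fundus photographs.
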