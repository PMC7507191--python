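"""Optimal-integration predictions from unisensory thresholds.

Given one subject's audio and visual thresholds, the maximum-likelihood
model predicts the bimodal threshold (always below the better unisensory
one) and the PSE shift under each audio-visual conflict.  With equal
thresholds the weights are equal, conflicts cancel, and the combined
variance is halved; with strong auditory dominance the PSE follows the
audio stimulus (-delta).
"""

from tempobind import mle_threshold, mle_weights, predict_from_unisensory

for sigma_v, sigma_a, label in [
    (200.0, 100.0, "precise audition (typical-like)"),
    (300.0, 300.0, "equal noise (dyslexic-like)"),
]:
    pred = predict_from_unisensory(sigma_v=sigma_v, sigma_a=sigma_a)
    print(f"{label}: sigma_V={sigma_v:.0f} ms, sigma_A={sigma_a:.0f} ms")
    print(f"  weights        w_V={pred.w_v:.2f}, w_A={pred.w_a:.2f}")
    print(f"  bimodal sigma  {pred.sigma_va:.1f} ms "
          f"(vs best unisensory {min(sigma_v, sigma_a):.0f} ms)")
    shifts = {d: f"{s:+.1f}" for d, s in pred.predicted_shift.items()}
    print(f"  predicted PSE shift per conflict (ms): {shifts}\n")

print("equal-noise sanity check: combined threshold = sigma / sqrt(2):",
      f"{mle_threshold(300, 300):.1f} ms")
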