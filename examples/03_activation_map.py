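"""Where does the backbone look? Activation map of one axial slice.

Computes the channel-averaged last-convolution activation for a mid-brain
slice and a blank padded slice, and writes a heatmap overlay PNG. The
padded slice shows no activation at all, confirming that blank padding is
non-informative.
"""

from pathlib import Path

from slicemap import (BackboneSpec, PhantomSpec, build_extractor, compute_cam,
                      make_phantom_volume, overlay, preprocess_array)

spec = PhantomSpec(n_per_class=1, native_slices=150, in_plane=192, slice_jitter=0, seed=3)
stack = preprocess_array(make_phantom_volume(1, spec, subject_seed=2))
extractor = build_extractor(BackboneSpec())

mid = stack.n_slices // 2
hm_brain = compute_cam(extractor, stack.data[mid], source_slice_index=mid)
hm_blank = compute_cam(extractor, stack.data[0], source_slice_index=0)
print(f"brain slice {mid}: activation range [{hm_brain.values.min():.2f}, "
      f"{hm_brain.values.max():.2f}]")
print(f"blank slice 0:  activation max {hm_blank.values.max():.2f} (no response)")

out = Path("scratch/cam_overlay.png")
out.parent.mkdir(parents=True, exist_ok=True)
overlay(hm_brain, stack.data[mid, :, :, 0], alpha=0.4, out_path=out)
print("overlay written to", out)
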