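"""Pre-process one phantom into the 180x180 tumor slice the CNN consumes.

The pipeline resamples in-plane to 1x1 mm, masks the scan to the GTV,
picks the slice with the largest tumor area, crops 180x180 pixels around
the tumor centroid, windows the HU values (default level 125 / width 350),
smooths with a Gaussian, and clips to [0, 1].
"""

from hncnet.phantom import PhantomSpec, generate_phantom_volume
from hncnet.preprocess import PreprocessConfig, WindowSpec, preprocess_case, quantize_png8, write_png

spec = PhantomSpec(texture_heterogeneity=40.0, seed=3)
vol, mask = generate_phantom_volume(spec)
print(f"volume {vol.shape} at spacing {vol.spacing} mm, GTV voxels: {mask.voxels.sum()}")

ts = preprocess_case(vol, mask, PreprocessConfig(window=WindowSpec(125, 350)))
print(f"selected slice index: {ts.source_slice_index}")
print(f"tumor centroid (row, col): {ts.tumor_center}")
print(f"output shape: {ts.pixels.shape}, range [{ts.pixels.min():.3f}, {ts.pixels.max():.3f}]")

write_png(quantize_png8(ts.pixels), "tumor_slice.png")
print("wrote tumor_slice.png (8-bit grayscale)")
print("-> background (outside the GTV) maps to 0; in-tumor texture sits in")
print("   mid-gray because the window is centered on soft-tissue HU.")
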