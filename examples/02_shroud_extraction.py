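"""Extract the Amsterdam Shroud diaphragm waveform from projection stacks.

Each frame is log-transformed, differentiated vertically and collapsed to a
single column; the concatenated columns form the shroud image.  After
dual-imager superimposition, trimming and local normalization, the first
principal-component score of the columns is the respiratory waveform.
"""

import numpy as np

import as4dpm as m

schedule = m.build_schedule(1.5, 70, 0.3)
case = m.simulate_case(m.BreathingParams(seed=7), schedule)

# step by step for one imager
img = m.make_as_image(case.projections[0])
print(f"shroud image               : {img.n_rows} rows x {img.n_frames} frames")
trimmed = m.trim_as(img, "support")
print(f"trimmed to ridge band      : rows {trimmed.row_offset}.."
      f"{trimmed.row_offset + trimmed.n_rows - 1}")
normalized = m.local_normalize(trimmed)
single = m.extract_as_waveform(normalized)

# the convenience pipeline, dual-imager
dual = m.shroud_waveform(case.projections)

truth = case.diaphragm.values
for label, wav in (("single imager", single), ("dual imager", dual)):
    r = np.corrcoef(wav.samples, truth)[0, 1]
    print(f"corr(W_AS, diaphragm) {label:14s}: {r:.4f}")
print("values near 1 mean the shroud waveform faithfully tracks the "
      "diaphragm despite never seeing the ground truth")
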