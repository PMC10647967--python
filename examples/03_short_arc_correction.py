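"""Build the tiled short-arc waveform and correct it with the shroud signal.

The short-arc waveform compresses the 60 s training trajectory into one
8-phase cycle and stretches it back over every breathing cycle — cheap to
obtain without implanted markers, but low temporal resolution and (here,
emulated with a 0.7 shrink) amplitude-underestimating.  Global + local
matching against the shroud waveform restores amplitude and phase detail.
"""

import numpy as np

import as4dpm as m

schedule = m.build_schedule(1.5, 70, 0.3)
case = m.simulate_case(m.BreathingParams(seed=3), schedule)
prep = m.prepare_case(case, shrink_4d=0.7)

train = m.TRAIN_SLICE
truth = case.true_target.window(train)
w4d = prep.w_4d
shroud = m.shroud_waveform(case.projections)
corrected = m.correct_waveform(
    w4d, shroud.samples[train], m.MatchingParams(p_upper=85, p_lower=10, window=21)
)


def rmse(a, b):
    return np.sqrt(np.mean((a - b) ** 2))


si = m.AXES.index("SI")
print(f"SI RMSE vs truth, tiled short-arc  : {rmse(w4d.values[:, si], truth.values[:, si]):.2f} mm")
print(f"SI RMSE vs truth, shroud-corrected : {rmse(corrected.waveform.values[:, si], truth.values[:, si]):.2f} mm")
print(f"applied shroud signs (LR, SI, AP)  : {corrected.signs.tolist()}")
print("the correction narrows the gap left by phase-sorted averaging; the "
      "negative LR/AP signs reflect tumour motion anti-correlated with the "
      "diaphragm in those directions")
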