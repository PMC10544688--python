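"""Pairwise LDA decoding of two touch conditions with a permutation null.

Simulates seen vs. blind arm touches where only the seen condition drives
a planted response, then decodes the pair in each 0.5 s bin: trials are
split 100 times into balanced halves, reduced to the top SVD components
of the training half, and classified with a shared-covariance linear
discriminant.  Significance tiers compare the accuracy distribution with
a label-shuffled null at the 95/97.5/99% CI levels.
"""

import touchdecode as td
from touchdecode.decoding import results_to_frame
from touchdecode.preprocess import normalize_by_baseline, rebin

design = td.make_task_design(conditions=("FPa", "BLa"))
truth = td.make_ground_truth(design, gains={"FPa": (list(range(25)), 2.5)})
raw, _ = td.simulate_session(design, truth, seed=7)
bundle = rebin(normalize_by_baseline(raw.drop_catch()), 0.5)

results = td.run_pairwise(bundle, window=(-1.0, 2.0), n_splits=100, seed=0)
frame = results_to_frame(results)
print(frame.round(3).to_string(index=False))
print("\nBins before touch onset sit at chance (~0.5, ns); bins after "
      "onset decode the planted response (tier *** = disjoint 99% CIs).")
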