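"""Longitudinal two-arm cohort: high-RI growth and per-week statistics.

Generates the default scaled-down cohort (6 organoids per arm, 4 weeks,
media switch at week 4), runs the full imaging chain, and summarizes the
high-RI fraction per group and week with Welch tests on a directional-cell
feature.
"""

import warnings

import pandas as pd

from organoidqpi import (
    AcquisitionSpec,
    CohortSpec,
    ReconConfig,
    compute_dpc,
    generate_two_group_cohort,
    phase_to_ri,
    reconstruct_phase,
    segment_high_ri,
    simulate_qobm_acquisition,
    track_fraction,
)
from organoidqpi.features import FeatureConfig, extract_feature_table
from organoidqpi.stats import longitudinal_compare

warnings.filterwarnings("ignore")

cspec = CohortSpec(seed=0)
acq = AcquisitionSpec(snr_db=20.0)
model = acq.transfer_model()

images, metas, fracs = [], [], []
for phantom, meta in generate_two_group_cohort(cspec):
    raw = simulate_qobm_acquisition(phantom, acq)
    rim = phase_to_ri(reconstruct_phase(compute_dpc(raw), model, ReconConfig()))
    seg = segment_high_ri(rim, phantom.organoid_mask)
    m = {k: meta[k] for k in ("group", "week", "organoid_id")}
    fracs.append({"fraction": seg.area_fraction, **m})
    images.append(rim.n_abs)
    metas.append(m)

print("high-RI area fraction (mean ± sd) per group × week:")
print(track_fraction(pd.DataFrame(fracs)).to_string(index=False))

table = extract_feature_table(images, metas, 1.0, FeatureConfig(families=("fractal",)))
res = longitudinal_compare(
    table, ["directional_pattern_7um"], switch_week=cspec.differentiation_switch_week
)
print("\ndirectional-cell pattern feature, Welch p per week:")
print(res["per_week"][["week", "t_p"]].to_string(index=False))
# Expected pattern: overlapping arms before the media switch, then the
# control arm loses directional cells and high-RI content grows faster in
# the experimental arm — weeks after the switch become significant.
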