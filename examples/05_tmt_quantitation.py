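"""TMT quantitation stack: impurity correction to normalized log ratios.

Generates reporter-level PSMs for features with a known log2 fold change
of 1.0 between two channel groups, pushes them through the full stack
(quant filter -> Cramer's-rule impurity correction -> log2 ratios ->
median aggregation -> median/MAD normalization) and reports how well the
truth is recovered.  Writes the final matrix as GCT 1.3.
"""

import numpy as np

from psmkit import quant, simulate
from psmkit.io import write_gct
from psmkit.simulate import SyntheticConfig

cfg = SyntheticConfig(
    n_features=100, n_signal_features=40, psms_per_feature=50,
    log2_fc=1.0, noise_sigma=0.3, coisolation_fraction=0.0,
    reference_channel="131",
)
records, design, truth = simulate.generate_quant_dataset(cfg, seed=11)
ref = design.channels.index(design.reference_channel)

ratios_by_feature = {}
n_excluded = 0
for psm in records:
    if not quant.psm_quant_filter(psm):
        n_excluded += 1
        continue
    corrected, _ = quant.correct_reporters(psm.reporter_intensities,
                                           truth.impurity)
    ratios, flagged = quant.psm_log_ratios(corrected, "reference-channel", ref)
    if not flagged:
        ratios_by_feature.setdefault(psm.candidate_proteins[0], []).append(ratios)

matrix = quant.aggregate_feature_ratios(ratios_by_feature, design.channels)
normalized, flagged_channels = quant.median_mad_normalize(matrix)

group_a, group_b, _ = simulate.quant_channel_groups(cfg)
idx = {f: i for i, f in enumerate(normalized.feature_ids)}
errors = []
for fid, mu in truth.feature_log2.items():
    if np.all(mu == 0):
        continue
    row = normalized.values[idx[fid]]
    est = np.nanmean(row[group_a]) - np.nanmean(row[group_b])
    true_fc = mu[group_a].mean() - mu[group_b].mean()
    errors.append(est - true_fc if true_fc > 0 else true_fc - est)
errors = np.array(errors)

print(f"PSMs: {len(records)}  excluded by quant filter: {n_excluded}")
print(f"features quantified: {len(normalized.feature_ids)}")
print(f"fold-change bias: {errors.mean():+.4f}  RMSE: "
      f"{np.sqrt((errors**2).mean()):.4f}  (truth |log2 FC| = 1.0)")
write_gct(normalized, "quant_example.gct")
print("wrote quant_example.gct (GCT 1.3, NA = missing, ratio counts as"
      " row metadata)")
print()
print("Bias near zero means impurity correction, ratio policy, median")
print("aggregation and normalization jointly preserve true abundance.")
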