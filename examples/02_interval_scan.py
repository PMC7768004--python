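"""Scan the cognitive ERP for significant trust-vs-distrust intervals.

Simulates six participants at 64 channels with the default condition
effects (injected over 372-796 ms in the credibility-loop parcels), then
compares trusting vs distrusting trials bin-by-bin (10 ms Mann-Whitney
scan) and reports the maximal runs of consecutive significant bins.
"""

from trusteeg import (
    ChoiceModel,
    CognitiveSet,
    ExperimentSpec,
    build_head_model,
    cognitive_channel_indices,
    default_effects,
    simulate_decisions,
    simulate_epochs,
)
from trusteeg.erp import D_ALL, T_ALL
from trusteeg.scanstats import scan_case_pair

spec = ExperimentSpec(n_participants=6, n_channels=64, seed=2)
lead = build_head_model(n_channels=64, n_dipoles=592)
decisions = simulate_decisions(spec, ChoiceModel())
epochs = simulate_epochs(spec, decisions, lead, default_effects())
cog = CognitiveSet(cognitive_channel_indices(lead, 26))

result = scan_case_pair(epochs, T_ALL, D_ALL, cog, alpha=0.01)
print(f"scanned {len(result.p_values)} bins of 10 ms over [250, 800) ms")
for run in result.runs:
    print(
        f"  significant {run.start_ms:.0f}-{run.end_ms:.0f} ms"
        f" ({run.n_bins} bins, max p = {run.p_summary:.2g})"
    )
longest = result.longest_run
print(
    f"longest joint interval: {longest.start_ms:.0f}-{longest.end_ms:.0f} ms;"
    " it should overlap the injected 372-796 ms window."
)
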