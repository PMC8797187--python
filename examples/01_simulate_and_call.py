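"""Simulate a knockdown experiment and call ADAR-dependent editing sites.

Builds a small synthetic transcriptome with 12 planted A-to-I editing sites
that vanish in the adar2 knockdown, simulates 4 control / 4 adar1 / 4 adar2
replicates plus a genomic DNA sample, and runs the contrast caller.
"""
from adarcall import CallerConfig, SimConfig, call_sites, evaluate_recovery, run_in_memory

cfg = SimConfig(
    n_transcripts=8,
    length_range=(800, 1000),
    n_edit_sites=12,
    control_freq_range=(0.15, 0.6),  # editing levels in the control animals
    kd_reduction=1.0,                # complete loss upon knockdown
    coverage_rna=60,
    error_rate=1e-3,
    seed=7,
)

data = run_in_memory(cfg, conditions=("adar1", "adar2"))

for condition in ("adar1", "adar2"):
    calls = call_sites(data.pileups, data.sheet, condition, data.consensus, CallerConfig())
    print(f"{condition} contrast: {len(calls)} sites called")
    for c in calls[:5]:
        print(
            f"  {c.transcript_id}:{c.pos + 1} {c.mismatch_class}"
            f"  control freq {c.mean_control_freq:.2f} -> kd {c.mean_kd_freq:.2f}"
            f"  (reduction {c.reduction:.0%})"
        )

stats = evaluate_recovery(data.truth, calls, "adar2")
print(f"\nprecision {stats.precision:.2f}, recall {stats.recall:.2f} "
      f"against the {len(data.truth.edit_sites)} planted sites")
# The adar1 contrast finds ~nothing because the sites were planted as
# adar2-dependent: their frequency is unchanged in adar1 knockdowns, so the
# >= 50%-reduction filter rejects them. The adar2 contrast recovers the
# planted sites whose read evidence clears the frequency/coverage/support
# floors in every control replicate.
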