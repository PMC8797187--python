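"""Mismatch spectrum and sequence context of called editing sites.

A-to-I editing shows up as A>G mismatches on the edited strand and T>C on
antisense-assembled transcripts; their joint share of all calls is the
editing signature. The +/-5 nt context matrix feeds sequence-logo drawers.
"""
from adarcall import SimConfig, call_sites, context_matrix, run_in_memory, spectrum

cfg = SimConfig(
    n_transcripts=10,
    n_edit_sites=20,
    control_freq_range=(0.2, 0.6),
    antisense_fraction=0.3,  # ~30% of transcripts assembled antisense -> T>C calls
    coverage_rna=60,
    seed=11,
)
data = run_in_memory(cfg, conditions=("adar2",))
calls = call_sites(data.pileups, data.sheet, "adar2", data.consensus)

spec = spectrum(calls)
print("mismatch spectrum (nonzero classes):")
for cls, n in spec.counts.items():
    if n:
        print(f"  {cls}: {n}")
print(f"A-to-I signature: {spec.signature_count}/{spec.total} "
      f"= {spec.signature_fraction:.0%} of calls are A>G or T>C\n")

seqs = {tid: data.consensus.sequence(tid) for tid in data.consensus.transcripts}
cm = context_matrix(calls, seqs, flank=5)
print("context matrix (rows A/C/G/T, columns -5..+5):")
print(cm.to_frame().to_string())
print("\nThe center column (offset 0) counts the edited base itself; its mass"
      "\nsits on A and T because every call is A>G or T>C in transcript space.")
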