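"""Full automated BAT workflow on one synthetic donor.

Simulates an allergic, IgE-responsive donor (unstimulated tube, anti-IgE
positive control, one allergen tube), runs the automated analysis —
pregating, threshold calibration on the unstimulated tube, frozen
threshold application — and prints the per-tube readouts and the calls.
"""

from binbat import SyntheticProfile, WorkflowConfig, analyze_experiment, generate_experiment

profile = SyntheticProfile(allergic=True, responder=True)
experiment = generate_experiment(profile, n_events=50_000, seed=11,
                                 donor_id="DEMO", allergen_name="birch")
result = analyze_experiment([(table, meta) for table, meta, _ in experiment],
                            WorkflowConfig())

print(f"donor {result.donor_id}")
for s in result.samples:
    flags = ", ".join(f.code.value for f in s.qc_flags) or "none"
    print(f"  {s.meta.condition.value:9s} gated={s.n_gated:6d} "
          f"basophils={s.n_basophils:4d} CD63+={s.cd63_pos_pct:5.2f}% "
          f"CD32+={s.cd32_pos_pct:5.2f}%  QC: {flags}")
print(f"responder status : {result.responder_status.value}")
for allergen, call in result.allergen_calls.items():
    print(f"allergen {allergen!r} : {call.value}")
print()
print("CD63+% is the activation readout among basophil-quadrant events; the")
print("unstimulated tube sits near the calibrated 1% floor, the positive")
print("control and an allergy-positive tube rise far above it.")
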