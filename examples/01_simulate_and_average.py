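"""Simulate a visual Go/Nogo session and extract its IRP difference wave.

Generates a 120+120-trial session at 250 Hz, preprocesses it (average
reference, 1-45 Hz FIR, epoching, behavioral rejection, region pooling),
averages per condition and subtracts: IRP(t) = ERP_go(t) - ERP_nogo(t).
The printed correlation tells how well the extracted IRP matches the
informational components that were injected; the component table lists the
detected negative/positive waves near 400 ms per region.
"""

import numpy as np

import irplab as il

cfg = il.vice_config(seed=1, fs=250.0)
rec, gt = il.simulate_session(cfg)
epochs, repochs = il.preprocess_session(rec, target_fs=None)

erp_go = il.compute_erp(repochs, "go")
erp_nogo = il.compute_erp(repochs, "nogo")
irp = il.compute_irp(erp_go, erp_nogo)

print(f"kept trials: {irp.n_trials_go} Go + {irp.n_trials_nogo} Nogo")
corr = il.irp_template_correlation(irp, gt)
print(f"correlation(IRP, injected informational components) = {corr:.3f}")
print("(1.0 would be perfect recovery; background noise that the "
      f"{irp.n_trials_go}-trial average cannot cancel explains the rest)\n")

report = il.detect_components(irp)
present = report[report.present]
print("components detected (|amplitude| > 3 x baseline SD):")
print(present[["label", "region", "latency_s", "amplitude_uv"]]
      .to_string(index=False))
print("\nExpected for the visual preset: a negative wave (IN400) in "
      "FL/PL/OL and a positive wave (IP400) in FR near 0.4 s.")
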