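# irplab

Analysis of **information-related potentials (IRPs)** in Go/Nogo EEG
experiments: synthetic session simulation with known ground truth,
ERP/difference-wave extraction, single-trial decoding with common
spatial-spectral patterns, and directed brain-network analysis with partial
directed coherence.

## The problem

In a Go/Nogo paradigm where both stimulus classes share their physical and
elemental attributes and differ *only* in informational content (e.g. element
arrangements that do or do not form a meaningful object), the evoked
potentials decompose additively:

```
ERP_nogo(t) = ERP_p(t) + ERP_e(t)
ERP_go(t)   = ERP_p(t) + ERP_e(t) + ERP_i(t)
IRP(t)      = ERP_go(t) − ERP_nogo(t) = ERP_i(t)
```

The difference wave isolates the potentials evoked by the informational
attributes — low-frequency (1–6 Hz) components near 400 ms for visual
stimuli and near 750 ms for auditory ones. Because real recordings of such
experiments are rarely shared, `irplab` ships a first-class generator that
simulates 64-channel sessions under exactly this additive model (Gabor-atom
components over 8 scalp regions + 1/f background), so every stage of the
analysis can be validated against the injected ground truth:

- **`irplab.simulate`** — sessions, backgrounds, component templates,
  behavioral (RT/accuracy) draws;
- **`irplab.preprocess`** — resampling, average reference, zero-phase FIR
  band-pass, epoching with baseline correction, behavioral trial rejection,
  pooling into 8 regions (FL/FR/PL/PR/TL/TR/OL/OR);
- **`irplab.erp`** — ERPs, IRPs, component detection, Morlet time–frequency
  maps, paired t-tests and Cohen's d (pooled-SD form,
  `d = (m_a − m_b)/√((s_a² + s_b²)/2)`);
- **`irplab.decode`** — sliding-window (200/100 ms) CSP/CSSP features
  (delay τ = 12 ms), linear SVM, stratified 5-fold cross-validation;
- **`irplab.network`** — pooled-trial MVAR fits, partial directed coherence
  `pdc(i,j,f) = |Ā_ij(f)| / √(Σ_k |Ā_kj(f)|²)`, fixed-density directed
  graphs, Fagiolo clustering coefficients, Go-vs-Nogo group tables;
- **`irplab.pipeline` / `irp` CLI** — config-driven end-to-end runs with
  seed control and checksummed, reproducible outputs.

## Worked example

```python
import irplab as il

cfg = il.vice_config(seed=1, fs=250.0)          # 120+120-trial visual session
rec, gt = il.simulate_session(cfg)
epochs, regions = il.preprocess_session(rec, target_fs=None)

irp = il.compute_irp(il.compute_erp(regions, "go"),
                     il.compute_erp(regions, "nogo"))
print(il.irp_template_correlation(irp, gt))     # 0.971
print(il.detect_components(irp).query("present")
      [["label", "region", "latency_s", "amplitude_uv"]].head(4))
```

```
label region  latency_s  amplitude_uv
IN400     FL      0.416     -3.228613
IN400     PL      0.424     -2.654909
IN400     OL      0.392     -2.443310
IP400     FR      0.408      4.490792
```

The correlation of 0.971 says the extracted difference wave almost exactly
matches the injected informational components — the residual is background
noise that a 111-trial average cannot fully cancel.  The component table
recovers the injected topography: a negative wave (IN400) in the left
frontal/parietal/occipital regions and a positive wave (IP400) in the right
frontal region near 400 ms.  Decoding the same session
(`examples/02_decode_sliding_window.py`) gives a cross-validated accuracy
curve that sits at chance (≈0.5) before stimulus onset and peaks (→1.0 at
this noise level) in the windows covering the 400 ms component.

Each script in `examples/` demonstrates one capability end to end and
prints a short interpretation of its numbers.

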