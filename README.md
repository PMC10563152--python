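# apobd

Label-free detection and profiling of apoptotic bodies (ApoBDs) in
nanowell time-lapse microscopy.

## The problem

High-throughput killing assays confine a few immune effector cells and
tumor target cells in each well of a nanowell array and image them every
5 minutes in phase contrast plus fluorescence channels. The conventional
apoptosis readout — Annexin-V staining — is unreliable in such assays:
only roughly 30% of apoptotic events show a detectable Annexin-V signal.
Dying cells do, however, release apoptotic bodies — small membrane-bound
vesicles (0.5–2.0 µm) visible in phase contrast beyond the cell body —
which provide a label-free visual cue for cell death.

`apobd` implements the analysis around that cue, for assay developers
and image-analysis engineers working with nanowell (e.g. TIMING-style)
data:

1. **Per-frame ApoBD presence** — a classifier contract plus a classical
   baseline: scale-normalized Laplacian-of-Gaussian (LoG) blob detection
   at both polarities, adaptive flood-fill mask growth, and a shape
   filter (aspect ratio ≥ 0.85, area 20–200 px).
2. **Onset of apoptosis** — an event is called when ApoBDs are detected
   in ≥ 3 consecutive frames; the onset is the first frame of the first
   qualifying run. Evaluation uses the frame-error metric
   |t̂ − t| with a full-sequence-length penalty (10 frames) for missed
   or hallucinated events.
3. **Apoptotic-cell identification** — each segmented ApoBD instance is
   mapped to cells; the cell with the least average centroid distance
   d̄(c) = (1/K) Σₖ ‖x_c − xₖ‖ to the K ApoBD centroids is assigned as
   the dying cell, with a majority vote across three frames.
4. **Weak-label dataset generation** — surviving RoIs become automatic
   instance annotations (COCO-style JSON); rejected ApoBD-like objects
   are erased from the training image by a disk-kernel median fill
   restricted to an attention region, so a downstream segmentation
   network never sees an unannotated vesicle.
5. **Killing attribution and Annexin-V profiling** — a killing event
   requires effector–target mask overlap for more than three consecutive
   frames; Annexin-V is *valid* when IoU(annexin mask, cell mask) > 0.1,
   *evenly distributed* when IoU > 0.5 (else localized), and its
   polarization toward the immune synapse is quantified by Pearson
   correlation of the Annexin image against the cell and synapse masks.

Everything is testable without real data through a bundled synthetic
nanowell simulator that renders textured cells, vesicle bursts with a
configurable onset frame, fluorescence channels consistent with the
ground-truth masks, and a ~30% Annexin-positive event rate.

## Worked example

```python
from apobd import SimConfig, simulate_video, analyze_video

sim = simulate_video(SimConfig(onset_frame=4, contact_frames=4, seed=42))
res = analyze_video(sim.video, sim.truth.cells)

print("frame labels:", [int(l.positive) for l in res.frame_labels])
print("event:", res.onset.is_event, "| onset frame:", res.onset.onset_frame,
      "| onset (min):", res.onset.onset_frame * 5)
print("apoptotic cell:", res.event.apoptotic_cell_id,
      "(truth:", str(sim.truth.apoptotic_cell_id) + ")")
print("killing event:", res.event.killing,
      "| annexin valid:", res.event.annexin_valid)
```

prints

```
frame labels: [0, 0, 0, 0, 1, 1, 1, 1, 1, 1]
event: True | onset frame: 4 | onset (min): 20
apoptotic cell: 2 (truth: 2)
killing event: True | annexin valid: False
```

The baseline classifier flags frames 4–9 as ApoBD-positive; three
consecutive positives starting at frame 4 call the onset at 20 minutes,
matching the simulated ground truth. Least-average-distance association
identifies cell 2 (the simulated dying target), the 4-frame pre-onset
effector contact marks the event as a killing, and — as for the majority
of real apoptotic events — the Annexin-V channel stays dark.

The same stages are available from the shell:

```sh
apobd simulate --out data --seed 5            # nanowell TIFFs + truth.json
apobd classify --video data/sim_000005 --out labels.csv
apobd onset --labels labels.csv --out events.csv
apobd analyze --video data/sim_000005 --out analysis.json
apobd weaklabel --video data/sim_000005 --out weak/   # filtered images + COCO JSON
apobd evaluate --out protocol.json            # synthetic-sequence benchmark
```

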