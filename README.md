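# mitodyn

Quantification of mitochondrial trafficking and dynamics in tumour cells
from fluorescence time-lapse microscopy, plus deconvolution of the pooled
shRNA screen used to find regulators of those behaviours (e.g. syntaphilin,
SNPH). The package is aimed at cell biologists who have single-channel
mitochondrial movies (mito-RFP or similar), manually or automatically
tracked trajectories, and half-hairpin amplicon sequencing from a pooled
screen, and who want reproducible numbers for organelle motility,
fission/fusion activity, and gene-level screen hits.

## What it computes

**Imaging pipeline.** Each frame is denoised by subtracting a disk-mean
low-pass background estimate (diameter 9 px) and median-filtering the
residual (diameter 5 px). Mitochondria are segmented as intensity peaks
anchored to connected components of an adaptive (tiled) Otsu foreground; a
component holding *k* peaks is an aggregate contributing *k* objects of
equal attributed area. Objects are linked between consecutive frames by a
minimum-cost assignment (Hungarian algorithm) over an augmented cost matrix:
link cost is the centroid distance *d*, links with *d* > 25 px/frame (the
maximal mitochondrial velocity, ≈0.32 μm s⁻¹) are inadmissible, and every
object may take a birth/death pseudo-assignment instead. Tracks shorter
than 3 frames are discarded. A track that **ends** within the
spatiotemporal association region of another track (25 px, ±1 frame) is a
**fusion**; a track that **appears** in such a region is a **fission**.
Per-frame event counts are normalized by the number of foreground
mitochondrial pixels, and conditions are compared with two-sample
Kolmogorov–Smirnov and Wilcoxon rank-sum tests.

**Motility metrics.** Per-track mean speed, cumulative and Euclidean
distance, and processivity — the fraction of intervals in motion, with
class `high` when processivity > 0.70. Chemotaxis summaries add
directionality = Euclidean/accumulated distance. Focal adhesions are
classified from the movie endpoints into decaying / newly formed / stable
sliding / stable mature with assembly and decay rates per hour. Cortical
quantification measures mitochondrial signal in a belt eroded inward from
the cell boundary, normalized to total signal and area.

**Screen deconvolution.** Reads matching
`TCGAG + [21-nt insert] + CCGGTGTTTCGTCCTTTCCACAAG` with every base call of
the 50-nt pattern at quality ≥ 35 are mapped exactly to the shRNA library
flatfile and counted per replicate. A gene is significant in a replicate
when ≥ 3 of its shRNAs have ≥ 500 reads, and is a hit when significant in
both replicates.

**Synthetic data.** `mitodyn.synthetic` generates movies (120 nm pixels,
10 s or 1 s frame intervals), trajectories, and screen FASTQ reads with full
ground truth — scheduled fissions and fusions, persistent-random-walk
motion, Poisson noise — so that every downstream stage is testable without
microscope data. See `docs/methods.md` for the model and its limits.

## Worked example

```python
import mitodyn as md

cfg = md.SimulationConfig(
    n_frames=100, height=200, width=200, n_mito=10,
    fission_schedule=[(20, 0), (45, 2)], fusion_schedule=[(5, 6, 60)],
    shot_noise=1.0, peak_intensity=25.0, seed=7,
)
stack, truth = md.simulate_movie(cfg)

segs = md.segment_stack(stack)
tcfg = md.TrackingConfig()                     # 25 px gate, 3-frame filter
tracks = md.filter_tracks(md.build_tracks(segs, tcfg), tcfg)
events = md.detect_events(
    tracks, md.EventConfig(border_margin_px=15.0),
    frame_shape=stack.frame_shape, frame_range=(0, stack.n_frames - 1),
)
for e in events:
    print(e.type, e.frame, round(e.x_px, 1), round(e.y_px, 1))
```

prints (one line per called event; locations in pixels):

```
fission 20 122.4 173.1
fission 45 77.9 141.8
fusion 59 129.8 141.9
```

i.e. the two scheduled fissions are recovered at their scheduled frames and
the fusion is observed at frame 59 — the terminating partner's last
observation, one frame before the merge. Normalizing and comparing two
conditions:

```python
summary = md.normalize_events(events, truth.per_frame_foreground_px)
stats = md.compare_conditions(
    summary["fission_rate_per_px"], summary["fusion_rate_per_px"])
```

The same pipeline is available from the shell:

```bash
mitodyn simulate movie --config sim.yaml --out sim --seed 7
mitodyn segment --in sim/movie.tif --out seg
mitodyn track --in seg/objects.csv --out tracks.csv
mitodyn events --tracks tracks.csv --foreground seg/foreground.csv \
    --height 200 --width 200 --out events
mitodyn screen --fastq exp1.fq exp2.fq --library trc.tsv --out screen
```

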