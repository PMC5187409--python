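# Methods

## Denoising and segmentation

Each frame is processed independently. Background is estimated by a uniform
disk-mean low-pass filter of diameter 9 px and subtracted (clipped at zero);
the residual is median-filtered with a disk of diameter 5 px to remove
high-frequency shot noise. The low-pass kernel type is not uniquely
determined by a "diameter" alone; a uniform disk is the simplest
diameter-parameterized choice, with the order background-subtraction →
median chosen because background varies slowly while shot noise is
pixel-scale. Denoising is not idempotent, but it is translation-equivariant
away from borders, which the test suite asserts.

Foreground is `denoised > max(T_local, T_global)` where `T_local` is a
per-tile Otsu threshold (64×64 px tiles, bilinearly interpolated between
tile centres) and `T_global` the whole-frame Otsu value. The global floor
suppresses the classic adaptive-threshold artifact in which empty tiles
promote noise to foreground; tile size is configurable.

Mitochondria are intensity peaks inside the foreground. Peak detection is
prominence-based: within each connected component, regional maxima whose
prominence (h-maxima) is at least 0.2 of that component's own maximum are
kept, deduplicated to a minimum mutual distance of 7 px (brightest first);
components dimmer than 0.2 of the frame maximum contribute no peaks.
Prominence is assessed per organelle rather than per frame so that a dim
mitochondrion beside a bright one is still found, while shallow
noise-induced secondary maxima on one organelle's plateau are rejected. The
7 px separation corresponds to roughly the half-length of a typical
mitochondrion at 120 nm pixels (~0.8 μm); at a peak signal-to-noise ratio of
5 these two choices are what keeps single organelles from shedding
persistent "ghost" objects, which would otherwise register as spurious
fission/fusion pairs downstream. A component with k peaks is an aggregate:
it yields k objects, each attributed area = component area / k (conserving
foreground pixels), with centroids computed as the intensity-weighted mean
of the component pixels nearest each peak. Intensity weighting makes
centroids subpixel and robust to threshold-induced flicker of edge pixels;
with unweighted centroids, per-interval speeds carry a positive bias of
several percent. Components without peaks are kept in the foreground pixel
count but produce no objects. Coordinates are 0-based, x = column,
y = row, centroids at pixel centres.

## Tracking

Objects in consecutive frames are associated by a minimum-cost linear
assignment over the augmented matrix: link cost is the Euclidean centroid
distance, pairs farther than the maximal-velocity gate (default 25 px/frame)
are inadmissible, and each object can instead take a birth/death
pseudo-assignment whose cost defaults to the gate — so a link is preferred
over a death+birth exactly when admissible. Equal-cost solutions are broken
toward lexicographically smallest object-id pairs by an infinitesimal
perturbation, making the output invariant to input row order. There is no
gap closing and no motion prediction: linking is strictly frame-to-frame,
and a one-frame detection dropout splits a track. Tracks shorter than 3
frames are removed. The stated gate of 0.32 μm s⁻¹ and 25 px/frame are not
mutually consistent at 120 nm pixels for either stated frame interval; the
pixel form (25 px/frame) is treated as authoritative and the μm s⁻¹ figure
as descriptive.

## Fission/fusion calling and comparison

A fusion is called when a track ends (before the last movie frame) and some
other track has an observation within `assoc_radius_px` (default: the 25 px
gate) during the window [end, end + 1] frames; a fission symmetrically for
track starts. The partner is the nearest qualifying track (ties to the lower
id); one termination or appearance yields at most one call. Because a fusion
is observed as the dying partner's last observation, a called fusion sits
one frame before, and up to a contact distance away from, the physical
merge. Ends/starts within `border_margin_px` of the image edge (default:
the radius) are suppressed as field-of-view crossings. Track starts at the
first movie frame and ends at the last are never called.

Per-frame event counts are divided by that frame's foreground pixel count so
cells of different size and mitochondrial content are comparable; frames
with zero foreground and nonzero counts are flagged NaN. Two conditions are
compared on their per-frame rate samples with the two-sample
Kolmogorov–Smirnov test (exact p where sample sizes permit) and the
two-sided Wilcoxon rank-sum test, computed exactly for small tie-free
samples — the test suite checks the exact branch against full enumeration of
all C(10,5) labelings.

## Motility, chemotaxis, focal adhesions, cortical signal

Per-interval speed is displacement × pixel size / frame interval.
Processivity is the fraction of intervals "in motion"; because automated
centroids are subpixel, motion means displacement > `motion_eps_px`
(default 0.5 px) rather than a literal nonzero, which is only meaningful for
integer manual clicks. The high/low cut is strictly > 0.70. Chemotaxis
speed is reported in μm/min, headline value the mean of instantaneous
frame-to-frame speeds (accumulated distance / total time can be derived from
the reported accumulated distance); directionality = Euclidean/accumulated
∈ [0, 1], NaN for a cell that never moved.

Focal adhesions are classified from their presence at the first and last
movie frame: present→absent = decaying, absent→present = newly formed,
present at both = stable sliding if net displacement exceeds
`slide_radius_px` (default ≈1 μm in pixels) else stable mature. An FA absent
at both endpoints (assembled and disassembled within the movie) is counted
as decaying; the endpoint-composite protocol this mirrors cannot observe
such adhesions at all, so any assignment is a convention. Rates are class
counts per hour of movie.

The cortical mask is the cell polygon minus its inward erosion by the belt
width (default 2.0 μm, the order of cortical-actin thickness; configurable
and echoed in output). Both the cortical intensity fraction and an
area-corrected density ratio are reported, since "normalized to total
intensity per cell and cell area" admits either reading; the density ratio
is 1 for spatially uniform signal by construction. A belt wider than the
cell inradius degenerates to the whole cell and is flagged, not an error.
The saturation flag is set when any in-cell pixel reaches the bit-depth
maximum (255 for 8-bit).

## Screen deconvolution

A read is accepted iff it starts with `TCGAG`, positions 27–50 equal the
fixed vector sequence `CCGGTGTTTCGTCCTTTCCACAAG`, and every base call in the
50-nt pattern has Phred quality ≥ 35 (the quality rule is applied to the
matched region; a flag widens it to the whole read). Inserts are mapped to
the library by exact 21-mer match — at Q ≥ 35 the inserts are near
error-free, and a unique-Hamming-1 fallback is available behind a flag.
Mapped + unmapped equals accepted reads per replicate by construction. Only
read 1 of a pair is deconvolved; the pattern anchors at the read start. Gene
significance per replicate requires ≥ 3 shRNAs at ≥ 500 reads; a hit must be
significant in both replicates. The rule is deliberately a counting rule,
not a statistical score; raising either threshold can only remove hits
(asserted as a property test).

## Synthetic data generator

The generator emulates the acquisition regimes the pipeline targets: 120 nm
pixels; 10 s/frame for 1,000 s (glioblastoma regime) or 1 s/frame for 300 s
(prostate regime); 12-bit-like intensities. Since no public imaging data
accompany the method, all validation runs on this generator, whose every
output carries exact ground truth.

**Motion.** Persistent random walk: each organelle draws a mean speed
uniformly from `speed_range_um_s` and a heading that diffuses by
`heading_sigma_rad` per frame, with specular reflection at an interior
margin. Per-frame step length is constant per object, so the configured
speed is exactly the realized speed — what the speed-recovery benchmark
measures is therefore purely pipeline error. Organelle density is a config
choice (`n_mito`, `min_spacing_px`), not inferred from any figure; initial
placement is rejection-sampled and falls back to a jittered lattice when the
requested spacing approaches the packing limit. Non-partner organelles
softly exclude each other below 12 px — without volume exclusion, blobs
drift into contact and register as unscheduled fusion/fission pairs, which
no peak-based segmentation could distinguish from real ones.

**Events.** A scheduled fission replaces the parent with two children offset
±5 px perpendicular to the heading, each carrying exactly half the parent's
integrated intensity (conservation is asserted to better than 1% before
noise); children recoil apart at 1.5 px/frame for 10 frames, emulating
fragments that separate rather than travel together. A scheduled fusion
steers the second partner toward the first, closing to a 16 px standoff and
holding it until the merge frame, at which the pair is replaced by one
organelle; later-scheduled fusions steer before earlier ones so chains
(fusing with a survivor that is itself being steered) do not oscillate. The
merged organelle is rendered as a modestly larger blob (major σ × 2^¼) at
the same peak brightness rather than an intensity-conserving elongated
ridge: a flat ridge twice as bright as its neighbours both destabilizes
relative thresholds and over-splits into spurious peaks under noise, and
intensity conservation is only claimed (and enforced) at fission.

**Rendering and noise.** Organelles are anisotropic Gaussian blobs (minor/
major axis ratio 0.6) oriented along the heading, major axis drawn from
`size_range_px` (default 10–13 px ≈ 1.2–1.6 μm — the scale at which both
parents and post-fission children remain above the erasure scale of the
5 px median filter). All organelles share one peak brightness
(`peak_intensity`). A linear background plane, optional Gaussian optical
blur (`psf_sigma_px`), and finally Poisson noise (`shot_noise` scales the
photon count; 0 disables noise) complete the frame, so the peak SNR is
√(peak_intensity × shot_noise) — the noisy benchmarks use peak 25 photons,
i.e. SNR 5. Ground-truth foreground pixels per frame are counted on the
clean signal above 5% of the nominal peak.

**What the generator does not emulate** — and hence what passing benchmarks
do not establish about real data: true tubular/branched mitochondrial
morphology (blobs are ellipsoidal), photobleaching, camera read noise and
gain, focus drift, membrane-potential heterogeneity of the dye, crowded
networks where organelles genuinely touch without fusing, and 3D motion
through the focal plane. Event recovery at SNR 5 on sparse fields is an
upper bound on performance in dense perinuclear regions.

**Screen reads.** Each read is prefix + 21-mer + vector sequence + random
tail at uniform quality (default Q40); a configured fraction of reads
carries one random substitution inside the insert, and truth counts tally
error-free reads only, so exact-match mapping recovers truth exactly at
error rate 0 and a binomial (1 − rate) fraction otherwise.

All generators are deterministic given `seed` (bit-identical reruns).

## Benchmark problem sizes

The validation experiments use 200×200 px movies of 100 frames with 10
organelles at >50 px nearest-neighbour spacing, 5 scheduled fissions and 3
fusions per movie (3 movies noise-free, 20 at SNR 5); speed recovery uses
220×220 px, 80 frames, 8 organelles, noise-free; the assignment oracle runs
500 random frame pairs with ≤6 objects (exhaustive enumeration is exact
there); the hit rule is compared with a brute-force loop on 1,000 random
50-gene tables. Event matching against ground truth allows ±1 frame (a
fusion is observed one frame before the merge) and 20 px (the standoff
geometry; below the 25 px association radius), and requires the detected
partner track to lie near a true participant of the matched event.

## Known limitations

- Pairwise linking without gap closing means any single-frame detection
  dropout fragments a track; the association window of 1 frame deliberately
  does not bridge such gaps (this suppresses dropout-induced false events at
  the cost of occasionally splitting long trajectories).
- Aggregate handling (equal area split among peaks) biases per-object areas
  toward the component mean; tracking uses centroids only, so this affects
  reported areas, not links.
- The screen hit rule is a threshold count; no enrichment statistics or
  variance modelling across replicates is attempted, and the hit-list export
  is one gene symbol per line for downstream enrichment tools.
- `compare_conditions` treats per-frame rates as exchangeable samples;
  temporal autocorrelation within one movie is ignored, as in the protocol
  it reimplements.
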