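# wormgrowth

Single-animal growth analytics for *C. elegans* fluorescence time-lapse
movies recorded in agarose microchambers — one chamber, one animal, one
frame every 10 minutes from egg to adult.

The package is for researchers who quantify larval development from such
movies: it segments the animal in each frame (Sobel edges, contour-gap
closing, automatic intensity-scale-invariant thresholds), flags faulty
frames with a 20-tree bagged decision-tree QC classifier, straightens the
worm along its midline and infers body volume assuming rotational
symmetry,

    V = Σᵢ π (wᵢ/2)² Δs · pixel_size³,

measures background-subtracted total fluorescence and per-pixel
concentration C = F/A, and turns the per-frame series into developmental
analytics: hatch and molt detection from the maximum of d²log V/dt²
(growth plateaus precede each ecdysis), 10-point boundary-volume
regressions, volume-specific growth rates g = dlog V/dt after median-3 +
15-point robust-lowess smoothing, Whittaker–Eilers smoothing (λ = 0.75 on
the hour axis), robust early-L1 window summaries (3.7 h window centred at
4.3 h post-hatch), rescaling of every larval stage to 100 progression
points, and cohort statistics (SEM bands, 1,000-repeat bootstrap
difference and recovery-ratio curves, exact-mode Wilcoxon rank-sum
tests).

Because public imaging data for this assay are scarce, the package ships
a first-class synthetic-data module: piecewise-exponential growth with
lethargus plateaus, exponentially recovering fluorescence concentration,
maternal-effect cohorts with known offsets, rendered chamber movies whose
drawn shapes have *exactly* the prescribed rotational-symmetry volume
(an analytic oracle for the volumetry), and corrupted masks for QC
training. Every analytical claim in the test suite is checked against
this ground truth.

## Worked example

Segment and measure a rendered frame with known truth
(`examples/02_segment_and_measure.py`):

```
$ python examples/02_segment_and_measure.py
segmentation: 958 px, Jaccard vs truth 0.998
midline length 95.9 px, mean width 9.9 px
volume 120410 µm³ (truth 120000, error +0.3%)
background 20.0, concentration 92.0 a.u./px
```

The worm was drawn with a volume of 1.2×10⁵ µm³ and uniform interior
intensity 100 over background 20: the mask overlaps the truth almost
perfectly, the rotational-symmetry volume is recovered to 0.3%, and the
measured concentration sits slightly below the drawn value only because
the optical blur moves edge intensity outside the mask (a factor that
cancels in every between-condition ratio).

Run the full pipeline on a simulated maternal-effect cohort
(`examples/05_full_pipeline.py`, 4 animals per group for the demo):

```
$ python examples/05_full_pipeline.py
simulate   {'animals': 8, 'frames': 840, ...}
segment    {'frames': 840, 'failed': 3, 'qc_fail': 65, 'oob_accuracy': 0.975, ...}
measure    {'rows': 840, ...}
events     {'animals': 8, 'excluded': [], ...}
cohort     {'animals': 8, ...}

recovered hatch-volume offset: -14.2% (simulated -13%)
recovered concentration offset: -11.2% (simulated -11%)
treated/control concentration ratio at M1: 0.990 (1.0 = fully recovered)
```

The treated group was simulated hatching 13% smaller with 11% lower
fluorescence concentration that recovers during L1; the pipeline —
running renderer output through segmentation, QC, volumetry, event
detection and cohort statistics — recovers both offsets and shows the
concentration ratio returning to ~1 by the first molt. The other
examples cover trajectory simulation/rendering, molt detection and
growth rates, and cohort comparison; each prints what it computes and
what the numbers mean.

The same pipeline is available from the shell:

```
wormgrowth all --seed 1 --output runs/demo      # or: simulate/segment/...
wormgrowth validate --config run.yaml
```

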