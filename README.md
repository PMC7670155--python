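# acromorph

Landmark-based 3D morphometry of the acromion. Given labelled shoulder bone
surface meshes (scapula with acromion label, distal clavicle, proximal
humerus) and a landmark annotation file, the pipeline

1. builds a scapular coordinate frame from three landmark constructs
   (best-fit circle centre of the inferior glenoid rim = origin; the
   spine/medial-border junction and the inferior angle fix the scapular
   plane; an anterior witness point orients the normal),
2. measures eight acromial shape parameters: the acromiohumeral interval
   (AHI), the anterior and inferior protrusions past the distal clavicle
   (AAP, AIP), the acromioclavicular angle at the most lateral point of the
   acromion (MLPA), and four parameters of the acromial anterolateral
   protrusion (AALP) — the widths *a* and *b* from its medial border to the
   MLPA, its antero-posterior diameter *c*, and the ratio c/(c+d) against
   the whole acromion — where the AALP medial border is detected as the
   maximal-concave-curvature crease on axial slice contours,
3. runs the study-level statistics: CV%/ICC% reliability, one-way ANOVA
   (from raw values or printed summaries), Welch/pooled pairwise tests,
   percent differences, and 95% reference ranges whose upper bounds serve as
   risk thresholds.

A fully parametric synthetic-shoulder generator provides watertight labelled
meshes with closed-form ground truth for every parameter, plus rater-noise
and three-group cohort simulators, so the entire pipeline is testable
without patient data.

## CLI

```sh
# generate a synthetic shoulder (STL meshes + landmarks + ground truth)
acromorph synth --out-dir out/shoulder --seed 1

# measure the eight parameters of one shoulder
acromorph measure --scapula out/shoulder/scapula.stl \
                  --clavicle out/shoulder/clavicle.stl \
                  --humerus out/shoulder/humerus.stl \
                  --landmarks out/shoulder/landmarks.json \
                  --out out/measured.json

# simulate a three-group cohort and build the comparison report
acromorph cohort --seed 1 --out out/cohort.csv
acromorph report --cohort out/cohort.csv --out out/report.csv

# reliability metrics from a long replicate table
acromorph reliability --table out/replicates.csv --out out/reliability.csv
```

Meshes are STL/OBJ/PLY (mm); landmarks are a versioned JSON schema
(`glenoid_rim` points, `B`, `C`, `AM`, `PM`, `anterior_witness`, `side`).
Vertex labels travel in a `<mesh>.stl.labels.json` sidecar. All measurement
defaults (slice step 0.625 mm, contour resampling 0.5 mm, curvature
threshold 0.15 /mm, ...) live in `acromorph.config.RunConfig` and can be
supplied as JSON via `--config`.

## Layout

```
src/acromorph/
  geometry.py        plane/circle fitting, mesh slicing, contour curvature
  scapular_frame.py  landmark frame construction, side normalisation
  model.py           ShoulderModel bundle
  measures.py        the eight parameter operators + measure_all
  synthetic.py       parametric shoulder generator, rater/cohort simulation
  stats.py           CV/ICC, ANOVA, pairwise tests, reference ranges, report
  io.py              STL/OBJ/PLY + landmark JSON
  cli.py             command-line interface
tests/               unit, property and acceptance suites
scripts/acceptance.py
```
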