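# Methods

## Model and procedure

The package implements single-descriptor QSAR by correlation-weight
optimisation.  A molecule's SMILES is treated as a symbol sequence and,
in parallel, parsed into its hydrogen-suppressed heavy-atom graph.  From
these two views a multiset of structural attributes is extracted, each
attribute carries one tunable real weight, and the molecule is summarised
by the scalar DCW(T, N) = Σ CW(A)·count(A).  The endpoint model is the
ordinary least-squares line pIC50 = C0 + C1·DCW fitted on the sub-training
set only.

The four-set protocol assigns every compound one role:

| role | size (packaged split 1) | use |
|---|---|---|
| sub-training | 131 | fits the weights and C0/C1 |
| invisible training | 131 | enters the optimisation objective only |
| calibration ("test") | 60 | overfitting monitor; selects a preferable N |
| validation | 60 | untouched final check |

The packaged dataset uses two printed vocabularies for these sets; the
report writer emits the table vocabulary (Sub-training / Calibration /
Test / Validation) while the API uses the protocol names
(`subtraining / invtraining / calibration / validation`, markers
`+ - # *`).

### Monte-Carlo optimisation

Weights start uniform in [0.5, 1.5] (the absolute scale is immaterial —
C1 absorbs it).  One epoch visits every active attribute once in random
order; the visited weight receives a proposed increment uniform in
[−step, +step] and the proposal is kept iff the target function

    TF = r_sub + r_inv − |r_sub − r_inv| · d_weight

strictly increases (r are Pearson correlations of DCW with pIC50).  The
accepted-TF trajectory is therefore non-decreasing by construction, and a
fixed seed drives initialisation, visit order, and proposals, making runs
bit-reproducible.  Equal-TF proposals are rejected by default
(`accept_equal` exists but is off).  The objective form and the greedy
acceptance rule are this package's declared choices: they are the simplest
members of the method family's conventions, and all knobs are recorded in
the model file so results are self-describing.

### Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `mode` | `hybrid` | attribute source: `smiles`, `graph`, or their union |
| `smiles_scheme` | `S1, S2` | token and canonical-pair attributes; `S3`, `NOSP`, `BOND`, `HALO` are switches |
| `ec_orders` | `0, 1, 2` | extended-connectivity orders on the H-suppressed graph |
| `threshold` T | 0 | block attributes seen in < T sub-training compounds (T=0 blocks nothing) |
| `n_epochs` N | 41 | Monte-Carlo epochs; the packaged dataset's published preferable value |
| `step` | 0.5 | proposal half-width (pIC50-free units) |
| `d_weight` | 0.01 | disbalance penalty between the two training correlations |
| `init_range` | [0.5, 1.5] | weight initialisation |

Which string/graph attribute switches the original software run enabled is
not recoverable; the defaults above are declared choices, not claims about
that run.

### Statistics

r² is the squared Pearson correlation of prediction vs observation.  q² is
the leave-one-out cross-validated coefficient of the *final* one-variable
regression with the weight table frozen — re-running the Monte-Carlo per
left-out compound would not define a cross-validated regression
coefficient and contradicts the q² ≈ r² pattern such models show.  The
closed-form hat-matrix shortcut is used and is tested to equal explicit
per-point refitting exactly.  F = r²(n−2)/(1−r²) is displayed rounded to
integer (full precision kept internally); the critical value is the upper
5% point of F(1, n−2) from scipy.  The report's `p_tail` column is the
true F-distribution tail probability; at these F magnitudes it is
vanishingly small (≪ 0.001), which is why no attempt is made to mimic
loosely defined "p-value" columns of the order 0.03–0.11 sometimes printed
next to such tables.  Published critical-value columns for these row sizes
are also garbled by formatting; the footnote definition is followed
instead.

### Endpoint summaries

Per-set min/max/middle pIC50 are *truncated*, not rounded, to two
decimals, and the middle is the truncated mean of the already-truncated
extremes.  This is forced by the packaged data (3.699 → 3.69;
(3.41 + 7.22)/2 = 5.315 → 5.31) and reproduces every printed summary cell
exactly.

### Applicability domain

The statistical defect of a molecule is
D = Σ count(A)·|p_sub(A) − p_inv(A)|/(n_sub(A) + n_inv(A)) over its
attribute instances; an attribute absent from both training sets makes D
infinite.  A molecule is an outlier when D strictly exceeds
`multiplier × mean defect of the sub-training compounds` (default
multiplier 2; a defect exactly at the cutoff is inside).  Screening
applies, in order: element filter (training alphabet), SMILES length cap
(default 150 characters), outlier rule, prediction.  Both the multiplier
and the element filter are configuration, because published screening runs
of this kind have admitted elements (e.g. bismuth) outside a strict
training-alphabet rule; the defect formula itself follows the method
family's convention since only the outcome counts were published.

## Synthetic studies and what they show

The generator concatenates 4–12 fragments from a 12-fragment ring-free
vocabulary (so any concatenation is tokenizable without a chemistry
engine) and assigns y = c0 + c1·Σ w_true(A)·count(A) + N(0, noise_sd²),
with one planted weight per vocabulary token, c0 = 5, c1 = 0.25 — giving
endpoints centred near pIC50 ≈ 5 with spread ≈ 1, the shape of the real
dataset.  The default study size is 382 compounds split 131/131/60/60.

Zero-noise studies are recovered almost perfectly out of sample
(validation r² ≈ 0.99), and the mean validation r² over seeds decreases
monotonically across noise_sd ∈ {0, 0.2, 0.5, 1.0} (≈ 0.99 / 0.81 / 0.41 /
0.14).  This validates the mechanics — attribute extraction, optimisation,
splitting, reporting — end to end.  What it does **not** show: real
activity data are not affine in fragment counts, fragments co-occur with
chemical correlation structure, and assay noise is not i.i.d. Gaussian, so
synthetic recovery says nothing about attainable accuracy on real
endpoints.

## Known limitations

* **Blind accuracy on the packaged dataset.**  With the declared attribute
  families and optimizer, hybrid split-1 models reach blind validation
  r² ≈ 0.60–0.73 (best of several seeds and configurations), with an
  in-sample/out-of-sample gap of 0.1–0.3.  The originally published model
  reports ≈ 0.81–0.83 on *all four* sets — essentially gap-free.  Raising
  epochs here pushes sub-training r² to that level, but calibration and
  validation quality then falls: in this attribute space the additional
  in-sample fit is variance.  Matching the published blind quality would
  require the original run's unpublished weight table and attribute
  conventions (e.g. hydrogen-filled-graph connectivity or further
  invariants), which are outside what this package declares.
* SMILES are used verbatim: no standardisation, aromatisation, desalting,
  or valence checking (an optional RDKit sanity check could warn but never
  alters input; it is not a dependency).
* Graph attributes ignore bond order and charge; no 3D information.
* Only the printed quality columns are computed — no Y-scrambling or
  bootstrap.
* The degenerate case of a zero-variance descriptor (e.g. all compounds
  identical) raises a named error rather than producing a model; r² = 1
  sets display F as infinite rather than failing.

## Problem sizes used by tests and the acceptance script

Full-size runs are cheap (a 41-epoch hybrid fit on 262 training compounds
takes well under a second), so tests use the real 382-compound dataset and
full-size 382-compound synthetic studies throughout; only the noise curve
averages over 5 seeds per level.
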