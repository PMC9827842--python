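# Methods

This note documents the models, parameters and design choices behind
`neuroihc`: what is simulated, how it is measured, which knobs matter, and
what the synthetic experiments do and do not demonstrate about real
tissue.

## Study design being emulated

A case/control brightfield-IHC study of C9orf72-ALS cortex: five stains
(Iba1, CD68, GFAP, pTDP-43, FUS) over four Brodmann areas (BA4 motor;
BA39/BA44/BA46 linked to the ECAS language/fluency/executive domains),
each sampled in grey and white matter with three vascular-adjacent (VA)
and three non-vascular-adjacent (NVA) 500×500 µm fields — a full
factorial of 240 ROIs per case, 4,800 for a 20-case cohort. VA fields are
centred on a vessel larger than a small capillary (operationalised as
lumen diameter ≥ 10 µm, shared between generator and validator; the
centring tolerance is the central 20% of the field, a declared choice
since "centred" needs a tolerance). NVA fields keep ≥ 250 µm clearance
from any qualifying vessel. Fields violating both rules are `invalid` and
must be resampled.

The clinical sheet carries sex, age, disease duration (months), onset
region, ECAS availability, per-domain impairment and ALSFRS data-point
counts. `study_cohort()` reproduces the published 10+10 demographics used
for stratification: language-impaired n=4 vs language-unimpaired n=3
among the seven ECAS-assessed disease cases (the multi-domain FTD case
counts as impaired in each of its constituent domains; the
executive-dysfunction case counts as language-unimpaired), and
long-survivor n=5 at the >48-month duration cutoff. Statistical
comparisons are refused whenever a group has n < 3.

## Optical model and quantification

Stains mix additively in optical density (Beer–Lambert):
`OD_c = -log10((I_c + ε)/I0_c)` per channel with `I0 = 255` and
`ε = 1/255` (avoids −∞ at intensity 0), clipped at 0 so white background
has zero OD. Unmixing uses the published Ruifrok–Johnston haematoxylin
(0.650, 0.704, 0.286) and DAB (0.268, 0.570, 0.776) unit vectors
(configurable) by least squares (pseudoinverse), densities clipped at 0;
with a two-stain basis the residual norm is returned as the third
component. On noise-free synthetic mixtures the 8-bit render → OD →
unmix round trip recovers planted densities to < 0.02 OD (the dominant
error is uint8 quantisation, ≈ 0.009 OD at OD 1).

Superpixels come from SLIC on the DAB density (single channel,
`compactness = 0.2`, Gaussian pre-smoothing `sigma = 1.5` px,
connectivity enforced, labels from 1). The smoothing + moderate
compactness combination was chosen so boundaries adhere to stained-object
edges: it removes the systematic undercounting of partially covered
boundary superpixels that a noisier gradient produces (planted 30% burden
is then measured to within ±0.05, typically ±0.01). The target superpixel
area (default 400 µm²) and the intensity-class thresholds (default mean
DAB OD 0.2/0.4/0.6 for 1+/2+/3+, half-open intervals `[t_k, t_{k+1})`)
are configuration, not constants — the original analysis's exact values
live in software configuration that is not published, so defaults are
declared rather than inferred. Circularity is `4πA/P²` with the
chain-code perimeter of the region border, clipped at 1 (rasterisation
can overshoot); stated explicitly because discretisation makes
"circularity" ambiguous. Distance-to-vessel is measured centroid to
nearest vessel-mask pixel, in µm; it is structurally absent in NVA
fields. Coordinates are 0-based pixels, x right / y down, centroids in µm
from the ROI top-left.

The digital Allred score uses the standard clinical bins: proportion
score 0–5 on the positive (class ≥ 1) superpixel fraction
{0; (0,0.01]; (0.01,0.1]; (0.1,1/3]; (1/3,2/3]; (2/3,1]} and intensity
score = mean positive class rounded half-up (implemented as
`floor(x+0.5)` to avoid banker's rounding), 0 when nothing is positive.
The total is therefore 0 iff no superpixel is positive, monotone
non-decreasing in positive fraction at a fixed class profile and in the
class profile at a fixed fraction. (Raising a *negative* superpixel to
1+ can lower the intensity component while raising the proportion
component — monotonicity is only claimed under the two perturbations
above.)

Cell segmentation thresholds the haematoxylin density (default OD 0.15),
splits touching nuclei by a distance-transform watershed, removes
fragments < 8 µm², types cells neuron/glia at a nuclear area of 70 µm²
(declared default; the original method states only "nuclear area
thresholding"), and grows a cytoplasmic ring by 3 µm bounded expansion
clipped at neighbours. N/C ratio = nuclear / cytoplasmic mean DAB OD,
undefined (NaN) when the cytoplasmic mean is below 1e-3 OD.

## Synthetic data generator

The generator has two tiers sharing one effect model; both are
first-class, tested code.

**Effect model.** Each stain has a control baseline (positive-area
fraction, mean intensity class, object geometry, vessel-proximity mean,
N/C ratio) and a disease effect (`StainEffect`): added positive density,
intensity-class shift, circularity shift, vessel-proximity shift, glial
N/C shift, and optionally a sharp detection-level mean-OD shift in units
of the marginal OD sd (0.10). The latent per-ROI burden is
`(baseline + disease_delta + u_case) · (1 + e_roi)` with `u_case ~
N(0, case_sd)` a case-level random intercept (default sd 0.02) and
`e_roi ~ N(0, roi_sd)` per-ROI multiplicative noise (default sd 0.15) —
the nested ROI-within-case structure the statistics layer assumes. The
default study effects encode the reported effect directions: raised
microglial (Iba1) burden/intensity with less circular, more
vessel-proximal objects; milder CD68/GFAP increases; sparse extra
pTDP-43 aggregates; raised glial N/C FUS ratio. Baseline burdens
(Iba1 0.12, CD68 0.06, GFAP 0.15, pTDP-43 0.015, FUS cellular) are
plausibility choices for cortical IHC at these markers, fixed once.

**Pixel tier** (`render.render_roi`): 0.5 µm/px by default (the study
scanned at 40×, ≈0.23 µm/px; 0.5 is a desk-scale default and a config
knob — most experiments here run at 1–2 µm/px for speed). Nuclei are
ellipses at ~3,200/mm² with two nuclear-area modes (glia r≈3 µm, neurons
r≈5.5 µm; neuron fraction 25% GM / 5% WM); DAB textures are random-walk
disk unions (ramified/amoeboid for Iba1/CD68, long thin walks for
fibrillar GFAP, single puncta for pTDP-43) painted until the planted
fraction is reached, with per-object intensity class drawn from a
discretised normal over {1,2,3}; FUS paints every cell's nucleus and
cytoplasmic ring at ODs whose ratio is the planted N/C target. VA fields
get a centred lumen + wall annulus; objects in VA fields are placed at
exponentially distributed distances from the vessel so proximity shifts
are expressible. Fields mix through the stain vectors, take Gaussian OD
noise (sd 0.015) and invert to 8-bit RGB. Identical (spec, config, seed)
give byte-identical images; ground truth (realised positive fraction,
mean class, object/nucleus counts, vessel mask and annotation, per-cell
compartment ODs) is returned with each image.

**Detection tier** (`featuresim.sample_detections`): draws superpixel and
cell records directly from the same latent-burden model without
rasterising, for experiments needing thousands of ROIs (classifier
calibration/power). Superpixel mean OD is uniform within the class band;
geometry is lognormal/Gaussian around the baseline; the ROI-level
positive fraction and count are additionally broadcast to detections as
"staining-extent" features.

**What the generator does not emulate:** photorealistic texture, staining
batch artefacts beyond the multiplicative term, spatial correlation of
cells beyond vessel proximity, section-level gradients, and whole-slide
context. Passing tests therefore demonstrate the *pipeline's* internal
consistency and statistical behaviour under a controlled model — not that
the defaults match any particular tissue series.

**Manual grading emulation:** ordinal severity 0–3 by fixed burden bins
(0.02/0.10/0.25 positive fraction), with mislabel probability
`kappa_noise` moving a grade ±1. FUS is excluded from severity grading
(localisation, not intensity, is its relevant readout). The concordance
suite renders a burden ladder with intensity deepening alongside burden
(severe tissue stains darker — without this coupling the Allred intensity
component is pure noise relative to a burden-only grade and the rank
correlation saturates near 0.86 rather than >0.93).

**qPCR plates:** per-sample RNA-input offsets are shared by target and
reference genes so ΔCt isolates expression; disease ΔCt is lowered by the
planted log2 fold change; technical-replicate noise is `ct_sd`. Samples
whose triplicate Ct sd exceeds 0.5 for either gene are excluded
("consistent among triplicates", operationalised). The control-group mean
ΔΔCt is 0 by construction, so control fold changes have geometric mean 1.

## Classifier

scikit-learn's `RandomForestClassifier` with `criterion="entropy"`
(information gain) stands behind `train_forest`; 1,000 trees is the
configured default, with smaller forests used in simulation loops where
the tree count is a convergence knob, not a finding. Features are
z-scored with train-split statistics only. Structurally missing values
(vessel distance in NVA fields, cell-only features on superpixel rows)
are sentinel-encoded (−1) with paired missingness indicators.

Splits and folds are group-wise (default unit: ROI, so all detections of
one field stay together; `detection` and `case` units available) and
label-stratified. The evaluation hierarchy is overall → stain →
stain×region → ×matter → ×adjacency; strata with an empty margin are
flagged untested rather than tested. χ² is Pearson with df=1 and no
continuity correction (the large-count regime; correction available).

**Within-case leakage and calibration.** With case-level random
intercepts, an ROI-level split lets the forest partially re-identify
cases, so predictions correlate with truth even when no group effect
exists; and any cluster-shared signal (case intercepts, ROI noise, or
the broadcast extent features) makes pooled detections pseudoreplicates,
inflating the detection-level χ². These are properties of the design
being emulated, not implementation defects. The type-I calibration suite
therefore runs the classifier on *exchangeable* null cohorts — zero
disease deltas, zero case/ROI noise, detection-unique features only —
where the nominal-rate property is well-posed; there the per-stratum
rejection rate is 5% (the residual ~0.5% excess is the uncorrected χ²'s
small-sample behaviour). Because one cohort's five stain strata share a
forest and a split, the independent replicate for the calibration CI is
the cohort, not the stratum. The power suite plants a 2σ detection-level
mean-OD shift in a single stain (the per-detection analogue of a
feature-group mean shift; a 2σ shift has Bayes accuracy Φ(1) ≈ 84%) and
asks that the planted stain tops the per-stain sensitivity+specificity
ranking.

Leave-one-out retrains without each feature (or feature group) on the
same split and reports sensitivity/specificity deltas; the ranking
statistic for "top-k features" is mean impurity-decrease importance (the
ranking statistic behind the original top-50 list is unstated; LOO deltas
are reported alongside). The attribution experiment uses one informative
feature among eight pure-noise features at 4,000 detections and 120
trees — sized so that refit randomness keeps noise-feature deltas below
2 points while dropping the informative feature collapses accuracy to
chance.

## Statistics layer

Normality gating uses Shapiro–Wilk at α=0.05 per group (a zero-range
sample routes to the rank branch); parametric = unpaired t-test
(pooled variance) or one-way ANOVA with Tukey pairwise; nonparametric =
Mann–Whitney U or pairwise Wilcoxon rank-sum with Holm–Šidák correction
(family = the pairwise comparisons of one panel; the original does not
define families). Spearman p-values use scipy's tie-corrected asymptotic
test. Regression comparison fits the single interaction model
`y ~ x * group`: the group main effect tests the intercept difference,
the interaction tests the slope difference; per-group coefficients equal
independent least-squares fits exactly. Homogeneity of variance for the
qPCR group test — "visually inspected" in the emulated workflow — is a
Levene test at α=0.05, reported as a flag rather than a gate, since
visual inspection is not automatable.

Triplicate averaging is the arithmetic mean over replicate fields per
(case, stain, region, matter, adjacency) cell, flagged when incomplete;
case-level averaging (mean of a case's region-cell means) is applied
whenever regional stratification is dropped, so each case contributes one
observation (pseudoreplication guard).

## Problem sizes and numerical choices

Simulation sizes are chosen for desk-scale runs on one CPU: renderer
experiments at 1–2 µm/px over tens of fields; classifier experiments on
6+6-case cohorts × 5 stains × 8 ROIs × 12 superpixels (≈5,800
detections) with 30-tree forests inside replicate loops; 200 null-cohort
calibration replicates; 50 power seeds; 30 regression seeds; 10 qPCR
plates per planted fold change. The end-to-end pipeline default renders a
4+4-case, two-stain, one-region cohort at 2 µm/px in a few minutes.
Seeds fan out from one global seed via a CRC-mixed per-stage scheme
(`stage_seed`), so stages are independently reproducible; every run
directory carries a manifest with a config hash and per-file checksums,
and identical configs reproduce identical checksums.

Known limitations: superpixel intensity classes are diluted at object
boundaries, so measured mean class sits slightly below the planted value
(fraction recovery is unbiased; class recovery is conservative); the
renderer's FUS tier controls the N/C ratio but not the positive fraction
independently; cross-validation summary sds at 3 folds are coarse; and
none of the planted effect sizes are calibrated to the real cohort — the
published headline percentages depend on the deposited slide images and
are deliberately not targets of the synthetic experiments.
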