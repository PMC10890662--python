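# Methods

This note documents the models, conventions and design choices behind
`glcga`, in the order the pipeline uses them.

## Mass arithmetic and channel construction

Element monoisotopic masses are CODATA/IUPAC values hard-coded to 8
decimals; deuterium is the distinct symbol `D`.  `[M+H]+` adds the proton
mass 1.007276 Da; fragment ions given as cation formulas (e.g. C4H10N+)
are element-mass sums minus one electron (0.000549 Da).  Both conventions
were chosen because together they reproduce the reference m/z values of
derivatized Glc-GAs to within 0.0005 Th.

Derivatization stoichiometry is amide formation: the neutral derivatized
formula is native + C4H12N2 − H2O.  Published tabulations of derivatized
formulas sometimes carry two extra hydrogens (consistent with listing a
different species); the amide stoichiometry is the one that reproduces all
printed [M+H]+ values and is used throughout.  The formic-acid neutral
loss is implemented at the monoisotopic mass of CH2O2, 46.0055 Da.

The d4 label shifts every channel by 4·(m(D) − m(H)) = 4.02511 Da, a
constant offset independent of the candidate.

Candidate channels: each registry GA is glucosylated, derivatized,
protonated and heavy-shifted; candidates whose light m/z agree within
0.001 Th (i.e. identical formulas) merge into one isobaric channel.
Observed-m/z lookups use 10 ppm.  GAs whose only carboxyl is conjugated
(glucosyl esters, registry column `carboxyls = 0`) do not react with the
amine reagent and are excluded from channel building.

Limitations: no isotope fine structure, no multiply charged species, no
adducts beyond [M+H]+.

## The fixture registry

The full conjugate registry behind the published channel tables is not
deposited.  The built-in registry covers the 66 GAs named in the reported
channels plus GA8 and GA9, each with: parent formula (as implied by its
isobaric channel), an A-ring lactone flag, and an A-ring hydroxyl count.
The lactone/hydroxyl annotations are **synthetic**: they encode the
structural classes that the reported filtering outcomes imply, not curated
structure data, and two members (GA12, GA45) take the channel's implied
formula although literature formulas differ.  Users supply their own
registry CSV (`name, formula, lactone, hydroxyls, carboxyls,
predicted_ri`) for real analyses.

## LC-MS model, XICs and peak picking

Runs hold centroided MS1 full scans (default emulated range m/z 300–700
over a 40-min gradient) plus DDA MS2 spectra.  mzML I/O is a deliberately
narrow reader/writer pair for standard files: 32/64-bit float arrays,
plain or zlib-compressed, one selected ion per precursor; the writer emits
deterministic, timestamp-free XML so simulated runs are byte-reproducible.

XICs sum intensities within ±10 ppm per MS1 scan.  The peak picker:
moving-average smoothing (5 scans), baseline = trace median, noise =
1.4826·MAD (floored at 1 count), local maxima above `min_snr` (default 3)
× noise, bounds at flanking valleys, minimum width 5 scans.  The apex RT
is refined by a three-point quadratic fit, giving sub-scan accuracy — this
matters because the pairing criterion tolerates only 0–0.013 min of
light/heavy offset while MS1 scans are ~0.008 min apart.  Peak *height*
(smoothed, baseline-subtracted), not area, feeds the intensity-ratio
criterion, since the pairing rule is stated in terms of peak intensity.

## Pair matching and the five-class screen

Pair criteria default to RT(light) − RT(heavy) ∈ [0, 0.013] min (the
deuterated species never elutes later on reversed phase) and ratio ∈
[0.76, 1.50]; both windows are configurable for other label chemistries.
All criteria-satisfying (light, heavy) combinations are ranked by |ΔRT|
(ties: ratio closest to 1) and assigned greedily 1:1; the result is
invariant under permutation of the peak lists.

Neutral-loss ladders are chained to depth 4, seeded both at the precursor
and at the anchor [M − Glc − (CH3)2NH]+, with 10 ppm fragment tolerance
(HCD at resolution 30,000).  Class labels follow the last loss in the
explaining path.  "Odd-numbered CxHy+" is interpreted as odd hydrogen
count (even-electron hydrocarbon cations, odd nominal mass), x ∈ [5, 18],
m/z ∈ [80, 230].

The pass policy is not uniquely determined by the published narratives, so
it is configurable; the default requires classes 5 (glucose loss),
1 (DMED) and 2 (A-ring) plus at least one of classes 3 or 4, which matches
every reported positive example.  Class 4 needs ≥ 2 annotated skeleton
fragments so a single coincidental hydrocarbon match cannot carry it.

## A-ring inference

From the anchor, loss combinations of up to four steps over {H2O, HCOOH,
CO2, CO2+2H2O} are searched in the spectrum.  Hydroxyl count = the maximum
number of H2O units lost, counting a combined CO2+2H2O loss as one
hydroxyl water (its other water and the CO2 belong to the opened lactone);
lactone = 1 if an HCOOH, a combined, or a CO2-with-water loss is present.
This rule reproduces all three published worked patterns (one lactone +
one hydroxyl; one lactone + two hydroxyls via the combined loss; one
lactone + two sequential waters).  Step 2 keeps a candidate when its
annotated lactone flag equals the inferred one and its annotated hydroxyl
count is ≥ the inferred count (a hydroxyl can fail to dehydrate; it cannot
appear from nothing).

## Retention indices and the QSRR filter

RT→RI calibration is generic piecewise-linear interpolation over user
anchors (linear extrapolation with a warning outside them).  The built-in
fixture series uses the eleven reported (RT, RI) pairs, which are monotone,
so replays reproduce the printed RIs exactly.  The anchor compounds of the
original RI scale are not published, so experimental RIs are fixture
inputs, not recomputable ab initio.

The QSRR model itself is a pluggable descriptor matrix + ordinary
least-squares fit (n ≥ p + 2, full rank enforced); leave-one-out RMSE uses
the exact PRESS identity e_i/(1 − h_ii).  The descriptor set behind the
published model is out of scope; predicted RIs for the reported candidates
ship as a fixture table.  The retention filter is one-sided:
retain iff RI_exp < RI_pred + 69.5832 (the published cross-validated RMS
error).  Positive deviations of any size retain — this reproduces every
published retain/exclude decision, including retained deviations of +80.28
and +104.70.  Candidates without a prediction are retained with a warning
(eliminate only on evidence).

## Standard comparison

Spectral similarity is cosine over greedily tolerance-matched fragments
(default 0.01 Da) with square-root intensity weighting, normalized by the
full-spectrum norms (range [0, 1]).  Step 4 removes a candidate whose
parent-GA standard scores < 0.5 and flags scores > 0.8 as "supported";
both thresholds are package defaults (the published comparison was
qualitative) and configurable.  The GA7 reference spectrum in the fixtures
is a synthetic stand-in (the real standard spectra are not deposited),
constructed with disjoint fragment chemistry; the GA34 stand-in shares the
compound-10 anchor ladder.

## Synthetic runs

The simulator emulates: Gaussian elution profiles (σ = 0.05 min) on the
light and heavy channels with a configurable apex offset (default
0.005 min, inside the pairing window) and height ratio (default 1.0),
Poisson counting noise on signals, 2 ppm mass jitter, uniform random noise
peaks (40/scan, exponential intensities), and one DDA MS2 per spike near
the apex whose fragments follow the candidate's annotated loss ladder with
a geometric intensity profile.  MS1 scan rate defaults to 2 Hz (the
original acquisition rate is unpublished).  Decoys probe one criterion
each: ratio-violating pairs, RT-offset-violating pairs, and spectra
lacking the glucose-loss branch.  The default study condition is 3 true
spikes + 5 decoys per 40-min run; the screening performance test runs 50
seeded replicates.

Not emulated: chromatographic tailing, ion suppression, isotope envelopes,
co-eluting isomers, retention drift across runs.  Passing the synthetic
study therefore shows that the screening logic is correct under its own
assumptions — clean peak shapes and rule-conformant fragmentation — not
that real plant extracts would yield the published compound counts, whose
raw data are not available.

## Numerical choices

Grouping tolerance 0.001 Th; MS1/MS2 match tolerance 10 ppm; loss-ladder
depth 4; fragment lookups are binary searches on sorted arrays with
nearest-match tie-break; MS2 selection for a pair takes the nearest RT
within ±0.2 min, ties broken toward higher TIC; identical inputs produce
byte-identical reports.
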