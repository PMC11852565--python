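# Methods

This note documents the models and procedures nbpanel implements, the
defaults it ships, the numerical choices behind them, and what the
synthetic generators do and do not emulate.

## Repertoire annotation

Clones are modelled as rearranged V(+D)+J nucleotide sequences carrying
somatic point mutations.  The reading frame is chosen as the one with the
longest stop-free translation (minimum 30 aa; ties to the smallest
offset), which is robust to cloning-vector offsets of one or two bases.

Germline assignment is semi-global pairwise alignment (match 1,
mismatch 0, gap open −10, extend −1; free end gaps on the germline side)
of each reference V and J against the clone; the highest identity over
the aligned span wins, ties breaking lexicographically on gene name so
results are reproducible.  Counts are defined as:

- **V nucleotide mutations** — mismatches plus gapped columns inside the
  V alignment.  Indels count one per affected column (simplest auditable
  rule).
- **Amino-acid changes** — mismatched residues between the codon-aligned
  clone V region and the germline V translation; a codon disrupted by an
  indel counts once.  Because of silent and multi-hit codons the
  nucleotide count is typically 2–3× the residue count, and neither bound
  is enforced.

D segments are short and often trimmed beyond recognition, so D is
searched only in the junction between the V and J footprints by local
alignment and assigned only above a floor (≥ 8 aligned nt at ≥ 80%
identity); otherwise the call is left absent, which mirrors how real VHH
clades frequently have no identifiable D.  The V identity floor is 60%;
below it the clone is reported unassignable rather than given a
meaningless best hit.

CDR/framework intervals are fixed anchors on the germline V translation
(an IMGT-like scheme), transferred to the clone through the V alignment;
the CDR3 end comes from the assigned J gene's FR4-start anchor (the
tryptophan of the W-G-x-G motif).  Insertions inside CDRs beyond anchor
transfer are out of scope.

Candidate selection for NHS-ester biotinylation requires zero CDR3
lysines and at least three lysines elsewhere.  The comparator is
configurable (`at_least` vs `strict_greater`) because the campaign's
stated rule ("more than three") conflicts with its own selected panel,
which contains a clone with exactly three framework lysines; the default
follows the data.

Percent values in census tables are rounded to one decimal, half-up.
The identity matrix uses global protein alignment with identity =
matches / alignment columns; the cladogram is neighbor-joining
(scikit-bio) on distance = 100 − identity, with negative NJ branch
lengths clamped to zero.  NJ reproduces additive matrices exactly, which
the tests verify against path-length oracles on four-leaf trees.

## Dose–response

The 4PL model is fit by Levenberg–Marquardt least squares with the EC50
parametrized as log10(EC50) for conditioning.  Initialization is fixed
and data-driven (bottom = min y, top = max y, EC50 = dose nearest the
half-range crossing, hill = 1), so fits are deterministic.  Negative hill
solutions are canonicalized by swapping asymptotes.  A series whose
blank-subtracted span is below `min_response` (0.02 AU, about twice the
plate noise) is reported as `no_response` rather than fitted; an EC50
more than a decade outside the dosed range is flagged `extrapolated_ec50`.
Bottom/top are unconstrained (flags substitute for constraints).
Standard errors come from the Gauss–Newton covariance with a delta-method
transform for EC50.

Concentrations are stored in molar; mass-per-volume units are converted
with a per-clone molecular mass (default 14 kDa, a typical tagged VHH).

AUC is the trapezoid area of blank-subtracted A450 over log10 dose —
the log axis gives each step of a geometric (3-fold) dilution series
equal weight.  Negative blank-subtracted values are clamped to zero
before integration because the area feeds a ratio statistic.  With
replicates, fits pool all points while AUC averages per-replicate areas.

Apo-vs-RNP affinity comparison reports the EC50 fold difference
(larger/smaller) and calls "similar" at ≤ 3-fold, a conventional margin
for plate-assay reproducibility.  Cross-reactivity requires both a
maximum signal ≥ 3× the blank standard deviation and a converged,
in-range 4PL fit, so noise-only series fail both ways.

## Epitope binning

Percent binding is normalized to the largest corrected AUC *within the
same capture experiment* by default.  The alternative — normalizing to a
global direct-ELISA maximum — is available through
`bins_from_scores`/custom scoring, but per-experiment normalization
controls plate-to-plate gain and is the default because the
classification thresholds (25%/60%) were calibrated on per-plate
percentages.  Corrected areas below zero are clamped: an analyte binding
worse than the capture clone's own blocked twin is noise, not negative
binding.

A flat experiment (corrected-area spread below 10% of the largest raw
area) is disambiguated by absolute signal: mean net absorbance below
0.15 AU means no analyte bound — the capture clone blocks every epitope
probed, and all analytes are called same-epitope; a flat *high* signal
means the capture failed to block even its own biotinylated twin, and
the experiment is flagged unusable (no edges contributed).  The 0.15 AU
level sits well below any credible binding plateau (> 0.5 AU in these
assays) and well above blocked-signal leakage at realistic blockade.
One consequence: a panel in which *every* clone shares one epitope and
affinities differ widely can still defeat per-experiment normalization
when the capture is the weakest binder; resolving that case requires an
uncompeted reference plate.

Bins are connected components of the same-epitope graph.  Indeterminate
percentages (between the thresholds) contribute no edge — forcing them
would fabricate certainty.  Pairs called same-epitope in one experiment
and different in another keep their edge but are flagged as conflicts;
intra-bin pairs never directly assayed are flagged
"inferred by transitivity".

## Mass photometry

Calibration is a least-squares line from ≥ 2 protein standards.
Mixture fitting removes events below a 40 kDa floor (free 12–14 kDa
nanobodies are below the technique's detection limit), then fits
Gaussian mixtures for k = 1..max_k with quantile-spaced initial means
and a fixed seed, selecting k by BIC; candidates with any component
weight under 5% or sd under 1 kDa are rejected and the order reduced.

**Resolution limit.**  Populations separated by less than about 1.5 peak
widths are not identifiable by mixture likelihood at realistic event
counts: for two 12 kDa-wide populations 10 kDa apart, the global maximum
of the likelihood (verified by truth-initialized EM and exhaustive
multistart optimization) lies several kDa from the true means and the
information criteria prefer the merged model.  This is a property of the
statistical problem, not of the optimizer.  nbpanel therefore analyzes a
stepwise-binding titration the way the instrument acquires it — one
event set per incubation step, each with a single dominant complex
population — and reconstructs the mass ladder from the per-acquisition
dominant peaks.  At 10,000 events per step the dominant mean is
estimated to ±0.4 kDa (3 s.e.), far inside the 2 kDa agreement required
to read single-nanobody steps.

Complex assignment enumerates all nanobody subsets, minimizing
|antigen + Σ masses − peak|, ties preferring fewer bound nanobodies then
lexicographic order (so results are independent of input order).  The
±8 kDa tolerance separates single-nanobody steps (10–20 kDa) without
merging them.

## Cleavage kinetics

Percent cleavage per lane is 100·Σproducts/(uncut+Σproducts); band
intensities are taken as already mass-proportional (stain scaling), with
optional per-band weights.  A once-cut linear substrate contributes two
product bands summed unweighted.  Time courses are triplicate means with
sample standard deviations (ddof = 1).  The inhibition call compares
control and treated on the union grid of their overlapping time ranges
(linear interpolation) and declares inhibition when the absolute
difference exceeds 15 percentage points anywhere — a deliberately
conservative threshold for a qualitative equal-activity claim; the
magnitude is symmetric in argument order.  Assay composition (14 nM RNP,
28 nM nanobody, 1.4 nM plasmid) is carried as metadata only.

## Synthetic generators

All generators are bit-reproducible from (config, seed) and emit a
ground-truth sidecar.  Defaults encode the campaign's study conditions:
12-point 3-fold dilutions from ~80 µg/mL (5.7 µM to 32 pM at 14 kDa), a
nine-clone EC50 ladder spanning 2–63.4 nM, three epitopes partitioned
{C1} / {F9, C7} / {E6, F1, F8, G10, G7, D9}, absorbance noise sd 0.02 AU
with blank 0.05 AU, mass peaks 160/180/190/209 kDa at 12 kDa width, and
cleavage time points 1/5/10/60 min in triplicate.  Where the campaign
reports only ranges, single values were fixed once: the four weaker-clone
EC50s (18.5/21/37/63.4 nM) respect the published two- and three-fold
ratios within the clade, and the cleavage rate constant 0.45 min⁻¹ puts
the 1-, 5- and 10-minute points on the rising phase as in the reported
traces.

The repertoire generator plants substitutions only (no indels) in the V
segment, choosing silent or non-silent codon changes with a configurable
fraction and never creating stop codons; this keeps the mutation-count
oracle exact (position-wise comparison to the source germline).  An
exact per-clone mutation count can be planted to reproduce the selected
panel's census.  Competition plates model blockade as a multiplicative
occupancy factor ε = 0.05 when analyte and capture share an epitope —
sufficient to exercise the statistic without a ternary-complex
equilibrium model.  Gel noise is multiplicative (densitometry error
scales with band intensity).

What the generators do *not* emulate: plate-position and edge-well
effects, hook effects at high dose, avidity and partial epitope overlap
(blockade is binary), mass-photometry contrast nonlinearity and binding
on the coverslip, gel background subtraction, and indel-containing
somatic variants (available behind the substitution-only default but not
part of the tested oracle).  Passing tests therefore demonstrate
correctness of the statistics and estimators under idealized noise, not
robustness to every plate artifact.

## Problem sizes

The test suite and the reproduction script use: exhaustive epitope maps
over ≤ 4 clones plus 100 seeds of the nine-clone layout at noise 0.02;
100 simulated curves per noise level for EC50 recovery; 10,000 events
per mass-photometry acquisition; 100 equal-rate gel pairs for the
inhibition verdict.  These sizes give binomial uncertainty below 5
percentage points on all reported rates while keeping a full run in
seconds.
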