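# Methods

## The measurement model

The assay digests a lysate above a molecular-weight-cutoff filter and
collects the filtrate at the end of every sampling interval (hourly, 1–8 h
by default). Undigested protein stays above the filter; released peptides
pass through. Each filtrate fraction is TMT-labelled, so one multiplexed
run quantifies all time points of both conditions for one replicate. The
analysis operates on the resulting per-peptide, per-channel reporter
intensities; everything upstream (labelling chemistry, LC-MS/MS, database
search) is out of scope and is assumed to have produced a MaxQuant-style
peptide table.

## Per-peptide statistic

Profiles are normalized per replicate within each condition (each profile
divided by its own maximum). The center of gravity
CoG = Σtᵢaᵢ/Σaᵢ is computed per replicate from the raw normalized points —
never from a smoothed fit — and is scale-invariant in the abundances, so
the normalization choice affects exported curves only. The per-replicate
normalization (rather than normalizing a replicate-averaged profile) makes
each centroid independent of between-replicate loading differences, which
the subsequent unpaired test requires.

ΔCoG = mean(CoG treated) − mean(CoG control) is tested with a two-sided
equal-variance Student's t test on the centroids (df = n₁+n₂−2). Zero
pooled variance leaves the p-value undefined (NaN, flagged), never 0 or 1.
Significance cutoffs are strict inequalities: p < 0.05 and |ΔCoG| > 0.5 h.
A fourth-order polynomial fit is available for curve export and requires
five distinct time points; it plays no role in inference.

Peptides missing any point of any profile are excluded from testing by
default (`min_points` relaxes this): centroids computed on different
supports are biased toward the observed interval, and the bias differs
between conditions when missingness does. Intensities of exactly zero are
treated as missing (non-detection), following the MaxQuant reporter
convention. Modified-sequence variants collapse onto the bare sequence by
summation; the peptide key is (sequence, protein group).

## Protein-level aggregation

Peptide p-values of a protein are combined with Fisher's method,
χ² = −2Σln pᵢ on 2k degrees of freedom. Only peptides unique to one
protein group enter the combination — shared peptides are reported but
excluded, since they smear evidence across groups and undermine the
independence assumption. That assumption is already approximate (peptides
of one protein share its kinetics); the method is applied as-is and the
caveat stands. p-values of exactly zero are floored at 1e−300 with a
warning before the logarithm. The protein ΔCoG is the median over its
tested peptides' shifts; the Bonferroni multiplier is the number of
proteins with at least one tested peptide. Rank-sum prioritization ranks
|ΔCoG| descending and p ascending with average ranks for ties; ranking on
p is monotone-equivalent to ranking on log₁₀(p) and avoids log-of-zero
handling. Ties in the final ordering break by p, then sequence.

## Concentration mode

At a fixed digestion time (2 h default) over a dilution series
(0, 0.1, 1, 10, 100, 1000 nM default), the fold change divides the mean
relative abundance of the two lowest treatment concentrations by that of
the two highest. The 0 nM vehicle is not a treatment concentration and is
excluded by default (`include_vehicle` reverses this). No test is implied
by the fold change itself; the accompanying p-value is a two-sided pooled
t-test between the pooled low and pooled high abundances — the same
machinery as time mode, chosen as the most parsimonious option since no
specific test is canonical for this design. An abundance filter keeps the
top 30,000 peptides by mean raw intensity (inclusive at ties) before
ranking. No sigmoid or occupancy curve is fitted for calling; the
simulator's occupancy model is available as a diagnostic overlay only.

## Binding-site localization

The top-k (default 3) peptides by p-value are placed on the structure by
exact substring search of each chain's one-letter sequence (residues in
author-number order; nonstandard residues map to 'X' and break matches,
which is reported). Unmapped peptides are skipped and replaced by the next
candidates; ambiguous multi-chain matches resolve deterministically to the
span nearest the ligand. ΔCoM is the Euclidean distance between the
mass-weighted center of mass of all atoms of those peptides and that of
every residue with any atom within 5 Å (inclusive, atom–atom) of any
ligand atom. Mass weighting is the default reading of "center of mass"; an
unweighted option exists. Hydrogens absent from crystal structures are
simply not counted. Waters are dropped at parse time and alternate
locations resolve to the highest-occupancy conformer.

## Simulator

Ground truth is generated from a first-order release model: peptide j with
rate k has interval yields y_j = A·[exp(−k·t_{j−1}) − exp(−k·t_j)], t₀ = 0,
i.e. the buffer replacement above the filter is ideal and interval yields
are independent increments. Ligand binding multiplies the rate of affected
peptides of target proteins: protected peptides use ρ·k (ρ = 0.5 default)
and flexibilized peptides k/ρ. In concentration mode occupancy follows a
one-site isotherm θ(c) = c/(c + K_d) and k_eff = k·(1 − θ·(1 − ρ)) at a
fixed 2 h digestion. Noise is multiplicative log-normal per channel
(σ = 0.1 default, reporter-ion behaviour; no channel cross-talk or isotope
impurity), and channels drop to missing independently with probability
0.02 by default.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| time grid | 1–8 h hourly | the emulated sampling scheme |
| rate law | ln k ~ N(ln 0.5, 0.5²) h⁻¹ | median release half-life ≈ 1.4 h, keeping most peptides informative within the 8 h window |
| protection factor ρ | 0.5 | a two-fold local rate change; gives noiseless ΔCoG ≈ 0.5–0.9 h over the bulk of the rate law |
| noise σ | 0.1 | ~10% reporter CV, typical of fractionated TMT |
| replicates | 3 | the emulated design |
| target fraction | 0.01 | drugs hit few proteins proteome-wide |
| protected/flexibilized per target | 3 / 1 | a binding site touches a minority of a protein's peptides |
| K_d | 10 nM | centred in the 0.1–1000 nM series |
| missing rate | 0.02 | low within-run TMT missingness |

What the simulator does *not* emulate: sequence-realistic tryptic digestion
(peptides are random strings, not cleavage products of a FASTA proteome),
correlated missingness (real TMT missingness is mostly per-run, not
per-channel), ratio compression, batch effects between TMT sets, or any
dependence between peptides of one protein beyond the shared protein
abundance. Pipeline power and calibration measured on simulated data
therefore characterize the statistics under the stated kinetic model, not
the full error structure of real LC-MS/MS data.

Evaluation configurations: calibration uses a 500-protein × 10-peptide
null proteome; power and ranking use 300 proteins × 10 peptides with 4%
targets over three seeds; concentration-mode recovery uses 1% targets with
protection-only effects, matching the emulated dose-response experiment in
which every responding target peptide was protected. These runs set the
missing rate to 0 so that completeness filtering does not confound the
power and error-rate estimates; problem sizes are chosen to give stable
proportions (≥100 protected peptides for the power estimate) at
desk-scale runtimes.

## Numerical choices and degeneracies

- All-zero or all-missing profiles raise a degenerate-profile error and are
  excluded with a logged reason, never silently.
- The t statistic is computed from the pooled sum of squares directly;
  p-values use the exact t distribution (scipy), and the Fisher χ² tail is
  the exact chi-square survival function.
- Row bookkeeping is an invariant: input peptides = tested + dropped, by
  recorded reason, checked in the pipeline and surfaced in logs and
  `summary()`.
- Boundary behaviour is documented and strict: volcano cutoffs use < and >,
  the 5 Å shell uses ≤, the abundance filter keeps boundary ties.
- Same seed ⇒ bit-identical simulated tables; every stochastic draw flows
  from one `numpy` Generator.

## Known limitations

A flexibilized peptide at a fixed digestion time is saturation-limited: if
k·T is already large, doubling the rate barely changes 1 − exp(−k_eff·T),
so concentration mode has intrinsically weak power for flexibilization —
protections dominate its calls. Time mode has the complementary blind
spot: very fast or very slow digesting peptides compress the attainable
|ΔCoG| below the 0.5 h cutoff regardless of effect size. Fisher's
combination treats peptide p-values as independent, which they are not
within a protein; the resulting protein p-values are optimistic and the
Bonferroni correction is partly compensatory. Binding-site localization
reports a point estimate (ΔCoM) with no uncertainty; with fewer than three
mappable peptides it proceeds with a warning.
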