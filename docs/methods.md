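# Methods

This note documents the models, estimators, parameter defaults and design
choices behind `phagecocktail`, and what the synthetic-data generators do
and do not emulate.

## Susceptibility matrices and coverage

The central object is a dense phage × strain matrix whose cells are either
qualitative plaque calls (`clear` / `turbid` / `none`) or nonnegative EOP
values. Binarization is deterministic and recorded: `clear` → susceptible,
`none` → resistant, `turbid` → resistant by default (host range counts
clear plaques; the call is configurable), EOP susceptible iff strictly
greater than a threshold (default 0, i.e. any plaque formation counts —
host range here scores lysis, not plating efficiency).

Percentages are rounded half-up to one decimal. This rule is load-bearing:
it makes count↔percent inversion exact for the published panel statistics
(80/156 ↔ 51.3, 48/156 ↔ 30.8, 85/156 ↔ 54.5, 12/156 ↔ 7.7, 133/156 ↔ 85.3,
119/156 ↔ 76.3, 87/156 ↔ 55.8), which the test suite verifies by a
round-trip oracle. Complementarity of a pair is strict inequality of the
union over both singles **on counts**, never on rounded percentages, to
avoid rounding ties.

Matrix files are phage-rows × strain-columns. The transposed layout is the
classic corruption mode for these tables, so it is auto-corrected only when
catalog ids disambiguate the orientation and rejected when ambiguous. Ids
are compared case-sensitively after whitespace trimming.

## Marginal-consistent matrix reconstruction

The strain-level susceptibility matrix behind the published per-phage host
ranges is not deposited; only marginals are available: 25 single coverages,
21 pairwise unions among the seven cocktail candidates, and named set
unions (the 7-phage candidate mix, the 5-phage PAM2 mix, the 5-phage PAM1
mix, and the whole-panel unions). `reconstruct_matrix` recovers a binary
matrix consistent with all of them:

- Percent targets are inverted to counts by round-half-up; two pairwise
  cells (61.6 and 60.1) are not expressible as k/156 under any standard
  rounding and are matched to the nearest count, leaving irreducible
  deviations of 0.1 and 0.2 percentage points — inside the 0.2 pp
  tolerance the spec of the reconstruction carries.
- Counts are checked against union bounds (max single ≤ pair union ≤ sum of
  singles, capped by the panel) before any search; violations raise an
  infeasible-spec error.
- Search: simulated annealing over row-preserving swaps. A move exchanges
  one susceptible and one resistant strain within a single phage row, so
  per-phage coverages set at initialization are invariants of the search.
  The objective is the summed squared deviation of every pair/set union
  from its target count. Support is restricted to a covered region sized by
  the whole-panel union (133 of 156 strains), which makes the all-phage
  union constraint structural rather than searched. Geometric temperature
  schedule 4.0 → 0.02, default 400k iterations with up to 8 restarts;
  the published system is solved in a few seconds and is satisfiable at
  every seed tried.
- The return value always carries a per-constraint report (target count and
  percent, achieved count and percent, deviation); an unsatisfied search
  returns the best matrix found with its deviations stated, never a silent
  pass.

The reconstruction pins unions, not higher-order structure: any statistic
beyond the constrained marginals (e.g. three-way overlaps among
non-candidate phages) is an artifact of the sampler, and analyses on the
reconstructed matrix should only ever read the constrained quantities.

## Resistance frequencies and interaction classification

The denominator of a resistance frequency is back-calculated from
serial-dilution titration counts (replicate mean of count/(dilution ×
volume), scaled to the challenged volume). Zero resistant colonies yield a
censored estimate at the detection limit 1/denominator, printed `<value`;
the true frequency lies in (0, bound]. A typical titration of the assay
design (114 colonies at 10⁻⁶ dilution from 0.1 mL, 0.1 mL challenged)
implies the bound 8.77 × 10⁻⁹ seen throughout the published table.

Pair interactions compare the mix frequency with the **minimum** of the two
single frequencies. The minimum — not the product — because a colony on the
mix overlay need only resist the more restrictive phage; the published mix
values track the min single, not the product of singles. Defaults:

- synergy: log10(expected/mix) ≥ 0.5. The published "roughly 1-log lower"
  pairs span ≈0.4–0.95 logs against the min single, so a 1.0 threshold
  would miss most of them; 0.5 is the default and a config knob.
- antagonism: mix ≥ 10 × the larger single.
- censoring: intervals are propagated conservatively. A censored mix below
  an uncensored expected value is "synergy (censored)" only when the bound
  itself guarantees the threshold; when the expected value is itself a
  bound (both members censored), the comparison is undecidable and the call
  is "indeterminate" — never a hard class.

Monte-Carlo calibration (Poisson counts at known frequency) shows the
estimator's mean relative error < 5% once the expected resistant count
N·f reaches 100, verified over 1,000 seeded replicates in the suite.
Fluctuation analysis (mutation *rates*) is out of scope; the pipeline works
with frequencies as assayed.

## Receptor inference

Receptor classes are inferred from plaque outcomes on twelve PAO1
knockouts. Each mutant is modeled as the wild-type feature set minus known
losses (e.g. `wbpL` initiates both A- and B-band synthesis, so its loss
removes A, B and both chain-length classes; `rmlC` truncates the core and
thereby removes everything distal). A phage of class *c* lyses a mutant iff
the mutant retains every feature in *c*'s requirement set:

| class | required features |
|---|---|
| 1 | T4P + A band |
| 2 | T4P + core |
| 3 | T4P + long & very long B band |
| 4 | T4P + A, B, long-B, very-long-B |
| 5 | T4P + A, B |

Inference inverts this forward model deterministically from the loss
pattern. Decisions that were genuinely open:

- `reduced` plaques count as lysis for classification but are flagged in
  the evidence trail (the published conclusions are binary).
- Flagellar (`fliA`) losses never change the class — no phage in the
  catalog is flagellotropic — and are reported as a warning.
- The two independently sourced `rmlC` mutants must agree; disagreement is
  an inconsistent panel, not a judgment call.
- A `wapQ`-only loss (inner-core phosphate) has no published mapping; it is
  treated as core dependence (class 2) and flagged.
- A phage lysing wild type with *no* LPS-mutant loss matches none of the
  five classes and raises an inconsistent-panel error; the table is total
  over outcome maps generated by the five classes plus the
  PAO1-nonpermissive (unknown) pattern, which the generator/inferrer
  round-trip property exercises for every class.

## Stability and compatibility

Stability compares every later titer against the initial one:
max log10 drop, clamped at zero for increases, against an allowance of
0.5 log — the conventional plaque-titration error band; the method's error
is not quantified in the source assays, so the default is a documented
choice, configurable per call. Below-LOD points contribute the implied drop
as a lower bound and force instability when the bound exceeds the
allowance. No decay curve is fitted: verdicts mirror direct plate-count
comparisons and a single storage condition per series. A pair is compatible
iff the mix and both singles are stable; the failure report distinguishes
single-phage decay from mix-specific decay.

## Biofilm assays

Crystal-violet dispersal uses the percent reduction of mean OD595, treated
vs control, with a dispersal call requiring (i) reduction ≥ 20% (effect
floor) and (ii) a one-sided Mann–Whitney test below alpha = 0.05 (Welch's t
available). The published assay reports sextuplicate ODs but names no test;
the rank test is the default because plate ODs are heteroscedastic and
often skewed. The null false-positive rate of the combined rule stays below
1.5× alpha (seeded simulation in the suite). Bactericidal effect is
log10(control/treated) CFU; "most concentrated countable dilution" is
operationalized as 3–300 colonies, ties toward more colonies; a below-LOD
treated count yields a censored "≥" bound.

## Cocktail optimization

Candidates are filtered with machine-readable exclusion reasons: temperate
or undetermined lifestyles are always excluded when strictly lytic phages
are required; a host-range floor (the published analysis treats ≥30% as
broad) removes narrow phages. Fully complementary candidate sets are
cliques of the pairwise-complementarity graph (networkx enumeration,
brute-force-verified in tests). Cocktail ranking uses the key (coverage
desc, worst single-phage resistance asc, receptor diversity desc, genus
diversity desc, member ids), encoding the narrative priority of the design:
resistance separates coverage-equivalent sets, as when EPa17/EPa43 were
preferred over broader candidates on resistance grounds. Censored
resistance bounds count as their bound value — conservative for a cap,
optimistic in ranking — and both uses are visible in the evaluation.
Exhaustive mode refuses beyond a subset budget (default 10⁶) rather than
silently truncating; greedy mode is plain accretive maximum coverage with
no local search, keeping the (1 − 1/e) guarantee analyzable, and the suite
checks that bound against the exhaustive oracle on seeded instances.

## Synthetic panels

`generate_panel`/`generate_matrix` emulate the *mechanism* the receptor
analysis implies: strains carry hierarchical receptor genotypes (A/B bands
require an intact core; chain-length classes require the B band), phages
require their class's feature set, and an independent per-(strain, phage)
immunity draw (default 0.25) stands in for abortive infection, CRISPR and
restriction systems. Defaults (T4P 0.9; core 0.95; A 0.7 and B 0.8 given
core; long-B 0.6 and very-long-B 0.55 given B) give a mean single-phage
host range near 35%, matching the scale of the published panel, and
sequence-type labels follow a skewed few-common/many-rare distribution with
a guaranteed ST richness (156 strains / 106 STs at panel scale).

What the generators do **not** emulate: phylogenetic correlation between
strains (STs are labels, not genotypes), receptor-independent host-range
structure, temperature dependence of stability, or plaque-morphology
detail. Tests passing on synthetic panels therefore validate the
estimators' arithmetic and invariants, not the biology of any particular
strain collection.

## Problem sizes and determinism

Every stochastic component takes an explicit seed and is a pure function of
(configuration, seed). The suite runs the full 25 × 156 reconstruction once
(seconds), 1,000-replicate Monte-Carlo calibrations, a 10,000-draw null
simulation for the dispersal test, and exhaustive-oracle comparisons up to
12 phages choose 4 — sizes chosen so the whole suite completes in well
under a minute while leaving the estimators' asymptotics visible.

## Known limitations

- The reconstruction constrains only the published marginals; it is one
  member of a large equivalence class of matrices.
- Two published pairwise cells are internally inconsistent with the panel
  size (see above); they are matched to the nearest achievable count and
  reported, not forced.
- The receptor decision table is a reconstruction of the published
  *conclusions*; per-mutant raw patterns were not published, so only its
  internal consistency and generator round-trip are testable.
- Censored comparisons deliberately refuse a class ("indeterminate") where
  the intervals cannot decide; downstream code must handle that outcome.
- No pharmacokinetics, dosing, or in-vivo efficacy prediction: animal-model
  outcomes are reported metadata, outside the package's scope.
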