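# Methods

This note documents the measurement model, the classification rules, the
kinematic relations, the synthetic-data generator, and the numerical
conventions, together with the design choices made where the problem was
genuinely open and the limits of what the tests demonstrate.

## Measurement model

A track is six required landmarks in a planar, cm-scaled frame with an
arbitrary origin: `tip_II`, `tip_III`, `tip_IV` (digitized at the digit pad
terminus — ungual/claw marks are excluded from all lengths by digitization
convention, because their preservation varies too much between tracks),
`hypex_II_III`, `hypex_III_IV` (the interdigital notches), and `heel` (the
posterior track margin).  Optional landmarks carry the hallux
(`hallux_tip`, `hallux_base`); additional points use an `x_` extension
namespace.

Definitions:

* **L** = |tip_III − heel|; the track axis is the heel → tip_III ray.
* **W** = |tip_II − tip_IV| (the anterior-triangle base), so that mesaxony
  te/W is the standard anterior-triangle ratio.
* **te** = perpendicular distance from tip_III to the line through the
  lateral tips.  Collinear tips (within 1e-9 cm) give te = 0 with a warning.
* **L_II, L_IV** = distance from the adjacent hypex to the tip; **L_III** =
  distance from the midpoint of the two hypexes to its tip.
* **α, β** = interdigital angles II–III and III–IV, measured at the proximal
  intersection of the digit midlines.

The angle vertex deserves a comment, because it is the one place where the
obvious construction fails.  Digit midlines are directions fitted along each
digit; on weakly splayed tracks they intersect *posterior of the footprint*
(a virtual point), and no combination of the six required landmarks can
stand in for that vertex in general: tying the vertex to the heel or to the
hypexes forces an algebraic relation between W, te and α+β (approximately
total divarication ≈ 2·atan(W / (2(L − te)))) that strongly mesaxonic,
narrowly divaricated tracks — a combination that real grallatorid-grade
material routinely exhibits — cannot satisfy.  The package therefore treats
the midline intersection as its own (virtual, digitizable) point, carried in
landmark files as the extension label `x_axis_apex`; when it is absent
(e.g. heavily worn material where midlines cannot be traced) the heel is
used as the fallback vertex and the angles should be read as
tip-subtension angles rather than midline divarication.

Derived metrics: l/w = L/W, III/II = L_III/L_II, III/IV = L_III/L_IV,
III/L = 100·L_III/L (%), mesaxony = te/W, total divarication = α + β
(exact by construction).  Missing constituents or zero denominators
propagate as explicit missing values; nothing is zero-filled.

**Siding and relief.**  Positive-relief tracks are infill casts on the base
of beds, so their apparent footedness is reversed: an observed right is
catalogued left, with a `mirrored_for_relief` flag.  In measurement tables a
`*` after the L/R letter marks such casts.

**Record validation** checks the arithmetic identities a measurement row
must satisfy (divarication additivity to 0.02°, the three ratio columns to
0.02 / 0.05 for the III/L percentage — tolerances that absorb two-decimal
rounding of the raw columns) and the length class against the standard bins
(tiny < 10 cm ≤ small < 20 ≤ medium < 30 ≤ large < 50 ≤ giant).

## Classification: the Hebridean rule engine

Rules live in `data/hebridean_rules.yaml` (versioned; the series can be
extended without code changes).  Each subgroup carries:

* a **size gate** on the length class (hard; a missing length never gates);
  additionally no track ≥ 15 cm is ever assigned to HBR_B3 and none ≥ 10 cm
  to HBR_B4.  HBR_B1.3's nominal "approximately 30 cm" straddles the
  medium/large bin boundary, so its gate admits both.
* **morphology gates**: a posterior (reversed) hallux restricts candidates
  to HBR_B4; an anterolateral padded hallux to HBR_B1.2; a known digit
  shape must be among the subgroup's allowed shapes (parallel-sided for
  B1.1/B1.4, sub-parallel for B1.2/B1.3/B1.4, spindle for B2.1/B2.2,
  broad-round for B2.3, gracile for B3.x/B4); broad-round digits enclosing
  sinuous inner margins are definitional for HBR_B2.3.
* **metric predicates** with bounds transcribed from the subgroup diagnoses
  and widened by half a unit in the last printed place (0.005 on ratios,
  0.5° on angles), because the diagnosed ranges are themselves quoted at two
  decimals from rounded measurements; evaluating recomputed full-precision
  ratios against unwidened bounds would misjudge boundary rows whose printed
  values satisfy them.  Hedged bounds ("generally", "typically", "often")
  are soft predicates contributing to a score; the one unhedged bound that
  separates a subgroup pair — the B2.1/B2.2 split at l/w 1.30 — is a hard
  gate.
* a **combination rule**: `all` (every applicable predicate) or `at least
  k` — the B3.1/B3.2 pair uses "at least two of" its three opposing bounds,
  mirroring how those forms grade into one another.

Scores are normalized by the number of *applicable* predicates (a predicate
on a missing metric or flag never counts satisfied and never inflates the
denominator).  Fully matching candidates outrank partial matches, then the
higher score wins; exact ties fall to a fixed preference order (B1.x < B2.x
< B3.x < B4) with the co-maximal alternatives recorded as ambiguity — a
record invariant: ambiguity is non-empty exactly when a tie-break chose.

**Status** is grade-driven: grade ≥ 1.5 characterizes; grade 1 characterizes
only when an explicit `wear_acceptable` flag says surface wear permits it
(that judgement is the operator's, not the engine's); grade in [1, 1.5)
otherwise refers; grade < 1 refers at best.  Note the source tables
themselves characterize one broad-digited subgroup (HBR_B2.3) from sub-grade
material; the packaged table therefore carries the published status as its
own column, and abundance counts use that column rather than re-deriving
status.

On the packaged 85-track table with curated morphology flags the engine
recovers the published subgroup for 85/85 records.  Withholding the flags
(metrics only) drops agreement to 70/85 and raises the number of
tie-broken, ambiguity-carrying records from 0 to 25 — the morphology
carries real information, and the audit separates "ambiguous" from
"misassigned" so nothing fails silently.

## Trackway kinematics

From ordered reference points (IPs) in a surface frame: pace = consecutive
IP distance (alternate feet; violations are flagged, not fatal), stride =
next-but-one distance, WAP = perpendicular distance from the middle IP to
the stride line, pace angulation = interior angle at the middle IP, and
rotation = angle between a track's long axis and the trackway midline (the
polyline through pace-line midpoints), signed positive away from the
midline.  With n steps: n−1 paces, n−2 strides/WAPs/angulations.

Estimates use h = 4·FL (FL = unrounded mean track length), V = c·g^0.5·
λ^1.67·h^−1.17 with g = 9.81 m s⁻² fixed and c = 0.25 or 0.226 (the two
variants differ by the exact factor 0.904 for all inputs), and gait = λ/h
(2.0 is reported as "boundary").  All estimates are computed from unrounded
intermediates; display rounding (half-up, two decimals) happens only at
serialization.  Two-track sequences are accepted as associations yielding a
pace or stride but never estimates.

Two reproduction caveats, both documented rather than silently matched:
the published velocity pair for the small packaged trackway prints the
recalibrated velocity *above* the classic one, which the fixed 0.904 ratio
forbids — full-precision evaluation gives ≈ 0.75/0.68 m s⁻¹ and the pair is
reproduced unordered; and that trackway's published gait of 1.26 arises only
if the stride is first rounded to 0.52 m, whereas the canonical
full-precision value is 1.27.  Likewise the packaged trackway coordinates
match the printed paces and stride exactly; the printed pace angulation is
then over-determined and emerges 0.06° lower.

## Assemblage statistics

Subgroup summary means average the recorded display-precision columns over
characterized rows only (the tables' own convention), column-wise over
present values.  Correlations are sample Pearson coefficients over rows
selected by an explicit named inclusion rule (`both-present`,
`characterized`, `exclude-subgroups:...`) with n recorded, undefined below
n = 3 or at zero variance — published scatterplot exclusion sets are rarely
recoverable exactly, so the rule is part of the result.  The toe-extension
allometry panel emits (L − te, te) pairs with a descriptive OLS slope, no
inference.  Windroses bin bearings into [k·w, (k+1)·w) (default w = 15°,
the conventional rose resolution) and report the circular mean and mean
resultant length R̄ from the unit-vector sum; R̄ near zero is reported as
"no preferred direction".

## Synthetic data

`sample_metrics` draws L, l/w, mesaxony, divarication, III/L and the digit
ratios **uniformly** within each subgroup's diagnosed/described ranges —
the sources report ranges, not distributions, so uniform is the
least-informative choice; synthetic realism is accordingly limited to range
containment, and the generator makes no claim about covariance structure,
substrate effects, or intra-trackway correlation in real assemblages.
Passing tests therefore demonstrate correctness of the pipeline's
arithmetic and logic under the diagnosed ranges, not robustness to every
taphonomic situation in the field.

`construct_landmarks` inverts the measurement exactly and in closed form:
digit III along +y with the heel at the origin; the axis apex at depth
a = W/(tan α + tan β) − (L − te) below the heel so the lateral tips lie on
the apex rays *and* on a width line perpendicular to the axis at height
L − te (making W and te exact simultaneously); hypexes by circle
intersection so the three digit lengths are exact, with the hypex midpoint
on the axis and the II-side branch chosen deterministically.  Infeasible
requests (te ≥ L, digit lengths incompatible with the tip geometry, angles
outside (0°, 90°)) raise an error naming the violated constraint; the
sampler rejects and redraws such combinations.  Round-tripping
measure ∘ construct over 1 000 mixed draws stays below 1e-12 cm/deg —
the module's central contract, asserted at 1e-6 in the tests.  A seeded
random rigid motion can be applied to mimic arbitrary digitization frames;
metrics are invariant under it and under mirroring.

**Strict draws** sample from ranges nested inside each subgroup's exclusive
metric region, so that together with the subgroup's template morphology
flags the classifier recovers them at 100 % with zero noise.  Two subgroups
have no exclusive metric region and are flag-defined instead (HBR_B1.2 by
its hallux + heel, HBR_B2.3 by its broad-round inner-margin digits); the
"wide" tiny form HBR_B3.2 restricts strict draws to lengths above 10 cm to
stay out of the HBR_B4 size class.

**Wear model.**  Severity s ∈ [0, 1] jitters every landmark (Gaussian,
0.35·s cm), erodes digit tips toward the track centroid (0.30·s cm),
drops optional landmarks (probability 0.35·s each — losing the digitized
axis apex degrades the angle measurement realistically), and maps severity
to a preservation grade linearly from 3 down to 0.5 in half steps.
Severity 0 is the identity.  The defaults are chosen so that a severity of
1 visibly corrupts a tiny (≈ 7 cm) track's metrics while a severity of 0.25
mostly survives classification; classification accuracy on strict
narrow-form draws is monotone non-increasing across severities
{0, 0.25, 0.5, 0.75} (Monte-Carlo, n = 500 per severity, fixed seed).

**Trackways** are generated straight: one track length per trackway, stride
λ = gait·4L, alternating lateral offsets of half the step width, so the
estimator recovers the requested gait exactly at zero jitter (within 1 %
asserted over 20 seeds).  **Assemblages** mix subgroups by weight and draw
bearings from either a von Mises model (directed movement, default κ = 8 —
tight enough that R̄ typically exceeds 0.8 at n = 36) or a uniform model
(undirected "milling"); the discrimination test compares R̄ against the
95th percentile of the uniform null at the same n.

## Numerical conventions

* Stored values are full precision; display rounding is half-up at two
  decimals (the tables' precision) and applied only at serialization.
* Comparisons against printed values use tolerances absorbing the sources'
  own rounding: ±0.02 on ratio columns, ±0.05 on the III/L percentage,
  ±0.01 (+half-ULP) on summary means; grade averages are printed at one
  decimal in places and compared accordingly.
* Tie tolerance in the classifier is 1e-9 on normalized scores.
* Seeds: every stochastic routine takes a seed or a numpy Generator;
  identical seeds give identical outputs, and the acceptance script derives
  all of its randomness from its `--seed` argument.

## Known limitations

* Landmarks arrive digitized; there is no image processing or outline
  extraction, and no automated preservation grading (the grade is operator
  input by design — the criteria are qualitative).
* Digit lengths measured from hypexes do not attempt to include proximal
  pad extents (e.g. a digit-IV metatarsophalangeal pad); agreement with
  published tables is therefore asserted on ratios, not raw digit lengths.
* The rule set encodes the Hebridean series only; other regional morphotype
  schemes would ship as alternative rules files.
* Correlation reproduction is sign- and magnitude-level, not digit-exact,
  wherever the published exclusion set is ambiguous.
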