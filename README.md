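# trackmorph

Quantitative ichnology for tridactyl (three-toed) dinosaur footprints:
landmark-based track measurement, rule-based classification into the
Hebridean morphotype series, trackway kinematics and trackmaker estimation,
and assemblage-level statistics — with a synthetic track generator so every
stage is testable without any download.

## Who it is for

Ichnologists and palaeontology students working with digitized footprint
outlines (orthophotos, photogrammetric models) who want the standard
measurements, a reproducible and auditable morphotype assignment, and the
classic trackway biomechanics, all from plain delimited text files.

## The science in brief

A tridactyl pes track is reduced to six landmarks: the three digit-tip pad
termini (ungual marks excluded), the two interdigital hypexes, and the heel.
From these the package measures total length *L* (heel to digit-III tip),
width *W* (between the lateral digit tips), digit lengths *L*<sub>II</sub>–*L*<sub>IV</sub>,
the digit-III toe extension *te* (height of the anterior triangle whose base
joins the lateral tips) and the interdigital angles *α* (II–III) and *β*
(III–IV).  Derived ratios are *L/W*, the digit ratios III/II and III/IV,
III/*L* (%), and mesaxony *te/W* — the anterior-triangle ratio expressing how
far the central digit projects.

Classification follows the Hebridean series: four bipedal morphotypes
(HBR_B1–B4, ten subgroups) diagnosed by metric ranges and morphology — e.g.
HBR_B3.1 ("narrow" grallatorid form) needs at least two of *l/w* > 1.50,
mesaxony > 0.7, divarication < 50°, while HBR_B3.2 ("wide" form) needs the
opposing pair of bounds.  The engine scores every subgroup, gates candidates
on size class and morphology (a reversed hallux is unique to HBR_B4, an
anterolateral padded hallux to HBR_B1.2), and records tie-breaks as explicit
ambiguity.  Preservation grade (0–3) governs whether an assignment counts as
*characterized* or merely *referred*.

Trackway kinematics use the classic relations

    h    = 4 · FL                       (hip height from track length)
    V    = c · g^0.5 · λ^1.67 · h^-1.17 (c = 0.25, or 0.226 recalibrated)
    gait = λ / h                        (< 2 walking, > 2 running)

with *λ* the stride, *g* = 9.81 m s⁻², and FL the trackway-mean track length.

## Worked example

The packaged 85-track characterization table (transcribed measurement
tables from the two Isle of Skye localities) pipes straight into the
classifier:

```sh
$ trackmorph fixture | trackmorph classify -
specimen,subgroup,series,status,ambiguity,suggested_ichnotaxon
2002.004,HBR_B1.1,HBR_B1,characterized,n/a,Megalosauripus isp.
...
trackmorph: audit report:
trackmorph:   records: 85
trackmorph:   with published subgroup: 85
trackmorph:   agree: 85 (100.0%)
```

The rule engine recovers the published subgroup for all 85 characterized
tracks.  The large-theropod trackway fixture reproduces the published
biomechanics:

```sh
$ trackmorph trackway VA10
# trackway VA10 (n=3 tracks)
track,L_cm,p_m,lambda_m,WAP_cm,alpha_deg,gamma_deg
VA10-1,35.75,1.05,2.1,10.26,5.56,n/a
VA10-2,33.95,1.06,n/a,n/a,5.52,168.84
VA10-3,32.79,n/a,n/a,n/a,n/a,n/a
estimates: mean L 34.16 cm, h 1.37 m, lambda 2.1 m, V(A) 1.88 m/s, V(RT) 1.7 m/s, gait 1.54 (walking)
```

i.e. a trackmaker about 1.37 m at the hip walking (gait ratio 1.54) at
1.7–1.9 m s⁻¹.  Assemblage statistics come from `summarize`, `correlate`
(e.g. `trackmorph correlate mesaxony total_div` prints the negative
mesaxony–divarication relationship, r ≈ −0.41 over 81 tracks) and `rose`
for windrose bearing analysis.  `trackmorph simulate` generates whole
synthetic surfaces; `trackmorph rules-audit` prints the active rule set with
its diagnostic bases and the metric overlaps between subgroups.

## Layout

```
src/trackmorph/
  types.py       # domain types (landmarks, metrics, records, trackways)
  geometry.py    # measurement model + derived metrics + validation
  classify.py    # Hebridean rule engine (rules in data/hebridean_rules.yaml)
  kinematics.py  # pace/stride/WAP/angulation + hip height, velocity, gait
  assemblage.py  # summaries, counts, correlations, windroses
  synthetic.py   # metric sampling, exact landmark inversion, wear model
  io.py          # delimited-text readers/writers, packaged fixtures
  cli.py         # the `trackmorph` command
docs/methods.md  # model, conventions, parameter choices, limitations
```
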