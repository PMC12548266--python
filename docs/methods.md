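# Methods

## The analysis in brief

Lake sturgeon are long-lived, adfluvial, intermittently spawning fish:
most individuals live in lakes and migrate into rivers to spawn, but
populations also contain river residents, summer- and winter-river
migrants, fall-entering "two-step" migrants that overwinter near the
spawning site, and interlake migrants that commute between lakes through
connecting channels. The package reconstructs these behaviors from
receiver detections alone. A receiver's position stands in for the fish's
position; daily state sequences are the analysis substrate; sequence
dissimilarity plus clustering provide a statistical guide; and a
deterministic rule cascade produces the final behavior labels.

## Daily location histories

Detections are bucketed into UTC calendar days (the choice of a single
time standard favors reproducibility over local-time fidelity; at daily
resolution the difference is at most one day at transition boundaries).
For each day with detections the day's state is the **first** detection's
location; carry-forward for subsequent undetected days starts from the
**last** detection of the most recent detection day. This matters on
transition days when a fish is detected in two habitats: the day is
attributed to where the fish started, while the following days correctly
reflect where it ended up.

Left-missing days (before the first detection, e.g. a fish tagged after
the analysis window opens) stay coded MISSING; right-missing days (after
the final detection) are coded VOID. MISSING participates in distance
computation at a fixed substitution cost; VOID runs are stripped and
excluded entirely. Truncating a sequence to an analysis window never
re-anchors it: temporal alignment across fish is preserved.

## Cost model and optimal matching

The substitution-cost matrix reflects geography rather than label
identity: 0 for the same habitat/region, 1 for adjacent ones, 2 for
non-adjacent ones. The constant indel cost of 1 is half the maximum
substitution cost, so an indel is never cheaper than the substitution it
could emulate. MISSING versus any observed state costs 2; two MISSING
days cost 0 (two unobserved fish carry no evidence of dissimilarity —
penalizing them would invent structure). The cost of 2 on missing days
equals the cost of deleting and re-inserting a day, so a sequence with a
missing prefix can never profit from sliding left to align with an
earlier-starting sequence; this is property-tested against a brute-force
oracle.

The edit distance is computed with the full O(nm) dynamic program (one
numpy-vectorized row at a time; the insertion dependency is resolved with
a running minimum over `candidate − j·indel`). Raw distances are
normalized by the longer sequence length — the "maxlength" reading of
length normalization, adopted because it keeps normalized values in
[0, 2] and makes identical-after-void-stripping pairs exactly 0. The
pairwise matrix computation deduplicates byte-identical encoded sequences
first; this is a pure optimization and is tested to leave results
unchanged.

## Clustering and group selection

Ward's method runs on the squared dissimilarities via the Lance–Williams
update (the ward.D2 convention, matching scipy's reference
implementation, against which partitions are oracle-tested at every k on
random instances). Merge ties break toward the lowest index pair for
cross-platform determinism. Average silhouette width uses the standard
`(b − a) / max(a, b)` with singletons and 0/0 scored 0. The starting
group number is the smallest k (2 ≤ k ≤ min(10, n−1)) with ASW at or
above the 0.5 benchmark, else the k with the highest ASW (ties toward
smaller k). The benchmark comparison uses ≥ 0.5.

As in the field, silhouette-guided clustering separates fish mainly by
residence time rather than transition timing, so cluster labels are
recorded as a guide (with the disagreement rate against rule labels)
while the behavior labels come from the rule cascade.

## The rule cascade

Rules are evaluated in a fixed order; the first match wins:

1. **river_resident** — lake residency ≤ 0.10. The threshold sits above
   observed river-resident lake fractions (a few percent) with margin.
2. **annual_interlake** — ≥ 2 years showing Lake St. Clair habitat in
   winter (Feb 1), open-lake habitat in summer (Jul 15), and a river
   episode that year. Only fires when the alphabet distinguishes Lake
   St. Clair.
3. **annual_winter_river** — episodes entering Jul 1–Oct 31 and exiting
   Mar 1–May 31, in ≥ max(1, ⌊observed years⌋ − 1) years.
4. **annual_summer_river** — episodes entering Mar 1–Jun 30 and exiting
   Aug 1–Oct 31, with the same near-annual requirement.
5. **intermittent_two_step** — any episode entering Sep 1–Dec 31 whose
   stay reaches the following year's spawning window.
6. **spring-river migrant** — all spawning-window episodes are short
   (≤ 45 days, operationalizing "one-to-three-week" spawning trips with
   margin before a stay reads as summer residence); the periodicity ratio
   (observed years / spring-trip years, fractional years) splits annual
   (≤ 1.5) from intermittent (> 1.5).
7. **UNCLASSIFIED** otherwise.

The near-annual requirement (observed years minus one) tolerates cycles
truncated by the analysis window and a single missed year from detection
gaps. Residency classes use a 0.35–0.60 band for "50:50 lake:river",
bracketing reported values for long-stay two-step migrants; below is
river-dominant, above lake-dominant. Lake St. Clair days count as lake
time. All windows and thresholds live in `RuleConfig` because the
field's verbal definitions carry no exact numbers; the defaults are the
package's own operationalization.

Known limitation: a two-step variant that transits a river in fall to
overwinter in Lake St. Clair before a short spring spawning trip has no
fall episode spanning the spawning window, so the cascade reads it as an
intermittent spring-river migrant. Distinguishing it would need a rule
keyed on overwinter location, which the present cascade deliberately
avoids to stay within the published behavior definitions.

## Contingents and summaries

A fish's route signature is the region order of one representative
migratory cycle: per calendar year, regions deduplicated in first-use
order; the modal yearly signature wins, ties toward the earliest year.
Contingents are distinct (behavior, signature) pairs within a population.
Frequency tables recompute whole-percent shares from counts with half-up
rounding; residency summaries report sample SD (ddof = 1) and flag
biennial-behavior groups observed for under two full cycles, whose
residency fractions are unreliable. The sex-ratio test is the textbook
one-degree-of-freedom chi-square against expected counts n·r/(1+r) and
n/(1+r), with a warning when an expected count falls below 5.

## The synthetic generator

Each archetype is a deterministic daily calendar of true regions:
transition dates are the midpoints of the archetype's entry/exit windows,
plus per-cycle Gaussian jitter (SD in days) when configured; jitter can
never invert a cycle. Detection is Bernoulli per fish-day; a detected day
emits a two-ping burst 300 s apart at one station of the occupied region,
which is what lets synthetic data pass the min-lag false-detection filter
the way real near-receiver ping trains do. An optional extra morning ping
at the previous day's region on transition days exercises the
first-detection-of-day rule. Defaults: 10 fish per archetype, 6 years
(within the 6–10-year span of the long-term arrays this emulates),
detection probability 1, jitter 0, biennial periodicity for intermittent
archetypes, with a 3+-year option.

What the generator does **not** emulate: receiver-coverage gaps and array
redeployments, range variation with weather and season, tag collisions
producing actual false detections, behavior switching between years, and
movement between regions that bypasses receivers. Passing recovery tests
therefore shows the pipeline inverts its own generative assumptions —
detection thinning and transition jitter — not that it is robust to every
artifact of field data.

## Numerical choices and problem sizes

Distances are exact rational multiples of 0.5 so oracle comparisons use
exact equality; metric properties are property-tested on random triples.
Years are counted as 365.25 days. The end-to-end checks use 7 archetypes
× 10 fish × 6 years noise-free (expected 100% label recovery, exactly 7
distinct labels) and the same cohort at detection probability 0.3 with
7-day jitter over five seeds (observed recovery ≈ 98%; the occasional
failure is a spring trip stretched past 45 days by jitter plus
carry-forward delay, which lands in UNCLASSIFIED rather than in a wrong
behavior). Oracle suites run at small n (sequence length ≤ 12, alphabet
≤ 5, matrices n ≤ 10), where brute force is feasible and exact.
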