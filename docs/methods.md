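# Methods

## Data model and units

A *recording* is all spikes detected on one plate during one session:
rows of (time in seconds from recording start, well id, electrode id,
optional amplitude in mV), validated against a plate layout (default
12 wells × 64 electrodes on an 8×8 grid). The recording length is a
configured constant — 900 s by default — and is never inferred from the
last spike time, because rate denominators (spikes per second, bursts
per minute) must not shrink on quiet days. Experiments with more wells
than one plate (e.g. 17 control + 16 treated wells) are pooled onto a
multi-plate layout with plate-prefixed well ids; every computation is
per-well, so pooling plates is exact.

## Quality control

Two activity rules, both parameterised:

* an electrode is **active** on a day iff its spike count ≥
  `min_spikes_per_min` × duration/60 (default 5/min; the boundary counts
  as active);
* a well is **excluded** iff the fraction of its recorded days with
  fewer than `min_active_electrodes` (default 16) active electrodes is
  strictly greater than `max_inactive_day_fraction` (default 0.30; a
  well at exactly 30 % is retained).

Electrode activity is re-assessed per day, and each day's feature
normalisation uses that day's active set; a switchable global-set mode
was considered and rejected because per-day masks match per-day
reporting of MFR. The day-fraction denominator is the days actually
recorded for that well's plate, which keeps the rule stable when a
recording day is missed. Activity decisions depend only on counts,
never on spike timing.

## Burst detection

The max-interval family, with the common cortical-culture
parameterisation as defaults: `max_begin_isi` 0.1 s, `max_end_isi`
0.25 s, `min_ibi` 0.8 s, `min_duration` 0.05 s, `min_spikes` 5. Rules,
in order: (1) a burst begins at a spike whose following ISI ≤
`max_begin_isi`; (2) it extends while ISIs ≤ `max_end_isi`; (3) bursts
separated by less than `min_ibi` merge (chained); (4) bursts shorter
than `min_duration` or smaller than `min_spikes` are discarded.
Burst duration is last-spike minus first-spike time, unpadded. When two
bursts merge, every spike between the merged bounds — including spikes
in the bridged gap — belongs to the merged burst, so burst membership
is exactly interval membership and no spike belongs to two bursts.
Inter-burst intervals are end-to-next-start gaps on the same electrode,
pooled across a well's active electrodes for the well-day mean. All
five parameters are exposed in one place because appropriate values are
preparation-dependent.

The implementation is vectorised (runs of qualifying ISIs, trimmed at
the front to the first begin-qualifying spike); the test suite holds it
equal to a literal loop transcription of rules (1)–(4) on a thousand
random trains.

## Network events

Participation is counted in distinct electrodes, never spikes, and
events recruiting fewer than `min_participants` electrodes are
filtered. The default threshold is 16 = 25 % of a 64-electrode well;
`NetworkParams.for_layout` keeps the 25 % semantics on other layouts.

*Network spikes*: the time axis is cut into fixed half-open bins of
`ns_bin_s` (default 25 ms, a typical population-spike window; the value
is exposed because it is a genuine free parameter). A bin with ≥
`min_participants` distinct active electrodes qualifies; consecutive
qualifying bins merge into one event whose bounds are the outer bin
edges and whose participants are the union over bins. Fixed bins were
chosen over a sliding window for determinism and O(n) cost.

*Network bursts*: a boundary sweep over per-electrode burst intervals
(closed, so a burst ending exactly when another starts still overlaps
at that instant; starts are processed before ends at ties) finds
maximal intervals with ≥ `min_participants` electrodes simultaneously
in burst. `nb_merge_gap_s` defaults to 0 — no merging — since no
merging rule is part of the method's definition; it is available for
sensitivity analysis.

## Feature table

One row per (included well, recording day): active-electrode count,
MFR = total spikes on active electrodes / duration / n_active (Hz),
burst rate per active electrode per minute, mean burst duration, mean
pooled IBI, network-spike count, network-burst rate per second, and the
percentages of active-electrode spikes inside bursts and inside network
events. Days on which an included well has no active electrodes carry
missing values (NaN), never zeros: absence of evidence is not a zero
rate. Means are arithmetic means over events pooled within the
well-day, matching the well-level unit of the downstream statistics.

## Statistics

Both tiers are two-sided and rank-based; no multiple-testing correction
is applied across features (all features are reported side by side).

*Mann-Whitney U*: exact by enumeration of all C(N, n_a) label splits
when both groups have ≤ 8 observations — midranks make the enumeration
valid under ties, and the two-sided p is the probability of a U at
least as far from n_a·n_b/2 as observed, so two identical samples give
exactly p = 1 — otherwise the tie-corrected, continuity-corrected
normal approximation.

*Fisher combination*: χ² = −2 Σ ln pᵢ on 2k df over the per-day p's of
the analysis window (default DIV 8–16). Days with fewer than two
non-missing wells per group are skipped and reported.

*Permutation test*: each well's window values reduce to one observation
(default: the mean over available days; a `concat` mode keeps well-day
observations while still permuting labels per well). The observed and
every permuted labeling share one vectorised rank-sum p computation
(tie- and continuity-corrected normal), so observed and null p-values
are on an identical scale; comparing p's is then equivalent to
comparing |z|. The empirical p uses the add-one correction
(1 + #{p_perm ≤ p_obs})/(n_perm + 1) — the attainable minimum at
10,000 permutations is 1/10,001 — and ties between a permuted and the
observed p count against the observed one (conservative). The
permutation unit is the well, the independent experimental unit, which
preserves exchangeability under within-well correlation across days;
this is also why the `mean` reducer is the default. Group sizes are
preserved by every shuffle, and each comparison draws from a single
seeded generator recorded in the output.

## Synthetic experiments

Each alive electrode (alive with probability 0.85, fixed per well
across days) superimposes three stationary point processes over the
recording:

* homogeneous Poisson background firing, default 1.0 Hz;
* bursts: Poisson onsets (default 0.2/min/electrode), each emitting
  1 + Poisson(7) spikes with exponential within-burst ISIs (mean 20 ms);
* plate-wide synchronous events: Poisson onsets per well (default
  0.2/min); each event recruits alive electrodes independently with
  probability 0.75, a recruit emitting 8 spikes at 10-ms mean ISIs
  after a few-ms jitter.

All rates scale multiplicatively by (i) the condition's effect
multipliers on background rate, burst rate, burst duration, IBI
(implemented as an inverse multiplier on burst-onset rate) and
network-event rate — the control condition is pinned at 1 — (ii) a
sigmoidal maturation factor rising from near 0 at DIV 3 to a plateau of
1 by about DIV 10 (midpoint 6.5, scale 1.5 days), mimicking network
development in culture without asserting particular values, and
(iii) a per-well lognormal random effect with mean 1 and CV 0.3, shared
across days, so wells genuinely differ as the permutation test assumes.

Background firing deliberately dominates the spike count (~96 % under
the defaults), so an imposed background multiplier maps nearly
one-to-one onto the MFR group ratio and parameter recovery is a direct
end-to-end check. This is a stylisation: in mature real cultures the
majority of spikes sit inside bursts and network events, spatial
structure exists on the 8×8 grid, and electrodes drift — none of which
the generator emulates. Passing tests therefore certify the pipeline's
arithmetic, thresholds and statistical calibration on data with the
assumed independence structure, not the biology of any particular
preparation.

Known interaction, visible in the recovery report of the acceptance
run: fixed-parameter max-interval detection is rate-sensitive, so
raising background firing super-linearly raises coincidence bursts;
with a simultaneous background effect the detected burst-rate group
ratio overshoots the imposed burst-rate multiplier. This is a property
of the detector family, not a defect of the generator, and is the
reason burst-rate recovery is cleanest when probed with the background
rate held at 1.

## Study sizes

The simulation studies fix their problem sizes as follows:

* **Null calibration** (type-I error of the permutation test): 1,000
  replicates of the 17-vs-16-well design at 1,000 permutations each, on
  a reduced plate — 8 electrodes/well, 60-s recordings, one analysis
  day, well rule scaled to 2 electrodes (25 % of the layout). The
  operating characteristic under label exchange does not depend on
  plate scale, so the reduced plate measures the same quantity as the
  full one at a fraction of the cost.
* **Power** against a 1.5× background-rate effect on MFR: 100
  replicates at full per-well scale (64 electrodes, 900 s, CV 0.3,
  17-vs-16 wells) with one analysis-window day per replicate — the
  between-well random effect is shared across days, so additional days
  add essentially no power while multiplying cost.
* **Treated experiment**: one full-scale run over the whole DIV 8–16
  window with the example excitability effect set (background 1.5×,
  burst rate 1.5×, burst duration 1.3×, IBI 0.7×, network events 1.5×),
  10,000 permutations per feature.

## Numerical and degenerate-input conventions

Timestamps are kept as 64-bit seconds; file parsing uses correctly
rounded float conversion so write→read round trips are exact. Sorting
is stable everywhere ties can occur, and identical seeds give
byte-identical outputs across the whole chain. Empty spike lists are
valid (a warning, not an error); unsorted trains passed to the burst
detector are an error rather than silently re-sorted; zero active
electrodes yields missing features; a zero-spike denominator makes the
affected percentage missing; p-values of 0 are impossible by
construction (Fisher rejects p ≤ 0, the permutation p is floored at
1/(n_perm + 1)).

## Limitations

Only activity-based QC is implemented (no impedance or noise criteria);
only the fixed-parameter max-interval burst family (no adaptive
Poisson-surprise-style detectors); within-well synchrony only (no
cross-well or propagation analysis); and the original studies' exact
burst/network parameter values are preparation-specific, so the
defaults here are declared, exposed, and intended to be overridden per
dataset rather than claimed universal.
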