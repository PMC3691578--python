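# Methods

This note documents the models and procedures `aalsim` implements, the
parameters that matter, what the synthetic ward does and does not emulate,
and the numerical choices that make runs reproducible.

## Context model and reasoning

The environment is a set of typed entities (Patient, Caregiver, Location,
Sensor, InteractionDevice, AssistiveService, Activity, Deviance, Object)
and ground facts `(subject, predicate, object)` over a closed predicate
vocabulary of twelve relations.  The vocabulary is extensible per
deployment; the shipped platform adds two relations: `lastUser`, which the
event layer maintains to bind a wash-room fixture (sink, shower, toilet)
to the resident identified at its occupancy onset, and `hasModality`,
which types interaction devices (speaker, smartphone, console).  The store
has set semantics (assertion is idempotent), no inference of its own, and
a line-oriented text serialization used for checkpoints.

Rules are universally quantified conjunctions of triple patterns with
optional entity-kind guards acting as sorted quantifiers.  Negation is
deliberately excluded: conditions like "the patient is not on the bed" are
encoded as positive sensor-status facts (`hasStatus silent`) kept current
by the event layer.  This keeps the semantics monotone, so the naive
forward-chaining fixpoint is finite, confluent under rule reordering, and
reached in at most as many sweeps as there are derivable facts.  An
iteration cap of |constants|² × |predicates| derived facts guards against
misconfigured rule bases.  Derived facts are never persisted: every
reasoning cycle starts from the current base facts (structure + sensor
statuses + day/night phase + attribution) and recomputes, which avoids
truth maintenance when a sensor flips between cycles.  A derivation trace
maps each derived fact to the rule application that first produced it;
`explain` rebuilds the proof tree down to base facts.

The bundled rule base is small: bed occupancy implies sleeping; an empty
bed plus bedroom motion at night implies its owner is wandering; a bound
fixture (`lastUser`) plus its sensor signature implies the corresponding
deviance condition (water running unattended at the sink; shower motion
plus pipe vibration; a sustained height drop at the toilet ceiling
sensor); the service-selection rule maps performed deviances to services
via `needService`; and a caregiver monitoring the patient's location takes
charge.  The full deployed rule inventory is not published anywhere, so
everything beyond the service-selection rule is this package's own
reconstruction, constrained to reproduce the documented night-wandering
derivation exactly.

A known limitation of the sensor-level wandering rule: when two residents
are out of bed at night simultaneously (one wandering, one in the
wash-room), both satisfy "bed silent + bedroom motion + night" and both
are marked wandering.  This ambiguity is inherent to bed-and-motion
sensing; it cannot produce an alarm in a deviance-free period, because the
bedroom motion must itself persist past the wandering guard.

## Services

Each service is a `(deviance, guard, reminder policy, channels)` tuple.
The deviance condition must persist `guard` seconds before the service
reacts (measured on simulation time at 1 s resolution — the sensors are
event-driven and sub-second precision would be meaningless).  Reaction is
a ladder: up to `max_repeats` reminders to the patient at `interval_s`
spacing, then a single escalation to the caregiver in charge
(smartphone, mirrored to the nursing console as one action).  Defaults,
all configurable per patient, and chosen by this package since no deployed
thresholds are published:

| parameter | default | rationale |
|---|---|---|
| night window | 21:00–07:00 | ward lights-out schedule |
| wandering guard | 60 s | longer than a bedroom transit (~25 s) |
| shower-too-long guard | 15 min | continuous motion + pipe vibration |
| tap escalation delay | 60 s | after proximity loses the patient |
| fall | drop ≥ 40 cm within 2 s, then 60 s stillness | ceiling ranging sensor |
| reminder interval / repeats | 30 s / 3 | caregiver-configurable |

Wandering and fall services have no patient channel (no interaction with
the intended patient at night; a fallen patient needs a caregiver, not
audio).  Reminders are converted to caregiver notifications at night.  If
a recipient has no registered device the action is dropped with a
health-log entry rather than crashing the cycle.  When two services fire
at the same instant, actions are emitted in service-name order — a
deterministic tie-break that is also invariant to registration order,
which the hot-swap equivalence property relies on.

## Identity resolution

Attribution is two-tier: a single resident directly read at the
activity's location within the association window (default 120 s) claims
the activity (a co-present caregiver is assumed to be assisting); failing
that, if exactly one roster member is not positively located elsewhere —
a direct read at a different location within the window — the activity is
theirs by exclusion; anything else abstains (`Unknown`).  Two residents
read at the same place is ambiguous and abstains.  Caregivers are
roster-external tagged agents: read at the activity location they claim
it; never read, they are treated as absent.  The resolver never assigns a
resident who is positively elsewhere; with fault-free streams every
non-Unknown assignment on simulator output is correct (tested).

## Plug & play

Discovery is replaced by explicit `register`/`unregister` calls (the
deployed network stack is out of scope); semantics are preserved: a
component's semantic representation (entities, binding triples, rules,
service spec) is merged into the live platform and participates in the
next reasoning cycle without reconstruction.  The registry records
exactly which triples each registration added, with reference counts, so
a sensor backing several services is not torn down prematurely, and
unregistering a service cancels its pending timers.  The headline
property — a dynamically assembled platform produces the same action
stream as a statically built one — holds because no rule consumes the
`usesSensor`/`usesDevice` bookkeeping triples and service evaluation
order is name-canonical.

## The synthetic ward

One simulated day covers 86 400 s for a shared room (default: three
residents, one caregiver, the full sensor complement).  Residents rest in
bed by default; excursions are carved out: night toilet visits
(Poisson, λ = 1/night, ~4 min, 2% fall risk), a morning shower (30%
over-long, i.e. past the 15-min guard), tap uses (Poisson, λ = 1.5/day,
40% left running ~6 min), a 4-h common-area block, and night wandering
episodes (25%/night, ~10 min).  The wash-room is single-occupancy:
excursions across residents (and the daily 20-min caregiver cleaning
block) are placed against a shared busy list.  These defaults calibrate
the room to ≈34 atomic events (tap uses + shower uses + believed-location
changes) and ≈7 complex events (deviance detections + service provisions)
per day; `scripts/acceptance.py` recomputes both over 200 days.

Emission maps each activity to its sensor signature: bed pressure spans,
PIR spans with a 15 s latch (short motion gaps are absorbed, as real PIRs
do), pipe-vibration spans, sink proximity, toilet-ceiling height readings
every 10 s (a fall emits a 170 cm → 40 cm step within 1 s), entrance RFID
reads on each wash-room entry/exit and periodic bed reads every 90 s.
Deviance episodes are constructed long enough that, fault-free, the
corresponding service must detect them — end-to-end recall is exactly
100% at zero fault rates, and that is a tested invariant, not an
observation.

Fault injection follows the deployment failure taxonomy: per-sensor
outages (removal, flat battery), per-event packet loss, Wi-Fi/ZigBee
delivery outages, and reasoning crashes with a recovery delay.  Hourly
caregiver log-sheets record each patient's modal location and five
abnormal-behaviour booleans; an optional hour-shift probability mimics
caregiver imprecision in logging time.  "Asked for something" is sampled
but has no sensor — as in a real deployment — so it only ever appears in
the sheets.

What the simulator does **not** emulate: radio physics (RSSI, battery
curves), multi-room interference, visitors without tags, residents using
one another's beds, and any behaviour correlation across days beyond the
optional deterioration change-day.  Passing tests therefore demonstrate
the platform logic under the modelled conditions, not field performance;
field evaluations face sheet-entry errors and hardware failures that the
matching-rate and fault-injection layers can imitate only statistically.

## Evaluation layer

*Classification*: atomic = tap uses + shower uses + believed-location
changes; complex = deviance detections + service provisions (one per
episode with at least one action).  *Matching rate*: system and sheet
grids are compared per patient-hour on location plus the four deviance
booleans — the only grid both sources share — aggregated weekly; with a
fraction *k* of cells corrupted the rate recovers 100(1−k)% within
binomial error.  *Uptime*: mean interval between crash records.
*Heatmaps*: days × 24 cells of class densities over {bathroom, common
area, room, away}; the sensor-log variant maps attributed wash-room time
to bathroom and bed-pressure time to room, with away-days rendered as a
distinct null class.  *Deterioration*: a day is flagged when the daily
reminder count exceeds 2× the maximum of a 14-day baseline window for two
consecutive days (matching the motivating "<6/day stepping to ~12/day"
shape); both factor and window are configurable.

*Next-hour prediction*: features are hour-of-day, day-of-week and the
previous three hourly activities; labels are {bathroom, common area,
room}.  The model is a committee of 25 depth-≤6 decision trees, each fit
on a half-size bootstrap bag with two candidate features per split —
random-subspace bagging keeps the committee diverse, which both the
majority vote and the active-learning signal rely on.  Active learning
queries the pool item with maximal vote entropy, ties broken toward
feature vectors not yet labelled, then uniformly at random; the paired
baseline draws uniformly.  On a planted weekly schedule the committee is
exact (100% held-out on clean data, within 5 points of the 1−ε Bayes rate
under label-noise ε), and reaches the random-sampling accuracy with half
the labels on average over 20 paired seeds.

## Design for failure

The day runner's entire mutable state — base facts, timer ladders,
stream cursors, believed locations, accumulated logs — serializes to
JSON.  The CLI checkpoints every simulated hour, so a crash (injected
reasoning bug or external kill) replays at most one hour on resume, and
resumed outputs are byte-identical to an uninterrupted run: determinism
comes from explicit seeds everywhere, canonical iteration orders, and
deadline comparisons that reuse the exact floating-point expressions that
scheduled them.  Crashes, recoveries, heartbeats and dropped actions are
appended to a health log for post-hoc analysis; a crash already recorded
there is not re-fired on resume.

## Problem sizes in the shipped tests

Unit and property tests run on models of up to a few hundred facts with
brute-force oracles (linear-scan unification, exhaustive substitution,
consistent-worlds enumeration, hand-written service automata).  The
calibration check simulates 200 days; recall/silence checks 30 days;
hot-swap equivalence 20 random registration schedules; crash transparency
10 random kill points; the active-learning comparison 20 paired seeds on
a 1 200-hour pool.  These sizes were chosen to make sampling error small
relative to the tested tolerances while keeping the full suite runnable
in minutes.
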