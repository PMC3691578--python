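# aalsim

An ambient-assisted-living (AAL) platform for shared nursing-home rooms,
with a synthetic ward simulator so the whole stack runs — and is tested —
without any hardware.

Dementia-ward residents progressively lose autonomy in activities of daily
living: they wander at night, stand in the shower long after they have
forgotten why, leave the wash-room tap running, and fall in the toilet.
`aalsim` implements the software side of a sensor-based assistance
platform for this setting, for researchers and engineers who want to study
context-aware assistance logic, multi-resident identity attribution, or
care analytics at desk scale:

* **Semantic context model** — a typed triple store over a closed relation
  vocabulary (`hasStatus`, `locatedIn`, `ownsBed`, `perform`,
  `needService`, `isInterestedIn`, `inChargeOf`, …) describing patients,
  caregivers, locations, sensors, interaction devices and assistive
  services.
* **Rule engine** — first-order conjunctive rules with sort guards,
  evaluated to a least fixpoint by forward chaining.  The service-selection
  rule at the core is

  ```
  ∀ User u, Deviance dv, Service s:
      (u, perform, dv) ∧ (dv, needService, s) ⇒ (u, isInterestedIn, s)
  ```

* **Assistive services** — night wandering, shower-too-long, tap-left-on
  and toilet-fall detection, each with a persistence guard, a configurable
  reminder ladder to the patient's speaker, and escalation to the
  caregiver's smartphone mirrored on the nursing console.  Patient-directed
  audio is suppressed at night so co-residents are not disturbed.
* **Identity resolution** — rooms are shared; wrist-worn RFID tags are read
  at beds and the wash-room entrance, and anonymous sensor activity is
  attributed by direct read or by exclusion over the room roster, never by
  guessing.
* **Plug & play** — sensors, devices and services register and unregister
  at runtime; a dynamically assembled platform behaves identically to a
  statically configured one.
* **Simulator & analytics** — resident behaviour profiles generate
  ground-truth timelines, sensor event streams, RFID reads, fault injection
  (dead batteries, packet loss, network outages, reasoning crashes) and
  hourly caregiver log-sheets; the analytics layer computes atomic/complex
  event classification, log-sheet matching rates, uptime, chronological
  heatmaps, deterioration flags, and next-hour activity prediction with
  vote-entropy active learning.

## Worked example

The signature scenario: at night, patient2 is asleep while patient1 gets
up and starts wandering.  The bed pressure pad falls silent, the bedroom
motion sensor fires, and the reasoner works out who needs what:

```sh
$ aalsim demo-wandering
```

prints (abridged):

```
# Derived facts:
  caregiver1 inChargeOf patient1
  patient1 isInterestedIn wanderingAlert
  patient1 locatedIn bedroom
  patient1 perform wandering
  patient2 locatedIn bedroom
  patient2 perform sleeping
# Routing (night: the room speaker is suppressed):
  Notification for patient1 -> caregiver1 via caregiver-smartphone on iphoneCaregiver1
```

Reading it: from four sensor facts and the static room structure, the
fixpoint concludes that patient1 is wandering (bed silent + bedroom motion
+ night) while patient2 sleeps (bed firing); the service-selection rule
marks patient1 as needing the `wanderingAlert` service; and because it is
night, no reminder is played in the room — the caregiver's smartphone gets
the notification instead.

A full simulated day, end to end:

```sh
$ aalsim simulate -o run1 --seed 3 --days 1
$ aalsim reason   -o run1
15 actions over 1 day(s)
$ aalsim evaluate -o run1
{
  "crashes": 0,
  "mean_atomic_per_day": 41.0,
  "mean_complex_per_day": 12.0,
  "mean_uptime_days": 1.0
}
```

The action log (`run1/actions.jsonl`) holds one JSON object per reminder /
notification / alert with its timestamp, service, patient, channel and
device; `run1/sheets-day0.csv` holds the hourly ground-truth log-sheet the
caregivers would have filled in.  `aalsim reason` checkpoints hourly and
`aalsim resume` continues an interrupted run with byte-identical outputs.

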