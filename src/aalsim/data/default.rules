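# Default rule base, version 1.
#
# Generic context-understanding rules (bed occupancy, night wandering,
# service selection, caregiver escalation) plus the washroom-fixture rules
# generated for the default room binding (sink / shower / toilet with their
# attached vibration, proximity and motion sensors).  Fixture attribution
# relies on the `lastUser` relation maintained by the identity layer.

# A patient detected on their own bed is sleeping there.
rule sleeping: (?u:Patient, ownsBed, ?b:Object)
             & (?ps:Sensor, attachedTo, ?b)
             & (?ps, hasStatus, firing)
             & (?b, locatedIn, ?r:Location)
            => (?u, perform, sleeping) & (?u, locatedIn, ?r)

# Night, bed empty, motion in the bedroom: the bed's owner is wandering.
rule wandering: (?u:Patient, ownsBed, ?b:Object)
              & (?ps:Sensor, attachedTo, ?b)
              & (?ps, hasStatus, silent)
              & (?b, locatedIn, ?r:Location)
              & (?m:Sensor, monitors, ?r)
              & (?m, hasStatus, firing)
              & (?r, hasPhase, night)
             => (?u, perform, wandering) & (?u, locatedIn, ?r)

# Shower occupied and water running: the bound user is showering
# (the service guard decides when it has lasted too long).
rule shower_running: (shower, lastUser, ?u:Patient)
                   & (pirShower, hasStatus, firing)
                   & (vibShower, hasStatus, firing)
                  => (?u, perform, longShower) & (?u, locatedIn, washroom)

# Water running at the sink with nobody in front of it: tap left on,
# attributed to the last user of the sink.
rule tap_unattended: (sink, lastUser, ?u:Patient)
                   & (proxSink, hasStatus, silent)
                   & (vibSink, hasStatus, firing)
                  => (?u, perform, tapOn) & (?u, locatedIn, washroom)

# Sudden sustained height drop at the toilet ceiling sensor: a fall.
rule toilet_fall: (toilet, lastUser, ?u:Patient)
                & (proxToilet, hasStatus, heightDrop)
               => (?u, perform, toiletFall) & (?u, locatedIn, washroom)

# Service selection: for all patients u, deviances dv and services s,
# performing a deviance that needs a service makes the patient interested.
rule svc: (?u:Patient, perform, ?dv:Deviance)
        & (?dv, needService, ?s:AssistiveService)
       => (?u, isInterestedIn, ?s)

# A caregiver monitoring the patient's location takes charge.
rule charge: (?u:Patient, isInterestedIn, ?s:AssistiveService)
           & (?u, locatedIn, ?r:Location)
           & (?c:Caregiver, monitors, ?r)
          => (?c, inChargeOf, ?u)
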