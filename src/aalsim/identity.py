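"""Resident identification from RFID reads plus exclusion reasoning.

Rooms are shared by two to four residents, and caregivers come in to clean
and assist, so anonymous sensor activity (motion in the washroom, presence
at the sink) must be attributed before a service can be personalised.
Passive RFID tags worn as bracelets are read at points of interest (beds,
the washroom entrance).  Attribution follows two steps:

1. *direct read* — a tag read at a reader co-located with the activity,
   within the association window;
2. *exclusion* — failing that, if exactly one roster member is not
   positively located elsewhere (a direct read at a different location
   within the window), the activity is theirs.

Anything still ambiguous is left Unknown: the resolver abstains rather than
guesses, and never assigns a resident who is positively elsewhere.
Caregivers are roster-external tagged agents; their presence both claims
their own activity and blocks exclusion-based attribution at that location.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import NamedTuple, Sequence

__all__ = [
    "RFIDRead",
    "IdentityAssignment",
    "UnknownTagError",
    "resolve",
]

UNKNOWN = "Unknown"


class UnknownTagError(ValueError):
    pass


class RFIDRead(NamedTuple):
    t: float
    reader: str
    tag: str


@dataclass(frozen=True)
class IdentityAssignment:
    event_index: int          # position in the input event sequence
    t: float
    location: str
    resident: str             # resident id, caregiver id, or "Unknown"
    basis: str                # direct-read | exclusion | abstain


class _ReadIndex:
    """Time-sorted reads per agent, queryable by window."""

    def __init__(self, reads: Sequence[RFIDRead], tag_map: dict[str, str], reader_location: dict[str, str]):
        self.by_agent: dict[str, list[tuple[float, str]]] = {}
        for r in reads:
            if r.tag not in tag_map:
                raise UnknownTagError(f"unregistered tag: {r.tag}")
            loc = reader_location.get(r.reader)
            if loc is None:
                raise UnknownTagError(f"reader with no location: {r.reader}")
            self.by_agent.setdefault(tag_map[r.tag], []).append((r.t, loc))
        for seq in self.by_agent.values():
            seq.sort()

    def locations_near(self, agent: str, t: float, window: float) -> set[str]:
        seq = self.by_agent.get(agent, [])
        lo = bisect.bisect_left(seq, (t - window, ""))
        out = set()
        for i in range(lo, len(seq)):
            rt, loc = seq[i]
            if rt > t + window:
                break
            out.add(loc)
        return out


def resolve(
    events: Sequence,
    reads: Sequence[RFIDRead],
    *,
    roster: Sequence[str],
    tag_map: dict[str, str],
    sensor_location: dict[str, str],
    reader_location: dict[str, str],
    window: float = 120.0,
) -> list[IdentityAssignment]:
    """Attribute each presence-onset sensor event to a resident.

    ``events`` are objects with ``t``, ``sensor`` and ``status`` attributes;
    only occupancy onsets (``status == "firing"`` on a sensor with a known
    location) are attributed.  ``roster`` lists the room's residents;
    ``tag_map`` maps tags to agents (residents or roster-external
    caregivers).  Readers and sensors are mapped to locations at the same
    granularity (e.g. ``bedroom`` / ``washroom``).
    """
    if not roster:
        raise ValueError("empty roster")
    index = _ReadIndex(reads, tag_map, reader_location)
    agents = sorted(set(tag_map.values()))

    out: list[IdentityAssignment] = []
    for i, ev in enumerate(events):
        if getattr(ev, "status", None) != "firing":
            continue
        loc = sensor_location.get(ev.sensor)
        if loc is None:
            continue
        t = ev.t

        # 1. direct read at the activity's location.  A single resident read
        #    here claims the activity (a co-present caregiver is assumed to
        #    be assisting); two residents read here is ambiguous — abstain.
        direct = sorted(a for a in agents if loc in index.locations_near(a, t, window))
        direct_residents = [a for a in direct if a in roster]
        if len(direct_residents) == 1:
            out.append(IdentityAssignment(i, t, loc, direct_residents[0], "direct-read"))
            continue
        if len(direct_residents) >= 2:
            out.append(IdentityAssignment(i, t, loc, UNKNOWN, "abstain"))
            continue
        if len(direct) == 1:  # caregiver or other external agent present
            out.append(IdentityAssignment(i, t, loc, direct[0], "direct-read"))
            continue
        if len(direct) >= 2:
            out.append(IdentityAssignment(i, t, loc, UNKNOWN, "abstain"))
            continue

        # 2. exclusion over the roster
        candidates = []
        for resident in sorted(roster):
            elsewhere = index.locations_near(resident, t, window)
            if elsewhere and loc not in elsewhere:
                continue  # positively located elsewhere
            candidates.append(resident)
        # externals read at this location were caught by the direct branch,
        # externals read elsewhere are irrelevant; externals never read are
        # treated as absent from the room.
        if len(candidates) == 1:
            out.append(IdentityAssignment(i, t, loc, candidates[0], "exclusion"))
        else:
            out.append(IdentityAssignment(i, t, loc, UNKNOWN, "abstain"))
    return out
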