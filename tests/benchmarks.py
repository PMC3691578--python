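"""Planted-structure benchmarks for the next-hour activity predictor.

``daily`` — the same schedule every day over {bathroom, common area, room};
perfectly periodic, exactly representable by the default ensemble, so clean
held-out accuracy must hit 100% and the Bayes rate under label noise eps is
1 - eps (up to chance agreement).

``weekly`` — adds a weekend variant, making some (hour, day-of-week)
patterns rare; used for the active-learning comparison, where the bar is
the paired random-sampling run, not perfection.
"""

import numpy as np

from aalsim.analytics import LABELS, featurize

DAILY = {7: "bathroom", 20: "bathroom", 12: "common area", 13: "common area",
         16: "common area", 17: "common area"}
WEEKEND = {8: "bathroom", 21: "bathroom", 10: "common area", 11: "common area",
           14: "common area", 15: "common area"}


def planted_label(hour: int, dow: int, weekly: bool = False) -> str:
    table = WEEKEND if (weekly and dow >= 5) else DAILY
    return table.get(hour, "room")


def planted_schedule(n_hours: int, noise: float = 0.0, seed: int = 0, weekly: bool = False) -> list[str]:
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_hours):
        lab = planted_label(i % 24, (i // 24) % 7, weekly)
        if noise and rng.random() < noise:
            lab = LABELS[int(rng.integers(len(LABELS)))]
        out.append(lab)
    return out


def planted_xy(n_hours: int, noise: float = 0.0, seed: int = 0, history: int = 3,
               weekly: bool = False, start: int = 0):
    return featurize(planted_schedule(n_hours, noise, seed, weekly), history, start=start)
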