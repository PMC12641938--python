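#!/usr/bin/env python
"""Distribute detected fixations over the three scene surfaces.

Assigns each session's fixation centroids to the HUD, instrument-field,
and peripheral polygons and tabulates the per-session shares — the gaze
distribution that separates experts (HUD-dominant) from novices.
"""

import pandas as pd

from common import RESULTS, detect, get_cohort
from surgaze import aoi as am


def main() -> None:
    records, _, geometry, surfaces = get_cohort()
    rows = []
    for r in records:
        fixations, _, _ = detect(r, geometry)
        dist = am.gaze_distribution(am.assign_fixations(fixations, surfaces, geometry))
        rows.append(
            {
                "label": r.label,
                "replicate": r.replicate,
                "hud": dist.proportions.get("HUD", 0.0),
                "instrument_field": dist.proportions.get("instrument_field", 0.0),
                "peripheral": dist.proportions.get("peripheral", 0.0),
                "assigned": dist.assigned_count,
            }
        )
    df = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "gaze_distribution.csv", index=False)

    grp = (100 * df.groupby("label", sort=False)[["hud", "instrument_field", "peripheral"]]
           .mean()).round(1)
    print("mean fixation share per surface (%):")
    print(grp)


if __name__ == "__main__":
    main()
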