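"""Extract the molt-cycle milestones from the fitted trajectories and
correlate them by subtraction of the fitted locations.

Reads results/cohort.csv and the fits from 02 (re-running the upstream
steps if needed); writes results/milestones.json and results/offsets.tsv.
"""

import runpy
from pathlib import Path

import pandas as pd

from moltstage.milestones import milestones_to_json
from moltstage.pipeline import (
    extract_milestones,
    fit_channels,
    pairwise_offsets,
    prepare_channels,
)
from moltstage.simulate import read_cohort

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    if not (RESULTS / "cohort.csv").exists():
        runpy.run_path(str(Path(__file__).with_name("01_simulate_cohort.py")),
                       run_name="__main__")
    table = read_cohort(RESULTS / "cohort.csv")
    fits = fit_channels(prepare_channels(table))
    mean_ecd = float(table.drop_duplicates("nymph_id")["ecdysis_day"].mean())
    milestones = extract_milestones(fits, mean_ecd)
    offsets = pairwise_offsets(milestones)

    present = [m for m in milestones.values() if m is not None]
    milestones_to_json(present, offsets, RESULTS / "milestones.json")
    pd.DataFrame(
        [{"from": o.from_milestone, "to": o.to_milestone,
          "delta_days": o.delta, "se_days": o.se} for o in offsets]
    ).to_csv(RESULTS / "offsets.tsv", sep="\t", index=False)

    for m in present:
        print(f"{m.name}: {m.render()}")
    for o in offsets:
        print(o.render())
    print(f"wrote {RESULTS / 'milestones.json'} and {RESULTS / 'offsets.tsv'}")


if __name__ == "__main__":
    main()
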