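"""Simulate the study cohort: 14 female fifth-instar nymphs, daily
measurements of body weight, inter-wing distance and hemolymph
ecdysteroid titer from day 4 until the adult molt.

Writes results/cohort.csv and results/cohort_means.csv.
"""

from pathlib import Path

from moltstage.config import CohortConfig
from moltstage.pipeline import add_weight_increase
from moltstage.simulate import cohort_means, generate_cohort, write_cohort

SEED = 17
RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    config = CohortConfig(seed=SEED)
    table = generate_cohort(config)
    write_cohort(table, RESULTS / "cohort.csv")

    means = cohort_means(
        add_weight_increase(table),
        axis="days_prior_to_ecdysis",
        values=("weight", "weight_increase", "inter_wing_distance",
                "ecdysteroid_titer"),
    )
    means.to_csv(RESULTS / "cohort_means.csv", index=False)

    durations = table.groupby("nymph_id")["ecdysis_day"].first()
    print(f"cohort: {durations.size} nymphs, {len(table)} records")
    print(f"instar durations: {durations.min()}-{durations.max()} days "
          f"(mean {durations.mean():.2f})")
    print(f"wrote {RESULTS / 'cohort.csv'} and {RESULTS / 'cohort_means.csv'}")


if __name__ == "__main__":
    main()
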