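"""Stage every nymph from its non-invasive measurements alone: first day
the inter-wing distance reaches 1.8 mm (N5IW), the weight peak (N5WP)
and the first >= 0.1 g weight decrease (N5WD).

Reads results/cohort.csv; writes results/staging.tsv.
"""

import runpy
from pathlib import Path

from moltstage.simulate import read_cohort
from moltstage.staging import StagingRuleSet, stage_cohort, staging_to_tsv

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    if not (RESULTS / "cohort.csv").exists():
        runpy.run_path(str(Path(__file__).with_name("01_simulate_cohort.py")),
                       run_name="__main__")
    table = read_cohort(RESULTS / "cohort.csv")
    results, summary = stage_cohort(table, StagingRuleSet())
    staging_to_tsv(results, RESULTS / "staging.tsv")
    print(summary.to_string(index=False))
    print(f"wrote {RESULTS / 'staging.tsv'}")


if __name__ == "__main__":
    main()
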