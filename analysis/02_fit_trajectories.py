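"""Fit the three trajectory models to the cohort means: a Lorentzian to
the ecdysteroid titer, a lognormal to the weight increase, and a
logistic-linked linear/constant curve to the inter-wing distance.

Reads results/cohort.csv (running 01_simulate_cohort.py first if absent)
and writes results/fit_{ecdysteroid,weight,iw}.json.
"""

import runpy
from pathlib import Path

from moltstage.pipeline import fit_channels, prepare_channels
from moltstage.simulate import read_cohort

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    if not (RESULTS / "cohort.csv").exists():
        runpy.run_path(str(Path(__file__).with_name("01_simulate_cohort.py")),
                       run_name="__main__")
    table = read_cohort(RESULTS / "cohort.csv")
    fits = fit_channels(prepare_channels(table))
    for name, fit in fits.items():
        fit.to_json(RESULTS / f"fit_{name}.json")
        mu = fit.params["mu"]
        print(f"{name:12s} converged={fit.converged} mu={mu:+.3f} "
              f"se(mu)={fit.standard_errors['mu']:.3f} "
              f"chi2_red={fit.chi2_red:.2f} (dof {fit.dof})")
    print(f"wrote fit_*.json under {RESULTS}")


if __name__ == "__main__":
    main()
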