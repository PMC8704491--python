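"""Rule-based molt-cycle staging from non-invasive measurements.

Three milestones are assigned per nymph from its daily weight and
inter-wing-distance series alone (no hormone measurement needed):

* N5IW — first day the inter-wing distance reaches at least 1.8 mm;
* N5WD — first day the body weight has dropped by at least 0.1 g from the
  reference (running maximum by default, or the previous day's value);
* N5WP — the day of maximum weight strictly before N5WD (the weight peak).

Days whose measurement is missing cannot fire a rule but do not abort
staging; a rule that never fires leaves its milestone absent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import InputError


@dataclass(frozen=True)
class StagingRuleSet:
    """Thresholds for the staging rules.

    iw_threshold : mm, inter-wing distance that defines N5IW (default 1.8).
    wd_threshold : g, minimal weight decrease that defines N5WD (default 0.1).
    reference : 'running_max' compares each day to the largest weight seen so
        far (robust to a noisy plateau day); 'previous_day' compares to the
        last observed weight.
    """

    iw_threshold: float = 1.8
    wd_threshold: float = 0.1
    reference: str = "running_max"

    def __post_init__(self):
        if self.iw_threshold <= 0 or self.wd_threshold <= 0:
            raise InputError("staging thresholds must be > 0")
        if self.reference not in {"running_max", "previous_day"}:
            raise InputError(f"unknown reference {self.reference!r}")


@dataclass(frozen=True)
class StagingResult:
    nymph_id: str
    n5iw_day: int | None
    n5wp_day: int | None
    n5wd_day: int | None
    triggering_values: dict


def stage_nymph(series: pd.DataFrame, rules: StagingRuleSet) -> StagingResult:
    """Assign N5IW/N5WP/N5WD days for one nymph.

    ``series`` holds one nymph's records sorted by ``day_of_instar`` with
    ``weight`` and ``inter_wing_distance`` columns (NaN allowed).
    """
    days = series["day_of_instar"].to_numpy()
    if np.any(np.diff(days) <= 0):
        raise InputError("records must be sorted by day_of_instar without duplicates")
    weight = series["weight"].to_numpy(dtype=float)
    iw = series["inter_wing_distance"].to_numpy(dtype=float)
    if np.isfinite(weight).sum() < 2 or np.isfinite(iw).sum() < 2:
        raise InputError("need weight and inter-wing distance on at least 2 days")
    nymph_id = str(series["nymph_id"].iloc[0]) if "nymph_id" in series else ""

    trig: dict = {}

    # N5IW: first day the inter-wing distance reaches the threshold
    n5iw_day = None
    hit = np.flatnonzero(np.isfinite(iw) & (iw >= rules.iw_threshold))
    if hit.size:
        n5iw_day = int(days[hit[0]])
        trig["n5iw_mm"] = float(iw[hit[0]])

    # N5WD: first day the weight has dropped >= threshold from the reference
    n5wd_day = None
    n5wp_day = None
    ref = -np.inf
    prev = np.nan
    for d, w in zip(days, weight):
        if not np.isfinite(w):
            continue
        comparand = ref if rules.reference == "running_max" else prev
        if np.isfinite(comparand) and w <= comparand - rules.wd_threshold:
            n5wd_day = int(d)
            trig["n5wd_drop_g"] = float(comparand - w)
            break
        ref = max(ref, w)
        prev = w

    if n5wd_day is not None:
        before = (days < n5wd_day) & np.isfinite(weight)
        if before.any():
            wmax = np.nanmax(weight[before])
            # tie-break: the latest qualifying day (WP immediately precedes WD)
            idx = np.flatnonzero(before & (weight == wmax))[-1]
            n5wp_day = int(days[idx])
            trig["n5wp_g"] = float(wmax)

    return StagingResult(nymph_id, n5iw_day, n5wp_day, n5wd_day, trig)


def stage_cohort(
    table: pd.DataFrame, rules: StagingRuleSet | None = None
) -> tuple[list[StagingResult], pd.DataFrame]:
    """Stage every nymph and summarize milestone days prior to ecdysis.

    Returns the per-nymph results and a summary frame with one row per
    milestone: mean and SEM of (ecdysis_day - milestone_day), computed
    over the nymphs where the rule fired, with that count.
    """
    rules = rules or StagingRuleSet()
    if table.empty:
        raise InputError("cohort table is empty")
    results = []
    rows = []
    for nymph_id, g in table.groupby("nymph_id", sort=True):
        g = g.sort_values("day_of_instar")
        res = stage_nymph(g, rules)
        results.append(res)
        ecd = float(g["ecdysis_day"].iloc[0])
        rows.append(
            {
                "nymph_id": nymph_id,
                "n5iw_prior": None if res.n5iw_day is None else ecd - res.n5iw_day,
                "n5wp_prior": None if res.n5wp_day is None else ecd - res.n5wp_day,
                "n5wd_prior": None if res.n5wd_day is None else ecd - res.n5wd_day,
            }
        )
    per = pd.DataFrame(rows)
    summary_rows = []
    for name, col in (
        ("N5IW", "n5iw_prior"),
        ("N5WP", "n5wp_prior"),
        ("N5WD", "n5wd_prior"),
    ):
        v = pd.to_numeric(per[col], errors="coerce").dropna()
        n = len(v)
        summary_rows.append(
            {
                "milestone": name,
                "mean_days_prior": v.mean() if n else np.nan,
                "sem_days": v.std(ddof=1) / np.sqrt(n) if n >= 2 else np.nan,
                "n": n,
            }
        )
    return results, pd.DataFrame(summary_rows)


def staging_to_tsv(results: Iterable[StagingResult], path) -> None:
    df = pd.DataFrame(
        [
            {
                "nymph_id": r.nymph_id,
                "n5iw_day": r.n5iw_day,
                "n5wp_day": r.n5wp_day,
                "n5wd_day": r.n5wd_day,
                **{f"trigger_{k}": v for k, v in r.triggering_values.items()},
            }
            for r in results
        ]
    )
    df.to_csv(path, sep="\t", index=False)
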