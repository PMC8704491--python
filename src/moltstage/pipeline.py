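"""End-to-end pipeline: cohort -> means -> fits -> milestones -> staging.

The pipeline prepares each measurement channel on its fit axis, performs
the three weighted nonlinear fits, extracts the milestones with
propagated uncertainties, forms all pairwise offsets, and stages every
nymph with the rule set.  A run is fully determined by (config, seed):
all randomness flows from the one seed through named substreams.

Fit axes
--------
ecdysteroid   Lorentzian on days prior to ecdysis (symmetric, so the
              positive-before-ecdysis orientation is immaterial).
weight        Lognormal of the weight increase (relative to each nymph's
              first sampled day) on days since the start of the instar;
              the reference day itself is excluded from the fit.
inter-wing    Linked linear/constant on signed days relative to ecdysis
              (x = -days_prior, forward time) so the linear rise precedes
              the plateau; the milestone is -mu.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from ._version import __version__ as _version
from .config import CohortConfig, ConfigurationError
from .errors import InferenceError, InputError
from .fitting import FitResult, fit_model
from .milestones import (
    MilestoneEstimate,
    OffsetEstimate,
    ecdysteroid_peak_time,
    iw_midpoint_time,
    milestone_offset,
    milestones_to_json,
    weight_peak_time,
)
from .models import (
    linked_linear_constant_spec,
    lognorm_increase_spec,
    lorentzian_spec,
)
from .simulate import cohort_means, generate_cohort, read_cohort, write_cohort
from .staging import StagingRuleSet, stage_cohort, staging_to_tsv

logger = logging.getLogger("moltstage")

CHANNELS = ("ecdysteroid", "weight", "iw")


@dataclass(frozen=True)
class RunConfig:
    """One reproducible pipeline run.

    Exactly one of ``cohort`` (synthetic-cohort configuration) and
    ``data_path`` (a measured cohort CSV) must be set.
    """

    cohort: CohortConfig | None = None
    data_path: str | None = None
    sigma_link: float = 0.25
    rules: StagingRuleSet = field(default_factory=StagingRuleSet)
    outdir: str | None = None
    seed: int = 0

    def __post_init__(self):
        if (self.cohort is None) == (self.data_path is None):
            raise ConfigurationError(
                "exactly one of cohort-config and data-path must be given"
            )
        if self.sigma_link <= 0:
            raise ConfigurationError("sigma_link must be > 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, Mapping):
            raise ConfigurationError(f"{path}: expected a mapping at top level")
        d = dict(raw)
        if "cohort" in d and d["cohort"] is not None:
            d["cohort"] = CohortConfig.from_dict(d["cohort"])
        if "rules" in d and d["rules"] is not None:
            d["rules"] = StagingRuleSet(**d["rules"])
        return cls(**d)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def provenance_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    fits: dict[str, FitResult]
    milestones: dict[str, MilestoneEstimate | None]
    offsets: list[OffsetEstimate]
    staging_summary: pd.DataFrame
    provenance: dict[str, Any]

    def hash(self) -> str:
        return hashlib.sha256(render_report(self).encode()).hexdigest()


# ---------------------------------------------------------------------------
# channel preparation


def add_weight_increase(table: pd.DataFrame) -> pd.DataFrame:
    """Add per-nymph weight increase relative to the first sampled weight."""
    table = table.copy()

    def _inc(g: pd.DataFrame) -> pd.Series:
        g = g.sort_values("day_of_instar")
        present = g["weight"].dropna()
        ref = present.iloc[0] if len(present) else np.nan
        return g["weight"] - ref

    table["weight_increase"] = (
        table.groupby("nymph_id", group_keys=False)[["day_of_instar", "weight"]]
        .apply(_inc)
        .reset_index(level=0, drop=True)
    )
    return table


def prepare_channels(table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Cohort means for each channel on its fit axis.

    Returns per channel a frame with columns (x, mean, sem, n); ``x`` is
    already on the axis the model is fitted on (see module docstring).
    """
    table = add_weight_increase(table)

    prior = cohort_means(
        table, axis="days_prior_to_ecdysis",
        values=("ecdysteroid_titer", "inter_wing_distance"),
    )
    ecd = prior[prior["variable"] == "ecdysteroid_titer"].copy()
    ecd["x"] = ecd["time"]

    iw = prior[prior["variable"] == "inter_wing_distance"].copy()
    iw["x"] = -iw["time"]

    wt = cohort_means(table, axis="day_of_instar", values=("weight_increase",))
    wt["x"] = wt["time"].astype(float)

    out = {}
    for name, df in (("ecdysteroid", ecd), ("weight", wt), ("iw", iw)):
        out[name] = df.sort_values("x")[["x", "mean", "sem", "n"]].reset_index(
            drop=True
        )
    return out


def _weights_for(
    df: pd.DataFrame, mode: str, true_sd: float | None, n_free: int
):
    """Select (x, y, y_err) under the requested weighting scheme.

    'empirical' uses per-point SEMs where defined, falling back to unit
    weights when too few points carry a positive SEM (e.g. noiseless
    cohorts); 'true' uses a known noise sd / sqrt(n); 'none' is unit
    weights.
    """
    x = df["x"].to_numpy(dtype=float)
    y = df["mean"].to_numpy(dtype=float)
    if mode == "none":
        return x, y, None
    if mode == "true":
        if true_sd is None:
            raise InputError("weighting mode 'true' requires a noise sd")
        if true_sd == 0:
            return x, y, None
        return x, y, true_sd / np.sqrt(df["n"].to_numpy(dtype=float))
    if mode == "empirical":
        sem = df["sem"].to_numpy(dtype=float)
        ok = np.isfinite(sem) & (sem > 0)
        if ok.sum() >= n_free + 2:
            return x[ok], y[ok], sem[ok]
        return x, y, None
    raise InputError(f"unknown weighting mode {mode!r}")


def fit_channels(
    channels: Mapping[str, pd.DataFrame],
    sigma_link: float = 0.25,
    weighting: str = "empirical",
    true_sd: Mapping[str, float] | None = None,
) -> dict[str, FitResult]:
    """Fit the three trajectory models to prepared channel means."""
    weight_df = channels["weight"]
    x_ref = float(weight_df["x"].min())
    specs = {
        "ecdysteroid": lorentzian_spec(),
        "weight": lognorm_increase_spec(x_ref),
        "iw": linked_linear_constant_spec(sigma_link),
    }
    fits = {}
    for name, spec in specs.items():
        df = channels[name]
        if name == "weight":
            # the reference day's increase is identically zero; exclude it
            df = df[df["x"] > x_ref]
        sd = None if true_sd is None else true_sd.get(name)
        x, y, y_err = _weights_for(df, weighting, sd, len(spec.free_params))
        fits[name] = fit_model(spec, x, y, y_err=y_err)
        logger.info(
            "fit %-12s converged=%s chi2_red=%.3g dof=%d",
            name, fits[name].converged, fits[name].chi2_red, fits[name].dof,
        )
    return fits


def extract_milestones(
    fits: Mapping[str, FitResult], mean_ecdysis_day: float
) -> dict[str, MilestoneEstimate | None]:
    """Milestones from the three fits; an unconverged channel yields None."""
    out: dict[str, MilestoneEstimate | None] = {}
    extractors = {
        "ecdysteroid": lambda: ecdysteroid_peak_time(fits["ecdysteroid"]),
        "weight": lambda: weight_peak_time(fits["weight"], mean_ecdysis_day),
        "iw": lambda: iw_midpoint_time(fits["iw"], axis="days_rel_ecdysis"),
    }
    for name, fn in extractors.items():
        try:
            out[name] = fn()
        except InferenceError as exc:
            logger.warning("milestone %s unavailable: %s", name, exc)
            out[name] = None
    return out


def pairwise_offsets(
    milestones: Mapping[str, MilestoneEstimate | None]
) -> list[OffsetEstimate]:
    present = [m for m in milestones.values() if m is not None]
    offs = []
    for i, a in enumerate(present):
        for b in present[i + 1:]:
            offs.append(milestone_offset(a, b))
    return offs


# ---------------------------------------------------------------------------
# the run


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute simulate/load -> means -> fits -> milestones -> staging."""
    if config.data_path is not None:
        table = read_cohort(config.data_path)
        source = f"measured:{config.data_path}"
    else:
        cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
        table = generate_cohort(cohort_cfg)
        source = "synthetic"
    logger.info("cohort: %d nymphs, %d records",
                table["nymph_id"].nunique(), len(table))

    channels = prepare_channels(table)
    fits = fit_channels(channels, sigma_link=config.sigma_link)
    mean_ecd = float(
        table.drop_duplicates("nymph_id")["ecdysis_day"].mean()
    )
    milestones = extract_milestones(fits, mean_ecd)
    offsets = pairwise_offsets(milestones)
    results, summary = stage_cohort(table, config.rules)

    report = RunReport(
        fits=fits,
        milestones=milestones,
        offsets=offsets,
        staging_summary=summary,
        provenance={
            "config_hash": config.provenance_hash(),
            "seed": config.seed,
            "version": _version,
            "source": source,
            "n_nymphs": int(table["nymph_id"].nunique()),
            "mean_ecdysis_day": mean_ecd,
        },
    )

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_cohort(table, outdir / "cohort.csv")
        means_all = cohort_means(add_weight_increase(table),
                                 axis="days_prior_to_ecdysis",
                                 values=("weight", "weight_increase",
                                         "inter_wing_distance",
                                         "ecdysteroid_titer"))
        means_all.to_csv(outdir / "means.csv", index=False)
        for name, fit in fits.items():
            fit.to_json(outdir / f"fit_{name}.json")
        milestones_to_json(
            [m for m in milestones.values() if m is not None], offsets,
            outdir / "milestones.json",
        )
        pd.DataFrame(
            [
                {"from": o.from_milestone, "to": o.to_milestone,
                 "delta_days": o.delta, "se_days": o.se}
                for o in offsets
            ]
        ).to_csv(outdir / "offsets.tsv", sep="\t", index=False)
        staging_to_tsv(results, outdir / "staging.tsv")
        (outdir / "report.txt").write_text(render_report(report))
    return report


_CHANNEL_LABEL = {
    "ecdysteroid": "ecdysteroid peak",
    "weight": "weight peak (N5WP)",
    "iw": "inter-wing midpoint (N5IW)",
}


def render_report(report: RunReport) -> str:
    """Human-readable run summary; one decimal day, explicit sign language."""
    lines = ["molt-cycle milestone report", "=" * 27, ""]
    lines.append("milestones (from fitted trajectories):")
    for name in CHANNELS:
        m = report.milestones.get(name)
        label = _CHANNEL_LABEL[name]
        if m is None:
            lines.append(f"  {label}: unavailable (fit did not converge)")
        else:
            lines.append(f"  {label}: {m.render()}")
    lines.append("")
    lines.append("offsets (subtraction of fitted locations):")
    for o in report.offsets:
        lines.append(f"  {o.render()}")
    lines.append("")
    lines.append("fit diagnostics:")
    for name, fit in report.fits.items():
        chi = "n/a" if not np.isfinite(fit.chi2_red) else f"{fit.chi2_red:.2f}"
        lines.append(
            f"  {name}: chi2_red = {chi} (dof {fit.dof}), "
            f"converged = {fit.converged}"
        )
    lines.append("")
    lines.append("rule-based staging summary (days prior to ecdysis):")
    for _, row in report.staging_summary.iterrows():
        if row["n"] == 0:
            lines.append(f"  {row['milestone']}: never fired (n = 0)")
        else:
            sem = row["sem_days"]
            sem_s = "n/a" if not np.isfinite(sem) else f"{sem:.1f}"
            lines.append(
                f"  {row['milestone']}: {row['mean_days_prior']:.1f} ± {sem_s} "
                f"(n = {int(row['n'])})"
            )
    lines.append("")
    p = report.provenance
    lines.append(
        f"provenance: config {p['config_hash']}, seed {p['seed']}, "
        f"version {p['version']}, source {p['source']}"
    )
    return "\n".join(lines) + "\n"
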