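"""Synthetic calibration targets and the bundled life-table fixture.

The calibration data are generated by the model itself: the microsimulation
is run at the known "true" parameter values many times, and the
replication-to-replication spread of each age-specific outcome provides its
standard error. Four target types are produced — adenoma prevalence, the
proportion of small adenomas (cohorts of 500, mirroring small endoscopy
studies) and clinical early/late CRC incidence (cohorts of 100,000,
mirroring registry data) — so targets carry realistically different amounts
of information.

The background-mortality input is a packaged Gompertz–Makeham
approximation, ``mu(a) = c + b*exp(theta*a)``, with parameters chosen to
reproduce the level of 2014-era US female all-cause mortality (remaining
life expectancy at 50 of about 33-34 years).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .config import load_natural_history
from .microsim import aggregate_outputs, precompute_transitions, simulate_individuals
from .model_core import AgeBins, DEFAULT_BINS, LifeTable
from .params import CalibratedParams, FixedParams

__all__ = ["LifeTableFixture", "default_life_table", "make_life_table",
           "TargetSet", "generate_targets"]

logger = logging.getLogger(__name__)

SE_FLOOR = 1e-6  # keeps the likelihood finite for degenerate zero-variance targets


@dataclass(frozen=True)
class LifeTableFixture:
    """Gompertz–Makeham specification of background mortality.

    ``mu(a) = makeham_c + makeham_b * exp(makeham_theta * a)`` for integer
    ages 0..age_max. ``csv_path``, when given, overrides the parametric form
    with a bundled ``age,mortality_rate`` table.
    """

    makeham_c: float = 3.0e-4
    makeham_b: float = 3.5e-5
    makeham_theta: float = 0.0875
    age_max: int = 100
    label: str = "synthetic US females 2014 (Gompertz-Makeham approximation)"
    csv_path: Optional[str] = None


def make_life_table(spec: LifeTableFixture) -> LifeTable:
    """Materialise a :class:`LifeTable` from a fixture specification."""
    if spec.csv_path is not None:
        return LifeTable.from_csv(spec.csv_path)
    if spec.makeham_c < 0 or spec.makeham_b < 0:
        raise ValueError("Makeham components must be non-negative")
    ages = np.arange(0, spec.age_max + 1)
    rates = spec.makeham_c + spec.makeham_b * np.exp(spec.makeham_theta * ages)
    return LifeTable(ages, rates)


def default_life_table() -> LifeTable:
    """The packaged default mortality fixture (see data/natural_history.yaml)."""
    cfg = load_natural_history()["life_table"]
    return make_life_table(LifeTableFixture(
        makeham_c=float(cfg["makeham_c"]), makeham_b=float(cfg["makeham_b"]),
        makeham_theta=float(cfg["makeham_theta"]), age_max=int(cfg["age_max"]),
        label=str(cfg["label"])))


@dataclass
class TargetSet:
    """Age-binned calibration targets with replication-based uncertainty.

    ``data`` has one row per target cell: ``target_type, age_lo, age_hi,
    mean, se, n`` where ``n`` is the cohort size each replication simulated.
    """

    data: pd.DataFrame
    n_reps: int
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        req = {"target_type", "age_lo", "age_hi", "mean", "se", "n"}
        if not req <= set(self.data.columns):
            raise ValueError(f"TargetSet columns must include {sorted(req)}")
        if np.any(self.data["se"].to_numpy() <= 0):
            raise ValueError("every target must have se > 0")

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path, meta_path=None) -> None:
        self.data.to_csv(path, index=False)
        if meta_path is not None:
            with open(meta_path, "w") as fh:
                yaml.safe_dump({"n_reps": self.n_reps, "seed": self.seed}, fh)

    @classmethod
    def from_csv(cls, path, meta_path=None) -> "TargetSet":
        df = pd.read_csv(path)
        n_reps, seed = 0, None
        if meta_path is not None:
            with open(meta_path) as fh:
                meta = yaml.safe_load(fh)
            n_reps, seed = int(meta.get("n_reps", 0)), meta.get("seed")
        return cls(df, n_reps=n_reps, seed=seed)


def generate_targets(truth: CalibratedParams, theta_k: FixedParams,
                     lt: LifeTable, n_reps: int = 100, n_adenoma: int = 500,
                     n_cancer: int = 100_000, bins: AgeBins = DEFAULT_BINS,
                     seed: int = 0) -> TargetSet:
    """Generate the four synthetic target types at the true parameter values.

    Each of ``n_reps`` replications simulates one adenoma-study cohort of
    ``n_adenoma`` and one registry cohort of ``n_cancer``; a target's mean is
    the across-replication average and its standard error the
    across-replication standard deviation (ddof=1) — i.e. the sampling error
    of a single study of the stated size, which is what the calibration
    likelihood requires. Cells undefined in every replication are dropped
    with a warning.
    """
    if n_reps < 2:
        raise ValueError("need at least 2 replications to estimate an SE")
    ss = np.random.SeedSequence([seed, 0x7A6E75])
    rep_seeds = ss.generate_state(2 * n_reps, dtype=np.uint32)
    age_end = bins.max_age + 1
    P = precompute_transitions(truth, theta_k, lt, 50, age_end)

    per_rep = []
    for r in range(n_reps):
        paths_a = simulate_individuals(truth, theta_k, lt, n_adenoma,
                                       int(rep_seeds[2 * r]), age_end=age_end,
                                       P_stack=P)
        paths_c = simulate_individuals(truth, theta_k, lt, n_cancer,
                                       int(rep_seeds[2 * r + 1]), age_end=age_end,
                                       P_stack=P)
        out_a = aggregate_outputs(paths_a, bins)
        out_c = aggregate_outputs(paths_c, bins)
        adeno = out_a["target_type"].isin(["adenoma_prev", "prop_small"])
        rep = pd.concat([out_a[adeno], out_c[~adeno]], ignore_index=True)
        per_rep.append(rep)

    keys = ["target_type", "age_lo", "age_hi"]
    stacked = pd.concat(per_rep, ignore_index=True)
    grouped = stacked.groupby(keys, sort=False)["value"]
    agg = grouped.agg(mean="mean", se=lambda v: v.std(ddof=1),
                      n_defined="count").reset_index()

    dropped = agg[agg["n_defined"] == 0]
    for _, row in dropped.iterrows():
        logger.warning("target %s [%s, %s] undefined in every replication; dropped",
                       row["target_type"], row["age_lo"], row["age_hi"])
    agg = agg[agg["n_defined"] > 0].copy()
    agg["se"] = agg["se"].fillna(0.0).clip(lower=SE_FLOOR)
    agg["n"] = np.where(agg["target_type"].isin(["adenoma_prev", "prop_small"]),
                        n_adenoma, n_cancer)
    return TargetSet(agg.drop(columns="n_defined"), n_reps=n_reps, seed=seed)
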