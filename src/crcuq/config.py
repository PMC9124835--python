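"""Configuration: packaged parameter tables, run profiles, YAML round trip.

All printed constants of the analysis (true natural-history values, priors,
CEA parameter table, life-table fixture) live in the packaged YAML files
under ``crcuq/data`` so that alternative scenarios are plain config edits;
nothing numeric is hard-coded in the pipeline stages.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass
from importlib import resources

import yaml

from .params import CalibratedParams, FixedParams, fixed_from_dict, params_from_dict

__all__ = ["load_natural_history", "load_cea_config", "load_truth",
           "load_fixed", "RunConfig", "PROFILES"]


def _read_packaged(name: str) -> dict:
    with resources.files("crcuq.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


def load_natural_history() -> dict:
    return _read_packaged("natural_history.yaml")


def load_cea_config() -> dict:
    return _read_packaged("cea.yaml")


def load_truth() -> CalibratedParams:
    """The generative parameter values used to produce synthetic targets."""
    return params_from_dict(load_natural_history()["truth"])


def load_fixed() -> FixedParams:
    """The external (non-calibrated) natural-history parameters."""
    return fixed_from_dict(load_natural_history()["fixed"])


#: stage-size presets. ``desk`` runs the whole pipeline on a laptop-class
#: machine; ``full`` mirrors the cohort and sampler sizes of a cluster-scale
#: analysis.
PROFILES = {
    "desk": dict(
        n_reps=100, n_adenoma=500, n_cancer=100_000,
        imis_n0=1000, imis_b=100, ess_target=1000, max_iters=100,
        n_resample=5000,
        n_predictive=5000,
        n_psa=500, n_micro=2000,
        cea_n=10_000,
    ),
    "full": dict(
        n_reps=100, n_adenoma=500, n_cancer=100_000,
        imis_n0=5000, imis_b=500, ess_target=5000, max_iters=100,
        n_resample=5000,
        n_predictive=5000,
        n_psa=5000, n_micro=100_000,
        cea_n=100_000,
    ),
}


@dataclass
class RunConfig:
    """Concrete sizes, seeds and economic settings for one pipeline run."""

    profile: str = "desk"
    seed: int = 1
    # synthetic targets
    n_reps: int = 100
    n_adenoma: int = 500
    n_cancer: int = 100_000
    # calibration (IMIS)
    imis_n0: int = 1000
    imis_b: int = 100
    ess_target: int = 1000
    max_iters: int = 100
    n_resample: int = 5000
    # internal validation
    n_predictive: int = 5000
    # CEA / PSA / EVPI
    cea_n: int = 10_000
    n_psa: int = 500
    n_micro: int = 2000
    discount_rate: float = 0.03
    wtp_max: float = 150_000.0
    wtp_step: float = 1000.0

    @classmethod
    def from_profile(cls, profile: str = "desk", seed: int = 1, **overrides) -> "RunConfig":
        if profile not in PROFILES:
            raise ValueError(f"unknown profile {profile!r}; choose from {sorted(PROFILES)}")
        kwargs = dict(PROFILES[profile])
        kwargs.update(overrides)
        return cls(profile=profile, seed=seed, **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        profile = raw.pop("profile", "desk")
        seed = raw.pop("seed", 1)
        return cls.from_profile(profile, seed=seed, **raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        """Stable hash of the fully resolved configuration."""
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the run seed."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "little") % (2**31 - 1)
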