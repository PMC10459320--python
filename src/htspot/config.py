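"""Run configuration: defaults, TOML loading and CLI-flag overrides.

The config file is flat TOML with up to four sections::

    [model]
    slope = -0.0070
    intercept = 1.32
    ht_domain_low = 20
    ht_domain_high = 70

    [simulation]
    n = 1000000
    seed = 12345
    truncate = false

    [screening]
    ht_cal = 50.0
    correct_all = false

    [report]
    tolerance_levels = [1, 3, 5]

CLI flags override file values; everything has a sensible default, so no
config file is required.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path

from .dispersion import DispersionModel

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    """Effective configuration of one command run.

    ``ht_cal_policy`` selects between a fixed calibration hematocrit
    (``"fixed"``, using ``ht_cal``) and one matched to each subpopulation's
    mean (``"population_mean"``).
    """

    model: DispersionModel = field(default_factory=DispersionModel)
    ht_cal_policy: str = "fixed"  # "fixed" | "population_mean"
    ht_cal: float = 50.0
    tolerance_levels: tuple[float, ...] = (1.0, 3.0, 5.0)
    mc_n: int = 1_000_000
    seed: int = 0
    truncate: bool = False
    correct_all: bool = False
    out_dir: Path = Path(".")
    verbosity: int = 0

    def __post_init__(self) -> None:
        if self.ht_cal_policy not in ("fixed", "population_mean"):
            raise ValueError("ht_cal_policy must be 'fixed' or 'population_mean'")
        levels = tuple(self.tolerance_levels)
        if any(lv <= 0 for lv in levels):
            raise ValueError("tolerance levels must be positive")
        if list(levels) != sorted(levels):
            raise ValueError("tolerance levels must be sorted ascending")


def load_config(path: str | Path | None) -> RunConfig:
    """Build a RunConfig from a TOML file (or defaults when path is None)."""
    if path is None:
        return RunConfig()
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    model_raw = raw.get("model", {})
    model = DispersionModel(
        slope=float(model_raw.get("slope", -0.0070)),
        intercept=float(model_raw.get("intercept", 1.32)),
        ht_domain=(
            float(model_raw.get("ht_domain_low", 20.0)),
            float(model_raw.get("ht_domain_high", 70.0)),
        ),
    )
    sim = raw.get("simulation", {})
    scr = raw.get("screening", {})
    rep = raw.get("report", {})
    return RunConfig(
        model=model,
        ht_cal_policy=str(scr.get("ht_cal_policy", "fixed")),
        ht_cal=float(scr.get("ht_cal", 50.0)),
        tolerance_levels=tuple(float(x) for x in rep.get("tolerance_levels", (1, 3, 5))),
        mc_n=int(sim.get("n", 1_000_000)),
        seed=int(sim.get("seed", 0)),
        truncate=bool(sim.get("truncate", False)),
        correct_all=bool(scr.get("correct_all", False)),
    )
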