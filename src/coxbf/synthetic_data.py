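"""Ground-truth survival data generators for testing and validation.

Event times are exponential with a proportional-hazards group effect: the
control hazard is ``baseline_rate`` and the experimental hazard is
``baseline_rate * exp(beta_true)``, so the generating log hazard ratio is
known exactly and proportional hazards holds by construction.  (Cox
inference is baseline-agnostic, so the exponential shape is a convenience,
not a restriction.)  Censoring is independent exponential, optionally
combined with an administrative cutoff.

``make_fixture`` emulates the overall shapes (total sample sizes, two
groups, moderate censoring) of three classic survival datasets commonly
used to exercise survival software — times-to-infection in kidney patients
(n = 76), advanced lung cancer survival (n = 228), and colon cancer
adjuvant-chemotherapy survival (n = 929).  These are synthetic stand-ins
generated by this module, not the original datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .survival_core import InvalidDataError, SurvivalData

__all__ = [
    "SimulationSpec",
    "simulate_survival",
    "rescale_min_time",
    "make_fixture",
    "FIXTURE_PROFILES",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of a two-group exponential proportional-hazards simulation.

    Attributes
    ----------
    n_control, n_experimental : group sizes.
    beta_true : generating log hazard ratio.
    baseline_rate : exponential event hazard in the control group
        (1 / mean control event time).
    censor_rate : independent exponential censoring hazard; 0 disables
        random censoring.
    admin_cutoff : administrative censoring time; ``None`` disables it.
    seed : RNG seed; the same spec always yields the same dataset.
    """

    n_control: int
    n_experimental: int
    beta_true: float = 0.0
    baseline_rate: float = 1.0
    censor_rate: float = 0.0
    admin_cutoff: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_experimental < 1:
            raise InvalidDataError("group sizes must be >= 1")
        if not (self.baseline_rate > 0 and math.isfinite(self.baseline_rate)):
            raise InvalidDataError("baseline_rate must be positive")
        if self.censor_rate < 0:
            raise InvalidDataError("censor_rate must be >= 0")
        if self.admin_cutoff is not None and not self.admin_cutoff > 0:
            raise InvalidDataError("admin_cutoff must be positive")
        if not math.isfinite(self.beta_true):
            raise InvalidDataError("beta_true must be finite")


def simulate_survival(spec: SimulationSpec) -> SurvivalData:
    """Draw one dataset under the spec's proportional-hazards model.

    Observed time = min(event time, censoring time, admin cutoff); the event
    indicator is 1 exactly when the event time attains the minimum.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_control + spec.n_experimental
    groups = np.concatenate([np.zeros(spec.n_control),
                             np.ones(spec.n_experimental)])
    rates = spec.baseline_rate * np.exp(spec.beta_true * groups)
    event_times = rng.exponential(1.0 / rates)
    observed = event_times.copy()
    if spec.censor_rate > 0:
        censor_times = rng.exponential(1.0 / spec.censor_rate, size=n)
        observed = np.minimum(observed, censor_times)
    if spec.admin_cutoff is not None:
        observed = np.minimum(observed, spec.admin_cutoff)
    events = (event_times <= observed).astype(int)
    return SurvivalData(observed, events, groups)


def rescale_min_time(data: SurvivalData, min_time: float = 1.0) -> SurvivalData:
    """Multiplicatively rescale times so the smallest equals ``min_time``.

    Rank-preserving, hence invisible to the partial likelihood; used to put
    simulated data on the [1, tmax] scale the reconstruction machinery
    assumes.
    """
    if not min_time > 0:
        raise InvalidDataError("min_time must be positive")
    return data.with_times(data.times * (min_time / data.times.min()))


# Synthetic stand-in profiles: (n_control, n_experimental, beta_true,
# censor_rate).  Total sizes 76 / 228 / 929 match the classic datasets; the
# group splits, effect sizes and exponential censoring rates (chosen for
# roughly 30-60% censoring under a unit baseline hazard) are this package's
# own choices — the originals' censoring patterns are not reproduced.
FIXTURE_PROFILES = {
    "kidney_like": (38, 38, -0.9, 0.8),
    "lung_like": (138, 90, 0.4, 0.6),
    "colon_like": (465, 464, 0.15, 0.9),
}


def make_fixture(profile: str, seed: int) -> SurvivalData:
    """A named synthetic two-group dataset with a realistic shape.

    Times are rescaled so the minimum is 1, making the fixture directly
    usable as a reconstruction source.
    """
    if profile not in FIXTURE_PROFILES:
        raise InvalidDataError(
            f"unknown profile {profile!r}; choose from "
            f"{sorted(FIXTURE_PROFILES)}")
    nc, ne, beta, censor_rate = FIXTURE_PROFILES[profile]
    spec = SimulationSpec(n_control=nc, n_experimental=ne, beta_true=beta,
                          baseline_rate=1.0, censor_rate=censor_rate,
                          seed=seed)
    return rescale_min_time(simulate_survival(spec))
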