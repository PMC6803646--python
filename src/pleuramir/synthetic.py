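"""Synthetic qPCR-array cohorts with known ground truth.

Emulates the statistical structure of a TaqMan OpenArray miRNA screen on a
small two-group cohort: a fixed panel of probes, heavy undetected censoring
at the Ct = 40 instrument ceiling, a handful of tightly-detected endogenous
reference probes, and a set of probes spiked with a group effect of known
sign and magnitude. Every downstream pipeline stage can therefore be tested
against the generating truth without any deposited dataset.

Model
-----
Each probe gets a baseline Ct drawn uniformly from ``baseline_range``;
per-sample values add Gaussian noise (``noise_sd`` Ct units, or the much
tighter ``reference_sd`` for designed reference probes). A fraction
``frac_never_detected`` of probes gets a baseline above the detection
ceiling so that every well censors to exactly Ct 40. Spiked probes shift the
*cancer* group mean by ``effect_size`` Ct before censoring; a probe spiked
"up" (higher expression in cancer) has a *lower* Ct in cancer, matching the
sign convention of the differential-expression stage. Values are censored to
the ceiling after all shifts.

The Gaussian-with-censoring noise model is an assumption, not a measured
property of real OpenArray data; see the methods note for what it does and
does not emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SyntheticConfig", "GroundTruth", "SyntheticConfigError", "generate"]

DETECT_CEILING = 40.0
#: floor applied after noise so emitted Ct stays strictly positive
_CT_FLOOR = 0.01


class SyntheticConfigError(ValueError):
    """Raised when a :class:`SyntheticConfig` violates its invariants."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one simulated cohort.

    Defaults mirror the cohort the pipeline targets: a 754-probe panel,
    20 control and 14 cancer samples surviving QC, 5 probes up- and 9
    down-regulated in cancer, and a few designed low-variance reference
    probes.
    """

    n_probes: int = 754
    n_control: int = 20
    n_cancer: int = 14
    n_up: int = 5
    n_down: int = 9
    effect_size: float = 5.0
    n_reference: int = 6
    baseline_range: tuple[float, float] = (18.0, 34.0)
    noise_sd: float = 0.8
    reference_sd: float = 0.15
    frac_never_detected: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_probes", "n_control", "n_cancer", "n_up", "n_down",
                     "n_reference"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise SyntheticConfigError(
                    f"{name} must be a non-negative integer, got {v!r}")
        for name in ("effect_size", "noise_sd", "reference_sd"):
            if getattr(self, name) < 0:
                raise SyntheticConfigError(f"{name} must be >= 0")
        if self.n_up + self.n_down + self.n_reference > self.n_probes:
            raise SyntheticConfigError(
                "n_up + n_down + n_reference exceeds n_probes")
        if not 0.0 <= self.frac_never_detected <= 1.0:
            raise SyntheticConfigError("frac_never_detected must be in [0, 1]")
        lo, hi = self.baseline_range
        if not (0 < lo <= hi):
            raise SyntheticConfigError(
                "baseline_range must satisfy 0 < low <= high")
        if self.n_probes and self.n_control + self.n_cancer == 0:
            raise SyntheticConfigError("n_control + n_cancer must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Bookkeeping of what the generator spiked, for test oracles."""

    spiked_up: frozenset[str]
    spiked_down: frozenset[str]
    designed_references: frozenset[str]
    never_detected: frozenset[str]
    #: probe -> signed shift on the expression scale (positive = up in cancer)
    true_effects: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.spiked_up & self.designed_references or \
           self.spiked_down & self.designed_references:
            raise ValueError("spiked sets must be disjoint from references")


def _probe_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"sim-miR-{i:0{width}d}" for i in range(1, n + 1)]


def _sample_ids(n_control: int, n_cancer: int) -> list[str]:
    return ([f"CTRL-{i:02d}" for i in range(1, n_control + 1)]
            + [f"LC-{i:02d}" for i in range(1, n_cancer + 1)])


def generate(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate one cohort.

    Returns ``(ct_matrix, sample_sheet, truth)`` where *ct_matrix* is a
    probes x samples DataFrame of censored Ct values, *sample_sheet* has
    columns ``sample_id`` and ``group``, and *truth* records the spiked and
    reference probe sets.

    The function is a pure function of ``config`` (including its seed).
    Randomness is drawn from independent per-purpose streams, and per-probe
    noise comes from one stream per probe, so enlarging the panel appends
    probes without reshuffling the values of existing ones.
    """
    config.validate()
    n_samples = config.n_control + config.n_cancer
    probes = _probe_ids(config.n_probes)
    samples = _sample_ids(config.n_control, config.n_cancer)

    # Independent streams: 0 = role assignment, 1 = baselines; per-probe
    # noise streams are keyed by (seed, 2, probe index).
    role_rng = np.random.default_rng([config.seed, 0])
    base_rng = np.random.default_rng([config.seed, 1])

    order = role_rng.permutation(config.n_probes)
    refs = set(order[: config.n_reference])
    up = set(order[config.n_reference: config.n_reference + config.n_up])
    down = set(order[config.n_reference + config.n_up:
                     config.n_reference + config.n_up + config.n_down])

    # Never-detected probes: a fraction of the whole panel, preferentially
    # placed on unassigned probes; spills into spiked/reference probes only
    # when the fraction demands it (e.g. frac_never_detected = 1).
    n_never = int(round(config.frac_never_detected * config.n_probes))
    special = list(refs | up | down)
    plain = [i for i in order if i not in refs | up | down]
    never = set(plain[:n_never])
    if n_never > len(plain):
        never |= set(role_rng.permutation(special)[: n_never - len(plain)])

    lo, hi = config.baseline_range
    baselines = base_rng.uniform(lo, hi, size=config.n_probes)
    # censored probes sit far enough above the ceiling that no noise draw
    # can bring a well back under it: every value censors to exactly 40
    baselines[sorted(never)] = base_rng.uniform(
        DETECT_CEILING + 2.0, DETECT_CEILING + 6.0, size=len(never))

    is_cancer = np.array([0] * config.n_control + [1] * config.n_cancer, bool)
    values = np.empty((config.n_probes, n_samples))
    true_effects: dict[str, float] = {}
    for i in range(config.n_probes):
        rng_i = np.random.default_rng([config.seed, 2, i])
        sd = config.reference_sd if i in refs else config.noise_sd
        row = baselines[i] + rng_i.normal(0.0, sd, size=n_samples)
        if i in up:       # higher expression in cancer -> lower Ct
            row[is_cancer] -= config.effect_size
            true_effects[probes[i]] = +config.effect_size
        elif i in down:
            row[is_cancer] += config.effect_size
            true_effects[probes[i]] = -config.effect_size
        values[i] = row

    values = np.clip(values, _CT_FLOOR, DETECT_CEILING)
    if never:
        values[sorted(never)] = DETECT_CEILING

    ct = pd.DataFrame(values, index=pd.Index(probes, name="probe_id"),
                      columns=samples)
    sheet = pd.DataFrame({
        "sample_id": samples,
        "group": ["control"] * config.n_control + ["cancer"] * config.n_cancer,
    })
    truth = GroundTruth(
        spiked_up=frozenset(probes[i] for i in up),
        spiked_down=frozenset(probes[i] for i in down),
        designed_references=frozenset(probes[i] for i in refs),
        never_detected=frozenset(probes[i] for i in never),
        true_effects=true_effects,
    )
    return ct, sheet, truth
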