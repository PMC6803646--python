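"""Probe/sample QC and reference-based delta-Ct normalization.

The QC stage mirrors standard qPCR-array practice: probes undetected
(Ct = 40) in every sample are removed, then samples in which more than a
threshold fraction (default 80%) of the remaining probes are undetected are
removed. Endogenous reference probes are chosen among probes undetected in
at most ``max_undetected`` samples as the ``k`` probes with the lowest
interquartile range of Ct across retained samples; each sample's mean
reference Ct is then subtracted from every probe (delta-Ct).

Undetected wells that survive QC are kept as numeric 40 through
normalization and statistics (the HTqPCR-style convention). Because the
reader clamps every value at the 40-cycle ceiling, the "above 40" sample
filter is implemented as Ct >= 40.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["QcReport", "ReferenceSet", "PreprocessError",
           "filter_probes", "filter_samples", "select_references",
           "delta_normalize", "undetected_fraction"]

CT_CEILING = 40.0


class PreprocessError(ValueError):
    """QC or normalization cannot proceed on this input."""


@dataclass(frozen=True)
class QcReport:
    n_probes_in: int
    n_probes_removed_all40: int
    n_probes_kept: int
    n_samples_in: int
    n_samples_removed: int
    n_samples_kept: int
    sample_undetected_fraction: dict[str, float]

    def __post_init__(self) -> None:
        assert self.n_probes_in == self.n_probes_removed_all40 + self.n_probes_kept
        assert self.n_samples_in == self.n_samples_removed + self.n_samples_kept


@dataclass(frozen=True)
class ReferenceSet:
    """The k lowest-IQR probes eligible as endogenous controls."""

    probe_ids: tuple[str, ...]
    eligibility_max_undetected: int
    iqr: dict[str, float]


def undetected_fraction(ct: pd.DataFrame) -> pd.Series:
    """Per-sample fraction of probes at the detection ceiling."""
    return (ct >= CT_CEILING).mean(axis=0)


def filter_probes(ct: pd.DataFrame) -> tuple[pd.DataFrame, QcReport]:
    """Drop probes with Ct = 40 in every sample; survivor order preserved."""
    if ct.empty:
        raise PreprocessError("empty Ct matrix")
    all40 = (ct >= CT_CEILING).all(axis=1)
    kept = ct.loc[~all40]
    if kept.empty:
        raise PreprocessError("no detected probes: every probe is Ct 40 in all samples")
    report = QcReport(
        n_probes_in=ct.shape[0],
        n_probes_removed_all40=int(all40.sum()),
        n_probes_kept=kept.shape[0],
        n_samples_in=ct.shape[1],
        n_samples_removed=0,
        n_samples_kept=ct.shape[1],
        sample_undetected_fraction=undetected_fraction(ct).to_dict(),
    )
    return kept, report


def filter_samples(ct: pd.DataFrame, threshold: float = 0.80,
                   groups: pd.Series | None = None,
                   ) -> tuple[pd.DataFrame, QcReport]:
    """Drop samples whose undetected fraction strictly exceeds *threshold*.

    If *groups* (sample -> label) is given, a group losing all of its
    samples raises :class:`PreprocessError` naming the group.
    """
    frac = undetected_fraction(ct)
    drop = frac > threshold
    kept = ct.loc[:, ~drop.values]
    if groups is not None:
        g = pd.Series(groups)
        for label in g.unique():
            members = g.index[g == label]
            if not any(s in kept.columns for s in members):
                raise PreprocessError(
                    f"sample QC removed every sample of group {label!r}")
    elif kept.shape[1] == 0:
        raise PreprocessError("sample QC removed every sample")
    report = QcReport(
        n_probes_in=ct.shape[0],
        n_probes_removed_all40=0,
        n_probes_kept=ct.shape[0],
        n_samples_in=ct.shape[1],
        n_samples_removed=int(drop.sum()),
        n_samples_kept=kept.shape[1],
        sample_undetected_fraction=frac.to_dict(),
    )
    return kept, report


def _iqr(values: np.ndarray) -> float:
    q1, q3 = np.percentile(values, [25.0, 75.0], method="linear")
    return float(q3 - q1)


def select_references(ct: pd.DataFrame, k: int = 4,
                      max_undetected: int | float = 3,
                      fraction: bool = False) -> ReferenceSet:
    """Pick the *k* eligible probes with smallest Ct IQR.

    Eligibility: Ct = 40 in at most *max_undetected* retained samples (an
    absolute count, or a fraction of samples when ``fraction=True``). IQR is
    Q3 - Q1 with linear-interpolation quantiles, computed over all retained
    samples including 40s. Ties break by probe ID ascending.
    """
    if k < 1:
        raise PreprocessError("k must be >= 1")
    limit = max_undetected * ct.shape[1] if fraction else max_undetected
    n_undet = (ct >= CT_CEILING).sum(axis=1)
    eligible = ct.index[n_undet <= limit]
    if len(eligible) < k:
        raise PreprocessError(
            f"only {len(eligible)} probes are undetected in <= {limit} samples "
            f"but k={k} references requested; lower k or raise max_undetected")
    iqr = {p: _iqr(ct.loc[p].to_numpy()) for p in eligible}
    ranked = sorted(eligible, key=lambda p: (iqr[p], p))
    chosen = tuple(ranked[:k])
    return ReferenceSet(probe_ids=chosen,
                        eligibility_max_undetected=int(limit),
                        iqr={p: iqr[p] for p in chosen})


def delta_normalize(ct: pd.DataFrame, refs: ReferenceSet) -> pd.DataFrame:
    """dCt[p, s] = Ct[p, s] - mean over reference probes of Ct[ref, s].

    Reference probes stay in the output; by construction their per-sample
    mean dCt is exactly zero.
    """
    if not refs.probe_ids:
        raise PreprocessError("empty reference set")
    missing = [p for p in refs.probe_ids if p not in ct.index]
    if missing:
        raise PreprocessError(f"reference probes absent from matrix: {missing}")
    ref_mean = ct.loc[list(refs.probe_ids)].mean(axis=0)
    return ct.sub(ref_mean, axis=1)
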