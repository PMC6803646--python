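"""Two-group differential expression with empirical-Bayes moderated t.

Works on the delta-Ct matrix. The expression proxy is e = -dCt, so a
positive log-fold-change means higher abundance in the cancer group (lower
Ct). Because Ct is a log2-scale quantity, differences on this proxy are
log2-like fold changes.

Variance moderation follows the classical hierarchical model for gene-wise
variances: each probe's residual variance s_g^2 is assumed to follow a
scaled chi-square around a prior variance s0^2 with prior degrees of
freedom d0, both estimated by moment-matching the log-variances,

    z_g = log s_g^2,  e_g = z_g - digamma(d/2) + log(d/2),
    trigamma(d0/2) = var(e_g) - trigamma(d/2),
    s0^2 = exp( mean(e_g) + digamma(d0/2) - log(d0/2) ),

after which the moderated variance is the df-weighted compromise
s~^2 = (d0 s0^2 + d s^2) / (d0 + d) and the moderated t-statistic

    t = logFC / sqrt( s~^2 (1/n1 + 1/n2) )

is referred to a Student t distribution on d0 + d degrees of freedom
(standard normal when d0 is infinite). Multiple testing is controlled by
Benjamini-Hochberg step-up FDR, and candidates are gated on both the
adjusted p-value and the fold-change magnitude.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = ["GroupDesign", "ModerationFit", "DiffexprError",
           "compute_group_stats", "fit_moderation", "moderated_test",
           "bh_adjust", "select_candidates", "run_diffexpr"]

log = logging.getLogger("pleuramir")

#: d0 values above this are declared infinite (complete shrinkage)
_D0_INFINITE = 1e7
_D0_BRACKET = (1e-6, 1e8)


class DiffexprError(ValueError):
    pass


@dataclass(frozen=True)
class GroupDesign:
    """Two-group contrast: which samples are control, which are cancer."""

    control: tuple[str, ...]
    cancer: tuple[str, ...]

    @classmethod
    def from_sample_sheet(cls, sheet: pd.DataFrame,
                          sample_ids=None) -> "GroupDesign":
        keep = set(sample_ids) if sample_ids is not None else None
        rows = sheet if keep is None else sheet[sheet["sample_id"].isin(keep)]
        return cls(
            control=tuple(rows.loc[rows["group"] == "control", "sample_id"]),
            cancer=tuple(rows.loc[rows["group"] == "cancer", "sample_id"]),
        )

    @property
    def n1(self) -> int:
        return len(self.control)

    @property
    def n2(self) -> int:
        return len(self.cancer)

    def validate(self) -> None:
        if self.n1 < 2 or self.n2 < 2:
            raise DiffexprError(
                f"need >= 2 samples per group, got {self.n1} control / "
                f"{self.n2} cancer")


@dataclass(frozen=True)
class ModerationFit:
    """Estimated variance prior and per-probe moderated variances."""

    d0: float                 # prior df; may be +inf
    s0_sq: float              # prior variance
    d: float                  # residual df per probe
    s_sq: np.ndarray          # per-probe residual variances
    s_tilde_sq: np.ndarray    # moderated variances

    @property
    def df_total(self) -> float:
        return self.d0 + self.d


def compute_group_stats(dct: pd.DataFrame, design: GroupDesign) -> pd.DataFrame:
    """Per-probe logFC, pooled within-group variance and residual df.

    Expression proxy e = -dCt; logFC = mean e(cancer) - mean e(control).
    """
    design.validate()
    missing = [s for s in design.control + design.cancer
               if s not in dct.columns]
    if missing:
        raise DiffexprError(f"samples not in matrix: {missing}")
    e = -dct
    a = e[list(design.control)].to_numpy()
    b = e[list(design.cancer)].to_numpy()
    n1, n2 = design.n1, design.n2
    logfc = b.mean(axis=1) - a.mean(axis=1)
    ss_a = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss_b = ((b - b.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    d = n1 + n2 - 2
    s_sq = (ss_a + ss_b) / d
    return pd.DataFrame({"logFC": logfc, "s_sq": s_sq, "d": float(d)},
                        index=dct.index)


def _inv_trigamma(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (trigamma is monotone decreasing)."""
    lo, hi = 1e-8, 1e9
    return optimize.brentq(lambda x: special.polygamma(1, x) - y, lo, hi,
                           xtol=1e-12, rtol=1e-12, maxiter=200)


def fit_moderation(s_sq: np.ndarray, d: float) -> ModerationFit:
    """Moment-match the variance prior (d0, s0^2) on the log scale.

    Probes with s_sq = 0 are excluded from the moment matching but still
    receive a moderated variance d0*s0^2/(d0+d).
    """
    s_sq = np.asarray(s_sq, dtype=float)
    pos = s_sq > 0
    if pos.sum() < 2:
        raise DiffexprError(
            "degenerate variance distribution: need >= 2 probes with "
            "positive residual variance")
    z = np.log(s_sq[pos])
    e_g = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    excess = np.var(e_g, ddof=1) - special.polygamma(1, d / 2.0)
    if excess <= 0 or not np.isfinite(excess):
        d0 = np.inf
    else:
        d0 = 2.0 * _inv_trigamma(excess)
        d0 = max(min(d0, _D0_BRACKET[1]), _D0_BRACKET[0])
        if d0 > _D0_INFINITE:
            d0 = np.inf
    if np.isinf(d0):
        s0_sq = float(np.exp(e_g.mean()))
        s_tilde = np.full_like(s_sq, s0_sq)
    else:
        s0_sq = float(np.exp(e_g.mean() + special.digamma(d0 / 2.0)
                             - np.log(d0 / 2.0)))
        s_tilde = (d0 * s0_sq + d * s_sq) / (d0 + d)
    return ModerationFit(d0=float(d0), s0_sq=s0_sq, d=float(d),
                         s_sq=s_sq, s_tilde_sq=s_tilde)


def moderated_test(logfc: np.ndarray, fit: ModerationFit,
                   n1: int, n2: int) -> tuple[np.ndarray, np.ndarray]:
    """Moderated t and two-sided p on d0 + d degrees of freedom."""
    logfc = np.asarray(logfc, dtype=float)
    se = np.sqrt(fit.s_tilde_sq * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / np.where(se > 0, se, 1.0), np.inf * np.sign(logfc))
    t = np.where((se == 0) & (logfc == 0), 0.0, t)
    if np.any(fit.s_tilde_sq == 0):
        warnings.warn("zero moderated variance for some probes; p set to 0",
                      stacklevel=2)
    if np.isinf(fit.df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), fit.df_total)
    p = np.where(np.isinf(t), 0.0, p)
    p = np.where((se == 0) & (logfc == 0), 1.0, p)
    return t, np.clip(p, 0.0, 1.0)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise DiffexprError("p must be a 1-d vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DiffexprError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def select_candidates(results: pd.DataFrame, p_cut: float = 0.05,
                      lfc_cut: float = 3.0) -> pd.DataFrame:
    """Candidates: adj_p < p_cut and |logFC| > lfc_cut, sorted by adj_p."""
    flag = (results["adj_p"] < p_cut) & (results["logFC"].abs() > lfc_cut)
    out = results.assign(candidate=flag)
    return out.loc[flag].sort_values(["adj_p", "probe_id"]).reset_index(drop=True)


def run_diffexpr(dct: pd.DataFrame, design: GroupDesign,
                 p_cut: float = 0.05, lfc_cut: float = 3.0,
                 ) -> tuple[pd.DataFrame, ModerationFit]:
    """Full moderated differential-expression table for all probes.

    Returns (table sorted by adj_p with columns probe_id, logFC, t_mod, p,
    adj_p, candidate; ModerationFit).
    """
    stats_df = compute_group_stats(dct, design)
    fit = fit_moderation(stats_df["s_sq"].to_numpy(), stats_df["d"].iloc[0])
    t, p = moderated_test(stats_df["logFC"].to_numpy(), fit,
                          design.n1, design.n2)
    adj = bh_adjust(p)
    table = pd.DataFrame({
        "probe_id": stats_df.index,
        "logFC": stats_df["logFC"].to_numpy(),
        "t_mod": t,
        "p": p,
        "adj_p": adj,
    })
    table["candidate"] = (table["adj_p"] < p_cut) & (table["logFC"].abs() > lfc_cut)
    table = table.sort_values(["adj_p", "probe_id"]).reset_index(drop=True)
    log.info("differential expression: %d probes, %d candidates "
             "(adj_p < %g, |logFC| > %g), d0 = %.3g",
             len(table), int(table["candidate"].sum()), p_cut, lfc_cut, fit.d0)
    return table, fit
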