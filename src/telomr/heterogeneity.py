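"""Goodness-of-fit heterogeneity test and instrument-pruning procedures.

Under the MR exclusion-restriction assumption every instrument's outcome
association is proportional to its exposure association, with the causal
effect as the common slope.  The goodness-of-fit statistic contrasts the
unconstrained K-df chi-square of the outcome associations with the 1-df
chi-square of the fitted risk score:

    X_k^2  = sum_k y_k^2 / sigma_yk^2        (K df, unconstrained)
    X_rs^2 = (beta_IVW / SE(beta_IVW))^2     (1 df, risk score)
    Q_rs   = X_k^2 - X_rs^2                  ~ chi2(K - 1) under the null.

A significant Q_rs flags at least one disproportionate (potentially
pleiotropic) instrument; stepwise pruning removes, at each step, the SNP
whose exclusion yields the greatest reduction in Q_rs, until the test is no
longer significant.  The statistic assumes uncorrelated SNPs, so LD pruning
must happen upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegreesOfFreedomError
from .estimators import ivw_estimate
from .summary_io import InstrumentSet

logger = logging.getLogger("telomr")


@dataclass(frozen=True)
class GofReport:
    """Goodness-of-fit test result for one instrument set."""

    q_stat: float
    df: int
    p_value: float
    x2_unconstrained: float
    x2_score: float


@dataclass(frozen=True)
class PruneStep:
    removed_snp_id: str
    q_before: float
    q_after: float
    p_after: float


@dataclass
class PruneHistory:
    """Trace of a stepwise goodness-of-fit pruning run."""

    steps: list[PruneStep]
    final_set: InstrumentSet
    final_report: GofReport
    floor_reached: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"step": i + 1, "removed_snp": s.removed_snp_id,
              "q_before": s.q_before, "q_after": s.q_after,
              "p_after": s.p_after} for i, s in enumerate(self.steps)],
            columns=["step", "removed_snp", "q_before", "q_after", "p_after"])


def gof_statistic(instruments: InstrumentSet) -> GofReport:
    """Q_rs goodness-of-fit test of proportionality for K >= 2 instruments."""
    k = len(instruments)
    if k < 2:
        raise DegreesOfFreedomError(
            f"goodness-of-fit test needs K >= 2 instruments, got {k}")
    y, sy = instruments.y, instruments.sigma_y
    x2_unconstrained = float(np.sum((y / sy) ** 2))
    est = ivw_estimate(instruments)
    x2_score = float((est.beta / est.se) ** 2)
    q = x2_unconstrained - x2_score
    df = k - 1
    return GofReport(q_stat=q, df=df, p_value=float(stats.chi2.sf(q, df)),
                     x2_unconstrained=x2_unconstrained, x2_score=x2_score)


def stepwise_prune(instruments: InstrumentSet, alpha: float = 0.05,
                   floor: int = 3) -> PruneHistory:
    """Stepwise removal of the SNP whose exclusion most reduces Q_rs.

    Repeats while the goodness-of-fit P-value is below ``alpha`` and more
    than ``floor`` instruments remain.  Ties on the resulting Q are broken
    lexicographically by snp_id, making the trace deterministic.  Hitting
    the floor while still significant logs a warning and flags the history
    rather than raising.
    """
    if len(instruments) < 2:
        raise DegreesOfFreedomError("pruning needs K >= 2 instruments")
    current = instruments
    steps: list[PruneStep] = []
    report = gof_statistic(current)
    floor_reached = False
    while report.p_value < alpha:
        if len(current) <= floor:
            floor_reached = True
            logger.warning(
                "prune floor of %d SNPs reached with GOF p=%.3g still < %g",
                floor, report.p_value, alpha)
            break
        candidates = []
        for v in current:
            reduced = current.drop([v.snp_id], reason="gof-candidate")
            q_after = gof_statistic(reduced).q_stat
            candidates.append((q_after, v.snp_id))
        q_after, victim = min(candidates)
        current = current.drop([victim], reason="goodness-of-fit")
        new_report = gof_statistic(current)
        steps.append(PruneStep(removed_snp_id=victim,
                               q_before=report.q_stat,
                               q_after=new_report.q_stat,
                               p_after=new_report.p_value))
        logger.info("gof prune step %d: removed %s (Q %.3f -> %.3f, p=%.3g)",
                    len(steps), victim, report.q_stat, new_report.q_stat,
                    new_report.p_value)
        report = new_report
    return PruneHistory(steps=steps, final_set=current, final_report=report,
                        floor_reached=floor_reached)


def strict_subset(instruments: InstrumentSet,
                  drop: tuple[str, ...] = ("rs6772228",)) -> InstrumentSet:
    """The "strict" sensitivity subset: drop instruments whose exposure
    association is considered questionable (by default the PXK-region SNP).

    Absent ids warn and are ignored; an empty ``drop`` is the identity.
    """
    drop = tuple(drop)
    if not drop:
        return instruments
    present = set(instruments.snp_ids)
    to_drop = [s for s in drop if s in present]
    for s in drop:
        if s not in present:
            logger.warning("strict_subset: %s not in instrument set", s)
    if not to_drop:
        return instruments
    return instruments.drop(to_drop, reason="strict")
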