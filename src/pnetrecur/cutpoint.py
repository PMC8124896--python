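"""Minimum p-value scan for an early-recurrence cut-off.

The scan takes the recurred patients of a cohort, sweeps a grid of candidate
recurrence-free-survival (RFS) thresholds, splits the patients at each
candidate into early (RFS ≤ c) and late (RFS > c) arms, and compares
post-recurrence survival (PRS) between the arms with the log-rank test.  The
candidate with the smallest p-value is the selected cut-off — the classical
minimum-p / maximally-selected-statistic approach to threshold detection.

Because the same data choose the threshold and test it, the naive minimum p
is anti-conservative.  :func:`permutation_adjusted_p` estimates the null
distribution of the minimum p by permuting the PRS outcomes against the RFS
labels, which preserves both marginals while breaking their association; the
naive p is still reported (it is what clinical studies print), the adjusted
p is opt-in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .records import PatientRecord, MIN_RFS_MONTHS
from .survival import logrank_test, LogRankResult

__all__ = [
    "CandidateResult",
    "CutpointScan",
    "DEFAULT_GRID",
    "DEFAULT_MIN_PER_ARM",
    "scan_cutoffs",
    "select_optimal",
    "permutation_adjusted_p",
]

#: Candidate thresholds in months.  Recurrences within 3 months are excluded
#: upstream, so the grid starts safely above that floor; the upper end covers
#: the range where late recurrences remain plentiful.
DEFAULT_GRID = tuple(range(6, 49))

#: Minimum recurred patients required in each arm for a candidate to be
#: tested; guards the chi-square approximation of the log-rank statistic.
DEFAULT_MIN_PER_ARM = 10


@dataclass(frozen=True)
class CandidateResult:
    cutoff: float
    n_early: int
    n_late: int
    eligible: bool
    result: Optional[LogRankResult] = None

    @property
    def p_value(self) -> Optional[float]:
        return None if self.result is None else self.result.p_value


@dataclass
class CutpointScan:
    grid: np.ndarray
    candidates: list
    optimal_cutoff: float
    min_p: float
    adjusted_p: Optional[float] = None
    n_recurred: int = 0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "candidate_month": c.cutoff,
                    "n_early": c.n_early,
                    "n_late": c.n_late,
                    "statistic": c.result.statistic if c.result else float("nan"),
                    "p": c.p_value if c.result else float("nan"),
                    "eligible": int(c.eligible),
                }
                for c in self.candidates
            ]
        )


def _extract_arrays(recurred: Sequence[PatientRecord]):
    rfs, prs_t, prs_e = [], [], []
    for rec in recurred:
        if not rec.recurrence:
            raise ValueError(f"patient {rec.patient_id}: not a recurrence")
        if rec.rfs_months is None or rec.prs_months is None or rec.prs_event is None:
            raise ValueError(f"patient {rec.patient_id}: missing RFS/PRS fields")
        if rec.rfs_months < MIN_RFS_MONTHS:
            raise ValueError(
                f"patient {rec.patient_id}: recurrence inside the "
                f"{MIN_RFS_MONTHS}-month exclusion window"
            )
        rfs.append(rec.rfs_months)
        prs_t.append(rec.prs_months)
        prs_e.append(rec.prs_event)
    return (
        np.asarray(rfs, dtype=float),
        np.asarray(prs_t, dtype=float),
        np.asarray(prs_e, dtype=bool),
    )


def scan_cutoffs(
    recurred: Sequence[PatientRecord],
    grid: Sequence[float] = DEFAULT_GRID,
    min_per_arm: int = DEFAULT_MIN_PER_ARM,
) -> CutpointScan:
    """Scan candidate cut-offs and select the minimum-p threshold.

    At each candidate c the recurred patients split into early (RFS ≤ c) and
    late (RFS > c) arms; candidates leaving fewer than ``min_per_arm``
    patients in either arm are flagged ineligible and not tested.  Ties in
    the minimum are broken toward the smallest cut-off.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be nonempty and strictly increasing")
    rfs, prs_t, prs_e = _extract_arrays(recurred)

    candidates = []
    best_p, best_cutoff = np.inf, None
    for c in grid:
        early = rfs <= c
        n_early = int(early.sum())
        n_late = rfs.size - n_early
        if n_early < min_per_arm or n_late < min_per_arm:
            candidates.append(CandidateResult(float(c), n_early, n_late, False))
            continue
        result = logrank_test(
            [(prs_t[early], prs_e[early]), (prs_t[~early], prs_e[~early])]
        )
        candidates.append(CandidateResult(float(c), n_early, n_late, True, result))
        if result.p_value < best_p:
            best_p, best_cutoff = result.p_value, float(c)
    if best_cutoff is None:
        raise ValueError(
            f"no candidate leaves at least {min_per_arm} recurred patients "
            f"in both arms (n_recurred = {rfs.size})"
        )
    return CutpointScan(
        grid=grid,
        candidates=candidates,
        optimal_cutoff=best_cutoff,
        min_p=best_p,
        n_recurred=rfs.size,
    )


def select_optimal(scan: CutpointScan) -> tuple[float, float]:
    """Return (cut-off, p) at the scan's minimum; smallest month wins ties."""
    best = None
    for c in scan.candidates:
        if c.eligible and (best is None or c.p_value < best.p_value):
            best = c
    if best is None:
        raise ValueError("scan has no eligible candidate")
    return best.cutoff, best.p_value


# ---------------------------------------------------------------------------
# Vectorised grid evaluation — used for the permutation null, where the
# two-group log-rank must be recomputed for every candidate of every
# permutation.  Results match `logrank_test` exactly (tested); the public
# scan keeps the readable per-candidate path.
# ---------------------------------------------------------------------------

class _GridLogrank:
    """Precomputed PRS risk-set structure for repeated grid evaluations."""

    def __init__(self, prs_t: np.ndarray, prs_e: np.ndarray, grid: np.ndarray,
                 min_per_arm: int):
        self.grid = grid
        self.min_per_arm = min_per_arm
        self.n = prs_t.size
        event_times = np.unique(prs_t[prs_e])
        if event_times.size == 0:
            raise ValueError("log-rank undefined: no PRS events")
        # K x n indicators: at risk at each event time / event at each time.
        self.at_risk = (prs_t[None, :] >= event_times[:, None]).astype(float)
        self.d_ind = (
            (prs_t[None, :] == event_times[:, None]) & prs_e[None, :]
        ).astype(float)
        self.n_tot = self.at_risk.sum(axis=1)            # (K,)
        self.d_tot = self.d_ind.sum(axis=1)              # (K,)
        ok = self.n_tot > 1
        self.var_scale = np.where(
            ok, self.d_tot * (self.n_tot - self.d_tot) / np.maximum(self.n_tot - 1, 1), 0.0
        )

    def p_values(self, rfs: np.ndarray) -> np.ndarray:
        """Two-group log-rank p per candidate; NaN where an arm is too small."""
        member = (rfs[:, None] <= self.grid[None, :]).astype(float)  # n x C
        n1 = self.at_risk @ member                                   # K x C
        d1 = self.d_ind @ member
        frac = n1 / self.n_tot[:, None]
        u = (d1 - self.d_tot[:, None] * frac).sum(axis=0)
        v = (self.var_scale[:, None] * frac * (1.0 - frac)).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            chi2 = np.where(v > 0, u * u / v, 0.0)
        p = np.where(chi2 > 0, stats.chi2.sf(chi2, 1), 1.0)
        n_early = member.sum(axis=0)
        ineligible = (n_early < self.min_per_arm) | (self.n - n_early < self.min_per_arm)
        return np.where(ineligible, np.nan, p)

    def min_p(self, rfs: np.ndarray) -> float:
        p = self.p_values(rfs)
        if np.all(np.isnan(p)):
            raise ValueError("no eligible candidate on the grid")
        return float(np.nanmin(p))


def permutation_adjusted_p(
    recurred: Sequence[PatientRecord],
    grid: Sequence[float] = DEFAULT_GRID,
    min_per_arm: int = DEFAULT_MIN_PER_ARM,
    n_perm: int = 999,
    seed: Optional[int] = None,
) -> float:
    """Multiplicity-adjusted p for the selected cut-off.

    Permutes the (PRS time, PRS event) pairs against the RFS values ``n_perm``
    times, recomputes the minimum eligible p on each permuted dataset, and
    returns ``(1 + #{permuted min-p ≤ observed min-p}) / (n_perm + 1)`` — the
    standard add-one permutation p, valid under exchangeability of PRS across
    recurred patients.  Deterministic for a fixed ``seed``.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    grid = np.asarray(grid, dtype=float)
    rfs, prs_t, prs_e = _extract_arrays(recurred)
    engine = _GridLogrank(prs_t, prs_e, grid, min_per_arm)
    observed = engine.min_p(rfs)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm_rfs = rng.permutation(rfs)
        if engine.min_p(perm_rfs) <= observed:
            hits += 1
    return (1 + hits) / (n_perm + 1)
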