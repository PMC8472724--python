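"""Identification filters, target-decoy FDR and replicate repeatability.

PSM filtering applies the classic per-charge Xcorr cut (strictly greater
than 1.5/2.0/2.5/3.0 for charges 1-4, charge > 4 reuses the charge-4
threshold), a peptide-probability upper bound and a consensus-score lower
bound. FDR is the simple decoy/target ratio from a reversed-database
search. Repeatability regresses one replicate's spectral counts on
another's.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import PsmRecord, RunList
from .errors import DegenerateRegressionError, UndefinedFdrError, ValidationError

#: Default minimum Xcorr per precursor charge state.
DEFAULT_XCORR_BY_CHARGE: dict[int, float] = {1: 1.5, 2: 2.0, 3: 2.5, 4: 3.0}
DEFAULT_MAX_PROB = 1e-3
DEFAULT_MIN_CONSENSUS = 10.0


@dataclass(frozen=True)
class RepeatabilityResult:
    """OLS fit of one replicate's SpC on another's."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValidationError(f"r_squared out of [0, 1]: {self.r_squared}")
        if self.n_points < 2:
            raise ValidationError("repeatability needs >= 2 points")


def _threshold_for(charge: int, xcorr_by_charge: Mapping[int, float]) -> float:
    if charge in xcorr_by_charge:
        return xcorr_by_charge[charge]
    return xcorr_by_charge[max(xcorr_by_charge)]


def filter_psms(
    psms: Iterable[PsmRecord],
    xcorr_by_charge: Mapping[int, float] | None = None,
    max_prob: float = DEFAULT_MAX_PROB,
    min_consensus: float = DEFAULT_MIN_CONSENSUS,
) -> list[PsmRecord]:
    """Keep PSMs passing all three identification filters.

    A PSM survives iff xcorr > charge threshold (strict), probability
    <= ``max_prob`` and consensus_score > ``min_consensus``.
    """
    thresholds = dict(DEFAULT_XCORR_BY_CHARGE if xcorr_by_charge is None else xcorr_by_charge)
    for charge in (1, 2, 3, 4):
        if charge not in thresholds:
            raise ValidationError(f"xcorr threshold missing for charge {charge}")
    return [
        p
        for p in psms
        if p.xcorr > _threshold_for(p.charge, thresholds)
        and p.probability <= max_prob
        and p.consensus_score > min_consensus
    ]


def compute_fdr(psms: Iterable[PsmRecord]) -> float:
    """Decoy/target ratio; 0 decoys -> 0.0, 0 targets -> error."""
    n_target = n_decoy = 0
    for p in psms:
        if p.is_decoy:
            n_decoy += 1
        else:
            n_target += 1
    if n_target == 0:
        raise UndefinedFdrError("FDR undefined with zero target PSMs")
    return n_decoy / n_target


def _paired_counts(
    run_a: RunList, run_b: RunList, shared_only: bool
) -> tuple[np.ndarray, np.ndarray]:
    if shared_only:
        proteins = sorted(set(run_a.entries) & set(run_b.entries))
    else:
        proteins = sorted(set(run_a.entries) | set(run_b.entries))
    x = np.array([run_a.entries.get(p, 0) for p in proteins], dtype=float)
    y = np.array([run_b.entries.get(p, 0) for p in proteins], dtype=float)
    return x, y


def repeatability(
    run_a: RunList, run_b: RunList, shared_only: bool = True
) -> RepeatabilityResult:
    """OLS of ``run_b`` SpC on ``run_a`` SpC over shared (default) or union proteins.

    ``shared_only=False`` fills zeros for proteins missing from one run.
    """
    x, y = _paired_counts(run_a, run_b, shared_only)
    if x.size < 2:
        raise ValidationError(
            f"repeatability needs >= 2 proteins in the comparison set, got {x.size}"
        )
    if np.ptp(x) == 0:
        raise DegenerateRegressionError(
            f"constant predictor: run {run_a.run_id!r} has no SpC variation"
        )
    fit = stats.linregress(x, y)
    return RepeatabilityResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        n_points=int(x.size),
    )


def replicate_pairs(runs: Sequence[RunList]) -> list[tuple[RunList, RunList]]:
    """All ordered-by-input pairs of runs belonging to the same subject."""
    pairs = []
    for i, a in enumerate(runs):
        for b in runs[i + 1:]:
            if a.subject_id == b.subject_id:
                pairs.append((a, b))
    return pairs


__all__ = [
    "DEFAULT_MAX_PROB",
    "DEFAULT_MIN_CONSENSUS",
    "DEFAULT_XCORR_BY_CHARGE",
    "RepeatabilityResult",
    "compute_fdr",
    "filter_psms",
    "repeatability",
    "replicate_pairs",
]
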