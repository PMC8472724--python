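"""Cohort-level profiling: aSpC, depth normalization, Venn partitioning,
virtual 2D MW/pI maps and subcellular-location summaries."""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import COHORTS, AnnotationTable, ProteinRecord, SpectralCountMatrix
from .errors import ValidationError

#: aSpC cutoff for "average list" membership: a protein belongs to a
#: cohort's average list when its mean SpC rounds to at least one spectrum.
AVERAGE_LIST_MIN_ASPC = 0.5

DEFAULT_MW_BOUNDS = (10.0, 200.0)
DEFAULT_PI_BOUNDS = (4.0, 10.0)


@dataclass
class CohortProfile:
    """Average spectral counts of one cohort over its replicate runs."""

    cohort: str
    aspc: pd.Series  # indexed by protein, zeros included in the mean
    n_runs: int

    @property
    def identified(self) -> set[str]:
        """Proteins seen in at least one of the cohort's runs (aSpC > 0)."""
        return set(self.aspc.index[self.aspc > 0])

    def members(self, membership: str = "any_run") -> set[str]:
        """Cohort protein set under a membership convention.

        ``any_run``: present in >= 1 run (aSpC > 0). ``average_list``:
        mean SpC >= 0.5, i.e. the average list a downstream comparison
        would print with at least one whole spectrum.
        """
        if membership == "any_run":
            return self.identified
        if membership == "average_list":
            return set(self.aspc.index[self.aspc >= AVERAGE_LIST_MIN_ASPC])
        raise ValidationError(f"unknown membership mode {membership!r}")


@dataclass
class VennPartition:
    """Disjoint 7-region partition of three cohort protein sets."""

    cohorts: tuple[str, str, str]
    regions: dict[frozenset[str], set[str]] = field(default_factory=dict)

    @property
    def sizes(self) -> dict[frozenset[str], int]:
        return {k: len(v) for k, v in self.regions.items()}

    def region(self, *cohorts: str) -> set[str]:
        """Proteins belonging to exactly the given cohorts."""
        return self.regions.get(frozenset(cohorts), set())

    @property
    def shared(self) -> set[str]:
        return self.region(*self.cohorts)

    def specific(self, cohort: str) -> set[str]:
        return self.region(cohort)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key, members in sorted(self.regions.items(),
                                   key=lambda kv: (len(kv[0]), sorted(kv[0]))):
            rows.append(("&".join(sorted(key)), len(members)))
        return pd.DataFrame(rows, columns=["region", "n_proteins"])


def cohort_aspc(matrix: SpectralCountMatrix, cohort: str) -> CohortProfile:
    """Mean SpC per protein over the cohort's runs, zeros included."""
    run_ids = matrix.cohort_run_ids(cohort)
    if not run_ids:
        raise ValidationError(f"no runs for cohort {cohort!r}")
    aspc = matrix.counts[run_ids].mean(axis=1)
    return CohortProfile(cohort=cohort, aspc=aspc, n_runs=len(run_ids))


def all_profiles(matrix: SpectralCountMatrix) -> dict[str, CohortProfile]:
    present = [c for c in COHORTS if matrix.cohort_run_ids(c)]
    return {c: cohort_aspc(matrix, c) for c in present}


def normalize_runs(matrix: SpectralCountMatrix, mode: str = "total") -> pd.DataFrame:
    """Depth-normalize runs, returning a real-valued proteins x runs frame.

    ``total`` (default) rescales each column so its total equals the mean
    of the original column totals — global SpC mass is conserved exactly.
    ``nsaf`` computes spectral-abundance factors: SpC / MW share per run
    (requires an ``mw`` series via :func:`nsaf_normalize` instead).
    """
    if mode != "total":
        raise ValidationError(f"unknown normalization mode {mode!r} (use nsaf_normalize for NSAF)")
    totals = matrix.counts.sum(axis=0).astype(float)
    if (totals == 0).any():
        empty = totals.index[totals == 0].tolist()
        raise ValidationError(f"empty run(s): {empty}")
    target = float(totals.mean())
    return matrix.counts.astype(float) * (target / totals)


def nsaf_normalize(matrix: SpectralCountMatrix, mw_kda: pd.Series) -> pd.DataFrame:
    """Normalized spectral-abundance factor per protein and run.

    SpC is divided by protein size (MW in kDa stands in for length) and
    each column rescaled to sum to 1. Proteins without a positive MW raise.
    """
    mw = mw_kda.reindex(matrix.counts.index)
    if mw.isna().any() or (mw <= 0).any():
        missing = mw.index[mw.isna() | (mw <= 0)].tolist()
        raise ValidationError(f"NSAF needs positive MW for every protein; bad: {missing[:5]}")
    saf = matrix.counts.astype(float).div(mw, axis=0)
    totals = saf.sum(axis=0)
    if (totals == 0).any():
        raise ValidationError("empty run in NSAF normalization")
    return saf / totals


def venn_partition(
    profiles: Mapping[str, CohortProfile] | Sequence[CohortProfile],
    membership: str = "any_run",
) -> VennPartition:
    """Partition the union of three cohort protein sets into 7 disjoint regions."""
    if isinstance(profiles, Mapping):
        profs = list(profiles.values())
    else:
        profs = list(profiles)
    if len(profs) != 3:
        raise ValidationError(f"venn_partition needs exactly 3 cohorts, got {len(profs)}")
    names = tuple(p.cohort for p in profs)
    if len(set(names)) != 3:
        raise ValidationError("cohort labels must be distinct")
    sets = {p.cohort: p.members(membership) for p in profs}
    universe = set().union(*sets.values())
    regions: dict[frozenset[str], set[str]] = {}
    for protein in universe:
        key = frozenset(c for c in names if protein in sets[c])
        regions.setdefault(key, set()).add(protein)
    # materialize all 7 regions, empty ones included
    for mask in range(1, 8):
        key = frozenset(names[i] for i in range(3) if mask & (1 << i))
        regions.setdefault(key, set())
    return VennPartition(cohorts=names, regions=regions)


@dataclass
class Virtual2DMap:
    """Tail counts and the (MW, pI) scatter table of a protein collection."""

    table: pd.DataFrame  # columns: accession, mw_kda, pi
    mw_bounds: tuple[float, float]
    pi_bounds: tuple[float, float]
    n_excluded: int

    @property
    def n_mw_low(self) -> int:
        return int((self.table["mw_kda"] < self.mw_bounds[0]).sum())

    @property
    def n_mw_high(self) -> int:
        return int((self.table["mw_kda"] > self.mw_bounds[1]).sum())

    @property
    def n_mw_extreme(self) -> int:
        return self.n_mw_low + self.n_mw_high

    @property
    def n_pi_high(self) -> int:
        return int((self.table["pi"] > self.pi_bounds[1]).sum())

    @property
    def n_pi_low(self) -> int:
        return int((self.table["pi"] < self.pi_bounds[0]).sum())

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def virtual_2d_map(
    records: Iterable[ProteinRecord],
    mw_bounds: tuple[float, float] = DEFAULT_MW_BOUNDS,
    pi_bounds: tuple[float, float] = DEFAULT_PI_BOUNDS,
) -> Virtual2DMap:
    """Build the virtual 2D map table; records missing MW or pI are excluded."""
    rows, excluded = [], 0
    for rec in records:
        if np.isnan(rec.mw_kda) or np.isnan(rec.pi):
            excluded += 1
            continue
        rows.append((rec.accession, rec.mw_kda, rec.pi))
    table = pd.DataFrame(rows, columns=["accession", "mw_kda", "pi"])
    return Virtual2DMap(table, mw_bounds, pi_bounds, excluded)


def location_summary(
    proteins: Iterable[str], ann: AnnotationTable
) -> dict[str, float]:
    """Fraction of proteins per subcellular location, over known locations only."""
    counts: dict[str, int] = {}
    for accession in proteins:
        rec = ann.record(accession)
        loc = rec.location if rec is not None else "unknown"
        if loc == "unknown":
            continue
        counts[loc] = counts.get(loc, 0) + 1
    total = sum(counts.values())
    if total == 0:
        return {}
    return {loc: n / total for loc, n in sorted(counts.items())}


__all__ = [
    "AVERAGE_LIST_MIN_ASPC",
    "CohortProfile",
    "DEFAULT_MW_BOUNDS",
    "DEFAULT_PI_BOUNDS",
    "VennPartition",
    "Virtual2DMap",
    "all_profiles",
    "cohort_aspc",
    "location_summary",
    "normalize_runs",
    "nsaf_normalize",
    "venn_partition",
    "virtual_2d_map",
]
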