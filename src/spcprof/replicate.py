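"""Replication harness: recompute the original study's headline numbers
from its deposited per-run protein lists, when those lists are available.

The harness is deliberately failure tolerant: the supplementary lists are
a separate download, so absent or malformed files mark individual targets
``unavailable`` instead of failing. Observed values are reported next to
the reference values published for the original dataset.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import diff, lda, profiling, qc
from .config import load_dataset
from .core import assemble_matrix
from .errors import SpcprofError

logger = logging.getLogger(__name__)

#: Values reported for the original 19-run dataset, used for side-by-side
#: comparison only — never substituted for computed output.
REFERENCE = {
    "t1": ("distinct_proteins", 3458),
    "t2": ("venn_shared", 1478),
    "t3": ("venn_wt_only", 448),
    "t4": ("dep_union", 192),
    "t5": ("dep_wt_vs_ho", 147),
    "t6": ("dep_he_vs_ho", 28),
    "t7": ("lda_sp_count", 475),
    "t8": ("lda_dep_overlap", 128),
    "t9": ("replicate_r_squared", 0.95),
    "t10": ("ho_average_list", 2560),
}


@dataclass
class ReplicationReport:
    """Observed-vs-reference table over the replication targets."""

    targets: dict[str, dict] = field(default_factory=dict)
    errors: list[str] = field(default_factory=list)

    def mark_unavailable(self, reason: str) -> None:
        for target_id, (name, ref) in REFERENCE.items():
            self.targets[target_id] = {
                "name": name,
                "status": "unavailable",
                "value": None,
                "reference": ref,
                "reason": reason,
            }

    def set(self, target_id: str, value) -> None:
        name, ref = REFERENCE[target_id]
        self.targets[target_id] = {
            "name": name,
            "status": "ok",
            "value": value,
            "reference": ref,
        }

    @property
    def available(self) -> dict[str, dict]:
        return {k: v for k, v in self.targets.items() if v["status"] == "ok"}

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"targets": self.targets, "errors": self.errors}, fh, indent=2)

    def validate_schema(self) -> None:
        for target_id, entry in self.targets.items():
            if target_id not in REFERENCE:
                raise SpcprofError(f"unknown target {target_id}")
            for key in ("name", "status", "value", "reference"):
                if key not in entry:
                    raise SpcprofError(f"{target_id} missing field {key}")


def replicate_study(
    dataset_dir,
    dave_thr: float = 0.4,
    dci_thr: float = 15.0,
    f_thr: float = 3.4,
    p_thr: float = 0.01,
    membership: str = "any_run",
) -> ReplicationReport:
    """Recompute all replication targets from a dataset directory.

    ``p_thr`` defaults to the stricter 0.01 preset used for the published
    selected-protein count; pass 0.05 for the looser methods-section preset.
    """
    report = ReplicationReport()
    root = Path(dataset_dir)
    if not root.is_dir() or not (root / "manifest.tsv").exists():
        report.mark_unavailable(f"no dataset manifest under {root}")
        return report
    try:
        runs, ann = load_dataset(root)
        matrix = assemble_matrix(runs)
    except SpcprofError as exc:
        report.errors.append(str(exc))
        report.mark_unavailable(f"dataset unreadable: {exc}")
        return report

    profiles = profiling.all_profiles(matrix)

    report.set("t1", int(matrix.shape[0]))

    if len(profiles) == 3:
        venn = profiling.venn_partition(profiles, membership=membership)
        report.set("t2", len(venn.shared))
        report.set("t3", len(venn.specific("Wt")))

        reports = diff.compare_all_pairs(profiles, dave_thr=dave_thr, dci_thr=dci_thr)
        by_pair = {frozenset(r.pair): r for r in reports}
        union = diff.dep_union(reports)
        report.set("t4", len(union))
        report.set("t5", by_pair[frozenset(("Wt", "Ho"))].n_dep)
        report.set("t6", by_pair[frozenset(("He", "Ho"))].n_dep)

        try:
            records = lda.select_lda_sps(
                matrix, f_thr=f_thr, p_thr=p_thr, collapse_by_gene=True, ann=ann
            )
            selected = set(lda.selected_proteins(records))
            report.set("t7", len(selected))
            union_genes = union
            if ann is not None:
                union_genes = {ann.gene_of(p) or p for p in union}
            report.set("t8", len(selected & union_genes))
        except SpcprofError as exc:
            report.errors.append(f"lda: {exc}")

        if "Ho" in profiles:
            report.set(
                "t10",
                len(profiles["Ho"].members("average_list")),
            )

    pairs = qc.replicate_pairs(runs)
    tech_pairs = [(a, b) for a, b in pairs if a.replicate_kind == "technical"]
    if tech_pairs:
        r2 = [qc.repeatability(a, b, shared_only=True).r_squared for a, b in tech_pairs]
        report.set("t9", float(sum(r2) / len(r2)))

    # leave any untouched target marked unavailable
    for target_id, (name, ref) in REFERENCE.items():
        if target_id not in report.targets:
            report.targets[target_id] = {
                "name": name,
                "status": "unavailable",
                "value": None,
                "reference": ref,
                "reason": "not computable from the provided dataset",
            }
    return report


__all__ = ["REFERENCE", "ReplicationReport", "replicate_study"]
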