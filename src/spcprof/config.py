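"""Declarative pipeline configuration and dataset-directory loading.

A dataset directory holds one TSV per run plus a ``manifest.tsv`` naming
each run's file, subject, cohort and replicate kind, and optionally an
``annotation.tsv`` / ``terms.tsv`` / ``network.tsv``. The pipeline config
is a flat YAML document; CLI flags override config values.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from .core import AnnotationTable, RunList, read_run_list
from .errors import ConfigError, ParseError

SCHEMA_VERSION = 1

MEMBERSHIP_MODES = ("any_run", "average_list")
COVARIANCE_MODES = ("diagonal_pooled", "shrunk_pooled")
LINKAGES = ("ward", "average")


@dataclass
class PipelineConfig:
    """All knobs of an end-to-end run."""

    dataset_dir: str | None = None
    network_path: str | None = None
    terms_path: str | None = None
    out_dir: str = "spcprof_out"
    dave_thr: float = 0.4
    dci_thr: float = 15.0
    f_thr: float = 3.4
    p_thr: float = 0.05
    alpha: float = 0.001
    membership: str = "any_run"
    covariance_mode: str = "diagonal_pooled"
    linkage: str = "ward"
    collapse_by_gene: bool = True
    min_degree: int = 0
    seed: int = 0
    schema_version: int = SCHEMA_VERSION

    def validate(self) -> None:
        for name in ("dave_thr", "dci_thr", "f_thr", "p_thr", "alpha"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"threshold {name} must be positive")
        if self.membership not in MEMBERSHIP_MODES:
            raise ConfigError(f"membership must be one of {MEMBERSHIP_MODES}")
        if self.covariance_mode not in COVARIANCE_MODES:
            raise ConfigError(f"covariance_mode must be one of {COVARIANCE_MODES}")
        if self.linkage not in LINKAGES:
            raise ConfigError(f"linkage must be one of {LINKAGES}")

    def digest(self) -> str:
        """Stable short hash of the analysis parameters, stamped into outputs.

        Path fields are excluded so the same analysis written elsewhere
        carries the same stamp.
        """
        payload = asdict(self)
        for path_field in ("dataset_dir", "network_path", "terms_path", "out_dir"):
            payload.pop(path_field)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        try:
            with open(path, encoding="utf-8") as fh:
                raw = yaml.safe_load(fh) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise ParseError(f"cannot read config at {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError(f"config at {path} must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def write_dataset(
    out_dir,
    runs: list[RunList],
    ann: AnnotationTable | None = None,
    truth=None,
) -> Path:
    """Write run lists + manifest (+ annotation, truth) into a directory."""
    from .core import write_run_list  # local import avoids cycle in docs builds

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for run in runs:
        fname = f"{run.run_id}.tsv"
        write_run_list(run, out / fname)
        rows.append((run.run_id, run.subject_id, run.cohort, run.replicate_kind, fname))
    pd.DataFrame(
        rows, columns=["run_id", "subject_id", "cohort", "replicate_kind", "path"]
    ).to_csv(out / "manifest.tsv", sep="\t", index=False)
    if ann is not None:
        ann.to_tsv(out / "annotation.tsv")
    if truth is not None:
        truth.to_tsv(out / "truth.tsv")
    return out


def load_dataset(dataset_dir) -> tuple[list[RunList], AnnotationTable | None]:
    """Load all runs (manifest order) and the annotation table if present."""
    root = Path(dataset_dir)
    manifest = root / "manifest.tsv"
    if not manifest.exists():
        raise ConfigError(f"no manifest.tsv in {root}")
    try:
        meta = pd.read_csv(manifest, sep="\t", dtype=str)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"cannot read {manifest}: {exc}") from exc
    for col in ("run_id", "subject_id", "cohort", "replicate_kind", "path"):
        if col not in meta.columns:
            raise ConfigError(f"manifest missing column {col!r}")
    runs = [
        read_run_list(
            root / row.path,
            run_id=row.run_id,
            subject_id=row.subject_id,
            cohort=row.cohort,
            replicate_kind=row.replicate_kind,
        )
        for row in meta.itertuples()
    ]
    ann = None
    if (root / "annotation.tsv").exists():
        term_path = root / "terms.tsv"
        ann = AnnotationTable.from_tsv(
            root / "annotation.tsv",
            term_path if term_path.exists() else None,
        )
    return runs, ann


__all__ = [
    "COVARIANCE_MODES",
    "LINKAGES",
    "MEMBERSHIP_MODES",
    "PipelineConfig",
    "load_dataset",
    "write_dataset",
]
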