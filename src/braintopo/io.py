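"""File formats, manifest handling, run configuration, and provenance.

All tabular artifacts are UTF-8 tab-delimited text with headers; nested
results are JSON.  Group labels in files are neutral ("A"/"B") with a
display mapping, so the pipeline is reusable beyond any one study.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from braintopo.cohort import SubjectRecord as CohortSubject
from braintopo.timeseries import (
    DEFAULT_MAX_ROTATION_DEG,
    DEFAULT_MAX_TRANSLATION_MM,
    MotionParams,
    RoiTimeSeries,
    motion_exclusion,
)

GROUP_DISPLAY = {"A": "PTSD", "B": "HC"}


def write_timeseries_tsv(ts: RoiTimeSeries, path: str | Path) -> None:
    df = pd.DataFrame(ts.data, columns=ts.region_labels)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_timeseries_tsv(path: str | Path, tr_seconds: float = 2.0) -> RoiTimeSeries:
    df = pd.read_csv(path, sep="\t")
    return RoiTimeSeries(
        data=df.to_numpy(dtype=float),
        region_labels=list(df.columns),
        tr_seconds=tr_seconds,
    )


def write_motion_txt(mp: MotionParams, path: str | Path) -> None:
    """SPM rp_*.txt dialect: 6 whitespace-separated columns, no header."""
    np.savetxt(path, mp.data, fmt="%+.10e")


def read_motion_txt(path: str | Path) -> MotionParams:
    data = np.loadtxt(path)
    data = np.atleast_2d(data)
    if data.shape[1] != 6:
        raise ValueError(
            f"motion file {path} has {data.shape[1]} columns, expected 6 "
            "(3 translations mm, 3 rotations deg)"
        )
    return MotionParams(data=data)


@dataclass(frozen=True)
class ManifestRecord:
    """One cohort-manifest row with motion-screening flags."""

    subject_id: str
    group: str
    timeseries_path: Path
    motion_path: Path | None = None
    motion_excluded: bool = False

    @property
    def display_group(self) -> str:
        return GROUP_DISPLAY.get(self.group, self.group)


def write_cohort(
    records: list[CohortSubject], out_dir: str | Path, tr_seconds: float = 2.0
) -> Path:
    """Write per-subject TSV/motion files plus the manifest CSV; returns its path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        ts_path = out_dir / f"{rec.subject_id}_timeseries.tsv"
        mo_path = out_dir / f"{rec.subject_id}_motion.txt"
        write_timeseries_tsv(rec.timeseries, ts_path)
        write_motion_txt(rec.motion, mo_path)
        rows.append(
            {
                "subject_id": rec.subject_id,
                "group": rec.group,
                "timeseries_path": ts_path.name,
                "motion_path": mo_path.name,
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    meta = {"tr_seconds": tr_seconds, "n_subjects": len(records)}
    (out_dir / "cohort.json").write_text(json.dumps(meta, indent=2))
    return manifest


def validate_manifest(
    path: str | Path,
    max_translation_mm: float = DEFAULT_MAX_TRANSLATION_MM,
    max_rotation_deg: float = DEFAULT_MAX_ROTATION_DEG,
) -> list[ManifestRecord]:
    """Parse and validate the cohort manifest.

    Subjects whose motion trace violates the exclusion rule are flagged
    (never silently dropped).  Problems are aggregated into a single
    error message naming every offending row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    df = pd.read_csv(path)
    required = {"subject_id", "group", "timeseries_path"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"manifest missing required columns: {sorted(missing_cols)}")
    problems: list[str] = []
    seen: set[str] = set()
    records: list[ManifestRecord] = []
    for i, row in df.iterrows():
        sid = str(row["subject_id"])
        if sid in seen:
            problems.append(f"row {i}: duplicate subject_id {sid!r}")
            continue
        seen.add(sid)
        group = str(row["group"])
        if group not in ("A", "B"):
            problems.append(f"row {i}: unknown group label {group!r} (expected A/B)")
            continue
        ts_path = path.parent / str(row["timeseries_path"])
        if not ts_path.exists():
            problems.append(f"row {i}: missing time-series file {ts_path}")
            continue
        motion_path = None
        excluded = False
        if "motion_path" in df.columns and pd.notna(row.get("motion_path")):
            motion_path = path.parent / str(row["motion_path"])
            if not motion_path.exists():
                problems.append(f"row {i}: missing motion file {motion_path}")
                continue
            excluded = motion_exclusion(
                read_motion_txt(motion_path), max_translation_mm, max_rotation_deg
            )
        records.append(
            ManifestRecord(
                subject_id=sid,
                group=group,
                timeseries_path=ts_path,
                motion_path=motion_path,
                motion_excluded=excluded,
            )
        )
    if problems:
        raise ValueError("manifest validation failed:\n" + "\n".join(problems))
    return records


@dataclass(frozen=True)
class RunConfig:
    """Declarative defaults for every pipeline stage."""

    # cohort
    n_group_a: int = 33
    n_group_b: int = 53
    n_regions: int = 90
    n_timepoints: int = 200
    tr_seconds: float = 2.0
    effect_regions: tuple[int, ...] = (10, 25, 40, 55, 70)
    effect_size: float = 3.0
    noise_sd: float = 0.0
    motion_severity: float = 0.2
    # preprocessing
    n_discard: int = 10
    low_hz: float = 0.01
    high_hz: float = 0.08
    regress_global_signal: bool = True
    max_translation_mm: float = DEFAULT_MAX_TRANSLATION_MM
    max_rotation_deg: float = DEFAULT_MAX_ROTATION_DEG
    # connectome & topology
    shrinkage: str = "auto"
    s_min: float = 0.05
    s_max: float = 0.40
    s_step: float = 0.01
    null_ensemble_size: int = 100
    # classifier
    sae_hidden_sizes: tuple[int, ...] = (128, 64, 32, 10)
    pretrain_epochs: int = 30
    finetune_epochs: int = 100
    learning_rate: float = 1e-2
    c_grid: tuple[float, ...] = (1e-3, 1e-2, 1e-1, 1.0, 1e1, 1e2, 1e3, 1e4)
    k_outer: int = 10
    k_inner: int = 5
    n_permutations: int = 1000
    # global
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz < 1.0 / (2 * self.tr_seconds):
            raise ValueError("band must satisfy 0 < low < high < Nyquist")
        if not 0 < self.s_min <= self.s_max < 1:
            raise ValueError("sparsity endpoints must satisfy 0 < s_min <= s_max < 1")
        if self.null_ensemble_size < 1:
            raise ValueError("null_ensemble_size must be >= 1")
        if self.k_outer < 2 or self.k_inner < 2:
            raise ValueError("fold counts must be >= 2")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("effect_regions", "sae_hidden_sizes", "c_grid"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class Provenance:
    """Seed, config hash and per-stage notes embedded in every artifact."""

    seed: int
    config_hash: str
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, **info) -> None:
        self.stages[stage] = info

    def to_json(self, path: str | Path) -> None:
        from braintopo import __version__

        doc = {
            "package_version": __version__,
            "seed": self.seed,
            "config_hash": self.config_hash,
            "stages": self.stages,
        }
        Path(path).write_text(json.dumps(doc, indent=2, default=str))


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=2, default=str))
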