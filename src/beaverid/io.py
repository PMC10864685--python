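"""Configuration, manifests, feature-database serialization and the
end-to-end pipeline.

A run is described by a TOML config (feature-extraction, matching,
preprocessing and evaluation sections).  Every artifact written by the
pipeline carries a short digest of the configuration that produced it, and
artifacts from different digests refuse to mix.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import imaging
from .evaluation import (aggregate_report, evaluate_sample,
                         make_sample_blocks, split_dataset)
from .matching import FeatureDatabase, MatchConfig
from .sift import FeatureSet, Keypoint, SIFTConfig, extract_features
from .synthetic import PatternSpec, TransformRanges, make_benchmark

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "load_manifest",
    "save_database",
    "load_database",
    "run_pipeline",
]

MANIFEST_COLUMNS = ("image_path", "individual_id", "group")


@dataclass(frozen=True)
class EvaluationConfig:
    db_fraction: float = 0.7
    seed: int = 42
    per_sample_individuals: int = 25


@dataclass(frozen=True)
class SynthConfig:
    """Optional synthetic-benchmark source for a run."""

    enabled: bool = False
    n_individuals: int = 25
    images_per_individual: int = 8
    global_seed: int = 42
    canvas_width: int = 1330
    canvas_height: int = 889
    transforms_enabled: bool = True


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration (round-trips through TOML losslessly)."""

    sift: SIFTConfig = field(default_factory=SIFTConfig)
    match: MatchConfig = field(default_factory=MatchConfig)
    enhance_preset: str = "none"
    working_width: int = 640
    working_height: int = 480
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    synth: SynthConfig = field(default_factory=SynthConfig)
    manifest_path: str = ""
    out_dir: str = "beaverid_out"

    def __post_init__(self) -> None:
        if self.enhance_preset not in imaging.PRESETS:
            raise ValueError(
                f"unknown enhance preset {self.enhance_preset!r}; "
                f"choose from {sorted(imaging.PRESETS)}")

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_toml(self) -> str:
        return _emit_toml(dataclasses.asdict(self))

    @classmethod
    def from_toml(cls, text: str) -> "RunConfig":
        data = tomllib.loads(text)
        kwargs = dict(data)
        if "sift" in kwargs:
            kwargs["sift"] = SIFTConfig(**kwargs["sift"])
        if "match" in kwargs:
            kwargs["match"] = MatchConfig(**kwargs["match"])
        if "evaluation" in kwargs:
            kwargs["evaluation"] = EvaluationConfig(**kwargs["evaluation"])
        if "synth" in kwargs:
            kwargs["synth"] = SynthConfig(**kwargs["synth"])
        return cls(**kwargs)

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_toml(Path(path).read_text())

    def save(self, path) -> None:
        Path(path).write_text(self.to_toml())


def _emit_toml(data: dict, prefix: str = "") -> str:
    """Minimal TOML emitter for the flat/nested-scalar configs used here."""
    scalars, tables = [], []
    for key, val in data.items():
        if isinstance(val, dict):
            tables.append((key, val))
        else:
            scalars.append((key, val))
    lines = []
    for key, val in scalars:
        if isinstance(val, bool):
            rep = "true" if val else "false"
        elif isinstance(val, (int, float)):
            rep = repr(val)
        elif isinstance(val, str):
            rep = json.dumps(val)
        else:
            raise TypeError(f"cannot emit {key}={val!r} as TOML")
        lines.append(f"{key} = {rep}")
    for key, val in tables:
        name = f"{prefix}{key}"
        lines.append(f"\n[{name}]")
        lines.append(_emit_toml(val, prefix=f"{name}."))
    return "\n".join(lines) + ("\n" if not prefix else "")


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------


def load_manifest(path, check_files: bool = True) -> pd.DataFrame:
    """Load and validate a dataset manifest (CSV with columns image_path,
    individual_id, group).  Adds an ``image_id`` column (file stem).  Missing
    files are reported with their row numbers."""
    df = pd.read_csv(path)
    missing_cols = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"manifest {path} lacks columns: {missing_cols}")
    if df.empty:
        raise ValueError(f"manifest {path} is empty")
    if check_files:
        bad = [(i + 2, p) for i, p in enumerate(df["image_path"])
               if p and not Path(p).is_file()]
        if bad:
            listing = "; ".join(f"row {r}: {p}" for r, p in bad[:10])
            raise FileNotFoundError(f"manifest references missing files: {listing}")
    if "image_id" not in df.columns:
        df = df.assign(image_id=[Path(p).stem for p in df["image_path"]])
    return df


# ---------------------------------------------------------------------------
# Feature database (HDF5)
# ---------------------------------------------------------------------------

KEYPOINT_FIELDS = ("x", "y", "sigma", "orientation", "response",
                   "octave", "level")


def save_database(db: FeatureDatabase, path) -> None:
    """Write a feature database to one HDF5 container."""
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "beaverid-feature-db-v1"
        f.attrs["sift_digest"] = db.sift_digest or ""
        f.attrs["match_digest"] = db.match_digest or ""
        for i, fs in enumerate(db.entries):
            g = f.create_group(f"entry_{i:05d}")
            g.attrs["image_id"] = fs.image_id
            g.attrs["individual_id"] = fs.individual_id or ""
            g.attrs["group"] = fs.group
            g.attrs["config_digest"] = fs.config_digest
            kp = np.array([[k.x, k.y, k.sigma, k.orientation, k.response,
                            k.octave, k.level] for k in fs.keypoints],
                          dtype=np.float64).reshape(len(fs.keypoints), 7)
            g.create_dataset("keypoints", data=kp)
            g.create_dataset("descriptors",
                             data=fs.descriptors.astype(np.float64))


def load_database(path, expected_digest: str | None = None) -> FeatureDatabase:
    """Load a feature database; refuses containers whose extraction-config
    digest does not match ``expected_digest`` (when given)."""
    entries = []
    try:
        with h5py.File(path, "r") as f:
            if f.attrs.get("format") != "beaverid-feature-db-v1":
                raise ValueError(f"{path} is not a feature database")
            sift_digest = str(f.attrs.get("sift_digest", ""))
            if expected_digest and sift_digest and sift_digest != expected_digest:
                raise ValueError(
                    f"config digest mismatch: database {sift_digest!r} vs "
                    f"requested {expected_digest!r}")
            for name in sorted(f.keys()):
                g = f[name]
                kp_arr = np.asarray(g["keypoints"])
                kps = [Keypoint(x=float(r[0]), y=float(r[1]),
                                octave=int(r[5]), level=int(r[6]),
                                sigma=float(r[2]), response=float(r[4]),
                                orientation=float(r[3]))
                       for r in kp_arr]
                entries.append(FeatureSet(
                    image_id=str(g.attrs["image_id"]),
                    individual_id=str(g.attrs["individual_id"]) or None,
                    group=str(g.attrs["group"]),
                    keypoints=kps,
                    descriptors=np.asarray(g["descriptors"]),
                    config_digest=str(g.attrs["config_digest"])))
            mdig = str(f.attrs.get("match_digest", ""))
    except OSError as exc:
        raise ValueError(f"cannot read feature database {path}: {exc}") from exc
    return FeatureDatabase(entries=entries, sift_digest=sift_digest,
                           match_digest=mdig)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline: source images -> preprocessing -> feature
    extraction -> database/test split -> per-sample identification ->
    aggregated accuracy report.

    Stage outputs (working images are kept in memory; features, confusion
    matrices and the report are cached on disk under ``config.out_dir``)
    are reproducible from the config and its seeds alone.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    digest = config.digest()
    preset = imaging.PRESETS[config.enhance_preset]

    # --- source stage -----------------------------------------------------
    if config.synth.enabled:
        sc = config.synth
        ranges = TransformRanges() if sc.transforms_enabled else \
            _identity_ranges()
        ds = make_benchmark(
            n_individuals=sc.n_individuals,
            images_per_individual=sc.images_per_individual,
            global_seed=sc.global_seed,
            pattern_defaults=PatternSpec(
                individual_seed=0,
                canvas=(sc.canvas_width, sc.canvas_height)),
            transform_ranges=ranges)
        manifest = ds.manifest
        get_image = ds.images.__getitem__
    else:
        if not config.manifest_path:
            raise ValueError("config names neither a manifest nor a "
                             "synthetic source")
        manifest = load_manifest(config.manifest_path)
        paths = dict(zip(manifest["image_id"], manifest["image_path"]))

        def get_image(image_id: str) -> np.ndarray:
            return imaging.load_image(paths[image_id])

    # --- preprocessing + extraction ----------------------------------------
    logger.info("extracting features from %d images", len(manifest))
    features: dict[str, FeatureSet] = {}
    for _, row in manifest.iterrows():
        try:
            work = imaging.preprocess(
                get_image(row["image_id"]), roi=None, params=preset,
                target_width=config.working_width,
                target_height=config.working_height)
            features[row["image_id"]] = extract_features(
                work, config.sift, image_id=row["image_id"],
                individual_id=row["individual_id"], group=row["group"])
        except Exception as exc:
            raise RuntimeError(
                f"stage 'extract' failed on {row['image_id']!r}: {exc}"
            ) from exc
        logger.debug("%s: %d keypoints", row["image_id"],
                     len(features[row["image_id"]]))

    db_all = FeatureDatabase(entries=list(features.values()),
                             match_digest=config.match.digest())
    save_database(db_all, out / "features.h5")

    # --- split + per-sample evaluation --------------------------------------
    split = split_dataset(manifest, config.evaluation.db_fraction,
                          config.evaluation.seed)
    samples = []
    for group in sorted(manifest["group"].unique()):
        inds = sorted(
            manifest.loc[manifest["group"] == group, "individual_id"].unique())
        for block in make_sample_blocks(
                inds, group, config.evaluation.per_sample_individuals):
            try:
                cm = evaluate_sample(block, split, features, config.match)
            except Exception as exc:
                raise RuntimeError(
                    f"stage 'evaluate' failed on block {block.sample_id!r}: "
                    f"{exc}") from exc
            cm.to_frame().to_csv(out / f"confusion_{block.sample_id}.csv")
            samples.append((block.sample_id, group, cm))

    report = aggregate_report(samples)
    report["config_digest"] = digest
    report["n_images"] = len(manifest)
    report["n_database"] = len(split.database_items)
    report["n_test"] = len(split.test_items)
    (out / "report.json").write_text(json.dumps(report, indent=2))
    config.save(out / "config.toml")
    return report


def _identity_ranges() -> TransformRanges:
    from .synthetic import IDENTITY_RANGES
    return IDENTITY_RANGES
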