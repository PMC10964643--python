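"""Trace files, dataset manifests, and run configuration.

On-disk contract
----------------
A *trace file* is a UTF-8 CSV holding one recording. Metadata comes first as
``#key=value`` comment lines, then the header ``time_s,potential_mV`` and one
row per sample::

    #sample_id=leaf8_Normal_000
    #leaf=8
    #condition=Normal
    #wound_index=2000
    #sampling_rate_hz=100.0
    time_s,potential_mV
    0.000000,-0.013200
    ...

A *manifest* is a CSV with header ``sample_id,leaf,condition,trace_file``
listing the traces of one dataset (one leaf). Paths are resolved relative to
the manifest's directory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import yaml

from swpkit.errors import ConfigError, DataError, FormatError, SchemaError

CONDITIONS: tuple[str, ...] = ("Normal", "SED", "LED")
LEAVES: tuple[int, ...] = (8, 13)
PROVENANCES: tuple[str, ...] = ("measured", "synthetic", "augmented")

_META_KEYS = ("sample_id", "leaf", "condition", "wound_index", "sampling_rate_hz")


@dataclass(frozen=True)
class RawRecording:
    """A single surface-potential recording at fixed sampling rate.

    Parameters
    ----------
    sample_id : str
        Unique identifier within a dataset.
    leaf : int
        8 (wounded, local response) or 13 (systemic response).
    condition : str
        Light regime label: ``Normal``, ``SED`` or ``LED``.
    values : numpy.ndarray
        Surface potential in mV, ordered in time.
    wound_index : int
        Index of the wounding event within ``values``.
    sampling_rate_hz : float
        Acquisition rate; 100 Hz for the recordings this package targets.
    """

    sample_id: str
    leaf: int
    condition: str
    values: np.ndarray
    wound_index: int
    sampling_rate_hz: float = 100.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if self.leaf not in LEAVES:
            raise SchemaError(f"leaf must be one of {LEAVES}, got {self.leaf!r}")
        if self.condition not in CONDITIONS:
            raise SchemaError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        if values.ndim != 1 or values.size < 2:
            raise DataError("values must be a 1-D sequence of length >= 2")
        if not np.all(np.isfinite(values)):
            raise DataError(f"non-finite potential values in {self.sample_id!r}")
        if not (0 <= int(self.wound_index) < values.size):
            raise DataError(
                f"wound_index {self.wound_index} out of range for "
                f"{values.size} samples"
            )
        if not self.sampling_rate_hz > 0:
            raise DataError("sampling_rate_hz must be positive")

    @property
    def n_samples(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class ManifestRecord:
    sample_id: str
    leaf: int
    condition: str
    trace_file: str


@dataclass(frozen=True)
class DatasetManifest:
    """Index of trace files making up one dataset."""

    records: tuple[ManifestRecord, ...]
    provenance: str = "measured"

    def __post_init__(self) -> None:
        if self.provenance not in PROVENANCES:
            raise SchemaError(
                f"provenance must be one of {PROVENANCES}, got {self.provenance!r}"
            )
        ids = [r.sample_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SchemaError(f"duplicate sample_ids in manifest: {dupes}")
        for r in self.records:
            if r.condition not in CONDITIONS:
                raise SchemaError(
                    f"manifest row {r.sample_id!r}: condition {r.condition!r} "
                    f"not in {CONDITIONS}"
                )

    def __len__(self) -> int:
        return len(self.records)


def write_trace(rec: RawRecording, path: str | Path) -> Path:
    """Write a recording to a self-describing trace CSV. Returns the path."""
    path = Path(path)
    t = np.arange(rec.n_samples) / rec.sampling_rate_hz
    lines = [
        f"#sample_id={rec.sample_id}",
        f"#leaf={rec.leaf}",
        f"#condition={rec.condition}",
        f"#wound_index={rec.wound_index}",
        f"#sampling_rate_hz={rec.sampling_rate_hz!r}",
        "time_s,potential_mV",
    ]
    lines.extend(f"{ti:.6f},{vi:.6f}" for ti, vi in zip(t, rec.values))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_trace(path: str | Path) -> RawRecording:
    """Read a trace CSV written by :func:`write_trace`.

    The time column is used only to validate that the grid is uniform at
    ``1/sampling_rate_hz`` (relative tolerance 1e-6).
    """
    path = Path(path)
    meta: dict[str, str] = {}
    times: list[float] = []
    pots: list[float] = []
    with path.open(encoding="utf-8") as fh:
        header_seen = False
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "=" not in line:
                    raise SchemaError(f"{path}: malformed metadata line {line!r}")
                key, _, value = line[1:].partition("=")
                meta[key.strip()] = value.strip()
                continue
            if not header_seen:
                if line != "time_s,potential_mV":
                    raise SchemaError(
                        f"{path}: expected header 'time_s,potential_mV', got {line!r}"
                    )
                header_seen = True
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise FormatError(f"{path}: bad data row {line!r}")
            times.append(float(parts[0]))
            pots.append(float(parts[1]))
    missing = [k for k in _META_KEYS if k not in meta]
    if missing:
        raise SchemaError(f"{path}: missing metadata keys {missing}")
    values = np.asarray(pots, dtype=float)
    if np.any(np.isnan(values)):
        raise DataError(f"{path}: NaN in potential_mV")
    rate = float(meta["sampling_rate_hz"])
    if rate <= 0:
        raise SchemaError(f"{path}: sampling_rate_hz must be positive")
    if len(times) >= 2:
        expected = np.arange(len(times)) / rate
        if not np.allclose(times, expected, rtol=1e-6, atol=1e-6 / rate):
            raise FormatError(f"{path}: time grid not uniform at 1/{rate} s spacing")
    try:
        leaf = int(meta["leaf"])
    except ValueError as exc:
        raise SchemaError(f"{path}: leaf must be an integer") from exc
    return RawRecording(
        sample_id=meta["sample_id"],
        leaf=leaf,
        condition=meta["condition"],
        values=values,
        wound_index=int(meta["wound_index"]),
        sampling_rate_hz=rate,
    )


def write_manifest(
    manifest: DatasetManifest, path: str | Path
) -> Path:
    """Write a manifest CSV; trace paths are stored as given."""
    path = Path(path)
    lines = ["sample_id,leaf,condition,trace_file"]
    lines += [
        f"{r.sample_id},{r.leaf},{r.condition},{r.trace_file}"
        for r in manifest.records
    ]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_manifest(path: str | Path, provenance: str = "measured") -> DatasetManifest:
    path = Path(path)
    lines = [ln for ln in path.read_text(encoding="utf-8").splitlines() if ln.strip()]
    if not lines or lines[0] != "sample_id,leaf,condition,trace_file":
        raise SchemaError(
            f"{path}: expected header 'sample_id,leaf,condition,trace_file'"
        )
    records = []
    for ln in lines[1:]:
        parts = ln.split(",")
        if len(parts) != 4:
            raise SchemaError(f"{path}: bad manifest row {ln!r}")
        sample_id, leaf_s, condition, trace_file = (p.strip() for p in parts)
        try:
            leaf = int(leaf_s)
        except ValueError as exc:
            raise SchemaError(f"{path}: leaf must be an integer in row {ln!r}") from exc
        records.append(ManifestRecord(sample_id, leaf, condition, trace_file))
    return DatasetManifest(records=tuple(records), provenance=provenance)


def load_dataset(
    manifest_path: str | Path, provenance: str = "measured"
) -> tuple[list[RawRecording], DatasetManifest]:
    """Load every recording listed in a manifest, order preserved.

    Raises
    ------
    SchemaError
        On manifest schema violations (duplicate ids, bad enums).
    DataError
        Aggregated if any member trace fails to load; the message names the
        offending rows.
    """
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path, provenance=provenance)
    base = manifest_path.parent
    recordings: list[RawRecording] = []
    failures: list[str] = []
    for row_no, rec in enumerate(manifest.records, start=1):
        trace_path = Path(rec.trace_file)
        if not trace_path.is_absolute():
            trace_path = base / trace_path
        try:
            recordings.append(read_trace(trace_path))
        except Exception as exc:  # aggregate, naming the row
            failures.append(f"row {row_no} ({rec.sample_id}): {exc}")
    if failures:
        raise DataError(
            f"{manifest_path}: {len(failures)} trace(s) failed to load: "
            + "; ".join(failures)
        )
    return recordings, manifest


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_DEFAULT_CONFIG: dict = {
    "preprocess": {"window": 100, "target_length": 411, "zero_fill": True},
    "feature": {"kind": "deriv_1st"},
    "augment": {
        "method": "aae",
        "n_per_group": 50,
        "epochs": 200,
        "recon_lr": 1e-4,
        "gen_lr": 5e-4,
        "dropout": 0.2,
        "seed": 10,
    },
    "classify": {"kind": "random_forest", "params": {}},
    "protocol": {"kind": "loocv", "folds": 5, "train_only_augmentation": True},
    "seed": 10,
}


@dataclass
class RunConfig:
    """Validated run configuration with printed-constant defaults.

    Unknown keys at either nesting level are rejected so that typos never
    silently fall back to defaults.
    """

    preprocess: dict = field(default_factory=lambda: dict(_DEFAULT_CONFIG["preprocess"]))
    feature: dict = field(default_factory=lambda: dict(_DEFAULT_CONFIG["feature"]))
    augment: dict = field(default_factory=lambda: dict(_DEFAULT_CONFIG["augment"]))
    classify: dict = field(default_factory=lambda: dict(_DEFAULT_CONFIG["classify"]))
    protocol: dict = field(default_factory=lambda: dict(_DEFAULT_CONFIG["protocol"]))
    seed: int = 10

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        unknown = set(data) - set(_DEFAULT_CONFIG)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        merged = {}
        for key, default in _DEFAULT_CONFIG.items():
            if key == "seed":
                continue
            section = dict(default)
            user = data.get(key, {})
            if not isinstance(user, dict):
                raise ConfigError(f"config section {key!r} must be a mapping")
            bad = set(user) - set(default)
            if bad:
                raise ConfigError(f"unknown keys in config section {key!r}: {sorted(bad)}")
            section.update(user)
            merged[key] = section
        return cls(seed=int(data.get("seed", _DEFAULT_CONFIG["seed"])), **merged)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: top-level config must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return {
            "preprocess": dict(self.preprocess),
            "feature": dict(self.feature),
            "augment": dict(self.augment),
            "classify": dict(self.classify),
            "protocol": dict(self.protocol),
            "seed": self.seed,
        }


def group_key(rec) -> tuple[int, str]:
    """(leaf, condition) — the unit at which templates and augmenters operate."""
    return (rec.leaf, rec.condition)


def is_augmented_id(sample_id: str) -> bool:
    """Augmented samples carry an ``aug_`` prefix so splits can exclude them."""
    return sample_id.startswith("aug_")
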