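"""Readers and writers for every external artifact.

Time-series matrices travel as TSV (one row per ROI) with a JSON sidecar
holding ``subject_id``, ``roi_labels`` and ``sample_rate_hz``, or — for
large runs — as a single HDF5 container with the same fields.  Atlas/RSN
definitions are JSON, cognitive scores and control norms are CSV, and
result tables leave as TSV next to a JSON run manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

DEFAULT_ATLAS_RESOURCE = "aal78_cortical.json"

#: float format that round-trips IEEE doubles exactly through text
_FLOAT_FMT = "%.17g"


@dataclass(frozen=True)
class RoiTimeSeries:
    """A (ROI x sample) signal matrix with its labels and sample rate."""

    subject_id: str
    roi_labels: tuple[str, ...]
    data: np.ndarray
    sample_rate_hz: float

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "roi_labels", tuple(self.roi_labels))
        if data.ndim != 2:
            raise ValidationError(f"data must be 2-D (ROI x sample), got ndim={data.ndim}")
        n, t = data.shape
        if n < 2:
            raise ValidationError(f"need at least 2 ROIs, got {n}")
        if t < 1:
            raise ValidationError("need at least 1 sample")
        if len(self.roi_labels) != n:
            raise ValidationError(
                f"{len(self.roi_labels)} labels for {n} data rows"
            )
        if len(set(self.roi_labels)) != n:
            raise ValidationError("roi_labels must be unique")
        if not self.sample_rate_hz > 0:
            raise ValidationError(f"sample_rate_hz must be > 0, got {self.sample_rate_hz}")
        if not np.isfinite(data).all():
            raise ValidationError("time series contains non-finite values")

    @property
    def n_rois(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class AtlasDefinition:
    """Ordered ROI labels plus named resting-state-network memberships."""

    roi_labels: tuple[str, ...]
    rsn_memberships: dict[str, tuple[str, ...]]
    name: str = "atlas"

    def __post_init__(self) -> None:
        object.__setattr__(self, "roi_labels", tuple(self.roi_labels))
        if len(set(self.roi_labels)) != len(self.roi_labels):
            raise ValidationError("atlas roi_labels must be unique")
        memberships = {
            rsn: tuple(members) for rsn, members in self.rsn_memberships.items()
        }
        object.__setattr__(self, "rsn_memberships", memberships)
        known = set(self.roi_labels)
        for rsn, members in memberships.items():
            missing = [m for m in members if m not in known]
            if missing:
                raise ValidationError(
                    f"RSN {rsn!r} members not in roi_labels: {missing}"
                )
            if len(set(members)) != len(members):
                raise ValidationError(f"RSN {rsn!r} has duplicate members")

    @property
    def n_rois(self) -> int:
        return len(self.roi_labels)

    def rsn_indices(self, rsn: str) -> np.ndarray:
        """Row indices of the member ROIs of ``rsn``, in label order."""
        if rsn not in self.rsn_memberships:
            raise ValidationError(f"unknown RSN {rsn!r}")
        pos = {label: i for i, label in enumerate(self.roi_labels)}
        return np.array([pos[m] for m in self.rsn_memberships[rsn]], dtype=int)


@dataclass(frozen=True)
class CognitiveTable:
    """Long-form raw scores plus matched-control norms per test.

    ``scores`` columns: subject_id, group, test, raw_score.
    ``norms`` columns: test, control_mean, control_sd.
    """

    scores: pd.DataFrame
    norms: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"subject_id", "group", "test", "raw_score"}
        if not need.issubset(self.scores.columns):
            raise FormatError(f"scores table needs columns {sorted(need)}")
        need = {"test", "control_mean", "control_sd"}
        if not need.issubset(self.norms.columns):
            raise FormatError(f"norms table needs columns {sorted(need)}")
        if not set(self.scores["group"]).issubset({"patient", "control"}):
            raise ValidationError("group must be 'patient' or 'control'")
        if (self.norms["control_sd"] <= 0).any():
            raise ValidationError("control_sd must be > 0 for every test")
        tested = set(self.scores["test"])
        normed = set(self.norms["test"])
        if not tested.issubset(normed):
            raise ValidationError(
                f"tests without control norms: {sorted(tested - normed)}"
            )

    def norm_for(self, test: str) -> tuple[float, float]:
        row = self.norms[self.norms["test"] == test]
        if row.empty:
            raise ValidationError(f"no control norm for test {test!r}")
        return float(row["control_mean"].iloc[0]), float(row["control_sd"].iloc[0])


# ---------------------------------------------------------------------------
# time series


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_timeseries(ts: RoiTimeSeries, path: str | Path, header_path: str | Path | None = None) -> None:
    """Write a :class:`RoiTimeSeries` as TSV+JSON sidecar, or HDF5 for ``.h5``."""
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        import h5py

        with h5py.File(path, "w") as fh:
            dset = fh.create_dataset("data", data=ts.data)
            dset.attrs["subject_id"] = ts.subject_id
            dset.attrs["sample_rate_hz"] = ts.sample_rate_hz
            fh.create_dataset(
                "roi_labels", data=np.array(ts.roi_labels, dtype=object),
                dtype=h5py.string_dtype(),
            )
        return
    np.savetxt(path, ts.data, fmt=_FLOAT_FMT, delimiter="\t")
    header = {
        "subject_id": ts.subject_id,
        "roi_labels": list(ts.roi_labels),
        "sample_rate_hz": ts.sample_rate_hz,
    }
    hp = Path(header_path) if header_path is not None else _sidecar_path(path)
    hp.write_text(json.dumps(header, indent=1) + "\n")


def read_timeseries(path: str | Path, header_path: str | Path | None = None) -> RoiTimeSeries:
    """Read a time-series matrix (TSV+JSON sidecar, or HDF5 by extension)."""
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        import h5py

        with h5py.File(path, "r") as fh:
            data = fh["data"][()]
            labels = [s.decode() if isinstance(s, bytes) else str(s) for s in fh["roi_labels"][()]]
            subject_id = str(fh["data"].attrs["subject_id"])
            fs = float(fh["data"].attrs["sample_rate_hz"])
        return RoiTimeSeries(subject_id, tuple(labels), data, fs)

    hp = Path(header_path) if header_path is not None else _sidecar_path(path)
    try:
        header = json.loads(hp.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"header {hp} is not valid JSON: {exc}") from exc
    for key in ("subject_id", "roi_labels", "sample_rate_hz"):
        if key not in header:
            raise FormatError(f"header {hp} missing key {key!r}")
    try:
        data = np.loadtxt(path, delimiter="\t", ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{path} does not parse as a numeric matrix: {exc}") from exc
    labels = header["roi_labels"]
    if data.shape[0] != len(labels):
        raise FormatError(
            f"{path}: {data.shape[0]} rows but header lists {len(labels)} labels"
        )
    return RoiTimeSeries(
        subject_id=str(header["subject_id"]),
        roi_labels=tuple(labels),
        data=data,
        sample_rate_hz=float(header["sample_rate_hz"]),
    )


# ---------------------------------------------------------------------------
# atlas


def read_atlas(path: str | Path) -> AtlasDefinition:
    """Read an atlas/RSN definition from JSON."""
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path} is not valid JSON: {exc}") from exc
    for key in ("roi_labels", "rsn_memberships"):
        if key not in raw:
            raise FormatError(f"atlas {path} missing key {key!r}")
    return AtlasDefinition(
        roi_labels=tuple(raw["roi_labels"]),
        rsn_memberships={k: tuple(v) for k, v in raw["rsn_memberships"].items()},
        name=raw.get("name", path.stem),
    )


def write_atlas(atlas: AtlasDefinition, path: str | Path) -> None:
    payload = {
        "name": atlas.name,
        "roi_labels": list(atlas.roi_labels),
        "rsn_memberships": {k: list(v) for k, v in atlas.rsn_memberships.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def default_atlas() -> AtlasDefinition:
    """The packaged 78-ROI cortical AAL atlas with DMN / FPN_left / FPN_right."""
    ref = resources.files("mnc.data").joinpath(DEFAULT_ATLAS_RESOURCE)
    raw = json.loads(ref.read_text())
    return AtlasDefinition(
        roi_labels=tuple(raw["roi_labels"]),
        rsn_memberships={k: tuple(v) for k, v in raw["rsn_memberships"].items()},
        name=raw["name"],
    )


# ---------------------------------------------------------------------------
# cognition


def read_cognition(scores_path: str | Path, norms_path: str | Path) -> CognitiveTable:
    scores = pd.read_csv(scores_path)
    norms = pd.read_csv(norms_path)
    return CognitiveTable(scores=scores, norms=norms)


def write_cognition(table: CognitiveTable, scores_path: str | Path, norms_path: str | Path) -> None:
    table.scores.to_csv(scores_path, index=False)
    table.norms.to_csv(norms_path, index=False)


# ---------------------------------------------------------------------------
# result tables


def write_report(tables: dict[str, pd.DataFrame], path: str | Path, manifest: dict | None = None) -> None:
    """Write each result table as ``<name>.tsv`` plus a JSON run manifest.

    Floats are formatted with a fixed precision so reruns with identical
    inputs produce byte-identical files.
    """
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, table in tables.items():
        table.to_csv(outdir / f"{name}.tsv", sep="\t", index=False, float_format="%.10g")
    payload = dict(manifest or {})
    payload.setdefault("tables", sorted(tables))
    (outdir / "manifest.json").write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
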