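"""Reading EHG records, record groups, and feature-table persistence.

Records follow the PhysioNet WFDB layout used by the term-preterm EHG
datasets: a plain-text ``<record>.hea`` header naming the signal file,
storage format, gain and channel descriptions, plus a binary ``.dat`` file
with interleaved 16-bit little-endian samples.  Only the subset of the WFDB
header grammar that those datasets use is supported (single segment, one
``.dat`` file, format 16).  Record-level metadata (gestational ages,
delivery mode, recording epoch) is carried in ``#``-comment lines of the
header, mirroring how the source datasets embed clinical information.

Group construction: later-recorded premature records form group ``PL``
regardless of delivery mode; later-recorded term records split by delivery
mode into ``TL`` (spontaneous), ``IL`` (induced), ``CL`` (cesarean) and
``ICL`` (induced-cesarean).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError, UnsupportedRecordError

PREMATURE_WEEKS = 37.0  # delivery before 37 completed weeks is premature
CHANNEL_NAMES = ("S1", "S2", "S3")
#: fallback "later" recording-epoch threshold (weeks at recording) when the
#: dataset does not label the epoch itself
DEFAULT_LATER_THRESHOLD = 26.0


class DeliveryMode(str, Enum):
    SPONTANEOUS = "spontaneous"
    INDUCED = "induced"
    CESAREAN = "cesarean"
    INDUCED_CESAREAN = "induced_cesarean"


class Dataset(str, Enum):
    TPEHG_DB = "TPEHG_DB"
    TPEHGT_DS = "TPEHGT_DS"
    ICEHG_DS = "ICEHG_DS"
    SYNTHETIC = "SYNTHETIC"


class GroupLabel(str, Enum):
    PL = "PL"  # premature later
    TL = "TL"  # term later, spontaneous
    IL = "IL"  # term later, induced
    CL = "CL"  # term later, cesarean
    ICL = "ICL"  # term later, induced-cesarean


TERM_GROUP_BY_MODE = {
    DeliveryMode.SPONTANEOUS: GroupLabel.TL,
    DeliveryMode.INDUCED: GroupLabel.IL,
    DeliveryMode.CESAREAN: GroupLabel.CL,
    DeliveryMode.INDUCED_CESAREAN: GroupLabel.ICL,
}


@dataclass(frozen=True)
class RecordMetadata:
    gestation_at_recording: float  # weeks
    gestation_at_delivery: float  # weeks
    delivery_mode: DeliveryMode
    dataset: Dataset
    epoch: str | None = None  # "early"/"later" when the dataset labels it

    def __post_init__(self) -> None:
        if self.gestation_at_delivery < self.gestation_at_recording:
            raise IntegrityError(
                "gestation at delivery precedes gestation at recording "
                f"({self.gestation_at_delivery} < {self.gestation_at_recording})"
            )

    @property
    def premature(self) -> bool:
        return self.gestation_at_delivery < PREMATURE_WEEKS


@dataclass
class EHGRecord:
    """One subject's 3-channel EHG signal block plus metadata."""

    record_id: str
    signals: dict[str, np.ndarray]  # S1/S2/S3 -> voltage samples
    fs: float
    meta: RecordMetadata

    #: hard floor on analyzable length: twice the zero-phase filter trim
    #: (2 x 15 s) plus a short entropy window
    MIN_SAMPLES_FACTOR_S = 40.0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise IntegrityError(f"{self.record_id}: fs must be positive, got {self.fs}")
        lengths = {name: len(x) for name, x in self.signals.items()}
        if set(lengths) != set(CHANNEL_NAMES):
            raise UnsupportedRecordError(
                f"{self.record_id}: expected channels {CHANNEL_NAMES}, got {sorted(lengths)}"
            )
        if len(set(lengths.values())) != 1:
            raise IntegrityError(f"{self.record_id}: channel lengths differ: {lengths}")
        if self.n_samples < self.MIN_SAMPLES_FACTOR_S * self.fs:
            raise IntegrityError(
                f"{self.record_id}: only {self.n_samples} samples; "
                f"need at least {self.MIN_SAMPLES_FACTOR_S} s of signal"
            )

    @property
    def n_samples(self) -> int:
        return len(self.signals["S1"])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


def assign_group(meta: RecordMetadata) -> GroupLabel:
    """Map record metadata to its study group (total on valid metadata)."""
    if meta.premature:
        return GroupLabel.PL
    return TERM_GROUP_BY_MODE[DeliveryMode(meta.delivery_mode)]


@dataclass
class RecordCollection:
    records: list[EHGRecord]
    groups: dict[str, GroupLabel] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.record_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise IntegrityError("duplicate record ids in collection")
        for rec in self.records:
            self.groups.setdefault(rec.record_id, assign_group(rec.meta))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def group_counts(self) -> dict[GroupLabel, int]:
        counts = {g: 0 for g in GroupLabel}
        for g in self.groups.values():
            counts[g] += 1
        return counts

    def labels(self) -> dict[str, int]:
        """record_id -> 1 (premature) / 0 (term)."""
        return {r.record_id: int(r.meta.premature) for r in self.records}


# ---------------------------------------------------------------------------
# WFDB-style header / signal IO (format 16 subset)
# ---------------------------------------------------------------------------

_META_KEYS = {
    "gestation_at_recording": float,
    "gestation_at_delivery": float,
    "delivery_mode": str,
    "dataset": str,
    "epoch": str,
}


def _parse_header(path: Path):
    try:
        lines = [
            ln.strip()
            for ln in path.read_text().splitlines()
            if ln.strip()
        ]
    except OSError as exc:
        raise FormatError(f"cannot read header {path}: {exc}") from exc
    body = [ln for ln in lines if not ln.startswith("#")]
    comments = [ln[1:].strip() for ln in lines if ln.startswith("#")]
    if not body:
        raise FormatError(f"{path}: empty header")
    rec_fields = body[0].split()
    if len(rec_fields) < 4:
        raise FormatError(f"{path}: malformed record line {body[0]!r}")
    name = rec_fields[0].split("/")[0]
    try:
        n_sig = int(rec_fields[1])
        fs = float(rec_fields[2].split("/")[0])
        n_samples = int(rec_fields[3])
    except ValueError as exc:
        raise FormatError(f"{path}: malformed record line {body[0]!r}") from exc
    sig_lines = body[1 : 1 + n_sig]
    if len(sig_lines) < n_sig:
        raise FormatError(f"{path}: header declares {n_sig} signals, found {len(sig_lines)}")
    signals = []
    for ln in sig_lines:
        f = ln.split()
        if len(f) < 2:
            raise FormatError(f"{path}: malformed signal line {ln!r}")
        fname, fmt = f[0], f[1]
        gain = 200.0  # WFDB default ADC gain
        if len(f) >= 3:
            gain_tok = f[2].split("(")[0].split("/")[0]
            try:
                gain = float(gain_tok)
            except ValueError:
                raise FormatError(f"{path}: bad gain token {f[2]!r}") from None
            if gain == 0:
                gain = 200.0
        desc = f[-1] if len(f) > 8 else None
        signals.append({"file": fname, "fmt": fmt, "gain": gain, "desc": desc})
    meta_raw: dict[str, object] = {}
    for c in comments:
        parts = c.split(None, 1)
        if len(parts) == 2 and parts[0] in _META_KEYS:
            meta_raw[parts[0]] = _META_KEYS[parts[0]](parts[1].strip())
    return name, n_sig, fs, n_samples, signals, meta_raw


def read_ehg_record(path: str | Path) -> EHGRecord:
    """Read a WFDB-style record (``.hea`` + format-16 ``.dat``) from disk."""
    path = Path(path)
    if path.suffix != ".hea":
        path = path.with_suffix(".hea")
    if not path.exists():
        raise FormatError(f"header not found: {path}")
    name, n_sig, fs, n_samples, sig_info, meta_raw = _parse_header(path)
    if n_sig < 3:
        raise UnsupportedRecordError(
            f"{name}: {n_sig} channels declared, need at least 3"
        )
    fmts = {s["fmt"] for s in sig_info}
    if fmts != {"16"}:
        raise FormatError(f"{name}: unsupported signal format(s) {sorted(fmts)}")
    dat_files = {s["file"] for s in sig_info}
    if len(dat_files) != 1:
        raise FormatError(f"{name}: multi-file records are not supported")
    dat_path = path.parent / sig_info[0]["file"]
    if not dat_path.exists():
        raise FormatError(f"signal file not found: {dat_path}")
    raw = np.fromfile(dat_path, dtype="<i2")
    if raw.size < n_samples * n_sig:
        raise FormatError(
            f"{name}: signal file truncated "
            f"({raw.size} values, expected {n_samples * n_sig})"
        )
    digital = raw[: n_samples * n_sig].reshape(n_samples, n_sig)

    # map channels to S1/S2/S3 by description when present, else by order
    descs = [s["desc"] for s in sig_info]
    idx_by_name: dict[str, int] = {}
    for want in CHANNEL_NAMES:
        matches = [i for i, d in enumerate(descs) if d == want]
        if matches:
            idx_by_name[want] = matches[0]
    if len(idx_by_name) != 3:
        idx_by_name = {want: i for i, want in enumerate(CHANNEL_NAMES)}

    signals = {
        want: digital[:, i].astype(np.float64) / sig_info[i]["gain"]
        for want, i in idx_by_name.items()
    }

    defaults = {
        "gestation_at_recording": 31.0,
        "gestation_at_delivery": 40.0,
        "delivery_mode": DeliveryMode.SPONTANEOUS.value,
        "dataset": Dataset.SYNTHETIC.value,
        "epoch": None,
    }
    defaults.update(meta_raw)
    meta = RecordMetadata(
        gestation_at_recording=float(defaults["gestation_at_recording"]),
        gestation_at_delivery=float(defaults["gestation_at_delivery"]),
        delivery_mode=DeliveryMode(defaults["delivery_mode"]),
        dataset=Dataset(defaults["dataset"]),
        epoch=defaults["epoch"],
    )
    return EHGRecord(record_id=name, signals=signals, fs=fs, meta=meta)


def write_ehg_record(rec: EHGRecord, directory: str | Path, gain: float = 1000.0) -> Path:
    """Write a record as a WFDB-style ``.hea``/``.dat`` pair; returns header path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n = rec.n_samples
    digital = np.empty((n, 3), dtype="<i2")
    for j, name in enumerate(CHANNEL_NAMES):
        q = np.round(rec.signals[name] * gain)
        if np.any(np.abs(q) > 32767):
            raise IntegrityError(
                f"{rec.record_id}: samples overflow int16 at gain {gain}"
            )
        digital[:, j] = q.astype("<i2")
    dat_name = f"{rec.record_id}.dat"
    digital.tofile(directory / dat_name)
    hdr = io.StringIO()
    hdr.write(f"{rec.record_id} 3 {rec.fs:g} {n}\n")
    for j, name in enumerate(CHANNEL_NAMES):
        first = int(digital[0, j])
        chks = int(np.sum(digital[:, j], dtype=np.int64) % 65536)
        hdr.write(f"{dat_name} 16 {gain:g}(0)/mV 16 0 {first} {chks} 0 {name}\n")
    m = rec.meta
    hdr.write(f"# gestation_at_recording {m.gestation_at_recording:g}\n")
    hdr.write(f"# gestation_at_delivery {m.gestation_at_delivery:g}\n")
    hdr.write(f"# delivery_mode {m.delivery_mode.value}\n")
    hdr.write(f"# dataset {m.dataset.value}\n")
    if m.epoch is not None:
        hdr.write(f"# epoch {m.epoch}\n")
    hea_path = directory / f"{rec.record_id}.hea"
    hea_path.write_text(hdr.getvalue())
    return hea_path


def load_dataset(
    paths: Sequence[str | Path],
    later_threshold: float = DEFAULT_LATER_THRESHOLD,
) -> RecordCollection:
    """Load records from directories / header paths, keeping later records only.

    A record is "later" when the dataset labels it so (``epoch`` metadata),
    falling back to ``gestation_at_recording >= later_threshold`` when no
    epoch label is present.
    """
    header_paths: list[Path] = []
    for p in paths:
        p = Path(p)
        if p.is_dir():
            header_paths.extend(sorted(p.rglob("*.hea")))
        else:
            header_paths.append(p)
    records = []
    for hp in header_paths:
        rec = read_ehg_record(hp)
        if rec.meta.epoch is not None:
            keep = rec.meta.epoch == "later"
        else:
            keep = rec.meta.gestation_at_recording >= later_threshold
        if keep:
            records.append(rec)
    if not records:
        warnings.warn("load_dataset: no later records found", stacklevel=2)
    return RecordCollection(records=records)


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------


@dataclass
class FeatureTable:
    """records x features matrix with class labels and group provenance.

    ``values`` is indexed by record id; ``labels`` holds 1 for premature and
    0 for term; ``groups`` (optional) the group label string per record.
    """

    values: pd.DataFrame
    labels: pd.Series
    groups: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise IntegrityError("duplicate record ids in feature table")
        self.labels = self.labels.reindex(self.values.index)
        if self.labels.isna().any():
            raise IntegrityError("missing label for some records")
        self.labels = self.labels.astype(int)
        if self.groups is not None:
            self.groups = self.groups.reindex(self.values.index)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def record_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def y(self) -> np.ndarray:
        return self.labels.to_numpy()

    def class_counts(self) -> dict[int, int]:
        vc = self.labels.value_counts()
        return {int(k): int(v) for k, v in vc.items()}

    def canonical(self) -> "FeatureTable":
        """Rows sorted by record id; makes seeded operations order-stable."""
        order = sorted(self.values.index)
        return FeatureTable(
            self.values.loc[order],
            self.labels.loc[order],
            None if self.groups is None else self.groups.loc[order],
        )

    def subset(self, ids: Iterable[str]) -> "FeatureTable":
        ids = list(ids)
        return FeatureTable(
            self.values.loc[ids],
            self.labels.loc[ids],
            None if self.groups is None else self.groups.loc[ids],
        )

    def select_features(self, names: Sequence[str]) -> "FeatureTable":
        return FeatureTable(self.values[list(names)], self.labels, self.groups)

    def equals(self, other: "FeatureTable") -> bool:
        return (
            self.values.equals(other.values)
            and self.labels.equals(other.labels)
        )


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Persist a feature table as CSV (lossless float round trip)."""
    if len(table) == 0:
        raise IntegrityError("refusing to write empty feature table")
    if table.values.isna().any().any():
        raise IntegrityError("feature table contains NaN values")
    df = table.values.copy()
    df.insert(0, "label", table.labels)
    if table.groups is not None:
        df.insert(0, "group", table.groups)
    df.index.name = "record_id"
    # repr() of a float is shortest-round-trip in py3, so to_csv is lossless
    df.to_csv(path)


def read_feature_table(path: str | Path) -> FeatureTable:
    df = pd.read_csv(path, index_col="record_id", float_precision="round_trip")
    if df.index.has_duplicates:
        raise IntegrityError(f"{path}: duplicate record ids")
    labels = df.pop("label").astype(int)
    groups = df.pop("group") if "group" in df.columns else None
    return FeatureTable(values=df, labels=labels, groups=groups)


def collection_feature_table(
    collection: RecordCollection, values: Mapping[str, Mapping[str, float]]
) -> FeatureTable:
    """Assemble a FeatureTable from per-record feature dicts."""
    ids = sorted(values)
    df = pd.DataFrame.from_dict({rid: dict(values[rid]) for rid in ids}, orient="index")
    labels = pd.Series(collection.labels()).reindex(ids)
    groups = pd.Series({k: v.value for k, v in collection.groups.items()}).reindex(ids)
    return FeatureTable(values=df, labels=labels, groups=groups)
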