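"""Deterministic synthetic EEG-like and generic containers with ground truth.

Every module of the store is testable without downloading recordings: the
generators here emit containers whose structural properties (event count,
unique event-type count, per-event attribute count, event times) are known
by construction.  Only structure matters — the signal itself is white noise,
not a realistic EEG spectrum.

Randomness uses numpy's PCG64 generator seeded explicitly, so the same spec
and seed reproduce the identical container on any platform.  Container file
I/O uses the MAT-file format with the EEGLAB field layout (``data``,
``srate``, ``event``, ``urevent``, ``chanlocs``); the 116-byte MAT text
header is fixed so serialization is byte-deterministic.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Union

import numpy as np
from scipy.io import loadmat, savemat

from .modalities import EEGStruct, GenericStruct
from .schema_core import ValidationError

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate_eeg",
    "generate_generic",
    "write_container",
    "read_container",
    "eeg_to_bytes",
    "eeg_from_bytes",
    "generic_to_bytes",
    "generic_from_bytes",
]


# ---------------------------------------------------------------------------
# Specs and ground truth

@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic recording.

    Defaults mirror a typical curated EEG collection: 32 channels,
    30 000 frames at 128 Hz, 154 events drawn from a 2-type vocabulary.
    """

    n_channels: int = 32
    n_frames: int = 30_000
    srate: float = 128.0
    n_events: int = 154
    n_event_types: int = 2
    event_attr_fields: int = 2
    certainty_mode: str = "all-one"  # or "uniform-random"
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_channels, self.n_frames, self.n_events,
                  self.n_event_types, self.event_attr_fields)
        if any(c < 0 for c in counts):
            raise ValidationError("all counts must be >= 0")
        if self.n_event_types > self.n_events:
            raise ValidationError(
                "n_event_types must not exceed n_events"
            )
        if self.n_events > 0 and self.n_event_types == 0:
            raise ValidationError("events require at least one event type")
        if self.srate <= 0:
            raise ValidationError("srate must be positive")
        if self.certainty_mode not in ("all-one", "uniform-random"):
            raise ValidationError(
                f"unknown certainty_mode {self.certainty_mode!r}"
            )


@dataclass(frozen=True)
class GroundTruth:
    """Structural facts about a generated container, by construction."""

    n_events: int
    n_unique_types: int
    attrs_per_event: int
    event_times: tuple[float, ...]
    certainties: tuple[float, ...]


def _type_vocabulary(n: int) -> list[str]:
    return [f"type_{i:02d}" for i in range(n)]


def _draw_type_indices(rng: np.random.Generator, n_events: int,
                       n_types: int) -> np.ndarray:
    """Indices into the vocabulary with every type used at least once."""
    if n_events == 0:
        return np.zeros(0, dtype=np.int64)
    idx = np.concatenate([
        np.arange(n_types, dtype=np.int64),
        rng.integers(0, n_types, size=n_events - n_types),
    ])
    rng.shuffle(idx)
    return idx


# ---------------------------------------------------------------------------
# Generators

def generate_eeg(spec: SyntheticSpec) -> tuple[EEGStruct, GroundTruth]:
    """Generate an EEG-like container matching *spec* exactly.

    Latencies are drawn uniformly over [1, n_frames] (1-based samples) and
    sorted; event types come from a ``type_00 ...`` vocabulary of size
    ``n_event_types`` with each type used at least once; every event gets
    ``event_attr_fields`` numeric modifier fields ``attr_00 ...``.
    """
    rng = np.random.default_rng(spec.seed)
    data = rng.standard_normal((spec.n_channels, spec.n_frames))
    vocab = _type_vocabulary(spec.n_event_types)
    latencies = np.sort(rng.integers(1, spec.n_frames + 1, size=spec.n_events))
    type_idx = _draw_type_indices(rng, spec.n_events, spec.n_event_types)

    events: list[dict[str, Any]] = []
    for i in range(spec.n_events):
        ev: dict[str, Any] = {
            "type": vocab[type_idx[i]],
            "latency": float(latencies[i]),
        }
        for k in range(spec.event_attr_fields):
            ev[f"attr_{k:02d}"] = float(np.round(rng.uniform(0, 100), 6))
        events.append(ev)
    urevents = [{"type": ev["type"], "latency": ev["latency"]} for ev in events]
    chanlocs = [
        {
            "labels": f"ch{i + 1}",
            "X": float(np.round(rng.uniform(-1, 1), 6)),
            "Y": float(np.round(rng.uniform(-1, 1), 6)),
            "Z": float(np.round(rng.uniform(-1, 1), 6)),
        }
        for i in range(spec.n_channels)
    ]
    eeg = EEGStruct(data=data, srate=float(spec.srate), event=events,
                    urevent=urevents, chanlocs=chanlocs)
    truth = GroundTruth(
        n_events=spec.n_events,
        n_unique_types=len(set(ev["type"] for ev in events)),
        attrs_per_event=spec.event_attr_fields,
        event_times=tuple((float(l) - 1.0) / spec.srate for l in latencies),
        certainties=tuple(1.0 for _ in range(spec.n_events)),
    )
    return eeg, truth


def generate_generic(spec: SyntheticSpec) -> tuple[GenericStruct, GroundTruth]:
    """Generate a generic container with explicit start/end/certainty.

    About half of the events are instantaneous markers (start == end);
    the rest have positive durations.  ``certainty_mode='all-one'`` emulates
    hardware-inserted markers; ``'uniform-random'`` emulates algorithmically
    detected events with a confidence in [0, 1].
    """
    rng = np.random.default_rng(spec.seed)
    duration_s = spec.n_frames / spec.srate
    vocab = _type_vocabulary(spec.n_event_types)
    type_idx = _draw_type_indices(rng, spec.n_events, spec.n_event_types)
    starts = np.sort(rng.uniform(0, duration_s, size=spec.n_events))
    instantaneous = rng.random(spec.n_events) < 0.5
    if spec.certainty_mode == "all-one":
        certainties = np.ones(spec.n_events)
    else:
        certainties = rng.uniform(0, 1, size=spec.n_events)

    events: list[dict[str, Any]] = []
    for i in range(spec.n_events):
        start = float(np.round(starts[i], 6))
        dur = 0.0 if instantaneous[i] else float(np.round(rng.uniform(0.01, 1.0), 6))
        ev: dict[str, Any] = {
            "type": vocab[type_idx[i]],
            "start_time": start,
            "end_time": start + dur,
            "certainty": float(np.round(certainties[i], 6)),
        }
        for k in range(spec.event_attr_fields):
            ev[f"attr_{k:02d}"] = float(np.round(rng.uniform(0, 100), 6))
        events.append(ev)

    g = GenericStruct(
        element=[{"label": f"elem_{i}", "description": "synthetic element"}
                 for i in range(min(spec.n_channels, 4))],
        event=events,
        feature=[{"name": "synthetic_feature", "kind": "demo"}],
        metadata=[{"origin": "synthetic", "seed": float(spec.seed)}],
    )
    truth = GroundTruth(
        n_events=spec.n_events,
        n_unique_types=len(set(ev["type"] for ev in events)),
        attrs_per_event=spec.event_attr_fields,
        event_times=tuple(ev["start_time"] for ev in events),
        certainties=tuple(ev["certainty"] for ev in events),
    )
    return g, truth


# ---------------------------------------------------------------------------
# MAT-file container I/O (EEGLAB field layout)

_FIXED_MAT_HEADER = b"MATLAB 5.0 MAT-file, deterministic container".ljust(116)


def _records_to_structarr(records: list[dict[str, Any]]) -> np.ndarray:
    if not records:
        # empty struct array; field set is irrelevant when length is zero
        return np.empty((0,), dtype=[("type", object)])
    fields: list[str] = []
    for rec in records:
        for key in rec:
            if key not in fields:
                fields.append(key)
    arr = np.empty((len(records),), dtype=[(f, object) for f in fields])
    for i, rec in enumerate(records):
        for f in fields:
            arr[i][f] = rec.get(f, "")
    return arr


def _scalarize(value: Any) -> Any:
    """Collapse loadmat's numpy scalars/0-d arrays back to python values."""
    if isinstance(value, np.ndarray):
        if value.size == 0:
            return ""
        if value.size == 1:
            return _scalarize(value.item() if value.ndim == 0 else value.flat[0])
        return value
    if isinstance(value, (np.floating, np.integer)):
        return float(value)
    if isinstance(value, np.str_):
        return str(value)
    return value


def _structarr_to_records(obj: Any) -> list[dict[str, Any]]:
    if obj is None:
        return []
    if isinstance(obj, np.ndarray) and obj.size == 0:
        return []
    items = np.atleast_1d(obj) if isinstance(obj, np.ndarray) else [obj]
    records = []
    for item in items:
        fields = getattr(item, "_fieldnames", None)
        if fields is None:
            continue
        records.append({f: _scalarize(getattr(item, f)) for f in fields})
    return records


def _eeg_to_matdict(eeg: EEGStruct) -> dict[str, Any]:
    return {
        "EEG": {
            "data": np.asarray(eeg.data, dtype=np.float64),
            "srate": float(eeg.srate),
            "event": _records_to_structarr(eeg.event),
            "urevent": _records_to_structarr(eeg.urevent),
            "chanlocs": _records_to_structarr(eeg.chanlocs),
        }
    }


def _matstruct_to_eeg(obj: Any) -> EEGStruct:
    fields = set(getattr(obj, "_fieldnames", ()))
    for section in ("event", "urevent", "chanlocs"):
        if section not in fields:
            warnings.warn(
                f"container is missing the {section!r} field; treating as empty",
                stacklevel=3,
            )
    data = np.atleast_2d(np.asarray(getattr(obj, "data"), dtype=np.float64))
    return EEGStruct(
        data=data,
        srate=float(_scalarize(getattr(obj, "srate"))),
        event=_structarr_to_records(getattr(obj, "event", None)),
        urevent=_structarr_to_records(getattr(obj, "urevent", None)),
        chanlocs=_structarr_to_records(getattr(obj, "chanlocs", None)),
    )


def eeg_to_bytes(eeg: EEGStruct) -> bytes:
    """Serialize an EEG container to deterministic MAT-file bytes."""
    buf = io.BytesIO()
    savemat(buf, _eeg_to_matdict(eeg), format="5", long_field_names=True)
    raw = bytearray(buf.getvalue())
    raw[:116] = _FIXED_MAT_HEADER  # savemat stamps a timestamp here
    return bytes(raw)


def eeg_from_bytes(raw: bytes) -> EEGStruct:
    mat = loadmat(io.BytesIO(raw), squeeze_me=True, struct_as_record=False)
    if "EEG" not in mat:
        raise ValidationError("MAT container has no 'EEG' variable")
    return _matstruct_to_eeg(mat["EEG"])


def generic_to_bytes(g: GenericStruct) -> bytes:
    """Serialize a generic container as canonical JSON bytes."""
    payload = {s: getattr(g, s) for s in ("element", "event", "feature", "metadata")}
    return json.dumps(payload, sort_keys=True).encode("utf-8")


def generic_from_bytes(raw: bytes) -> GenericStruct:
    try:
        payload = json.loads(raw.decode("utf-8"))
    except (UnicodeDecodeError, json.JSONDecodeError) as exc:
        raise ValidationError(f"malformed generic container: {exc}") from exc
    return GenericStruct(**{k: payload.get(k, []) for k in
                            ("element", "event", "feature", "metadata")})


Container = Union[EEGStruct, GenericStruct]


def write_container(path: Union[str, Path], struct: Container) -> None:
    """Write a container to disk (MAT file for EEG, JSON for generic)."""
    path = Path(path)
    if isinstance(struct, EEGStruct):
        path.write_bytes(eeg_to_bytes(struct))
    elif isinstance(struct, GenericStruct):
        path.write_bytes(generic_to_bytes(struct))
    else:
        raise ValidationError(f"unsupported container type {type(struct)!r}")


def read_container(path: Union[str, Path]) -> Container:
    """Read a container written by :func:`write_container`."""
    raw = Path(path).read_bytes()
    if raw[:6] == b"MATLAB":
        try:
            return eeg_from_bytes(raw)
        except Exception as exc:
            raise ValidationError(f"malformed MAT container: {exc}") from exc
    return generic_from_bytes(raw)
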