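"""Readers and writers for records, models, annotations and reports.

CSV records use one header line ``sample_index,mV``.  WFDB-format reading
is optional (guarded import: the ``wfdb`` package is not a hard
dependency); the WFDB beat-annotation symbol mapping itself is a plain
function so it can be used and tested without the library.
"""

from __future__ import annotations

import json
from pathlib import Path
import numpy as np
import pandas as pd

from .hmm import AnnotatedSequence, HmmModel
from .records import BeatClass, BeatFeatures, BeatLabel, EcgRecord

__all__ = [
    "read_record",
    "read_record_csv",
    "write_record_csv",
    "wfdb_symbol_to_class",
    "read_model",
    "write_model",
    "read_annotation",
    "write_annotation",
    "write_features_csv",
    "write_labels",
    "write_report",
]

#: WFDB beat annotation codes -> beat classes (N normal, V ventricular
#: ectopic, A atrial premature; everything else is outside this model's
#: classes and maps to Invalid).
_WFDB_MAP = {"N": BeatClass.NORMAL, "V": BeatClass.PVC, "A": BeatClass.APC}


def wfdb_symbol_to_class(symbol: str) -> BeatClass:
    return _WFDB_MAP.get(symbol, BeatClass.INVALID)


def read_record_csv(path: str | Path, sampling_rate: float = 400.0) -> EcgRecord:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
    if header.split(",")[:2] != ["sample_index", "mV"]:
        raise ValueError(
            f"{path}: line 1 must be the header 'sample_index,mV', got {header!r}"
        )
    df = pd.read_csv(path)
    idx = df["sample_index"].to_numpy()
    if idx.size and not np.array_equal(idx, np.arange(idx.size)):
        raise ValueError(f"{path}: non-uniform or non-contiguous sample index")
    return EcgRecord(samples=df["mV"].to_numpy(dtype=float),
                     sampling_rate=sampling_rate, record_id=path.stem)


def write_record_csv(record: EcgRecord, path: str | Path) -> None:
    df = pd.DataFrame({"sample_index": np.arange(len(record)),
                       "mV": record.samples})
    df.to_csv(path, index=False)


def read_record(path: str | Path, format: str = "csv",
                sampling_rate: float = 400.0) -> EcgRecord:
    """Read an ECG record from CSV or a WFDB record (optional dependency)."""
    if format == "csv":
        return read_record_csv(path, sampling_rate)
    if format == "wfdb":
        try:
            import wfdb  # type: ignore
        except ImportError as exc:  # pragma: no cover - optional extra
            raise ImportError(
                "WFDB support requires the optional 'wfdb' package "
                "(pip install ecghmm[wfdb])"
            ) from exc
        rec = wfdb.rdrecord(str(path))
        return EcgRecord(samples=np.asarray(rec.p_signal[:, 0], dtype=float),
                         sampling_rate=float(rec.fs), record_id=rec.record_name)
    raise ValueError(f"unknown record format {format!r}")


def write_model(model: HmmModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=1))


def read_model(path: str | Path) -> HmmModel:
    return HmmModel.from_dict(json.loads(Path(path).read_text()))


def write_annotation(seq: AnnotatedSequence, path: str | Path) -> None:
    Path(path).write_text(json.dumps({
        "annotator_id": seq.annotator_id,
        "observations": seq.observations.tolist(),
        "states": seq.state_labels.tolist(),
    }))


def read_annotation(path: str | Path) -> AnnotatedSequence:
    d = json.loads(Path(path).read_text())
    return AnnotatedSequence(observations=np.array(d["observations"]),
                             state_labels=np.array(d["states"]),
                             annotator_id=d.get("annotator_id", ""))


def write_features_csv(features: list[BeatFeatures], path: str | Path) -> None:
    pd.DataFrame([vars(f) for f in features]).to_csv(path, index=False)


def write_labels(labels: list[BeatLabel], path: str | Path) -> None:
    Path(path).write_text(json.dumps(
        [{"beat_index": l.beat_index, "class": l.beat_class.value} for l in labels],
        indent=0))


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=1))
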