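"""Readers and writers: WFDB and CPSC-style MAT records, HDF5 containers
for recordings and preprocessed spectrogram tensors, YAML run configs.

Lead order is canonicalized to the standard 12-lead sequence (I, II, III,
aVR, aVL, aVF, V1-V6) at read time — channel-ablation results would be
meaningless otherwise — and records with missing readings are rejected.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import yaml
from scipy.io import loadmat

from .model import ModelConfig
from .preprocess import FilterSpec, PreprocessConfig, SpectrogramTensor, STFTConfig
from .recording import LEAD_NAMES, InvalidInputError, Recording
from .synth import SynthConfig
from .train import TrainConfig
from .wiring import WiringConfig


class UnknownFormatError(ValueError):
    pass


class MissingLeadError(InvalidInputError):
    pass


# -- WFDB (.hea/.dat, format 16) ----------------------------------------------


def _parse_hea(path: Path) -> tuple[dict, list[dict]]:
    lines = [
        ln.strip()
        for ln in path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    head = lines[0].split()
    info = {
        "record": head[0].split("/")[0],
        "n_sig": int(head[1]),
        "fs": float(head[2]) if len(head) > 2 else 250.0,
        "n_samples": int(head[3]) if len(head) > 3 else 0,
    }
    signals = []
    for ln in lines[1 : 1 + info["n_sig"]]:
        tok = ln.split()
        fmt = tok[1].split("x")[0].split(":")[0].split("+")[0]
        gain_tok = tok[2] if len(tok) > 2 else "200"
        baseline = 0
        if "(" in gain_tok:
            gain_tok, rest = gain_tok.split("(", 1)
            baseline = int(rest.split(")")[0])
        gain = float(gain_tok.split("/")[0]) or 200.0
        signals.append(
            {
                "file": tok[0],
                "fmt": fmt,
                "gain": gain,
                "baseline": baseline,
                "name": tok[-1] if len(tok) >= 9 else f"ch{len(signals)}",
            }
        )
    return info, signals


def read_wfdb(header_path: str | Path) -> Recording:
    """Read a WFDB record pair (.hea plus a single format-16 .dat file)."""
    header_path = Path(header_path)
    if header_path.suffix != ".hea":
        header_path = header_path.with_suffix(".hea")
    info, signals = _parse_hea(header_path)
    fmts = {s["fmt"] for s in signals}
    if fmts != {"16"}:
        raise UnknownFormatError(f"only WFDB format 16 is supported, got {fmts}")
    dat_files = {s["file"] for s in signals}
    if len(dat_files) != 1:
        raise UnknownFormatError("multi-file WFDB records are not supported")
    raw = np.fromfile(header_path.parent / dat_files.pop(), dtype="<i2")
    n_sig = info["n_sig"]
    raw = raw[: (len(raw) // n_sig) * n_sig].reshape(-1, n_sig).T.astype(float)
    for i, s in enumerate(signals):
        raw[i] = (raw[i] - s["baseline"]) / s["gain"]
    rec = Recording(signal=raw, fs=info["fs"], record_id=info["record"])
    return _canonicalize_leads(rec, [s["name"] for s in signals])


def _canonicalize_leads(rec: Recording, names: list[str]) -> Recording:
    rec.require_finite()
    if rec.n_channels != 12:
        return rec
    lookup = {n.upper(): i for i, n in enumerate(names)}
    order = []
    for lead in LEAD_NAMES:
        if lead.upper() not in lookup:
            if len(set(lookup) & {l.upper() for l in LEAD_NAMES}) > 6:
                raise MissingLeadError(f"lead {lead} missing from record {rec.record_id!r}")
            return rec  # names unrecognized entirely: keep file order
        order.append(lookup[lead.upper()])
    out = rec.replace(signal=rec.signal[order])
    out.meta["lead_order"] = list(LEAD_NAMES)
    return out


# -- CPSC-style MAT -----------------------------------------------------------

#: default dotted key path into CPSC-2018 challenge .mat files
MAT_KEY_MAP = {"signal": "ECG.data", "fs": None}


def read_mat(path: str | Path, key_map: dict | None = None, fs: float = 500.0) -> Recording:
    """Read a CPSC-2018-style MAT record (12 x n array under ECG.data)."""
    key_map = {**MAT_KEY_MAP, **(key_map or {})}
    m = loadmat(str(path), squeeze_me=False)
    node = m
    for part in key_map["signal"].split("."):
        if isinstance(node, dict):
            node = node[part]
        else:  # MATLAB struct: structured ndarray
            node = node[part][0, 0] if node.dtype.names else node
    sig = np.asarray(node, dtype=float)
    while sig.ndim > 2:
        sig = sig[0]
    if sig.ndim != 2:
        raise UnknownFormatError(f"could not locate a 2-D signal in {path}")
    if sig.shape[0] > sig.shape[1]:
        sig = sig.T  # stored samples x channels
    rec = Recording(signal=sig, fs=fs, record_id=Path(path).stem)
    rec.require_finite()
    return rec


# -- HDF5 containers ----------------------------------------------------------


def write_recording_h5(rec: Recording, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("signal", data=rec.signal)
        f.attrs["fs"] = rec.fs
        f.attrs["record_id"] = rec.record_id
        if rec.labels is not None:
            f.create_dataset("labels", data=rec.labels)


def read_recording_h5(path: str | Path) -> Recording:
    with h5py.File(path, "r") as f:
        rec = Recording(
            signal=f["signal"][()],
            fs=float(f.attrs["fs"]),
            labels=f["labels"][()] if "labels" in f else None,
            record_id=str(f.attrs.get("record_id", "")),
        )
    rec.require_finite()
    return rec


def read_record(path: str | Path, format: str = "wfdb", **kw) -> Recording:
    """Dispatch to the WFDB, MAT or HDF5 reader."""
    readers = {"wfdb": read_wfdb, "mat": read_mat, "hdf5": read_recording_h5}
    if format not in readers:
        raise UnknownFormatError(f"unknown format {format!r}; expected {sorted(readers)}")
    return readers[format](path, **kw)


def save_spectrogram_dataset(
    path: str | Path,
    spectrograms: np.ndarray,
    labels: np.ndarray,
    record_ids: list[str],
    config: dict | None = None,
) -> None:
    """HDF5 container for preprocessed tensors: /spectrogram, /labels,
    /record_ids plus the resolved configuration as a YAML attribute."""
    with h5py.File(path, "w") as f:
        f.create_dataset("spectrogram", data=np.asarray(spectrograms))
        f.create_dataset("labels", data=np.asarray(labels))
        f.create_dataset(
            "record_ids", data=np.array(record_ids, dtype=h5py.string_dtype())
        )
        f.attrs["config"] = yaml.safe_dump(config or {})


def load_spectrogram_dataset(path: str | Path):
    with h5py.File(path, "r") as f:
        spect = f["spectrogram"][()]
        labels = f["labels"][()]
        ids = [s.decode() if isinstance(s, bytes) else str(s) for s in f["record_ids"][()]]
        config = yaml.safe_load(f.attrs.get("config", "{}"))
    return spect, labels, ids, config


# -- run configuration --------------------------------------------------------


@dataclasses.dataclass
class RunConfig:
    """Resolved configuration of a full run; serialized next to artifacts."""

    synth: SynthConfig = dataclasses.field(default_factory=SynthConfig)
    preprocess: PreprocessConfig = dataclasses.field(default_factory=PreprocessConfig)
    model: ModelConfig = dataclasses.field(default_factory=ModelConfig)
    train: TrainConfig = dataclasses.field(default_factory=TrainConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _build(cls, d: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    return cls(**d)


def run_config_from_dict(d: dict) -> RunConfig:
    d = dict(d or {})
    synth = _build(SynthConfig, d.pop("synth", {}))
    pp = dict(d.pop("preprocess", {}))
    preprocess = PreprocessConfig(
        filter=_build(FilterSpec, pp.pop("filter", {})),
        stft=_build(STFTConfig, pp.pop("stft", {})),
        **pp,
    )
    md = dict(d.pop("model", {}))
    model = ModelConfig(wiring=_build(WiringConfig, md.pop("wiring", {})), **md)
    train = _build(TrainConfig, d.pop("train", {}))
    return RunConfig(synth=synth, preprocess=preprocess, model=model, train=train, **d)


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as f:
        data = yaml.safe_load(f) or {}
    return run_config_from_dict(data)


def save_run_config(cfg: RunConfig, path: str | Path) -> None:
    d = cfg.to_dict()
    # tuples serialize cleanly as lists
    with open(path, "w") as f:
        yaml.safe_dump(json.loads(json.dumps(d)), f, sort_keys=False)
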