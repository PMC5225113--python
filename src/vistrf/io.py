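"""Readers and writers for the package's on-disk formats.

Formats are deliberately plain:

* audio — WAV (PCM or float), via :mod:`scipy.io.wavfile`;
* video — a directory of grayscale PGM/PNG frames, or a ``.fstk`` raw
  frame stack with a one-line text header (rows cols n_frames rate dtype);
* phoneme alignments — TSV ``label<TAB>onset_s<TAB>offset_s``;
* viseme maps — TSV ``phoneme<TAB>viseme_id``;
* stimulus/EEG matrices — a ``.npz`` binary container (bit-exact round
  trip) or headered TSV text (round trip to ~1e-6);
* TRF models — ``.npz`` plus a delimited long-format export for plotting;
* prediction results — a tidy TSV (subject, model, trial, channel, r, lambda).
"""

from __future__ import annotations

import importlib.resources
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .crossval import PredictionResult
from .trf import LagWindow, TRFModel
from .types import (
    AudioSignal,
    EEGRecording,
    FrameStack,
    InputError,
    PhonemeAlignment,
    StimulusFeature,
    VisemeMap,
    VisemeSequence,
)

__all__ = [
    "read_wav",
    "read_frames",
    "write_frames",
    "read_alignment",
    "read_viseme_map",
    "load_default_viseme_map",
    "read_electrodes",
    "read_matrix",
    "write_matrix",
    "read_trf",
    "write_trf",
    "export_trf_long",
    "write_results",
    "read_viseme_sequence",
    "write_viseme_sequence",
]


def read_wav(path) -> AudioSignal:
    """Read a WAV file; integer PCM is rescaled to [-1, 1]; stereo is averaged."""
    from scipy.io import wavfile

    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(float)
    if data.ndim == 2:
        data = data.mean(axis=1)
    return AudioSignal(data, float(rate))


def read_frames(path, rate: float = 30.0) -> FrameStack:
    """Read video frames from a directory of images or a ``.fstk`` stack.

    A directory is scanned for ``.pgm``/``.png`` files in sorted order (color
    images are converted to grayscale by channel averaging); ``rate`` applies.
    A ``.fstk`` file carries its own header: one text line
    ``rows cols n_frames rate dtype`` followed by raw frame data.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".pgm", ".png"))
        if not files:
            raise InputError(f"no .pgm/.png frames found in {path}")
        import imageio.v3 as iio

        frames = []
        for f in files:
            img = np.asarray(iio.imread(f), dtype=float)
            if img.ndim == 3:
                img = img.mean(axis=2)
            frames.append(img)
        shapes = {f.shape for f in frames}
        if len(shapes) != 1:
            raise InputError(f"frames differ in shape: {sorted(shapes)}")
        return FrameStack(np.stack(frames), rate)

    with open(path, "rb") as fh:
        header = fh.readline().decode("ascii").split()
        if len(header) != 5:
            raise InputError(
                f"{path}: header line 1 must be 'rows cols n_frames rate dtype'"
            )
        rows, cols, n_frames = (int(v) for v in header[:3])
        file_rate = float(header[3])
        dtype = np.dtype(header[4])
        raw = np.frombuffer(fh.read(), dtype=dtype)
    expected = rows * cols * n_frames
    if raw.size != expected:
        raise InputError(
            f"{path}: expected {expected} values, found {raw.size}"
        )
    return FrameStack(raw.reshape(n_frames, rows, cols).astype(float), file_rate)


def write_frames(video: FrameStack, path, dtype: str = "float64") -> None:
    """Write a ``.fstk`` raw frame stack with a one-line text header."""
    n, rows, cols = video.frames.shape
    with open(path, "wb") as fh:
        fh.write(f"{rows} {cols} {n} {video.rate} {dtype}\n".encode("ascii"))
        fh.write(np.ascontiguousarray(video.frames, dtype=np.dtype(dtype)).tobytes())


def read_alignment(path) -> PhonemeAlignment:
    """Read a phoneme alignment TSV (label, onset_s, offset_s per line)."""
    entries = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise InputError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, got {len(parts)}"
                )
            try:
                entries.append((parts[0], float(parts[1]), float(parts[2])))
            except ValueError:
                raise InputError(f"{path}:{lineno}: non-numeric onset/offset") from None
    try:
        return PhonemeAlignment(entries)
    except InputError as exc:
        raise InputError(f"{path}: {exc}") from None


def read_viseme_map(path) -> VisemeMap:
    """Read a phoneme -> viseme-id TSV mapping."""
    mapping = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise InputError(
                    f"{path}:{lineno}: expected 'phoneme<TAB>viseme_id'"
                )
            try:
                mapping[parts[0]] = int(parts[1])
            except ValueError:
                raise InputError(f"{path}:{lineno}: viseme id must be an integer") from None
    return VisemeMap(mapping)


def load_default_viseme_map() -> VisemeMap:
    """The bundled 12-category ARPAbet phoneme -> viseme mapping.

    Groupings follow the visual-similarity classes of Auer & Bernstein
    (e.g. bilabials /b, p, m/ together, labiodentals /f, v/ together); the
    TSV under ``vistrf/data`` is user-editable and any replacement with
    contiguous ids 1..K is accepted.
    """
    ref = importlib.resources.files("vistrf") / "data" / "viseme_map_default.tsv"
    with importlib.resources.as_file(ref) as path:
        return read_viseme_map(path)


def read_electrodes(path, channel_names: list[str] | None = None) -> list[int]:
    """Read an electrode subset: one entry per line, index or channel name."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            token = line.strip()
            if not token or token.startswith("#"):
                continue
            if token.isdigit():
                out.append(int(token))
            elif channel_names is not None and token in channel_names:
                out.append(channel_names.index(token))
            else:
                raise InputError(
                    f"{path}:{lineno}: {token!r} is neither an index nor a known channel"
                )
    if not out:
        raise InputError(f"{path}: electrode set is empty")
    return out


# --------------------------------------------------------------------------
# matrix containers (StimulusFeature / EEGRecording)
# --------------------------------------------------------------------------

_KINDS = {"stimulus": StimulusFeature, "eeg": EEGRecording}


def write_matrix(obj: StimulusFeature | EEGRecording, path) -> None:
    """Write a stimulus or EEG matrix; ``.npz`` = binary, anything else = TSV."""
    kind = "stimulus" if isinstance(obj, StimulusFeature) else "eeg"
    labels = obj.labels if kind == "stimulus" else obj.channel_names
    path = Path(path)
    if path.suffix == ".npz":
        np.savez(path, kind=kind, values=obj.values, rate=obj.rate,
                 labels=np.array(labels))
        return
    with open(path, "w") as fh:
        fh.write(f"# kind: {kind}\n# rate: {obj.rate}\n")
        fh.write("# labels: " + ",".join(labels) + "\n")
        np.savetxt(fh, obj.values, delimiter="\t", fmt="%.10g")


def read_matrix(path) -> StimulusFeature | EEGRecording:
    """Read a matrix container written by :func:`write_matrix`."""
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            kind = str(z["kind"])
            values, rate = z["values"], float(z["rate"])
            labels = [str(s) for s in z["labels"]]
    else:
        meta = {}
        with open(path) as fh:
            pos = fh.tell()
            for lineno in range(1, 4):
                line = fh.readline()
                if not line.startswith("# ") or ":" not in line:
                    raise InputError(f"{path}:{lineno}: malformed header line")
                key, _, val = line[2:].partition(":")
                meta[key.strip()] = val.strip()
                pos = fh.tell()
            fh.seek(pos)
            values = np.loadtxt(fh, delimiter="\t", ndmin=2)
        kind, rate = meta["kind"], float(meta["rate"])
        labels = meta["labels"].split(",") if meta["labels"] else []
    if kind not in _KINDS:
        raise InputError(f"{path}: unknown container kind {kind!r}")
    if kind == "stimulus":
        return StimulusFeature(values, rate, labels)
    return EEGRecording(values, rate, labels)


# --------------------------------------------------------------------------
# TRF models and results
# --------------------------------------------------------------------------

def write_trf(model: TRFModel, path) -> None:
    np.savez(
        path,
        weights=model.weights,
        t_min=model.window.t_min,
        t_max=model.window.t_max,
        rate=model.window.rate,
        lam=model.lam,
        feature_labels=np.array(model.feature_labels),
        channel_names=np.array(model.channel_names),
    )


def read_trf(path) -> TRFModel:
    with np.load(path, allow_pickle=False) as z:
        window = LagWindow(float(z["t_min"]), float(z["t_max"]), float(z["rate"]))
        return TRFModel(
            z["weights"], window, float(z["lam"]),
            [str(s) for s in z["feature_labels"]],
            [str(s) for s in z["channel_names"]],
        )


def export_trf_long(model: TRFModel, path) -> None:
    """Write weights as long-format TSV (lag_ms, feature, channel, weight)."""
    lags_ms = model.window.lags_s * 1000.0
    L, F, C = model.weights.shape
    idx = np.indices((L, F, C))
    df = pd.DataFrame({
        "lag_ms": lags_ms[idx[0].ravel()],
        "feature": np.array(model.feature_labels)[idx[1].ravel()],
        "channel": np.array(model.channel_names)[idx[2].ravel()],
        "weight": model.weights.ravel(),
    })
    df.to_csv(path, sep="\t", index=False)


def write_results(results: list[PredictionResult], path, subject_id: str = "",
                  channel_names: list[str] | None = None) -> None:
    """Append-free tidy results table: subject, model, trial, channel, r, lambda."""
    rows = []
    for res in results:
        n_trials, n_channels = res.per_trial_r.shape
        names = channel_names or [f"ch{j + 1:03d}" for j in range(n_channels)]
        for t in range(n_trials):
            for c in range(n_channels):
                rows.append((subject_id, res.model_label, t, names[c],
                             res.per_trial_r[t, c], res.lam))
    pd.DataFrame(
        rows, columns=["subject", "model", "trial", "channel", "r", "lambda"]
    ).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# viseme sequences
# --------------------------------------------------------------------------

def write_viseme_sequence(seq: VisemeSequence, path) -> None:
    with open(path, "w") as fh:
        for vid, on, off in seq.intervals:
            fh.write(f"{vid}\t{on:.6f}\t{off:.6f}\n")


def read_viseme_sequence(path) -> VisemeSequence:
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise InputError(f"{path}:{lineno}: expected 'id<TAB>onset<TAB>offset'")
            intervals.append((int(parts[0]), float(parts[1]), float(parts[2])))
    return VisemeSequence(intervals)


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
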