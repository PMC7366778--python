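"""Session and model persistence, plus BrainVision import.

A *session bundle* is a directory with three components:

* ``header.yaml`` — sampling rate, channel labels, grid layout, timing,
  targets, seed and provenance;
* ``signal.f32`` — little-endian 32-bit floats, channel-major (row = channel);
* ``markers.tsv`` — tab-delimited flash table with a header line:
  ``onset_sample  onset_s  stim_id  is_target  char_index  repetition``
  (0-based samples; epochs are half-open ``[onset, onset+window)``);
* optional ``groundtruth.yaml`` for synthetic sessions.

Round-trips are lossless: the signal is stored at float32 and compared
bit-exactly on re-read.  Fitted models are stored as a YAML of scalars plus
plain-text matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import LDAModel, MLPModel, SVMModel
from .paradigm import FlashEvent, FlashSchedule, SpellerGrid, TimingParams
from .preprocess import ContinuousRecording
from .synthdata import GroundTruth
from .xdawn import XdawnModel

__all__ = ["SessionBundle", "write_session", "read_session",
           "import_brainvision", "save_xdawn", "load_xdawn",
           "save_classifier", "load_classifier"]

_MARKER_COLUMNS = ["onset_sample", "onset_s", "stim_id", "is_target",
                   "char_index", "repetition"]


@dataclass
class SessionBundle:
    recording: ContinuousRecording
    grid: SpellerGrid
    seed: int | None = None
    provenance: str = ""
    ground_truth: GroundTruth | None = None

    @property
    def schedule(self) -> FlashSchedule | None:
        return self.recording.markers


def _timing_to_dict(t: TimingParams) -> dict:
    return {"flash_s": t.flash_s, "gap_s": t.gap_s, "inter_rep_s": t.inter_rep_s,
            "inter_char_s": t.inter_char_s, "n_reps": t.n_reps}


def write_session(bundle: SessionBundle, path: "str | Path") -> Path:
    """Write a bundle to ``path`` (created if needed); returns the directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rec = bundle.recording
    sched = bundle.schedule
    header = {
        "format": "p300bci-session-v1",
        "fs": rec.fs,
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "channel_labels": list(rec.channel_labels),
        "grid": bundle.grid.characters,
        "seed": bundle.seed,
        "provenance": bundle.provenance,
        "dtype": "<f4",
    }
    if sched is not None:
        header["timing"] = _timing_to_dict(sched.timing)
        header["targets"] = [str(t) for t in sched.targets]
    (path / "header.yaml").write_text(yaml.safe_dump(header, sort_keys=False))
    rec.data.astype("<f4").tofile(path / "signal.f32")
    if sched is not None:
        pd.DataFrame(
            [
                {
                    "onset_sample": e.onset_sample,
                    "onset_s": e.onset_s,
                    "stim_id": e.stim_id,
                    "is_target": int(e.is_target),
                    "char_index": e.char_index,
                    "repetition": e.repetition,
                }
                for e in sched.events
            ]
        ).to_csv(path / "markers.tsv", sep="\t", index=False)
    if bundle.ground_truth is not None:
        gt = bundle.ground_truth
        (path / "groundtruth.yaml").write_text(yaml.safe_dump({
            "spatial_pattern": [float(x) for x in gt.spatial_pattern],
            "targets": [str(t) for t in gt.targets],
            "target_latencies": [float(x) for x in gt.target_latencies],
        }))
    return path


def read_session(path: "str | Path") -> SessionBundle:
    """Read a bundle; errors name the missing/mismatched component file."""
    path = Path(path)
    header_file = path / "header.yaml"
    if not header_file.exists():
        raise FileNotFoundError(f"missing component file: {header_file}")
    header = yaml.safe_load(header_file.read_text())
    signal_file = path / "signal.f32"
    if not signal_file.exists():
        raise FileNotFoundError(f"missing component file: {signal_file}")
    raw = np.fromfile(signal_file, dtype="<f4")
    n_ch, n_s = header["n_channels"], header["n_samples"]
    if raw.size != n_ch * n_s:
        raise ValueError(
            f"signal.f32 holds {raw.size} values, header promises {n_ch}x{n_s}"
        )
    data = raw.reshape(n_ch, n_s).astype(np.float64)

    schedule = None
    marker_file = path / "markers.tsv"
    if marker_file.exists():
        mk = pd.read_csv(marker_file, sep="\t")
        bad = mk[(mk.onset_sample < 0) | (mk.onset_sample >= n_s)]
        if len(bad):
            raise ValueError(
                f"markers.tsv rows outside signal bounds: {bad.index.tolist()}"
            )
        timing = TimingParams(**header["timing"])
        events = tuple(
            FlashEvent(onset_s=float(r.onset_s), onset_sample=int(r.onset_sample),
                       stim_id=str(r.stim_id), is_target=bool(r.is_target),
                       char_index=int(r.char_index), repetition=int(r.repetition))
            for r in mk.itertuples()
        )
        schedule = FlashSchedule(events=events, timing=timing,
                                 targets=tuple(header["targets"]),
                                 fs=float(header["fs"]))

    rec = ContinuousRecording(data=data, fs=float(header["fs"]),
                              channel_labels=list(header["channel_labels"]),
                              markers=schedule)
    truth = None
    gt_file = path / "groundtruth.yaml"
    if gt_file.exists():
        g = yaml.safe_load(gt_file.read_text())
        truth = GroundTruth(
            spatial_pattern=np.asarray(g["spatial_pattern"], dtype=float),
            targets=tuple(g["targets"]),
            target_latencies=np.asarray(g["target_latencies"], dtype=float),
        )
    return SessionBundle(recording=rec, grid=SpellerGrid(header["grid"]),
                         seed=header.get("seed"),
                         provenance=header.get("provenance", ""),
                         ground_truth=truth)


def import_brainvision(vhdr_path: "str | Path", code_table: dict,
                       grid: SpellerGrid | None = None,
                       timing: TimingParams | None = None,
                       targets: "tuple[str, ...] | None" = None) -> SessionBundle:
    """Import a BrainVision ``.vhdr``/``.vmrk``/``.eeg`` triplet.

    ``code_table`` maps the recording's marker descriptions (e.g.
    ``"Stimulus/S  3"``) to stimulus ids ``R0``-``C5``; descriptions absent
    from the table raise with the full list of unmapped codes.  ``is_target``
    flags are derived from ``targets`` when given (requires ``grid``),
    otherwise left False.
    """
    import mne  # deferred: heavy optional dependency

    vhdr_path = Path(vhdr_path)
    if not vhdr_path.exists():
        raise FileNotFoundError(f"missing component file: {vhdr_path}")
    vmrk = vhdr_path.with_suffix(".vmrk")
    if not vmrk.exists():
        raise FileNotFoundError(f"missing component file: {vmrk}")
    raw = mne.io.read_raw_brainvision(vhdr_path, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    data = raw.get_data() * 1e6  # volts -> µV

    annots = [(a["onset"], a["description"]) for a in raw.annotations
              if not a["description"].startswith("New Segment")]
    unmapped = sorted({d for _, d in annots if d not in code_table})
    if unmapped:
        raise KeyError(f"code table lacks marker codes: {unmapped}")

    timing = timing or TimingParams(flash_s=0.1, gap_s=0.05, inter_rep_s=0.5,
                                    inter_char_s=5.0)
    grid = grid or SpellerGrid()
    n_per_trial = timing.n_reps * timing.n_stim_per_rep
    events = []
    for k, (onset, desc) in enumerate(annots):
        stim = code_table[desc]
        ci, within = divmod(k, n_per_trial)
        rep = within // timing.n_stim_per_rep
        is_tgt = False
        if targets is not None and ci < len(targets):
            t = targets[ci]
            is_tgt = stim in {f"R{grid.row_of(t)}", f"C{grid.col_of(t)}"}
        events.append(FlashEvent(onset_s=float(onset),
                                 onset_sample=round(float(onset) * fs),
                                 stim_id=stim, is_target=is_tgt,
                                 char_index=ci, repetition=rep))
    schedule = FlashSchedule(events=tuple(events), timing=timing,
                             targets=targets or (), fs=fs)
    rec = ContinuousRecording(data=data, fs=fs,
                              channel_labels=list(raw.ch_names),
                              markers=schedule)
    return SessionBundle(recording=rec, grid=grid,
                         provenance=f"brainvision:{vhdr_path.name}")


# --------------------------------------------------------------------------
# model persistence (YAML scalars + whitespace-delimited text matrices)
# --------------------------------------------------------------------------

def _save_matrix(path: Path, arr: np.ndarray) -> None:
    np.savetxt(path, np.atleast_2d(arr), fmt="%.17g")


def _load_matrix(path: Path) -> np.ndarray:
    return np.loadtxt(path)


def save_xdawn(model: XdawnModel, path: "str | Path") -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    (path / "xdawn.yaml").write_text(yaml.safe_dump({
        "kind": "xdawn",
        "epoch_len": int(model.epoch_len),
        "n_components": int(model.n_components),
        "ssnr_values": [float(v) for v in model.ssnr_values],
    }))
    _save_matrix(path / "U.txt", model.U)
    _save_matrix(path / "A1.txt", model.A1_hat)
    return path


def load_xdawn(path: "str | Path") -> XdawnModel:
    path = Path(path)
    meta = yaml.safe_load((path / "xdawn.yaml").read_text())
    U = _load_matrix(path / "U.txt")
    if U.ndim == 1:
        U = U[:, None]
    return XdawnModel(A1_hat=_load_matrix(path / "A1.txt"), U=U,
                      ssnr_values=np.asarray(meta["ssnr_values"]),
                      epoch_len=int(meta["epoch_len"]))


def save_classifier(model, path: "str | Path") -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if isinstance(model, LDAModel):
        meta = {"kind": "lda", "bias": float(model.bias), "J": float(model.J)}
        _save_matrix(path / "V.txt", model.V_EEG)
        _save_matrix(path / "class_means.txt", model.class_means)
    elif isinstance(model, SVMModel):
        meta = {"kind": "svm", "b": float(model.b), "C": float(model.C),
                "kkt_gap": float(model.kkt_gap)}
        _save_matrix(path / "support_vectors.txt", model.support_vectors)
        _save_matrix(path / "alphas.txt", model.alphas)
        _save_matrix(path / "support_labels.txt", model.support_labels)
    elif isinstance(model, MLPModel):
        meta = {"kind": "mlp", "n_layers": len(model.weights),
                "shapes": [list(W.shape) for W in model.weights]}
        for i, (W, b) in enumerate(zip(model.weights, model.biases)):
            _save_matrix(path / f"W{i}.txt", W)
            _save_matrix(path / f"b{i}.txt", b)
        _save_matrix(path / "x_mean.txt", model.x_mean)
        _save_matrix(path / "x_sd.txt", model.x_sd)
    else:
        raise TypeError(f"unknown model type {type(model).__name__}")
    (path / "model.yaml").write_text(yaml.safe_dump(meta))
    return path


def load_classifier(path: "str | Path"):
    path = Path(path)
    meta = yaml.safe_load((path / "model.yaml").read_text())
    kind = meta["kind"]
    if kind == "lda":
        V = _load_matrix(path / "V.txt").ravel()
        means = _load_matrix(path / "class_means.txt")
        d = len(V)
        return LDAModel(V_EEG=V, bias=float(meta["bias"]), class_means=means,
                        S_b=np.zeros((d, d)), S_w=np.zeros((d, d)),
                        J=float(meta["J"]))
    if kind == "svm":
        return SVMModel(
            support_vectors=np.atleast_2d(_load_matrix(path / "support_vectors.txt")),
            support_labels=_load_matrix(path / "support_labels.txt").ravel(),
            alphas=_load_matrix(path / "alphas.txt").ravel(),
            b=float(meta["b"]), C=float(meta["C"]), class_weight=None,
            kkt_gap=float(meta["kkt_gap"]),
        )
    if kind == "mlp":
        n = int(meta["n_layers"])
        Ws = tuple(
            _load_matrix(path / f"W{i}.txt").reshape(meta["shapes"][i])
            for i in range(n)
        )
        bs = tuple(np.atleast_1d(_load_matrix(path / f"b{i}.txt")).ravel()
                   for i in range(n))
        return MLPModel(weights=Ws, biases=bs,
                        x_mean=_load_matrix(path / "x_mean.txt").ravel(),
                        x_sd=_load_matrix(path / "x_sd.txt").ravel(),
                        loss_trace=np.array([]))
    raise ValueError(f"unknown model kind {kind!r} in {path}")
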