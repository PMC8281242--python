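"""On-disk session format: stylus TSV, layout/ground-truth JSON, EEG files.

EEG is written as EDF+C (16-bit, 1 s data records, trigger annotations in an
'EDF Annotations' signal) or as a BrainVision triplet (.vhdr/.vmrk/.eeg with
IEEE float32 multiplexed data). Neither writer exists in the installed stack,
so both are implemented here minimally and are validated in the test suite by
reading the files back through MNE. Outputs are byte-identical for a fixed
seed (no wall-clock timestamps are embedded).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from tmteeg.eeg_prep import EEGRecording
from tmteeg.kinematics import SegmentationResult, StylusTrace
from tmteeg.synth.layout import StimulusLayout

__all__ = [
    "write_stylus_tsv",
    "write_edf",
    "write_brainvision",
    "write_session",
    "edf_quantization_step",
]

_TSV_HEADER = (
    "# tablet stylus log; coordinates: origin top-left, x right, y down, pixels\n"
    "t_ms\tx_px\ty_px\tpen_down\n"
)


def write_stylus_tsv(trace: StylusTrace, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(_TSV_HEADER)
        for t, x, y, p in zip(trace.t_ms, trace.x_px, trace.y_px, trace.pen_down):
            fh.write(f"{t:.3f}\t{x:.3f}\t{y:.3f}\t{int(p)}\n")


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"field too long: {text!r} > {width}")
    return b.ljust(width)


def edf_quantization_step(data_ch: np.ndarray) -> float:
    pmin, pmax = float(data_ch.min()), float(data_ch.max())
    if pmax <= pmin:
        pmin, pmax = pmin - 1.0, pmax + 1.0
    return (pmax - pmin) / 65535.0


def write_edf(rec: EEGRecording, path: Path) -> None:
    """Minimal EDF+C writer: int16 samples, 1 s records, TAL annotations."""
    fs = rec.sfreq
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sample rate")
    n_ch, n_samp = rec.data.shape
    n_rec = int(np.ceil(n_samp / spr))
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, :n_samp] = rec.data

    phys_min = padded.min(axis=1)
    phys_max = padded.max(axis=1)
    flat = phys_max <= phys_min
    phys_min[flat] -= 1.0
    phys_max[flat] += 1.0
    scale = 65535.0 / (phys_max - phys_min)
    digital = np.round(
        (padded - phys_min[:, None]) * scale[:, None] - 32768.0
    ).astype("<i2")

    # annotation TALs per record
    tals: list[bytes] = []
    events_by_rec: dict[int, list[tuple[float, str]]] = {}
    for sample, code in rec.events:
        onset = sample / fs
        events_by_rec.setdefault(int(onset // 1), []).append((onset, code))
    for r in range(n_rec):
        tal = f"+{r}\x14\x14\x00".encode("ascii")
        for onset, code in events_by_rec.get(r, []):
            tal += f"+{onset:.4f}\x14{code}\x14\x00".encode("ascii")
        tals.append(tal)
    ann_bytes = max(16, max(len(t) for t in tals))
    ann_spr = (ann_bytes + 1) // 2  # 2 bytes per 'sample'

    ns = n_ch + 1
    header = b""
    header += _pad("0", 8)
    header += _pad("X X X X", 80)
    header += _pad("Startdate 01-JAN-2000 X X X", 80)
    header += _pad("01.01.00", 8)
    header += _pad("00.00.00", 8)
    header += _pad(str(256 * (ns + 1)), 8)
    header += _pad("EDF+C", 44)
    header += _pad(str(n_rec), 8)
    header += _pad("1", 8)
    header += _pad(str(ns), 4)

    labels = [_pad(c, 16) for c in rec.ch_names] + [_pad("EDF Annotations", 16)]
    transducer = [_pad("", 80)] * ns
    dims = [_pad("uV", 8)] * n_ch + [_pad("", 8)]
    pmins = [_pad(f"{v:.6g}"[:8], 8) for v in phys_min] + [_pad("-1", 8)]
    pmaxs = [_pad(f"{v:.6g}"[:8], 8) for v in phys_max] + [_pad("1", 8)]
    dmins = [_pad("-32768", 8)] * ns
    dmaxs = [_pad("32767", 8)] * ns
    prefilter = [_pad("", 80)] * ns
    sprs = [_pad(str(spr), 8)] * n_ch + [_pad(str(ann_spr), 8)]
    reserved = [_pad("", 32)] * ns
    for fields in (labels, transducer, dims, pmins, pmaxs, dmins, dmaxs,
                   prefilter, sprs, reserved):
        header += b"".join(fields)

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())
            fh.write(tals[r].ljust(ann_spr * 2, b"\x00"))


def write_brainvision(rec: EEGRecording, basepath: Path) -> None:
    """BrainVision triplet writer (IEEE float32 multiplexed, µV)."""
    basepath = Path(basepath)
    stem = basepath.stem
    vhdr, vmrk, eeg = (basepath.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))
    n_ch = len(rec.ch_names)
    sampling_interval_us = 1e6 / rec.sfreq
    with open(vhdr, "w") as fh:
        fh.write("Brain Vision Data Exchange Header File Version 1.0\n\n")
        fh.write("[Common Infos]\n")
        fh.write(f"DataFile={stem}.eeg\nMarkerFile={stem}.vmrk\n")
        fh.write("DataFormat=BINARY\nDataOrientation=MULTIPLEXED\n")
        fh.write(f"NumberOfChannels={n_ch}\n")
        fh.write(f"SamplingInterval={sampling_interval_us:.10g}\n\n")
        fh.write("[Binary Infos]\nBinaryFormat=IEEE_FLOAT_32\n\n")
        fh.write("[Channel Infos]\n")
        for i, ch in enumerate(rec.ch_names, start=1):
            fh.write(f"Ch{i}={ch},,1,µV\n")
    with open(vmrk, "w") as fh:
        fh.write("Brain Vision Data Exchange Marker File, Version 1.0\n\n")
        fh.write("[Common Infos]\n")
        fh.write(f"DataFile={stem}.eeg\n\n")
        fh.write("[Marker Infos]\n")
        fh.write("Mk1=New Segment,,1,1,0,00000000000000000000\n")
        for i, (sample, code) in enumerate(rec.events, start=2):
            fh.write(f"Mk{i}=Stimulus,{code},{sample + 1},1,0\n")
    with open(eeg, "wb") as fh:
        fh.write(np.ascontiguousarray(rec.data.T, dtype="<f4").tobytes())


def _layout_dict(layout: StimulusLayout) -> dict:
    return {
        "items": [asdict(s) for s in layout.items],
        "width": layout.width,
        "height": layout.height,
        "part": layout.part,
        "variant_id": layout.variant_id,
    }


def _truth_dict(truth: SegmentationResult, sequence) -> dict:
    return {
        "linking_intervals_ms": [list(iv) for iv in truth.linking_intervals],
        "nonlinking_intervals_ms": [list(iv) for iv in truth.nonlinking_intervals],
        "n_links": truth.n_links_found,
        "link_sequence": [list(link) for link in sequence],
    }


def write_session(session, out_dir: str | Path, eeg_format: str = "edf") -> list[Path]:
    """Write a synthetic session to disk; returns the file list.

    Layout: ``stylus/part-X_trial-NN.tsv`` logs, ``layouts.json``,
    ``ground_truth.json``, ``session.json`` metadata, and the EEG recording as
    ``eeg.edf`` or a BrainVision triplet ``eeg.vhdr/.vmrk/.eeg``.
    """
    out_dir = Path(out_dir)
    (out_dir / "stylus").mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    layouts: dict[str, dict] = {}
    truths: dict[str, dict] = {}
    for part, records in session.trials.items():
        for rec in records:
            key = f"part-{part}_trial-{rec.trial_index:02d}"
            tsv = out_dir / "stylus" / f"{key}.tsv"
            write_stylus_tsv(rec.trace, tsv)
            written.append(tsv)
            layouts[key] = _layout_dict(rec.layout)
            truths[key] = _truth_dict(rec.truth, rec.sequence)
            truths[key]["onset_s"] = rec.onset_s
    for name, obj in (("layouts.json", layouts), ("ground_truth.json", truths)):
        p = out_dir / name
        p.write_text(json.dumps(obj, indent=1, sort_keys=True))
        written.append(p)
    meta = {
        "participant": session.participant,
        "seed": session.seed,
        "design": asdict(session.design),
        "eeg_format": eeg_format,
    }
    p = out_dir / "session.json"
    p.write_text(json.dumps(meta, indent=1, sort_keys=True))
    written.append(p)
    if session.recording is not None:
        if eeg_format == "edf":
            p = out_dir / "eeg.edf"
            write_edf(session.recording, p)
            written.append(p)
        elif eeg_format == "brainvision":
            write_brainvision(session.recording, out_dir / "eeg.vhdr")
            written += [out_dir / f"eeg{s}" for s in (".vhdr", ".vmrk", ".eeg")]
        else:
            raise ValueError(f"unknown eeg_format {eeg_format!r}")
    return written
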