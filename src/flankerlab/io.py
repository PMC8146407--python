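"""On-disk formats: BrainVision EEG, delimited fNIRS series, sidecars.

The BrainVision triplet (.vhdr header, .vmrk markers, .eeg binary data)
is written and read natively: multiplexed orientation, INT_16 (with
per-channel resolution) or IEEE_FLOAT_32 binary formats, stimulus
markers as ``S<code>`` with 1-based sample positions.  fNIRS intensity
series go to tab-separated text with a channel-map sidecar.
"""

from __future__ import annotations

import json
import os
import re

import numpy as np
import pandas as pd

from .eeg import ContinuousEEG
from .fnirs import FNIRS_REGIONS, OpticalSeries

__all__ = [
    "write_brainvision",
    "read_brainvision",
    "write_fnirs_series",
    "read_fnirs_series",
    "write_ground_truth",
]


def write_brainvision(eeg: ContinuousEEG, vhdr_path: str,
                      binary_format: str = "IEEE_FLOAT_32",
                      resolution_uv: float = 0.1) -> None:
    """Write a BrainVision triplet next to ``vhdr_path``.

    ``resolution_uv`` applies to INT_16 only (stored value x resolution
    = microvolt); float data are stored in microvolt directly.
    """
    base = os.path.splitext(os.path.basename(vhdr_path))[0]
    root = os.path.dirname(os.path.abspath(vhdr_path))
    eeg_name, vmrk_name = base + ".eeg", base + ".vmrk"

    if binary_format == "IEEE_FLOAT_32":
        raw = eeg.data.astype("<f4")
        res = 1.0
    elif binary_format == "INT_16":
        res = resolution_uv
        raw = np.clip(np.round(eeg.data / res), -32768, 32767).astype("<i2")
    else:
        raise ValueError(f"unsupported binary format {binary_format!r}")
    raw.T.reshape(-1).tofile(os.path.join(root, eeg_name))  # multiplexed

    sampling_interval_us = 1e6 / eeg.sfreq
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "; Written by flankerlab",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg_name}",
        f"MarkerFile={vmrk_name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={len(eeg.channels)}",
        f"SamplingInterval={sampling_interval_us:g}",
        "",
        "[Binary Infos]",
        f"BinaryFormat={binary_format}",
        "",
        "[Channel Infos]",
    ]
    for k, ch in enumerate(eeg.channels, start=1):
        lines.append(f"Ch{k}={ch},,{res:g},µV")
    with open(vhdr_path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")

    mlines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg_name}",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,00000000000000000000",
    ]
    for k, (sample, code, _label) in enumerate(eeg.events, start=2):
        mlines.append(f"Mk{k}=Stimulus,S{code:>3d},{sample + 1},1,0")
    with open(os.path.join(root, vmrk_name), "w", encoding="utf-8") as fh:
        fh.write("\n".join(mlines) + "\n")


def _parse_ini(path: str) -> dict[str, dict[str, str]]:
    sections: dict[str, dict[str, str]] = {}
    current = None
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(";"):
                continue
            if line.startswith("[") and line.endswith("]"):
                current = line[1:-1]
                sections[current] = {}
            elif "=" in line and current is not None:
                key, val = line.split("=", 1)
                sections[current][key.strip()] = val.strip()
    return sections


def read_brainvision(vhdr_path: str) -> ContinuousEEG:
    """Read a BrainVision triplet (multiplexed INT_16 / IEEE_FLOAT_32)."""
    root = os.path.dirname(os.path.abspath(vhdr_path))
    hdr = _parse_ini(vhdr_path)
    common = hdr.get("Common Infos", {})
    if common.get("DataOrientation", "MULTIPLEXED").upper() != "MULTIPLEXED":
        raise ValueError("only multiplexed orientation is supported")
    n_ch = int(common["NumberOfChannels"])
    sfreq = 1e6 / float(common["SamplingInterval"])
    fmt = hdr.get("Binary Infos", {}).get("BinaryFormat", "IEEE_FLOAT_32")

    channels, resolutions = [], []
    for k in range(1, n_ch + 1):
        entry = hdr["Channel Infos"][f"Ch{k}"]
        parts = entry.split(",")
        channels.append(parts[0])
        resolutions.append(float(parts[2]) if len(parts) > 2 and parts[2] else 1.0)

    data_path = os.path.join(root, common["DataFile"])
    if not os.path.exists(data_path):
        raise FileNotFoundError(f"missing data file {data_path}")
    if fmt == "IEEE_FLOAT_32":
        raw = np.fromfile(data_path, dtype="<f4")
    elif fmt == "INT_16":
        raw = np.fromfile(data_path, dtype="<i2")
    else:
        raise ValueError(f"unsupported binary format {fmt!r}")
    if raw.size % n_ch:
        raise ValueError(
            f"truncated data file: {raw.size} values is not a multiple of "
            f"{n_ch} channels")
    data = raw.reshape(-1, n_ch).T.astype(np.float32)
    data *= np.asarray(resolutions, dtype=np.float32)[:, None]

    events = []
    vmrk = os.path.join(root, common.get("MarkerFile", ""))
    if common.get("MarkerFile") and os.path.exists(vmrk):
        mk = _parse_ini(vmrk).get("Marker Infos", {})
        for key in sorted(mk, key=lambda k: int(k[2:])):
            parts = mk[key].split(",")
            if parts[0] != "Stimulus":
                continue
            m = re.match(r"S\s*(\d+)", parts[1])
            if not m:
                continue
            events.append((int(parts[2]) - 1, int(m.group(1)), parts[1].strip()))
    elif common.get("MarkerFile"):
        raise FileNotFoundError(f"missing marker file {vmrk}")
    return ContinuousEEG(tuple(channels), sfreq, data, events)


def write_fnirs_series(optical: OpticalSeries, path: str) -> None:
    """Tab-separated intensities (one column per channel x wavelength)
    plus a channel-map sidecar ``<path>.channels.tsv`` and block onsets
    in ``<path>.blocks.tsv``."""
    t = np.arange(optical.n_samples) / optical.sfreq
    cols = {"time_s": t}
    for ci, ch in enumerate(optical.channels):
        for wi, wl in enumerate(optical.wavelengths):
            cols[f"{ch}@{wl}"] = optical.data[ci, wi]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.8g")

    rows = [{"channel": ch,
             "region": FNIRS_REGIONS.get(ch, ("unknown", ""))[0],
             "hemisphere": FNIRS_REGIONS.get(ch, ("", "unknown"))[1],
             "distance_cm": optical.distance_cm}
            for ch in optical.channels]
    pd.DataFrame(rows).to_csv(path + ".channels.tsv", sep="\t", index=False)
    pd.DataFrame(optical.block_onsets, columns=["onset_s", "block_type"]).to_csv(
        path + ".blocks.tsv", sep="\t", index=False)


def read_fnirs_series(path: str, sfreq: float | None = None) -> OpticalSeries:
    df = pd.read_csv(path, sep="\t")
    t = df["time_s"].to_numpy()
    if sfreq is None:
        sfreq = 1.0 / np.median(np.diff(t))
    names = [c for c in df.columns if "@" in c]
    channels = list(dict.fromkeys(c.split("@")[0] for c in names))
    wavelengths = sorted({int(c.split("@")[1]) for c in names})
    data = np.stack([
        np.stack([df[f"{ch}@{wl}"].to_numpy() for wl in wavelengths])
        for ch in channels
    ])
    blocks = []
    bpath = path + ".blocks.tsv"
    if os.path.exists(bpath):
        bdf = pd.read_csv(bpath, sep="\t")
        blocks = list(bdf.itertuples(index=False, name=None))
    dist = 3.5
    cpath = path + ".channels.tsv"
    if os.path.exists(cpath):
        cdf = pd.read_csv(cpath, sep="\t")
        if "distance_cm" in cdf:
            dist = float(cdf["distance_cm"].iloc[0])
    return OpticalSeries(tuple(channels), float(sfreq), data, kind="intensity",
                         wavelengths=tuple(wavelengths), distance_cm=dist,
                         block_onsets=blocks)


def write_ground_truth(truth, path: str) -> None:
    """Serialize a SubjectTruth (or any dataclass-like) to JSON."""
    def _convert(x):
        if isinstance(x, np.ndarray):
            return x.tolist()
        if isinstance(x, dict):
            return {str(k): _convert(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [_convert(v) for v in x]
        if isinstance(x, (np.integer, np.floating)):
            return x.item()
        return x
    payload = _convert(vars(truth))
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
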