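"""Spectrum interchange format (versioned) and truth-table I/O.

Text form: a CSV whose first line is a ``#``-prefixed JSON header carrying
axis metadata, followed by one row per transient
(``transient_index, edit_label, s0, s1, ...`` with real spectral samples).
Binary form: an HDF5 container with identical field names.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .spectra_sim import AcquisitionConfig, SpectralAcquisition

FORMAT_VERSION = 1

_HEADER_FIELDS = (
    "n_points",
    "spectral_width",
    "transmitter_freq",
    "reference_ppm",
)


def _header(acq: SpectralAcquisition) -> dict:
    cfg = acq.config
    return {
        "format": "stereomrs-spectra",
        "version": FORMAT_VERSION,
        **{k: getattr(cfg, k) for k in _HEADER_FIELDS},
        "n_transients": int(acq.transients.shape[0]),
    }


def _acq_from(header: dict, data: np.ndarray, labels: np.ndarray) -> SpectralAcquisition:
    cfg = AcquisitionConfig(
        n_transients=int(data.shape[0]),
        n_points=int(header["n_points"]),
        spectral_width=float(header["spectral_width"]),
        transmitter_freq=float(header["transmitter_freq"]),
        reference_ppm=float(header["reference_ppm"]),
    )
    return SpectralAcquisition(np.asarray(data, float), np.asarray(labels), cfg)


def write_spectra_csv(acq: SpectralAcquisition, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(_header(acq)) + "\n")
        fh.write(
            "transient_index,edit_label,"
            + ",".join(f"s{i}" for i in range(acq.transients.shape[1]))
            + "\n"
        )
        for i, (lab, row) in enumerate(zip(acq.edit_labels, acq.transients)):
            fh.write(f"{i},{lab}," + ",".join(f"{v:.8g}" for v in row) + "\n")


def read_spectra_csv(path: str | Path) -> SpectralAcquisition:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise ValueError(f"{path}: missing JSON header line")
        header = json.loads(first.lstrip("# "))
        if header.get("format") != "stereomrs-spectra":
            raise ValueError(f"{path}: not a stereomrs spectra file")
        df = pd.read_csv(fh)
    labels = df["edit_label"].to_numpy()
    data = df.drop(columns=["transient_index", "edit_label"]).to_numpy(float)
    return _acq_from(header, data, labels)


def write_spectra_h5(acq: SpectralAcquisition, path: str | Path) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("transients", data=acq.transients)
        h5.create_dataset(
            "edit_label", data=np.asarray(acq.edit_labels, dtype="S3")
        )
        for k, v in _header(acq).items():
            h5.attrs[k] = v


def read_spectra_h5(path: str | Path) -> SpectralAcquisition:
    with h5py.File(path, "r") as h5:
        header = dict(h5.attrs)
        if header.get("format") != "stereomrs-spectra":
            raise ValueError(f"{path}: not a stereomrs spectra file")
        data = h5["transients"][...]
        labels = h5["edit_label"][...].astype(str)
    return _acq_from(header, data, labels)


def write_truth_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_truth_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
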