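"""File-format adapters: TIFF image stacks with JSON sidecars, CSV/JSON
decay histograms, CSV spectra and tables, FASTA sequences, XYZ snapshots.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd
import tifffile
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cellquant import CellImageStack
from .flim import DecayHistogram
from .fretspec import EmissionSpectrum

CHANNEL_ORDER = ("DxDm", "DxAm", "AxAm")


def write_stack_tiff(stack: CellImageStack, path) -> None:
    """Multi-page float32 TIFF (pages DxDm, DxAm, AxAm [, lifetime]) with a
    JSON sidecar recording channel order and pixel size."""
    path = Path(path)
    pages = [getattr(stack, ch).astype(np.float32) for ch in CHANNEL_ORDER]
    channels = list(CHANNEL_ORDER)
    if stack.lifetime is not None:
        pages.append(stack.lifetime.astype(np.float32))
        channels.append("lifetime")
    tifffile.imwrite(path, np.stack(pages))
    sidecar = {
        "channels": channels,
        "pixel_size_um": stack.pixel_size,
        "z_planes": stack.z_planes,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_stack_tiff(path) -> CellImageStack:
    path = Path(path)
    pages = tifffile.imread(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    channels = dict(zip(sidecar["channels"], pages))
    return CellImageStack(
        DxDm=channels["DxDm"],
        DxAm=channels["DxAm"],
        AxAm=channels["AxAm"],
        lifetime=channels.get("lifetime"),
        pixel_size=sidecar.get("pixel_size_um", 1.0),
        z_planes=sidecar.get("z_planes", 1),
    )


def write_decay_csv(decay: DecayHistogram, path) -> None:
    df = pd.DataFrame({"bin_center_ns": decay.bin_centers, "counts": decay.counts})
    header = f"# rep_period_ns={decay.rep_period} irf_sigma_ns={decay.irf_sigma}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def read_decay_csv(path) -> DecayHistogram:
    with open(path) as fh:
        meta = fh.readline().lstrip("# ").split()
        kv = dict(item.split("=") for item in meta)
        df = pd.read_csv(fh)
    return DecayHistogram(
        bin_centers=df["bin_center_ns"].to_numpy(),
        counts=df["counts"].to_numpy(),
        rep_period=float(kv["rep_period_ns"]),
        irf_sigma=float(kv.get("irf_sigma_ns", 0.0)),
    )


def write_spectrum_csv(spec: EmissionSpectrum, path) -> None:
    pd.DataFrame(
        {"wavelength_nm": spec.wavelengths, "intensity": spec.intensities}
    ).to_csv(path, index=False)


def read_spectrum_csv(path) -> EmissionSpectrum:
    df = pd.read_csv(path)
    return EmissionSpectrum(
        wavelengths=df["wavelength_nm"].to_numpy(),
        intensities=df["intensity"].to_numpy(),
    )


def read_sequences(path) -> dict:
    """FASTA file -> {id: sequence} (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_sequences(sequences: dict, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_xyz(coords_list: List[np.ndarray], path, comment: str = "") -> None:
    """Bead coordinates as a multi-frame XYZ file (element CA per bead)."""
    with open(path, "w") as fh:
        for coords in coords_list:
            fh.write(f"{len(coords)}\n{comment}\n")
            for x, y, z in coords:
                fh.write(f"CA {x:.4f} {y:.4f} {z:.4f}\n")
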