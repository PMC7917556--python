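"""Reading and writing recording bundles.

A whole experiment round-trips through one HDF5 file:

    /channels/<name>/sweep<k>/movie        (n_planes, n_frames, rows, cols)
    /channels/<name>/sweep<k>/timestamps_s
    /protocols                              (JSON attr per channel)
    /ephys/sweep<k>/{time_s,command_mV,current_pA,cm_fF}
    /ground_truth                           (JSON string dataset)

Movies can also be exported as multi-page TIFF, one file per channel per
plane, and label images as 16-bit TIFF.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .protocols import VoltageProtocol
from .synthgen import (EphysSweep, EphysTraces, GroundTruthSet,
                       RecordingBundle, Sweep)


def save_bundle(bundle: RecordingBundle, path) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["pixel_size_nm"] = bundle.pixel_size_nm
        f.attrs["plane_spacing_um"] = bundle.plane_spacing_um
        ch_grp = f.create_group("channels")
        for name, sweeps in bundle.channels.items():
            g = ch_grp.create_group(name)
            for k, sw in enumerate(sweeps):
                sg = g.create_group(f"sweep{k:03d}")
                sg.create_dataset("movie", data=sw.movie,
                                  compression="gzip", compression_opts=1)
                sg.create_dataset("timestamps_s", data=sw.timestamps_s)
                sg.attrs["rate_hz"] = sw.rate_hz
                sg.attrs["stim_onset_index"] = sw.stim_onset_index
                sg.attrs["stim_json"] = json.dumps(sw.stim)
        prot = f.create_group("protocols")
        for name, p in bundle.protocols.items():
            prot.attrs[name] = json.dumps(p.to_dict())
        if bundle.ephys is not None:
            eg = f.create_group("ephys")
            eg.attrs["rate_hz"] = bundle.ephys.rate_hz
            eg.attrs["leak_pA"] = bundle.ephys.leak_pA
            for k, sw in enumerate(bundle.ephys.sweeps):
                sg = eg.create_group(f"sweep{k:03d}")
                sg.create_dataset("time_s", data=sw.time_s)
                sg.create_dataset("command_mV", data=sw.command_mV)
                sg.create_dataset("current_pA", data=sw.current_pA)
                if sw.cm_fF is not None:
                    sg.create_dataset("cm_fF", data=sw.cm_fF)
                sg.attrs["stim_json"] = json.dumps(sw.stim)
        if bundle.ground_truth is not None:
            f.create_dataset("ground_truth",
                             data=bundle.ground_truth.to_json())


def load_bundle(path) -> RecordingBundle:
    with h5py.File(Path(path), "r") as f:
        channels: dict[str, list[Sweep]] = {}
        for name, g in f["channels"].items():
            sweeps = []
            for key in sorted(g.keys()):
                sg = g[key]
                sweeps.append(Sweep(
                    movie=sg["movie"][...],
                    rate_hz=float(sg.attrs["rate_hz"]),
                    timestamps_s=sg["timestamps_s"][...],
                    stim_onset_index=int(sg.attrs["stim_onset_index"]),
                    stim=json.loads(sg.attrs["stim_json"])))
            channels[name] = sweeps
        protocols = {name: VoltageProtocol.from_dict(json.loads(val))
                     for name, val in f["protocols"].attrs.items()}
        ephys = None
        if "ephys" in f:
            eg = f["ephys"]
            esweeps = []
            for key in sorted(k for k in eg.keys()):
                sg = eg[key]
                esweeps.append(EphysSweep(
                    time_s=sg["time_s"][...],
                    command_mV=sg["command_mV"][...],
                    current_pA=sg["current_pA"][...],
                    cm_fF=sg["cm_fF"][...] if "cm_fF" in sg else None,
                    stim=json.loads(sg.attrs["stim_json"])))
            ephys = EphysTraces(sweeps=esweeps,
                                rate_hz=float(eg.attrs["rate_hz"]),
                                leak_pA=float(eg.attrs["leak_pA"]))
        gt = None
        if "ground_truth" in f:
            raw = f["ground_truth"][()]
            if isinstance(raw, bytes):
                raw = raw.decode()
            gt = GroundTruthSet.from_json(raw)
        return RecordingBundle(
            channels=channels, protocols=protocols, ephys=ephys,
            pixel_size_nm=float(f.attrs["pixel_size_nm"]),
            plane_spacing_um=float(f.attrs["plane_spacing_um"]),
            ground_truth=gt)


def export_tiff(bundle: RecordingBundle, out_dir) -> list[Path]:
    """Write each channel/plane as a multi-page TIFF (frames concatenated
    across sweeps).  Returns the written paths."""
    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, sweeps in bundle.channels.items():
        n_planes = sweeps[0].movie.shape[0]
        for p in range(n_planes):
            stack = np.concatenate([sw.movie[p] for sw in sweeps], axis=0)
            path = out_dir / f"{name}_plane{p}.tif"
            tifffile.imwrite(path, stack.astype(np.float32))
            written.append(path)
    return written


def write_label_tiff(label_image: np.ndarray, path) -> None:
    import tifffile

    tifffile.imwrite(Path(path), label_image.astype(np.uint16))
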