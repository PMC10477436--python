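"""Reading and writing recordings and configs.

Two on-disk forms are supported:

* a two-column CSV (``time_s, amplitude``) with a JSON sidecar
  (``<stem>.json``) carrying the sampling rate, labels and provenance —
  samples are written at full precision (%.17g) so they round-trip
  bit-equal;
* an HDF5 container with the hierarchy
  ``/<group>/<nerve>/<condition>/animal_NN`` and ``fs`` / label / seed
  attributes on each dataset.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np

from .errors import FormatError
from .simulate import (
    CarrierPeak,
    EnvelopeComponent,
    GeneratorConfig,
    Labels,
    Recording,
)


def write_recording_csv(recording: Recording, path: str | Path) -> Path:
    path = Path(path)
    t = np.arange(len(recording.samples)) / recording.fs
    with open(path, "w") as fh:
        fh.write("time_s,amplitude\n")
        for ti, xi in zip(t, recording.samples):
            fh.write(f"{ti:.17g},{xi:.17g}\n")
    meta = {
        "fs": recording.fs,
        "labels": dataclasses.asdict(recording.labels),
        "provenance": recording.provenance,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def read_recording_csv(path: str | Path) -> Recording:
    path = Path(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FormatError(f"missing metadata sidecar {sidecar.name} (required field: fs)")
    meta = json.loads(sidecar.read_text())
    if "fs" not in meta:
        raise FormatError(f"{sidecar.name} is missing the 'fs' field")
    if "labels" not in meta:
        raise FormatError(f"{sidecar.name} is missing the 'labels' field")
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    samples = np.atleast_2d(data)[:, 1]
    return Recording(
        samples,
        float(meta["fs"]),
        Labels(**meta["labels"]),
        provenance=meta.get("provenance", str(path)),
    )


def write_recordings_h5(recordings: list[Recording], path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as h5:
        for rec in recordings:
            lab = rec.labels
            grp = h5.require_group(f"{lab.group}/{lab.nerve}/{lab.condition}")
            ds = grp.create_dataset(f"animal_{lab.animal_id:02d}", data=rec.samples)
            ds.attrs["fs"] = rec.fs
            ds.attrs["animal_id"] = lab.animal_id
            ds.attrs["provenance"] = rec.provenance
    return path


def read_recordings_h5(path: str | Path) -> list[Recording]:
    out = []
    with h5py.File(path, "r") as h5:
        for group in h5:
            for nerve in h5[group]:
                for condition in h5[group][nerve]:
                    node = h5[group][nerve][condition]
                    for name in node:
                        ds = node[name]
                        if "fs" not in ds.attrs:
                            raise FormatError(
                                f"dataset /{group}/{nerve}/{condition}/{name} "
                                "is missing the 'fs' attribute"
                            )
                        out.append(
                            Recording(
                                ds[()],
                                float(ds.attrs["fs"]),
                                Labels(group, nerve, condition, int(ds.attrs.get("animal_id", 0))),
                                provenance=str(ds.attrs.get("provenance", str(path))),
                            )
                        )
    return out


def load_recordings(paths: list[str | Path]) -> list[Recording]:
    """Load a mixed list of CSV and HDF5 recording files."""
    out = []
    for p in paths:
        p = Path(p)
        if p.suffix in (".h5", ".hdf5"):
            out.extend(read_recordings_h5(p))
        elif p.suffix == ".csv":
            out.append(read_recording_csv(p))
        else:
            raise FormatError(f"unsupported recording format: {p.name}")
    return out


def config_to_json(config: GeneratorConfig, path: str | Path | None = None) -> str:
    text = json.dumps(dataclasses.asdict(config), indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def config_from_json(source: str | Path) -> GeneratorConfig:
    if isinstance(source, Path) or not str(source).lstrip().startswith("{"):
        payload = json.loads(Path(source).read_text())
    else:
        payload = json.loads(str(source))
    payload["envelope_components"] = tuple(
        EnvelopeComponent(**c) for c in payload.get("envelope_components", ())
    )
    payload["carrier_peaks"] = tuple(CarrierPeak(**c) for c in payload.get("carrier_peaks", ()))
    return GeneratorConfig(**payload)
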