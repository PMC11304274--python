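"""File formats, configuration and run manifests.

Spectra travel either as delimited text (two columns: frequency in Hz and
intensity, '#'-prefixed metadata header) or inside an HDF5 container;
datasets of training pairs are stored in HDF5 with input/label matrices and
per-pair metadata.  A minimal JCAMP-DX importer covers the plain AFFN
``(X++(Y..Y))`` dialect used for externally processed 1D real spectra.
Every CLI run writes a JSON manifest with the resolved configuration, master
seed and file digests so it can be replayed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

from .simkit import (
    Dataset,
    NUSSchedule,
    PeakParams,
    PeakSet,
    SimConfig,
    Spectrum1D,
    TrainingPair,
)

__all__ = [
    "save_spectrum",
    "load_spectrum",
    "load_jcampdx",
    "save_dataset",
    "load_dataset",
    "export_dataset_text",
    "RunManifest",
    "load_config",
    "spawn_seeds",
]


class ParseError(ValueError):
    """Malformed spectrum or dataset file."""


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

def save_spectrum(path: str | Path, spectrum: Spectrum1D) -> None:
    """Write a spectrum; dialect chosen by extension (.h5/.hdf5 binary,
    anything else delimited text)."""
    path = Path(path)
    if path.suffix.lower() in {".h5", ".hdf5"}:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("values", data=spectrum.values)
            fh.create_dataset("axis_hz", data=spectrum.axis_hz)
            fh.attrs["norm_factor"] = spectrum.norm_factor
    else:
        with open(path, "w") as fh:
            fh.write(f"# norm_factor\t{float(spectrum.norm_factor)!r}\n")
            fh.write("# axis_hz\tvalue\n")
            for a, v in zip(spectrum.axis_hz.tolist(), spectrum.values.tolist()):
                fh.write(f"{a!r}\t{v!r}\n")


def load_spectrum(path: str | Path) -> Spectrum1D:
    """Read a spectrum written by :func:`save_spectrum` (lossless)."""
    path = Path(path)
    if path.suffix.lower() in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as fh:
            return Spectrum1D(
                values=fh["values"][:],
                axis_hz=fh["axis_hz"][:],
                norm_factor=float(fh.attrs["norm_factor"]),
            )
    axis, values, norm = [], [], 1.0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split("\t")
                if parts and parts[0].strip() == "norm_factor":
                    norm = float(parts[1])
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 fields, got "
                                 f"{len(parts)}")
            try:
                axis.append(float(parts[0]))
                values.append(float(parts[1]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    if not values:
        raise ParseError(f"{path}: no data rows")
    return Spectrum1D(values=np.array(values), axis_hz=np.array(axis),
                      norm_factor=norm)


def load_jcampdx(path: str | Path) -> Spectrum1D:
    """Import a 1D real spectrum from a simple JCAMP-DX file.

    Supports the uncompressed AFFN ``##XYDATA=(X++(Y..Y))`` form with
    ##FIRSTX/##LASTX/##NPOINTS/##YFACTOR records; squeezed/packed/difference
    duplicate encodings are out of scope.
    """
    path = Path(path)
    records: dict[str, str] = {}
    y: list[float] = []
    in_data = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("$$"):
                continue
            if line.startswith("##"):
                key, _, val = line[2:].partition("=")
                key = key.strip().upper().replace(" ", "")
                records[key] = val.strip()
                if key == "XYDATA":
                    in_data = True
                elif key == "END":
                    in_data = False
                continue
            if in_data:
                try:
                    nums = [float(tok) for tok in line.replace(",", " ").split()]
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: {exc}") from None
                y.extend(nums[1:])        # first number per line is X
    if not y:
        raise ParseError(f"{path}: no XYDATA points found")
    try:
        first_x = float(records["FIRSTX"])
        last_x = float(records["LASTX"])
        npoints = int(float(records["NPOINTS"]))
    except KeyError as exc:
        raise ParseError(f"{path}: missing JCAMP record {exc}") from None
    yfactor = float(records.get("YFACTOR", "1"))
    if len(y) != npoints:
        raise ParseError(f"{path}: NPOINTS={npoints} but {len(y)} Y values")
    values = np.array(y) * yfactor
    axis = np.linspace(first_x, last_x, npoints)
    norm = float(np.max(np.abs(values)))
    if norm > 0:
        values = values / norm
    return Spectrum1D(values=values, axis_hz=axis, norm_factor=norm)


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------

def save_dataset(path: str | Path, dataset: Dataset) -> None:
    """Write inputs, labels and per-pair metadata to one HDF5 file."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("inputs", data=dataset.inputs)
        fh.create_dataset("labels", data=dataset.labels)
        fh.attrs["seed"] = dataset.seed
        fh.attrs["config_json"] = json.dumps(dataset.config.to_dict())
        meta = fh.create_group("pairs")
        for i, pair in enumerate(dataset.pairs):
            g = meta.create_group(str(i))
            g.create_dataset("schedule", data=np.array(pair.schedule.sampled))
            g.attrs["n_chunks"] = pair.schedule.n_chunks
            g.attrs["sigma"] = pair.sigma
            peak_table = np.array(
                [(p.freq_hz, p.amplitude, p.lw_hz, p.phase_rad)
                 for p in pair.peaks]
            )
            g.create_dataset("peaks", data=peak_table)


def load_dataset(path: str | Path) -> Dataset:
    with h5py.File(path, "r") as fh:
        config = SimConfig.from_dict(json.loads(fh.attrs["config_json"]))
        seed = int(fh.attrs["seed"])
        inputs = fh["inputs"][:]
        labels = fh["labels"][:]
        axis = np.fft.fftshift(
            np.fft.fftfreq(config.acq.n_ft, d=config.acq.dwell_s)
        )
        pairs = []
        for i in range(inputs.shape[0]):
            g = fh["pairs"][str(i)]
            schedule = NUSSchedule(
                sampled=tuple(int(v) for v in g["schedule"][:]),
                n_chunks=int(g.attrs["n_chunks"]),
            )
            peaks = PeakSet(tuple(
                PeakParams(freq_hz=row[0], amplitude=row[1], lw_hz=row[2],
                           phase_rad=row[3])
                for row in g["peaks"][:]
            ))
            pairs.append(TrainingPair(
                input=Spectrum1D(inputs[i].astype(np.float64), axis),
                label=Spectrum1D(labels[i].astype(np.float64), axis),
                schedule=schedule,
                peaks=peaks,
                sigma=float(g.attrs["sigma"]),
                seed=i,
            ))
    return Dataset(inputs=inputs, labels=labels, pairs=pairs, config=config,
                   seed=seed)


def export_dataset_text(path: str | Path, dataset: Dataset,
                        which: str = "inputs") -> None:
    """Delimited-text interchange export: one spectrum per row."""
    matrix = getattr(dataset, which)
    np.savetxt(path, matrix, delimiter="\t")


# ---------------------------------------------------------------------------
# manifests, config, seeds
# ---------------------------------------------------------------------------

def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record written once per CLI run."""

    command: str
    config: dict
    master_seed: int
    started: str = ""
    finished: str = ""
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)

    def add_input(self, path: str | Path) -> None:
        self.inputs[str(path)] = _digest(Path(path))

    def add_output(self, path: str | Path) -> None:
        self.outputs[str(path)] = _digest(Path(path))

    def write(self, path: str | Path) -> None:
        self.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)

    @classmethod
    def start(cls, command: str, config: dict, master_seed: int) -> "RunManifest":
        return cls(command=command, config=config, master_seed=master_seed,
                   started=time.strftime("%Y-%m-%dT%H:%M:%S"))


def load_config(path: str | Path) -> dict:
    """Read a YAML key-value configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Fan a master seed out into independent per-stage child seeds."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]
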