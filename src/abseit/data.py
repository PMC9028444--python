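"""Dataset generation pipeline and the HDF5 interchange format.

One generated sample is (voltage frame, impedance map, ground-truth raster)
for a random phantom; optional augmentation expands each simulated sample
into its 16 rotations and perturbs the maps with the three measurement-noise
models.  Everything is reproducible from the manifest seeds.

HDF5 layout::

    /samples/frame   (N, 208)   float64
    /samples/eim     (N, 16, 16)
    /samples/target  (N, 64, 64)
    attrs: schema_version, n_phantoms, seed, config (YAML)
"""

from __future__ import annotations

import os
import tempfile
import warnings
from dataclasses import asdict, dataclass

import h5py
import numpy as np
import yaml

from .augment import (QUANTIZATION_STD, THERMAL_JITTER_STD, Sample,
                      apply_channel_gain, apply_quantization,
                      apply_thermal_jitter, expand_rotations)
from .eim import build_eim
from .forward import ElectrodeModel, sample_contact_impedance, simulate_voltages
from .mesh import build_mesh
from .phantom import build_phantom, rasterize_target, sample_phantom_spec

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the dataset generator; defaults are the stated world."""

    n_phantoms: int = 100
    radius: float = 28.0
    n_rings: int = 14
    n_enclosures: tuple = (1, 4)
    rotation_expand: bool = True
    thermal_jitter_std: float = THERMAL_JITTER_STD
    quantization_std: float = QUANTIZATION_STD
    channel_gain_std: float = 0.0     # off by default; enable per experiment
    grid_size: int = 64


def generate_samples(config: SimConfig, seed: int = 0) -> list:
    """Simulate ``n_phantoms`` random phantoms and augment per config."""
    rng = np.random.default_rng(seed)
    mesh = build_mesh(config.radius, config.n_rings)
    base = ElectrodeModel().contact_impedance[0]
    out = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # off-slice enclosures are expected
        for i in range(config.n_phantoms):
            spec = sample_phantom_spec(rng, config.radius, config.n_enclosures)
            phantom = build_phantom(mesh, spec, rng)
            z = sample_contact_impedance(rng, base, spec.contact_std)
            frame = simulate_voltages(mesh, phantom.sigma,
                                      ElectrodeModel(contact_impedance=z),
                                      meta={"phantom": i})
            sample = Sample(eim=build_eim(frame),
                            target=rasterize_target(phantom,
                                                    grid_size=config.grid_size),
                            provenance={"phantom": i})
            group = expand_rotations(sample) if config.rotation_expand else [sample]
            for s in group:
                e = s.eim
                if config.thermal_jitter_std:
                    e = apply_thermal_jitter(e, config.thermal_jitter_std, rng)
                if config.quantization_std:
                    e = apply_quantization(e, config.quantization_std, rng)
                if config.channel_gain_std:
                    e = apply_channel_gain(e, config.channel_gain_std, rng)
                out.append(Sample(eim=e, target=s.target,
                                  provenance=s.provenance))
    return out


def samples_to_arrays(samples: list) -> tuple:
    """(eims (N, 16, 16), targets (N, 64, 64)) float arrays."""
    eims = np.stack([s.eim for s in samples])
    targets = np.stack([s.target for s in samples])
    return eims, targets


def save_dataset(path: str, samples: list, config: SimConfig,
                 seed: int) -> None:
    """Atomic HDF5 write (temp file + rename; never a half-written dataset)."""
    from .eim import flatten_eim

    eims, targets = samples_to_arrays(samples)
    # frames recovered from the (possibly noise-augmented) maps
    frames = np.stack([flatten_eim(s.eim).values for s in samples])
    d = os.path.dirname(os.path.abspath(path)) or "."
    os.makedirs(d, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".h5.tmp")
    os.close(fd)
    try:
        with h5py.File(tmp, "w") as f:
            g = f.create_group("samples")
            g.create_dataset("frame", data=frames, chunks=(1, 208))
            g.create_dataset("eim", data=eims, chunks=(1, 16, 16))
            g.create_dataset("target", data=targets, chunks=(1, 64, 64))
            f.attrs["schema_version"] = SCHEMA_VERSION
            f.attrs["n_phantoms"] = config.n_phantoms
            f.attrs["n_samples"] = len(samples)
            f.attrs["seed"] = seed
            f.attrs["config"] = yaml.safe_dump(asdict(config))
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def load_dataset(path: str) -> dict:
    """Read a dataset back: arrays plus the manifest attributes."""
    with h5py.File(path, "r") as f:
        out = {
            "frame": f["samples/frame"][:],
            "eim": f["samples/eim"][:],
            "target": f["samples/target"][:],
            "manifest": dict(f.attrs),
        }
    if out["manifest"].get("schema_version") != SCHEMA_VERSION:
        raise ValueError("unsupported dataset schema version")
    return out


def smoke_dataset(n_phantoms: int = 32, seed: int = 0,
                  n_rings: int = 10) -> tuple:
    """Small single-enclosure training set for CPU smoke training.

    Uses the standard sampling distributions but one enclosure per phantom
    and a coarser mesh, and relies on rotation expansion for most of the
    sample count (n_phantoms FEM solves -> 16 * n_phantoms samples).
    """
    cfg = SimConfig(n_phantoms=n_phantoms, n_rings=n_rings,
                    n_enclosures=(1, 1), rotation_expand=True)
    return samples_to_arrays(generate_samples(cfg, seed))
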