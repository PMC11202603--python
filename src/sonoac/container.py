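"""HDF5 dataset container: phantoms, acquisitions and split assignments.

Layout (format version 1):

    /meta                attrs: format_version, master_seed, config_hash
    /phantoms/<id>/      datasets sos, ac, density, label, scatterers
                         attrs: seed, liver_ac_truth, cell_size
    /acq/<id>/           datasets rf, env, bmode  (optional per record)
    /records             datasets envelopes, bmodes, targets, ids
                         (training-ready tensors, optional)
    /splits/<name>       index arrays; names partition all record ids
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .errors import ConfigurationError, InputError
from .phantom import TissueMap
from .pipeline import PhantomDataset

__all__ = ["FORMAT_VERSION", "write_dataset", "read_dataset",
           "write_phantom", "read_phantom"]

FORMAT_VERSION = 1


def write_phantom(group: h5py.Group, tmap: TissueMap) -> None:
    for name, arr in (("sos", tmap.sos_map), ("ac", tmap.ac_map),
                      ("density", tmap.density_map), ("label", tmap.label_map),
                      ("scatterers", tmap.scatterers)):
        group.create_dataset(name, data=arr, compression="gzip", compression_opts=1)
    group.attrs["seed"] = tmap.seed
    group.attrs["liver_ac_truth"] = tmap.liver_ac_truth
    group.attrs["cell_size"] = tmap.cell_size


def read_phantom(group: h5py.Group) -> TissueMap:
    return TissueMap(
        sos_map=group["sos"][()], ac_map=group["ac"][()],
        density_map=group["density"][()], label_map=group["label"][()],
        scatterers=group["scatterers"][()],
        liver_ac_truth=float(group.attrs["liver_ac_truth"]),
        seed=int(group.attrs["seed"]), cell_size=float(group.attrs["cell_size"]),
    )


def write_dataset(path: str | Path, dataset: PhantomDataset,
                  master_seed: int = 0, config_hash: str = "") -> None:
    """Lossless serialization of a training-ready dataset."""
    with h5py.File(path, "w") as f:
        meta = f.create_group("meta")
        meta.attrs["format_version"] = FORMAT_VERSION
        meta.attrs["master_seed"] = master_seed
        meta.attrs["config_hash"] = config_hash
        rec = f.create_group("records")
        rec.create_dataset("envelopes", data=dataset.envelopes,
                           compression="gzip", compression_opts=1)
        rec.create_dataset("bmodes", data=dataset.bmodes,
                           compression="gzip", compression_opts=1)
        rec.create_dataset("targets", data=dataset.targets)
        rec.create_dataset("ids", data=dataset.ids)
        spl = f.create_group("splits")
        for name, idx in dataset.splits.items():
            spl.create_dataset(name, data=np.asarray(idx, dtype=np.int64))


def read_dataset(path: str | Path) -> PhantomDataset:
    """Read a container back; verifies version and that splits partition ids."""
    with h5py.File(path, "r") as f:
        if "meta" not in f or "format_version" not in f["meta"].attrs:
            raise ConfigurationError(f"{path}: missing /meta/format_version")
        version = int(f["meta"].attrs["format_version"])
        if version != FORMAT_VERSION:
            raise ConfigurationError(
                f"{path}: container format v{version} needs migration "
                f"(supported: v{FORMAT_VERSION})")
        rec = f["records"]
        splits = {name: f["splits"][name][()] for name in f["splits"]}
        ds = PhantomDataset(
            envelopes=rec["envelopes"][()], bmodes=rec["bmodes"][()],
            targets=rec["targets"][()], ids=rec["ids"][()], splits=splits,
            meta={"master_seed": int(f["meta"].attrs["master_seed"]),
                  "config_hash": str(f["meta"].attrs["config_hash"])},
        )
    all_idx = np.sort(np.concatenate(list(ds.splits.values())))
    if not np.array_equal(all_idx, np.arange(len(ds.ids))):
        raise InputError(f"{path}: split ids do not partition the records")
    return ds
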