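"""Serialization of solved policies to HDF5.

A policy container holds datasets ``times``, ``V``, ``A`` and ``margin``,
plus the full solver configuration embedded as a JSON attribute with a
content hash, so a loaded policy can be traced back to exactly the inputs
that produced it.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .config import bellman_from_dict, bellman_to_dict, config_digest
from .policy import PolicyGrid

__all__ = ["save_policy", "load_policy", "SCHEMA_VERSION"]

SCHEMA_VERSION = 1


def save_policy(p: PolicyGrid, path) -> None:
    cfg_dict = bellman_to_dict(p.config)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["config"] = json.dumps(cfg_dict, sort_keys=True)
        f.attrs["config_sha256"] = config_digest(cfg_dict)
        if p.rho is not None:
            f.attrs["rho"] = p.rho
        f.create_dataset("times", data=p.times)
        f.create_dataset("V", data=p.values, compression="gzip", compression_opts=4)
        f.create_dataset("A", data=p.actions, compression="gzip", compression_opts=4)
        f.create_dataset("margin", data=p.margin, compression="gzip", compression_opts=4)


def load_policy(path) -> PolicyGrid:
    path = Path(path)
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise IOError(
                f"policy container schema version {version} does not match "
                f"supported version {SCHEMA_VERSION}"
            )
        for name in ("times", "V", "A", "margin"):
            if name not in f:
                raise IOError(f"policy container is missing dataset {name!r}")
        cfg_dict = json.loads(f.attrs["config"])
        stored = str(f.attrs["config_sha256"])
        if config_digest(cfg_dict) != stored:
            raise IOError("embedded config hash mismatch: container corrupted")
        rho = float(f.attrs["rho"]) if "rho" in f.attrs else None
        return PolicyGrid(
            times=np.asarray(f["times"]),
            values=np.asarray(f["V"]),
            actions=np.asarray(f["A"], dtype=np.int8),
            margin=np.asarray(f["margin"]),
            config=bellman_from_dict(cfg_dict),
            rho=rho,
        )
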