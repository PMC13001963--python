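"""Save/load trained models as portable HDF5 archives."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np

from .agtm import AGTMNet, AgtmConfig
from .datp_core import DATPModel
from .skeleton_io import JointLayout, ModelConfig

__all__ = ["save_model", "load_model"]


def _layout_meta(layout: JointLayout) -> str:
    return json.dumps({"joint_names": list(layout.joint_names),
                       "parents": list(layout.parents)})


def save_model(model, path: str | Path) -> None:
    if isinstance(model, DATPModel):
        kind, config = "datp", model.config
        extra = {"max_len": int(model.pos.shape[0]) if model.pos is not None else 512,
                 "in_coords": model.in_coords}
    elif isinstance(model, AGTMNet):
        kind, config = "agtm", model.config
        extra = {"in_dim": int(model.wq.shape[0])}
    else:
        raise TypeError(f"cannot save {type(model).__name__}")
    with h5py.File(path, "w") as h5:
        h5.attrs["kind"] = kind
        h5.attrs["config"] = json.dumps(dataclasses.asdict(config))
        h5.attrs["layout"] = _layout_meta(model.layout)
        h5.attrs["extra"] = json.dumps(extra)
        grp = h5.create_group("state")
        for key, value in model.state_dict().items():
            grp.create_dataset(key, data=value)


def load_model(path: str | Path):
    with h5py.File(path, "r") as h5:
        kind = h5.attrs["kind"]
        cfg = json.loads(h5.attrs["config"])
        lay = json.loads(h5.attrs["layout"])
        extra = json.loads(h5.attrs["extra"])
        state = {k: np.asarray(v) for k, v in h5["state"].items()}
    layout = JointLayout(tuple(lay["joint_names"]), tuple(lay["parents"]))
    if kind == "datp":
        config = ModelConfig(**{k: (tuple(v) if isinstance(v, list) else v)
                                for k, v in cfg.items()})
        model = DATPModel(layout, config, max_len=extra["max_len"],
                          in_coords=extra["in_coords"])
    elif kind == "agtm":
        config = AgtmConfig(**{k: (tuple(v) if isinstance(v, list) else v)
                               for k, v in cfg.items()})
        model = AGTMNet(layout, config, in_dim=extra["in_dim"])
    else:
        raise ValueError(f"unknown model kind: {kind!r}")
    model.load_state_dict(state)
    return model
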