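"""Dataset and checkpoint containers (HDF5)."""
from __future__ import annotations

import json

import h5py
import numpy as np

from .diffusion import NoiseSchedule, make_schedule
from .model import EpsPredictor, ModelConfig
from .spade import SpadeConfig

__all__ = ["save_dataset", "load_dataset", "save_checkpoint",
           "load_checkpoint", "CHECKPOINT_VERSION"]

CHECKPOINT_VERSION = 1


def save_dataset(path: str, records: np.ndarray, labels: np.ndarray,
                 fs: float, lead_names) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("records", data=records)
        f.create_dataset("labels", data=labels)
        f.attrs["fs"] = float(fs)
        f.attrs["lead_names"] = json.dumps(list(lead_names))


def load_dataset(path: str) -> tuple[np.ndarray, np.ndarray, float, list[str]]:
    with h5py.File(path, "r") as f:
        records = f["records"][...]
        labels = f["labels"][...]
        fs = float(f.attrs["fs"])
        lead_names = json.loads(f.attrs["lead_names"])
    return records, labels, fs, lead_names


def _model_config_dict(cfg: ModelConfig) -> dict:
    d = dict(vars(cfg))
    d["spade"] = dict(vars(cfg.spade))
    d["diff_embed_dims"] = list(cfg.diff_embed_dims)
    return d


def _model_config_from_dict(d: dict) -> ModelConfig:
    d = dict(d)
    d["spade"] = SpadeConfig(**d["spade"])
    d["diff_embed_dims"] = tuple(d["diff_embed_dims"])
    return ModelConfig(**d)


def save_checkpoint(path: str, model: EpsPredictor, schedule: NoiseSchedule,
                    step: int, optimizer_state: dict | None = None,
                    rng_state: dict | None = None,
                    ema_state: dict | None = None,
                    extra: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["version"] = CHECKPOINT_VERSION
        f.attrs["step"] = int(step)
        f.attrs["model_config"] = json.dumps(_model_config_dict(model.cfg))
        f.attrs["schedule"] = json.dumps(
            {"T": schedule.T, "beta_start": float(schedule.beta[0]),
             "beta_end": float(schedule.beta[-1])})
        if rng_state is not None:
            f.attrs["rng_state"] = json.dumps(rng_state, default=int)
        if extra:
            f.attrs["extra"] = json.dumps(extra)
        gp = f.create_group("params")
        for name, p in model.parameters().items():
            gp.create_dataset(name, data=p.data)
        gb = f.create_group("buffers")
        for name, a in model.buffers().items():
            gb.create_dataset(name, data=a)
        if ema_state is not None:
            ge = f.create_group("ema")
            for name, a in ema_state.items():
                ge.create_dataset(name, data=a)
        if optimizer_state is not None:
            go = f.create_group("optimizer")
            go.attrs["t"] = int(optimizer_state["t"])
            gm = go.create_group("m")
            gv = go.create_group("v")
            for name in optimizer_state["m"]:
                gm.create_dataset(name, data=optimizer_state["m"][name])
                gv.create_dataset(name, data=optimizer_state["v"][name])


def load_checkpoint(path: str, prefer_ema: bool = False) -> dict:
    """Rebuild the model (and schedule) from a checkpoint file.

    prefer_ema=True loads the exponential-moving-average weights (when
    stored) into the model — the right choice for sampling; the raw weights
    remain the ones to resume training from."""
    with h5py.File(path, "r") as f:
        cfg = _model_config_from_dict(json.loads(f.attrs["model_config"]))
        model = EpsPredictor(cfg, seed=0)
        params = model.parameters()
        for name in f["params"]:
            params[name].data[...] = f["params"][name][...]
        buffers = model.buffers()
        for name in f["buffers"]:
            buffers[name][...] = f["buffers"][name][...]
        if "ema" in f and prefer_ema:
            for name in f["ema"]:
                params[name].data[...] = f["ema"][name][...]
        sched_d = json.loads(f.attrs["schedule"])
        schedule = make_schedule(sched_d["T"], sched_d["beta_start"],
                                 sched_d["beta_end"])
        out = {"model": model, "schedule": schedule,
               "step": int(f.attrs["step"])}
        if "ema" in f:
            out["ema_state"] = {n: f["ema"][n][...] for n in f["ema"]}
        if "optimizer" in f:
            go = f["optimizer"]
            out["optimizer_state"] = {
                "t": int(go.attrs["t"]),
                "m": {n: go["m"][n][...] for n in go["m"]},
                "v": {n: go["v"][n][...] for n in go["v"]},
            }
        if "rng_state" in f.attrs:
            out["rng_state"] = json.loads(f.attrs["rng_state"])
        if "extra" in f.attrs:
            out["extra"] = json.loads(f.attrs["extra"])
    return out
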