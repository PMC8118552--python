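"""Single-file HDF5 persistence for trained models.

Each archive stores the model kind, a format version, the spec, the seed,
and the full parameter state (including batch-norm running statistics), plus
gene/channel orderings where the model has them. Loading is version-checked.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np

from .autoencoder import DecoderModel, DecoderSpec, EncoderModel, EncoderSpec
from .cgan import DiscriminatorModel, DiscriminatorSpec, GeneratorModel, GeneratorSpec

__all__ = ["save_model", "load_model", "FORMAT_VERSION"]

FORMAT_VERSION = 1

_KINDS = {
    EncoderModel: ("encoder", EncoderSpec),
    DecoderModel: ("decoder", DecoderSpec),
    GeneratorModel: ("generator", GeneratorSpec),
    DiscriminatorModel: ("discriminator", DiscriminatorSpec),
}


def _net_of(model):
    return model if isinstance(model, EncoderModel) else model.net


def _state_of(model):
    if isinstance(model, EncoderModel):
        return model.get_state()
    return model.net.get_state()


def save_model(model, path, metadata: dict | None = None) -> Path:
    """Write a trained model to a single HDF5 archive."""
    kind, _ = _KINDS[type(model)]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    spec = asdict(model.spec)
    with h5py.File(path, "w") as f:
        f.attrs["kind"] = kind
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["seed"] = int(model.seed)
        f.attrs["spec"] = json.dumps(spec)
        if metadata:
            f.attrs["metadata"] = json.dumps(metadata)
        if hasattr(model, "gene_ids"):
            f.create_dataset("gene_ids", data=np.array(model.gene_ids, dtype="S"))
        if hasattr(model, "channel_ids"):
            f.create_dataset("channel_ids", data=np.array(model.channel_ids, dtype="S"))
        grp = f.create_group("state")
        for i, arr in enumerate(_state_of(model)):
            grp.create_dataset(f"a{i:04d}", data=arr)
    return path


def load_model(path):
    """Load a model archive written by :func:`save_model`."""
    with h5py.File(path, "r") as f:
        version = int(f.attrs["format_version"])
        if version != FORMAT_VERSION:
            raise ValueError(
                f"archive format version {version} unsupported (expected {FORMAT_VERSION})")
        kind = f.attrs["kind"]
        spec_dict = json.loads(f.attrs["spec"])
        seed = int(f.attrs["seed"])
        gene_ids = ([g.decode() for g in f["gene_ids"][...]]
                    if "gene_ids" in f else None)
        channel_ids = ([c.decode() for c in f["channel_ids"][...]]
                       if "channel_ids" in f else None)
        state = [f["state"][k][...] for k in sorted(f["state"])]

    for key in ("hidden_dims",):
        if key in spec_dict and isinstance(spec_dict[key], list):
            spec_dict[key] = tuple(spec_dict[key])
    if kind == "encoder":
        model = EncoderModel(EncoderSpec(**spec_dict), gene_ids, channel_ids, seed)
        model.set_state(state)
    elif kind == "decoder":
        model = DecoderModel(DecoderSpec(**spec_dict), gene_ids, seed)
        model.net.set_state(state)
    elif kind == "generator":
        model = GeneratorModel(GeneratorSpec(**spec_dict), channel_ids, seed)
        model.net.set_state(state)
    elif kind == "discriminator":
        model = DiscriminatorModel(DiscriminatorSpec(**spec_dict), seed)
        model.net.set_state(state)
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    return model
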