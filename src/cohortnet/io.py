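"""HDF5-backed serialization for tokens, streams, models and fit results."""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from cohortnet.lexicon import FRAME_RATE, Lexicon, Token
from cohortnet.linking import PredictorSet
from cohortnet.models import ModelConfig, WordRecognizer
from cohortnet.streams import Annotation, OutputCoding, Stream


def save_lexicon_table(lexicon: Lexicon, path: str) -> None:
    lexicon.to_table().to_csv(path, sep="\t", index=False)


def save_tokens(tokens: dict[tuple[int, int], Token], path: str) -> None:
    """Store tokens keyed by (word_id, talker_id) with a frame-rate attr."""
    with h5py.File(path, "w") as f:
        f.attrs["frame_rate"] = FRAME_RATE
        for (w, t), tok in tokens.items():
            f.create_dataset(f"{w}_{t}", data=tok.spectrogram)


def load_tokens(path: str) -> dict[tuple[int, int], Token]:
    out = {}
    with h5py.File(path, "r") as f:
        rate = float(f.attrs["frame_rate"])
        for key, ds in f.items():
            w, t = (int(v) for v in key.split("_"))
            out[(w, t)] = Token(w, t, ds[...], rate)
    return out


def save_stream(stream: Stream, path: str) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["frame_rate"] = stream.frame_rate
        f.create_dataset("input", data=stream.input)
        if stream.targets is not None:
            f.create_dataset("targets", data=stream.targets)
        ann = np.array(
            [(a.word_id, a.talker_id, a.onset, a.offset) for a in stream.annotations]
        )
        f.create_dataset("annotations", data=ann)


def load_stream(path: str) -> Stream:
    with h5py.File(path, "r") as f:
        ann = [Annotation(*map(int, row)) for row in f["annotations"][...]]
        targets = f["targets"][...] if "targets" in f else None
        return Stream(f["input"][...], ann, targets, float(f.attrs["frame_rate"]))


def annotations_to_bed(annotations: list[Annotation], path: str) -> None:
    """Annotations as a BED-like table in 0-based half-open frame coords."""
    pd.DataFrame(
        [(a.word_id, a.talker_id, a.onset, a.offset) for a in annotations],
        columns=["word_id", "talker_id", "onset_frame", "offset_frame"],
    ).to_csv(path, sep="\t", index=False)


def save_model(model: WordRecognizer, path: str) -> None:
    """Portable weight dump with a JSON manifest of the architecture."""
    cfg = model.config
    manifest = {
        "layer_sizes": cfg.layer_sizes,
        "input_dim": cfg.input_dim,
        "loss": cfg.loss,
        "c": cfg.c,
        "lr": cfg.lr,
        "seed": cfg.seed,
        "coding_kind": cfg.coding.kind,
        "coding_dim": cfg.coding.dim,
        "srv_k": cfg.coding.srv_k,
    }
    with h5py.File(path, "w") as f:
        f.attrs["manifest"] = json.dumps(manifest)
        for i, p in enumerate(model.parameters()):
            f.create_dataset(f"param_{i}", data=p)
        f.create_dataset("word_vectors", data=cfg.coding.word_vectors)


def load_model(path: str) -> WordRecognizer:
    with h5py.File(path, "r") as f:
        manifest = json.loads(f.attrs["manifest"])
        vecs = f["word_vectors"][...]
        coding = OutputCoding(
            manifest["coding_kind"], manifest["coding_dim"], vecs,
            srv_k=manifest["srv_k"],
        )
        if coding.kind == "srv":
            elements = {w: np.flatnonzero(vecs[w]) for w in range(vecs.shape[0])}
            coding = OutputCoding(coding.kind, coding.dim, vecs, coding.srv_k, elements)
        cfg = ModelConfig(
            coding=coding,
            layer_sizes=list(manifest["layer_sizes"]),
            input_dim=manifest["input_dim"],
            loss=manifest["loss"],
            c=manifest["c"],
            lr=manifest["lr"],
            seed=manifest["seed"],
        )
        model = WordRecognizer(cfg)
        weights = [f[f"param_{i}"][...] for i in range(len(model.parameters()))]
        model.set_weights(weights)
    return model


def save_predictor_set(ps: PredictorSet, path: str) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["rate"] = ps.rate
        f.attrs["names"] = json.dumps(ps.names)
        f.create_dataset("data", data=ps.data)


def load_predictor_set(path: str) -> PredictorSet:
    with h5py.File(path, "r") as f:
        return PredictorSet(
            json.loads(f.attrs["names"]), f["data"][...], float(f.attrs["rate"])
        )
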