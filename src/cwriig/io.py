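"""Persistence: decompositions, stacks and network checkpoints.

Arrays go into ``.npz`` containers; a JSON sidecar (same stem, ``.json``)
carries keys, shapes, labels and provenance so a directory of artifacts is
self-describing.  Stack channels can also be exported as 16-bit PNGs for
visual inspection.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .images import save_gray
from .keys import SubbandKey
from .parametric import SubbandStack
from .transforms import ContourletDecomposition, CurveletDecomposition

__all__ = [
    "save_decomposition",
    "save_stack",
    "load_stack",
    "export_stack_pngs",
    "save_checkpoint",
    "load_checkpoint",
    "fit_results_csv",
]


def fit_results_csv(path: str | Path, results: dict) -> None:
    """Write {key -> FitResult} rows (key, alpha/m, beta, delta/omega, loglik, converged)."""
    import csv
    import dataclasses

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["key", "params", "loglik", "converged", "n"])
        for key, res in results.items():
            writer.writerow([key, json.dumps(dataclasses.asdict(res.params)),
                             res.loglik, res.converged, res.n])


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def save_decomposition(path: str | Path, dec) -> None:
    """Persist a decomposition as npz + JSON key listing."""
    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    meta: dict = {"shape": list(dec.shape)}
    if isinstance(dec, ContourletDecomposition):
        meta["transform"] = "contourlet"
        arrays["lowpass"] = dec.lowpass
        bands = []
        for level, by_count in sorted(dec.levels.items()):
            for d, blist in sorted(by_count.items()):
                for i, b in enumerate(blist):
                    name = f"P{level}D{d}_{i}"
                    arrays[name] = b
                    bands.append({"name": name, "shape": list(b.shape)})
        meta["bands"] = bands
    elif isinstance(dec, CurveletDecomposition):
        meta["transform"] = "curvelet"
        meta["n_scales"] = dec.n_scales
        arrays["coarse"] = dec.coarse
        bands = []
        for (scale, L), group in sorted(dec.wedges.items()):
            for i, c in enumerate(group):
                name = f"S{scale}A{L}_{i}"
                arrays[name] = c
                bands.append({"name": name, "shape": list(c.shape)})
        meta["bands"] = bands
    else:
        raise TypeError(f"unsupported decomposition {type(dec).__name__}")
    np.savez_compressed(path, **arrays)
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def save_stack(path: str | Path, stack: SubbandStack) -> None:
    path = Path(path)
    np.savez_compressed(path, channels=stack.channels.astype(np.float32))
    meta = {
        "keys": [[k.transform, k.level, k.n_directions, k.index] for k in stack.keys],
        "label": stack.label,
        "source_id": stack.source_id,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def load_stack(path: str | Path) -> SubbandStack:
    path = Path(path)
    with np.load(path.with_suffix(".npz")) as z:
        channels = z["channels"].astype(np.float64)
    meta = json.loads(_sidecar(path).read_text())
    keys = tuple(SubbandKey(t, l, d, i) for t, l, d, i in meta["keys"])
    return SubbandStack(channels, keys, label=meta["label"], source_id=meta["source_id"])


def export_stack_pngs(directory: str | Path, stack: SubbandStack) -> list[Path]:
    """Write each channel as a 16-bit PNG (values mapped from [-1,1] to [0,1])."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = []
    for ch, key in zip(stack.channels, stack.keys):
        p = directory / f"{key.short_name}_{key.index}.png"
        save_gray(p, (ch + 1.0) / 2.0, bitdepth=16)
        out.append(p)
    return out


def save_checkpoint(path: str | Path, network, meta: dict | None = None) -> None:
    path = Path(path)
    np.savez_compressed(path, **{f"p{i}": p for i, p in enumerate(network.params)})
    info = dict(meta or {})
    info["gap_mode"] = getattr(getattr(network, "spec", None), "gap_mode", "flatten")
    _sidecar(path).write_text(json.dumps(info, indent=1))


def load_checkpoint(path: str | Path):
    """Rebuild the default network and load saved weights into it."""
    from .cnn import NetworkSpec, build_network

    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    net = build_network(NetworkSpec(gap_mode=meta.get("gap_mode", "flatten")), seed=0)
    with np.load(path.with_suffix(".npz")) as z:
        saved = [z[f"p{i}"] for i in range(len(net.params))]
    for p, s in zip(net.params, saved):
        if p.shape != s.shape:
            raise ValueError(f"checkpoint shape {s.shape} does not match network {p.shape}")
        p[...] = s
    return net, meta
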