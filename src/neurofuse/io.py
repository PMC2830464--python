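"""Delimited-text tables, model containers, and run configuration.

Dialect: tab-separated values, '.' decimal point, mandatory header row,
'#'-prefixed comment lines for provenance.  Emitted tables use a 1-based
timestep column; arrays are 0-based in memory.  Trained models are stored
as JSON documents holding named numeric arrays plus a metadata block, so
every artifact is plain text and round-trips exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from .decoders import DecoderEstimate, KalmanModel, LinearFilterModel, PVAModel
from .errors import ConfigError, InputError, TableFormatError
from .evaluation import ExperimentConfig
from .fusion import ANNModel, ANNTopology, FusionObservationSeries
from .synthetic import NeuronTuning, SpikeCountMatrix, Trajectory, VelocitySeries

__all__ = [
    "read_table",
    "write_table",
    "save_model",
    "load_model",
    "load_config",
    "config_template",
]

TABLE_KINDS = ("trajectory", "velocity", "spikes", "tuning", "estimate",
               "observations", "matrix")


# ---------------------------------------------------------------------------
# tables


def _format_row(values, int_mask) -> str:
    cells = []
    for v, is_int in zip(values, int_mask):
        cells.append(str(int(v)) if is_int else repr(float(v)))
    return "\t".join(cells)


def write_table(path, kind: str, value, comments: list[str] | None = None) -> None:
    """Write a typed value as a TSV table with a header and provenance comments."""
    if kind not in TABLE_KINDS:
        raise InputError(f"unknown table kind {kind!r}; known: {TABLE_KINDS}")
    path = Path(path)
    lines = [f"# kind: {kind}"]
    for c in comments or []:
        lines.append(f"# {c}")

    if kind == "matrix":
        matrix, row_labels, col_labels = value
        matrix = np.asarray(matrix, dtype=float)
        lines.append("\t".join(["h1\\h2", *map(str, col_labels)]))
        for label, row in zip(row_labels, matrix):
            lines.append("\t".join([str(label), *map(repr, map(float, row))]))
    elif kind == "tuning":
        lines.append("neuron\ttheta_p\ta0\tap")
        for i in range(value.n_neurons):
            lines.append(_format_row(
                [i + 1, value.theta_p[i], value.a0[i], value.ap[i]],
                [True, False, False, False]))
    else:
        if kind == "trajectory":
            data, header = value.positions, ["t", "x", "y"]
            ints = [True, False, False]
        elif kind == "velocity":
            data, header = value.velocities, ["t", "vx", "vy"]
            ints = [True, False, False]
        elif kind == "estimate":
            data, header = value.velocities, ["t", "vx", "vy"]
            ints = [True, False, False]
            lines.insert(1, f"# decoder_id: {value.decoder_id}")
        elif kind == "observations":
            data = value.observations
            header = ["t"] + [f"{d}_{ax}" for d in value.decoder_ids for ax in ("vx", "vy")]
            ints = [True] + [False] * data.shape[1]
            lines.insert(1, f"# decoder_ids: {','.join(value.decoder_ids)}")
        elif kind == "spikes":
            data = value.counts
            header = ["t"] + [f"n{i + 1}" for i in range(value.n_neurons)]
            ints = [True] * (data.shape[1] + 1)
        lines.append("\t".join(header))
        for t, row in enumerate(data, start=1):
            lines.append(_format_row([t, *row], ints))
    path.write_text("\n".join(lines) + "\n")


def _parse_rows(path: Path):
    """Yield (line_number, comment_or_none, cells_or_none) for each line."""
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.lstrip().startswith("#"):
            yield lineno, line.lstrip()[1:].strip(), None
        else:
            yield lineno, None, line.split("\t")


def read_table(path, kind: str):
    """Read and validate a TSV table; returns the corresponding typed value."""
    if kind not in TABLE_KINDS:
        raise InputError(f"unknown table kind {kind!r}; known: {TABLE_KINDS}")
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")

    header = None
    header_line = 0
    rows: list[tuple[int, list[str]]] = []
    meta: dict[str, str] = {}
    for lineno, comment, cells in _parse_rows(path):
        if comment is not None:
            if ":" in comment:
                key, _, val = comment.partition(":")
                meta[key.strip()] = val.strip()
            continue
        if header is None:
            header, header_line = cells, lineno
        else:
            rows.append((lineno, cells))
    if header is None:
        raise TableFormatError("table has no header row")

    if kind == "matrix":
        if header[0] != "h1\\h2":
            raise TableFormatError(f"expected matrix header starting with 'h1\\h2', got {header[0]!r}",
                                   header_line)
        col_labels = header[1:]
        row_labels, data = [], []
        for lineno, cells in rows:
            if len(cells) != len(header):
                raise TableFormatError(f"expected {len(header)} cells, got {len(cells)}", lineno)
            row_labels.append(cells[0])
            data.append(_floats(cells[1:], lineno))
        return np.asarray(data), row_labels, col_labels

    expected_header = {
        "trajectory": ["t", "x", "y"],
        "velocity": ["t", "vx", "vy"],
        "estimate": ["t", "vx", "vy"],
        "tuning": ["neuron", "theta_p", "a0", "ap"],
    }
    if kind in expected_header and header != expected_header[kind]:
        raise TableFormatError(
            f"bad header for kind {kind!r}: expected {expected_header[kind]}, got {header}",
            header_line)
    if kind == "spikes" and (header[0] != "t" or any(not h.startswith("n") for h in header[1:])):
        raise TableFormatError(f"bad spikes header: {header}", header_line)
    if kind == "observations" and header[0] != "t":
        raise TableFormatError(f"bad observations header: {header}", header_line)

    data = []
    for lineno, cells in rows:
        if len(cells) != len(header):
            raise TableFormatError(f"expected {len(header)} cells, got {len(cells)}", lineno)
        data.append(_floats(cells, lineno))
    arr = np.asarray(data, dtype=float)
    if arr.size == 0:
        raise TableFormatError("table has no data rows")

    body = arr[:, 1:]  # drop the timestep column
    if kind == "trajectory":
        return Trajectory(positions=body)
    if kind == "velocity":
        return VelocitySeries(velocities=body)
    if kind == "estimate":
        return DecoderEstimate(decoder_id=meta.get("decoder_id", "estimate"), velocities=body)
    if kind == "observations":
        ids = tuple(meta.get("decoder_ids", "").split(",")) if meta.get("decoder_ids") \
            else tuple(f"decoder{i}" for i in range(body.shape[1] // 2))
        return FusionObservationSeries(observations=body, decoder_ids=ids)
    if kind == "spikes":
        if np.any(body < 0):
            bad = int(np.argwhere(np.any(body < 0, axis=1))[0][0])
            raise TableFormatError("negative spike count", rows[bad][0])
        if not np.allclose(body, np.rint(body)):
            bad = int(np.argwhere(np.any(body != np.rint(body), axis=1))[0][0])
            raise TableFormatError("non-integer spike count", rows[bad][0])
        return SpikeCountMatrix(counts=body.astype(np.int64))
    # tuning
    return NeuronTuning(theta_p=arr[:, 1], a0=arr[:, 2], ap=arr[:, 3])


def _floats(cells: list[str], lineno: int) -> list[float]:
    out = []
    for c in cells:
        try:
            out.append(float(c))
        except ValueError:
            raise TableFormatError(f"non-numeric cell {c!r}", lineno) from None
    return out


# ---------------------------------------------------------------------------
# model containers (JSON of named arrays + metadata)


def _arrays_to_lists(d: dict) -> dict:
    return {k: np.asarray(v).tolist() for k, v in d.items()}


def save_model(path, model) -> None:
    """Serialize a trained model to a JSON container of named arrays."""
    path = Path(path)
    if isinstance(model, KalmanModel):
        doc = {
            "kind": "kalman",
            "metadata": {"state_labels": list(model.state_labels), **model.meta,
                         "d_state": model.d_state, "d_obs": model.d_obs},
            "arrays": _arrays_to_lists({
                "A": model.A, "W": model.W, "H": model.H, "Q": model.Q,
                "x0": model.x0, "P0": model.P0,
                "state_mean": model.state_mean, "obs_mean": model.obs_mean,
            }),
        }
    elif isinstance(model, PVAModel):
        doc = {
            "kind": "pva",
            "metadata": {"n_neurons": model.n_neurons},
            "arrays": _arrays_to_lists({
                "a0": model.a0, "ap": model.ap, "theta_p": model.theta_p,
                "cx": model.cx, "cy": model.cy,
                "iterations": model.iterations, "rss": model.rss,
            }),
        }
    elif isinstance(model, LinearFilterModel):
        doc = {
            "kind": "linear",
            "metadata": {"window_length": model.window_length, "delay": model.delay,
                         "n_neurons": model.n_neurons,
                         "include_intercept": model.include_intercept},
            "arrays": _arrays_to_lists({"coef": model.coef}),
        }
    elif isinstance(model, ANNModel):
        doc = {
            "kind": "ann",
            "metadata": {"topology": asdict(model.topology),
                         "best_epoch": model.best_epoch},
            "arrays": _arrays_to_lists({
                **{f"W{i}": W for i, W in enumerate(model.weights)},
                **{f"b{i}": b for i, b in enumerate(model.biases)},
                "input_mean": model.input_mean, "input_sd": model.input_sd,
                "train_curve": model.train_curve, "val_curve": model.val_curve,
            }),
        }
    else:
        raise InputError(f"cannot serialize model of type {type(model).__name__}")
    path.write_text(json.dumps(doc, indent=1))


def load_model(path):
    """Load a model container saved by :func:`save_model`."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    doc = json.loads(path.read_text())
    kind = doc.get("kind")
    arrays = {k: np.asarray(v, dtype=float) for k, v in doc.get("arrays", {}).items()}
    meta = doc.get("metadata", {})
    if kind == "kalman":
        extra = {k: v for k, v in meta.items()
                 if k not in ("state_labels", "d_state", "d_obs")}
        return KalmanModel(A=arrays["A"], W=arrays["W"], H=arrays["H"], Q=arrays["Q"],
                           x0=arrays["x0"], P0=arrays["P0"],
                           state_mean=arrays["state_mean"], obs_mean=arrays["obs_mean"],
                           state_labels=tuple(meta["state_labels"]), meta=extra)
    if kind == "pva":
        return PVAModel(a0=arrays["a0"], ap=arrays["ap"], theta_p=arrays["theta_p"],
                        cx=arrays["cx"], cy=arrays["cy"],
                        iterations=arrays["iterations"].astype(int), rss=arrays["rss"])
    if kind == "linear":
        return LinearFilterModel(window_length=int(meta["window_length"]),
                                 coef=arrays["coef"], n_neurons=int(meta["n_neurons"]),
                                 include_intercept=bool(meta["include_intercept"]),
                                 delay=int(meta["delay"]))
    if kind == "ann":
        topo = ANNTopology(**meta["topology"])
        n_layers = len(topo.layer_sizes) + 1
        return ANNModel(topology=topo,
                        weights=[arrays[f"W{i}"] for i in range(n_layers)],
                        biases=[arrays[f"b{i}"] for i in range(n_layers)],
                        input_mean=arrays["input_mean"], input_sd=arrays["input_sd"],
                        train_curve=arrays.get("train_curve", np.empty(0)),
                        val_curve=arrays.get("val_curve", np.empty(0)),
                        best_epoch=int(meta.get("best_epoch", 0)))
    raise InputError(f"unknown model kind {kind!r} in {path}")


# ---------------------------------------------------------------------------
# configuration


def load_config(path) -> ExperimentConfig:
    """Load a YAML run configuration; unknown keys are rejected."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"no such config file: {path}")
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"invalid YAML in {path}: {exc}") from exc
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ConfigError("config must be a mapping")
    return config_from_dict(doc)


def config_from_dict(doc: dict) -> ExperimentConfig:
    known = set(ExperimentConfig.__dataclass_fields__)
    unknown = set(doc) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}; known keys: {sorted(known)}")
    clean = {}
    for k, v in doc.items():
        if isinstance(v, list):
            v = tuple(v)
        clean[k] = v
    try:
        return ExperimentConfig(**clean)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid config: {exc}") from exc


def config_template() -> str:
    """YAML text listing every config key with its default value."""
    cfg = ExperimentConfig()
    doc = {}
    for name in ExperimentConfig.__dataclass_fields__:
        v = getattr(cfg, name)
        if isinstance(v, tuple):
            v = list(v)
        doc[name] = v
    return yaml.safe_dump(doc, sort_keys=False)
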