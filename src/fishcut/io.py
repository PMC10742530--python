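"""File formats: point-cloud CSV / array container, feature and score
tables, PCA and regressor model files, YAML configuration.

CSV dialect: comma-separated, dot decimal, mandatory header, UTF-8.  Output
files carry provenance comment lines (tool version, config hash, seed) that
readers skip.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datatypes import PointCloud, RadialProfile
from .errors import ConfigError, InvalidArgumentError, ParseError
from .features import PCAModel
from .models import BPNetwork, LSSVMModel, LSTMModel, TrainedRegressor, _GATES

__all__ = [
    "provenance_lines",
    "write_cloud_csv", "write_cloud_npz", "read_point_cloud",
    "write_matrix_csv", "read_matrix_csv",
    "save_pca_model", "load_pca_model",
    "save_regressor", "load_regressor",
    "load_config_yaml", "dump_config_yaml",
]


def provenance_lines(config_hash: str = "-", seed: int | str = "-") -> list[str]:
    return [
        f"# fishcut {__version__}",
        f"# config_sha256={config_hash} seed={seed}",
    ]


def write_cloud_csv(cloud: PointCloud, path, config_hash: str = "-",
                    seed: int | str = "-") -> None:
    """Long-form x,y,z CSV (mm), one row per point, frames in x order."""
    path = Path(path)
    frames = cloud.frames
    xs = np.concatenate([np.full(f.n_points, f.x) for f in frames])
    ys = np.concatenate([f.y for f in frames])
    zs = np.concatenate([f.z for f in frames])
    with path.open("w", encoding="utf-8") as fh:
        for line in provenance_lines(config_hash, seed):
            fh.write(line + "\n")
        fh.write(f"# frame_spacing={cloud.frame_spacing!r}")
        if cloud.belt_height is not None:
            fh.write(f" belt_height={cloud.belt_height!r}")
        fh.write("\n")
        fh.write("x,y,z\n")
        for x, y, z in zip(xs, ys, zs):
            fh.write(f"{float(x)!r},{float(y)!r},{float(z)!r}\n")


def write_cloud_npz(cloud: PointCloud, path, config_hash: str = "-",
                    seed: int | str = "-") -> None:
    """Compact array container: one 2-column (y, z) matrix per frame plus
    frame positions and metadata."""
    arrays = {
        f"frame_{k:05d}": np.column_stack([f.y, f.z])
        for k, f in enumerate(cloud.frames)
    }
    arrays["frame_x"] = cloud.frame_positions
    meta = {
        "frame_spacing": cloud.frame_spacing,
        "belt_height": cloud.belt_height,
        "version": __version__,
        "config_hash": config_hash,
        "seed": seed,
    }
    if "seed" in cloud.metadata:
        meta["scan_seed"] = int(cloud.metadata["seed"])
    if "params" in cloud.metadata:
        meta["params"] = dataclasses.asdict(cloud.metadata["params"])
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta, default=float).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def _read_cloud_csv(path: Path) -> PointCloud:
    frame_spacing = None
    belt_height = None
    with path.open("r", encoding="utf-8") as fh:
        head = []
        for line in fh:
            if line.startswith("#"):
                head.append(line)
            else:
                break
    for line in head:
        for token in line.lstrip("# ").split():
            if token.startswith("frame_spacing="):
                frame_spacing = float(token.split("=", 1)[1])
            elif token.startswith("belt_height="):
                belt_height = float(token.split("=", 1)[1])
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if df.empty:
        raise ParseError(f"{path}: no data rows")
    missing = {"x", "y", "z"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    bad = df[["x", "y", "z"]].isna().any(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(f"{path}: malformed row {row + 2} (header-relative)")
    frames = []
    for x, grp in df.groupby("x", sort=True):
        grp = grp.sort_values("y")
        yv = grp["y"].to_numpy(float)
        if np.any(np.diff(yv) <= 0):
            raise ParseError(f"{path}: duplicate lateral positions in frame x={x}")
        frames.append(RadialProfile(float(x), yv, grp["z"].to_numpy(float)))
    if frame_spacing is None:
        xs = np.array(sorted({f.x for f in frames}))
        frame_spacing = float(np.min(np.diff(xs))) if xs.size > 1 else 1.0
    return PointCloud(frames, frame_spacing=frame_spacing, belt_height=belt_height)


def _read_cloud_npz(path: Path) -> PointCloud:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"]).decode())
        xs = data["frame_x"]
        frames = []
        for k, x in enumerate(xs):
            mat = data[f"frame_{k:05d}"]
            frames.append(RadialProfile(float(x), mat[:, 0], mat[:, 1]))
    return PointCloud(frames, frame_spacing=float(meta["frame_spacing"]),
                      belt_height=meta.get("belt_height"))


def read_point_cloud(path, format: str | None = None) -> PointCloud:
    """Read a point cloud from CSV (``x,y,z`` columns) or the npz container.

    Frames are grouped by ``x`` and points sorted by ``y`` within a frame,
    so row order in a CSV does not matter.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    fmt = format or ("container" if path.suffix == ".npz" else "csv")
    if fmt == "csv":
        return _read_cloud_csv(path)
    if fmt == "container":
        return _read_cloud_npz(path)
    raise InvalidArgumentError(f"unknown point-cloud format {fmt!r}")


def write_matrix_csv(matrix: np.ndarray, path, prefix: str = "f",
                     index: np.ndarray | None = None,
                     config_hash: str = "-", seed: int | str = "-") -> None:
    """One row per fish; columns ``<prefix>0..<prefix>{p-1}``."""
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    cols = [f"{prefix}{j}" for j in range(matrix.shape[1])]
    df = pd.DataFrame(matrix, columns=cols)
    if index is not None:
        df.insert(0, "sample", index)
    with Path(path).open("w", encoding="utf-8") as fh:
        for line in provenance_lines(config_hash, seed):
            fh.write(line + "\n")
        df.to_csv(fh, index=False)


def read_matrix_csv(path) -> np.ndarray:
    df = pd.read_csv(path, comment="#")
    if "sample" in df.columns:
        df = df.drop(columns=["sample"])
    return df.to_numpy(float)


def save_pca_model(model: PCAModel, path) -> None:
    np.savez(
        path,
        column_means=model.column_means,
        column_sds=model.column_sds,
        eigenvalues=model.eigenvalues,
        components=model.components,
        coefficient_matrix=model.coefficient_matrix,
        n_selected=np.array([model.n_selected]),
        variance_target=np.array([model.variance_target]),
    )


def load_pca_model(path) -> PCAModel:
    with np.load(path) as d:
        return PCAModel(
            column_means=d["column_means"],
            column_sds=d["column_sds"],
            eigenvalues=d["eigenvalues"],
            components=d["components"],
            coefficient_matrix=d["coefficient_matrix"],
            n_selected=int(d["n_selected"][0]),
            variance_target=float(d["variance_target"][0]),
        )


def save_regressor(reg: TrainedRegressor, path) -> None:
    """Single portable file: kind, parameters and scaling statistics."""
    arrays = {
        "kind": np.frombuffer(reg.kind.encode(), dtype=np.uint8),
        "x_mean": reg.x_mean, "x_sd": reg.x_sd,
        "y_stats": np.array([reg.y_mean, reg.y_sd]),
    }
    m = reg.model
    if reg.kind == "lssvm":
        arrays.update(support_inputs=m.support_inputs, alphas=m.alphas,
                      scalars=np.array([m.bias, m.gam, m.sig2]))
    elif reg.kind == "psobp":
        arrays.update(input_weights=m.input_weights, input_biases=m.input_biases,
                      output_weights=m.output_weights,
                      scalars=np.array([m.output_bias, m.learning_rate,
                                        m.max_iter, m.goal]))
    elif reg.kind == "lstm":
        for k in _GATES:
            arrays[f"W_{k}"] = m.W[k]
            arrays[f"V_{k}"] = m.V[k]
            arrays[f"b_{k}"] = m.b[k]
        arrays.update(dense_weights=m.dense_weights,
                      scalars=np.array([m.dense_bias, m.hidden_size,
                                        m.dropout_rate, m.learning_rate,
                                        m.gradient_clip, m.max_iter, m.seed]))
    else:
        raise InvalidArgumentError(f"unknown regressor kind {reg.kind!r}")
    np.savez(path, **arrays)


def load_regressor(path) -> TrainedRegressor:
    with np.load(path) as d:
        kind = bytes(d["kind"]).decode()
        y_mean, y_sd = d["y_stats"]
        if kind == "lssvm":
            bias, gam, sig2 = d["scalars"]
            model = LSSVMModel(support_inputs=d["support_inputs"],
                               alphas=d["alphas"], bias=float(bias),
                               gam=float(gam), sig2=float(sig2))
        elif kind == "psobp":
            b2, lr, mi, goal = d["scalars"]
            model = BPNetwork(input_weights=d["input_weights"],
                              input_biases=d["input_biases"],
                              output_weights=d["output_weights"],
                              output_bias=float(b2), learning_rate=float(lr),
                              max_iter=int(mi), goal=float(goal))
        elif kind == "lstm":
            b2, hs, dr, lr, gc, mi, seed = d["scalars"]
            model = LSTMModel(
                W={k: d[f"W_{k}"] for k in _GATES},
                V={k: d[f"V_{k}"] for k in _GATES},
                b={k: d[f"b_{k}"] for k in _GATES},
                dense_weights=d["dense_weights"], dense_bias=float(b2),
                hidden_size=int(hs), dropout_rate=float(dr),
                learning_rate=float(lr), gradient_clip=float(gc),
                max_iter=int(mi), seed=int(seed),
            )
        else:
            raise ParseError(f"unknown regressor kind {kind!r} in {path}")
        return TrainedRegressor(kind=kind, model=model, x_mean=d["x_mean"],
                                x_sd=d["x_sd"], y_mean=float(y_mean),
                                y_sd=float(y_sd))


def load_config_yaml(path):
    """Parse a pipeline configuration file (strict keys)."""
    from .pipeline import PipelineConfig

    with Path(path).open("r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return PipelineConfig.from_dict(data)


def dump_config_yaml(config, path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
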