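"""Readers/writers for the on-disk artifact formats.

Clouds are PLY (ascii or binary little-endian, vertices only, optional
integer ``label`` / ``source_index`` properties) or whitespace XYZ text.
Displacement fields are 3-column CSV aligned with source row order;
landmarks, correspondences, transforms, configs and manifests are JSON.
Text floats are written with 17 significant digits so round-trips are exact.
"""

from __future__ import annotations

import dataclasses
import json
import struct
from pathlib import Path
from typing import List, Union

import numpy as np
import yaml

from .errors import ParseError
from .geometry import CorrespondenceSet, DisplacementField, PointCloud, RigidTransform
from .synthetic import (
    GroupBounds,
    JointBounds,
    LandmarkSet,
    Sample,
    SimulationConfig,
)

_FMT = "%.17g"

_PLY_TYPES = {
    "float": ("f", np.float32),
    "float32": ("f", np.float32),
    "double": ("d", np.float64),
    "float64": ("d", np.float64),
    "int": ("i", np.int32),
    "int32": ("i", np.int32),
    "uint": ("I", np.uint32),
    "uint32": ("I", np.uint32),
    "int64": ("q", np.int64),
    "uchar": ("B", np.uint8),
    "uint8": ("B", np.uint8),
    "char": ("b", np.int8),
    "int8": ("b", np.int8),
    "short": ("h", np.int16),
    "int16": ("h", np.int16),
    "ushort": ("H", np.uint16),
    "uint16": ("H", np.uint16),
}


def read_point_cloud(path: Union[str, Path]) -> PointCloud:
    """Read a PLY (ascii / binary little-endian) or whitespace-XYZ file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"point cloud file not found: {path}")
    with open(path, "rb") as fh:
        magic = fh.read(3)
    if magic == b"ply":
        return _read_ply(path)
    return _read_xyz(path)


def _read_ply(path: Path) -> PointCloud:
    with open(path, "rb") as fh:
        header_lines = []
        while True:
            line = fh.readline()
            if not line:
                raise ParseError(f"{path}: unexpected end of PLY header")
            text = line.decode("ascii", errors="replace").strip()
            header_lines.append(text)
            if text == "end_header":
                break
        fmt = None
        n_vertex = None
        props: List[tuple] = []
        in_vertex = False
        for ln, text in enumerate(header_lines):
            parts = text.split()
            if not parts:
                continue
            if parts[0] == "format":
                fmt = parts[1]
            elif parts[0] == "element":
                in_vertex = parts[1] == "vertex"
                if in_vertex:
                    n_vertex = int(parts[2])
            elif parts[0] == "property" and in_vertex:
                if parts[1] == "list":
                    raise ParseError(f"{path}: list properties unsupported (line {ln + 1})")
                props.append((parts[2], parts[1]))
        if fmt not in ("ascii", "binary_little_endian"):
            raise ParseError(f"{path}: unsupported PLY format {fmt!r}")
        if n_vertex is None:
            raise ParseError(f"{path}: PLY header has no vertex element")
        names = [p[0] for p in props]
        for axis in ("x", "y", "z"):
            if axis not in names:
                raise ParseError(f"{path}: PLY vertex element lacks property {axis!r}")

        if fmt == "ascii":
            rows = []
            for i in range(n_vertex):
                line = fh.readline().decode("ascii").split()
                if len(line) != len(props):
                    raise ParseError(
                        f"{path}: vertex row {i} has {len(line)} values, expected {len(props)}"
                    )
                try:
                    rows.append([float(v) for v in line])
                except ValueError as e:
                    raise ParseError(f"{path}: bad value in vertex row {i}: {e}") from e
            data = np.asarray(rows, dtype=np.float64).reshape(n_vertex, len(props))
        else:
            fmt_str = "<" + "".join(_PLY_TYPES[t][0] for _, t in props)
            size = struct.calcsize(fmt_str)
            raw = fh.read(size * n_vertex)
            if len(raw) != size * n_vertex:
                raise ParseError(f"{path}: truncated binary PLY body")
            unpacked = struct.iter_unpack(fmt_str, raw)
            data = np.asarray(list(unpacked), dtype=np.float64)

    cols = {name: data[:, i] for i, (name, _) in enumerate(props)}
    pts = np.column_stack([cols["x"], cols["y"], cols["z"]])
    labels = cols["label"].astype(np.int64) if "label" in cols else None
    src_idx = cols["source_index"].astype(np.int64) if "source_index" in cols else None
    return PointCloud(pts, labels=labels, source_index=src_idx)


def _read_xyz(path: Path) -> PointCloud:
    rows = []
    with open(path, "r") as fh:
        for i, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) < 3:
                raise ParseError(f"{path}: row {i} has fewer than 3 columns")
            try:
                rows.append([float(v) for v in parts[:3]])
            except ValueError as e:
                raise ParseError(f"{path}: row {i}: {e}") from e
    if not rows:
        raise ParseError(f"{path}: no coordinate rows found")
    return PointCloud(np.asarray(rows))


def write_point_cloud(
    cloud: PointCloud,
    path: Union[str, Path],
    format: str = "ply",
    binary: bool = False,
) -> None:
    """Write a cloud as ascii/binary PLY or XYZ text."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "xyz":
        np.savetxt(path, cloud.points, fmt=_FMT)
        return
    if format != "ply":
        raise ValueError(f"unknown point cloud format {format!r}")
    props = [("x", "double"), ("y", "double"), ("z", "double")]
    extra = []
    if cloud.labels is not None:
        props.append(("label", "int64"))
        extra.append(cloud.labels)
    if cloud.source_index is not None:
        props.append(("source_index", "int64"))
        extra.append(cloud.source_index)
    header = ["ply"]
    header.append("format binary_little_endian 1.0" if binary else "format ascii 1.0")
    header.append(f"element vertex {len(cloud)}")
    header += [f"property {t} {n}" for n, t in props]
    header.append("end_header")
    if binary:
        fmt_str = "<" + "".join(_PLY_TYPES[t][0] for _, t in props)
        with open(path, "wb") as fh:
            fh.write(("\n".join(header) + "\n").encode("ascii"))
            for i in range(len(cloud)):
                vals = list(cloud.points[i]) + [int(e[i]) for e in extra]
                fh.write(struct.pack(fmt_str, *vals))
    else:
        with open(path, "w") as fh:
            fh.write("\n".join(header) + "\n")
            for i in range(len(cloud)):
                row = [(_FMT % v) for v in cloud.points[i]] + [str(int(e[i])) for e in extra]
                fh.write(" ".join(row) + "\n")


def write_field(phi: DisplacementField, path: Union[str, Path]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, phi.vectors, fmt=_FMT, delimiter=",", header="dx,dy,dz", comments="")


def read_field(path: Union[str, Path]) -> DisplacementField:
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    return DisplacementField(data)


def write_landmarks(landmarks: LandmarkSet, path: Union[str, Path]) -> None:
    write_json({k: v.tolist() for k, v in landmarks.landmarks.items()}, path)


def read_landmarks(path: Union[str, Path]) -> LandmarkSet:
    with open(path) as fh:
        data = json.load(fh)
    return LandmarkSet({k: np.asarray(v) for k, v in data.items()})


def write_transform(t: RigidTransform, path: Union[str, Path]) -> None:
    write_json({"matrix": t.as_matrix().tolist()}, path)


def read_transform(path: Union[str, Path]) -> RigidTransform:
    with open(path) as fh:
        data = json.load(fh)
    return RigidTransform.from_matrix(np.asarray(data["matrix"]))


def write_correspondences(sigma: CorrespondenceSet, path: Union[str, Path]) -> None:
    write_json({"pairs": sigma.pairs.tolist()}, path)


def read_correspondences(path: Union[str, Path]) -> CorrespondenceSet:
    with open(path) as fh:
        data = json.load(fh)
    return CorrespondenceSet(np.asarray(data["pairs"], dtype=np.int64))


def write_json(obj, path: Union[str, Path]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_report_csv(reports, path: Union[str, Path]) -> None:
    """One row per sample: sample_id, mde, chamfer, landmark_error, visible_ratio."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("sample_id,mde,chamfer,landmark_error,visible_ratio\n")
        for r in reports:
            fh.write(
                f"{r.sample_id},{_FMT % r.mde},{_FMT % r.chamfer},"
                f"{_FMT % r.landmark_error},{_FMT % r.visible_ratio}\n"
            )


def read_report_csv(path: Union[str, Path]):
    from .metrics import MetricReport

    reports = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("sample_id"):
            raise ParseError(f"{path}: missing report header")
        for line in fh:
            if not line.strip():
                continue
            sid, m, c, l, v = line.strip().split(",")
            reports.append(
                MetricReport(
                    mde=float(m),
                    chamfer=float(c),
                    landmark_error=float(l),
                    visible_ratio=float(v),
                    sample_id=sid,
                )
            )
    return reports


# ---------------------------------------------------------------------------
# samples and configs
# ---------------------------------------------------------------------------


def write_sample(sample: Sample, out_dir: Union[str, Path]) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_point_cloud(sample.template, out_dir / "template.ply")
    write_point_cloud(sample.variant, out_dir / "variant.ply")
    write_point_cloud(sample.target, out_dir / "target.ply")
    write_field(sample.gt_displacement, out_dir / "gt_displacement.csv")
    write_landmarks(sample.landmarks_template, out_dir / "landmarks_template.json")
    write_landmarks(sample.landmarks_target, out_dir / "landmarks_target.json")
    write_json({"visible_ratio": sample.visible_ratio}, out_dir / "meta.json")


def read_sample(sample_dir: Union[str, Path]) -> Sample:
    d = Path(sample_dir)
    template = read_point_cloud(d / "template.ply")
    variant = read_point_cloud(d / "variant.ply")
    target = read_point_cloud(d / "target.ply")
    with open(d / "meta.json") as fh:
        meta = json.load(fh)
    return Sample(
        template=template,
        target=target,
        gt_displacement=read_field(d / "gt_displacement.csv"),
        variant=variant,
        landmarks_template=read_landmarks(d / "landmarks_template.json"),
        landmarks_target=read_landmarks(d / "landmarks_target.json"),
        visible_ratio=meta["visible_ratio"],
    )


def simulation_config_to_dict(cfg: SimulationConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["lattice_resolution"] = list(cfg.lattice_resolution)
    d["occlusion_range"] = list(cfg.occlusion_range)
    d["visibility_lambda"] = (
        "inf" if not np.isfinite(cfg.visibility_lambda) else cfg.visibility_lambda
    )
    return d


def simulation_config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    if "nonrigid_bounds" in d:
        d["nonrigid_bounds"] = {
            k: GroupBounds(**v) if isinstance(v, dict) else v
            for k, v in d["nonrigid_bounds"].items()
        }
    if "rigid_bounds" in d:
        d["rigid_bounds"] = [
            JointBounds(**v) if isinstance(v, dict) else v for v in d["rigid_bounds"]
        ]
    if "lattice_resolution" in d:
        d["lattice_resolution"] = tuple(d["lattice_resolution"])
    if "occlusion_range" in d:
        d["occlusion_range"] = tuple(d["occlusion_range"])
    if d.get("visibility_lambda") == "inf":
        d["visibility_lambda"] = np.inf
    return SimulationConfig(**d)


def load_run_config(path: Union[str, Path]) -> dict:
    """Load a YAML or JSON run configuration into a plain dict."""
    path = Path(path)
    with open(path) as fh:
        if path.suffix in (".yaml", ".yml"):
            return yaml.safe_load(fh) or {}
        return json.load(fh)
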