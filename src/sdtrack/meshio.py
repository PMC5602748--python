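"""Readers and writers for the surface formats the pipeline exchanges.

Two input dialects are supported: OFF (``OFF`` header, counts line, vertex
lines, ``3 i j k`` face lines) and the FreeSurfer ASCII surface export
(``#!ascii`` comment line, ``V F`` counts, vertex lines with a trailing 0,
face lines with a trailing 0). PLY (ascii) is write-only and carries the
optional per-vertex scalar channel for heatmap export.
"""

from __future__ import annotations

import numpy as np

from .errors import MeshParseError, MeshValidationError
from .mesh import TriMesh

__all__ = ["read_surface", "write_surface"]

_FORMATS = ("off", "freesurfer_ascii", "ply")


def _sniff(path: str) -> str:
    with open(path) as fh:
        first = fh.readline().strip()
    if first.startswith("#!ascii"):
        return "freesurfer_ascii"
    if first.upper().startswith("OFF") or first.split() and all(
        t.replace(".", "").replace("-", "").isdigit() for t in first.split()[:1]
    ):
        return "off"
    raise MeshParseError("cannot infer surface format", path=path, line=1)


def read_surface(path: str, format: str | None = None) -> TriMesh:
    """Parse a triangle surface file into a validated :class:`TriMesh`."""
    if format is None:
        format = _sniff(path)
    if format == "off":
        mesh = _read_off(path)
    elif format == "freesurfer_ascii":
        mesh = _read_fs_ascii(path)
    else:
        raise ValueError(f"unsupported read format {format!r}")
    try:
        mesh.validate()
    except MeshValidationError as exc:
        raise MeshParseError(str(exc), path=path) from exc
    return mesh


def _read_off(path: str) -> TriMesh:
    with open(path) as fh:
        lines = fh.readlines()
    ln = 0

    def next_tokens():
        nonlocal ln
        while ln < len(lines):
            ln += 1
            s = lines[ln - 1].split("#")[0].strip()
            if s:
                return s.split()
        raise MeshParseError("unexpected end of file", path=path, line=ln)

    tok = next_tokens()
    if tok[0].upper() == "OFF":
        tok = tok[1:] or next_tokens()
    if len(tok) < 2:
        raise MeshParseError("malformed counts line", path=path, line=ln)
    try:
        nv, nf = int(tok[0]), int(tok[1])
    except ValueError:
        raise MeshParseError("malformed counts line", path=path, line=ln)

    verts = np.empty((nv, 3))
    for i in range(nv):
        tok = next_tokens()
        try:
            verts[i] = [float(tok[0]), float(tok[1]), float(tok[2])]
        except (ValueError, IndexError):
            raise MeshParseError(f"malformed vertex {i}", path=path, line=ln)
    faces = np.empty((nf, 3), dtype=np.int64)
    for i in range(nf):
        tok = next_tokens()
        try:
            if int(tok[0]) != 3:
                raise MeshParseError(
                    f"face {i} is not a triangle", path=path, line=ln
                )
            faces[i] = [int(tok[1]), int(tok[2]), int(tok[3])]
        except (ValueError, IndexError):
            raise MeshParseError(f"malformed face {i}", path=path, line=ln)
        if (faces[i] < 0).any() or (faces[i] >= nv).any():
            raise MeshParseError(
                f"face {i} references vertex out of range "
                f"({faces[i].tolist()} of {nv})",
                path=path,
                line=ln,
            )
    return TriMesh(verts, faces)


def _read_fs_ascii(path: str) -> TriMesh:
    with open(path) as fh:
        lines = fh.readlines()
    ln = 0
    if lines and lines[0].startswith("#"):
        ln = 1
    try:
        nv, nf = (int(x) for x in lines[ln].split()[:2])
    except (ValueError, IndexError):
        raise MeshParseError("malformed counts line", path=path, line=ln + 1)
    ln += 1
    verts = np.empty((nv, 3))
    for i in range(nv):
        tok = lines[ln + i].split()
        try:
            verts[i] = [float(tok[0]), float(tok[1]), float(tok[2])]
        except (ValueError, IndexError):
            raise MeshParseError(f"malformed vertex {i}", path=path, line=ln + i + 1)
    faces = np.empty((nf, 3), dtype=np.int64)
    for i in range(nf):
        tok = lines[ln + nv + i].split()
        try:
            faces[i] = [int(tok[0]), int(tok[1]), int(tok[2])]
        except (ValueError, IndexError):
            raise MeshParseError(
                f"malformed face {i}", path=path, line=ln + nv + i + 1
            )
        if (faces[i] < 0).any() or (faces[i] >= nv).any():
            raise MeshParseError(
                f"face {i} references vertex out of range "
                f"({faces[i].tolist()} of {nv})",
                path=path,
                line=ln + nv + i + 1,
            )
    return TriMesh(verts, faces)


def write_surface(mesh: TriMesh, path: str, format: str = "off") -> None:
    """Write ``mesh`` so that reading it back reproduces vertices within
    1e-6 mm and identical faces."""
    if mesh.n_vertices == 0 or mesh.n_faces == 0:
        raise ValueError("empty mesh")
    if format not in _FORMATS:
        raise ValueError(f"unsupported write format {format!r}")
    with open(path, "w") as fh:
        if format == "off":
            fh.write("OFF\n")
            fh.write(f"{mesh.n_vertices} {mesh.n_faces} 0\n")
            for v in mesh.vertices:
                fh.write(f"{v[0]:.9f} {v[1]:.9f} {v[2]:.9f}\n")
            for f in mesh.faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
        elif format == "freesurfer_ascii":
            fh.write("#!ascii version of surface\n")
            fh.write(f"{mesh.n_vertices} {mesh.n_faces}\n")
            for v in mesh.vertices:
                fh.write(f"{v[0]:.9f} {v[1]:.9f} {v[2]:.9f} 0\n")
            for f in mesh.faces:
                fh.write(f"{f[0]} {f[1]} {f[2]} 0\n")
        else:  # ply
            has_scalar = mesh.scalar is not None
            fh.write("ply\nformat ascii 1.0\n")
            fh.write(f"element vertex {mesh.n_vertices}\n")
            fh.write("property float x\nproperty float y\nproperty float z\n")
            if has_scalar:
                fh.write("property float quality\n")
            fh.write(f"element face {mesh.n_faces}\n")
            fh.write("property list uchar int vertex_indices\n")
            fh.write("end_header\n")
            for i, v in enumerate(mesh.vertices):
                line = f"{v[0]:.9f} {v[1]:.9f} {v[2]:.9f}"
                if has_scalar:
                    line += f" {mesh.scalar[i]:.9f}"
                fh.write(line + "\n")
            for f in mesh.faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
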