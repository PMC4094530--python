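"""Triangulated femoral diaphysis surfaces and their on-disk form.

A :class:`DiaphysisMesh` is a closed tube between the distal and proximal
epiphyseal lines, annotated with taxon, ontogenetic (dental) stage, a
specimen id, and the anatomical anterior direction used to reference the
angular coordinate of the morphometric map (anterior = 0 deg, medial = 90,
posterior = 180, lateral = 270).

Meshes travel as PLY/OBJ files plus a sidecar ``manifest.csv`` holding the
labels, axis endpoints and anterior vectors; :func:`save_sample` /
:func:`load_sample` round-trip a whole sample.  trimesh does the actual
file encoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh


@dataclass
class DiaphysisMesh:
    vertices: np.ndarray          # (n, 3) mm
    faces: np.ndarray             # (m, 3) vertex indices
    proximal_end: np.ndarray      # (3,) point on the proximal epiphyseal line
    distal_end: np.ndarray        # (3,)
    taxon: str
    stage: str
    specimen_id: str
    anterior: np.ndarray = field(default_factory=lambda: np.array([1.0, 0, 0]))

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.proximal_end = np.asarray(self.proximal_end, dtype=float)
        self.distal_end = np.asarray(self.distal_end, dtype=float)
        self.anterior = np.asarray(self.anterior, dtype=float)
        if self.length <= 0:
            raise ValueError("diaphyseal length must be positive")

    @property
    def length(self) -> float:
        """Diaphyseal length: |proximal_end - distal_end| in mm."""
        return float(np.linalg.norm(self.proximal_end - self.distal_end))

    @property
    def axis(self) -> np.ndarray:
        u = self.proximal_end - self.distal_end
        return u / np.linalg.norm(u)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces,
                               process=False)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray,
                    scale: float = 1.0) -> "DiaphysisMesh":
        """Rigidly moved (and optionally scaled) copy, labels preserved."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        return DiaphysisMesh(
            vertices=scale * self.vertices @ R.T + t,
            faces=self.faces.copy(),
            proximal_end=scale * R @ self.proximal_end + t,
            distal_end=scale * R @ self.distal_end + t,
            taxon=self.taxon, stage=self.stage,
            specimen_id=self.specimen_id,
            anterior=R @ self.anterior,
        )


# ----------------------------------------------------------------------
# sample-level IO

def save_sample(meshes, out_dir, fmt: str = "ply") -> Path:
    """Write each mesh as PLY/OBJ plus a ``manifest.csv`` sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for m in meshes:
        fname = f"{m.specimen_id}.{fmt}"
        m.to_trimesh().export(out_dir / fname)
        rows.append({
            "specimen_id": m.specimen_id, "taxon": m.taxon, "stage": m.stage,
            "file": fname,
            "prox_x": m.proximal_end[0], "prox_y": m.proximal_end[1],
            "prox_z": m.proximal_end[2],
            "dist_x": m.distal_end[0], "dist_y": m.distal_end[1],
            "dist_z": m.distal_end[2],
            "ant_x": m.anterior[0], "ant_y": m.anterior[1],
            "ant_z": m.anterior[2],
        })
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_sample(manifest_path) -> list:
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path)
    meshes = []
    for _, r in df.iterrows():
        tm = trimesh.load(base / r["file"], process=False)
        meshes.append(DiaphysisMesh(
            vertices=np.asarray(tm.vertices), faces=np.asarray(tm.faces),
            proximal_end=np.array([r["prox_x"], r["prox_y"], r["prox_z"]]),
            distal_end=np.array([r["dist_x"], r["dist_y"], r["dist_z"]]),
            taxon=str(r["taxon"]), stage=str(r["stage"]),
            specimen_id=str(r["specimen_id"]),
            anterior=np.array([r["ant_x"], r["ant_y"], r["ant_z"]]),
        ))
    return meshes
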