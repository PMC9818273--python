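"""Readers and writers for the standard interchange formats.

Masks travel as NIfTI (one binary volume per structure), cohorts as a
manifest CSV mapping patient id and structure name to a file path, clinical
data as a CSV with ``patient_id``, ``n_stage`` and per-endpoint
``time_<endpoint>`` / ``event_<endpoint>`` columns, and curves as a long
CSV (one row per patient/organ/histogram-type) with a JSON sidecar holding
the grids.

Masks are required to be pre-resampled to a common per-patient grid; a grid
mismatch is a validation error, never silently resampled.  Left and right
parotid structures are merged into a combined ``Parotids`` structure on
read.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .structures import StructureVolume, union

logger = logging.getLogger("lnspatial")

__all__ = [
    "PipelineConfig",
    "write_structure",
    "read_structure",
    "read_structures",
    "write_manifest",
    "read_manifest",
    "endpoint_frame",
    "write_curves",
    "read_curves",
]

#: structure vocabulary accepted in manifests
STRUCTURE_VOCABULARY = (
    "GTVn",
    "SpinalCord",
    "Parotid_L",
    "Parotid_R",
    "Parotids",
    "Mandible",
    "Larynx",
    "Brainstem",
)

ENDPOINTS = ("DFS", "OS", "RFS", "DMFS")


@dataclass
class PipelineConfig:
    """Tunable settings of the end-to-end analysis.

    Defaults follow the study design the pipeline implements: 1 mm OVH bins
    on [-10, 150] mm, 1 degree POV sampling, a 75% cumulative-variance rule
    for component selection, p < 0.05 screening, 1000 bootstrap iterations,
    and a 36-month horizon for 3-year survival rates.
    """

    ovh_lo_mm: float = -10.0
    ovh_hi_mm: float = 150.0
    ovh_step_mm: float = 1.0
    pov_step_deg: float = 1.0
    occlusion: str = "none"  # "none" | "before"
    fold_pov: bool = False
    variance_threshold: float = 0.75
    screen_alpha: float = 0.05
    n_boot: int = 1000
    seed: int = 0
    screening_endpoint: str = "DFS"
    endpoints: tuple[str, ...] = ENDPOINTS
    horizon_months: float = 36.0
    organs: tuple[str, ...] = ("SpinalCord", "Parotids")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("endpoints", "organs"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["endpoints"] = list(d["endpoints"])
        d["organs"] = list(d["organs"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


# ---------------------------------------------------------------------------
# NIfTI masks
# ---------------------------------------------------------------------------


def write_structure(vol: StructureVolume, path: str | Path) -> None:
    """Write a binary mask as NIfTI with a diagonal affine built from
    spacing and origin."""
    affine = np.diag(list(vol.spacing) + [1.0])
    affine[:3, 3] = vol.origin
    img = nib.Nifti1Image(vol.mask.astype(np.uint8), affine)
    nib.save(img, str(path))


def read_structure(path: str | Path, name: str) -> StructureVolume:
    """Read one structure mask; values are binarized at > 0 (a {0, 255}
    export is accepted with a logged note)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got {data.ndim}D")
    vals = np.unique(data)
    if not np.all(np.isin(vals, (0, 1))):
        logger.info("%s: non-{0,1} values %s binarized at > 0", path, vals[:5])
    affine = img.affine
    spacing = tuple(float(s) for s in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in affine[:3, 3])
    return StructureVolume(name=name, mask=data > 0, spacing=spacing, origin=origin)


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------


def write_manifest(rows: pd.DataFrame, path: str | Path) -> None:
    rows.to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    m = pd.read_csv(path, dtype={"patient_id": str})
    required = {"patient_id", "structure", "path"}
    if not required.issubset(m.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    bad = set(m["structure"]) - set(STRUCTURE_VOCABULARY)
    if bad:
        raise ValueError(f"unknown structure names in manifest: {sorted(bad)}")
    missing_gtv = set(m["patient_id"]) - set(m.loc[m["structure"] == "GTVn", "patient_id"])
    if missing_gtv:
        raise ValueError(f"patients without a GTVn entry: {sorted(missing_gtv)[:5]}")
    return m


def read_structures(manifest: pd.DataFrame, patient: str, base_dir: str | Path = ".") -> dict[str, StructureVolume]:
    """All validated structures of one patient, with left/right parotids
    merged into ``Parotids``; grids must match across structures."""
    sub = manifest[manifest["patient_id"] == patient]
    if sub.empty:
        raise ValueError(f"patient {patient!r} not in manifest")
    out: dict[str, StructureVolume] = {}
    for _, row in sub.iterrows():
        p = Path(base_dir) / row["path"]
        if not p.exists():
            raise FileNotFoundError(f"{patient}: missing file {p}")
        out[row["structure"]] = read_structure(p, row["structure"])
    if "GTVn" not in out:
        raise ValueError(f"{patient}: manifest has no GTVn mask")
    ref = out["GTVn"]
    for name, vol in out.items():
        if not ref.same_grid(vol):
            raise ValueError(
                f"{patient}: structure {name!r} is on a different grid than GTVn "
                f"(files must be resampled to a common grid upstream)"
            )
    lr = [out.pop(k) for k in ("Parotid_L", "Parotid_R") if k in out]
    if lr and "Parotids" not in out:
        out["Parotids"] = union("Parotids", *lr)
    return out


# ---------------------------------------------------------------------------
# clinical tables
# ---------------------------------------------------------------------------


def endpoint_frame(clinical: pd.DataFrame, endpoint: str) -> pd.DataFrame:
    """Per-endpoint survival view: index patient_id, columns
    ``n_stage`` / ``time`` / ``event``."""
    tcol, ecol = f"time_{endpoint}", f"event_{endpoint}"
    for c in ("patient_id", "n_stage", tcol, ecol):
        if c not in clinical.columns:
            raise ValueError(f"clinical table lacks column {c!r}")
    df = clinical.set_index("patient_id")[["n_stage", tcol, ecol]].rename(
        columns={tcol: "time", ecol: "event"}
    )
    if not df["n_stage"].isin([1, 2, 3]).all():
        raise ValueError("n_stage must be in {1, 2, 3}")
    if (df["time"] <= 0).any():
        raise ValueError(f"{endpoint}: non-positive follow-up times")
    if not df["event"].isin([0, 1]).all():
        raise ValueError(f"{endpoint}: event indicator must be 0/1")
    return df


# ---------------------------------------------------------------------------
# curve tables
# ---------------------------------------------------------------------------


def write_curves(curves: dict, grids: dict, path: str | Path) -> None:
    """Long-format curve CSV plus a JSON sidecar with the grids.

    ``curves`` maps ``(htype, organ)`` to a DataFrame (index patient_id,
    one column per bin); ``grids`` maps ``htype`` to the bin/angle grid.
    """
    path = Path(path)
    frames = []
    for (htype, organ), df in curves.items():
        f = df.copy()
        f.columns = [f"v{i}" for i in range(f.shape[1])]
        f.insert(0, "htype", htype)
        f.insert(1, "organ", organ)
        frames.append(f.reset_index())
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    sidecar = {h: np.asarray(g).tolist() for h, g in grids.items()}
    path.with_suffix(".grids.json").write_text(json.dumps(sidecar))


def read_curves(path: str | Path) -> tuple[dict, dict]:
    path = Path(path)
    grids = {h: np.asarray(g) for h, g in json.loads(path.with_suffix(".grids.json").read_text()).items()}
    long = pd.read_csv(path, dtype={"patient_id": str})
    curves: dict = {}
    for (htype, organ), sub in long.groupby(["htype", "organ"]):
        vcols = [c for c in sub.columns if c.startswith("v")]
        df = sub.set_index("patient_id")[vcols]
        df = df.iloc[:, : grids[htype].size]
        curves[(htype, organ)] = df
    return curves, grids
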