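"""File formats: SDF conformers, TSV tables, filter files and run config.

Everything tabular is TSV with a mandatory header and ``#``-prefixed metadata
comment lines, so artifacts stay diff-able and stream-able; structures travel
as SDF V2000.  Filter files round-trip bit-exactly (integer payload, fixed
field order, floats via repr).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from rdkit import Chem, RDLogger
from rdkit.Geometry import Point3D

from .filters import (
    BinConfig,
    DEFAULT_Q_BINSIZES,
    FilterSet,
    QuadrupoleFilter,
)
from .shape import BONDI_RADII, AMPLITUDE_DEFAULT, Conformer, DescriptorConfig, RadiusTable, ShapeDescriptors

__all__ = [
    "RunConfig",
    "read_descriptor_table",
    "read_filter",
    "read_filter_set",
    "read_pair_table",
    "read_sdf",
    "write_descriptor_table",
    "write_filter",
    "write_filter_set",
    "write_pair_table",
    "write_sdf",
]

logger = logging.getLogger("shapequad")

DESCRIPTOR_COLUMNS = ["id", "n_atoms", "v_an", "v_mp", "v_so", "qx", "qy", "qz", "rg"]

RDLogger.DisableLog("rdApp.*")  # bond-less records otherwise spam warnings


# ---------------------------------------------------------------------------
# SDF

def read_sdf(
    path: str | Path,
    id_property: str | None = None,
    skip_non_3d: bool = True,
) -> tuple[list[Conformer], int]:
    """Read one conformer per SDF V2000 record.

    Record ids come from the title line unless ``id_property`` names an SDF
    property.  Records without 3-D coordinates (all z = 0) are skipped with a
    warning when ``skip_non_3d``; the skip count is returned alongside.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        return [], 0
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    conformers: list[Conformer] = []
    skipped = 0
    for index, mol in enumerate(supplier):
        if mol is None:
            raise ValueError(f"unparseable SDF record at index {index} in {path}")
        if mol.GetNumConformers() == 0 or mol.GetNumAtoms() == 0:
            raise ValueError(f"SDF record {index} in {path} has no coordinates")
        conf = mol.GetConformer()
        coords = np.array(
            [list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())]
        )
        if skip_non_3d and np.allclose(coords[:, 2], 0.0):
            logger.warning("record %d in %s has no 3-D coordinates; skipped", index, path)
            skipped += 1
            continue
        if id_property is not None and mol.HasProp(id_property):
            cid = mol.GetProp(id_property)
        elif mol.HasProp("_Name") and mol.GetProp("_Name").strip():
            cid = mol.GetProp("_Name").strip()
        else:
            cid = f"record-{index}"
        elements = tuple(a.GetSymbol() for a in mol.GetAtoms())
        conformers.append(Conformer(cid, elements, coords))
    return conformers, skipped


def write_sdf(conformers: Iterable[Conformer], path: str | Path) -> None:
    """Write conformers as bond-less SDF V2000 records (id on the title line)."""
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for c in conformers:
            mol = Chem.RWMol()
            for el in c.elements:
                atom = Chem.Atom(el)
                atom.SetNoImplicit(True)
                mol.AddAtom(atom)
            conf = Chem.Conformer(c.n_atoms)
            for i, (x, y, z) in enumerate(c.coords):
                conf.SetAtomPosition(i, Point3D(float(x), float(y), float(z)))
            mol.AddConformer(conf)
            out = mol.GetMol()
            out.SetProp("_Name", c.id)
            writer.write(out)
    finally:
        writer.close()


# ---------------------------------------------------------------------------
# descriptor and pair tables

def write_descriptor_table(
    descriptors: Iterable[ShapeDescriptors], path: str | Path
) -> None:
    """TSV with columns id n_atoms v_an v_mp v_so qx qy qz rg (6 sig. digits)."""
    rows = [
        [d.id, d.n_atoms]
        + [float(f"{v:.6g}") for v in (d.v_an, d.v_mp, d.v_so, d.qx, d.qy, d.qz, d.rg)]
        for d in descriptors
    ]
    frame = pd.DataFrame(rows, columns=DESCRIPTOR_COLUMNS)
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_descriptor_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"id": str}, comment="#")
    missing = [c for c in DESCRIPTOR_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"descriptor table {path} lacks columns {missing}")
    return frame


def descriptor_map_from_frame(frame: pd.DataFrame) -> dict[str, ShapeDescriptors]:
    """Rehydrate table rows into descriptor records (no centroid/axes)."""
    out = {}
    for row in frame.itertuples(index=False):
        out[row.id] = ShapeDescriptors(
            id=row.id,
            n_atoms=int(row.n_atoms),
            v_an=float(row.v_an),
            v_mp=float(row.v_mp),
            v_so=float(row.v_so),
            qx=float(row.qx),
            qy=float(row.qy),
            qz=float(row.qz),
            rg=float(row.rg),
            centroid=np.full(3, np.nan),
            principal_axes=np.eye(3),
        )
    return out


def write_pair_table(pairs: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ("id1", "id2", "st", "v_ab") if c in pairs.columns]
    pairs.to_csv(path, sep="\t", index=False, columns=cols, float_format="%.6f")


def read_pair_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"id1": str, "id2": str}, comment="#")
    for col in ("id1", "id2"):
        if col not in frame.columns:
            raise ValueError(f"pair table {path} lacks column {col!r}")
    return frame


# ---------------------------------------------------------------------------
# filter files (qfilter-1)

def _format_float(x: float) -> str:
    return repr(float(x))


def write_filter(f: QuadrupoleFilter, path: str | Path) -> None:
    """qfilter-1 TSV: metadata comments, then sorted integer rows."""
    lines = [
        "#format qfilter-1",
        f"#volume_type {f.volume_type}",
        f"#component {f.component}",
        f"#st_threshold {_format_float(f.st_threshold)}",
        f"#vol_binsize {_format_float(f.cfg.vol_binsize)}",
        f"#q_binsize {_format_float(f.cfg.q_binsizes[f.component])}",
        "#rounding floor",
        "v1bin\tv2bin\tdqmin\tdqmax",
    ]
    for (v1, v2), (lo, hi) in sorted(f.entries.items()):
        lines.append(f"{v1}\t{v2}\t{lo}\t{hi}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_filter(path: str | Path, q_binsizes: Mapping[str, float] | None = None) -> QuadrupoleFilter:
    meta: dict[str, str] = {}
    rows: list[tuple[int, int, int, int]] = []
    header_seen = False
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        if line.startswith("#"):
            key, _, value = line[1:].partition(" ")
            meta[key] = value.strip()
            continue
        if not header_seen:
            if line.split("\t") != ["v1bin", "v2bin", "dqmin", "dqmax"]:
                raise ValueError(f"unexpected filter header in {path}: {line!r}")
            header_seen = True
            continue
        v1, v2, lo, hi = (int(x) for x in line.split("\t"))
        rows.append((v1, v2, lo, hi))
    if meta.get("format") != "qfilter-1":
        raise ValueError(f"{path} is not a qfilter-1 file")
    component = meta["component"]
    binsizes = dict(q_binsizes or DEFAULT_Q_BINSIZES)
    binsizes[component] = float(meta["q_binsize"])
    cfg = BinConfig(
        vol_binsize=float(meta["vol_binsize"]),
        q_binsizes=binsizes,
        volume_type=meta["volume_type"],
        st_threshold=float(meta["st_threshold"]),
    )
    return QuadrupoleFilter(
        component=component,
        volume_type=cfg.volume_type,
        st_threshold=cfg.st_threshold,
        cfg=cfg,
        entries={(v1, v2): (lo, hi) for v1, v2, lo, hi in rows},
    )


def write_filter_set(
    fs: FilterSet, prefix: str | Path, manifest_extra: dict | None = None
) -> dict[str, Path]:
    """Write F_x/F_y/F_z files plus a JSON manifest; returns the paths."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {}
    for comp in ("x", "y", "z"):
        p = prefix.with_name(prefix.name + f".q{comp}.tsv")
        write_filter(fs.member(comp), p)
        paths[comp] = p
    manifest = {
        "format": "qfilter-set-1",
        "volume_type": fs.volume_type,
        "st_threshold": fs.st_threshold,
        "vol_binsize": fs.cfg.vol_binsize,
        "q_binsizes": dict(fs.cfg.q_binsizes),
        "n_entries": {c: len(fs.member(c).entries) for c in ("x", "y", "z")},
        "files": {c: paths[c].name for c in ("x", "y", "z")},
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    mpath = prefix.with_name(prefix.name + ".manifest.json")
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    paths["manifest"] = mpath
    return paths


def read_filter_set(prefix: str | Path) -> FilterSet:
    prefix = Path(prefix)
    q_binsizes = {
        comp: float(
            next(
                line.split(" ", 1)[1]
                for line in prefix.with_name(prefix.name + f".q{comp}.tsv")
                .read_text()
                .splitlines()
                if line.startswith("#q_binsize")
            )
        )
        for comp in ("x", "y", "z")
    }
    members = {
        comp: read_filter(prefix.with_name(prefix.name + f".q{comp}.tsv"), q_binsizes)
        for comp in ("x", "y", "z")
    }
    return FilterSet(fx=members["x"], fy=members["y"], fz=members["z"])


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    """Resolved settings of a CLI run; round-trips through YAML losslessly."""

    radii: dict[str, float] = field(default_factory=lambda: dict(BONDI_RADII))
    default_radius: float = 1.70
    include_hydrogens: bool = False
    amplitude: float = AMPLITUDE_DEFAULT
    max_order: int = 3
    vol_binsize: float = 5.0
    q_binsizes: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_Q_BINSIZES))
    volume_type: str = "mp"
    st_threshold: float = 0.80
    unknown_key_policy: str = "pass"
    seed: int | None = None
    log_level: str = "INFO"

    def descriptor_config(self) -> DescriptorConfig:
        return DescriptorConfig(
            radii=RadiusTable(dict(self.radii), self.default_radius),
            amplitude=self.amplitude,
            include_hydrogens=self.include_hydrogens,
            max_order=self.max_order,
        )

    def bin_config(self) -> BinConfig:
        return BinConfig(
            vol_binsize=self.vol_binsize,
            q_binsizes=dict(self.q_binsizes),
            volume_type=self.volume_type,
            st_threshold=self.st_threshold,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys in {path}: {sorted(unknown)}")
        return cls(**data)
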