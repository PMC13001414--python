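"""Readers and writers for the formats the pipeline touches.

Multi-model PDB (one MODEL per frame, REMARK 250 lines carrying the
variant label and per-model replica id), tidy dihedral/occupancy CSV,
HILLS-style metadynamics traces, PMF CSV, and YAML region-map / run
configuration files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .rama import DihedralSeries, RegionMap
from .synth import Ensemble
from .variants import PeptideSequence
from .wtm import Hill, HillTrace, PMFProfile

__all__ = [
    "write_ensemble_pdb",
    "read_ensemble_pdb",
    "dihedrals_to_csv",
    "dihedrals_from_csv",
    "write_hills",
    "read_hills",
    "pmf_to_csv",
    "region_map_to_yaml",
    "region_map_from_yaml",
]

_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}
_ONE = {v: k for k, v in _THREE.items()}


def write_ensemble_pdb(ensemble: Ensemble, path: str | Path) -> None:
    """Write a multi-model PDB; REMARK 250 lines carry variant/replica."""
    lines = [f"REMARK 250 VARIANT {ensemble.variant_label}"]
    seq = ensemble.sequence.residues
    for f in range(ensemble.n_frames):
        lines.append(f"MODEL     {f + 1:>4d}")
        lines.append(f"REMARK 250 REPLICA {int(ensemble.replica_ids[f])}")
        for a in range(ensemble.n_atoms):
            res = int(ensemble.atom_residues[a])
            name = ensemble.atom_names[a]
            x, y, z = ensemble.xyz[f, a]
            lines.append(
                f"ATOM  {a + 1:>5d} {name:<4s} {_THREE[seq[res - 1]]:>3s} A"
                f"{res:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
                f"          {ensemble.atom_elements[a]:>2s}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


class PDBParseError(ValueError):
    pass


def read_ensemble_pdb(path: str | Path) -> Ensemble:
    """Read a multi-model PDB written by :func:`write_ensemble_pdb`.

    Fixed-column ATOM parsing; replica ids and the variant label are taken
    from REMARK 250 lines when present (single replica 0 otherwise).
    Malformed ATOM records raise :class:`PDBParseError` naming the line.
    """
    variant_label = ""
    frames: list[np.ndarray] = []
    replica_ids: list[int] = []
    atom_names: list[str] = []
    atom_elements: list[str] = []
    atom_residues: list[int] = []
    residue_names: dict[int, str] = {}
    current: list[tuple[float, float, float]] | None = None
    current_replica = 0
    first_model = True

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            rec = raw.rstrip("\n")
            if rec.startswith("REMARK 250 VARIANT"):
                variant_label = rec[len("REMARK 250 VARIANT"):].strip()
            elif rec.startswith("REMARK 250 REPLICA"):
                current_replica = int(rec.split()[-1])
            elif rec.startswith("MODEL"):
                current = []
                current_replica = 0
            elif rec.startswith("ENDMDL"):
                if current is None:
                    raise PDBParseError(f"line {lineno}: ENDMDL without MODEL")
                frames.append(np.array(current))
                replica_ids.append(current_replica)
                current = None
                first_model = False
            elif rec.startswith("ATOM"):
                if current is None:
                    raise PDBParseError(f"line {lineno}: ATOM record outside MODEL")
                if len(rec) < 54:
                    raise PDBParseError(f"line {lineno}: truncated ATOM record")
                try:
                    name = rec[12:16].strip()
                    resname = rec[17:20].strip()
                    resseq = int(rec[22:26])
                    x = float(rec[30:38])
                    y = float(rec[38:46])
                    z = float(rec[46:54])
                except ValueError as exc:
                    raise PDBParseError(f"line {lineno}: malformed ATOM record ({exc})")
                element = rec[76:78].strip() if len(rec) >= 78 else name[0]
                current.append((x, y, z))
                if first_model:
                    atom_names.append(name)
                    atom_elements.append(element or name[0])
                    atom_residues.append(resseq)
                    residue_names[resseq] = resname
    if not frames:
        raise ValueError(f"{path}: no MODEL records found")
    xyz = np.stack(frames)
    seq = "".join(_ONE[residue_names[i]] for i in sorted(residue_names))
    return Ensemble(
        sequence=PeptideSequence(seq, label=variant_label),
        xyz=xyz,
        atom_names=atom_names,
        atom_elements=atom_elements,
        atom_residues=np.array(atom_residues),
        replica_ids=np.array(replica_ids),
        variant_label=variant_label,
    )


def dihedrals_to_csv(series: DihedralSeries, path: str | Path) -> None:
    """Tidy CSV: frame, replica, residue_index, phi, psi."""
    series.to_frame().to_csv(path, index=False, float_format="%.14g")


def dihedrals_from_csv(path: str | Path, variant_label: str = "") -> DihedralSeries:
    df = pd.read_csv(path)
    residues = np.sort(df["residue_index"].unique())
    piv_phi = df.pivot(index="frame", columns="residue_index", values="phi")
    piv_psi = df.pivot(index="frame", columns="residue_index", values="psi")
    replicas = df.groupby("frame")["replica"].first().sort_index()
    angles = np.stack(
        [piv_phi[residues].to_numpy(), piv_psi[residues].to_numpy()], axis=-1
    )
    return DihedralSeries(
        angles=angles,
        residue_indices=residues,
        replica_ids=replicas.to_numpy(),
        variant_label=variant_label,
    )


def write_hills(trace: HillTrace, path: str | Path) -> None:
    """HILLS-style whitespace table: time, center, width, height, biasf."""
    lines = [
        "#! FIELDS time center width height biasf",
        f"#! SET temperature {trace.temperature}",
        f"#! SET nominal_height {trace.nominal_height}",
    ]
    for h in trace.hills:
        lines.append(
            f"{h.time_index} {h.center:.10g} {h.width:.10g} "
            f"{h.height:.10g} {trace.bias_factor:.10g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_hills(path: str | Path) -> HillTrace:
    temperature = 310.0
    nominal = None
    rows = []
    bias_factor = None
    for raw in Path(path).read_text().splitlines():
        if raw.startswith("#! SET temperature"):
            temperature = float(raw.split()[-1])
        elif raw.startswith("#! SET nominal_height"):
            nominal = float(raw.split()[-1])
        elif raw.startswith("#"):
            continue
        elif raw.strip():
            t, c, w, h, bf = raw.split()
            rows.append((int(t), float(c), float(w), float(h)))
            bias_factor = float(bf)
    if not rows:
        raise ValueError(f"{path}: no hills found")
    if nominal is None:
        nominal = max(r[3] for r in rows)
    trace = HillTrace(
        nominal_height=nominal,
        width=rows[0][2],
        bias_factor=bias_factor,
        temperature=temperature,
    )
    trace.hills = [Hill(*r) for r in rows]
    return trace


def pmf_to_csv(profiles: list[PMFProfile], path: str | Path) -> None:
    """CSV with columns s, F, fraction (one block per profile)."""
    frames = [
        pd.DataFrame({"s": p.grid, "F": p.values, "fraction": p.fraction})
        for p in profiles
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.10g")


def region_map_to_yaml(region_map: RegionMap, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(region_map.to_dict()))


def region_map_from_yaml(path: str | Path) -> RegionMap:
    return RegionMap.from_dict(yaml.safe_load(Path(path).read_text()))
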