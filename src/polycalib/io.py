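"""Readers and writers for the package's plain-text formats.

* internal crystal format (``.crys``): key/value header + site table,
  carrying everything a :class:`~polycalib.crystal.UnitCell` needs;
* minimal CIF subset (via gemmi): cell parameters and the fractional-
  coordinate atom-site loop, with molecule membership and charges supplied
  through a sidecar table keyed by site label (CIF itself carries neither);
* force-field parameter table, experimental-target table (CSV), and an
  XYZ-like multi-frame trajectory with a time comment per frame.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .crystal import AtomSite, UnitCell
from .forcefield import ForceField, LJType
from .objectives import PolymorphTarget
from .properties import TrajectorySet

__all__ = [
    "write_crystal",
    "read_crystal",
    "read_cif",
    "read_sidecar",
    "write_sidecar",
    "read_forcefield",
    "write_forcefield",
    "read_targets",
    "write_targets",
    "read_xyz_trajectory",
    "write_xyz_trajectory",
    "ParseError",
]


class ParseError(ValueError):
    def __init__(self, path, line, message):
        super().__init__(f"{path}:{line}: {message}")
        self.path, self.line = path, line


# ------------------------------------------------------- internal crystal
def write_crystal(cell: UnitCell, path) -> None:
    lines = ["# polycalib crystal v1"]
    lines.append("lengths: {:.10g} {:.10g} {:.10g}".format(*cell.lengths))
    lines.append("angles: {:.10g} {:.10g} {:.10g}".format(*cell.angles))
    lines.append(f"formula_units: {cell.formula_units}")
    lines.append("sites:")
    lines.append("# label element atom_type fx fy fz charge molecule_id")
    for s in cell.sites:
        lines.append(
            f"{s.label} {s.element} {s.atom_type} "
            f"{s.frac_pos[0]:.12g} {s.frac_pos[1]:.12g} {s.frac_pos[2]:.12g} "
            f"{s.charge:.12g} {s.molecule_id}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_crystal(path) -> UnitCell:
    lengths = angles = None
    z = 1
    sites = []
    in_sites = False
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if not in_sites:
            try:
                key, _, rest = line.partition(":")
                key = key.strip()
                if key == "lengths":
                    lengths = tuple(float(x) for x in rest.split())
                elif key == "angles":
                    angles = tuple(float(x) for x in rest.split())
                elif key == "formula_units":
                    z = int(rest)
                elif key == "sites":
                    in_sites = True
                else:
                    raise ValueError(f"unknown key {key!r}")
            except ValueError as exc:
                raise ParseError(path, ln, str(exc)) from None
        else:
            parts = line.split()
            if len(parts) != 8:
                raise ParseError(path, ln, f"expected 8 fields, got {len(parts)}")
            try:
                sites.append(AtomSite(
                    parts[0], parts[1], parts[2],
                    (float(parts[3]), float(parts[4]), float(parts[5])),
                    float(parts[6]), int(parts[7]),
                ))
            except ValueError as exc:
                raise ParseError(path, ln, str(exc)) from None
    if lengths is None or angles is None:
        raise ParseError(path, 0, "missing lengths/angles header")
    return UnitCell(lengths, angles, tuple(sites), formula_units=z)


# ------------------------------------------------------------ minimal CIF
def read_cif(path, sidecar=None) -> UnitCell:
    """Minimal CIF reader: cell parameters + fractional atom sites.

    No symmetry expansion — the CIF must list the full cell contents.
    ``sidecar`` supplies atom types, charges and molecule membership by
    site label (see :func:`read_sidecar`); without it every site gets its
    label as atom type, zero charge, and its own molecule.
    """
    import gemmi

    doc = gemmi.cif.read_file(str(path))
    block = doc.sole_block()

    def need(tag: str) -> float:
        val = block.find_value(tag)
        if val is None:
            raise ParseError(path, 0, f"missing {tag}")
        return float(gemmi.cif.as_number(val))

    lengths = tuple(need(f"_cell_length_{x}") for x in "abc")
    angles = tuple(need(f"_cell_angle_{x}") for x in ("alpha", "beta", "gamma"))
    table = block.find(
        "_atom_site_",
        ["label", "type_symbol", "fract_x", "fract_y", "fract_z"],
    )
    if len(table) == 0:
        raise ParseError(path, 0, "no _atom_site_ loop found")
    extra = read_sidecar(sidecar) if sidecar is not None else {}
    sites = []
    for i, row in enumerate(table):
        label = row[0]
        meta = extra.get(label, {})
        sites.append(AtomSite(
            label=label,
            element=row[1],
            atom_type=meta.get("atom_type", label),
            frac_pos=tuple(float(gemmi.cif.as_number(row[j])) for j in (2, 3, 4)),
            charge=meta.get("charge", 0.0),
            molecule_id=meta.get("molecule_id", i),
        ))
    return UnitCell(lengths, angles, tuple(sites))


def read_sidecar(path) -> dict:
    """Per-label metadata table: ``label atom_type charge molecule_id``."""
    out = {}
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ParseError(path, ln, f"expected 4 fields, got {len(parts)}")
        out[parts[0]] = {
            "atom_type": parts[1],
            "charge": float(parts[2]),
            "molecule_id": int(parts[3]),
        }
    return out


def write_sidecar(cell: UnitCell, path) -> None:
    lines = ["# label atom_type charge molecule_id"]
    for s in cell.sites:
        lines.append(f"{s.label} {s.atom_type} {s.charge:.12g} {s.molecule_id}")
    Path(path).write_text("\n".join(lines) + "\n")


# -------------------------------------------------------------- forcefield
def write_forcefield(ff: ForceField, path) -> None:
    lines = [
        "# polycalib forcefield v1",
        f"combining_rule: {ff.combining_rule}",
        f"exclusion_policy: {ff.exclusion_policy}",
        f"scale14_lj: {ff.scale14_lj:.12g}",
        f"scale14_coulomb: {ff.scale14_coulomb:.12g}",
        "types:",
        "# atom_type sigma_A epsilon_kJmol",
    ]
    for t in sorted(ff.lj_types):
        lj = ff.lj_types[t]
        lines.append(f"{t} {lj.sigma:.12g} {lj.epsilon:.12g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_forcefield(path) -> ForceField:
    header = {}
    types = {}
    in_types = False
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if not in_types:
            key, _, rest = line.partition(":")
            key = key.strip()
            if key == "types":
                in_types = True
            else:
                header[key] = rest.strip()
        else:
            parts = line.split()
            if len(parts) != 3:
                raise ParseError(path, ln, f"expected 3 fields, got {len(parts)}")
            types[parts[0]] = LJType(parts[0], float(parts[1]), float(parts[2]))
    return ForceField(
        types,
        combining_rule=header.get("combining_rule", "geometric"),
        exclusion_policy=header.get("exclusion_policy", "rigid-molecule"),
        scale14_lj=float(header.get("scale14_lj", 0.5)),
        scale14_coulomb=float(header.get("scale14_coulomb", 0.5)),
    )


# ------------------------------------------------------------------ targets
def write_targets(targets: list[PolymorphTarget], path) -> None:
    rows = [
        {"polymorph": t.name, "e_latt_exp": t.e_latt_exp,
         "a": t.cell_exp[0], "b": t.cell_exp[1], "c": t.cell_exp[2],
         "alpha": t.cell_exp[3], "beta": t.cell_exp[4], "gamma": t.cell_exp[5]}
        for t in targets
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_targets(path) -> list[PolymorphTarget]:
    df = pd.read_csv(path)
    required = {"polymorph", "e_latt_exp", "a", "b", "c", "alpha", "beta", "gamma"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(path, 0, f"missing columns {sorted(missing)}")
    return [
        PolymorphTarget(
            str(r.polymorph), float(r.e_latt_exp),
            (float(r.a), float(r.b), float(r.c),
             float(r.alpha), float(r.beta), float(r.gamma)),
        )
        for r in df.itertuples()
    ]


# --------------------------------------------------------------- trajectory
def write_xyz_trajectory(traj: TrajectorySet, path, name: str = "COM") -> None:
    buf = _io.StringIO()
    for t, frame in zip(traj.times, traj.com_positions):
        buf.write(f"{len(frame)}\n")
        buf.write(f"t= {t:.6g} ps\n")
        for p in frame:
            buf.write(f"{name} {p[0]:.8g} {p[1]:.8g} {p[2]:.8g}\n")
    Path(path).write_text(buf.getvalue())


def read_xyz_trajectory(path) -> TrajectorySet:
    """Multi-frame XYZ-like file; each row is one molecule's unwrapped COM."""
    lines = Path(path).read_text().splitlines()
    times, frames = [], []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            nat = int(lines[i].strip())
        except ValueError:
            raise ParseError(path, i + 1, "expected atom count") from None
        comment = lines[i + 1]
        try:
            t = float(comment.replace("t=", "").replace("ps", "").strip().split()[0])
        except (ValueError, IndexError):
            raise ParseError(path, i + 2, "expected 't= <time> ps' comment") from None
        frame = np.empty((nat, 3))
        for k in range(nat):
            parts = lines[i + 2 + k].split()
            frame[k] = [float(x) for x in parts[1:4]]
        times.append(t)
        frames.append(frame)
        i += 2 + nat
    return TrajectorySet(np.array(times), np.array(frames))
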