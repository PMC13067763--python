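"""Structure-geometry bookkeeping for deaminase engineering.

Three small geometric analyses support interpretation of the engineered
variants: inter-residue distance panels around the DNA-binding pocket
entrance (the four "gatekeeper" residues at positions 31, 76, 84 and 106),
aggregation and ranking of alanine-scan pocket surface areas computed
externally on replicate predicted structures, and trilateration of a point
from its distances to three anchor residues.

Coordinates are read from PDB or mmCIF files via gemmi (first model,
altloc A preferred). Pocket surface areas are consumed from tables; pocket
detection itself is out of scope.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "StructureModel",
    "load_structure",
    "sidechain_reference_atom",
    "residue_distance",
    "entrance_panel",
    "aggregate_alanine_scan",
    "trilaterate",
    "TrilaterationResult",
]

#: Default side-chain reference atoms for the distance rule. Residues not
#: listed fall back to CB (CA for glycine).
_SIDECHAIN_ATOMS = {"LYS": "NZ", "TYR": "OH"}


@dataclass(frozen=True)
class StructureModel:
    """Atom coordinates keyed by (chain, residue number, atom name)."""

    atoms: Mapping[tuple[str, int, str], np.ndarray]
    residue_names: Mapping[tuple[str, int], str]

    def chains(self) -> set[str]:
        return {c for c, _r in self.residue_names}

    def coord(self, chain: str, resnum: int, atom: str) -> np.ndarray:
        key = (chain, resnum, atom)
        if key not in self.atoms:
            resname = self.residue_names.get((chain, resnum), "?")
            raise KeyError(
                f"atom {atom} missing for residue {resname}{resnum} chain {chain}"
            )
        return self.atoms[key]


def load_structure(path: str | Path) -> StructureModel:
    """Read a PDB or mmCIF file (first model; altloc A preferred)."""
    structure = gemmi.read_structure(str(path))
    structure.setup_entities()
    model = structure[0]
    atoms: dict[tuple[str, int, str], np.ndarray] = {}
    names: dict[tuple[str, int], str] = {}
    for chain in model:
        for residue in chain:
            resnum = residue.seqid.num
            names[(chain.name, resnum)] = residue.name
            for atom in residue:
                if atom.has_altloc() and atom.altloc != "A":
                    continue
                key = (chain.name, resnum, atom.name)
                if key not in atoms:
                    atoms[key] = np.array(
                        [atom.pos.x, atom.pos.y, atom.pos.z], dtype=float
                    )
    return StructureModel(atoms=atoms, residue_names=names)


def sidechain_reference_atom(resname: str) -> str:
    """Reference atom for a residue under the side-chain rule."""
    if resname.upper() == "GLY":
        return "CA"
    return _SIDECHAIN_ATOMS.get(resname.upper(), "CB")


AtomRule = Callable[[str], str]


def _resolve_rule(atom_rule: str | AtomRule) -> AtomRule:
    if callable(atom_rule):
        return atom_rule
    if atom_rule == "sidechain":
        return sidechain_reference_atom
    if atom_rule == "ca":
        return lambda _resname: "CA"
    raise ValueError(f"unknown atom rule {atom_rule!r}")


def residue_distance(
    model: StructureModel,
    res_a: int,
    res_b: int,
    atom_rule: str | AtomRule = "sidechain",
    chain: str | None = None,
) -> float:
    """Euclidean distance (Å) between rule-selected atoms of two residues.

    The default rule picks a side-chain reference atom per residue type
    (NZ for lysine, OH for tyrosine, CB otherwise, CA for glycine);
    ``atom_rule='ca'`` measures between alpha carbons instead. Missing
    residues or atoms raise with the offending residue named.
    """
    rule = _resolve_rule(atom_rule)
    if chain is None:
        chains = sorted(model.chains())
        if not chains:
            raise ValueError("empty structure model")
        chain = chains[0]
    coords = []
    for res in (res_a, res_b):
        if (chain, res) not in model.residue_names:
            raise KeyError(f"residue {res} not present in chain {chain}")
        resname = model.residue_names[(chain, res)]
        coords.append(model.coord(chain, res, rule(resname)))
    return float(np.linalg.norm(coords[0] - coords[1]))


def entrance_panel(
    model: StructureModel,
    gatekeepers: Iterable[int] = (31, 76, 84, 106),
    atom_rule: str | AtomRule = "sidechain",
    chain: str | None = None,
) -> pd.DataFrame:
    """All pairwise distances among the pocket-entrance gatekeeper residues.

    Returns a DataFrame with columns ``res_a``, ``res_b``, ``label``
    (e.g. ``"K31-K106"``), ``distance`` and ``atom_rule``; for four
    gatekeepers that is six rows. Distances equal
    :func:`residue_distance` outputs by construction.
    """
    residues = sorted(set(gatekeepers))
    if len(residues) < 2:
        raise ValueError("need at least two gatekeeper residues")
    if chain is None:
        chains = sorted(model.chains())
        if not chains:
            raise ValueError("empty structure model")
        chain = chains[0]
    one_letter = {
        "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
        "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
        "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
        "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    }
    rows = []
    rule_name = atom_rule if isinstance(atom_rule, str) else "custom"
    for a, b in itertools.combinations(residues, 2):
        for res in (a, b):
            if (chain, res) not in model.residue_names:
                raise KeyError(f"gatekeeper residue {res} missing from chain {chain}")
        la = one_letter.get(model.residue_names[(chain, a)], "X")
        lb = one_letter.get(model.residue_names[(chain, b)], "X")
        rows.append(
            (
                a,
                b,
                f"{la}{a}-{lb}{b}",
                residue_distance(model, a, b, atom_rule, chain),
                rule_name,
            )
        )
    return pd.DataFrame(
        rows, columns=["res_a", "res_b", "label", "distance", "atom_rule"]
    )


def aggregate_alanine_scan(areas: pd.DataFrame) -> pd.DataFrame:
    """Aggregate replicate pocket surface areas into a ranked position table.

    ``areas`` must carry columns ``position`` and ``area`` (Å²), one row
    per replicate structure prediction (the scanning design uses five
    replicates per position). Replicate areas are averaged per position
    and positions ranked by descending mean — rank 1, the largest mean
    pocket, is the key site; ties break toward the lower residue number.
    Returns a DataFrame with ``position``, ``n_replicates``,
    ``mean_area`` and ``rank``, sorted by rank.
    """
    required = {"position", "area"}
    if areas.empty or not required <= set(areas.columns):
        raise ValueError("areas table must be non-empty with position/area columns")
    agg = (
        areas.groupby("position")["area"]
        .agg(["count", "mean"])
        .rename(columns={"count": "n_replicates", "mean": "mean_area"})
        .reset_index()
    )
    agg = agg.sort_values(
        ["mean_area", "position"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    agg["rank"] = np.arange(1, len(agg) + 1)
    return agg


def key_site(scan_table: pd.DataFrame) -> int:
    """Position ranked first (largest mean pocket area)."""
    return int(scan_table.loc[scan_table["rank"] == 1, "position"].iloc[0])


@dataclass(frozen=True)
class TrilaterationResult:
    """Candidate points plus sphere-equation residuals (empty if none)."""

    points: tuple[np.ndarray, ...]
    residual: float


def trilaterate(
    anchors: Sequence[Sequence[float]],
    distances: Sequence[float],
    tolerance: float = 1e-6,
) -> TrilaterationResult:
    """Points at given distances from three non-collinear anchors.

    Solves the three sphere equations in the anchor plane's orthonormal
    frame. Returns 0, 1 or 2 candidate points: two mirror-image solutions
    in the generic case, one when the point lies in the anchor plane
    (within ``tolerance`` Å), none when the distances are inconsistent —
    then ``residual`` reports how far (Å) the best attempt misses.
    Collinear anchors raise.
    """
    p1, p2, p3 = (np.asarray(a, dtype=float) for a in anchors)
    r1, r2, r3 = (float(d) for d in distances)
    if min(r1, r2, r3) <= 0:
        raise ValueError("distances must be positive")

    ex = p2 - p1
    d = np.linalg.norm(ex)
    if d == 0:
        raise ValueError("anchors 1 and 2 coincide")
    ex = ex / d
    v3 = p3 - p1
    i = float(ex @ v3)
    ey = v3 - i * ex
    j = np.linalg.norm(ey)
    if j < 1e-12:
        raise ValueError("anchors are collinear")
    ey = ey / j
    ez = np.cross(ex, ey)

    x = (r1**2 - r2**2 + d**2) / (2 * d)
    y = (r1**2 - r3**2 + i**2 + j**2 - 2 * i * x) / (2 * j)
    z_sq = r1**2 - x**2 - y**2
    z = math.sqrt(max(z_sq, 0.0))
    base = p1 + x * ex + y * ey

    def residual(point: np.ndarray) -> float:
        return max(
            abs(float(np.linalg.norm(point - p)) - r)
            for p, r in ((p1, r1), (p2, r2), (p3, r3))
        )

    if z <= tolerance:
        res = residual(base)
        if res <= tolerance:
            return TrilaterationResult(points=(base,), residual=res)
        return TrilaterationResult(points=(), residual=res)
    points = (base + z * ez, base - z * ez)
    return TrilaterationResult(
        points=points, residual=max(residual(p) for p in points)
    )
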