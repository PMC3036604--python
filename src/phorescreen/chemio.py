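"""Molecule and activity I/O, physicochemical descriptors, and conformer ensembles.

Activities are half-maximal inhibitory concentrations (IC50, stored in µM)
and their negative base-10 logarithm on the molar scale (pIC50).  Molecular
flexibility is represented by a bounded conformer ensemble: at most
``max_conformers`` members (default 250) within an ``energy_window``
(default 20 kcal/mol) of the lowest-energy member, deduplicated by
heavy-atom RMSD.

Drug-likeness screening uses the rule-of-five: a molecule is flagged when
MW > 500 Da, logP > 5, H-bond donors > 5, or H-bond acceptors > 10 (strict
inequalities; a single violation rejects).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem, Crippen, Descriptors
from rdkit.Chem import rdMolAlign

from ._smarts import HBA_SMARTS, HBD_SMARTS

__all__ = [
    "ROLES",
    "MoleculeRecord",
    "DescriptorSet",
    "ConformerSet",
    "to_pic50",
    "to_ic50",
    "load_activity_table",
    "write_activity_table",
    "read_smiles",
    "read_sdf",
    "lipinski_filter",
    "compute_descriptors",
    "generate_conformers",
    "write_conformers_sdf",
]

ROLES = {"train", "test", "active", "decoy", "library"}

#: rule name -> (descriptor attribute, strict upper bound)
LIPINSKI_RULES = {
    "MW": ("mw", 500.0),
    "logP": ("logp", 5.0),
    "HBD": ("hbd_count", 5),
    "HBA": ("hba_count", 10),
}


def to_pic50(ic50_um: float) -> float:
    """pIC50 = -log10 of the molar IC50; input is in µM."""
    if ic50_um <= 0:
        raise ValueError(f"IC50 must be strictly positive, got {ic50_um}")
    return -math.log10(ic50_um * 1e-6)


def to_ic50(pic50: float) -> float:
    """Inverse of :func:`to_pic50`; returns µM."""
    return 10.0 ** (-pic50) * 1e6


@dataclass
class MoleculeRecord:
    """One ligand: identifier, structure, optional activity, role label."""

    id: str
    structure: str  # SMILES
    ic50: Optional[float] = None  # µM
    pic50: Optional[float] = None
    role: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ic50 is not None:
            if self.ic50 <= 0:
                raise ValueError(
                    f"record {self.id!r}: IC50 must be strictly positive, got {self.ic50}"
                )
            derived = to_pic50(self.ic50)
            if self.pic50 is None:
                self.pic50 = derived
            elif abs(self.pic50 - derived) > 1e-6:
                raise ValueError(
                    f"record {self.id!r}: pIC50 {self.pic50} inconsistent with IC50 {self.ic50} µM"
                )
        if self.role is not None and self.role not in ROLES:
            raise ValueError(f"record {self.id!r}: unknown role {self.role!r}")

    def mol(self) -> Chem.Mol:
        m = Chem.MolFromSmiles(self.structure)
        if m is None:
            raise ValueError(f"record {self.id!r}: unparseable structure {self.structure!r}")
        return m


@dataclass
class DescriptorSet:
    """Rule-of-five descriptors: MW (Da), logP, H-bond donor/acceptor counts."""

    mw: Optional[float] = None
    logp: Optional[float] = None
    hbd_count: Optional[int] = None
    hba_count: Optional[int] = None

    def __post_init__(self) -> None:
        if self.mw is not None and self.mw <= 0:
            raise ValueError(f"MW must be positive, got {self.mw}")
        for name in ("hbd_count", "hba_count"):
            v = getattr(self, name)
            if v is not None and (v < 0 or int(v) != v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")


@dataclass
class ConformerSet:
    """A bounded, deduplicated conformer ensemble for one molecule.

    ``conformers`` holds per-conformer (n_atoms, 3) coordinate arrays in Å;
    ``rel_energies`` are kcal/mol above the minimum-energy member.
    """

    molecule_id: str
    conformers: Sequence[np.ndarray]
    rel_energies: Sequence[float]
    seed: int
    max_conformers: int = 250
    energy_window: float = 20.0
    mol: Optional[Chem.Mol] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        n = len(self.conformers)
        if not (1 <= n <= self.max_conformers):
            raise ValueError(
                f"{self.molecule_id}: conformer count {n} outside [1, {self.max_conformers}]"
            )
        if len(self.rel_energies) != n:
            raise ValueError(f"{self.molecule_id}: energies/conformers length mismatch")
        e = np.asarray(self.rel_energies, dtype=float)
        if abs(float(e.min())) > 1e-9:
            raise ValueError(f"{self.molecule_id}: minimum relative energy must be 0")
        if float(e.max()) > self.energy_window + 1e-9:
            raise ValueError(
                f"{self.molecule_id}: relative energy {e.max():.3f} exceeds window "
                f"{self.energy_window}"
            )

    def __len__(self) -> int:
        return len(self.conformers)


# ---------------------------------------------------------------------------
# activity tables


def load_activity_table(path) -> list[MoleculeRecord]:
    """Read a CSV activity table (columns: id, smiles, ic50_um[, pic50, role]).

    pIC50 is populated for every record carrying an IC50; input order is
    preserved.  Duplicate ids reject the whole file; a non-positive IC50
    rejects the offending record by id.
    """
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    if "id" not in cols:
        raise ValueError(f"{path}: missing 'id' column")
    smi_col = cols.get("smiles") or cols.get("structure")
    if smi_col is None:
        raise ValueError(f"{path}: missing 'smiles' column")
    ic_col = cols.get("ic50_um") or cols.get("ic50")
    ids = df[cols["id"]].astype(str)
    dup = ids[ids.duplicated()].unique()
    if len(dup):
        raise ValueError(f"{path}: duplicate ids {sorted(dup)}")
    records = []
    for _, row in df.iterrows():
        ic50 = None
        if ic_col is not None and pd.notna(row[ic_col]):
            ic50 = float(row[ic_col])
        pic50 = None
        if "pic50" in cols and pd.notna(row[cols["pic50"]]):
            pic50 = float(row[cols["pic50"]])
        role = None
        if "role" in cols and pd.notna(row[cols["role"]]):
            role = str(row[cols["role"]])
        records.append(
            MoleculeRecord(
                id=str(row[cols["id"]]),
                structure=str(row[smi_col]),
                ic50=ic50,
                pic50=pic50,
                role=role,
            )
        )
    return records


def write_activity_table(records: Sequence[MoleculeRecord], path) -> None:
    pd.DataFrame(
        {
            "id": [r.id for r in records],
            "smiles": [r.structure for r in records],
            "ic50_um": [r.ic50 for r in records],
            "pic50": [r.pic50 for r in records],
            "role": [r.role for r in records],
        }
    ).to_csv(path, index=False)


def read_sdf(path) -> list[MoleculeRecord]:
    """Read a V2000 SDF into molecule records (id from the title line)."""
    records = []
    supplier = Chem.SDMolSupplier(str(path), removeHs=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            raise ValueError(f"{path}: unparseable molecule at index {i}")
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{i}"
        records.append(MoleculeRecord(id=name, structure=Chem.MolToSmiles(mol)))
    return records


def read_smiles(path) -> list[MoleculeRecord]:
    """Read one-per-line ``SMILES id`` records."""
    records = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        smiles = parts[0]
        mid = parts[1] if len(parts) > 1 else f"mol{i}"
        records.append(MoleculeRecord(id=mid, structure=smiles))
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate ids")
    return records


# ---------------------------------------------------------------------------
# descriptors and drug-likeness


def _count_smarts_atoms(mol: Chem.Mol, smarts_list) -> int:
    atoms = set()
    for smarts in smarts_list:
        patt = Chem.MolFromSmarts(smarts)
        for match in mol.GetSubstructMatches(patt):
            atoms.add(match[0])
    return len(atoms)


def compute_descriptors(m: MoleculeRecord | Chem.Mol | str) -> DescriptorSet:
    """MW, Crippen logP, and H-bond donor/acceptor atom counts.

    Donor/acceptor counts use the shipped perception dictionary (one count
    per donor/acceptor heavy atom), keeping the rule-of-five filter
    consistent with 3D feature perception.
    """
    if isinstance(m, MoleculeRecord):
        mol = m.mol()
    elif isinstance(m, str):
        mol = Chem.MolFromSmiles(m)
        if mol is None:
            raise ValueError(f"unparseable structure {m!r}")
    else:
        mol = m
    return DescriptorSet(
        mw=Descriptors.MolWt(mol),
        logp=Crippen.MolLogP(mol),
        hbd_count=_count_smarts_atoms(mol, HBD_SMARTS),
        hba_count=_count_smarts_atoms(mol, HBA_SMARTS),
    )


def lipinski_filter(d: DescriptorSet) -> tuple[bool, list[str]]:
    """Rule-of-five check: returns (passes, violated rule names).

    A single strict-inequality violation fails the molecule.
    """
    violations = []
    for rule, (attr, bound) in LIPINSKI_RULES.items():
        value = getattr(d, attr)
        if value is None:
            raise ValueError(f"missing descriptor {attr!r} required for rule {rule}")
        if value > bound:
            violations.append(rule)
    return (len(violations) == 0, violations)


# ---------------------------------------------------------------------------
# conformers


def _heavy_rmsd_dedup(mol: Chem.Mol, conf_ids: list[int], threshold: float) -> list[int]:
    """Greedy energy-ordered dedup by best heavy-atom RMSD."""
    heavy = Chem.RemoveHs(mol)
    kept: list[int] = []
    for cid in conf_ids:
        dup = False
        for kid in kept:
            if rdMolAlign.GetBestRMS(heavy, heavy, prbId=cid, refId=kid) < threshold:
                dup = True
                break
        if not dup:
            kept.append(cid)
    return kept


def generate_conformers(
    m: MoleculeRecord,
    max_conformers: int = 250,
    energy_window: float = 20.0,
    seed: int = 0,
    dedup_rmsd: float = 0.5,
) -> ConformerSet:
    """Distance-geometry conformer ensemble with force-field ranking.

    ETKDG embedding (seeded, deterministic) followed by MMFF94 minimization;
    members above ``energy_window`` kcal/mol of the minimum are discarded and
    near-duplicate geometries (heavy-atom RMSD < ``dedup_rmsd`` Å) removed.
    """
    if max_conformers < 1:
        raise ValueError(f"max_conformers must be >= 1, got {max_conformers}")
    mol = Chem.AddHs(m.mol())
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) & 0x7FFFFFFF
    params.pruneRmsThresh = dedup_rmsd
    params.numThreads = 1
    cids = list(AllChem.EmbedMultipleConfs(mol, numConfs=max_conformers, params=params))
    if not cids:
        raise ValueError(f"record {m.id!r}: 3D embedding failed")
    energies = {}
    if AllChem.MMFFHasAllMoleculeParams(mol):
        results = AllChem.MMFFOptimizeMoleculeConfs(mol, numThreads=1, maxIters=500)
        for cid, (converged, energy) in zip(cids, results):
            energies[cid] = float(energy)
    else:  # pragma: no cover - exotic elements only
        results = AllChem.UFFOptimizeMoleculeConfs(mol, numThreads=1, maxIters=500)
        for cid, (converged, energy) in zip(cids, results):
            energies[cid] = float(energy)
    e_min = min(energies.values())
    ordered = sorted(cids, key=lambda c: (energies[c], c))
    within = [c for c in ordered if energies[c] - e_min <= energy_window]
    kept = _heavy_rmsd_dedup(mol, within, dedup_rmsd)[:max_conformers]
    coords = [np.array(mol.GetConformer(c).GetPositions(), dtype=float) for c in kept]
    rel = [energies[c] - e_min for c in kept]
    return ConformerSet(
        molecule_id=m.id,
        conformers=coords,
        rel_energies=rel,
        seed=int(seed),
        max_conformers=max_conformers,
        energy_window=energy_window,
        mol=mol,
    )


def write_conformers_sdf(cs: ConformerSet, path) -> None:
    """Write the ensemble as a multi-record V2000 SDF."""
    if cs.mol is None:
        raise ValueError(f"{cs.molecule_id}: no structure attached to ensemble")
    writer = Chem.SDWriter(str(path))
    mol = Chem.Mol(cs.mol)
    mol.RemoveAllConformers()
    for i, xyz in enumerate(cs.conformers):
        conf = Chem.Conformer(mol.GetNumAtoms())
        for a in range(mol.GetNumAtoms()):
            conf.SetAtomPosition(a, [float(x) for x in xyz[a]])
        conf.SetId(i)
        mol.AddConformer(conf, assignId=False)
    for i in range(len(cs.conformers)):
        mol.SetProp("_Name", cs.molecule_id)
        mol.SetProp("rel_energy_kcal_mol", f"{cs.rel_energies[i]:.4f}")
        writer.write(mol, confId=i)
    writer.close()
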