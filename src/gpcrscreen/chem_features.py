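"""Molecular feature representation for GPCR ligand classification.

A ligand is represented by five physicochemical descriptors (MW, LogP,
HBD, HBA, TPSA — supplied as inputs, typically sourced from PubChem or
SwissADME), its docking-derived conformational-selectivity score
(``DeltaAffinity``), and a 2048-bit radius-2 circular (Morgan/ECFP4)
fingerprint.  Fingerprint bits are hashed atom environments; the module
keeps the bit -> atom-environment map so that influential bits can be
translated back into substructure fragments.

Note on bit indices: hashed fingerprints are implementation-specific, so
bit numbers are only meaningful within one fingerprinting configuration.
Downstream analyses refer to "top-k bits" positionally, never to absolute
indices from other toolchains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

__all__ = [
    "LigandRecord",
    "Fingerprint",
    "DESCRIPTOR_COLUMNS",
    "FEATURE_COLUMNS",
    "compute_fingerprint",
    "count_lipinski_violations",
    "map_bit_to_substructures",
    "build_feature_matrix",
    "read_ligand_table",
    "write_feature_matrix",
    "read_feature_matrix",
]

DEFAULT_RADIUS = 2
DEFAULT_NBITS = 2048

#: Descriptor block, in the fixed feature-matrix order.
DESCRIPTOR_COLUMNS = ("MW", "LogP", "HBD", "HBA", "TPSA", "DeltaAffinity")


def FEATURE_COLUMNS(nbits: int = DEFAULT_NBITS) -> list[str]:
    """Full feature-matrix column order: descriptors then bit_0000..bit_NNNN."""
    return list(DESCRIPTOR_COLUMNS) + [f"bit_{i:04d}" for i in range(nbits)]


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecular graph."""


@dataclass
class Fingerprint:
    """Folded binary circular fingerprint with its bit -> environment map.

    ``bit_atom_map`` maps a set bit index to the ``(atom_index, radius)``
    environments that hashed to it (several environments may collide on
    one bit).
    """

    bits: np.ndarray
    radius: int = DEFAULT_RADIUS
    nbits: int = DEFAULT_NBITS
    bit_atom_map: dict[int, tuple[tuple[int, int], ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.shape != (self.nbits,):
            raise ValueError(
                f"fingerprint length {self.bits.shape} does not match nbits={self.nbits}"
            )

    @property
    def on_bits(self) -> np.ndarray:
        return np.flatnonzero(self.bits)


@dataclass
class LigandRecord:
    """One molecule with descriptors, optional fingerprint and functional label.

    ``label`` follows the classification convention agonist=0, antagonist=1;
    ``None`` means unknown (e.g. screening-library compounds).  Synthetic
    compounds may carry a fingerprint directly and no SMILES.
    """

    ligand_id: str
    mw: float
    logp: float
    hbd: float
    hba: float
    tpsa: float
    smiles: str | None = None
    label: int | None = None
    fingerprint: Fingerprint | None = None

    def __post_init__(self) -> None:
        if self.mw is not None and not self.mw > 0:
            raise ValueError(f"ligand {self.ligand_id}: mw must be positive, got {self.mw}")
        for name in ("hbd", "hba", "tpsa"):
            val = getattr(self, name)
            if val is not None and val < 0:
                raise ValueError(f"ligand {self.ligand_id}: {name} must be >= 0, got {val}")
        if self.label not in (0, 1, None):
            raise ValueError(f"ligand {self.ligand_id}: label must be 0, 1 or None")

    def descriptors(self) -> dict[str, float]:
        missing = [n for n in ("mw", "logp", "hbd", "hba", "tpsa") if getattr(self, n) is None]
        if missing:
            raise ValueError(
                f"ligand {self.ligand_id}: missing descriptor(s) {', '.join(missing)}"
            )
        return {
            "MW": float(self.mw),
            "LogP": float(self.logp),
            "HBD": float(self.hbd),
            "HBA": float(self.hba),
            "TPSA": float(self.tpsa),
        }


def _parse_smiles(smiles: str, ligand_id: str | None = None) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        who = f" (ligand {ligand_id})" if ligand_id else ""
        raise SmilesParseError(f"unparsable SMILES{who}: {smiles!r}")
    return mol


def compute_fingerprint(
    smiles: str,
    radius: int = DEFAULT_RADIUS,
    nbits: int = DEFAULT_NBITS,
    *,
    use_chirality: bool = False,
    ligand_id: str | None = None,
) -> Fingerprint:
    """Hash circular atom environments of radius 0..`radius` into `nbits` bits.

    The atom invariants are the standard connectivity set (element, degree,
    charge, attached hydrogens, ring membership); stereochemistry is ignored
    unless ``use_chirality`` is set.  Deterministic: equivalent SMILES of the
    same molecule (aromatic or kekulized) yield identical bit vectors.
    """
    mol = _parse_smiles(smiles, ligand_id)
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=radius, fpSize=nbits, includeChirality=use_chirality
    )
    ao = rdFingerprintGenerator.AdditionalOutput()
    ao.AllocateBitInfoMap()
    bv = gen.GetFingerprint(mol, additionalOutput=ao)
    bits = np.zeros(nbits, dtype=np.uint8)
    bits[list(bv.GetOnBits())] = 1
    bit_map = {
        int(b): tuple((int(a), int(r)) for a, r in envs)
        for b, envs in ao.GetBitInfoMap().items()
    }
    return Fingerprint(bits=bits, radius=radius, nbits=nbits, bit_atom_map=bit_map)


def count_lipinski_violations(record: LigandRecord) -> int:
    """Count violations of the classic four drug-likeness rules.

    Rules: MW > 500 g/mol, LogP > 5, HBD > 5, HBA > 10.  Libraries are
    conventionally pre-filtered at "no more than one violation".
    """
    d = record.descriptors()
    return int(d["MW"] > 500) + int(d["LogP"] > 5) + int(d["HBD"] > 5) + int(d["HBA"] > 10)


def _environment_fragment(mol: Chem.Mol, atom_idx: int, env_radius: int) -> str:
    """SMILES fragment of the circular environment that set a bit."""
    if env_radius == 0:
        return Chem.MolFragmentToSmiles(mol, atomsToUse=[atom_idx], canonical=True)
    bond_ids = Chem.FindAtomEnvironmentOfRadiusN(mol, env_radius, atom_idx)
    atoms = {atom_idx}
    for bid in bond_ids:
        bond = mol.GetBondWithIdx(bid)
        atoms.add(bond.GetBeginAtomIdx())
        atoms.add(bond.GetEndAtomIdx())
    return Chem.MolFragmentToSmiles(
        mol, atomsToUse=sorted(atoms), bondsToUse=list(bond_ids), canonical=True
    )


def map_bit_to_substructures(
    ligands: Sequence[LigandRecord],
    bit: int,
    radius: int = DEFAULT_RADIUS,
    nbits: int = DEFAULT_NBITS,
) -> list[str]:
    """Fragment SMILES of every atom environment that sets `bit` in the collection.

    Returns an empty list when no ligand sets the bit.  Ligands without a
    SMILES (pure-fingerprint synthetic compounds) cannot be mapped and are
    skipped.
    """
    if not 0 <= bit < nbits:
        raise ValueError(f"bit {bit} out of range for nbits={nbits}")
    fragments: list[str] = []
    seen: set[str] = set()
    for rec in ligands:
        if rec.smiles is None:
            continue
        fp = rec.fingerprint
        if fp is None or fp.nbits != nbits or fp.radius != radius:
            fp = compute_fingerprint(rec.smiles, radius, nbits, ligand_id=rec.ligand_id)
        envs = fp.bit_atom_map.get(bit)
        if not envs:
            continue
        mol = _parse_smiles(rec.smiles, rec.ligand_id)
        for atom_idx, env_radius in envs:
            frag = _environment_fragment(mol, atom_idx, env_radius)
            if frag not in seen:
                seen.add(frag)
                fragments.append(frag)
    return fragments


def build_feature_matrix(
    ligands: Sequence[LigandRecord],
    affinities: Mapping[str, float] | Sequence,
    radius: int = DEFAULT_RADIUS,
    nbits: int = DEFAULT_NBITS,
) -> pd.DataFrame:
    """Assemble the model's feature matrix: descriptors + DeltaAffinity + bits.

    Parameters
    ----------
    ligands:
        Feature rows, in the order they should appear.
    affinities:
        Target-receptor ``DeltaAffinity`` per ligand id — either a mapping
        ``ligand_id -> value`` or a sequence of objects with ``ligand_id``
        and ``delta_affinity`` attributes.

    Returns a DataFrame indexed by ligand id, with the fixed column order
    ``MW, LogP, HBD, HBA, TPSA, DeltaAffinity, bit_0000 .. bit_{nbits-1}``.
    """
    if not isinstance(affinities, Mapping):
        amap: dict[str, float] = {}
        for rec in affinities:
            if rec.ligand_id in amap:
                raise ValueError(f"duplicate affinity record for ligand {rec.ligand_id}")
            amap[rec.ligand_id] = rec.delta_affinity
        affinities = amap
    missing = [r.ligand_id for r in ligands if r.ligand_id not in affinities]
    if missing:
        raise ValueError(f"ligands missing a target-receptor affinity: {missing}")

    columns = FEATURE_COLUMNS(nbits)
    rows = np.empty((len(ligands), len(columns)), dtype=float)
    ids = []
    for i, rec in enumerate(ligands):
        d = rec.descriptors()
        fp = rec.fingerprint
        if fp is None:
            if rec.smiles is None:
                raise ValueError(f"ligand {rec.ligand_id} has neither fingerprint nor SMILES")
            fp = compute_fingerprint(rec.smiles, radius, nbits, ligand_id=rec.ligand_id)
        elif fp.nbits != nbits:
            raise ValueError(
                f"ligand {rec.ligand_id}: fingerprint nbits {fp.nbits} != expected {nbits}"
            )
        rows[i, :5] = [d["MW"], d["LogP"], d["HBD"], d["HBA"], d["TPSA"]]
        rows[i, 5] = float(affinities[rec.ligand_id])
        rows[i, 6:] = fp.bits
        ids.append(rec.ligand_id)
    return pd.DataFrame(rows, index=pd.Index(ids, name="ligand_id"), columns=columns)


# ---------------------------------------------------------------------------
# I/O

def read_ligand_table(path) -> list[LigandRecord]:
    """Read ligands from delimited text.

    Two layouts are accepted: a headered CSV/TSV with at least a
    ``ligand_id`` column plus either a ``smiles`` column or precomputed
    fingerprint columns ``bit_0000..`` (descriptor columns
    ``mw, logp, hbd, hba, tpsa`` and ``label`` optional), or a plain
    two-column ``id<TAB>smiles`` file without a header.
    """
    with open(path) as fh:
        first = fh.readline()
    if "ligand_id" in first.lower():
        sep = "\t" if "\t" in first else ","
        df = pd.read_csv(path, sep=sep)
        df.columns = [c.strip().lower() for c in df.columns]
        bit_cols = sorted(c for c in df.columns if c.startswith("bit_"))
        records = []
        for _, row in df.iterrows():
            label = row.get("label")
            if label is not None and (isinstance(label, float) and math.isnan(label)):
                label = None
            fingerprint = None
            if bit_cols:
                bits = row[bit_cols].to_numpy(dtype=np.uint8)
                fingerprint = Fingerprint(bits=bits, radius=DEFAULT_RADIUS,
                                          nbits=len(bit_cols))
            records.append(
                LigandRecord(
                    ligand_id=str(row["ligand_id"]),
                    smiles=str(row["smiles"]) if "smiles" in df.columns else None,
                    mw=float(row.get("mw", math.nan)),
                    logp=float(row.get("logp", math.nan)),
                    hbd=float(row.get("hbd", math.nan)),
                    hba=float(row.get("hba", math.nan)),
                    tpsa=float(row.get("tpsa", math.nan)),
                    label=int(label) if label is not None else None,
                    fingerprint=fingerprint,
                )
            )
        return records
    # headerless id<TAB>smiles
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            lig_id, smiles = line.split("\t" if "\t" in line else ",", 1)
            records.append(
                LigandRecord(
                    ligand_id=lig_id.strip(), smiles=smiles.strip(),
                    mw=None, logp=None, hbd=None, hba=None, tpsa=None,
                )
            )
    return records


def write_feature_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, index=True)


def read_feature_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="ligand_id")
    bit_cols = [c for c in df.columns if c.startswith("bit_")]
    df[bit_cols] = df[bit_cols].astype(float)
    return df
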