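"""Docking-derived conformational-selectivity scores.

Each ligand is docked against two conformers of every receptor in the
panel: the *active* (G-protein-coupled / agonist-bound) state and the
*inactive* (resting / antagonist-bound) state.  This module turns the
best-pose binding free energies (kcal/mol) into:

* ``DeltaAffinity`` = dG(active) - dG(inactive).  Positive values mean
  the ligand binds the inactive conformer more tightly — the behaviour
  expected of an antagonist.
* the *off-target score* = sum of |DeltaAffinity| over every panel
  receptor other than the screening target — a promiscuity proxy
  (higher = more promiscuous).

Docking itself happens upstream (e.g. AutoDock Vina); this module only
ingests its per-pose results.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "DockingRecord",
    "AffinityRecord",
    "OffTargetProfile",
    "delta_affinity",
    "pair_docking_records",
    "apply_borderline_exclusion",
    "off_target_score",
    "build_offtarget_profiles",
    "screen_affinity_filter",
    "read_docking_csv",
    "parse_vina_log",
    "BORDERLINE_WINDOW",
]

logger = logging.getLogger(__name__)

#: Half-width (kcal/mol) of the borderline band around DeltaAffinity = 0
#: inside which a ligand's conformer preference is considered noise.
BORDERLINE_WINDOW = 0.3

CONFORMERS = ("active", "inactive")


@dataclass(frozen=True)
class DockingRecord:
    """Best-pose binding free energy for one (ligand, receptor, conformer)."""

    ligand_id: str
    receptor_id: str
    conformer: str  # "active" | "inactive"
    dg: float  # kcal/mol

    def __post_init__(self) -> None:
        if self.conformer not in CONFORMERS:
            raise ValueError(f"conformer must be one of {CONFORMERS}, got {self.conformer!r}")
        if not math.isfinite(self.dg):
            raise ValueError(
                f"non-finite dG for ({self.ligand_id}, {self.receptor_id}, {self.conformer})"
            )


@dataclass(frozen=True)
class AffinityRecord:
    """DeltaAffinity (kcal/mol) of one ligand on one receptor."""

    ligand_id: str
    receptor_id: str
    delta_affinity: float


@dataclass
class OffTargetProfile:
    """Per-receptor DeltaAffinity map and the summed off-target score."""

    ligand_id: str
    target_receptor: str
    per_receptor: dict[str, float]
    off_target_score: float

    @property
    def target_delta_affinity(self) -> float | None:
        return self.per_receptor.get(self.target_receptor)


def delta_affinity(dg_active: float, dg_inactive: float) -> float:
    """dG(active) − dG(inactive); positive ⇒ inactive-state preference."""
    if not (math.isfinite(dg_active) and math.isfinite(dg_inactive)):
        raise ValueError("binding free energies must be finite")
    return dg_active - dg_inactive


def pair_docking_records(
    records: Iterable[DockingRecord],
    *,
    strict: bool = False,
) -> list[AffinityRecord]:
    """Pair active/inactive dG per (ligand, receptor) into AffinityRecords.

    Duplicate (ligand, receptor, conformer) entries are an error: pose
    selection is the docking tool's job, so exactly one best-pose energy is
    accepted per cell.  A (ligand, receptor) with only one conformer docked
    is skipped with a warning (or raises if ``strict``).
    """
    table: dict[tuple[str, str], dict[str, float]] = {}
    order: list[tuple[str, str]] = []
    for rec in records:
        key = (rec.ligand_id, rec.receptor_id)
        entry = table.setdefault(key, {})
        if key not in order:
            order.append(key)
        if rec.conformer in entry:
            raise ValueError(
                f"duplicate docking record for ({rec.ligand_id}, {rec.receptor_id}, "
                f"{rec.conformer}); one best-pose energy per cell"
            )
        entry[rec.conformer] = rec.dg
    out: list[AffinityRecord] = []
    for key in order:
        entry = table[key]
        if len(entry) < 2:
            msg = f"ligand {key[0]} lacks the {next(c for c in CONFORMERS if c not in entry)!r} conformer on receptor {key[1]}"
            if strict:
                raise ValueError(msg)
            logger.warning("%s; skipping", msg)
            continue
        out.append(
            AffinityRecord(key[0], key[1], delta_affinity(entry["active"], entry["inactive"]))
        )
    return out


def apply_borderline_exclusion(
    records: Sequence[AffinityRecord],
    window: float = BORDERLINE_WINDOW,
    keep_ids: Iterable[str] = (),
) -> list[AffinityRecord]:
    """Drop ligands whose |DeltaAffinity| falls inside the borderline band.

    Ligands with |DeltaAffinity| <= window (closed interval) show no clear
    conformer preference and are excluded, except ids in ``keep_ids``
    (e.g. an endogenous ligand retained for physiological relevance).
    Survivors keep their input order.
    """
    if not window > 0:
        raise ValueError("window must be positive")
    keep = set(keep_ids)
    survivors = []
    for rec in records:
        if abs(rec.delta_affinity) <= window and rec.ligand_id not in keep:
            logger.info(
                "borderline exclusion: %s on %s (DeltaAffinity=%.3f)",
                rec.ligand_id, rec.receptor_id, rec.delta_affinity,
            )
            continue
        survivors.append(rec)
    return survivors


def off_target_score(
    per_receptor: Mapping[str, float],
    target: str,
) -> float:
    """Sum |DeltaAffinity| over every receptor except the target."""
    if not per_receptor:
        logger.warning("off_target_score: empty receptor map; returning 0.0")
        return 0.0
    return float(sum(abs(v) for r, v in per_receptor.items() if r != target))


def build_offtarget_profiles(
    records: Sequence[AffinityRecord],
    target: str,
) -> list[OffTargetProfile]:
    """Aggregate panel AffinityRecords into one OffTargetProfile per ligand."""
    per_ligand: dict[str, dict[str, float]] = {}
    order: list[str] = []
    for rec in records:
        if rec.ligand_id not in per_ligand:
            per_ligand[rec.ligand_id] = {}
            order.append(rec.ligand_id)
        per_ligand[rec.ligand_id][rec.receptor_id] = rec.delta_affinity
    return [
        OffTargetProfile(
            ligand_id=lid,
            target_receptor=target,
            per_receptor=per_ligand[lid],
            off_target_score=off_target_score(per_ligand[lid], target),
        )
        for lid in order
    ]


def screen_affinity_filter(
    records: Sequence[AffinityRecord],
    threshold: float = BORDERLINE_WINDOW,
) -> list[AffinityRecord]:
    """Keep target-receptor records with DeltaAffinity strictly above threshold.

    This is the antagonist-consistency filter of the screening funnel:
    it retains compounds with a clear (> threshold kcal/mol) preference for
    the inactive conformer.  Complementary to `apply_borderline_exclusion`
    (which removes |Δ| <= window): together they partition the sign-positive
    axis with no gap.
    """
    return [r for r in records if r.delta_affinity > threshold]


# ---------------------------------------------------------------------------
# I/O

DOCKING_COLUMNS = ("ligand_id", "receptor_id", "conformer", "dg_kcal_mol")


def read_docking_csv(path) -> list[DockingRecord]:
    """Read the canonical docking table (CSV with DOCKING_COLUMNS)."""
    df = pd.read_csv(path)
    missing = [c for c in DOCKING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"docking table {path} missing column(s): {missing}")
    return [
        DockingRecord(
            ligand_id=str(r.ligand_id),
            receptor_id=str(r.receptor_id),
            conformer=str(r.conformer).strip().lower(),
            dg=float(r.dg_kcal_mol),
        )
        for r in df.itertuples(index=False)
    ]


def write_docking_csv(records: Sequence[DockingRecord], path) -> None:
    pd.DataFrame(
        [(r.ligand_id, r.receptor_id, r.conformer, r.dg) for r in records],
        columns=list(DOCKING_COLUMNS),
    ).to_csv(path, index=False)


_VINA_RESULT = re.compile(r"^\s*(\d+)\s+(-?\d+(?:\.\d+)?)\s+[\d.]+\s+[\d.]+\s*$")


def parse_vina_log(text: str) -> float:
    """Best-pose affinity (kcal/mol) from an AutoDock Vina log excerpt.

    Tolerant: scans for the result table and returns the affinity of the
    first (best) mode, i.e. the first line matching
    ``<mode>  <affinity>  <rmsd l.b.>  <rmsd u.b.>``.
    """
    for line in text.splitlines():
        if line.lstrip().startswith("REMARK"):
            continue
        m = _VINA_RESULT.match(line)
        if m:
            return float(m.group(2))
    raise ValueError("no Vina result line found in log text")
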