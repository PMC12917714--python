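"""Multi-stage virtual-screening funnel for selective antagonist candidates.

Stages, in order:

1. *Substructure filter*: keep library compounds whose fingerprint sets at
   least one (``any``, default) or all (``all``) of the top antagonist-driver
   bits identified by attribution.
2. *Affinity filter*: keep compounds with target-receptor DeltaAffinity
   strictly above the borderline threshold (inactive-conformer preference).
3. *Classifier*: predict with the trained SVM; keep predicted antagonists.
4. *Confidence percentile*: keep the top (100 − pct)% most confidently
   predicted antagonists.
5. *Off-target prioritization*: rank survivors by ascending off-target
   score (ties: descending target DeltaAffinity, then ligand id).
6. *Bit–selectivity correlation*: Spearman correlation between each
   informative fingerprint bit (prevalence strictly between 0 and 1 in the
   prioritized set) and the off-target score; positive r flags
   promiscuity-associated substructures, negative r selectivity-associated
   ones.

Candidate counts are non-increasing through the funnel, and re-running the
funnel on its own survivors is the identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .affinity_scoring import OffTargetProfile
from .attribution import TopBits
from .chem_features import LigandRecord, compute_fingerprint
from .classifier import PredictionRecord

__all__ = [
    "ScreeningCandidate",
    "BitCorrelation",
    "substructure_filter",
    "percentile_select",
    "prioritize",
    "informative_bits",
    "bit_offtarget_correlation",
    "SELECTIVITY_R_THRESHOLD",
]

logger = logging.getLogger(__name__)

#: Spearman-r threshold below which a bit is flagged as selectivity-associated.
SELECTIVITY_R_THRESHOLD = -0.4


@dataclass
class ScreeningCandidate:
    """A library compound's state as it moves through the funnel."""

    ligand: LigandRecord
    source_library: str = ""
    target_delta_affinity: float | None = None
    prediction: PredictionRecord | None = None
    off_target: OffTargetProfile | None = None

    @property
    def ligand_id(self) -> str:
        return self.ligand.ligand_id


@dataclass(frozen=True)
class BitCorrelation:
    bit: int
    spearman_r: float

    @property
    def direction(self) -> str:
        return "off-target-associated" if self.spearman_r > 0 else "selectivity-associated"

    @property
    def selective(self) -> bool:
        return self.spearman_r < SELECTIVITY_R_THRESHOLD


def _bits_of(record: LigandRecord) -> np.ndarray:
    fp = record.fingerprint
    if fp is None:
        if record.smiles is None:
            raise ValueError(f"ligand {record.ligand_id} has neither fingerprint nor SMILES")
        fp = compute_fingerprint(record.smiles, ligand_id=record.ligand_id)
        record.fingerprint = fp
    return fp.bits


def substructure_filter(
    library: Sequence[LigandRecord],
    top_bits: TopBits | Sequence[int],
    mode: str = "any",
) -> list[LigandRecord]:
    """Keep compounds setting >=1 ('any') or all ('all') of the driver bits.

    Fingerprints must use the training configuration (same radius/nbits),
    otherwise bit indices are meaningless.
    """
    bits = list(top_bits)
    if not bits:
        raise ValueError("top_bits is empty; nothing to filter on")
    if mode not in ("any", "all"):
        raise ValueError(f"mode must be 'any' or 'all', got {mode!r}")
    kept = []
    for rec in library:
        fp_bits = _bits_of(rec)
        hits = sum(int(fp_bits[b]) for b in bits)
        if (mode == "any" and hits >= 1) or (mode == "all" and hits == len(bits)):
            kept.append(rec)
    logger.info("substructure filter (%s of %d bits): %d/%d compounds retained",
                mode, len(bits), len(kept), len(library))
    return kept


def percentile_select(
    predictions: Sequence[PredictionRecord], pct: float = 90.0
) -> list[PredictionRecord]:
    """Keep predictions whose confidence percentile strictly exceeds pct/100.

    The percentile is the weak within-batch rank (fraction of scores <=
    the score); the strict cut makes the selection size exactly
    ceil((100-pct)/100 * n) whenever scores are distinct.  Fully tied
    batches share the top percentile (1.0) and are all selected (logged).
    """
    if not predictions:
        return []
    scores = np.array([p.confidence_score for p in predictions])
    order = np.sort(scores)
    n = len(scores)
    pct_ranks = np.searchsorted(order, scores, side="right") / n
    selected = [p for p, q in zip(predictions, pct_ranks) if q > pct / 100.0]
    if len(selected) == n and n > 1:
        logger.warning("percentile_select: all %d scores tied; selecting the whole batch", n)
    return selected


def prioritize(candidates: Sequence[ScreeningCandidate]) -> list[ScreeningCandidate]:
    """Order candidates by selectivity: ascending off-target score.

    Ties break by descending target DeltaAffinity, then ligand id.  Every
    candidate must carry an off-target profile and a positive target
    DeltaAffinity (the funnel's affinity stage guarantees the latter).
    """
    bad = [c.ligand_id for c in candidates
           if c.target_delta_affinity is None or c.target_delta_affinity <= 0]
    if bad:
        raise ValueError(
            f"candidates without positive target DeltaAffinity rejected: {bad}"
        )
    missing = [c.ligand_id for c in candidates if c.off_target is None]
    if missing:
        raise ValueError(f"candidates missing an off-target profile: {missing}")
    return sorted(
        candidates,
        key=lambda c: (c.off_target.off_target_score, -c.target_delta_affinity, c.ligand_id),
    )


def informative_bits(ligands: Sequence[LigandRecord]) -> list[int]:
    """Bit indices whose prevalence in the set is strictly between 0 and 1.

    Bits present in all or none of the ligands carry no rank information
    and are filtered out before correlation.
    """
    if len(ligands) < 2:
        raise ValueError("need at least 2 ligands to define informative bits")
    bits = np.stack([_bits_of(rec) for rec in ligands])
    prevalence = bits.mean(axis=0)
    return [int(b) for b in np.flatnonzero((prevalence > 0) & (prevalence < 1))]


def bit_offtarget_correlation(
    ligands: Sequence[LigandRecord],
    off_target_scores: Sequence[float],
    top_n: int = 20,
    bit_mapper: Callable[[int], list[str]] | None = None,
) -> list[BitCorrelation]:
    """Spearman correlation of informative-bit presence vs off-target score.

    Returns the ``top_n`` bits by |r| (average-rank tie handling), labelled
    by direction: r > 0 flags substructures associated with promiscuous
    binding, r < 0 with receptor-specific binding.  If a ``bit_mapper`` is
    given, bits it cannot translate to any substructure are dropped with a
    log message.
    """
    scores = np.asarray(off_target_scores, float)
    if len(ligands) != len(scores):
        raise ValueError("ligands and off_target_scores length mismatch")
    if np.all(scores == scores[0]):
        raise ValueError("off-target scores are constant; Spearman correlation undefined")
    bits_matrix = np.stack([_bits_of(rec) for rec in ligands])
    results = []
    for b in informative_bits(ligands):
        r = stats.spearmanr(bits_matrix[:, b], scores).statistic
        results.append(BitCorrelation(bit=b, spearman_r=float(r)))
    results.sort(key=lambda bc: (-abs(bc.spearman_r), bc.bit))
    selected = results[:top_n]
    if bit_mapper is not None:
        mapped = []
        for bc in selected:
            if bit_mapper(bc.bit):
                mapped.append(bc)
            else:
                logger.warning("bit %d could not be mapped to a substructure; excluded", bc.bit)
        selected = mapped
    return selected
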