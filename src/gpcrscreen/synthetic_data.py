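"""Synthetic data generation for end-to-end pipeline testing.

The generator emulates the statistical structure the pipeline assumes,
without any chemistry download:

* a two-class ligand population (agonist=0 / antagonist=1) whose
  fingerprints contain a handful of *driver bits* far more prevalent in
  antagonists, on top of i.i.d. background bits;
* class-shifted molecular weight (antagonists heavier), other
  descriptors drawn from shared distributions;
* per-receptor docking ΔG pairs constructed from a planted DeltaAffinity
  (so that ΔG_active − ΔG_inactive recovers it exactly by
  construction): positive-shifted for antagonists on the target
  receptor, centred at zero off target;
* toy 3D receptor/ligand structures (a spherical atom shell with a
  pocket) for surface-area burial fixtures.

Synthetic compounds carry fingerprints directly and no SMILES; a small
list of real molecules (`REAL_SMILES_FIXTURES`) exercises the
SMILES-to-fingerprint path.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .affinity_scoring import DockingRecord
from .chem_features import DEFAULT_NBITS, Fingerprint, LigandRecord
from .sasa import Structure, golden_spiral_points

__all__ = [
    "GeneratorConfig",
    "SyntheticLibrary",
    "generate_training_set",
    "generate_screening_library",
    "generate_toy_complex",
    "REAL_SMILES_FIXTURES",
]

#: Curated real molecules for the SMILES path (id -> SMILES).
REAL_SMILES_FIXTURES: dict[str, str] = {
    "aspirin": "CC(=O)Oc1ccccc1C(=O)O",
    "caffeine": "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "benzene": "c1ccccc1",
    "lactate": "CC(O)C(=O)O",
    "gamma-hydroxybutyrate": "OCCCC(=O)O",
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic population.

    Defaults mirror the training regime the pipeline is designed for:
    144 ligands with a 78/144 antagonist share, five driver bits with a
    0.8 vs 0.1 class prevalence contrast, a 12-receptor docking panel and
    an antagonist DeltaAffinity shift of +2.5 kcal/mol on the target.
    """

    n_ligands: int = 144
    class_balance: float = 78 / 144          # antagonist fraction
    deterministic_counts: bool = True        # exact round(balance*n) antagonists
    nbits: int = DEFAULT_NBITS
    #: planted antagonist-driver bit positions; None -> five fixed fractional
    #: positions of the bit width (so any nbits gets a valid default)
    driver_bits: tuple[int, ...] | None = None
    driver_prevalence: tuple[float, float] = (0.8, 0.1)   # (antagonist, agonist)
    background_bit_rate: float = 0.02
    mw_means: tuple[float, float] = (310.0, 420.0)        # (agonist, antagonist) g/mol
    mw_sigma: float = 80.0
    logp_mu: float = 2.5
    logp_sigma: float = 1.5
    hbd_lambda: float = 2.0
    hba_lambda: float = 5.0
    tpsa_mu: float = 85.0
    tpsa_sigma: float = 30.0
    target_delta_mu: tuple[float, float] = (0.0, 2.5)     # (agonist, antagonist) kcal/mol
    delta_sigma: float = 1.0
    off_target_sigma: float = 1.5
    dg_active_mu: float = -6.5
    dg_active_sigma: float = 1.0
    n_receptors: int = 12
    target_receptor: str = "HCAR1"
    library_antagonist_rate: float = 0.25
    seed: int = 42

    def __post_init__(self) -> None:
        if self.driver_bits is None:
            fractions = (0.0083, 0.103, 0.2437, 0.44, 0.75)
            object.__setattr__(
                self, "driver_bits",
                tuple(int(round(self.nbits * f)) for f in fractions),
            )
        for p in (self.class_balance, *self.driver_prevalence,
                  self.background_bit_rate, self.library_antagonist_rate):
            if not 0 <= p <= 1:
                raise ValueError(f"probability out of [0,1]: {p}")
        for s in (self.mw_sigma, self.delta_sigma, self.off_target_sigma):
            if not s > 0:
                raise ValueError("sigmas must be positive")
        if any(b >= self.nbits or b < 0 for b in self.driver_bits):
            raise ValueError(
                f"driver bit index out of range for nbits={self.nbits}: {self.driver_bits}"
            )

    @property
    def receptor_panel(self) -> list[str]:
        others = [f"GPCR{i:02d}" for i in range(1, self.n_receptors)]
        return [self.target_receptor] + others


def _draw_labels(cfg: GeneratorConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    if cfg.deterministic_counts:
        n_ant = int(round(cfg.class_balance * n))
        labels = np.array([1] * n_ant + [0] * (n - n_ant))
        rng.shuffle(labels)
        return labels
    return (rng.random(n) < cfg.class_balance).astype(int)


def _draw_fingerprint(cfg: GeneratorConfig, label: int, rng: np.random.Generator) -> Fingerprint:
    bits = (rng.random(cfg.nbits) < cfg.background_bit_rate).astype(np.uint8)
    p_driver = cfg.driver_prevalence[0] if label == 1 else cfg.driver_prevalence[1]
    for b in cfg.driver_bits:
        bits[b] = 1 if rng.random() < p_driver else 0
    return Fingerprint(bits=bits, radius=2, nbits=cfg.nbits)


def _draw_descriptors(cfg: GeneratorConfig, label: int, rng: np.random.Generator) -> dict:
    mw_mu = cfg.mw_means[1] if label == 1 else cfg.mw_means[0]
    return {
        "mw": float(max(50.0, rng.normal(mw_mu, cfg.mw_sigma))),
        "logp": float(rng.normal(cfg.logp_mu, cfg.logp_sigma)),
        "hbd": float(rng.poisson(cfg.hbd_lambda)),
        "hba": float(rng.poisson(cfg.hba_lambda)),
        "tpsa": float(max(0.0, rng.normal(cfg.tpsa_mu, cfg.tpsa_sigma))),
    }


def _draw_docking(
    cfg: GeneratorConfig, ligand_id: str, label: int, rng: np.random.Generator
) -> list[DockingRecord]:
    """Per-receptor ΔG pairs derived from a planted DeltaAffinity.

    ΔG_inactive = ΔG_active − DeltaAffinity, so pairing the records
    reproduces the planted value exactly.
    """
    records = []
    for receptor in cfg.receptor_panel:
        if receptor == cfg.target_receptor:
            mu = cfg.target_delta_mu[1] if label == 1 else cfg.target_delta_mu[0]
            delta = rng.normal(mu, cfg.delta_sigma)
        else:
            delta = rng.normal(0.0, cfg.off_target_sigma)
        dg_active = rng.normal(cfg.dg_active_mu, cfg.dg_active_sigma)
        records.append(DockingRecord(ligand_id, receptor, "active", float(dg_active)))
        records.append(DockingRecord(ligand_id, receptor, "inactive", float(dg_active - delta)))
    return records


def generate_training_set(
    config: GeneratorConfig = GeneratorConfig(),
) -> tuple[list[LigandRecord], list[DockingRecord]]:
    """Labelled ligand set plus its full docking-panel table; fully seeded."""
    rng = np.random.default_rng(config.seed)
    labels = _draw_labels(config, config.n_ligands, rng)
    ligands, docking = [], []
    for i, label in enumerate(labels):
        lig_id = f"SYN{i:04d}"
        desc = _draw_descriptors(config, int(label), rng)
        ligands.append(
            LigandRecord(
                ligand_id=lig_id, label=int(label),
                fingerprint=_draw_fingerprint(config, int(label), rng),
                **desc,
            )
        )
        docking.extend(_draw_docking(config, lig_id, int(label), rng))
    return ligands, docking


@dataclass
class SyntheticLibrary:
    """A screening library with the generating truth retained for scoring."""

    ligands: list[LigandRecord]          # labels hidden (None)
    hidden_labels: np.ndarray            # 1 = antagonist-like, 0 = decoy
    docking: list[DockingRecord]


def generate_screening_library(
    config: GeneratorConfig = GeneratorConfig(), n: int = 500
) -> SyntheticLibrary:
    """Mixture of antagonist-like compounds and decoys, labels hidden.

    Antagonist-like compounds follow the antagonist generative regime
    (driver bits, MW shift, positive target DeltaAffinity); decoys follow
    the agonist regime.  The true class is kept separately so downstream
    enrichment can be scored.
    """
    rng = np.random.default_rng(config.seed + 1)
    hidden = (rng.random(n) < config.library_antagonist_rate).astype(int)
    ligands, docking = [], []
    for i, label in enumerate(hidden):
        lig_id = f"LIB{i:05d}"
        desc = _draw_descriptors(config, int(label), rng)
        ligands.append(
            LigandRecord(
                ligand_id=lig_id, label=None,
                fingerprint=_draw_fingerprint(config, int(label), rng),
                **desc,
            )
        )
        docking.extend(_draw_docking(config, lig_id, int(label), rng))
    return SyntheticLibrary(ligands=ligands, hidden_labels=hidden, docking=docking)


def generate_toy_complex(
    n_receptor_atoms: int = 60,
    n_ligand_atoms: int = 3,
    burial: str = "deep",
    seed: int = 42,
    shell_radius: float = 4.0,
) -> tuple[Structure, Structure, Structure]:
    """Toy receptor/ligand/complex triple for burial fixtures.

    The receptor is a spherical shell of carbon atoms with a conical
    pocket opening toward +z; the ligand is a small carbon cluster placed
    at the shell centre (``deep``) or at the pocket mouth (``shallow``).
    The complex is the union of the two.  Deterministic for a given seed.
    """
    if n_receptor_atoms < 1 or n_ligand_atoms < 1:
        raise ValueError("atom counts must be >= 1")
    if burial not in ("deep", "shallow"):
        raise ValueError(f"burial must be 'deep' or 'shallow', got {burial!r}")
    rng = np.random.default_rng(seed)
    # oversample the sphere, drop atoms inside the pocket cone (z-axis, ~35°)
    pts = golden_spiral_points(int(n_receptor_atoms * 1.3)) * shell_radius
    cone = pts[:, 2] / shell_radius > np.cos(np.deg2rad(35.0))
    shell = pts[~cone][:n_receptor_atoms]
    shell = shell + rng.normal(0.0, 0.05, shell.shape)
    receptor = Structure(elements=["C"] * len(shell), coords=shell)

    centre = np.zeros(3) if burial == "deep" else np.array([0.0, 0.0, shell_radius + 1.5])
    lig_coords = centre + rng.normal(0.0, 0.6, (n_ligand_atoms, 3))
    ligand = Structure(elements=["C"] * n_ligand_atoms, coords=lig_coords)
    return receptor, ligand, receptor + ligand
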