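"""QTL architectures, true breeding values and phenotypes.

Four preset architectures (strategies I-IV) place 100 to 10,000 additive
QTL with effects drawn from three zero-mean normal distributions —
N(0, 1e-4), N(0, 1e-3) and N(0, 1e-2) on a nominal effect-variance scale
of sigma_g^2 = 1 — for small-, medium- and large-effect classes.  The true
breeding value of individual i is TBV_i = sum_j x_ij a_j with dosage x
coded 0/1/2, and phenotypes add an i.i.d. normal environmental deviate
whose variance is set from the *realized* genetic variance so that the
realized heritability matches the target in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel import GenotypePanel

__all__ = [
    "ArchitectureStrategy",
    "STRATEGIES",
    "QTLSet",
    "TraitSim",
    "sample_qtl",
    "compute_tbv",
    "simulate_phenotypes",
]

# variance multipliers (x sigma_g^2) per effect class
EFFECT_CLASS_VARIANCE = {"small": 1e-4, "medium": 1e-3, "large": 1e-2}


@dataclass(frozen=True)
class ArchitectureStrategy:
    """Counts of small/medium/large-effect QTL making up an architecture."""

    name: str
    n_small: int
    n_medium: int
    n_large: int

    def __post_init__(self) -> None:
        if min(self.n_small, self.n_medium, self.n_large) < 0:
            raise ValueError("negative QTL count")
        if self.n_qtl_total == 0:
            raise ValueError("architecture has no QTL")

    @property
    def n_qtl_total(self) -> int:
        return self.n_small + self.n_medium + self.n_large


STRATEGIES: dict[str, ArchitectureStrategy] = {
    "I": ArchitectureStrategy("I", 0, 0, 100),
    "II": ArchitectureStrategy("II", 1361, 614, 25),
    "III": ArchitectureStrategy("III", 4595, 390, 15),
    "IV": ArchitectureStrategy("IV", 10_000, 0, 0),
}


@dataclass
class QTLSet:
    marker_indices: np.ndarray  # unique indices into the panel
    effects: np.ndarray  # allele-substitution effect per QTL
    effect_class: np.ndarray  # 'small' | 'medium' | 'large'
    strategy: str = ""

    def __post_init__(self) -> None:
        self.marker_indices = np.asarray(self.marker_indices, dtype=np.int64)
        self.effects = np.asarray(self.effects, dtype=np.float64)
        self.effect_class = np.asarray(self.effect_class, dtype=object)
        if len(np.unique(self.marker_indices)) != len(self.marker_indices):
            raise ValueError("duplicate QTL indices")
        if not (len(self.effects) == len(self.marker_indices) == len(self.effect_class)):
            raise ValueError("QTL field lengths disagree")

    @property
    def n_qtl(self) -> int:
        return len(self.marker_indices)


@dataclass
class TraitSim:
    h2: float
    tbv: np.ndarray
    env: np.ndarray
    realized_vg: float
    sigma_g2: float = 1.0

    @property
    def phenotype(self) -> np.ndarray:
        return self.tbv + self.env

    @property
    def realized_h2(self) -> float:
        return float(np.var(self.tbv) / np.var(self.phenotype))


def sample_qtl(
    panel: GenotypePanel,
    strategy: ArchitectureStrategy | str,
    seed: int,
    sigma_g2: float = 1.0,
) -> QTLSet:
    """Draw QTL positions uniformly without replacement over the panel's
    markers and effects from the class-specific normal distributions.

    QTL are sampled across the pooled panel, so in a multi-breed panel they
    segregate in all breeds with breed-specific allele frequencies.
    """
    if isinstance(strategy, str):
        strategy = STRATEGIES[strategy]
    n_total = strategy.n_qtl_total
    if panel.n_markers < n_total:
        raise ValueError(
            f"panel has {panel.n_markers} markers, fewer than {n_total} QTL"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(panel.n_markers, size=n_total, replace=False)
    classes = np.concatenate(
        [
            np.full(n, label, dtype=object)
            for label, n in [
                ("small", strategy.n_small),
                ("medium", strategy.n_medium),
                ("large", strategy.n_large),
            ]
        ]
    )
    sd = np.sqrt(
        np.array([EFFECT_CLASS_VARIANCE[c] for c in classes]) * sigma_g2
    )
    effects = rng.normal(0.0, 1.0, size=n_total) * sd
    return QTLSet(idx, effects, classes, strategy.name)


def compute_tbv(panel: GenotypePanel, qtl: QTLSet) -> np.ndarray:
    """TBV_i = sum over QTL of dosage_ij * effect_j."""
    if qtl.n_qtl and qtl.marker_indices.max() >= panel.n_markers:
        raise ValueError("QTL index out of range")
    dosage = panel.haplotypes[:, :, qtl.marker_indices].sum(axis=1, dtype=np.float64)
    return dosage @ qtl.effects


def simulate_phenotypes(tbv: np.ndarray, h2: float, seed: int) -> TraitSim:
    """Add environmental noise targeting heritability ``h2``.

    env ~ N(0, Vg (1 - h2) / h2) i.i.d., with Vg the realized variance of
    ``tbv`` in this population, so var(tbv)/var(y) ~= h2 at large n.
    """
    tbv = np.asarray(tbv, dtype=np.float64)
    if not 0.0 < h2 < 1.0:
        raise ValueError(f"h2={h2} outside (0, 1)")
    vg = float(np.var(tbv))
    if vg == 0.0:
        raise ValueError("var(tbv) = 0: cannot scale environmental noise")
    rng = np.random.default_rng(seed)
    env = rng.normal(0.0, np.sqrt(vg * (1.0 - h2) / h2), size=len(tbv))
    return TraitSim(h2=h2, tbv=tbv, env=env, realized_vg=vg)
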