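"""Block-wise haplotype resampling: expand small founder panels to large
simulated populations that retain founder LD and allele frequencies.

Each breed's founders provide a pool of 2 x n_founder phased haplotypes.
Markers are partitioned, within each chromosome, into consecutive blocks of
a fixed number of adjacent markers (default 500; the final block on a
chromosome may be shorter, blocks never span chromosomes).  Every simulated
gamete is a mosaic: for each block, one founder haplotype segment drawn
uniformly with replacement.  Within a block the full founder haplotype
structure (LD, phase, frequencies) is preserved; across block boundaries
draws are independent, so long-range LD attenuates — emulating strong
recombination hotspots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .panel import GenotypePanel, MarkerMap

__all__ = ["ResampleConfig", "block_boundaries", "expand_breed", "expand_panel"]


@dataclass
class ResampleConfig:
    block_size_markers: int = 500
    n_simulated_per_breed: int = 1500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.block_size_markers < 1:
            raise ValueError("block_size_markers must be >= 1")
        if self.n_simulated_per_breed < 1:
            raise ValueError("n_simulated_per_breed must be >= 1")


def block_boundaries(markers: MarkerMap, block_size: int) -> list[tuple[int, int]]:
    """(start, stop) marker-index pairs; blocks are fixed from each
    chromosome's first marker, deterministic given the map."""
    blocks = []
    for c in markers.chromosomes:
        idx = np.flatnonzero(markers.chromosome == c)
        start, stop = idx[0], idx[-1] + 1
        for b in range(start, stop, block_size):
            blocks.append((b, min(b + block_size, stop)))
    return blocks


def _complete_haplotypes(panel: GenotypePanel, breed: str) -> np.ndarray:
    """Founder haplotype pool (2n, M); missing calls are mode-imputed."""
    sub = panel.breed_panel(breed)
    haps = sub.haplotype_matrix().copy()
    if sub.missing is not None and sub.missing.any():
        warnings.warn(
            f"breed {breed}: {int(sub.missing.sum())} missing founder calls "
            "mode-imputed before resampling",
            stacklevel=3,
        )
        freq = sub.allele_freq()
        fill = (np.nan_to_num(freq) >= 0.5).astype(np.int8)
        miss_h = np.repeat(sub.missing, 2, axis=0)
        haps[miss_h] = np.broadcast_to(fill, haps.shape)[miss_h]
    return haps


def expand_breed(
    panel: GenotypePanel, breed: str, config: ResampleConfig | None = None
) -> GenotypePanel:
    """Simulate ``n_simulated_per_breed`` individuals of one breed.

    For each simulated individual, each of its two gametes draws one founder
    haplotype segment per block, uniformly with replacement from the breed's
    haplotype pool.  The output carries the founder marker map and the breed
    label; block boundaries and the seed are recorded in metadata.
    """
    config = config or ResampleConfig()
    rng = np.random.default_rng(config.seed)
    pool = _complete_haplotypes(panel, breed)  # (2n_founder, M)
    n_hap, m = pool.shape
    blocks = block_boundaries(panel.markers, config.block_size_markers)

    n_sim = config.n_simulated_per_breed
    out = np.empty((n_sim, 2, m), dtype=np.int8)
    for start, stop in blocks:
        # independent uniform draw per (individual, gamete, block)
        pick = rng.integers(0, n_hap, size=(n_sim, 2))
        out[:, :, start:stop] = pool[pick, start:stop]
    ids = np.array([f"{breed}_sim{i + 1:04d}" for i in range(n_sim)], dtype=object)
    return GenotypePanel(
        panel.markers,
        out,
        ids,
        np.array([breed] * n_sim, dtype=object),
        metadata={
            "seed": config.seed,
            "block_size_markers": config.block_size_markers,
            "block_boundaries": blocks,
            "n_founder_haplotypes": n_hap,
        },
    )


def expand_panel(
    panel: GenotypePanel, config: ResampleConfig | None = None
) -> GenotypePanel:
    """Expand every breed in the panel; per-breed child seeds are spawned
    deterministically from ``config.seed``."""
    config = config or ResampleConfig()
    seeds = np.random.SeedSequence(config.seed).spawn(len(panel.breed_names))
    parts = []
    for breed, ss in zip(panel.breed_names, seeds):
        sub_cfg = ResampleConfig(
            config.block_size_markers,
            config.n_simulated_per_breed,
            seed=int(ss.generate_state(1)[0] % (2**31)),
        )
        parts.append(expand_breed(panel, breed, sub_cfg))
    merged = GenotypePanel.concatenate(parts)
    merged.metadata = {
        "seed": config.seed,
        "block_size_markers": config.block_size_markers,
        "block_boundaries": parts[0].metadata["block_boundaries"],
    }
    return merged
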