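"""Core data containers: marker maps and phased genotype panels.

A :class:`GenotypePanel` holds phased diploid genotypes as a
``(n_individuals, 2, n_markers)`` binary haplotype array together with a
:class:`MarkerMap` and per-individual breed labels.  Dosages (0/1/2 counts
of the alternate allele) are derived, never stored, so haplotypes and
genotypes can never disagree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MarkerMap", "GenotypePanel"]


@dataclass
class MarkerMap:
    """Physical and genetic positions of markers, ordered by (chromosome, bp).

    Parameters
    ----------
    chromosome : array of int
        1-based chromosome identifier per marker.
    position_bp : array of int
        Physical position in base pairs; strictly increasing within a
        chromosome.
    genetic_pos_cm : array of float
        Genetic map position in centiMorgans; non-decreasing with physical
        position within a chromosome.
    allele1, allele2 : arrays of str
        Symbolic allele codes; haplotype value 1 counts ``allele2``.
    """

    chromosome: np.ndarray
    position_bp: np.ndarray
    genetic_pos_cm: np.ndarray
    allele1: np.ndarray
    allele2: np.ndarray
    names: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chromosome = np.asarray(self.chromosome, dtype=np.int64)
        self.position_bp = np.asarray(self.position_bp, dtype=np.int64)
        self.genetic_pos_cm = np.asarray(self.genetic_pos_cm, dtype=np.float64)
        self.allele1 = np.asarray(self.allele1, dtype=object)
        self.allele2 = np.asarray(self.allele2, dtype=object)
        if self.names is None:
            self.names = np.array(
                [f"snp{c}_{p}" for c, p in zip(self.chromosome, self.position_bp)],
                dtype=object,
            )
        else:
            self.names = np.asarray(self.names, dtype=object)
        n = len(self.chromosome)
        for arr, label in [
            (self.position_bp, "position_bp"),
            (self.genetic_pos_cm, "genetic_pos_cm"),
            (self.allele1, "allele1"),
            (self.allele2, "allele2"),
            (self.names, "names"),
        ]:
            if len(arr) != n:
                raise ValueError(f"{label} length {len(arr)} != {n} markers")
        if n == 0:
            raise ValueError("empty marker map")
        if self.chromosome.min() < 1:
            raise ValueError("chromosome ids must be >= 1")
        for c in np.unique(self.chromosome):
            sel = self.chromosome == c
            pos = self.position_bp[sel]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {c}")
            if np.any(np.diff(self.genetic_pos_cm[sel]) < 0):
                raise ValueError(f"genetic positions decrease on chromosome {c}")

    @property
    def n_markers(self) -> int:
        return len(self.chromosome)

    @property
    def chromosomes(self) -> np.ndarray:
        """Distinct chromosome ids in order of appearance."""
        _, idx = np.unique(self.chromosome, return_index=True)
        return self.chromosome[np.sort(idx)]

    def subset(self, marker_idx: np.ndarray) -> "MarkerMap":
        marker_idx = np.asarray(marker_idx)
        return MarkerMap(
            self.chromosome[marker_idx],
            self.position_bp[marker_idx],
            self.genetic_pos_cm[marker_idx],
            self.allele1[marker_idx],
            self.allele2[marker_idx],
            self.names[marker_idx],
        )


@dataclass
class GenotypePanel:
    """Phased diploid genotypes for a set of individuals.

    ``haplotypes`` has shape ``(n_individuals, 2, n_markers)`` with values in
    {0, 1}; ``missing`` (optional) is a boolean ``(n_individuals, n_markers)``
    mask marking genotype calls to be treated as absent.
    """

    markers: MarkerMap
    haplotypes: np.ndarray
    ids: np.ndarray
    breeds: np.ndarray
    missing: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.ids = np.asarray(self.ids, dtype=object)
        self.breeds = np.asarray(self.breeds, dtype=object)
        if self.haplotypes.ndim != 3 or self.haplotypes.shape[1] != 2:
            raise ValueError("haplotypes must have shape (n_individuals, 2, n_markers)")
        n, _, m = self.haplotypes.shape
        if m != self.markers.n_markers:
            raise ValueError("haplotype marker dimension disagrees with map")
        if len(self.ids) != n or len(self.breeds) != n:
            raise ValueError("ids/breeds length disagrees with haplotypes")
        if len(np.unique(self.ids)) != n:
            raise ValueError("individual ids must be unique")
        if self.missing is not None:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != (n, m):
                raise ValueError("missing mask must be (n_individuals, n_markers)")

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[2]

    @property
    def breed_names(self) -> list[str]:
        """Distinct breed labels in order of first appearance."""
        seen: dict[str, None] = {}
        for b in self.breeds:
            seen.setdefault(b, None)
        return list(seen)

    def validate(self) -> None:
        """Check the haplotype array is strictly binary."""
        vals = np.unique(self.haplotypes)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError(f"non-binary haplotype values: {vals}")

    def dosage(self, dtype=np.int8) -> np.ndarray:
        """Alternate-allele dosage matrix (n_individuals, n_markers) in {0,1,2}."""
        return self.haplotypes.sum(axis=1, dtype=dtype)

    def haplotype_matrix(self) -> np.ndarray:
        """All haplotypes stacked to (2 * n_individuals, n_markers)."""
        return self.haplotypes.reshape(-1, self.n_markers)

    def allele_freq(self) -> np.ndarray:
        """Per-marker alternate-allele frequency, ignoring missing calls."""
        if self.missing is None:
            return self.haplotypes.mean(axis=(0, 1))
        dos = self.dosage(np.float64)
        ok = ~self.missing
        called = ok.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(called > 0, (dos * ok).sum(axis=0) / (2 * called), np.nan)

    def subset_individuals(self, idx: np.ndarray) -> "GenotypePanel":
        idx = np.asarray(idx)
        return GenotypePanel(
            self.markers,
            self.haplotypes[idx],
            self.ids[idx],
            self.breeds[idx],
            None if self.missing is None else self.missing[idx],
            dict(self.metadata),
        )

    def subset_markers(self, marker_idx: np.ndarray) -> "GenotypePanel":
        marker_idx = np.asarray(marker_idx)
        return GenotypePanel(
            self.markers.subset(marker_idx),
            self.haplotypes[:, :, marker_idx],
            self.ids,
            self.breeds,
            None if self.missing is None else self.missing[:, marker_idx],
            dict(self.metadata),
        )

    def breed_panel(self, breed: str) -> "GenotypePanel":
        """Individuals of one breed."""
        sel = np.flatnonzero(self.breeds == breed)
        if sel.size == 0:
            raise KeyError(f"breed {breed!r} not present")
        return self.subset_individuals(sel)

    @staticmethod
    def concatenate(panels: list["GenotypePanel"]) -> "GenotypePanel":
        """Stack panels sharing one marker map along the individual axis."""
        if not panels:
            raise ValueError("no panels to concatenate")
        first = panels[0]
        for p in panels[1:]:
            if p.n_markers != first.n_markers or not np.array_equal(
                p.markers.position_bp, first.markers.position_bp
            ):
                raise ValueError("panels must share an identical marker map")
        missing = None
        if any(p.missing is not None for p in panels):
            missing = np.concatenate(
                [
                    p.missing
                    if p.missing is not None
                    else np.zeros((p.n_individuals, p.n_markers), dtype=bool)
                    for p in panels
                ]
            )
        return GenotypePanel(
            first.markers,
            np.concatenate([p.haplotypes for p in panels]),
            np.concatenate([p.ids for p in panels]),
            np.concatenate([p.breeds for p in panels]),
            missing,
        )
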