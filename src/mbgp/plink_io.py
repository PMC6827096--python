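"""Text PLINK (.ped/.map) reading and writing.

The breed label travels in the family-id column.  A ``.map`` file carries
(chromosome, name, cM, bp); genotypes are written as two allele letters per
marker with ``0 0`` for missing.  Because ``.ped/.map`` does not record
which allele is counted, :func:`write_plink` also emits an ``.alleles``
sidecar (marker, allele1, allele2); :func:`read_plink` uses it when present
and otherwise codes the minor allele as the counted allele, as PLINK does.

Haplotype phase is preserved through the within-genotype allele order,
which is how phased text PED files are conventionally interpreted.
"""

from __future__ import annotations

import os

import numpy as np

from .panel import GenotypePanel, MarkerMap

__all__ = ["write_plink", "read_plink"]

_MISSING = "0"


def write_plink(panel: GenotypePanel, prefix: str | os.PathLike) -> None:
    """Write ``<prefix>.ped``, ``<prefix>.map`` and ``<prefix>.alleles``."""
    prefix = os.fspath(prefix)
    m = panel.markers
    with open(prefix + ".map", "w") as fh:
        for c, name, cm, bp in zip(
            m.chromosome, m.names, m.genetic_pos_cm, m.position_bp
        ):
            fh.write(f"{c}\t{name}\t{cm:.6f}\t{bp}\n")
    with open(prefix + ".alleles", "w") as fh:
        for name, a1, a2 in zip(m.names, m.allele1, m.allele2):
            fh.write(f"{name}\t{a1}\t{a2}\n")

    # allele letters per (marker, haplotype value)
    codes = np.stack([m.allele1, m.allele2], axis=1)  # (M, 2) object
    with open(prefix + ".ped", "w") as fh:
        for i in range(panel.n_individuals):
            hap = panel.haplotypes[i]
            letters = [
                codes[j, hap[0, j]] + " " + codes[j, hap[1, j]]
                if panel.missing is None or not panel.missing[i, j]
                else _MISSING + " " + _MISSING
                for j in range(panel.n_markers)
            ]
            fh.write(
                f"{panel.breeds[i]} {panel.ids[i]} 0 0 0 -9 " + " ".join(letters) + "\n"
            )


def _read_map(path: str) -> tuple[np.ndarray, ...]:
    chrom, names, cm, bp = [], [], [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            chrom.append(int(parts[0]))
            names.append(parts[1])
            cm.append(float(parts[2]))
            bp.append(int(parts[3]))
    return (
        np.array(chrom),
        np.array(names, dtype=object),
        np.array(cm),
        np.array(bp),
    )


def read_plink(prefix: str | os.PathLike) -> GenotypePanel:
    """Read ``<prefix>.ped`` + ``<prefix>.map`` into a :class:`GenotypePanel`."""
    prefix = os.fspath(prefix)
    chrom, names, cm, bp = _read_map(prefix + ".map")
    n_markers = len(chrom)

    fids, iids, rows = [], [], []
    with open(prefix + ".ped") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_markers:
                raise ValueError(
                    f"PED record for {parts[1] if len(parts) > 1 else '?'} has "
                    f"{len(parts) - 6} allele fields, expected {2 * n_markers}"
                )
            fids.append(parts[0])
            iids.append(parts[1])
            rows.append(np.array(parts[6:], dtype=object).reshape(n_markers, 2))
    if not rows:
        raise ValueError(f"no individuals in {prefix}.ped")
    alleles = np.stack(rows)  # (N, M, 2)

    a1 = np.empty(n_markers, dtype=object)
    a2 = np.empty(n_markers, dtype=object)
    sidecar = prefix + ".alleles"
    if os.path.exists(sidecar):
        coded = {}
        with open(sidecar) as fh:
            for line in fh:
                parts = line.split()
                if parts:
                    coded[parts[0]] = (parts[1], parts[2])
        for j, name in enumerate(names):
            if name not in coded:
                raise ValueError(f"marker {name} missing from {sidecar}")
            a1[j], a2[j] = coded[name]
    else:
        for j in range(n_markers):
            col = alleles[:, j, :].ravel()
            obs, counts = np.unique(col[col != _MISSING], return_counts=True)
            if len(obs) > 2:
                raise ValueError(f"marker {names[j]} has >2 alleles: {list(obs)}")
            if len(obs) == 0:
                a1[j], a2[j] = "A", "B"  # fully missing column
            elif len(obs) == 1:
                a1[j], a2[j] = obs[0], "B" if obs[0] != "B" else "A"
            else:
                # count the minor allele, ties broken lexicographically
                order = np.lexsort((obs, counts))
                a2[j], a1[j] = obs[order[0]], obs[order[1]]

    haplotypes = np.zeros((alleles.shape[0], 2, n_markers), dtype=np.int8)
    missing = np.zeros((alleles.shape[0], n_markers), dtype=bool)
    for j in range(n_markers):
        col = alleles[:, j, :]  # (N, 2)
        miss = (col[:, 0] == _MISSING) | (col[:, 1] == _MISSING)
        missing[:, j] = miss
        for h in (0, 1):
            is_a2 = col[:, h] == a2[j]
            bad = ~miss & ~is_a2 & (col[:, h] != a1[j])
            if np.any(bad):
                raise ValueError(
                    f"marker {names[j]}: unknown allele code "
                    f"{col[np.flatnonzero(bad)[0], h]!r}"
                )
            haplotypes[:, h, j] = is_a2
    haplotypes[np.broadcast_to(missing[:, None, :], haplotypes.shape)] = 0

    markers = MarkerMap(chrom, bp, cm, a1, a2, names)
    return GenotypePanel(
        markers,
        haplotypes,
        np.array(iids, dtype=object),
        np.array(fids, dtype=object),
        missing if missing.any() else None,
    )
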