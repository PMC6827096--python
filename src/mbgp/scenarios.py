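"""Reference-population designs and the accuracy experiment grid.

The study design compares GBLUP accuracy under different reference
compositions, each totalling 1,200 phenotyped individuals:

* ``single_breed`` — all 1,200 from one breed; the remaining 300 of that
  breed validate within-breed, and random samples of every other breed
  measure across-breed accuracy;
* ``three_breed`` — 400 from each of three breeds (either all from one
  K-means group or one breed per group);
* ``combined_ten`` — 120 from each of the ten breeds.

For every (design, architecture strategy, heritability, replicate) cell the
grid simulates QTL and phenotypes, fits GBLUP on the reference, predicts
held-out GEBVs and records the per-validation-breed Pearson correlation
with the true breeding values.  Genotypes and the GRM are fixed across
replicates; QTL, phenotypes and splits are redrawn, with all child seeds
spawned deterministically from one master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gblup import GRM, GBLUPSolver
from .panel import GenotypePanel
from .pheno import STRATEGIES, sample_qtl, simulate_phenotypes

__all__ = [
    "Design",
    "Splits",
    "standard_designs",
    "make_splits",
    "accuracy",
    "run_grid",
    "summarize",
]


@dataclass(frozen=True)
class Design:
    """One reference-population composition."""

    name: str
    reference_breeds: tuple[str, ...]
    n_reference: int = 1200
    n_validation: int = 300

    def __post_init__(self) -> None:
        if not self.reference_breeds:
            raise ValueError("design needs at least one reference breed")
        if self.n_reference % len(self.reference_breeds):
            raise ValueError(
                f"{self.n_reference} reference individuals do not split "
                f"equally over {len(self.reference_breeds)} breeds"
            )

    @property
    def quota(self) -> int:
        return self.n_reference // len(self.reference_breeds)


@dataclass
class Splits:
    reference_idx: np.ndarray
    validation_idx: dict[str, np.ndarray] = field(default_factory=dict)


def standard_designs(
    groups: dict[str, str],
    cross_group_breeds: tuple[str, ...] | None = None,
) -> dict[str, Design]:
    """The full design set for a breed -> group assignment.

    Returns per-breed single-breed designs, one three-breed design per
    3-breed group, one cross-group three-breed design (one breed per
    group; by default the last breed of each group), and the combined
    ten-breed design.
    """
    breeds = list(groups)
    designs: dict[str, Design] = {}
    for b in breeds:
        designs[f"single_{b}"] = Design(f"single_{b}", (b,))
    by_group: dict[str, list[str]] = {}
    for b, g in groups.items():
        by_group.setdefault(g, []).append(b)
    for g, members in by_group.items():
        if len(members) == 3:
            designs[f"group_{g}"] = Design(f"group_{g}", tuple(members))
    if cross_group_breeds is None:
        cross_group_breeds = tuple(members[-1] for members in by_group.values())
    if len(cross_group_breeds) == 3:
        designs["cross_group"] = Design("cross_group", tuple(cross_group_breeds))
    designs["combined_ten"] = Design("combined_ten", tuple(breeds))
    return designs


def make_splits(panel: GenotypePanel, design: Design, seed: int) -> Splits:
    """Reference/validation split for one design.

    Reference individuals are drawn without replacement, ``quota`` per
    reference breed.  Validation: for reference breeds, up to
    ``n_validation`` of that breed's non-reference individuals; for other
    breeds, a random ``n_validation`` individuals.  The two sets are
    disjoint by construction.
    """
    rng = np.random.default_rng(seed)
    ref_parts = []
    validation: dict[str, np.ndarray] = {}
    for breed in panel.breed_names:
        rows = np.flatnonzero(panel.breeds == breed)
        if breed in design.reference_breeds:
            if design.quota > len(rows):
                raise ValueError(
                    f"breed {breed} has {len(rows)} individuals < quota {design.quota}"
                )
            perm = rng.permutation(rows)
            ref_parts.append(np.sort(perm[: design.quota]))
            rest = perm[design.quota :]
            validation[breed] = np.sort(rest[: design.n_validation])
        else:
            take = min(design.n_validation, len(rows))
            validation[breed] = np.sort(
                rng.choice(rows, size=take, replace=False)
            )
    return Splits(np.concatenate(ref_parts), validation)


def accuracy(gebv: np.ndarray, tbv: np.ndarray) -> float:
    """Pearson correlation between predicted and true breeding values;
    NaN when undefined (fewer than 3 pairs or a constant vector)."""
    gebv = np.asarray(gebv, dtype=np.float64)
    tbv = np.asarray(tbv, dtype=np.float64)
    if len(gebv) != len(tbv):
        raise ValueError("length mismatch")
    if len(gebv) < 3 or np.std(gebv) == 0 or np.std(tbv) == 0:
        return float("nan")
    return float(np.corrcoef(gebv, tbv)[0, 1])


def _breed_design_matrix(breeds: np.ndarray) -> np.ndarray | None:
    """Intercept plus breed indicator columns (first breed as baseline);
    None (intercept only) for a single breed."""
    levels = list(dict.fromkeys(breeds))
    if len(levels) == 1:
        return None
    cols = [np.ones(len(breeds))]
    cols += [(breeds == b).astype(float) for b in levels[1:]]
    return np.column_stack(cols)


def _seed_for(master_seed: int, *key: int) -> int:
    return int(
        np.random.SeedSequence(entropy=master_seed, spawn_key=key).generate_state(1)[0]
        % 2**31
    )


def _standardize(x_int: np.ndarray, p: np.ndarray) -> np.ndarray:
    """float32 standardized dosages (x - 2p) / sqrt(2p(1-p))."""
    z = x_int.astype(np.float32)
    z -= (2.0 * p).astype(np.float32)
    z /= np.sqrt(2.0 * p * (1.0 - p)).astype(np.float32)
    return z


def _grm_blocks_excluding(
    grm: GRM,
    rows: np.ndarray,
    n_ref: int,
    qtl_idx: np.ndarray,
    keep_idx: np.ndarray,
    xq_all: np.ndarray,
    xc_all: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray]:
    """(G_rr, G_vr) recomputed as if the QTL markers were not genotyped.

    ``rows`` is reference indices followed by validation indices.  Uses a
    rank-downdate of the stored GRM when the QTL set is the smaller of
    QTL/complement, otherwise rebuilds the blocks from the complement
    markers directly; the Yang diagonal is always corrected exactly.
    """
    m = grm.n_markers
    nq = len(qtl_idx)
    ref_rows = rows[:n_ref]
    if xc_all is None:  # downdate path
        z = _standardize(xq_all[rows], grm.freqs[qtl_idx])
        prod = z @ z[:n_ref].T  # (len(rows), n_ref)
        g = grm.matrix[np.ix_(rows, ref_rows)].astype(np.float32)
        g *= m
        g -= prod
        g /= m - nq
    else:  # complement-scratch path
        z = _standardize(xc_all[rows], grm.freqs[keep_idx])
        g = z @ z[:n_ref].T
        g /= m - nq
    # Yang diagonal of the reference block: 1 + mean of own-terms over kept
    # markers; own-term sums of the QTL markers are removed from the stored
    # diagonal, which already averages over all m markers.
    p = grm.freqs[qtl_idx]
    het = 2.0 * p * (1.0 - p)
    xq = xq_all[ref_rows].astype(np.float64)
    dq = ((xq * xq - (1.0 + 2.0 * p) * xq + 2.0 * p**2) / het).sum(axis=1)
    diag_full = grm.matrix[ref_rows, ref_rows].astype(np.float64)
    diag_ex = 1.0 + (m * (diag_full - 1.0) - dq) / (m - nq)
    g_rr = g[:n_ref].astype(np.float64)
    np.fill_diagonal(g_rr, diag_ex)
    return g_rr, g[n_ref:].astype(np.float64)


def run_grid(
    panel: GenotypePanel,
    grm: GRM,
    designs: dict[str, Design],
    strategies: dict[str, list[float]],
    n_replicates: int = 10,
    master_seed: int = 0,
    ridge: float = 1e-6,
    exclude_qtl_from_grm: bool = True,
    validation_scope: str = "all",
) -> pd.DataFrame:
    """Run the accuracy grid and return tidy per-cell records.

    ``strategies`` maps architecture-strategy name -> list of target
    heritabilities.  lambda is taken from the simulated heritability,
    lambda = (1 - h2)/h2.  QTL (per strategy) and environmental noise (per
    strategy x h2) are redrawn each replicate and shared by all designs in
    that replicate; splits are redrawn per (design, replicate); genotypes
    and the GRM are fixed throughout.  Any cell failure is recorded
    (status column) and the grid continues.

    ``exclude_qtl_from_grm`` (default) evaluates each trait with the GRM
    recomputed as if that trait's QTL markers were not on the chip.  At
    real chip densities the distinction is immaterial, but on a scaled-
    down panel the causal markers would otherwise carry an unrealistically
    large share of the relationship signal and inflate across-breed
    prediction.

    ``validation_scope`` limits which validation breeds are scored:
    ``"all"`` (default), ``"own"`` (only breeds in the reference) or
    ``"foreign"`` (only breeds outside it) — the latter two skip work when
    only one side of the comparison is needed.
    """
    if not np.array_equal(grm.ids, panel.ids):
        raise ValueError("GRM ids must match panel ids (same order)")
    if validation_scope not in ("all", "own", "foreign"):
        raise ValueError("validation_scope must be 'all', 'own' or 'foreign'")
    records: list[dict] = []
    design_list = list(designs.items())
    splits_cache_per_rep: list[dict[str, Splits]] = [
        {
            dname: make_splits(panel, design, _seed_for(master_seed, 1000 + d_idx, rep))
            for d_idx, (dname, design) in enumerate(design_list)
        }
        for rep in range(n_replicates)
    ]
    all_markers = np.arange(grm.n_markers)
    # markers x individuals dosage cache: row gathers of marker subsets are
    # contiguous, which keeps per-trait QTL lookups off the critical path
    dosage_t = np.ascontiguousarray(panel.dosage(np.int8).T)

    def _tbv_from_cache(qtl) -> np.ndarray:
        out = np.zeros(panel.n_individuals)
        step = 2048
        for i in range(0, qtl.n_qtl, step):
            idx = qtl.marker_indices[i : i + step]
            out += qtl.effects[i : i + step] @ dosage_t[idx].astype(np.float64)
        return out

    for rep in range(n_replicates):
        splits_cache = splits_cache_per_rep[rep]
        for s_idx, strat in enumerate(strategies):
            qtl = sample_qtl(
                panel, STRATEGIES[strat], _seed_for(master_seed, rep, s_idx, 0)
            )
            tbv = _tbv_from_cache(qtl)
            traits = {
                h2: simulate_phenotypes(
                    tbv, h2, _seed_for(master_seed, rep, s_idx, 1 + h_idx)
                )
                for h_idx, h2 in enumerate(strategies[strat])
            }
            xq_all = xc_all = keep_idx = None
            if exclude_qtl_from_grm:
                qidx = qtl.marker_indices
                keep_idx = np.setdiff1d(all_markers, qidx)
                xq_all = np.ascontiguousarray(dosage_t[qidx].T)
                if len(keep_idx) < len(qidx):  # rebuilding beats downdating
                    xc_all = np.ascontiguousarray(dosage_t[keep_idx].T)
            for dname, design in design_list:
                splits = splits_cache[dname]
                ref = splits.reference_idx
                x_ref = _breed_design_matrix(panel.breeds[ref])
                val_breeds = [
                    vb
                    for vb in splits.validation_idx
                    if validation_scope == "all"
                    or (validation_scope == "own")
                    == (vb in design.reference_breeds)
                ]
                if not val_breeds:
                    continue
                val_all = np.concatenate(
                    [splits.validation_idx[b] for b in val_breeds]
                )
                bounds = np.cumsum(
                    [0] + [len(splits.validation_idx[b]) for b in val_breeds]
                )
                rows = np.concatenate([ref, val_all])
                if exclude_qtl_from_grm:
                    g_rr, g_vr = _grm_blocks_excluding(
                        grm, rows, len(ref), qtl.marker_indices, keep_idx,
                        xq_all, xc_all,
                    )
                else:
                    g_rr = grm.matrix[np.ix_(ref, ref)].astype(np.float64)
                    g_vr = grm.matrix[np.ix_(val_all, ref)].astype(np.float64)
                for h2 in strategies[strat]:
                    lam = (1.0 - h2) / h2
                    trait = traits[h2]
                    try:
                        solver = GBLUPSolver(g_rr, x_ref, lam, ridge=ridge)
                        _, gebv_val = solver.predict(trait.phenotype[ref], g_vr)
                    except Exception as exc:  # record and continue
                        for vb in val_breeds:
                            records.append(
                                _record(dname, design, strat, h2, rep, vb, 0,
                                        np.nan, f"solver: {exc}")
                            )
                        continue
                    for k, vb in enumerate(val_breeds):
                        vidx = splits.validation_idx[vb]
                        acc = accuracy(
                            gebv_val[bounds[k] : bounds[k + 1]], trait.tbv[vidx]
                        )
                        records.append(
                            _record(dname, design, strat, h2, rep, vb, len(vidx),
                                    acc, "ok")
                        )
    return pd.DataFrame.from_records(records)


def _record(dname, design, strat, h2, rep, val_breed, n_val, acc, status) -> dict:
    return {
        "design": dname,
        "reference_breeds": "+".join(design.reference_breeds),
        "strategy": strat,
        "h2": h2,
        "replicate": rep,
        "validation_breed": val_breed,
        "in_reference": val_breed in design.reference_breeds,
        "n_val": n_val,
        "accuracy": acc,
        "status": status,
    }


def summarize(
    records: pd.DataFrame, by: list[str] | None = None
) -> pd.DataFrame:
    """Mean and sd of accuracy over replicates (and anything not in ``by``)."""
    by = by or ["design", "strategy", "h2", "in_reference"]
    out = (
        records.groupby(by, dropna=False)["accuracy"]
        .agg(["mean", "std", "count"])
        .reset_index()
        .rename(columns={"mean": "accuracy_mean", "std": "accuracy_sd"})
    )
    return out
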