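"""Genotype quality control: call-rate, MAF and Hardy-Weinberg filters.

Filters mirror standard PLINK practice and are applied in a fixed, recorded
order: samples by call rate first, then SNPs by call rate, minor-allele
frequency and HWE.  The HWE test defaults to the 1-df chi-square
goodness-of-fit; an exact (mid-p) variant is available for small samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .panel import GenotypePanel

__all__ = ["QCThresholds", "QCReport", "QCError", "hwe_test", "qc_filter"]


@dataclass
class QCThresholds:
    sample_call_rate_min: float = 0.90
    snp_call_rate_min: float = 0.90
    maf_min: float = 0.01
    hwe_p_min: float = 1.0e-6
    autosomes_only: bool = True
    hwe_method: str = "chisq"  # or "midp" exact
    hwe_per_breed: bool = False

    def __post_init__(self) -> None:
        for v, label in [
            (self.sample_call_rate_min, "sample_call_rate_min"),
            (self.snp_call_rate_min, "snp_call_rate_min"),
            (self.maf_min, "maf_min"),
            (self.hwe_p_min, "hwe_p_min"),
        ]:
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{label}={v} outside [0, 1]")
        if self.hwe_method not in ("chisq", "midp"):
            raise ValueError("hwe_method must be 'chisq' or 'midp'")


@dataclass
class QCReport:
    """Removal counts per rule, in order of application."""

    n_samples_in: int
    n_snps_in: int
    samples_removed_call_rate: list = field(default_factory=list)
    snps_removed_call_rate: int = 0
    snps_removed_maf: int = 0
    snps_removed_hwe: int = 0
    order: tuple = ("sample_call_rate", "snp_call_rate", "maf", "hwe")

    @property
    def n_samples_out(self) -> int:
        return self.n_samples_in - len(self.samples_removed_call_rate)

    @property
    def n_snps_out(self) -> int:
        return (
            self.n_snps_in
            - self.snps_removed_call_rate
            - self.snps_removed_maf
            - self.snps_removed_hwe
        )


class QCError(RuntimeError):
    def __init__(self, message: str, report: QCReport):
        super().__init__(message)
        self.report = report


def _hwe_exact_midp(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact HWE test (mid-p) by enumeration of heterozygote counts."""
    n = n_aa + n_ab + n_bb
    n_b = 2 * n_bb + n_ab  # rarer-allele count after orientation below
    n_a = 2 * n_aa + n_ab
    if n_b > n_a:
        n_a, n_b = n_b, n_a
    het_values = np.arange(n_b % 2, n_b + 1, 2)
    # log P(het = h | n, n_b) up to a constant, via log-factorials
    n_hom_rare = (n_b - het_values) // 2
    n_hom_common = n - het_values - n_hom_rare
    logp = (
        het_values * np.log(2.0)
        - gammaln(n_hom_rare + 1)
        - gammaln(het_values + 1)
        - gammaln(n_hom_common + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[np.flatnonzero(het_values == n_ab)[0]]
    p = probs[probs <= p_obs + 1e-12].sum() - 0.5 * p_obs
    return float(min(1.0, max(p, 0.0)))


def hwe_test(counts, method: str = "chisq") -> float:
    """Hardy-Weinberg p-value from a genotype-count triple (n_AA, n_Aa, n_aa).

    The default is the 1-df chi-square goodness-of-fit against expectations
    at the observed allele frequency; ``method='midp'`` gives the exact
    mid-p test.  Monomorphic SNPs return p = 1 by convention.
    """
    n_aa, n_ab, n_bb = (int(c) for c in counts)
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("negative genotype count")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("empty genotype counts")
    p = (2 * n_aa + n_ab) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    if method == "midp":
        return _hwe_exact_midp(n_aa, n_ab, n_bb)
    q = 1.0 - p
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def _genotype_counts(dosage: np.ndarray, called: np.ndarray) -> np.ndarray:
    """Per-SNP (n_AA, n_Aa, n_aa) counts; dosage counts the alternate allele."""
    counts = np.empty((dosage.shape[1], 3), dtype=np.int64)
    for g in (0, 1, 2):
        counts[:, g] = ((dosage == g) & called).sum(axis=0)
    return counts


def qc_filter(
    panel: GenotypePanel, thresholds: QCThresholds | None = None
) -> tuple[GenotypePanel, QCReport]:
    """Apply sample and SNP filters; returns the filtered panel and a report.

    Raises :class:`QCError` (report attached) if every sample or every SNP
    is removed.
    """
    thresholds = thresholds or QCThresholds()
    if panel.n_individuals == 0 or panel.n_markers == 0:
        raise ValueError("empty panel")
    report = QCReport(n_samples_in=panel.n_individuals, n_snps_in=panel.n_markers)

    missing = (
        panel.missing
        if panel.missing is not None
        else np.zeros((panel.n_individuals, panel.n_markers), dtype=bool)
    )
    sample_cr = 1.0 - missing.mean(axis=1)
    keep_samples = sample_cr >= thresholds.sample_call_rate_min
    report.samples_removed_call_rate = list(panel.ids[~keep_samples])
    if not keep_samples.any():
        raise QCError("all samples removed by call-rate filter", report)
    panel = panel.subset_individuals(np.flatnonzero(keep_samples))
    missing = missing[keep_samples]

    called = ~missing
    snp_cr = called.mean(axis=0)
    keep = snp_cr >= thresholds.snp_call_rate_min
    report.snps_removed_call_rate = int((~keep).sum())

    dosage = panel.dosage(np.int8)
    counts = _genotype_counts(dosage, called)
    n_called = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = (2 * counts[:, 2] + counts[:, 1]) / (2 * n_called)
    maf = np.minimum(freq, 1.0 - freq)
    fail_maf = keep & ~(maf >= thresholds.maf_min)
    report.snps_removed_maf = int(fail_maf.sum())
    keep &= ~fail_maf

    fail_hwe = np.zeros(panel.n_markers, dtype=bool)
    candidates = np.flatnonzero(keep)
    if thresholds.hwe_per_breed:
        for breed in panel.breed_names:
            rows = panel.breeds == breed
            bc = _genotype_counts(dosage[rows], called[rows])
            for j in candidates:
                if not fail_hwe[j] and bc[j].sum() > 0:
                    if hwe_test(bc[j], thresholds.hwe_method) < thresholds.hwe_p_min:
                        fail_hwe[j] = True
    else:
        for j in candidates:
            if hwe_test(counts[j], thresholds.hwe_method) < thresholds.hwe_p_min:
                fail_hwe[j] = True
    report.snps_removed_hwe = int(fail_hwe.sum())
    keep &= ~fail_hwe

    if not keep.any():
        raise QCError("all SNPs removed by QC", report)
    out = panel.subset_markers(np.flatnonzero(keep))
    if out.missing is not None and not out.missing.any():
        out.missing = None
    return out, report
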