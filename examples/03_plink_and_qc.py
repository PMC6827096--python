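"""Round-trip a panel through text PLINK files and run quality control.

The QC mirrors standard practice for SNP-chip data: samples by call rate
first, then SNPs by call rate, minor-allele frequency >= 0.01 and a
Hardy-Weinberg test at p >= 1e-6.
"""

import tempfile
from pathlib import Path

import numpy as np

import mbgp

config = mbgp.FounderConfig(
    founders_per_breed={"B1": 30, "B2": 30},
    group_assignment={"B1": "g1", "B2": "g2"},
    n_markers=800,
    n_chromosomes=2,
    seed=5,
)
panel = mbgp.generate_founders(config)

# knock out some genotype calls to exercise the call-rate filters
rng = np.random.default_rng(0)
missing = rng.random((panel.n_individuals, panel.n_markers)) < 0.02
missing[0, : panel.n_markers // 2] = True  # one badly genotyped sample
panel = mbgp.GenotypePanel(panel.markers, panel.haplotypes, panel.ids,
                           panel.breeds, missing)

with tempfile.TemporaryDirectory() as tmp:
    prefix = Path(tmp) / "cohort"
    mbgp.write_plink(panel, prefix)
    print("wrote", [p.name for p in sorted(Path(tmp).iterdir())])
    back = mbgp.read_plink(prefix)

assert np.array_equal(back.dosage()[~back.missing], panel.dosage()[~missing])
print(f"round trip ok: {back.n_individuals} individuals, "
      f"{back.n_markers} markers, breeds {sorted(set(back.breeds))}")

filtered, report = mbgp.qc_filter(back, mbgp.QCThresholds())
print(f"QC: {report.n_samples_in} -> {report.n_samples_out} samples "
      f"(removed {report.samples_removed_call_rate})")
print(f"    {report.n_snps_in} -> {report.n_snps_out} SNPs "
      f"(call rate {report.snps_removed_call_rate}, "
      f"MAF {report.snps_removed_maf}, HWE {report.snps_removed_hwe})")
print("filters applied in order:", " -> ".join(report.order))
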