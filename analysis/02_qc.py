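"""Quality-control the simulated genotypes and extract the common SNP panel.

Applies the standard filter chain to founders and offspring separately —
duplicates, >10% individual missingness, >10% SNP missingness, Hardy-Weinberg
exact-test p < 1e-6, MAF < 0.005 — then intersects the two panels on marker
id and allele pair (dosage-flipping swapped alleles), mirroring how separate
parent/offspring genotyping arrays are reconciled before analysis.
"""

from pathlib import Path

from smoltgxe import intersect_panels, qc_panel, read_panel

IN = Path("results/simulation")
OUT = Path("results/qc")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    founders = read_panel(str(IN / "founders"))
    offspring = read_panel(str(IN / "offspring"))
    f_qc, f_rep = qc_panel(founders)
    o_qc, o_rep = qc_panel(offspring)
    f_rep.to_tsv(OUT / "qc_founders.tsv")
    o_rep.to_tsv(OUT / "qc_offspring.tsv")
    f_common, o_common = intersect_panels(f_qc, o_qc)
    f_common.write(str(OUT / "founders_qc"), "bed")
    o_common.write(str(OUT / "offspring_qc"), "bed")
    print(f"founders: {f_rep.n_markers_before} -> {f_rep.n_markers_after} SNPs; "
          f"offspring: {o_rep.n_markers_before} -> {o_rep.n_markers_after} SNPs")
    print(f"common panel used downstream: {o_common.n_markers} SNPs "
          f"({o_common.n_individuals} offspring, {f_common.n_individuals} parents)")


if __name__ == "__main__":
    main()
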