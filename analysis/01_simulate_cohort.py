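#!/usr/bin/env python
"""Generate the synthetic immunoprofiling cohort and write its tables.

Produces, under results/cohort/: genotypes (VCF + dosage TSV), paired
resting/stimulated expression, covariates, phenotypes (abundance, DI,
PI), and the ground-truth tables (planted eQTLs, signature genes).
"""

import argparse
from pathlib import Path

from temqtl import io
from temqtl.synth import SimCohortConfig, simulate_cohort


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/cohort"))
    args = ap.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    cfg = SimCohortConfig(seed=args.seed)
    co = simulate_cohort(cfg)

    io.write_vcf(co.genotypes, out / "genotypes.vcf")
    io.write_dosage_tsv(co.genotypes, out / "dosages.tsv", out / "snps.tsv")
    io.write_expression_tsv(co.expr_rest, out / "expression_rest.tsv")
    io.write_expression_tsv(co.expr_stim, out / "expression_stim.tsv")
    io.write_table(co.covariates, out / "covariates.tsv")
    io.write_table(co.phenotypes, out / "phenotypes.tsv")
    io.write_table(co.truth.eqtl_map, out / "truth_eqtl.tsv")
    io.write_table(co.truth.gene_annotation, out / "gene_annotation.tsv")
    io.write_table(co.truth.signature_genes, out / "truth_signature.tsv")

    ph = co.phenotypes
    print(f"cohort: {cfg.n_individuals} individuals, {cfg.n_snps} SNPs, "
          f"{cfg.n_genes} genes (seed {args.seed})")
    print(f"abundance {ph['abundance'].mean():.2f}% (SD {ph['abundance'].std():.2f}), "
          f"DI {ph['di'].mean():.2f} (SD {ph['di'].std():.2f}), "
          f"PI {ph['pi'].mean():.2f} (SD {ph['pi'].std():.2f})")
    print(f"planted eQTL genes: {len(co.truth.eqtl_map)}; "
          f"signature genes: {len(co.truth.signature_genes)}")
    print(f"tables written to {out}/")


if __name__ == "__main__":
    main()
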