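#!/usr/bin/env python
"""Quantify T_EM abundance and proliferation from simulated cytometry.

For a handful of synthetic samples: gate (CD45RA, CD45RO, CD62L) events
with the template-guided 7-component mixture and report T_EM abundance;
fit the CFSE division-peak mixture per stimulated well and report DI/PI.
Writes results/flow_cfse.tsv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from temqtl.cfse import fit_cfse_mixture, fit_resting_peak, proliferation_metrics
from temqtl.flow import fit_population_model, quantify_tem_abundance
from temqtl.synth import (
    SimCohortConfig,
    default_population_template,
    division_weights_from_di,
    simulate_cfse_experiment,
    simulate_cohort,
    simulate_flow_sample,
)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-samples", type=int, default=8)
    ap.add_argument("--n-events", type=int, default=20_000)
    ap.add_argument("--out", type=Path, default=Path("results/flow_cfse.tsv"))
    args = ap.parse_args()

    cfg = SimCohortConfig(seed=args.seed)
    co = simulate_cohort(cfg)
    template = default_population_template()
    rows = []
    for i, (ind, ph) in enumerate(co.phenotypes.head(args.n_samples).iterrows()):
        # flow: template weights with this individual's true T_EM share
        w = template.weights.copy()
        live = 1 - w[template.debris_index]
        tem_target = ph["abundance"] / 100 * live
        w[template.tem_index] = tem_target
        others = [k for k in range(7)
                  if k not in (template.tem_index, template.debris_index)]
        w[others] *= (live - tem_target) / w[others].sum()
        fs = simulate_flow_sample(template, w, args.n_events,
                                  seed=args.seed * 1000 + i)
        fit = fit_population_model(fs, template)
        abundance = quantify_tem_abundance(fit)

        # CFSE wells consistent with this individual's DI and PI
        weights = division_weights_from_di(ph["di"])
        ws = simulate_cfse_experiment(weights, cfg, n_events=10_000,
                                      seed=args.seed * 2000 + i)
        mu0, s0 = fit_resting_peak(ws.resting)
        di, pi, conv = [], [], True
        for well in ws.stimulated:
            mfit = fit_cfse_mixture(well, mu0, s0, seed=i)
            m = proliferation_metrics(mfit)
            di.append(m.di)
            pi.append(m.pi if m.pi is not None else np.nan)
            conv &= mfit.converged
        rows.append({
            "sample_id": ind,
            "abundance_true_pct": ph["abundance"],
            "abundance_pct": abundance,
            "di_true": ph["di"],
            "di": float(np.mean(di)),
            "pi": float(np.nanmean(pi)),
            "converged": conv,
        })
    tab = pd.DataFrame(rows).set_index("sample_id")
    args.out.parent.mkdir(parents=True, exist_ok=True)
    tab.to_csv(args.out, sep="\t", float_format="%.4f")
    err = (tab["abundance_pct"] - tab["abundance_true_pct"]).abs()
    derr = (tab["di"] - tab["di_true"]).abs()
    print(tab.round(3).to_string())
    print(f"\nabundance recovered within {err.max():.2f} pp (max over "
          f"{len(tab)} samples); DI within {derr.max():.3f}")
    print(f"written to {args.out}")


if __name__ == "__main__":
    main()
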