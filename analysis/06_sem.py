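#!/usr/bin/env python
"""Piecewise SEM: does functional or structural diversity mediate richness?

Restricts to experiments with concurrent height data, standardizes within
the SEM subset, fits the three model variants (no interaction, richness x
structural, FDis x structural) and both structural metrics (Gini vs CV),
and reports standardized paths, indirect effects, Fisher's C and AIC.
"""

from pathlib import Path

import pandas as pd

from overyield import inventory as inv
from overyield.sem import SemSpec, fit_piecewise
from overyield.standardize import apply_scaling

DATA = Path("results/data")
OUT = Path("results")


def main():
    met = pd.read_csv(OUT / "metrics.csv")
    plots = inv.read_plots(DATA / "plots.csv").set_index("plot_id")
    interval = met["plot_id"].map(plots["height_diam_interval_yr"])
    sem_data = met[(interval <= 1.0)].dropna(subset=["structural", "fdis_all"])
    print(f"SEM subset: {sem_data['experiment'].nunique()} experiments, "
          f"{len(sem_data)} plots")

    rows = []
    for metric in ("gini", "cv"):
        base = sem_data.copy()
        base["structural"] = base["gini_height"] if metric == "gini" else base["cv_height"]
        sub = apply_scaling(base)
        for interaction in ("none", "richness:structural", "fdis:structural"):
            res = fit_piecewise(SemSpec(interaction=interaction), sub)
            rows.append(dict(structural=metric, interaction=interaction,
                             aic=res.aic, c=res.c_stat, p=res.pvalue))
            if metric == "gini" and interaction == "richness:structural":
                main_res = res
                res.paths.to_csv(OUT / "sem_paths.csv", index=False)
                (OUT / "sem_report.txt").write_text(res.report() + "\n")
                print(res.report())

    if main_res.pvalue < 0.05:
        print("\nnote: the d-separation test rejects the three-node DAG on this "
              "generator, and should - height inequality here truly depends on "
              "trait dispersion given richness (diverse growth rates spread "
              "heights), a path the DAG omits.")

    comp = pd.DataFrame(rows)
    comp.to_csv(OUT / "sem_model_comparison.csv", index=False)
    best = comp.loc[comp["aic"].idxmin()]
    print(f"\nAIC comparison across variants (results/sem_model_comparison.csv); "
          f"best: {best['structural']} / {best['interaction']} (AIC {best['aic']:.1f})")
    print("wrote results/sem_paths.csv, results/sem_report.txt")


if __name__ == "__main__":
    main()
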