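"""Association statistics over the classified synthetic strain collection.

Reproduces the analysis battery on the synthetic strains: genome-level
metric comparisons between S and HU strains (Welch's t on apparent ploidy,
total chromosomes, aneuploid chromosomes/megabases), normalized
density-profile tables per CIN class, the 120-pair chromosome-imbalance
hypergeometric scan under both groupings, and the MAD2:MAD1-style 2x2
Fisher test on its published strain counts (18/0 vs 26/11).
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from karyocin.io import read_karyotype_table
from karyocin.chromosomes import CHROMOSOMES
from karyocin.karyotype import Karyotype, aneuploidy_metrics
from karyocin.stats import (
    StrainRecord,
    density_profile,
    fisher_exact,
    pairwise_imbalance_scan,
    welch_t,
)

parser = argparse.ArgumentParser()
parser.add_argument("--study", type=Path, default=Path("results/synthetic_study"))
parser.add_argument("--classification", type=Path,
                    default=Path("results/classification/cin_classification.tsv"))
parser.add_argument("--out", type=Path, default=Path("results/associations"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

classes = pd.read_csv(args.classification, sep="\t")
classes = classes[(classes["verdict"] == "ok")
                  & classes["cin_class"].isin(["S", "MU", "HU"])]

records, metric_rows = [], []
for _, row in classes.iterrows():
    table = read_karyotype_table(args.study / row["strain_id"] / "karyotypes.tsv")
    pop = table[table["role"] == "population"].iloc[0]
    karyo = Karyotype.from_iterable(int(pop[c]) for c in CHROMOSOMES)
    records.append(StrainRecord(row["strain_id"], karyo, row["cin_class"]))
    m = aneuploidy_metrics(karyo)
    metric_rows.append({
        "strain_id": row["strain_id"], "cin_class": row["cin_class"],
        "apparent_ploidy": m.apparent_ploidy, "basal_ploidy": m.basal_ploidy,
        "total_chromosomes": m.total_chromosomes, "total_mb": m.total_mb,
        "n_aneuploid": m.n_aneuploid_chromosomes, "mb_aneuploid": m.mb_aneuploid,
    })
metrics = pd.DataFrame(metric_rows)
metrics.to_csv(args.out / "strain_metrics.tsv", sep="\t", index=False)

print(f"{len(records)} classified strains "
      f"({(metrics['cin_class'] == 'S').sum()} S, "
      f"{(metrics['cin_class'] == 'MU').sum()} MU, "
      f"{(metrics['cin_class'] == 'HU').sum()} HU)")

# S vs HU comparisons of genome-level metrics
tests = []
for metric in ("apparent_ploidy", "total_chromosomes", "total_mb",
               "n_aneuploid", "mb_aneuploid"):
    s_vals = metrics.loc[metrics["cin_class"] == "S", metric].dropna()
    hu_vals = metrics.loc[metrics["cin_class"] == "HU", metric].dropna()
    if len(s_vals) < 2 or len(hu_vals) < 2:
        continue
    p = welch_t(s_vals, hu_vals)
    tests.append({"metric": metric, "mean_S": s_vals.mean(),
                  "mean_HU": hu_vals.mean(), "welch_p": p})
    print(f"S vs HU {metric}: means {s_vals.mean():.2f} vs {hu_vals.mean():.2f}, "
          f"Welch p = {p:.3g}")
pd.DataFrame(tests).to_csv(args.out / "s_vs_hu_welch.tsv", sep="\t", index=False)

# density-profile tables (peak-normalized, scaled by class share)
curves = []
for cls in ("S", "MU", "HU"):
    vals = metrics.loc[metrics["cin_class"] == cls, "apparent_ploidy"]
    if vals.empty:
        continue
    grid, curve = density_profile(vals, class_weight=len(vals) / len(metrics),
                                  grid=np.linspace(1.0, 2.0, 201))
    curves.append(pd.DataFrame({"cin_class": cls, "apparent_ploidy": grid,
                                "density": curve}))
pd.concat(curves).to_csv(args.out / "ploidy_density_profiles.tsv",
                         sep="\t", index=False)

# pairwise chromosome-imbalance scans
for grouping in ("hu-vs-rest", "s-vs-rest"):
    scan = pairwise_imbalance_scan(records, grouping=grouping)
    df = pd.DataFrame([{"chrom_a": a, "chrom_b": b, "p_value": p}
                       for (a, b), p in scan.items()])
    df.to_csv(args.out / f"imbalance_scan_{grouping}.tsv", sep="\t", index=False)
    top = df.nsmallest(1, "p_value").iloc[0]
    print(f"imbalance scan ({grouping}): strongest pair "
          f"{top['chrom_a']}-{top['chrom_b']} p = {top['p_value']:.3g}")

# MAD2:MAD1 ratio-class association, on its published strain counts
mad_table = [[18, 0], [26, 11]]
p_mad = fisher_exact(mad_table)
pd.DataFrame([{"unstable_ratio_half": 18, "stable_ratio_half": 0,
               "unstable_other": 26, "stable_other": 11,
               "fisher_p": p_mad}]).to_csv(
    args.out / "mad_ratio_fisher.tsv", sep="\t", index=False)
print(f"MAD2:MAD1 = 0.5 vs instability (18/0 vs 26/11): Fisher p = {p_mad:.4f}")
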