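"""Call karyotypes, reconstruct networks and classify CIN for every strain.

Reads the Ct and FACS tables written by 03_generate_study.py, re-derives an
integer karyotype per sample (qPCR stoichiometry + FACS apparent ploidy),
builds the parsimony karyotype network per strain, classifies each strain
S / MU / HU from the root-linked event count, and scores the classification
against the generator's ground truth.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from karyocin.calling import call_integer_karyotype
from karyocin.io import export_network, read_ct_table, read_facs_table
from karyocin.network import KaryotypeMatrix, build_network, classify_cin
from karyocin.synthetic import ratios_from_ct_table

parser = argparse.ArgumentParser()
parser.add_argument("--study", type=Path, default=Path("results/synthetic_study"))
parser.add_argument("--out", type=Path, default=Path("results/classification"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

truth = {t["strain_id"]: t
         for t in json.loads((args.study / "ground_truth.json").read_text())}

records = []
for strain_id, info in truth.items():
    sdir = args.study / strain_id
    ct = read_ct_table(sdir / "ct.tsv")
    facs = read_facs_table(sdir / "facs.tsv").set_index("sample_id")["g1_peak"]
    control = info["haploid_control_peak"]

    names = ["population"] + sorted(n for n in facs.index if n.startswith("colony"))
    calls = []
    for name in names:
        sample_ct = ct[ct["sample_id"].str.endswith(name.replace("population", "pop"))]
        ratios = ratios_from_ct_table(sample_ct)
        calls.append(call_integer_karyotype(ratios, facs[name] / control))
    if not all(c.ok for c in calls):
        records.append({"strain_id": strain_id, "verdict": "too_heterogeneous",
                        "true_rate": info["true_rate"]})
        continue

    matrix = KaryotypeMatrix(rows=tuple(c.karyotype.copies for c in calls),
                             root_row=0, sample_ids=tuple(names))
    networks = build_network(matrix)
    calls_cin, consensus = classify_cin(networks)
    export_network(networks[0], args.out / f"{strain_id}.gml")
    records.append({
        "strain_id": strain_id,
        "verdict": "ok",
        "true_rate": info["true_rate"],
        "true_root_events": info["true_root_events"],
        "n_root_events": calls_cin[0].n_root_events,
        "cin_class": consensus or "ambiguous",
        "n_cooptimal_networks": len(networks),
    })

df = pd.DataFrame(records)
df.to_csv(args.out / "cin_classification.tsv", sep="\t", index=False)

print(df.groupby(["true_rate", "cin_class"], dropna=False).size()
      .unstack(fill_value=0).to_string())

# accuracy is judged on the extreme rates; intermediate rates (1e-4, 5e-4)
# legitimately straddle the detection limit of 11 colonies at g25/g30
extreme = df[df["true_rate"].isin([0.0, 1e-3])]
ok = extreme[extreme["verdict"] == "ok"]
correct = ((ok["cin_class"] == "S") == (ok["true_rate"] == 0)).sum()
print(f"\nstable-vs-unstable recovery on extreme rates: {correct}/{len(extreme)} "
      f"= {correct / len(extreme):.1%} (rate 0 -> S; rate 1e-3 -> MU/HU)")
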