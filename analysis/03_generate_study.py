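"""Generate the synthetic strain collection that the later steps analyze.

Creates 60 strains: each seeded by a random triploid-meiosis spore, grown
under a per-strain mis-segregation rate drawn from {0, 1e-4, 5e-4, 1e-3},
and sampled as 11 colonies plus the population.  Writes, per strain, the
true karyotype matrix, the qPCR Ct table and the FACS peak table, plus a
ground-truth log (rates, seed karyotypes, root-linked event counts).
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from karyocin.io import write_karyotype_table, write_run_metadata
from karyocin.synthetic import SyntheticStudyConfig, generate_strain_collection

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--n-strains", type=int, default=60)
parser.add_argument("--cap", type=int, default=10_000)
parser.add_argument("--out", type=Path, default=Path("results/synthetic_study"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

config = SyntheticStudyConfig(
    n_strains=args.n_strains, population_cap=args.cap, rng_seed=args.seed
)
strains = generate_strain_collection(config)

truth = []
for strain in strains:
    sdir = args.out / strain.strain_id
    sdir.mkdir(exist_ok=True)
    karyos = [strain.population_modal_karyotype, *strain.colony_karyotypes]
    ids = ["population"] + [f"colony{j:02d}"
                            for j in range(1, len(strain.colony_karyotypes) + 1)]
    roles = ["population"] + ["colony"] * len(strain.colony_karyotypes)
    write_karyotype_table(sdir / "karyotypes.tsv", karyos, ids, roles)
    pd.concat(strain.ct_tables.values()).to_csv(sdir / "ct.tsv", sep="\t", index=False)
    pd.DataFrame({
        "sample_id": list(strain.facs_peaks),
        "g1_peak": list(strain.facs_peaks.values()),
    }).to_csv(sdir / "facs.tsv", sep="\t", index=False)
    truth.append({
        "strain_id": strain.strain_id,
        "true_rate": strain.true_rate,
        "generations": strain.generations,
        "true_root_events": strain.true_root_events,
        "seed_karyotype": str(strain.seed_karyotype),
        "haploid_control_peak": strain.haploid_control_peak,
    })

(args.out / "ground_truth.json").write_text(json.dumps(truth, indent=2) + "\n")
write_run_metadata(args.out / "run.json", command="03_generate_study",
                   seed=args.seed, n_strains=args.n_strains, cap=args.cap)
by_rate = pd.Series([t["true_rate"] for t in truth]).value_counts().sort_index()
print(f"wrote {len(strains)} strains to {args.out}")
print("strains per true rate:")
print(by_rate.to_string())
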