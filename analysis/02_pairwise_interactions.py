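"""Pairwise outcomes, relative yields, and the monoculture null model.

Classifies all 55 worm pairs as coexistence or exclusion, tests every pair
against the non-interacting null expectation (Welch test, BH-FDR), computes
bootstrap relative yields, and checks co-culture community sizes against the
larger monoculture.  Writes tidy tables to results/pairwise/.
"""

from pathlib import Path

import pandas as pd

from gutassembly import read_cfu_table, relative_yield
from gutassembly.composition import community_size_check, null_model_report
from gutassembly.data_model import Condition

SEED = 11
ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "pairwise"
OUT.mkdir(parents=True, exist_ok=True)

cfu = read_cfu_table(ROOT / "study" / "cfu_table.csv")

report = null_model_report(cfu, "worm", "AU37")
report.to_csv(OUT / "null_model.csv", index=False)
n = len(report)
n_coex = (report["category"] == "coexistence").sum()
n_sig = (report["p"] < 0.05).sum()
n_fdr = (report["p_fdr"] < 0.05).sum()
print(f"{n_coex}/{n} pairs coexist at the 2% threshold")
print(f"{n_sig}/{n} pairs deviate from the monoculture null at p<0.05 "
      f"({n_fdr} at FDR<0.05; {0.05 * n:.2f} expected by chance)")

# relative yields and community sizes
ry_rows, size_rows = [], []
for cond in cfu.conditions():
    if cond.n_species != 2 or cond.environment != "worm" or cond.host_strain != "AU37":
        continue
    wide = cfu.replicate_counts(cond)
    size_rows.append(community_size_check(cfu, cond))
    for focal, partner in (cond.fed_community, cond.fed_community[::-1]):
        mono = cfu.replicate_counts(
            Condition("worm", (focal,), "AU37")
        )[focal].to_numpy()
        ry = relative_yield(
            mono, wide[focal].to_numpy(), n_boot=10_000, seed=SEED,
            focal=focal, partner=partner,
        )
        ry_rows.append(
            {"focal": focal, "partner": partner,
             "log_ry": ry.log_ry_mean, "log_ry_sem": ry.log_ry_sem}
        )

ry_df = pd.DataFrame(ry_rows)
ry_df.to_csv(OUT / "relative_yields.csv", index=False)
sizes = pd.DataFrame(size_rows)
sizes.to_csv(OUT / "community_sizes.csv", index=False)

frac_harmed = (ry_df["log_ry"] < 0).mean()
frac_lower = (sizes["flag"] == "lower").mean()
print(f"{frac_harmed:.0%} of relative yields are below 1 (competitive harm)")
print(f"{frac_lower:.0%} of co-cultures reach lower totals than the larger monoculture")
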