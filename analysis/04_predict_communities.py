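"""Predict trio and 8-species compositions from monocultures and pairs.

Evaluates four predictors on every measured multispecies community —
uninformed 1/n, monoculture null, normalized arithmetic mean of pair
fractions without and with the assembly rule — against the replicate noise
floor, in the simplex metric for trios and L1 for the octet, and repeats
the error-ordering experiment over 50 fresh studies.
"""

from pathlib import Path

from gutassembly import evaluate_predictions, read_cfu_table
from gutassembly.studies import prediction_error_ordering

SEED = 11
ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "prediction"
OUT.mkdir(parents=True, exist_ok=True)

cfu = read_cfu_table(ROOT / "study" / "cfu_table.csv")

errs = evaluate_predictions(cfu, metric="simplex")
errs.to_csv(OUT / "errors_simplex.csv", index=False)
trios = errs[errs["n_species"] == 3]
print("trio mean simplex error by method (vs noise floor "
      f"{trios.drop_duplicates('community')['noise_floor'].mean():.1%}):")
for method, m in trios.groupby("method")["error"].mean().sort_values(ascending=False).items():
    print(f"  {method:18s} {m:.1%}")

octet = evaluate_predictions(
    cfu,
    communities=[c.fed_community for c in cfu.conditions()
                 if c.n_species == 8 and c.host_strain == "AU37"],
    metric="l1",
)
octet.to_csv(OUT / "errors_octet_l1.csv", index=False)
print("octet L1 error by method:")
for method, m in octet.groupby("method")["error"].mean().items():
    print(f"  {method:18s} {m:.1%}")

ordering = prediction_error_ordering(n_studies=50, seed=SEED)
ordering.to_csv(OUT / "error_ordering_50_studies.csv", index=False)
m = ordering.mean()
print(
    "50-study means: uninformed {:.1%} > monoculture {:.1%} > pairwise {:.1%} "
    ">= with rule {:.1%} ~ floor {:.1%}".format(
        m["uninformed"], m["monoculture_null"], m["pairwise"],
        m["pairwise_rule"], m["noise_floor"],
    )
)
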