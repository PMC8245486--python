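"""Worm gut vs liquid media: which pair outcomes does the host environment change?

Compares the 55 pair outcomes between the two environments pair by pair
(Welch tests, category shifts) and globally (competitive-ability
correlations), and checks how well media pairs predict worm trios.
"""

import json
from pathlib import Path

from gutassembly import compare_environments, evaluate_predictions, read_cfu_table
from gutassembly.composition import pairwise_outcomes

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "environment"
OUT.mkdir(parents=True, exist_ok=True)

cfu = read_cfu_table(ROOT / "study" / "cfu_table.csv")
oc_worm = pairwise_outcomes(cfu, "worm", "AU37")
oc_media = pairwise_outcomes(cfu, "media", None)
cmp = compare_environments(oc_worm, oc_media)
cmp.per_pair.to_csv(OUT / "per_pair.csv", index=False)

print(f"{cmp.n_significant}/{cmp.n_pairs} pairs differ significantly between environments")
print(f"shifts among significant pairs: {cmp.shift_counts}")
print(f"competitive-ability correlation across environments: "
      f"Spearman r = {cmp.ability_spearman[0]:.2f} (p = {cmp.ability_spearman[1]:.2g})")

# cross-environment prediction: worm trios from media pairs
errs = evaluate_predictions(
    cfu, pair_environment="media", pair_host_strain=None, metric="simplex",
    methods=("pairwise_rule",),
)
errs.to_csv(OUT / "worm_trios_from_media_pairs.csv", index=False)
trios = errs[errs["n_species"] == 3]
print(f"worm trios from media pairs (with rule): mean error {trios['error'].mean():.1%} "
      f"(noise floor {trios.drop_duplicates('community')['noise_floor'].mean():.1%})")

(OUT / "summary.json").write_text(json.dumps({
    "n_pairs": cmp.n_pairs,
    "n_significant": cmp.n_significant,
    "shift_counts": cmp.shift_counts,
    "ability_spearman": cmp.ability_spearman,
    "media_pair_trio_error": float(trios["error"].mean()),
}, indent=2))
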