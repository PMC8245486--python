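"""Phylogeny vs colonization traits: do related species colonize alike?

Builds a synthetic phylogeny (random binary tree), evolves log carrying
capacity along its branches by Brownian motion so that related species
colonize similarly, simulates monocultures and pairs, and Mantel-tests
patristic distances against trait dissimilarities (fold-difference in
monoculture colonization; normalized competitive-ability difference).
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from gutassembly import (
    build_competition_matrix,
    make_ground_truth,
    mantel_test,
    read_tree_distances,
    simulate_study,
    trait_dissimilarity,
)
from gutassembly.composition import competitive_abilities

SEED = 11
N = 12
BM_SIGMA = 0.8  # trait sd per unit branch length (log10 CFU scale)
ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "phylogeny"
OUT.mkdir(parents=True, exist_ok=True)
rng = np.random.default_rng(SEED)

# random binary topology as nested tuples ((child, branch_length), ...)
def random_tree(leaves):
    nodes = list(leaves)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b, a = nodes.pop(j), nodes.pop(i)
        la, lb = rng.uniform(0.05, 0.5, 2).round(4)
        nodes.append(((a, la), (b, lb)))
    return nodes[0]

def to_newick(node):
    if isinstance(node, str):
        return node
    return "(" + ",".join(f"{to_newick(ch)}:{ln}" for ch, ln in node) + ")"

def brownian(node, value, out):
    if isinstance(node, str):
        out[node] = value
        return
    for ch, ln in node:
        brownian(ch, value + rng.normal(0.0, BM_SIGMA * np.sqrt(ln)), out)

species = [f"sp{i:02d}" for i in range(N)]
tree = random_tree(species)
newick = to_newick(tree) + ";"
(OUT / "tree.nwk").write_text(newick + "\n")
dist = read_tree_distances(OUT / "tree.nwk", species_ids=species)

logk = {}
brownian(tree, 3.3, logk)
K = {s: float(10 ** np.clip(v, np.log10(2e2), np.log10(2e4))) for s, v in logk.items()}

gt = make_ground_truth(N, params={"K": K, "species_ids": species}, seed=SEED)
study = simulate_study(gt, design={"trios": None, "octet": None}, seed=SEED)

mono_means = {
    c.fed_community[0]: float(
        study.cfu_table.replicate_counts(c)[c.fed_community[0]].mean()
    )
    for c in study.cfu_table.conditions()
    if c.n_species == 1
}
M = build_competition_matrix(study.cfu_table)
ability = competitive_abilities(M)["ability"].to_dict()

D = pd.DataFrame(dist.d, index=species, columns=species)
results = {}
for name, trait, kind in [
    ("fold_difference_monoculture", mono_means, "fold_difference_log10"),
    ("normalized_ability_difference", ability, "normalized_difference"),
]:
    T = trait_dissimilarity(trait, kind).loc[species, species]
    stat, p = mantel_test(D, T, correlation="spearman", n_perm=10_000, seed=SEED)
    results[name] = {"spearman": stat, "p": p}
    print(f"patristic distance vs {name}: r_s = {stat:.2f}, p = {p:.3g} (Mantel)")

(OUT / "mantel.json").write_text(json.dumps(results, indent=2))
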